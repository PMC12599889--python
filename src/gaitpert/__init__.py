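"""Gait perturbation detection from wearable IMUs: synthetic cohort
generation, window extraction, DeepConvLSTM training, experimental matrix
and repeated-measures statistics."""

__version__ = "0.1.0"

from . import detector, synthgait, windowing

__all__ = [
    "synthgait",
    "windowing",
    "detector",
    "experiments",
    "statcompare",
    "interface",
    "__version__",
]


def __getattr__(name):
    # experiments/statcompare/interface import pandas & pingouin; keep the
    # base import light by loading them lazily
    if name in ("experiments", "statcompare", "interface"):
        import importlib

        return importlib.import_module(f".{name}", __name__)
    raise AttributeError(name)
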