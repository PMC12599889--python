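"""Synthetic multi-sensor IMU cohort generator.

Produces a virtual walking cohort: for every participant, one 60 s gait
trial plus three perturbation trials, recorded simultaneously at seven
wearing positions (lumbar, sternum, left/right ear, jacket pocket, pants
pocket, shoulder bag) by devices with position-specific sampling rates,
gains and noise.  Perturbations are injected as parameterized transients
from nine archetypes, scheduled pseudo-randomly with 20-30 s gaps, and
every injection is reported through treadmill-style interval markers.

All randomness flows through :func:`derive_seed`, a documented splitting
rule on top of ``numpy.random.SeedSequence``, so a cohort is byte-identical
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "POSITIONS",
    "TRIALS",
    "CHANNELS",
    "SensorSpec",
    "GaitProfile",
    "PerturbationArchetype",
    "ImuTrace",
    "PerturbationMarker",
    "CohortDataset",
    "DEFAULT_SENSOR_SPECS",
    "default_archetypes",
    "derive_seed",
    "generate_profile",
    "simulate_gait_trial",
    "simulate_perturbation_trial",
    "generate_cohort",
]

#: Canonical wearing positions (professional lumbar/sternum, hearing aids,
#: smartphone in jacket pocket / pants pocket / shoulder bag).
POSITIONS: Tuple[str, ...] = ("L", "S", "RHA", "LHA", "JP", "PP", "SB")

#: Trial identifiers: one gait trial and three perturbation trials.
TRIALS: Tuple[str, ...] = ("gait", "pert1", "pert2", "pert3")
PERT_TRIALS: Tuple[str, ...] = ("pert1", "pert2", "pert3")

#: Fixed channel order for all traces and windows.
CHANNELS: Tuple[str, ...] = ("ax", "ay", "az", "gx", "gy", "gz")

GRAVITY = 9.81  # m/s^2, optional constant on the device-vertical axis

#: Gyro white noise is scaled relative to accel noise (deg/s per m/s^2).
_GYRO_NOISE_SCALE = 5.0
#: Gyro transient peak relative to the accel transient peak (deg/s per m/s^2).
_GYRO_TRANSIENT_SCALE = 8.0


def derive_seed(*keys) -> int:
    """Deterministically derive a child seed from a tuple of keys.

    Strings are folded to stable integers first.  This is the single seed
    splitting rule used across the package.
    """
    ints = []
    for k in keys:
        if isinstance(k, str):
            ints.append(int.from_bytes(k.encode("utf8"), "little") % (2**31))
        else:
            ints.append(int(k))
    return int(np.random.SeedSequence(ints).generate_state(1)[0])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensorSpec:
    """Device characteristics for one wearing position.

    ``carry_noise_sd`` models slow orientation wobble of loosely carried
    devices (bags, pockets); it is zero for body-fixed sensors.
    """

    position_id: str
    nominal_rate: float
    rate_jitter_sd: float = 0.0
    gain: float = 1.0
    lowpass_cutoff: float = 20.0
    carry_noise_sd: float = 0.0
    noise_sd: float = 0.03  # white accel noise, m/s^2

    def __post_init__(self):
        if self.position_id not in POSITIONS:
            raise ValueError(f"unknown position_id {self.position_id!r}")
        if self.nominal_rate <= 0:
            raise ValueError("nominal_rate must be > 0")
        if self.rate_jitter_sd < 0:
            raise ValueError("rate_jitter_sd must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.carry_noise_sd < 0:
            raise ValueError("carry_noise_sd must be >= 0")


#: Default device fleet: professional sensors at 128 Hz, smartphones at
#: 100 Hz, hearing aids at 104 +/- 4 Hz (device-level rate tolerance).
#: Carry-noise severity ordering: SB > PP > JP > 0 = all body-fixed devices.
DEFAULT_SENSOR_SPECS: Dict[str, SensorSpec] = {
    "L": SensorSpec("L", 128.0),
    "S": SensorSpec("S", 128.0),
    "RHA": SensorSpec("RHA", 104.0, rate_jitter_sd=4.0),
    "LHA": SensorSpec("LHA", 104.0, rate_jitter_sd=4.0),
    "JP": SensorSpec("JP", 100.0, carry_noise_sd=0.15),
    "PP": SensorSpec("PP", 100.0, carry_noise_sd=0.35),
    "SB": SensorSpec("SB", 100.0, carry_noise_sd=0.60),
}


@dataclass(frozen=True)
class GaitProfile:
    """Per-participant gait parameters.

    ``harmonic_amps``/``gyro_amps`` are 3x3 nested tuples: per axis
    (x, y, z), the amplitudes of the first three harmonics of the step
    frequency.  The vertical (z) acceleration is dominated by the second
    harmonic (twice the step frequency).
    """

    participant_id: str
    cadence: float  # steps/s
    harmonic_amps: Tuple[Tuple[float, ...], ...]  # m/s^2
    gyro_amps: Tuple[Tuple[float, ...], ...]  # deg/s
    phase_jitter_sd: float  # radians / sqrt(s), random-walk intensity
    preferred_speed: float  # m/s

    def __post_init__(self):
        if self.cadence <= 0:
            raise ValueError("cadence must be > 0")
        for row in (*self.harmonic_amps, *self.gyro_amps):
            if any(a < 0 for a in row):
                raise ValueError("amplitudes must be >= 0")


#: Documented sampling ranges for :func:`generate_profile`.
PROFILE_RANGES = {
    "cadence": (1.4, 2.2),
    # accel harmonic amplitude ranges per axis, (low, high) per harmonic
    "accel": (
        ((0.5, 1.5), (0.2, 0.6), (0.05, 0.20)),  # ax (anteroposterior)
        ((0.4, 1.2), (0.2, 0.6), (0.05, 0.20)),  # ay (mediolateral)
        ((0.3, 0.8), (1.5, 3.0), (0.10, 0.40)),  # az (vertical, 2f dominant)
    ),
    "gyro": (
        ((10.0, 30.0), (4.0, 12.0), (1.0, 4.0)),
        ((8.0, 25.0), (4.0, 10.0), (1.0, 4.0)),
        ((5.0, 15.0), (2.0, 8.0), (0.5, 2.0)),
    ),
    "phase_jitter_sd": (0.02, 0.10),
    "preferred_speed": (0.8, 1.4),
}


@dataclass(frozen=True)
class PerturbationArchetype:
    """One of nine parameterized perturbation signatures.

    ``amplitude_ratio`` is the peak transient acceleration-norm magnitude
    divided by the participant's clean gait peak norm — the difficulty
    dial of the generator.  Every archetype affects at least one
    acceleration axis so that acceleration-norm anchoring is well defined.
    """

    archetype_id: int
    affected_axes: Tuple[str, ...]
    duration: float  # s
    amplitude_ratio: float
    shape: str  # burst | step_change | phase_break

    def __post_init__(self):
        if not 1 <= self.archetype_id <= 9:
            raise ValueError("archetype_id must be in 1..9")
        if not 0 < self.duration <= 2.0:
            raise ValueError("duration must be in (0, 2]")
        if self.amplitude_ratio <= 0:
            raise ValueError("amplitude_ratio must be > 0")
        if self.shape not in ("burst", "step_change", "phase_break"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not any(a in ("ax", "ay", "az") for a in self.affected_axes):
            raise ValueError("archetype must affect at least one accel axis")


def default_archetypes(amplitude_ratio: float = 4.0) -> List[PerturbationArchetype]:
    """The nine default archetypes: 3 shapes x 3 axis groups.

    Axis groups: pure acceleration, mixed accel+gyro, all six channels.
    """
    groups = [
        ("ax", "ay", "az"),
        ("az", "gx", "gy"),
        ("ax", "ay", "az", "gx", "gy", "gz"),
    ]
    shapes = [("burst", 0.8), ("step_change", 1.2), ("phase_break", 1.6)]
    out = []
    aid = 1
    for axes in groups:
        for shape, dur in shapes:
            out.append(
                PerturbationArchetype(aid, axes, dur, amplitude_ratio, shape)
            )
            aid += 1
    return out


@dataclass
class ImuTrace:
    """One device's 6-channel recording of one trial at one position."""

    participant_id: str
    position_id: str
    trial_id: str
    timestamps: np.ndarray  # (N,) s, strictly increasing
    accel: np.ndarray  # (3, N) m/s^2
    gyro: np.ndarray  # (3, N) deg/s
    nominal_rate: float

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        n = self.timestamps.shape[0]
        if self.accel.shape != (3, n) or self.gyro.shape != (3, n):
            raise ValueError("accel/gyro must be (3, N) matching timestamps")
        if n >= 2 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def channels(self) -> np.ndarray:
        """(6, N) array in the fixed (ax, ay, az, gx, gy, gz) order."""
        return np.vstack([self.accel, self.gyro])


@dataclass(frozen=True)
class PerturbationMarker:
    """Treadmill-declared perturbation interval.

    By construction the injected transient peak lies at the interval
    midpoint ``(t_start + t_end) / 2``.
    """

    trial_id: str
    archetype_id: int
    t_start: float
    t_end: float

    def __post_init__(self):
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")

    @property
    def center(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass
class CohortDataset:
    """Full virtual cohort: profiles, traces and markers.

    ``traces`` is keyed by ``(participant_id, position_id, trial_id)`` and
    ``markers`` by ``(participant_id, trial_id)``; the marker schedule of a
    perturbation trial is shared by all seven positions (one physical
    treadmill event stream).
    """

    participants: List[GaitProfile]
    traces: Dict[Tuple[str, str, str], ImuTrace]
    markers: Dict[Tuple[str, str], List[PerturbationMarker]]
    seed: int
    amplitude_ratio: float = 4.0

    @property
    def participant_ids(self) -> List[str]:
        return [p.participant_id for p in self.participants]

    def validate(self) -> None:
        """Check the protocol invariants (trial/marker counts)."""
        for p in self.participants:
            for pos in POSITIONS:
                for trial in TRIALS:
                    if (p.participant_id, pos, trial) not in self.traces:
                        raise ValueError(
                            f"missing trace {(p.participant_id, pos, trial)}"
                        )
            for trial in PERT_TRIALS:
                mk = self.markers.get((p.participant_id, trial), [])
                if len(mk) != 9:
                    raise ValueError(
                        f"{p.participant_id}/{trial}: expected 9 markers, "
                        f"got {len(mk)}"
                    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_profile(cohort_seed: int, participant_index: int) -> GaitProfile:
    """Draw one participant's gait profile, reproducible from the seeds.

    Cadence is uniform on [1.4, 2.2] steps/s; harmonic amplitudes come
    from the per-axis ranges in :data:`PROFILE_RANGES`.
    """
    if participant_index < 0:
        raise ValueError("participant_index must be >= 0")
    rng = np.random.default_rng(derive_seed(cohort_seed, "profile", participant_index))
    cadence = rng.uniform(*PROFILE_RANGES["cadence"])

    def draw(ranges):
        return tuple(
            tuple(float(rng.uniform(lo, hi)) for lo, hi in row) for row in ranges
        )

    return GaitProfile(
        participant_id=f"P{participant_index:03d}",
        cadence=float(cadence),
        harmonic_amps=draw(PROFILE_RANGES["accel"]),
        gyro_amps=draw(PROFILE_RANGES["gyro"]),
        phase_jitter_sd=float(rng.uniform(*PROFILE_RANGES["phase_jitter_sd"])),
        preferred_speed=float(rng.uniform(*PROFILE_RANGES["preferred_speed"])),
    )


def _realized_rate(spec: SensorSpec, rng: np.random.Generator) -> float:
    """One per-trace rate draw, truncated away from zero."""
    if spec.rate_jitter_sd == 0:
        return spec.nominal_rate
    rate = rng.normal(spec.nominal_rate, spec.rate_jitter_sd)
    return float(max(rate, 0.5 * spec.nominal_rate))


def _harmonic_signal(
    amps: Sequence[Sequence[float]],
    cadence: float,
    t: np.ndarray,
    phases: np.ndarray,
    phase_drift: np.ndarray,
) -> np.ndarray:
    """(3, N) sum of the first three step-frequency harmonics per axis."""
    sig = np.zeros((3, t.shape[0]))
    for i, row in enumerate(amps):
        for h, amp in enumerate(row, start=1):
            if amp == 0:
                continue
            sig[i] += amp * np.sin(
                2 * np.pi * h * cadence * t + phases[i, h - 1] + h * phase_drift
            )
    return sig


def _carry_noise(
    n: int, rate: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Slow orientation-wobble noise: smoothed white noise rescaled to sd."""
    if sd == 0 or n == 0:
        return np.zeros((3, n))
    raw = rng.standard_normal((3, n))
    smooth = gaussian_filter1d(raw, sigma=0.5 * rate, axis=1, mode="nearest")
    s = smooth.std(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return sd * smooth / s

def _lowpass(x: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    if cutoff >= 0.49 * rate:
        return x
    sos = butter(4, cutoff, btype="low", fs=rate, output="sos")
    return sosfiltfilt(sos, x, axis=-1)


def _synthesize(
    profile: GaitProfile,
    spec: SensorSpec,
    duration: float,
    rng: np.random.Generator,
    include_gravity: bool = False,
):
    """Common gait carrier for both trial kinds.

    Returns (timestamps, accel, gyro, phase arrays) before perturbation
    injection and before low-pass filtering.
    """
    rate = _realized_rate(spec, rng)
    # inclusive endpoint: the trace covers [0, duration] so downstream
    # resampling at any rate <= the native one keeps full window counts
    n = int(round(duration * rate)) + 1
    t = np.arange(n) / rate
    phases_a = rng.uniform(0, 2 * np.pi, size=(3, 3))
    phases_g = rng.uniform(0, 2 * np.pi, size=(3, 3))
    # random-walk phase drift shared by accel and gyro (one body)
    drift = np.cumsum(rng.normal(0.0, profile.phase_jitter_sd / np.sqrt(rate), n))
    accel = spec.gain * _harmonic_signal(
        profile.harmonic_amps, profile.cadence, t, phases_a, drift
    )
    gyro = spec.gain * _harmonic_signal(
        profile.gyro_amps, profile.cadence, t, phases_g, drift
    )
    if include_gravity:
        accel[2] += GRAVITY
    return t, accel, gyro, rate


def _finalize(
    profile: GaitProfile,
    spec: SensorSpec,
    t: np.ndarray,
    accel: np.ndarray,
    gyro: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    trial_id: str,
) -> ImuTrace:
    """Low-pass filter, then add white noise and carry noise."""
    accel = _lowpass(accel, spec.lowpass_cutoff, rate)
    gyro = _lowpass(gyro, spec.lowpass_cutoff, rate)
    if spec.noise_sd > 0:
        accel = accel + rng.normal(0, spec.noise_sd, accel.shape)
        gyro = gyro + rng.normal(0, spec.noise_sd * _GYRO_NOISE_SCALE, gyro.shape)
    accel = accel + _carry_noise(t.shape[0], rate, spec.carry_noise_sd, rng)
    return ImuTrace(
        participant_id=profile.participant_id,
        position_id=spec.position_id,
        trial_id=trial_id,
        timestamps=t,
        accel=accel,
        gyro=gyro,
        nominal_rate=spec.nominal_rate,
    )


def simulate_gait_trial(
    profile: GaitProfile,
    spec: SensorSpec,
    duration: float = 60.0,
    seed: int = 0,
    include_gravity: bool = False,
) -> ImuTrace:
    """Simulate one unperturbed gait trial (default one minute)."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    t, accel, gyro, rate = _synthesize(profile, spec, duration, rng, include_gravity)
    return _finalize(profile, spec, t, accel, gyro, rate, rng, "gait")


def gait_peak_norm(profile: GaitProfile) -> float:
    """Clean-gait peak acceleration norm, the amplitude_ratio reference.

    Evaluated on a dense noise-free two-second grid (covers >= 2 cycles).
    """
    t = np.arange(0, 2.0, 1 / 500.0)
    phases = np.zeros((3, 3))
    sig = _harmonic_signal(profile.harmonic_amps, profile.cadence, t, phases, 0 * t)
    return float(np.max(np.linalg.norm(sig, axis=0)))


def _transient_envelope(shape: str, t: np.ndarray, tc: float, duration: float):
    """Unit-peak additive envelope with its unique maximum at ``tc``."""
    crest_sigma = 0.03  # sharp crest so the norm argmax is unambiguous
    if shape == "burst":
        sigma = duration / 20.0
        return np.exp(-0.5 * ((t - tc) / sigma) ** 2)
    if shape == "step_change":
        # smooth offset ramp up and back down (raised cosine bump) topped
        # by a sharp crest
        x = (t - tc) / (duration / 2.0)
        bump = np.where(np.abs(x) < 1, 0.5 * (1 + np.cos(np.pi * x)), 0.0)
        crest = np.exp(-0.5 * ((t - tc) / crest_sigma) ** 2)
        return (bump + crest) / 2.0
    if shape == "phase_break":
        # carrier suppression handled by the caller; additive part is a
        # short impulse at the break
        return np.exp(-0.5 * ((t - tc) / crest_sigma) ** 2)
    raise ValueError(f"unknown shape {shape!r}")


def _inject(
    accel: np.ndarray,
    gyro: np.ndarray,
    t: np.ndarray,
    marker: PerturbationMarker,
    arch: PerturbationArchetype,
    peak_ref: float,
) -> None:
    """Add one transient in place; its norm peak lands at the marker center.

    The clean gait carrier is attenuated around the peak (a momentary break
    of the gait pattern) so the injected crest is the local norm maximum.
    """
    tc = marker.center
    core = np.exp(-0.5 * ((t - tc) / 0.35) ** 2)
    atten = 1.0 - 0.98 * core
    accel *= atten
    gyro *= atten

    env = _transient_envelope(arch.shape, t, tc, arch.duration)
    acc_axes = [i for i, c in enumerate(("ax", "ay", "az")) if c in arch.affected_axes]
    gyr_axes = [i for i, c in enumerate(("gx", "gy", "gz")) if c in arch.affected_axes]
    target = arch.amplitude_ratio * peak_ref
    amp_per_axis = target / np.sqrt(len(acc_axes))
    for i in acc_axes:
        accel[i] += amp_per_axis * env
    if gyr_axes:
        g_amp = arch.amplitude_ratio * peak_ref * _GYRO_TRANSIENT_SCALE
        g_amp /= np.sqrt(len(gyr_axes))
        for i in gyr_axes:
            gyro[i] += g_amp * env


def schedule_markers(
    archetypes: Sequence[PerturbationArchetype],
    order_seed: int,
    trial_id: str = "pert1",
    gap_bounds: Tuple[float, float] = (20.0, 30.0),
) -> List[PerturbationMarker]:
    """Pseudo-random order and 20-30 s onset gaps for the nine archetypes.

    The trial opens with a lead-in gap drawn from the same distribution.
    Deterministic in ``order_seed`` and shared by all sensor positions.
    """
    if len(archetypes) != 9:
        raise ValueError(f"exactly 9 archetypes required, got {len(archetypes)}")
    rng = np.random.default_rng(order_seed)
    order = rng.permutation(len(archetypes))
    gaps = rng.uniform(*gap_bounds, size=len(archetypes))
    onsets = np.cumsum(gaps)
    markers = []
    for k, idx in enumerate(order):
        arch = archetypes[idx]
        markers.append(
            PerturbationMarker(
                trial_id=trial_id,
                archetype_id=arch.archetype_id,
                t_start=float(onsets[k]),
                t_end=float(onsets[k] + arch.duration),
            )
        )
    return markers


def simulate_perturbation_trial(
    profile: GaitProfile,
    spec: SensorSpec,
    archetypes: Sequence[PerturbationArchetype],
    order_seed: int,
    noise_seed: int | None = None,
    trial_id: str = "pert1",
    tail: float = 5.0,
    include_gravity: bool = False,
) -> Tuple[ImuTrace, List[PerturbationMarker]]:
    """Simulate one perturbation trial and its treadmill markers.

    The marker schedule depends only on ``order_seed`` (so all positions of
    one physical trial share it); sensor noise uses ``noise_seed``.
    """
    markers = schedule_markers(archetypes, order_seed, trial_id)
    by_id = {a.archetype_id: a for a in archetypes}
    duration = markers[-1].t_end + tail
    rng = np.random.default_rng(noise_seed if noise_seed is not None else order_seed)
    t, accel, gyro, rate = _synthesize(profile, spec, duration, rng, include_gravity)
    peak_ref = gait_peak_norm(profile) * spec.gain
    for mk in markers:
        _inject(accel, gyro, t, mk, by_id[mk.archetype_id], peak_ref)
    trace = _finalize(profile, spec, t, accel, gyro, rate, rng, trial_id)
    return trace, markers


def generate_cohort(
    n_participants: int,
    cohort_seed: int,
    amplitude_ratio: float = 4.0,
    gait_duration: float = 60.0,
    sensor_specs: Mapping[str, SensorSpec] | None = None,
    include_gravity: bool = False,
) -> CohortDataset:
    """Generate the full cohort: 7 positions x (1 gait + 3 pert) trials each.

    Fully reproducible from ``cohort_seed``; all child seeds derive from it
    via :func:`derive_seed`.
    """
    if n_participants < 3:
        raise ValueError("need at least 3 participants (train/val/test splits)")
    specs = dict(sensor_specs) if sensor_specs is not None else DEFAULT_SENSOR_SPECS
    archetypes = default_archetypes(amplitude_ratio)
    participants: List[GaitProfile] = []
    traces: Dict[Tuple[str, str, str], ImuTrace] = {}
    markers: Dict[Tuple[str, str], List[PerturbationMarker]] = {}

    for idx in range(n_participants):
        prof = generate_profile(cohort_seed, idx)
        participants.append(prof)
        pid = prof.participant_id
        for pos in POSITIONS:
            spec = specs[pos]
            traces[(pid, pos, "gait")] = simulate_gait_trial(
                prof,
                spec,
                gait_duration,
                seed=derive_seed(cohort_seed, idx, pos, "gait"),
                include_gravity=include_gravity,
            )
        for trial in PERT_TRIALS:
            order_seed = derive_seed(cohort_seed, idx, trial, "order")
            for pos in POSITIONS:
                trace, mk = simulate_perturbation_trial(
                    participants[idx],
                    specs[pos],
                    archetypes,
                    order_seed=order_seed,
                    noise_seed=derive_seed(cohort_seed, idx, trial, pos, "noise"),
                    trial_id=trial,
                    include_gravity=include_gravity,
                )
                traces[(pid, pos, trial)] = trace
            markers[(pid, trial)] = mk

    ds = CohortDataset(
        participants=participants,
        traces=traces,
        markers=markers,
        seed=cohort_seed,
        amplitude_ratio=amplitude_ratio,
    )
    ds.validate()
    return ds
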