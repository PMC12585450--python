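"""Synthetic running-gait generation.

Produces treadmill-running-like trials (sagittal hip/knee/ankle angles plus a
vertical ground reaction force channel) and directly coupled joint-pair cycles
with known ground-truth coordination, so the whole vector-coding pipeline can
be exercised and validated without motion-capture recordings.

The trial generator emulates a five-second run at roughly 23 km/h: smooth
periodic joint waveforms (truncated Fourier series per joint) sampled at the
kinematic rate, and a vertical GRF sampled at its own higher rate that exceeds
the 20 N contact threshold only inside the configured stance windows.
Stride-to-stride variation enters through multiplicative Gaussian noise on
stride duration and, optionally, von Mises jitter on the waveform phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "JointWaveform",
    "GaitSimConfig",
    "MocapTrial",
    "generate_trial",
    "generate_coupled_pair",
    "simulate_cohort",
    "CohortRecord",
    "DEFAULT_WAVEFORMS",
]


@dataclass(frozen=True)
class JointWaveform:
    """Truncated Fourier series describing one joint's angle over the cycle.

    ``harmonics`` is a sequence of ``(order, amplitude_deg, phase_rad)``
    terms; the angle at cycle phase ``phi`` (in strides, i.e. phase 1.0 is one
    full cycle) is ``offset + sum(A * sin(2*pi*k*phi + p))``.
    """

    offset_deg: float
    harmonics: tuple[tuple[int, float, float], ...]

    def evaluate(self, phi: np.ndarray, phase_jitter: np.ndarray | float = 0.0) -> np.ndarray:
        out = np.full_like(phi, self.offset_deg, dtype=float)
        for order, amp, phase in self.harmonics:
            out += amp * np.sin(2.0 * np.pi * order * phi + phase + phase_jitter)
        return out


#: Sagittal-plane waveforms loosely shaped like high-speed running:
#: large hip excursion, knee flexion peak in swing, modest ankle excursion.
DEFAULT_WAVEFORMS: dict[str, JointWaveform] = {
    "hip": JointWaveform(20.0, ((1, 35.0, 0.6), (2, 6.0, 1.0))),
    "knee": JointWaveform(60.0, ((1, 32.0, -1.2), (2, 22.0, 0.5))),
    "ankle": JointWaveform(0.0, ((1, 14.0, 2.1), (2, 9.0, -0.4))),
}


@dataclass(frozen=True)
class GaitSimConfig:
    """Configuration of a synthetic running trial.

    Defaults describe the study conditions the generator emulates: a
    five-second capture containing at least eight strides, kinematics at
    120 Hz, force at 1000 Hz, stance occupying 40% of each ~0.62 s stride,
    and a GRF peak far above the 20 N event threshold.
    """

    n_strides: int = 8
    kinematic_rate: float = 120.0
    grf_rate: float = 1000.0
    stride_duration_s: float = 0.62
    stride_duration_cv: float = 0.02
    stance_fraction: float = 0.40
    joint_waveforms: dict[str, JointWaveform] = field(
        default_factory=lambda: dict(DEFAULT_WAVEFORMS)
    )
    grf_peak_N: float = 2000.0
    coupling_noise_kappa: float = math.inf
    seed: int = 0

    def validate(self) -> None:
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if self.kinematic_rate <= 0 or self.grf_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if self.stride_duration_s <= 0:
            raise ValueError("stride_duration_s must be positive")
        if self.stride_duration_cv < 0:
            raise ValueError("stride_duration_cv must be >= 0")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0, 1)")
        if self.grf_peak_N <= 20.0:
            raise ValueError("grf_peak_N must exceed the 20 N event threshold")
        if not (self.coupling_noise_kappa > 0):
            raise ValueError("coupling_noise_kappa must be > 0 (or inf)")


@dataclass
class MocapTrial:
    """One synchronized running trial: joint angles plus vertical GRF.

    All channels start at t = 0; the angle channels share the kinematic
    sampling grid and the GRF has its own grid. ``meta`` carries subject/
    group/time labels and, for generated trials, the ground-truth contact
    and toe-off times.
    """

    angles: dict[str, np.ndarray]
    kinematic_rate: float
    grf: np.ndarray
    grf_rate: float
    meta: dict = field(default_factory=dict)

    @property
    def angle_times(self) -> np.ndarray:
        n = len(next(iter(self.angles.values())))
        return np.arange(n) / self.kinematic_rate

    @property
    def grf_times(self) -> np.ndarray:
        return np.arange(len(self.grf)) / self.grf_rate


def _stride_phase(t: np.ndarray, contact_times: np.ndarray, durations: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear cycle phase and integer stride index at times ``t``.

    Phase 0 at the first contact; before it the phase extrapolates negative
    using the first stride's duration, after the last contact it continues
    with the last duration.
    """
    idx = np.searchsorted(contact_times, t, side="right") - 1
    idx = np.clip(idx, -1, len(contact_times) - 1)
    ref = contact_times[np.clip(idx, 0, None)]
    dur = durations[np.clip(idx, 0, len(durations) - 1)]
    phi = np.clip(idx, 0, None) + (t - ref) / dur
    return phi, idx


def generate_trial(config: GaitSimConfig) -> MocapTrial:
    """Generate one synthetic running trial.

    The trial contains ``n_strides`` complete contact-to-contact strides
    (``n_strides + 1`` foot contacts), with the GRF a smooth half-sine stance
    bump scaled to ``grf_peak_N`` that equals the 20 N threshold exactly at
    the stance boundaries and exceeds it strictly inside. Identical config
    and seed reproduce the trial bit-for-bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_strides
    durations = config.stride_duration_s * (
        1.0 + config.stride_duration_cv * rng.standard_normal(n + 1)
    )
    durations = np.clip(durations, 0.25 * config.stride_duration_s, None)

    lead_in = 0.6 * (1.0 - config.stance_fraction) * config.stride_duration_s
    contact_times = lead_in + np.concatenate(([0.0], np.cumsum(durations[:-1])))
    stance_lens = config.stance_fraction * durations
    toe_off_times = contact_times + stance_lens
    total_t = toe_off_times[-1] + 0.15

    # --- GRF channel ---
    tg = np.arange(int(round(total_t * config.grf_rate))) / config.grf_rate
    grf = np.zeros_like(tg)
    for c, L in zip(contact_times, stance_lens):
        u = (tg - c) / L
        inside = (u > 0.0) & (u < 1.0)
        grf[inside] = 20.0 + (config.grf_peak_N - 20.0) * np.sin(np.pi * u[inside])

    # --- angle channels ---
    tk = np.arange(int(round(total_t * config.kinematic_rate))) / config.kinematic_rate
    phi, stride_idx = _stride_phase(tk, contact_times, durations)

    angles: dict[str, np.ndarray] = {}
    kappa = config.coupling_noise_kappa
    n_jit_rows = n + 3  # stride indices -1 .. n+1
    for joint, wf in config.joint_waveforms.items():
        if math.isinf(kappa):
            jitter = np.zeros((n_jit_rows, len(wf.harmonics)))
        else:
            jitter = rng.vonmises(0.0, kappa, size=(n_jit_rows, len(wf.harmonics)))
        out = np.full(tk.shape, wf.offset_deg, dtype=float)
        rows = np.clip(stride_idx + 1, 0, n_jit_rows - 1)
        for h, (order, amp, phase) in enumerate(wf.harmonics):
            out += amp * np.sin(2.0 * np.pi * order * phi + phase + jitter[rows, h])
        angles[joint] = out

    meta = {
        "contact_times_s": contact_times,
        "toe_off_times_s": toe_off_times,
        "stride_durations_s": durations,
        "config": config,
    }
    return MocapTrial(
        angles=angles,
        kinematic_rate=config.kinematic_rate,
        grf=grf,
        grf_rate=config.grf_rate,
        meta=meta,
    )


def generate_coupled_pair(
    coupling_profile_deg: np.ndarray,
    kappa: float,
    n_strides: int,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate joint-pair cycles whose coupling angles are known exactly.

    Each of the 100 inter-point steps of each 101-point cycle is a unit step
    in the angle-angle plane whose direction is drawn from a von Mises
    distribution centred on ``coupling_profile_deg`` (degrees, one entry per
    step) with concentration ``kappa``; ``kappa = inf`` means the profile is
    followed exactly. Returns ``(prox, dist)`` arrays of shape
    ``(n_strides, 101)``.
    """
    profile = np.asarray(coupling_profile_deg, dtype=float)
    if profile.shape != (100,):
        raise ValueError(
            f"coupling_profile must have exactly 100 entries, got shape {profile.shape}"
        )
    if not (kappa > 0):
        raise ValueError("kappa must be > 0 (or inf)")
    if n_strides < 1:
        raise ValueError("n_strides must be >= 1")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = np.deg2rad(profile)
    if math.isinf(kappa):
        alpha = np.broadcast_to(mu, (n_strides, 100)).copy()
    else:
        alpha = rng.vonmises(mu, kappa, size=(n_strides, 100))

    dprox = np.sin(alpha)
    ddist = np.cos(alpha)
    prox = np.concatenate([np.zeros((n_strides, 1)), np.cumsum(dprox, axis=1)], axis=1)
    dist = np.concatenate([np.zeros((n_strides, 1)), np.cumsum(ddist, axis=1)], axis=1)
    return prox, dist


@dataclass
class CohortRecord:
    """Coupled joint-pair cycles for one subject at one measurement time."""

    subject: str
    group: str
    time: str
    prox: np.ndarray  # (n_strides, 101)
    dist: np.ndarray  # (n_strides, 101)


def simulate_cohort(
    profiles: dict[tuple[str, str], np.ndarray],
    n_per_group: int = 12,
    n_strides: int = 10,
    kappa: float = 10.0,
    subject_sd_deg: float = 8.0,
    groups: tuple[str, str] = ("RASH", "nonRASH"),
    times: tuple[str, str] = ("pre", "post"),
    seed: int = 0,
) -> list[CohortRecord]:
    """Simulate a two-group pre/post cohort of coupled joint-pair cycles.

    ``profiles[(group, time)]`` is the 100-step coupling-angle profile for
    that cell. Each subject carries a persistent angular offset drawn from a
    normal with SD ``subject_sd_deg`` (the between-subject variation that
    makes the mixed design meaningful); stride-to-stride noise is von Mises
    with concentration ``kappa``.
    """
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    for group in groups:
        for s in range(n_per_group):
            subject = f"{group}-{s + 1:02d}"
            offset = subject_sd_deg * rng.standard_normal()
            for time in times:
                profile = np.asarray(profiles[(group, time)], dtype=float) + offset
                prox, dist = generate_coupled_pair(profile % 360.0, kappa, n_strides, rng)
                records.append(CohortRecord(subject, group, time, prox, dist))
    return records
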