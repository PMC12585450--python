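"""Signal conditioning and stride extraction for running trials.

Order of operations mirrors standard treadmill-running workflows: interior
gaps in kinematic channels are filled by quintic-spline interpolation, all
channels are low-pass filtered with a zero-phase Butterworth filter (10 Hz
for kinematics, 50 Hz for the GRF), foot contact and toe-off are detected
from the vertical GRF with a 20 N threshold, strides are segmented contact to
ipsilateral contact, and each stride is resampled to 101 points (0-100% of
the gait cycle). The four analysis subphases are fixed percent windows of the
normalized cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline, make_interp_spline
from scipy.signal import butter, filtfilt

__all__ = [
    "GaitEvents",
    "NormalizedCycle",
    "SUBPHASE_WINDOWS",
    "subphase_point_indices",
    "subphase_step_indices",
    "lowpass_filter",
    "fill_gaps",
    "detect_gait_events",
    "segment_and_normalize",
    "require_min_strides",
]

#: Closed percent windows over the 101-point normalized gait cycle.
SUBPHASE_WINDOWS: dict[str, tuple[int, int]] = {
    "first_half_stance": (0, 20),
    "second_half_stance": (21, 40),
    "first_half_swing": (41, 70),
    "second_half_swing": (71, 100),
}


def subphase_point_indices(name: str) -> np.ndarray:
    """Indices of normalized-cycle points (0..100) inside a subphase."""
    lo, hi = SUBPHASE_WINDOWS[name]
    return np.arange(lo, hi + 1)


def subphase_step_indices(name: str) -> np.ndarray:
    """Indices of coupling-angle steps (0..99) inside a subphase.

    Step ``t`` (the increment from point ``t`` to ``t+1``) is assigned to the
    subphase containing point ``t``; point 100 begins no step.
    """
    lo, hi = SUBPHASE_WINDOWS[name]
    return np.arange(lo, min(hi, 99) + 1)


@dataclass
class GaitEvents:
    """Foot-contact and toe-off sample indices on the GRF grid."""

    contacts: np.ndarray
    toe_offs: np.ndarray
    rate: float

    @property
    def contact_times(self) -> np.ndarray:
        return self.contacts / self.rate

    @property
    def toe_off_times(self) -> np.ndarray:
        return self.toe_offs / self.rate


@dataclass
class NormalizedCycle:
    """One stride's joint angles resampled to 101 points (0-100% of cycle)."""

    points: dict[str, np.ndarray]
    stride_id: int
    toe_off_pct: float | None = None
    flagged: bool = False
    meta: dict = field(default_factory=dict)


def lowpass_filter(signal: np.ndarray, rate: float, cutoff: float, order: int = 3) -> np.ndarray:
    """Zero-phase (forward-backward) low-pass Butterworth filter.

    The filter of the stated ``order`` is applied once in each direction, so
    the effective magnitude response is squared and the phase response is
    zero (events are not shifted in time).
    """
    signal = np.asarray(signal, dtype=float)
    if not 0.0 < cutoff < rate / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={rate / 2.0} Hz)")
    if np.any(~np.isfinite(signal)):
        raise ValueError("signal contains non-finite values; fill gaps before filtering")
    b, a = butter(order, cutoff, btype="low", fs=rate)
    # reflect-pad long enough for the IIR transient to die out, so DC and
    # linear trends pass with gain 1 to numerical precision
    padlen = min(len(signal) - 1, max(3 * (order + 1), int(np.ceil(10.0 * rate / cutoff))))
    return filtfilt(b, a, signal, padlen=padlen)


def fill_gaps(signal: np.ndarray, max_gap: int = 10) -> np.ndarray:
    """Fill interior NaN runs of length <= ``max_gap`` by quintic spline.

    Only the missing samples are replaced; gaps longer than ``max_gap`` and
    leading/trailing gaps are refused (policy: occlusion gaps beyond 10
    frames are not trusted to interpolation).
    """
    signal = np.asarray(signal, dtype=float)
    missing = ~np.isfinite(signal)
    if not missing.any():
        return signal.copy()
    if missing[0] or missing[-1]:
        raise ValueError("leading or trailing gap cannot be interpolated")

    # locate maximal missing runs
    edges = np.diff(missing.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1  # exclusive
    for s, e in zip(starts, ends):
        if e - s > max_gap:
            raise ValueError(
                f"gap of {e - s} samples at index {s} exceeds max_gap={max_gap}"
            )

    x = np.arange(len(signal), dtype=float)
    spline = make_interp_spline(x[~missing], signal[~missing], k=5)
    out = signal.copy()
    out[missing] = spline(x[missing])
    return out


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as (start, end-exclusive)."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.diff(padded.astype(int))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list(zip(starts, ends))


def detect_gait_events(
    grf: np.ndarray,
    rate: float,
    threshold: float = 20.0,
    min_phase_s: float = 0.05,
) -> GaitEvents:
    """Detect foot contacts and toe-offs from the vertical GRF.

    Contact is the first sample of each maximal run with GRF strictly above
    ``threshold``; toe-off is the first sample after the run. Runs (above or
    below threshold) shorter than ``min_phase_s`` are treated as chatter and
    merged into their neighbours. Runs touching the start or end of the
    record are incomplete and discarded.
    """
    grf = np.asarray(grf, dtype=float)
    if np.any(~np.isfinite(grf)):
        raise ValueError("GRF contains non-finite values")
    min_n = max(1, int(round(min_phase_s * rate)))
    above = grf > threshold

    # drop short above-threshold spikes first, then merge short interior
    # dropouts into the surrounding stance
    for s, e in _bool_runs(above):
        if e - s < min_n:
            above[s:e] = False
    for s, e in _bool_runs(~above):
        if s > 0 and e < len(above) and e - s < min_n:
            above[s:e] = True

    contacts, toe_offs = [], []
    for s, e in _bool_runs(above):
        if s == 0 or e == len(above):
            continue  # incomplete stance at a record boundary
        contacts.append(s)
        toe_offs.append(e)

    if len(contacts) < 2:
        raise ValueError("insufficient strides: fewer than 2 foot contacts detected")
    return GaitEvents(np.asarray(contacts), np.asarray(toe_offs), rate)


def segment_and_normalize(
    angles: dict[str, np.ndarray],
    kinematic_rate: float,
    events: GaitEvents,
    grf_rate: float | None = None,
    stance_target_pct: float = 40.0,
    stance_tol_pct: float = 5.0,
) -> list[NormalizedCycle]:
    """Segment strides at foot contacts and resample each to 101 points.

    Event times from the GRF grid are snapped to the nearest kinematic
    sample (sub-frame alignment is below kinematic resolution); each channel
    is then spline-resampled onto 101 evenly spaced time points spanning
    contact to next contact. Cycles whose toe-off does not fall at
    ``stance_target_pct ± stance_tol_pct`` of the cycle are flagged, not
    dropped.
    """
    n = len(next(iter(angles.values())))
    for joint, y in angles.items():
        if len(y) != n:
            raise ValueError(f"channel '{joint}' length {len(y)} != {n}")
    t_max = (n - 1) / kinematic_rate

    contact_t = events.contact_times
    toe_t = events.toe_off_times
    if contact_t.min() < -0.5 / kinematic_rate or contact_t.max() > t_max + 0.5 / kinematic_rate:
        raise ValueError("events fall outside the kinematic time span")

    # snap contacts to the nearest kinematic sample
    snapped = np.round(contact_t * kinematic_rate) / kinematic_rate
    snapped = np.clip(snapped, 0.0, t_max)

    tk = np.arange(n) / kinematic_rate
    splines = {j: CubicSpline(tk, y) for j, y in angles.items()}

    cycles: list[NormalizedCycle] = []
    for i in range(len(snapped) - 1):
        t0, t1 = snapped[i], snapped[i + 1]
        if t1 <= t0:
            raise ValueError(f"non-increasing contact times at stride {i}")
        ts = np.linspace(t0, t1, 101)
        points = {j: sp(ts) for j, sp in splines.items()}
        to = toe_t[(toe_t > contact_t[i]) & (toe_t < contact_t[i + 1])]
        toe_pct = float((to[0] - t0) / (t1 - t0) * 100.0) if len(to) else None
        flagged = toe_pct is None or abs(toe_pct - stance_target_pct) > stance_tol_pct
        cycles.append(NormalizedCycle(points, stride_id=i, toe_off_pct=toe_pct, flagged=flagged))
    return cycles


def require_min_strides(cycles: list[NormalizedCycle], minimum: int = 8) -> list[NormalizedCycle]:
    """Enforce the minimum stride count needed for coordination variability."""
    if len(cycles) < minimum:
        raise ValueError(
            f"fewer than {minimum} strides: got {len(cycles)}; "
            "coordination variability needs at least this many"
        )
    return cycles
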