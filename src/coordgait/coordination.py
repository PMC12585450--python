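"""Modified vector coding and circular statistics.

The coupling angle between a proximal joint (hip or knee) and the distal
joint (ankle) at step t of the normalized gait cycle is the orientation,
relative to the right horizontal of the angle-angle plot (ankle on X,
proximal joint on Y), of the vector joining consecutive cycle points:

    theta(t) = atan2(dtheta_prox(t), dtheta_dist(t))  wrapped to [0, 360)

The two-argument arctangent is the quadrant-preserving realization of the
arctan-ratio-mod-360 formula common in the vector-coding literature: the
ratio form alone cannot distinguish opposite quadrants, while coordination
patterns are defined over the full circle.

Coupling angles are directional data, so averages and dispersions use
circular statistics: the mean resultant length R = |mean(exp(i*theta))|
and the circular standard deviation sqrt(-2 ln R) * 180/pi (degrees), which
is the coordination-variability measure.

Pattern classes tile the circle in 45-degree sectors: in-phase proximal
dominancy (0-45 or 180-225), in-phase distal/ankle dominancy (45-90 or
225-270), anti-phase distal dominancy (90-135 or 270-315) and anti-phase
proximal dominancy (135-180 or 315-360). Exactly 90 and 270 mean only the
proximal joint is moving.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .preprocess import SUBPHASE_WINDOWS, NormalizedCycle, subphase_step_indices

__all__ = [
    "CouplingSeries",
    "CircularSummary",
    "PatternClass",
    "SubphaseSummary",
    "ensemble_mean_cycle",
    "coupling_angles",
    "circular_mean",
    "classify_pattern",
    "subphase_coordination",
    "coordination_variability",
    "pre_post_delta",
    "analyze_coupled_cycles",
    "analyze_pair",
]


class PatternClass(str, enum.Enum):
    """Coordination pattern of a coupling angle (dominancy x phase)."""

    IN_PHASE_PROXIMAL = "in_phase_proximal"
    IN_PHASE_DISTAL = "in_phase_distal"
    ANTI_PHASE_DISTAL = "anti_phase_distal"
    ANTI_PHASE_PROXIMAL = "anti_phase_proximal"


# 45-degree sectors starting at 0; the sequence repeats every 180 degrees.
_SECTOR_ORDER = (
    PatternClass.IN_PHASE_PROXIMAL,
    PatternClass.IN_PHASE_DISTAL,
    PatternClass.ANTI_PHASE_DISTAL,
    PatternClass.ANTI_PHASE_PROXIMAL,
)


@dataclass
class CouplingSeries:
    """Coupling angles for one joint pair over one 101-point cycle.

    ``theta_deg`` holds 100 angles in [0, 360), one per inter-point step;
    steps where neither joint moved have no defined direction and are masked
    missing.
    """

    theta_deg: np.ndarray
    missing: np.ndarray
    pair: str = ""

    def __post_init__(self) -> None:
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.theta_deg.shape != (100,) or self.missing.shape != (100,):
            raise ValueError("CouplingSeries requires exactly 100 steps")


@dataclass
class CircularSummary:
    """Circular mean direction, mean resultant length and circular SD."""

    mean_deg: float
    R: float
    sd_deg: float
    n: int

    @property
    def undefined(self) -> bool:
        """True when R = 0 (antipodal cancellation): no mean direction."""
        return not math.isfinite(self.sd_deg)


def ensemble_mean_cycle(cycles: list[NormalizedCycle], joint: str) -> np.ndarray:
    """Pointwise mean joint-angle trajectory across strides.

    Joint angles are treated as linear quantities (sagittal excursions are
    far below a full revolution), so the arithmetic mean applies.
    """
    if not cycles:
        raise ValueError("no cycles to average")
    stack = np.stack([c.points[joint] for c in cycles])
    return stack.mean(axis=0)


def coupling_angles(prox: np.ndarray, dist: np.ndarray, pair: str = "") -> CouplingSeries:
    """Coupling angles of a proximal/distal trajectory pair.

    Both inputs must be 101-point trajectories in degrees. Steps where both
    increments are exactly zero are marked missing rather than assigned an
    arbitrary direction.
    """
    prox = np.asarray(prox, dtype=float)
    dist = np.asarray(dist, dtype=float)
    if prox.shape != (101,) or dist.shape != (101,):
        raise ValueError("trajectories must have exactly 101 points")
    if np.any(~np.isfinite(prox)) or np.any(~np.isfinite(dist)):
        raise ValueError("trajectories must be finite")
    dp = np.diff(prox)
    dd = np.diff(dist)
    missing = (dp == 0.0) & (dd == 0.0)
    theta = np.degrees(np.arctan2(dp, dd)) % 360.0
    theta[missing] = np.nan
    return CouplingSeries(theta, missing, pair=pair)


def circular_mean(angles_deg: np.ndarray) -> CircularSummary:
    """Circular mean, mean resultant length R and circular SD of angles.

    NaN entries are treated as missing and excluded. When R vanishes
    (perfectly dispersed data, e.g. antipodal pairs) the mean direction is
    undefined: ``mean_deg`` is NaN and ``sd_deg`` is +inf.
    """
    a = np.asarray(angles_deg, dtype=float).ravel()
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValueError("no non-missing angles to average")
    z = np.exp(1j * np.deg2rad(a)).mean()
    r = float(abs(z))
    if r < 1e-12:
        return CircularSummary(mean_deg=float("nan"), R=0.0, sd_deg=float("inf"), n=a.size)
    mean = float(np.degrees(np.angle(z)) % 360.0)
    sd = float(np.sqrt(-2.0 * np.log(min(r, 1.0))) * 180.0 / np.pi)
    return CircularSummary(mean_deg=mean, R=r, sd_deg=sd, n=a.size)


def classify_pattern(angle_deg: float) -> PatternClass:
    """Map a coupling angle to its coordination pattern class.

    Sectors are left-closed, right-open ([0,45) is in-phase proximal, [45,90)
    in-phase distal, ...), repeating every 180 degrees.
    """
    a = float(angle_deg) % 360.0
    sector = int(a // 45.0) % 4
    return _SECTOR_ORDER[sector]


def subphase_coordination(
    mean_coupling: CouplingSeries,
    windows: dict[str, tuple[int, int]] | None = None,
) -> dict[str, CircularSummary]:
    """Circular summary of a coupling series within each gait subphase."""
    windows = windows or SUBPHASE_WINDOWS
    out: dict[str, CircularSummary] = {}
    for name in windows:
        steps = subphase_step_indices(name)
        vals = mean_coupling.theta_deg[steps]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"all coupling steps missing in subphase '{name}'")
        out[name] = circular_mean(vals)
    return out


def coordination_variability(
    per_stride_couplings: list[CouplingSeries],
    windows: dict[str, tuple[int, int]] | None = None,
    method: str = "pointwise",
) -> dict[str, float]:
    """Across-stride coordination variability per subphase, in degrees.

    ``method="pointwise"`` (default, the dominant convention): at each cycle
    step the circular SD across strides is computed from the across-stride
    mean resultant length, and the subphase value is the arithmetic mean of
    the per-step SDs inside the window. Strides missing a step are excluded
    from that step; steps missing in every stride are skipped.

    ``method="stride_means"`` (alternative convention): the circular SD of
    the per-stride subphase mean angles.
    """
    if method not in ("pointwise", "stride_means"):
        raise ValueError(f"unknown variability method '{method}'")
    windows = windows or SUBPHASE_WINDOWS
    thetas = np.stack([c.theta_deg for c in per_stride_couplings])  # (S, 100)

    out: dict[str, float] = {}
    for name in windows:
        steps = subphase_step_indices(name)
        if method == "pointwise":
            sds = []
            for t in steps:
                col = thetas[:, t]
                col = col[np.isfinite(col)]
                if col.size == 0:
                    continue
                sds.append(circular_mean(col).sd_deg)
            if not sds:
                raise ValueError(f"subphase '{name}' has no usable steps")
            out[name] = float(np.mean(sds))
        else:
            means = []
            for s in range(thetas.shape[0]):
                row = thetas[s, steps]
                row = row[np.isfinite(row)]
                if row.size:
                    means.append(circular_mean(row).mean_deg)
            if not means:
                raise ValueError(f"subphase '{name}' has no usable strides")
            out[name] = circular_mean(np.asarray(means)).sd_deg
    return out


def pre_post_delta(pre_deg: float, post_deg: float) -> float:
    """Signed minimal circular difference post - pre, in (-180, 180]."""
    d = (float(post_deg) - float(pre_deg)) % 360.0
    return d - 360.0 if d > 180.0 else d


@dataclass
class SubphaseSummary:
    """Coordination summary of one joint pair in one subphase."""

    subphase: str
    coord_angle_deg: float
    R: float
    variability_deg: float
    pattern: PatternClass
    n_strides: int
    extra: dict = field(default_factory=dict)


def analyze_coupled_cycles(
    prox_cycles: np.ndarray,
    dist_cycles: np.ndarray,
    pair: str = "",
    variability_method: str = "pointwise",
) -> list[SubphaseSummary]:
    """Full coordination summary from raw per-stride trajectory pairs.

    The subphase coordination angle follows the mean-trajectory pathway
    (coupling angles of the across-stride ensemble-mean trajectories), while
    coordination variability follows the per-stride pathway (across-stride
    circular SD of per-stride coupling angles). ``prox_cycles`` and
    ``dist_cycles`` have shape (n_strides, 101).
    """
    prox_cycles = np.asarray(prox_cycles, dtype=float)
    dist_cycles = np.asarray(dist_cycles, dtype=float)
    if prox_cycles.shape != dist_cycles.shape or prox_cycles.ndim != 2:
        raise ValueError("cycle arrays must share shape (n_strides, 101)")

    mean_coupling = coupling_angles(prox_cycles.mean(axis=0), dist_cycles.mean(axis=0), pair)
    per_stride = [
        coupling_angles(prox_cycles[s], dist_cycles[s], pair)
        for s in range(prox_cycles.shape[0])
    ]
    coord = subphase_coordination(mean_coupling)
    var = coordination_variability(per_stride, method=variability_method)

    return [
        SubphaseSummary(
            subphase=name,
            coord_angle_deg=coord[name].mean_deg,
            R=coord[name].R,
            variability_deg=var[name],
            pattern=classify_pattern(coord[name].mean_deg),
            n_strides=prox_cycles.shape[0],
        )
        for name in SUBPHASE_WINDOWS
    ]


def analyze_pair(
    cycles: list[NormalizedCycle],
    prox_joint: str,
    dist_joint: str,
    variability_method: str = "pointwise",
) -> list[SubphaseSummary]:
    """Coordination summary for a joint pair from normalized stride cycles."""
    prox = np.stack([c.points[prox_joint] for c in cycles])
    dist = np.stack([c.points[dist_joint] for c in cycles])
    return analyze_coupled_cycles(
        prox, dist, pair=f"{prox_joint}-{dist_joint}", variability_method=variability_method
    )
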