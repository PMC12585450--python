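"""Angle-angle and polar coordination-pattern plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .coordination import PatternClass

__all__ = ["angle_angle_plot", "pattern_polar_plot"]

_PATTERN_LABELS = {
    PatternClass.IN_PHASE_PROXIMAL: "in-phase\nproximal",
    PatternClass.IN_PHASE_DISTAL: "in-phase\ndistal",
    PatternClass.ANTI_PHASE_DISTAL: "anti-phase\ndistal",
    PatternClass.ANTI_PHASE_PROXIMAL: "anti-phase\nproximal",
}


def angle_angle_plot(
    dist_pre: np.ndarray,
    prox_pre: np.ndarray,
    dist_post: np.ndarray | None = None,
    prox_post: np.ndarray | None = None,
    toe_off_pct: int = 40,
    prox_label: str = "proximal joint angle (deg)",
    dist_label: str = "ankle angle (deg)",
    title: str = "",
    out_path: str | Path | None = None,
):
    """Angle-angle diagram: distal joint on X, proximal on Y.

    Initial contact is marked with a filled circle and toe-off with a filled
    square; the optional post trajectory is drawn in a second style.
    """
    fig, ax = plt.subplots(figsize=(5, 5))
    for dist, prox, style, label in (
        (dist_pre, prox_pre, dict(color="k"), "pre"),
        (dist_post, prox_post, dict(color="tab:green"), "post"),
    ):
        if dist is None or prox is None:
            continue
        ax.plot(dist, prox, lw=1.5, label=label, **style)
        ax.plot(dist[0], prox[0], "o", ms=8, **style)
        ax.plot(dist[toe_off_pct], prox[toe_off_pct], "s", ms=8, **style)
    ax.set_xlabel(dist_label)
    ax.set_ylabel(prox_label)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig


def pattern_polar_plot(
    angles_deg: np.ndarray | None = None,
    title: str = "coordination pattern sectors",
    out_path: str | Path | None = None,
):
    """Polar plot of the 45-degree pattern sectors, optionally with data."""
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5.5, 5.5))
    colors = ["#c6dbef", "#9ecae1", "#6baed6", "#3182bd"]
    for k in range(8):
        cls = list(PatternClass)[k % 4]
        ax.bar(
            np.deg2rad(k * 45 + 22.5),
            1.0,
            width=np.deg2rad(45),
            color=colors[k % 4],
            alpha=0.5,
            edgecolor="w",
        )
        ax.text(
            np.deg2rad(k * 45 + 22.5), 0.7, _PATTERN_LABELS[cls],
            ha="center", va="center", fontsize=7,
        )
    if angles_deg is not None:
        a = np.deg2rad(np.asarray(angles_deg, dtype=float))
        ax.plot(a, np.full_like(a, 0.95), "ko", ms=4)
    ax.set_yticks([])
    ax.set_title(title)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
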