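"""Trap-binding efficiency and regime-transition analysis.

The trap-binding efficiency ``f_b(t)`` is the fraction of all proteins in
the system that sit on traps; per box, ``f_ib(t) = N_b[i]/(N_u[i]+N_b[i])``.
Each box with traps passes from a binding-dominated phase (efficiency
rising) to a synthesis-dominated phase (efficiency decaying like
``capacity/(alpha_syn t)``) at its transition time ``t*_i``, the time of
its efficiency maximum.  Globally the run is "pure-binding" before the
earliest per-box transition, "mixed" while some boxes have transitioned
and others have not, and "pure-synthesis" once the last box (the one
farthest from the synthesis sites) has transitioned.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import json
import numpy as np

from .simulate import Trajectory

__all__ = [
    "RegimeReport",
    "trap_binding_efficiency",
    "detect_regimes",
    "asymptotic_efficiency",
]


def _safe_fraction(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with the 0/0 -> 0 convention (empty system)."""
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    return out


def trap_binding_efficiency(trajectory: Trajectory):
    """Global and per-box trap-binding efficiency time series.

    Returns ``(f_b, f_per_box)`` where ``f_b`` has shape ``(n_times,)`` and
    ``f_per_box`` has shape ``(n_times, M)``.  Both use the convention
    0/0 -> 0 for boxes (or times) without any protein, and lie in [0, 1].
    """
    f_b = _safe_fraction(trajectory.total_bound, trajectory.total_protein)
    f_per_box = _safe_fraction(trajectory.N_b, trajectory.N_u + trajectory.N_b)
    return f_b, f_per_box


@dataclass
class RegimeReport:
    """Per-box and global transition times of one run.

    ``t_star_per_box[i]`` is NaN for boxes whose efficiency maximum was not
    reached within the horizon (still rising at the end) and for boxes
    without traps, which never have a binding-dominated phase.
    ``t_star_first``/``t_star_last`` are the earliest/latest per-box
    transitions; ``t_star_last`` is ``None`` unless *every* trap-carrying
    box has transitioned.  ``f_b_max`` is the maximum of the global
    efficiency and ``t_f_b_max`` its (earliest) time.
    """

    t_star_per_box: np.ndarray
    t_star_first: Optional[float]
    t_star_last: Optional[float]
    f_b_max: float
    t_f_b_max: float
    times: np.ndarray = field(repr=False)

    @property
    def regime_labels(self) -> np.ndarray:
        """Per recorded time: 'pure-binding', 'mixed', or 'pure-synthesis'."""
        labels = np.full(self.times.shape[0], "pure-binding", dtype="U14")
        if self.t_star_first is not None:
            labels[self.times >= self.t_star_first] = "mixed"
            if self.t_star_last is not None:
                labels[self.times >= self.t_star_last] = "pure-synthesis"
        return labels

    def to_dict(self) -> dict:
        tsb = [None if np.isnan(v) else float(v) for v in self.t_star_per_box]
        return {
            "t_star_per_box": tsb,
            "t_star_first": self.t_star_first,
            "t_star_last": self.t_star_last,
            "f_b_max": self.f_b_max,
            "t_f_b_max": self.t_f_b_max,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def detect_regimes(trajectory: Trajectory) -> RegimeReport:
    """Locate per-box and global efficiency maxima on the recorded grid.

    Transitions are read off the recorded time grid without interpolation
    (ties break to the earliest time), so the run must record every step:
    ``record_every != 1`` raises ``ValueError``.  A box still strictly
    rising at the final time is reported as "not reached" (NaN).
    """
    if trajectory.config.record_every != 1:
        raise ValueError(
            "regime analysis requires record_every=1 "
            f"(trajectory was recorded with record_every={trajectory.config.record_every})"
        )
    f_b, f_per_box = trap_binding_efficiency(trajectory)
    times = trajectory.times
    n = times.shape[0]
    has_traps = trajectory.traps.capacities > 0

    t_star = np.full(trajectory.M, np.nan)
    for i in range(trajectory.M):
        if not has_traps[i]:
            continue
        series = f_per_box[:, i]
        idx = int(np.argmax(series))  # earliest index on ties
        if idx == n - 1 or series[idx] == 0.0:
            continue  # maximum not (yet) attained inside the horizon
        t_star[i] = times[idx]

    reached = ~np.isnan(t_star)
    trap_boxes = int(has_traps.sum())
    t_first = float(np.nanmin(t_star)) if reached.any() else None
    t_last = (
        float(np.nanmax(t_star)) if trap_boxes > 0 and reached.sum() == trap_boxes else None
    )
    i_max = int(np.argmax(f_b))
    return RegimeReport(
        t_star_per_box=t_star,
        t_star_first=t_first,
        t_star_last=t_last,
        f_b_max=float(f_b[i_max]),
        t_f_b_max=float(times[i_max]),
        times=times,
    )


def asymptotic_efficiency(
    trajectory: Trajectory, t_star_last: Optional[float] = None
) -> dict:
    """Compare the simulated efficiency tail with its 1/t prediction.

    Deep in the synthesis-dominated regime virtually all traps are occupied
    while the protein total grows linearly, so
    ``f_b(t) ~ sum(capacities) / (alpha_syn |sources| t)``.  Returns the
    predicted and simulated values at the final recorded time and their
    relative deviation (which shrinks as the horizon grows).

    ``t_star_last`` may be supplied from a separate regime analysis (e.g.
    when this trajectory was recorded with decimation); otherwise it is
    detected here.  A run that never leaves the mixed regime raises
    ``ValueError``.
    """
    if t_star_last is None:
        t_star_last = detect_regimes(trajectory).t_star_last
    if t_star_last is None:
        raise ValueError("not in synthesis-dominated regime: t* not reached in every box")
    t_final = float(trajectory.times[-1])
    if t_final <= t_star_last:
        raise ValueError("not in synthesis-dominated regime: horizon ends before t*")
    n_src = len(trajectory.sources)
    alpha = trajectory.config.alpha_per_t
    if alpha * n_src <= 0:
        raise ValueError("tail prediction requires active synthesis")
    predicted = trajectory.traps.total_capacity / (alpha * n_src * t_final)
    f_b, _ = trap_binding_efficiency(trajectory)
    simulated = float(f_b[-1])
    return {
        "t_final": t_final,
        "predicted": float(predicted),
        "simulated": simulated,
        "rel_deviation": abs(simulated - predicted) / predicted,
    }
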