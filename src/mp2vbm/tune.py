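"""Operating-point estimation over the (smoothing x threshold) grid.

For each smoothing level the concordant rate C_R and false-positive rate
100 - S_P across statistical cutoffs trace a ROC curve; the reference
smoothing is the one with the highest trapezoidal AUC, and at that smoothing
the working threshold is the C_R/S_P intersection (on the discrete grid: the
cutoff minimizing |C_R - S_P|, ties resolved toward higher C_R, then toward
the lower cutoff). The Euclidean distance from the achieved (C_R, S_P) to
the ideal (100, 100) summarizes overall performance.

AUC anchoring: only the infinite-threshold limit (0, 0) is prepended — no
finding at all means zero false positives and zero concordance. No (100,
100) anchor is appended, so curves that never reach high C_R keep honestly
small areas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away

__all__ = [
    "PerformancePoint",
    "RocCurve",
    "OperatingChoice",
    "DEFAULT_THRESHOLD_GRID",
    "sweep_grid",
    "roc_auc",
    "select_smoothing",
    "select_threshold",
    "euclidean_distance",
    "cd_ratio",
    "lesional_sensitivity",
    "max_full_sensitivity_threshold",
    "choose_operating_point",
]

#: statistical cutoffs 2.5 .. 6.0, step 0.1
DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(2.5, 6.0 + 1e-9, 0.1), 1))


@dataclass(frozen=True)
class PerformancePoint:
    fwhm: float
    threshold: float
    c_r: float
    d_r: float
    s_p: float


@dataclass
class RocCurve:
    fwhm: float
    points: np.ndarray  # (n, 2) of (fpr, c_r), fpr ascending, anchored at (0, 0)
    auc: float


@dataclass(frozen=True)
class OperatingChoice:
    fwhm: float
    threshold: float
    c_r: float
    d_r: float
    s_p: float
    euclidean_distance: float


def sweep_grid(engine: Callable[[float, float], tuple[float, float, float]],
               fwhm_grid: Sequence[float],
               threshold_grid: Sequence[float]) -> pd.DataFrame:
    """Evaluate ``engine(fwhm, threshold) -> (c_r, d_r, s_p)`` over the grid."""
    if not len(fwhm_grid) or not len(threshold_grid):
        raise ValueError("fwhm and threshold grids must be nonempty")
    rows = []
    for fwhm in fwhm_grid:
        for thr in threshold_grid:
            c_r, d_r, s_p = engine(float(fwhm), float(thr))
            rows.append(PerformancePoint(float(fwhm), float(thr), c_r, d_r, s_p))
    return pd.DataFrame(rows)


def _as_fpr_cr(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        return np.column_stack([100.0 - points["s_p"].to_numpy(float),
                                points["c_r"].to_numpy(float)])
    return np.asarray(points, dtype=float).reshape(-1, 2)


def roc_auc(points, fwhm: float = float("nan")) -> RocCurve:
    """ROC curve and trapezoidal AUC from (fpr = 100 - S_P, C_R) points.

    Points are sorted by ascending fpr; among duplicate fprs only the highest
    C_R is kept; the (0, 0) anchor is prepended; the area under the
    piecewise-linear curve is normalized by the 100 x 100 square.
    """
    pts = _as_fpr_cr(points)
    if pts.size == 0:
        raise ValueError("need at least one ROC point")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    dedup = []
    for fpr, cr in pts:  # sorted: last of each fpr has max c_r
        if dedup and dedup[-1][0] == fpr:
            dedup[-1][1] = cr
        else:
            dedup.append([fpr, cr])
    curve = np.vstack([[0.0, 0.0], np.asarray(dedup)])
    auc = float(np.trapezoid(curve[:, 1], curve[:, 0]) / 1e4)
    return RocCurve(fwhm=float(fwhm), points=curve, auc=auc)


def select_smoothing(curves: Iterable[RocCurve]) -> float:
    """FWHM of the highest-AUC curve; exact ties break toward larger FWHM."""
    curves = list(curves)
    if not curves:
        raise ValueError("need at least one ROC curve")
    best = max(curves, key=lambda c: (c.auc, c.fwhm))
    return best.fwhm


def select_threshold(points: pd.DataFrame) -> float:
    """Discrete C_R/S_P intersection at one smoothing level.

    Minimizes |C_R - S_P|; among minimizers picks the highest C_R; remaining
    ties resolve to the lowest threshold.
    """
    if len(points) == 0:
        raise ValueError("need at least one performance point")
    df = points.copy()
    df["gap"] = (df["c_r"] - df["s_p"]).abs()
    df = df.sort_values(["gap", "c_r", "threshold"], ascending=[True, False, True],
                        kind="stable")
    return float(df.iloc[0]["threshold"])


def euclidean_distance(c_r: float, s_p: float) -> float:
    """Distance from (C_R, S_P) to the ideal (100, 100), one decimal."""
    if not (0.0 <= c_r <= 100.0 and 0.0 <= s_p <= 100.0):
        raise ValueError("rates must be in [0, 100]")
    return round_half_away(float(np.hypot(100.0 - c_r, 100.0 - s_p)), 1)


def cd_ratio(c_r: float, d_r: float) -> float:
    """Concordant-to-discordant rate ratio, two decimals; D_R = 0 rejected."""
    if d_r <= 0:
        raise ValueError("C_R/D_R undefined for D_R = 0")
    return round_half_away(c_r / d_r, 2)


def lesional_sensitivity(peak_ts: Sequence[float], threshold: float) -> float:
    """Percent of lesional cases whose peak t reaches the cutoff (inclusive)."""
    peaks = np.asarray(list(peak_ts), dtype=float)
    if peaks.size == 0:
        raise ValueError("no lesional cases")
    return round_half_away(100.0 * float(np.mean(peaks >= threshold)), 1)


def max_full_sensitivity_threshold(peak_ts: Iterable[float]) -> float:
    """Largest cutoff at which every case is still detected (the minimum peak)."""
    peaks = np.asarray(list(peak_ts), dtype=float)
    if peaks.size == 0:
        raise ValueError("no lesional cases")
    return float(peaks.min())


def choose_operating_point(performance: pd.DataFrame) -> tuple[OperatingChoice, list[RocCurve]]:
    """Full selection: ROC per smoothing, AUC argmax, C_R/S_P intersection.

    ``performance`` is the :func:`sweep_grid` table. Returns the chosen
    operating point (with its Euclidean distance) and all per-smoothing ROC
    curves.
    """
    curves = [roc_auc(grp, fwhm=fwhm) for fwhm, grp in performance.groupby("fwhm")]
    fwhm = select_smoothing(curves)
    at_fwhm = performance[performance["fwhm"] == fwhm]
    threshold = select_threshold(at_fwhm)
    row = at_fwhm[at_fwhm["threshold"] == threshold].iloc[0]
    choice = OperatingChoice(
        fwhm=float(fwhm), threshold=float(threshold), c_r=float(row["c_r"]),
        d_r=float(row["d_r"]), s_p=float(row["s_p"]),
        euclidean_distance=euclidean_distance(float(row["c_r"]), float(row["s_p"])),
    )
    return choice, curves
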