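"""Xenograft tumour-growth analytics.

Caliper measurements (length x width per mouse per day) are converted to
volumes with the ellipsoid approximation V = length * width^2 / 2 and
summarised per treatment arm.  Efficacy is reported as the tumour growth
inhibition rate

    TGI (%) = [1 - V_treated / V_control] * 100,

by default on arm mean volumes (ratio of means); a per-mouse
mean-of-ratios convention is available because published tables do not
always follow one convention consistently.  Between-arm comparisons use
unpaired two-sided t-tests (equal-variance by default, Welch by flag) or
one-way ANOVA followed by BH-adjusted pairwise tests.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import bh_adjust

__all__ = [
    "tumour_volume",
    "tgi",
    "tgi_from_volumes",
    "arm_summaries",
    "compare_arms",
]

MEASUREMENT_COLUMNS = ["mouse_id", "arm", "day", "length_mm", "width_mm"]


def tumour_volume(length: float, width: float) -> float:
    """Ellipsoid volume length * width^2 * 0.5 (mm^3 for mm inputs).

    If width exceeds length the two are swapped with a warning (caliper
    convention: length is the larger diameter).
    """
    if not (length > 0 and width > 0):
        raise ValueError(f"diameters must be positive; got {length} x {width}")
    if width > length:
        warnings.warn(
            f"width {width} > length {length}; swapping (caliper convention)",
            stacklevel=2,
        )
        length, width = width, length
    return length * width * width * 0.5


def tgi(mean_treated_volume: float, mean_control_volume: float) -> float:
    """Tumour growth inhibition, percent; may be negative.

    tgi(V, V) = 0 and tgi(0, V) = 100 exactly, and the value is
    invariant to a common unit rescaling of both volumes.
    """
    if mean_control_volume <= 0:
        raise ValueError("control volume must be positive")
    return (1.0 - mean_treated_volume / mean_control_volume) * 100.0


def tgi_from_volumes(
    treated, control, convention: str = "ratio_of_means"
) -> float:
    """TGI from per-mouse volume vectors.

    ``ratio_of_means`` (default): 1 - mean(treated)/mean(control).
    ``mean_of_ratios``: mean over treated mice of 1 - V_i/mean(control).
    The two agree when arms are balanced and noise-free but differ on
    real data; both are exposed rather than guessing a convention.
    """
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if convention == "ratio_of_means":
        return tgi(float(treated.mean()), float(control.mean()))
    if convention == "mean_of_ratios":
        vc = float(control.mean())
        if vc <= 0:
            raise ValueError("control volume must be positive")
        return float(np.mean(1.0 - treated / vc) * 100.0)
    raise ValueError(f"unknown TGI convention: {convention!r}")


def _volumes(measurements: pd.DataFrame) -> pd.DataFrame:
    if measurements.empty:
        raise ValueError("measurement table is empty")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in measurements.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns: {missing}")
    df = measurements.copy()
    df["volume_mm3"] = [
        tumour_volume(l, w) for l, w in zip(df["length_mm"], df["width_mm"])
    ]
    return df


def arm_summaries(measurements: pd.DataFrame, units: str = "mm3") -> pd.DataFrame:
    """Mean/SD volume and mouse count per (arm, day)."""
    df = _volumes(measurements)
    scale = {"mm3": 1.0, "cm3": 1e-3}[units]
    per_mouse = (
        df.groupby(["arm", "day", "mouse_id"])["volume_mm3"].mean().reset_index()
    )
    out = (
        per_mouse.groupby(["arm", "day"])["volume_mm3"]
        .agg(mean_volume="mean", sd_volume="std", n="count")
        .reset_index()
    )
    out["sd_volume"] = out["sd_volume"].fillna(0.0)
    out[["mean_volume", "sd_volume"]] *= scale
    return out.sort_values(["day", "arm"], kind="mergesort").reset_index(drop=True)


def compare_arms(
    measurements: pd.DataFrame,
    day: int,
    method: str = "t_test",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Pairwise between-arm statistics on volumes at one day.

    ``t_test``: unpaired two-sided t-test per arm pair, significance at
    p < 0.05.  ``anova_bh``: one-way ANOVA across all arms followed by
    pairwise t-tests with BH-adjusted q-values, significance at
    q < 0.05.  The ANOVA F and p are attached as ``result.attrs``.
    """
    df = _volumes(measurements)
    df = df[df["day"] == day]
    if df.empty:
        raise ValueError(f"no measurements at day {day}")
    groups = {
        arm: sub.groupby("mouse_id")["volume_mm3"].mean().to_numpy()
        for arm, sub in df.groupby("arm")
    }
    for arm, vols in groups.items():
        if len(vols) < 2:
            raise ValueError(f"arm {arm!r} has fewer than 2 mice at day {day}")
    if method not in ("t_test", "anova_bh"):
        raise ValueError(f"unknown method: {method!r}")

    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=equal_var)
        rows.append((a, b, float(t), float(p)))
    out = pd.DataFrame(rows, columns=["arm_a", "arm_b", "t", "p"])
    if method == "anova_bh":
        f, p_anova = stats.f_oneway(*(groups[a] for a in sorted(groups)))
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < 0.05
        out.attrs["anova_F"] = float(f)
        out.attrs["anova_p"] = float(p_anova)
    else:
        out["significant"] = out["p"] < 0.05
    return out
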