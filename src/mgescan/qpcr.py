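"""Real-time PCR standard-curve math and excision fold induction.

A dilution series gives a standard curve Ct = intercept + slope *
log10(dilution); reaction efficiency is E = 10^(-1/slope) - 1 (a perfect
doubling per cycle gives slope -1/log10(2) = -3.3219 and E = 1).  Amplicon
amounts are absolute quantities read off the curve, and excision activity
is expressed as the fold change of integrated (attR) versus excised
(attB, attI) junction amounts under DNA-damaging treatments relative to
untreated controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class StandardCurve:
    """Fitted dilution-series curve for one amplification target."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    points: list[tuple[float, float]] = field(default_factory=list)

    @property
    def ct_range(self) -> tuple[float, float]:
        cts = [ct for _, ct in self.points]
        return min(cts), max(cts)


@dataclass
class FoldInduction:
    """Treated/control quantity ratio for one target and condition."""

    target: str
    condition: str
    fold: float
    spread: tuple[float, float]   # min/max over replicate ratio combinations
    n_treated: int
    n_control: int


def efficiency_from_slope(slope: float) -> float:
    """E = 10^(-1/slope) - 1."""
    return 10.0 ** (-1.0 / slope) - 1.0


def fit_curve(points) -> StandardCurve:
    """Ordinary least squares of Ct on log10(dilution).

    ``points`` is an iterable of (log10_dilution, Ct).  At least three
    distinct dilutions are required and the slope must be negative (a
    positive slope signals an inverted dilution axis).
    """
    pts = [(float(x), float(y)) for x, y in points]
    xs = [x for x, _ in pts]
    if len(set(xs)) < 3:
        raise ValueError("standard curve needs >= 3 distinct dilutions")
    res = stats.linregress(xs, [y for _, y in pts])
    if res.slope >= 0:
        raise ValueError(
            f"positive slope {res.slope:.3f}: dilution axis looks inverted")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        efficiency=efficiency_from_slope(float(res.slope)),
        points=pts,
    )


def quantify(ct: float, curve: StandardCurve) -> float:
    """Absolute amount from a Ct value: 10^((ct - intercept)/slope), in the
    units of the dilution series.  Values outside the calibrated Ct range
    are extrapolated with a warning."""
    lo, hi = curve.ct_range
    if not lo <= ct <= hi:
        warnings.warn(
            f"Ct {ct:.2f} outside calibrated range [{lo:.2f}, {hi:.2f}]; "
            "extrapolating")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def fold_induction(treated_cts, control_cts, curve: StandardCurve,
                   target: str = "", condition: str = "") -> FoldInduction:
    """Fold change of curve-derived quantities, treated over control.

    Replicates are aggregated as the arithmetic mean of quantities (the
    curve is linear in log quantity, so quantities — not Ct values — are
    averaged).  The spread is the min/max over all treated/control
    replicate ratio combinations.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        q_t = [quantify(ct, curve) for ct in treated_cts]
        q_c = [quantify(ct, curve) for ct in control_cts]
    if not q_t or not q_c:
        raise ValueError("need >= 1 treated and >= 1 control replicate")
    mean_c = float(np.mean(q_c))
    if mean_c <= 0:
        raise ValueError("zero control quantity")
    ratios = [t / c for t in q_t for c in q_c if c > 0]
    return FoldInduction(
        target=target, condition=condition,
        fold=float(np.mean(q_t)) / mean_c,
        spread=(min(ratios), max(ratios)),
        n_treated=len(q_t), n_control=len(q_c),
    )


def analyze_qpcr(sample_table, dilution_table):
    """End-to-end qPCR analysis from tidy tables.

    ``dilution_table``: columns target, log10_dilution, Ct.
    ``sample_table``: columns target, condition, replicate, Ct; the
    condition named ``control`` is the reference.
    Returns (curves: {target: StandardCurve}, folds: list[FoldInduction]).
    """
    curves = {}
    for target, grp in dilution_table.groupby("target"):
        curves[target] = fit_curve(zip(grp["log10_dilution"], grp["Ct"]))
    folds = []
    for (target, condition), grp in sample_table.groupby(["target", "condition"]):
        if condition == "control":
            continue
        if target not in curves:
            raise ValueError(f"no standard curve for target {target!r}")
        control = sample_table[
            (sample_table["target"] == target)
            & (sample_table["condition"] == "control")]
        folds.append(fold_induction(
            grp["Ct"].tolist(), control["Ct"].tolist(), curves[target],
            target=target, condition=condition))
    return curves, folds
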