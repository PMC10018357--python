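"""Clonogenic survival processing, linear-quadratic fits and RBE.

Surviving fractions are colony counts normalised by cells plated and by the
plating efficiency of the unirradiated control.  Survival curves follow the
linear-quadratic model ``SF(D) = exp(-alpha*D - beta_lq*D**2)``; the dose
giving 10% survival (D10) comes either from the fitted parameters or from
log-linear interpolation between bracketing doses.  Relative biological
effectiveness at the 10% survival level is the ratio of reference (X-ray)
to test (carbon-ion) D10.  Group comparisons (micronuclei, chromatid
breaks) use fold changes and the unpaired two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .models import RBEResult, SurvivalCurve, SurvivalDataset

__all__ = [
    "surviving_fractions",
    "fit_lq",
    "d10",
    "rbe_d10",
    "group_compare",
    "GroupComparison",
]

LN10 = math.log(10.0)


def surviving_fractions(
    dataset: SurvivalDataset | None = None,
    *,
    doses: np.ndarray | None = None,
    colonies: np.ndarray | None = None,
    cells_plated: np.ndarray | None = None,
    replicate: np.ndarray | None = None,
) -> SurvivalCurve:
    """Normalise colony counts to surviving fractions.

    Plating efficiency is taken from the dose-0 wells (required); then
    ``SF(D) = (colonies / cells_plated) / plating_efficiency``.  Wells with
    zero colonies yield SF = 0 and are flagged for exclusion from log-space
    fitting.
    """
    if dataset is not None:
        doses = dataset.doses
        colonies = dataset.colonies
        cells_plated = dataset.cells_plated
        replicate = dataset.replicate
    doses = np.asarray(doses, dtype=float)
    colonies = np.asarray(colonies, dtype=float)
    cells_plated = np.asarray(cells_plated, dtype=float)
    if replicate is None:
        replicate = np.zeros(doses.shape, dtype=int)
    zero = doses == 0
    if not zero.any():
        raise ValueError("unirradiated (dose 0) control wells are required")
    pe = float(np.mean(colonies[zero] / cells_plated[zero]))
    if pe <= 0:
        raise ValueError("plating efficiency is zero; cannot normalise")
    sf = (colonies / cells_plated) / pe
    return SurvivalCurve(
        doses=doses,
        surviving_fraction=sf,
        replicate=np.asarray(replicate),
        plating_efficiency=pe,
        excluded=sf <= 0,
    )


def fit_lq(curve: SurvivalCurve) -> tuple[float, float]:
    """Least-squares linear-quadratic fit ``ln SF = -alpha*D - beta*D^2``.

    Constrained to alpha, beta >= 0.  SF <= 0 points are excluded (their
    log is undefined); at least three distinct positive doses with usable
    SF are required.  The fitted parameters are stored on the curve.
    """
    mask = (curve.surviving_fraction > 0) & (curve.doses > 0)
    d = curve.doses[mask]
    y = -np.log(curve.surviving_fraction[mask])
    if np.unique(d).size < 3:
        raise ValueError("need at least three distinct positive doses to fit")
    design = np.column_stack([d, d**2])
    coef, _ = optimize.nnls(design, y)
    alpha, beta = float(coef[0]), float(coef[1])
    curve.alpha, curve.beta_lq = alpha, beta
    curve.d10 = d10(curve, method="fit")
    return alpha, beta


def d10(curve: SurvivalCurve, method: str = "fit") -> float:
    """Dose (Gy) at which survival reaches 10%.

    ``fit``: positive root of ``alpha*D + beta*D**2 = ln 10`` using the
    stored linear-quadratic parameters.  ``interpolate``: log-linear
    interpolation between the dose points bracketing SF = 0.1 (mean SF per
    dose).
    """
    if method == "fit":
        if curve.alpha is None or curve.beta_lq is None:
            fit_lq(curve)
        a, b = curve.alpha, curve.beta_lq
        if a <= 0 and b <= 0:
            raise ValueError("degenerate fit: alpha = beta = 0")
        # cancellation-free form of the positive quadratic root
        root = 2 * LN10 / (a + math.sqrt(a**2 + 4 * b * LN10))
        curve.d10 = float(root)
        return float(root)
    if method == "interpolate":
        order = np.argsort(curve.doses)
        d_sorted = curve.doses[order]
        sf_sorted = curve.surviving_fraction[order]
        uniq = np.unique(d_sorted)
        mean_sf = np.array([sf_sorted[d_sorted == u].mean() for u in uniq])
        ok = mean_sf > 0
        uniq, mean_sf = uniq[ok], mean_sf[ok]
        below = mean_sf <= 0.1
        if not below.any() or below.all():
            raise ValueError("survival does not cross 10% within the dose range")
        j = int(np.argmax(below))
        d1, d2 = uniq[j - 1], uniq[j]
        s1, s2 = mean_sf[j - 1], mean_sf[j]
        frac = (math.log(0.1) - math.log(s1)) / (math.log(s2) - math.log(s1))
        return float(d1 + (d2 - d1) * frac)
    raise ValueError("method must be 'fit' or 'interpolate'")


def rbe_d10(d10_reference: float, d10_test: float) -> RBEResult:
    """Relative biological effectiveness at 10% survival.

    ``d10_reference`` is the X-ray dose and ``d10_test`` the carbon-ion dose
    giving 10% survival; RBE_D10 is their ratio, reported at full precision
    and rounded to two decimals for display.
    """
    if d10_reference <= 0 or d10_test <= 0:
        raise ValueError("D10 values must be positive")
    ratio = d10_reference / d10_test
    return RBEResult(
        d10_reference=d10_reference,
        d10_test=d10_test,
        rbe_d10=ratio,
        rbe_d10_display=round(ratio, 2),
    )


@dataclass
class GroupComparison:
    fold_change: float
    t_statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    welch: bool = False


def group_compare(
    group_a: np.ndarray | list[float],
    group_b: np.ndarray | list[float],
    welch: bool = False,
) -> GroupComparison:
    """Fold change (B over A) and two-sided unpaired t-test.

    Student's equal-variance t-test by default, Welch's on request.  The
    fold change needs one value per group; the t-test needs two, otherwise
    the statistic and p-value are NaN.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one value")
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    if mean_a == 0:
        raise ValueError("group A mean is zero; fold change undefined")
    fold = mean_b / mean_a
    if a.size >= 2 and b.size >= 2:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
    else:
        t = p = float("nan")
    return GroupComparison(
        fold_change=fold, t_statistic=t, p_value=p,
        mean_a=mean_a, mean_b=mean_b, n_a=int(a.size), n_b=int(b.size),
        welch=welch,
    )
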