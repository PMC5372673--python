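"""Dose-response phenotyping and small assay formulas.

``fit_ic50`` turns a survival curve (% of no-drug control at increasing
drug concentrations) into an IC50 via a constrained four-parameter
logistic fit, falling back to log-linear interpolation of the 50% crossing
when the fit cannot be trusted; curves that never cross 50% are censored
rather than extrapolated. ``log2_phenotypes`` collects the log2 IC50
vector and attaches a Lilliefors-corrected Kolmogorov-Smirnov normality
check (estimated mean/SD make the plain KS test anti-conservative).

Two scalar helpers round out the assay math: the ddCT qPCR fold change
(both sign conventions, labelled) and the relative-resistance ratio of a
knockdown condition versus its scrambled-siRNA control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "PhenotypeRow",
    "QpcrCts",
    "SurvivalQuartet",
    "fit_ic50",
    "fit_ic50_table",
    "log2_phenotypes",
    "ddct_fold_change",
    "relative_resistance",
]


@dataclass(frozen=True)
class PhenotypeRow:
    """One sample's fitted phenotype.

    ``censor_flag`` is ``"none"``, ``"below_min"`` (already under 50%
    survival at the lowest concentration) or ``"above_max"`` (never
    reaches 50%); censored rows carry no IC50.
    """

    sample: str
    ic50_uM: float | None
    log2_ic50: float | None
    censor_flag: str
    fit_method: str  # "fourpl" | "interpolation" | "censored"
    sse: float | None


@dataclass(frozen=True)
class QpcrCts:
    """The four qPCR threshold cycles entering a ddCT fold change."""

    ct_target_condition: float
    ct_reference_condition: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for name in ("ct_target_condition", "ct_reference_condition",
                     "ct_target_control", "ct_reference_control"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be a positive cycle count")


@dataclass(frozen=True)
class SurvivalQuartet:
    """Survival fractions for the relative-resistance ratio."""

    surv_condition_drug: float
    surv_condition_control: float
    surv_scramble_drug: float
    surv_scramble_control: float

    def __post_init__(self) -> None:
        if min(self.surv_condition_drug, self.surv_condition_control,
               self.surv_scramble_drug, self.surv_scramble_control) < 0:
            raise ValueError("survival values must be >= 0")
        if self.surv_condition_control <= 0 or self.surv_scramble_control <= 0:
            raise ValueError("control survivals must be > 0")


def _four_pl(c, bottom, top, log10_ic50, hill):
    return bottom + (top - bottom) / (1.0 + (c / 10.0**log10_ic50) ** hill)


def _fit_fourpl(conc: np.ndarray, surv: np.ndarray) -> tuple[float, float]:
    """Hierarchical logistic fit: pinned plateaus first, free 4PL on demand.

    A full four-parameter fit on a handful of points is weakly identified:
    letting bottom/top drift within their bounds inflates the IC50 error
    severalfold on noisy curves. Since the assay normalises to a no-drug
    control, the reduced model pins bottom = 0 and top = 100 and fits only
    (log10 IC50, hill). The free 4PL (bottom in [0, 30], top in [70, 130])
    replaces it only when an extra-sum-of-squares F-test says the plateau
    shift is real — the standard model-comparison rule in dose-response
    fitting. Returns ``(ic50, sse)`` of the selected model.
    """
    from scipy.stats import f as f_dist

    lo = [0.0, 70.0, math.log10(conc[0] / 10.0), 0.05]
    hi = [30.0, 130.0, math.log10(conc[-1] * 10.0), 10.0]
    guess_ic50 = _interpolate_crossing(conc, surv) or math.sqrt(conc[0] * conc[-1])
    l10 = min(max(math.log10(guess_ic50), lo[2]), hi[2])

    popt2, _ = curve_fit(
        lambda c, log10_ic50, hill: _four_pl(c, 0.0, 100.0, log10_ic50, hill),
        conc, surv, p0=[l10, 1.0], bounds=([lo[2], lo[3]], [hi[2], hi[3]]),
        maxfev=20000,
    )
    sse2 = float(np.sum((surv - _four_pl(conc, 0.0, 100.0, *popt2)) ** 2))

    df4 = conc.size - 4
    if df4 < 1:  # free plateaus unidentifiable: keep the reduced model
        return float(10.0 ** popt2[0]), sse2
    p0 = [
        min(max(surv.min(), lo[0]), hi[0]),
        min(max(surv.max(), lo[1]), hi[1]),
        float(popt2[0]),
        float(popt2[1]),
    ]
    try:
        popt4, _ = curve_fit(_four_pl, conc, surv, p0=p0, bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError):
        return float(10.0 ** popt2[0]), sse2
    sse4 = float(np.sum((surv - _four_pl(conc, *popt4)) ** 2))
    if sse4 <= 0.0:
        prefer_free = sse2 > 0.0
    else:
        f_stat = ((sse2 - sse4) / 2.0) / (sse4 / df4)
        prefer_free = f_stat > 0 and float(f_dist.sf(f_stat, 2, df4)) < 0.05
    if prefer_free:
        return float(10.0 ** popt4[2]), sse4
    return float(10.0 ** popt2[0]), sse2


def _interpolate_crossing(conc: np.ndarray, surv: np.ndarray) -> float | None:
    """First 50% crossing, linear on the log-concentration axis."""
    logc = np.log(conc)
    for i in range(conc.size):
        if surv[i] == 50.0:
            return float(conc[i])
        if i + 1 < conc.size and (surv[i] - 50.0) * (surv[i + 1] - 50.0) < 0:
            w = (surv[i] - 50.0) / (surv[i] - surv[i + 1])
            return float(math.exp(logc[i] + w * (logc[i + 1] - logc[i])))
    return None


def fit_ic50(
    concentrations,
    pct_survival,
    sample: str = "sample",
    method: str = "auto",
    non_monotone_tol: float = 10.0,
) -> PhenotypeRow:
    """Estimate the IC50 of one survival curve.

    The primary estimator is a bounded four-parameter logistic fit
    (bottom in [0, 30], top in [70, 130], positive hill slope, IC50 within
    [min conc / 10, max conc * 10]); the assay normalises to a no-drug
    control near 100%, and an unbounded 4PL on six points is ill-posed.
    The plateaus are pinned at (0, 100) unless an F-test prefers freeing
    them — see :func:`_fit_fourpl`. When the fit fails to converge, or
    the curve rises by more than
    ``non_monotone_tol`` percentage points between adjacent concentrations,
    the estimator falls back to interpolating the 50% crossing on the log
    concentration axis. Curves with no 50% crossing are censored.

    ``method`` may force ``"fourpl"`` or ``"interp"``; ``"auto"`` applies
    the fallback rule above.
    """
    conc = np.asarray(concentrations, dtype=float)
    surv = np.asarray(pct_survival, dtype=float)
    if conc.size != surv.size:
        raise ValueError("concentrations and survival must have equal length")
    if conc.size < 4:
        raise ValueError("need at least 4 concentrations to fit a curve")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if np.any(surv < 0):
        raise ValueError("survival values must be >= 0")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    if method not in ("auto", "fourpl", "interp"):
        raise ValueError("method must be 'auto', 'fourpl' or 'interp'")

    # censoring: no 50% crossing within the tested range
    if surv.min() > 50.0:
        return PhenotypeRow(sample, None, None, "above_max", "censored", None)
    if surv.max() < 50.0:
        return PhenotypeRow(sample, None, None, "below_min", "censored", None)
    if surv[0] < 50.0:
        # already past the midpoint at the lowest dose: crossing is off-grid
        return PhenotypeRow(sample, None, None, "below_min", "censored", None)

    non_monotone = bool(np.max(np.diff(surv)) > non_monotone_tol)
    use_4pl = method == "fourpl" or (method == "auto" and not non_monotone)

    if use_4pl:
        try:
            ic50, sse = _fit_fourpl(conc, surv)
            return PhenotypeRow(sample, ic50, math.log2(ic50), "none", "fourpl", sse)
        except (RuntimeError, ValueError):
            if method == "fourpl":
                raise
            # fall through to interpolation

    crossing = _interpolate_crossing(conc, surv)
    if crossing is None:
        # noise wiggles prevented a clean bracket; censor on the side of
        # the final observation
        flag = "above_max" if surv[-1] > 50.0 else "below_min"
        return PhenotypeRow(sample, None, None, flag, "censored", None)
    return PhenotypeRow(
        sample, crossing, math.log2(crossing), "none", "interpolation", None
    )


def fit_ic50_table(dose_response: pd.DataFrame, method: str = "auto") -> pd.DataFrame:
    """Fit every sample of a tidy dose-response table.

    Expects columns ``sample``, ``concentration_uM``, ``pct_survival``
    with replicate-averaged values; returns one phenotype row per sample.
    """
    required = {"sample", "concentration_uM", "pct_survival"}
    if not required.issubset(dose_response.columns):
        raise ValueError(f"dose-response table needs columns {sorted(required)}")
    rows = []
    for sample, grp in dose_response.groupby("sample", sort=False):
        grp = grp.sort_values("concentration_uM")
        r = fit_ic50(
            grp["concentration_uM"].to_numpy(),
            grp["pct_survival"].to_numpy(),
            sample=str(sample),
            method=method,
        )
        rows.append(
            (r.sample, r.ic50_uM, r.log2_ic50, r.censor_flag, r.fit_method, r.sse)
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "ic50_uM", "log2_ic50", "censor_flag", "fit_method", "sse"],
    )


def log2_phenotypes(phenotypes: pd.DataFrame, alpha: float = 0.05):
    """log2 IC50 phenotype vector plus a normality report.

    Uses uncensored samples only. The report carries the Lilliefors
    (KS with estimated mean/SD) p-value and a pass flag at ``p >= alpha``.
    A constant phenotype vector is a degenerate input and raises.
    """
    ok = phenotypes[phenotypes["censor_flag"] == "none"]
    values = ok["log2_ic50"].astype(float)
    if len(values) < 3:
        raise ValueError("need >= 3 uncensored samples")
    if float(values.max() - values.min()) == 0.0:
        raise ValueError("constant phenotype vector: normality is undefined")
    stat, p = lilliefors(values.to_numpy(), dist="norm", pvalmethod="table")
    report = {
        "n": int(len(values)),
        "ks_stat": float(stat),
        "ks_p": float(p),
        "normal": bool(p >= alpha),
        "alpha": alpha,
    }
    vec = pd.Series(values.to_numpy(), index=ok["sample"].to_numpy(), name="log2_ic50")
    return vec, report


def ddct_fold_change(cts: QpcrCts, convention: str = "livak") -> dict:
    """qPCR relative expression by the ddCT method.

    ``ddct = (ct_target_condition - ct_reference_condition)
    - (ct_target_control - ct_reference_control)``. The standard Livak
    convention reports ``2**(-ddct)`` (default); ``convention="paper"``
    returns ``2**(+ddct)``, the reciprocal form some reports print. The
    convention used is recorded in the output so no reader has to guess.
    """
    if convention not in ("livak", "paper"):
        raise ValueError("convention must be 'livak' or 'paper'")
    ddct = (cts.ct_target_condition - cts.ct_reference_condition) - (
        cts.ct_target_control - cts.ct_reference_control
    )
    fold = 2.0 ** (-ddct) if convention == "livak" else 2.0**ddct
    return {"fold_change": fold, "ddct": ddct, "convention": convention}


def relative_resistance(q: SurvivalQuartet) -> float:
    """Relative change in drug resistance of a knockdown vs its control:
    ``(cond_drug / cond_control) / (scramble_drug / scramble_control)``.
    """
    if q.surv_scramble_drug == 0:
        raise ZeroDivisionError("scramble drug survival is 0: ratio undefined")
    return (q.surv_condition_drug / q.surv_condition_control) / (
        q.surv_scramble_drug / q.surv_scramble_control
    )
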