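"""Four-parameter logistic dose-response fitting and EC50 reporting.

The response of each assay endpoint to nanoparticle dose is summarized by

    y(x) = bottom + (top - bottom) / (1 + (x / EC50)^hill),

fit by least squares on log10 dose with multi-start initialization (EC50
seeded at tested-dose quantiles, Hill slope at +-1 and +-3) so the direction
of the curve is inferred from the data.  The zero-dose control is used only
for normalization upstream and never enters the fit.

A fit is *accepted* only if the per-dose means are monotone within a noise
allowance, the fit explains the data (r2 above threshold) and the EC50 lies
inside the tested dose range — mirroring how non-monotonic dose-effect
series (e.g. drug-loaded particles with a mid-dose rebound) must be
reported as "EC50 not determined" rather than forced through a sigmoid.

Control-comparison statistics follow the conventional plate-assay recipe:
a one-way ANOVA gate across all groups, then per-dose Welch comparisons
against the medium control with Holm step-down family-wise adjustment,
starred at p < 0.05 (*), < 0.01 (**) and < 0.001 (***).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class RejectionReason(str, Enum):
    none = "none"
    non_monotonic = "non_monotonic"
    poor_fit = "poor_fit"
    ec50_out_of_range = "ec50_out_of_range"
    fit_failed = "fit_failed"


@dataclass
class DoseResponseFit:
    """4PL parameters with goodness-of-fit and acceptance flags."""

    bottom: float = np.nan
    top: float = np.nan
    ec50: float = np.nan
    hill: float = np.nan
    r2: float = np.nan
    accepted: bool = False
    rejection_reason: RejectionReason = RejectionReason.fit_failed
    ec50_sd_across_experiments: float | None = None
    assay: str = ""
    condition: str = ""

    def predict(self, dose: np.ndarray) -> np.ndarray:
        x = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.power(x / self.ec50, self.hill)
        return self.bottom + (self.top - self.bottom) / (1.0 + ratio)


class FourParameterLogistic(BaseEstimator, RegressorMixin):
    """Sklearn-style 4PL regressor on positive doses.

    Parameters
    ----------
    max_nfev : int
        Optimizer budget per start.

    Attributes (after ``fit``)
    --------------------------
    bottom_, top_, ec50_, hill_ : float
        Canonicalized so ``hill_ > 0`` and ``top_`` is the zero-dose
        asymptote (the two sign conventions describe the same curve).
    r2_ : float
        1 - SS_res / SS_tot on the training data (0 when the responses are
        constant).
    converged_ : bool
    """

    def __init__(self, max_nfev: int = 400):
        self.max_nfev = max_nfev

    @staticmethod
    def _model(theta: np.ndarray, logx: np.ndarray) -> np.ndarray:
        bottom, top, log_ec50, hill = theta
        expo = np.clip(hill * (logx - log_ec50), -300.0, 300.0)
        return bottom + (top - bottom) / (1.0 + 10.0**expo)

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("doses and responses must have equal length")
        keep = x > 0
        x, y = x[keep], y[keep]
        if len(np.unique(x)) < 4:
            raise ValueError("need at least 4 distinct positive doses")
        if not np.all(np.isfinite(y)):
            raise ValueError("responses must be finite")
        logx = np.log10(x)
        lo, hi = float(y.min()), float(y.max())
        spread = hi - lo
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        best = None
        ec50_starts = np.quantile(logx, [0.25, 0.5, 0.75])
        for le in ec50_starts:
            for h in (1.0, -1.0, 3.0, -3.0):
                theta0 = np.array([lo, hi, le, h])
                try:
                    res = optimize.least_squares(
                        lambda th: self._model(th, logx) - y,
                        theta0,
                        max_nfev=self.max_nfev,
                        method="lm" if len(y) >= 4 else "trf",
                    )
                except Exception:
                    continue
                sse = float(np.sum(res.fun**2))
                if res.success and (best is None or sse < best[0]):
                    best = (sse, res.x)
        if best is None:
            self.converged_ = False
            self.bottom_ = self.top_ = self.ec50_ = self.hill_ = np.nan
            self.r2_ = np.nan
            return self
        sse, (bottom, top, log_ec50, hill) = best
        if hill < 0:  # canonicalize: same curve with hill > 0
            bottom, top, hill = top, bottom, -hill
        self.converged_ = True
        self.bottom_ = float(bottom)
        self.top_ = float(top)
        self.ec50_ = float(10.0**log_ec50)
        self.hill_ = float(hill)
        self.r2_ = 1.0 - sse / ss_tot if ss_tot > 0 else 0.0
        if spread == 0.0:
            self.r2_ = 0.0
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        theta = np.array([self.bottom_, self.top_, np.log10(self.ec50_), self.hill_])
        with np.errstate(divide="ignore"):
            logx = np.log10(x)
        return self._model(theta, logx)


def fit_four_parameter_logistic(
    doses, responses, assay: str = "", condition: str = ""
) -> DoseResponseFit:
    """Fit the 4PL and package the result (acceptance flags unset).

    Zero-dose points are excluded from the fit (the control only sets the
    normalization scale; log 0 is undefined).
    """
    est = FourParameterLogistic()
    try:
        est.fit(np.asarray(doses, dtype=float), np.asarray(responses, dtype=float))
    except ValueError:
        raise
    if not est.converged_ or not np.isfinite(est.ec50_):
        return DoseResponseFit(
            rejection_reason=RejectionReason.fit_failed, assay=assay, condition=condition
        )
    return DoseResponseFit(
        bottom=est.bottom_,
        top=est.top_,
        ec50=est.ec50_,
        hill=est.hill_,
        r2=est.r2_,
        accepted=False,
        rejection_reason=RejectionReason.none,
        assay=assay,
        condition=condition,
    )


@dataclass
class AcceptanceRules:
    """Configurable gates for reporting an EC50."""

    rebound_k_sem: float = 3.0
    r2_threshold: float = 0.8
    require_ec50_in_range: bool = True


def _per_dose_stats(doses: np.ndarray, responses: np.ndarray):
    df = pd.DataFrame({"dose": doses, "y": responses})
    g = df.groupby("dose")["y"]
    means = g.mean()
    sems = g.sem().fillna(0.0)
    return means.index.to_numpy(), means.to_numpy(), sems.to_numpy()


def is_non_monotonic(
    doses, responses, k_sem: float = 3.0
) -> bool:
    """Rebound detection on per-dose means.

    The overall direction is taken from the first and last dose means; any
    consecutive move against that direction exceeding ``k_sem`` combined
    standard errors marks the series non-monotone.
    """
    d, means, sems = _per_dose_stats(
        np.asarray(doses, dtype=float), np.asarray(responses, dtype=float)
    )
    if len(d) < 3:
        return False
    direction = -1.0 if means[-1] < means[0] else 1.0
    diffs = direction * np.diff(means)
    allow = k_sem * np.hypot(sems[:-1], sems[1:])
    return bool(np.any(diffs < -allow - 1e-12))


def assess_fit_acceptance(
    fit: DoseResponseFit,
    doses,
    responses,
    rules: AcceptanceRules | None = None,
) -> DoseResponseFit:
    """Set acceptance flags on a fit, in priority order:

    non-monotone response pattern > failed/poor fit > EC50 outside the
    tested dose range.
    """
    rules = rules or AcceptanceRules()
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    # monotonicity is a property of the data, checked before fit quality
    if is_non_monotonic(doses, responses, rules.rebound_k_sem):
        fit.accepted = False
        fit.rejection_reason = RejectionReason.non_monotonic
        return fit
    if fit.rejection_reason is RejectionReason.fit_failed:
        return fit
    if not np.isfinite(fit.r2) or fit.r2 < rules.r2_threshold:
        fit.accepted = False
        fit.rejection_reason = RejectionReason.poor_fit
        return fit
    pos = doses[doses > 0]
    if rules.require_ec50_in_range and not (pos.min() <= fit.ec50 <= pos.max()):
        fit.accepted = False
        fit.rejection_reason = RejectionReason.ec50_out_of_range
        return fit
    fit.accepted = True
    fit.rejection_reason = RejectionReason.none
    return fit


# ---------------------------------------------------------------------------
# control-comparison statistics
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            return s
    return ""


def compare_to_control(
    groups: dict[float, np.ndarray],
    control: np.ndarray,
    anova_alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Per-dose comparisons against the medium control.

    One-way ANOVA across control and all dose groups acts as a gate: if it
    does not reject at ``anova_alpha``, no comparison is starred.  Otherwise
    each dose group is Welch-tested against the control and the p-values are
    Holm step-down adjusted before star assignment.

    Returns ``(table, anova_p)`` where the table has columns
    ``dose, p_raw, p_adj, stars, tie_flag``.
    """
    control = np.asarray(control, dtype=float)
    arrays = [control] + [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("need at least 2 replicates per group")
    all_zero_var = all(np.var(a) == 0 for a in arrays)
    tie_flag = False
    if all_zero_var:
        tie_flag = True
        means = [a.mean() for a in arrays]
        anova_p = 1.0 if np.allclose(means, means[0]) else 0.0
        p_raw = np.array(
            [0.0 if g.mean() != control.mean() else 1.0
             for g in arrays[1:]]
        )
    else:
        anova_p = float(stats.f_oneway(*arrays).pvalue)
        p_raw = np.array(
            [
                float(stats.ttest_ind(g, control, equal_var=False).pvalue)
                for g in arrays[1:]
            ]
        )
        p_raw = np.nan_to_num(p_raw, nan=1.0)
    # Holm step-down adjustment
    order = np.argsort(p_raw)
    m = len(p_raw)
    p_adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p_raw[idx])
        p_adj[idx] = min(running, 1.0)
    gate_open = anova_p < anova_alpha
    table = pd.DataFrame(
        {
            "dose": list(groups.keys()),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "stars": [_stars(p) if gate_open else "" for p in p_adj],
            "tie_flag": tie_flag,
        }
    )
    return table, anova_p


# ---------------------------------------------------------------------------
# cross-experiment summary
# ---------------------------------------------------------------------------

def summarize_ec50_across_experiments(
    fits: dict[str, list[DoseResponseFit]]
) -> pd.DataFrame:
    """Mean +- SD of per-experiment EC50s, per condition/assay key.

    Conditions with no accepted fit are reported as not determined
    (NaN mean, ``n_accepted`` = 0); a single accepted fit yields an SD of
    NaN (not available).
    """
    rows = []
    for key, fit_list in fits.items():
        values = np.array([f.ec50 for f in fit_list if f.accepted], dtype=float)
        n = len(values)
        rows.append(
            {
                "condition": key,
                "n_experiments": len(fit_list),
                "n_accepted": n,
                "ec50_mean": float(values.mean()) if n else np.nan,
                "ec50_sd": float(values.std(ddof=1)) if n > 1 else np.nan,
                "determined": n > 0,
                "label": (
                    f"{values.mean():.3g} ± {values.std(ddof=1):.2g} µg/mL"
                    if n > 1
                    else (f"{values.mean():.3g} µg/mL" if n else "not determined")
                ),
            }
        )
    return pd.DataFrame(rows)
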