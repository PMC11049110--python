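"""WST-8 viability and LDH release normalizations.

WST-8 (metabolic activity, endpoint absorbance):

    viability% = 100 * (OD450-620(sample) - OD450-620(background))
                       / (OD450-620(neg. control) - OD450-620(background))

where the 620 nm read corrects for turbidity, the background wells (reagent
without cells) remove spontaneous WST-8 conversion, and the medium-control
mean defines 100%.

LDH (membrane damage, kinetic absorbance at 492 nm, read once per minute
for 30 min): the per-well LDH activity is the regression slope over the linear
range of the kinetic series, and

    release% = 100 * (mOD(sample) - mOD(neg. control))
                     / (mOD(pos. control) - mOD(neg. control))

so the medium control maps to 0% and digitonin full lysis to 100%.  Values
are reported unclamped; noisy wells may legitimately fall outside [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class PlateInvalidError(ValueError):
    """Control signals do not support normalization (e.g. control <= background)."""


# ---------------------------------------------------------------------------
# WST-8
# ---------------------------------------------------------------------------

def wst8_viability(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-well relative viability from a wide WST-8 table.

    Expects columns ``well_id, role, od450, od620`` (plus any condition
    metadata, which is carried through).  Background and negative-control
    wells are identified by ``role``; the negative-control mean maps to
    exactly 100%.  Returns the sample/control rows with a ``viability_pct``
    column.
    """
    required = {"well_id", "role", "od450", "od620"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"WST-8 table missing columns: {sorted(missing)}")
    df = plate.copy()
    df["od_diff"] = df["od450"] - df["od620"]
    bg = df.loc[df["role"] == "background", "od_diff"]
    neg = df.loc[df["role"] == "negative_control", "od_diff"]
    if bg.empty or neg.empty:
        raise ValueError("WST-8 normalization requires background and negative_control wells")
    bg_mean = float(bg.mean())
    denom = float(neg.mean()) - bg_mean
    if denom <= 0:
        raise PlateInvalidError(
            "plate invalid: negative-control WST-8 signal does not exceed background"
        )
    out = df[df["role"] != "background"].copy()
    out["viability_pct"] = 100.0 * ((out["od_diff"] - bg_mean) / denom)
    return out.drop(columns=["od_diff"])


# ---------------------------------------------------------------------------
# LDH kinetic slope
# ---------------------------------------------------------------------------

@dataclass
class SlopeFit:
    slope_od_per_min: float
    linear_range_min: tuple[float, float]
    r2: float
    nonlinear_flag: bool


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Least-squares line; returns (slope, intercept, r2, max_std_residual)."""
    n = len(t)
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 1e-30:
        r2 = 1.0 if ss_res <= 1e-30 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    dof = max(n - 2, 1)
    sd = np.sqrt(ss_res / dof)
    max_std_res = 0.0 if sd <= 1e-15 else float(np.max(np.abs(y - pred)) / sd)
    return float(slope), float(intercept), r2, max_std_res


def ldh_kinetic_slope(
    minutes: np.ndarray,
    od492: np.ndarray,
    min_window: int = 5,
    r2_threshold: float = 0.99,
    extend_k: float = 4.0,
    slope_step_fraction: float = 0.25,
) -> SlopeFit:
    """Slope of the linear range of one kinetic series.

    Linear-range detection is seed-and-extend: the ``min_window``-point
    window with the highest r2 (earliest on ties) seeds the range, which is
    then grown point by point (rightward first, then leftward) as long as
    each new point's predictive residual against the current fit stays
    within ``max(extend_k * s, slope_step_fraction * |slope| * dt)``, where
    ``s`` is the current residual standard deviation.  The absolute term
    keeps exactly-linear data extendable (``s = 0``) while rejecting a
    plateau point, whose deviation is a full slope-step; the relative term
    tolerates ordinary read noise.  The final window must reach
    ``r2 >= r2_threshold``; otherwise the full-series slope is returned
    with ``nonlinear_flag`` set.
    """
    t = np.asarray(minutes, dtype=float)
    y = np.asarray(od492, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("minutes and od492 must be equal-length 1D arrays")
    if len(t) < min_window:
        raise ValueError(f"series shorter than the minimal window ({min_window} points)")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time stamps must be strictly increasing")
    n = len(t)

    # seed: best min_window window (highest r2, earliest start on ties)
    best = None
    for start in range(0, n - min_window + 1):
        sl = slice(start, start + min_window)
        _, _, r2, _ = _ols_line(t[sl], y[sl])
        if best is None or r2 > best[0] + 1e-12:
            best = (r2, start)
    lo, hi = best[1], best[1] + min_window - 1  # inclusive bounds

    def _admits(lo: int, hi: int, idx: int) -> bool:
        slope, intercept, _, _ = _ols_line(t[lo : hi + 1], y[lo : hi + 1])
        pred = slope * t[idx] + intercept
        resid = abs(y[idx] - pred)
        ss_res = float(
            np.sum((y[lo : hi + 1] - (slope * t[lo : hi + 1] + intercept)) ** 2)
        )
        s = np.sqrt(ss_res / max(hi - lo - 1, 1))
        dt = abs(t[idx] - (t[hi] if idx > hi else t[lo]))
        float_floor = 1e-12 * max(1.0, float(np.max(np.abs(y))))
        return resid <= max(extend_k * s, slope_step_fraction * abs(slope) * dt, float_floor)

    grew = True
    while grew:
        grew = False
        if hi + 1 < n and _admits(lo, hi, hi + 1):
            hi += 1
            grew = True
        if lo - 1 >= 0 and _admits(lo, hi, lo - 1):
            lo -= 1
            grew = True

    slope, _, r2, _ = _ols_line(t[lo : hi + 1], y[lo : hi + 1])
    if r2 >= r2_threshold:
        return SlopeFit(
            slope_od_per_min=slope,
            linear_range_min=(float(t[lo]), float(t[hi])),
            r2=r2,
            nonlinear_flag=False,
        )
    slope, _, r2, _ = _ols_line(t, y)
    return SlopeFit(
        slope_od_per_min=slope,
        linear_range_min=(float(t[0]), float(t[-1])),
        r2=r2,
        nonlinear_flag=True,
    )


def ldh_slopes_table(ldh_long: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-well linear-range slopes from a long kinetic table.

    Expects columns ``well_id, minute, od492`` plus well metadata (constant
    within each well), returned alongside ``slope, linear_start, linear_end,
    fit_r2, nonlinear_flag``.
    """
    required = {"well_id", "minute", "od492"}
    missing = required - set(ldh_long.columns)
    if missing:
        raise ValueError(f"LDH table missing columns: {sorted(missing)}")
    rows = []
    meta_cols = [
        c for c in ldh_long.columns if c not in ("minute", "od492")
    ]
    for well_id, sub in ldh_long.groupby("well_id", sort=False):
        sub = sub.sort_values("minute")
        fit = ldh_kinetic_slope(sub["minute"].to_numpy(), sub["od492"].to_numpy(), **kwargs)
        row = {c: sub.iloc[0][c] for c in meta_cols}
        row.update(
            slope=fit.slope_od_per_min,
            linear_start=fit.linear_range_min[0],
            linear_end=fit.linear_range_min[1],
            fit_r2=fit.r2,
            nonlinear_flag=fit.nonlinear_flag,
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LDH release
# ---------------------------------------------------------------------------

def ldh_release_percent(slopes: pd.DataFrame) -> pd.DataFrame:
    """Per-well LDH release from a slopes table with ``role`` and ``slope``.

    The negative-control mean slope maps to exactly 0% and the digitonin
    positive-control mean to exactly 100%.
    """
    required = {"well_id", "role", "slope"}
    missing = required - set(slopes.columns)
    if missing:
        raise ValueError(f"slopes table missing columns: {sorted(missing)}")
    neg = slopes.loc[slopes["role"] == "negative_control", "slope"]
    pos = slopes.loc[slopes["role"] == "positive_control", "slope"]
    if neg.empty or pos.empty:
        raise ValueError(
            "LDH normalization requires negative_control and positive_control slopes"
        )
    neg_mean = float(neg.mean())
    pos_mean = float(pos.mean())
    if pos_mean <= neg_mean:
        raise PlateInvalidError(
            "plate invalid: digitonin control slope does not exceed medium control"
        )
    out = slopes[slopes["role"] != "background"].copy()
    out["release_pct"] = 100.0 * ((out["slope"] - neg_mean) / (pos_mean - neg_mean))
    return out
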