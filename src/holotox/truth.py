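"""Ground-truth dose-effect models for simulation.

A :class:`DoseEffectTruth` describes how a single toxicity endpoint responds
to nanoparticle dose through a four-parameter logistic (4PL).  Three endpoint
kinds are distinguished:

* ``proliferation`` — population dry-mass growth over 24 h (DHM readout),
  decreasing with dose;
* ``viability`` — metabolic activity (WST-8 readout), decreasing with dose;
* ``death`` — membrane damage / LDH release, increasing with dose.

The same truth objects drive the imaging branch (scene growth factors) and
the plate-reader branch (absorbance signals), which is the point of the
multimodal design: all readouts see the same underlying cell populations.
"""

from __future__ import annotations

from enum import Enum
from typing import Sequence

import numpy as np
from pydantic import BaseModel, model_validator


class Endpoint(str, Enum):
    proliferation = "proliferation"
    viability = "viability"
    death = "death"


def four_parameter_logistic(
    dose: np.ndarray | float,
    bottom: float,
    top: float,
    ec50: float,
    hill: float,
) -> np.ndarray | float:
    """Evaluate the 4PL ``y = bottom + (top - bottom) / (1 + (x/ec50)^hill)``.

    For ``hill > 0`` the curve runs from ``top`` at zero dose to ``bottom``
    at infinite dose; a negative ``hill`` flips the direction.  Zero dose is
    handled by taking the exact limit.
    """
    x = np.asarray(dose, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    y = np.empty_like(x)
    zero = x == 0.0
    # limit x -> 0+: (x/ec50)^hill -> 0 for hill > 0, -> inf for hill < 0
    y[zero] = top if hill > 0 else bottom
    ratio = np.power(x[~zero] / ec50, hill)
    y[~zero] = bottom + (top - bottom) / (1.0 + ratio)
    return float(y[0]) if scalar else y


class DoseEffectTruth(BaseModel):
    """4PL ground truth for one endpoint.

    ``top_true`` and ``bottom_true`` are response fractions: for the
    decreasing endpoints, the zero-dose response is ``top_true`` and the
    infinite-dose floor is ``bottom_true``; for the ``death`` endpoint the
    curve increases from ``bottom_true`` to ``top_true``.
    """

    ec50_true: float
    hill_true: float = 2.0
    top_true: float = 1.0
    bottom_true: float = 0.0
    endpoint: Endpoint = Endpoint.proliferation

    @model_validator(mode="after")
    def _check(self) -> "DoseEffectTruth":
        if self.ec50_true <= 0:
            raise ValueError("ec50_true must be positive")
        if self.hill_true <= 0:
            raise ValueError("hill_true must be positive (direction set by endpoint)")
        if self.top_true < self.bottom_true:
            raise ValueError("top_true must be >= bottom_true")
        return self

    def response(self, dose: np.ndarray | float) -> np.ndarray | float:
        """True response fraction at ``dose``.

        Decreasing endpoints fall from ``top_true`` toward ``bottom_true``;
        the ``death`` endpoint rises from ``bottom_true`` toward ``top_true``.
        """
        if self.endpoint is Endpoint.death:
            down = four_parameter_logistic(
                dose, self.bottom_true, self.top_true, self.ec50_true, self.hill_true
            )
            # mirror: increasing from bottom_true to top_true
            return self.top_true + self.bottom_true - down
        return four_parameter_logistic(
            dose, self.bottom_true, self.top_true, self.ec50_true, self.hill_true
        )


class NonMonotoneDoseEffect(BaseModel):
    """Piecewise dose-effect truth with an interior rebound.

    Emulates responses where a mid-dose recovery interrupts the monotone
    trend (as seen with drug-loaded particle formulations): the response
    drops at low dose, rebounds over an intermediate window, and falls to a
    floor at high dose.  Such series cannot be described by a sigmoid and a
    half-maximal dose is undefined; downstream fitting must reject them.
    """

    dip_dose: float = 0.2
    rebound_doses: tuple[float, float] = (4.0, 8.0)
    dip_level: float = 0.35
    rebound_level: float = 0.75
    floor_level: float = 0.05
    endpoint: Endpoint = Endpoint.proliferation

    def response(self, dose: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(dose, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        lo, hi = self.rebound_doses
        logx = np.log10(np.maximum(x, 1e-12))
        y = np.empty_like(x)
        for i, (d, lx) in enumerate(zip(x, logx)):
            if d <= self.dip_dose:
                # interpolate 1.0 -> dip_level approaching the dip dose
                t = 0.0 if d == 0 else min(1.0, d / self.dip_dose)
                y[i] = 1.0 + t * (self.dip_level - 1.0)
            elif d <= lo:
                t = (lx - np.log10(self.dip_dose)) / (np.log10(lo) - np.log10(self.dip_dose))
                y[i] = self.dip_level + t * (self.rebound_level - self.dip_level)
            elif d <= hi:
                y[i] = self.rebound_level
            else:
                t = min(1.0, (lx - np.log10(hi)) / 1.5)
                y[i] = self.rebound_level + t * (self.floor_level - self.rebound_level)
        if self.endpoint is Endpoint.death:
            y = 1.0 - y
        return float(y[0]) if scalar else y


def default_dose_series(n_doses: int = 8, low: float = 0.5, high: float = 512.0) -> np.ndarray:
    """Geometric dose series in ug/mL, mirroring a 2-fold/4-fold plate design."""
    if n_doses < 2:
        raise ValueError("need at least two doses")
    return np.geomspace(low, high, n_doses)


def staggered_sensitivity_truths(
    ec50_proliferation: float = 10.0,
    ec50_viability: float = 25.0,
    ec50_death: float = 60.0,
    hill: float = 2.0,
) -> dict[str, DoseEffectTruth]:
    """Truth set in which proliferation is the most sensitive endpoint.

    Proliferation arrest occurs at lower dose than metabolic shutdown, which
    in turn precedes membrane rupture — the ordering observed for unloaded
    polymeric nanoparticles, where the imaging readout flags toxicity at
    lower concentration than either biochemical assay.
    """
    if not (ec50_proliferation < ec50_viability < ec50_death):
        raise ValueError("expected ec50_proliferation < ec50_viability < ec50_death")
    return {
        "proliferation": DoseEffectTruth(
            ec50_true=ec50_proliferation, hill_true=hill, endpoint=Endpoint.proliferation
        ),
        "viability": DoseEffectTruth(
            ec50_true=ec50_viability, hill_true=hill, endpoint=Endpoint.viability
        ),
        "death": DoseEffectTruth(
            ec50_true=ec50_death, hill_true=hill, endpoint=Endpoint.death
        ),
    }


def monotone_means(responses: Sequence[float], increasing: bool) -> bool:
    """Check strict weak monotonicity of a response sequence."""
    arr = np.asarray(responses, dtype=float)
    diffs = np.diff(arr)
    return bool(np.all(diffs >= 0) if increasing else np.all(diffs <= 0))
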