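"""Dose-time equivalence between external beam and radionuclide exposure.

Using the modeled proportion of a DNA species as the damage proxy, an EBRT
dose D and a radionuclide incubation time t are equivalent when they leave
the same species proportion.  For the supercoiled basis with a shared S0,
equating S0 exp(-ksr_t t) with S0 exp(-ksr_D D) gives the closed forms

    D = (ksr_t / ksr_D) * t        and        t = (ksr_D / ksr_t) * D.

Uncertainties on the rates are propagated to first order (delta method) for
the ratio, assuming independent errors:

    se(D) = D * sqrt((se_t / ksr_t)^2 + (se_D / ksr_D)^2)

For the relaxed and linear species the proportion curves are not simple
exponentials; equivalence is computed by numerically inverting the target
fit's species curve on a monotone branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .kinetics import ExposureAxis, KineticParams, RateEstimate

__all__ = [
    "EquivalenceResult",
    "equivalent_dose",
    "equivalent_time",
    "equivalent_exposure_numeric",
]

_SPECIES = ("supercoiled", "relaxed", "linear")


@dataclass(frozen=True)
class EquivalenceResult:
    """An equivalent exposure with its propagated standard error."""

    value: float
    se: float
    axis: ExposureAxis
    basis_species: str = "supercoiled"
    rate_from: RateEstimate | None = None
    rate_to: RateEstimate | None = None
    given_exposure: float = 0.0

    def __str__(self) -> str:
        return (
            f"equivalent {self.axis.value}: {self.value:.3g} ± {self.se:.2g} "
            f"{self.axis.units} (basis: {self.basis_species})"
        )


def _ratio_with_se(
    num: RateEstimate, den: RateEstimate, exposure: float
) -> tuple[float, float]:
    """value = (num/den) * exposure with first-order error propagation."""
    if den.value <= 0.0:
        raise ValueError("denominator rate must be > 0")
    if exposure < 0.0:
        raise ValueError("exposure must be >= 0")
    value = num.value / den.value * exposure
    if exposure == 0.0:
        return 0.0, 0.0
    # gradient of (num/den)*exposure w.r.t. (num, den); independent errors
    se = np.hypot(
        exposure / den.value * num.se,
        num.value * exposure / den.value**2 * den.se,
    )
    return value, float(se)


def equivalent_dose(
    ksr_time: RateEstimate, ksr_dose: RateEstimate, t: float
) -> EquivalenceResult:
    """EBRT dose (Gy) producing the same supercoiled loss as ``t`` hours
    of radionuclide incubation: D = (ksr_t / ksr_D) t."""
    if ksr_time.axis is not ExposureAxis.TIME or ksr_dose.axis is not ExposureAxis.DOSE:
        raise ValueError("equivalent_dose needs a time-axis and a dose-axis rate")
    value, se = _ratio_with_se(ksr_time, ksr_dose, t)
    return EquivalenceResult(
        value=value,
        se=se,
        axis=ExposureAxis.DOSE,
        rate_from=ksr_time,
        rate_to=ksr_dose,
        given_exposure=t,
    )


def equivalent_time(
    ksr_dose: RateEstimate, ksr_time: RateEstimate, dose: float
) -> EquivalenceResult:
    """Incubation time (h) producing the same supercoiled loss as ``dose``
    Gy of EBRT: t = (ksr_D / ksr_t) D."""
    if ksr_time.axis is not ExposureAxis.TIME or ksr_dose.axis is not ExposureAxis.DOSE:
        raise ValueError("equivalent_time needs a dose-axis and a time-axis rate")
    value, se = _ratio_with_se(ksr_dose, ksr_time, dose)
    return EquivalenceResult(
        value=value,
        se=se,
        axis=ExposureAxis.TIME,
        rate_from=ksr_dose,
        rate_to=ksr_time,
        given_exposure=dose,
    )


def _species_curve(params: KineticParams, species: str):
    idx = _SPECIES.index(species)

    def f(x: float) -> float:
        return float(params.proportions(np.array([x]))[idx][0])

    return f


def _relaxed_peak(params: KineticParams, x_max: float) -> float:
    """Location of the relaxed-fraction maximum on [0, x_max]."""
    res = minimize_scalar(
        lambda x: -_species_curve(params, "relaxed")(x),
        bounds=(0.0, x_max),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def equivalent_exposure_numeric(
    params_a: KineticParams,
    params_b: KineticParams,
    species: str,
    x_a: float,
    *,
    branch: str | None = None,
    x_max: float | None = None,
    tol: float = 1e-12,
) -> float:
    """Exposure on axis B at which fit B's ``species`` proportion matches
    fit A's at ``x_a``.

    The same-damage principle applied to any species: solve
    P_b(x_b) = P_a(x_a) by bracketing root search on a monotone branch.
    Supercoiled is monotone decreasing and linear nondecreasing, so no
    branch choice is needed; the relaxed proportion is unimodal and requires
    ``branch="rising"`` or ``"falling"``.

    Raises ``ValueError`` when the target proportion is unattainable on the
    chosen branch (e.g. positive linear target under krl = ksl = 0).
    """
    if species not in _SPECIES:
        raise ValueError(f"unknown species {species!r}")
    if x_a < 0.0:
        raise ValueError("x_a must be >= 0")
    target = _species_curve(params_a, species)(x_a)
    f = _species_curve(params_b, species)

    if x_max is None:
        # span enough exposure for the slowest rate to act
        slowest = min(k for k in (params_b.ksr, params_b.krl) if k > 0) if (
            params_b.ksr > 0 or params_b.krl > 0
        ) else 1.0
        x_max = 50.0 / slowest

    if species == "supercoiled":
        lo, hi = 0.0, x_max
        if not (f(hi) - target) * (f(lo) - target) <= 0:
            raise ValueError(
                f"target supercoiled fraction {target:.6g} unattainable on [0, {x_max:g}]"
            )
    elif species == "linear":
        lo, hi = 0.0, x_max
        if f(hi) < target - 1e-12:
            raise ValueError(
                f"target linear fraction {target:.6g} unattainable (max {f(hi):.6g})"
            )
    else:
        if branch not in ("rising", "falling"):
            raise ValueError(
                "relaxed proportion is unimodal: pass branch='rising' or 'falling'"
            )
        peak = _relaxed_peak(params_b, x_max)
        lo, hi = (0.0, peak) if branch == "rising" else (peak, x_max)
        fl, fh = f(lo), f(hi)
        if not (min(fl, fh) - 1e-12 <= target <= max(fl, fh) + 1e-12):
            raise ValueError(
                f"target relaxed fraction {target:.6g} outside the {branch} branch "
                f"range [{min(fl, fh):.6g}, {max(fl, fh):.6g}]"
            )

    g = lambda x: f(x) - target
    if abs(g(lo)) <= tol:
        return lo
    if abs(g(hi)) <= tol:
        return hi
    x_b = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    if abs(g(x_b)) > 1e-9:
        raise RuntimeError(
            f"numeric inversion did not reach |dP| <= 1e-9 (residual {g(x_b):.3g})"
        )
    return float(x_b)
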