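"""Relative biological effectiveness (RBE) with delta-method uncertainties.

Three estimators are provided:

* ``rbe_max`` — the low-dose-limit RBE_M, the ratio of the linear (alpha)
  coefficients of the test and reference dose-response curves.
* ``dose_specific_rbe`` — the ratio of the reference-radiation dose
  producing a given yield (by curve inversion) to the test-radiation dose
  that actually produced it.
* ``rbe_np_only`` — the Schmid-style decomposition isolating the high-LET
  14N(n,p)14C component of a mixed neutron + (n,gamma) exposure, assuming
  the photon component acts with the reference radiation's alpha.

All standard errors are first-order (delta-method) propagations; ratios of
independent estimates are treated as uncorrelated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dose_response import DoseResponseCurve, invert_curve
from .errors import DomainError

__all__ = ["RbeResult", "rbe_max", "dose_specific_rbe", "rbe_np_only"]


@dataclass
class RbeResult:
    """An RBE value with its standard error and provenance."""

    value: float
    se: float
    method: str  # "max", "dose_specific" or "np_only"
    numerator_label: str = ""
    denominator_label: str = ""

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("RBE must be positive")
        if self.se < 0:
            raise ValueError("standard error must be non-negative")


def rbe_max(alpha_n: float, se_n: float, alpha_ref: float, se_ref: float,
            numerator_label: str = "neutron",
            denominator_label: str = "reference") -> RbeResult:
    """RBE_M = alpha_n / alpha_ref with the relative errors added in
    quadrature (delta method for a ratio of independent estimates)."""
    if alpha_n <= 0 or alpha_ref <= 0:
        raise DomainError("RBE_M requires positive alpha coefficients")
    value = alpha_n / alpha_ref
    se = value * math.hypot(se_n / alpha_n, se_ref / alpha_ref)
    return RbeResult(value, se, "max", numerator_label, denominator_label)


def dose_specific_rbe(neutron_dose_Gy: float, neutron_yield: float,
                      ref_curve: DoseResponseCurve,
                      neutron_yield_se: float = 0.0) -> RbeResult:
    """Iso-effect RBE: reference dose for the observed yield / neutron dose.

    The reference dose is obtained by inverting the reference curve at the
    neutron yield.  The SE propagates the reference-curve coefficient
    covariance through the inversion by implicit differentiation:
    dD/dtheta = -(1, D, D^2) / (alpha + 2 beta D).  Uncertainty in the
    measured neutron yield is ignored unless ``neutron_yield_se`` is given.
    """
    if neutron_dose_Gy <= 0:
        raise DomainError("neutron dose must be positive")
    d_ref = invert_curve(ref_curve, neutron_yield)
    value = d_ref / neutron_dose_Gy

    beta = ref_curve.beta if ref_curve.model == "linear_quadratic" else 0.0
    slope = ref_curve.alpha + 2.0 * beta * d_ref  # dA/dD at the matched dose
    basis = [1.0, d_ref] + ([d_ref ** 2] if ref_curve.model == "linear_quadratic" else [])
    grad = -np.asarray(basis) / slope
    var_dref = float(grad @ ref_curve.covariance() @ grad)
    if neutron_yield_se > 0.0:
        var_dref += (neutron_yield_se / slope) ** 2
    se = math.sqrt(max(var_dref, 0.0)) / neutron_dose_Gy
    return RbeResult(value, se, "dose_specific",
                     numerator_label=ref_curve.label or "reference",
                     denominator_label="neutron")


def rbe_np_only(alpha_n: float, se_n: float, alpha_ref: float, se_ref: float,
                f_np: float,
                numerator_label: str = "neutron (n,p)",
                denominator_label: str = "reference") -> RbeResult:
    """RBE_M of the (n,p) component alone, Schmid-style.

    Assuming the (n,gamma) dose fraction (1 - f_np) acts with the
    reference alpha, the (n,p)-only linear coefficient is

        alpha_np = (alpha_n - (1 - f_np) * alpha_ref) / f_np

    and RBE_M(n,p) = alpha_np / alpha_ref.  SEs propagate first-order in
    (alpha_n, alpha_ref), treated as independent.  With f_np = 1 this
    reduces exactly to ``rbe_max``.
    """
    if not 0.0 < f_np <= 1.0:
        raise DomainError("f_np must be in (0, 1]")
    if alpha_ref <= 0:
        raise DomainError("reference alpha must be positive")
    alpha_np = (alpha_n - (1.0 - f_np) * alpha_ref) / f_np
    if alpha_np <= 0:
        raise DomainError(
            "gamma component exceeds total response: alpha_np <= 0"
        )
    value = alpha_np / alpha_ref
    # value = alpha_n / (f * alpha_ref) - (1 - f)/f
    d_dn = 1.0 / (f_np * alpha_ref)
    d_dref = -alpha_n / (f_np * alpha_ref ** 2)
    se = math.hypot(d_dn * se_n, d_dref * se_ref)
    return RbeResult(value, se, "np_only", numerator_label, denominator_label)
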