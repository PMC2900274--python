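"""Temporal expression profile taxonomy.

A gene's log2 trajectory over larval time is modelled as a quadratic
``f(t) = b0 + b1*t + b2*t**2``.  Retained genes are classified into one of
eight non-flat shapes by the signs of the coefficients and the location of
the parabola's vertex relative to the sampled day interval:

* ``LU`` / ``LD`` — linear up / down (no curvature),
* ``QLVU`` / ``QLCU`` / ``QLVD`` / ``QLCD`` — monotone quadratics
  (quadratic-linear, convex/concave, up/down; vertex outside the interval),
* ``QV`` / ``QC`` — transient valley / peak (vertex strictly inside).

``FLAT`` is the null shape (no change in abundance over time).
"""

from __future__ import annotations

from enum import Enum


class ProfileClass(str, Enum):
    FLAT = "flat"
    LU = "LU"
    LD = "LD"
    QLVU = "QLVU"
    QLCU = "QLCU"
    QLVD = "QLVD"
    QLCD = "QLCD"
    QV = "QV"
    QC = "QC"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Generalized direction of change for each profile class.
DIRECTION = {
    ProfileClass.FLAT: "none",
    ProfileClass.LU: "up",
    ProfileClass.QLVU: "up",
    ProfileClass.QLCU: "up",
    ProfileClass.LD: "down",
    ProfileClass.QLVD: "down",
    ProfileClass.QLCD: "down",
    ProfileClass.QV: "transient",
    ProfileClass.QC: "transient",
}

UP_CLASSES = frozenset({ProfileClass.LU, ProfileClass.QLVU, ProfileClass.QLCU})
DOWN_CLASSES = frozenset({ProfileClass.LD, ProfileClass.QLVD, ProfileClass.QLCD})
TRANSIENT_CLASSES = frozenset({ProfileClass.QV, ProfileClass.QC})


def classify_coefficients(
    b1: float,
    b2: float,
    t_lo: float,
    t_hi: float,
    *,
    use_quadratic: bool = True,
    use_linear: bool = True,
    zero_tol: float = 0.0,
) -> ProfileClass:
    """Map quadratic coefficients to a profile class by the sign/vertex rule.

    ``b1`` and ``b2`` are the linear and quadratic coefficients of the day
    polynomial (any consistent parameterization: the vertex location and the
    average slope over ``[t_lo, t_hi]`` are invariant to centring).
    ``use_quadratic`` / ``use_linear`` gate whether each coefficient is
    treated as real (for fitted coefficients these encode statistical
    significance; for planted truth both are True and magnitude decides).

    The rule: no real curvature -> LU/LD by the sign of ``b1`` (FLAT if that
    too is nil); real curvature with the vertex strictly inside
    ``(t_lo, t_hi)`` -> transient QV (valley, ``b2 > 0``) or QC (peak,
    ``b2 < 0``); vertex outside -> monotone quadratic, direction taken from
    the mean slope over the interval, curvature from the sign of ``b2``.
    """
    if t_hi <= t_lo:
        raise ValueError("t_range must satisfy t_lo < t_hi")
    b2_real = use_quadratic and abs(b2) > zero_tol
    if not b2_real:
        # without real curvature the direction is the mean slope over the
        # interval (equals b1 when the discarded b2 is exactly zero)
        slope = b1 + b2 * (t_lo + t_hi)
        if not use_linear or abs(slope) <= zero_tol:
            return ProfileClass.FLAT
        return ProfileClass.LU if slope > 0 else ProfileClass.LD
    vertex = -b1 / (2.0 * b2)
    if t_lo < vertex < t_hi:
        return ProfileClass.QV if b2 > 0 else ProfileClass.QC
    # mean slope of f over [t_lo, t_hi] = b1 + b2*(t_lo + t_hi)
    mean_slope = b1 + b2 * (t_lo + t_hi)
    if mean_slope > 0:
        return ProfileClass.QLVU if b2 > 0 else ProfileClass.QLCU
    return ProfileClass.QLCD if b2 < 0 else ProfileClass.QLVD
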