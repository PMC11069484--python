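"""Reaction parameters, derived kinetic constants and validity diagnostics.

The irreversible Michaelis-Menten mechanism

    E + S <-> C -> E + P

is governed by the two-dimensional mass-action system for substrate ``s``
and enzyme-substrate complex ``c``,

    ds/dt = -k1*e0*s + (k1*s + k_minus1)*c
    dc/dt =  k1*e0*s - (k1*s + k_minus1 + k2)*c

with total enzyme ``e0`` and typical initial data ``(s0, 0)``.  At low
initial substrate the dynamics are well approximated by the linear
(pseudo-first-order) system obtained by evaluating the Jacobian at the
origin.  This module holds the parameter container shared by every other
module, the three derived concentration scales

    K_S = k_minus1 / k1          (complex equilibrium constant)
    K_M = (k_minus1 + k2) / k1   (Michaelis constant)
    K   = k2 / k1 = K_M - K_S    (Van Slyke-Cullen constant)

and the validity diagnostics for the linearization.  The comparison
envelopes bracketing the nonlinear solution are usable precisely when
``s0 < K``, and tight when ``s0 << K``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "ReactionParameters",
    "DerivedConstants",
    "ValidityReport",
    "QualityThresholds",
    "derived_constants",
    "in_region_D",
    "validity_report",
]


@dataclass(frozen=True)
class ReactionParameters:
    """Rate constants and initial condition of the Michaelis-Menten system.

    Parameters
    ----------
    k1 : float
        Second-order binding rate constant (concentration^-1 time^-1).
    k_minus1 : float
        First-order dissociation rate constant (time^-1).
    k2 : float
        First-order catalytic rate constant (time^-1).
    e0 : float
        Total enzyme concentration (concentration).
    s0 : float
        Initial substrate concentration (concentration).
    c0 : float, optional
        Initial complex concentration, default 0.  The initial point
        ``(s0, c0)`` must lie in the invariant region ``D``.

    All quantities are in arbitrary but mutually consistent units.
    """

    k1: float
    k_minus1: float
    k2: float
    e0: float
    s0: float
    c0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k1", "k_minus1", "k2", "e0", "s0"):
            value = getattr(self, name)
            if not value > 0.0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.c0 < 0.0:
            raise ValueError(f"c0 must be nonnegative, got {self.c0!r}")
        if self.c0 > self.e0:
            raise ValueError(
                f"c0={self.c0!r} exceeds total enzyme e0={self.e0!r}"
            )

    def with_s0(self, s0: float) -> "ReactionParameters":
        """Return a copy with a different initial substrate concentration."""
        return replace(self, s0=s0)

    def to_dict(self) -> dict[str, float]:
        return {
            "k1": self.k1,
            "k_minus1": self.k_minus1,
            "k2": self.k2,
            "e0": self.e0,
            "s0": self.s0,
            "c0": self.c0,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionParameters":
        known = {k: float(v) for k, v in d.items() if k in
                 ("k1", "k_minus1", "k2", "e0", "s0", "c0")}
        return cls(**known)


@dataclass(frozen=True)
class DerivedConstants:
    """The three derived concentration scales and the small parameter.

    ``K = K_M - K_S`` holds exactly (to round-off) by construction, and
    ``epsilon = s0 / K_S`` gauges the entrywise convergence of the
    comparison matrices to the linearization.
    """

    K_S: float
    K_M: float
    K: float
    epsilon: float


@dataclass(frozen=True)
class QualityThresholds:
    """Policy thresholds for the qualitative linearization grade.

    The theory gives only an asymptotic smallness condition ``s0 << K``;
    numeric cutoffs are implementation policy and configurable.
    """

    good: float = 0.1
    marginal: float = 0.5


@dataclass(frozen=True)
class ValidityReport:
    """Diagnostics on whether the pseudo-first-order bounds apply.

    ``bounds_valid`` is the strict condition ``s0 < K``: beyond it the
    upper comparison matrix H acquires a nonnegative eigenvalue and the
    upper estimates become useless.  ``linearization_quality`` is a
    qualitative grade of ``s0/K`` against the (configurable) thresholds.
    """

    s0_over_K: float
    epsilon: float
    bounds_valid: bool
    linearization_quality: str
    thresholds: QualityThresholds = field(default_factory=QualityThresholds)


def derived_constants(params: ReactionParameters) -> DerivedConstants:
    """Compute K_S, K_M, K and epsilon = s0/K_S from the rate constants."""
    K_S = params.k_minus1 / params.k1
    K_M = (params.k_minus1 + params.k2) / params.k1
    K = params.k2 / params.k1
    return DerivedConstants(K_S=K_S, K_M=K_M, K=K, epsilon=params.s0 / K_S)


def in_region_D(s: float, c: float, params: ReactionParameters) -> bool:
    """Membership test for the compact invariant region

        D = { (s, c) : s >= 0, 0 <= c <= e0, s + c <= s0 }.

    D is convex and positively invariant, and on D the off-diagonal
    entries of the Jacobian are nonnegative, i.e. the system is
    cooperative there -- the structural fact underlying the comparison
    envelopes.  All inequalities are inclusive.
    """
    return (s >= 0.0) and (0.0 <= c <= params.e0) and (s + c <= params.s0)


def validity_report(params: ReactionParameters,
                    thresholds: QualityThresholds | None = None) -> ValidityReport:
    """Grade the pseudo-first-order approximation for the given parameters.

    ``bounds_valid`` requires the strict inequality ``s0 < K`` (at
    equality the upper comparison matrix is singular).  The qualitative
    grade is policy: ``s0/K <= good`` -> "good", ``<= marginal`` ->
    "marginal", ``< 1`` -> "poor", otherwise "invalid-for-bounds".
    """
    if thresholds is None:
        thresholds = QualityThresholds()
    dc = derived_constants(params)
    ratio = params.s0 / dc.K
    if ratio <= thresholds.good:
        grade = "good"
    elif ratio <= thresholds.marginal:
        grade = "marginal"
    elif ratio < 1.0:
        grade = "poor"
    else:
        grade = "invalid-for-bounds"
    return ValidityReport(
        s0_over_K=ratio,
        epsilon=dc.epsilon,
        bounds_valid=ratio < 1.0,
        linearization_quality=grade,
        thresholds=thresholds,
    )
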