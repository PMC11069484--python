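"""Comparison envelopes bracketing the nonlinear solution, and the
empirical O(s0^2) convergence study.

For initial data (s0, 0) with s0 < K = k2/k1, the flows of the lower
matrix G and upper matrix H bracket both the nonlinear solution (s, c)
and the pseudo-first-order solution (s*, c*) component-wise for all
forward time:

    s_up >= s  >= s_low        s_up >= s*  >= s_low
    c_up >= c  >= c_low        c_up >= c*  >= c_low

Since G and H differ from the linearization by O(s0) entries, the
envelope collapses at rate s0 relative to s0, i.e. the absolute
approximation error |s - s*| (and |c - c*|) is of order s0^2.  The
convergence study measures that exponent empirically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .linear import build_matrices, closed_form_solution, eigenstructure
from .nonlinear import simulate_nonlinear
from .parameters import ReactionParameters, derived_constants
from .timecourse import default_time_grid

__all__ = [
    "BoundsEnvelope",
    "ConvergenceStudy",
    "bounds_envelope",
    "verify_ordering",
    "approximation_error",
    "convergence_study",
]

DEFAULT_ORDERING_TOL = 1e-7


@dataclass
class BoundsEnvelope:
    """Pointwise lower/upper concentration envelopes on a shared grid.

    ``valid`` records the strict usability condition s0 < K; when it
    fails the curves are still computed but the upper pair grows without
    bound (H has a nonnegative eigenvalue) and carries no bounding
    meaning.
    """

    t: np.ndarray
    s_low: np.ndarray
    s_up: np.ndarray
    c_low: np.ndarray
    c_up: np.ndarray
    valid: bool
    ordering_ok: bool | None = None
    max_violation: float | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class ConvergenceStudy:
    """Sup-norm errors of the linear approximation across an s0 sweep.

    ``normalized_errors`` are sup-errors divided by s0^2; their
    approximate constancy (and the log-log ``slope`` near 2) is the
    empirical signature of second-order convergence.  ``C_hat`` is the
    empirical constant sup(error / s0^2) — a measured stand-in, not a
    theoretically derived bound.
    """

    s0_values: np.ndarray
    sup_errors_s: np.ndarray
    sup_errors_c: np.ndarray
    normalized_errors: np.ndarray
    slope: float
    C_hat: float
    K_star_half: float


def bounds_envelope(params: ReactionParameters,
                    t: np.ndarray | None = None) -> BoundsEnvelope:
    """Lower (G) and upper (H) linear-flow envelopes from (s0, 0).

    Requires c0 = 0: the bracketing statement is for the typical initial
    condition shared by all four trajectories.
    """
    if params.c0 != 0.0:
        raise ValueError("bounds_envelope requires c0 = 0")
    mats = build_matrices(params)
    dc = derived_constants(params)
    valid = params.s0 < dc.K
    if t is None:
        t = default_time_grid(eigenstructure(mats["linear"]).lambda_slow)
    low = closed_form_solution(mats["lower_G"], params.s0, t)
    up = closed_form_solution(mats["upper_H"], params.s0, t)
    return BoundsEnvelope(
        t=np.asarray(t, float),
        s_low=low.s, s_up=up.s, c_low=low.c, c_up=up.c,
        valid=valid,
        meta={**params.to_dict(), "K": dc.K},
    )


def verify_ordering(params: ReactionParameters,
                    t: np.ndarray | None = None,
                    tolerance: float = DEFAULT_ORDERING_TOL,
                    rtol: float = 1e-10, atol: float = 1e-12) -> BoundsEnvelope:
    """Check all eight bracketing inequalities pointwise on the grid.

    Both the nonlinear solution and the pseudo-first-order solution are
    compared against the envelope at every grid point.  Returns the
    envelope with ``ordering_ok`` set and ``max_violation`` the largest
    signed violation (positive = a genuine violation beyond 0).
    """
    dc = derived_constants(params)
    if not params.s0 < dc.K:
        raise ValueError(
            f"ordering verification requires s0 < K (s0={params.s0}, K={dc.K})"
        )
    env = bounds_envelope(params, t)
    t = env.t
    full = simulate_nonlinear(params, t, rtol=rtol, atol=atol)
    lin = closed_form_solution(build_matrices(params)["linear"], params.s0, t)

    violations = []
    for inner_s, inner_c in ((full.s, full.c), (lin.s, lin.c)):
        violations.append(env.s_low - inner_s)   # s >= s_low
        violations.append(inner_s - env.s_up)    # s <= s_up
        violations.append(env.c_low - inner_c)
        violations.append(inner_c - env.c_up)
    max_violation = float(max(np.max(v) for v in violations))
    env.ordering_ok = max_violation <= tolerance
    env.max_violation = max_violation
    env.meta.update({"tolerance": tolerance})
    return env


def approximation_error(params: ReactionParameters,
                        t: np.ndarray | None = None,
                        rtol: float = 1e-10, atol: float = 1e-12
                        ) -> tuple[float, float]:
    """Sup-norm gaps (sup|s - s*|, sup|c - c*|) between the full and
    pseudo-first-order trajectories on a shared grid."""
    if t is None:
        t = default_time_grid(
            eigenstructure(build_matrices(params)["linear"]).lambda_slow)
    full = simulate_nonlinear(params, t, rtol=rtol, atol=atol)
    lin = closed_form_solution(build_matrices(params)["linear"], params.s0, t)
    return (float(np.max(np.abs(full.s - lin.s))),
            float(np.max(np.abs(full.c - lin.c))))


def convergence_study(params_base: ReactionParameters,
                      s0_values: Sequence[float],
                      rtol: float = 1e-10, atol: float = 1e-12
                      ) -> ConvergenceStudy:
    """Measure the convergence exponent of the linear approximation.

    For each s0 in a decreasing sequence (>= 4 values, each <= K/2),
    integrates the nonlinear system, evaluates the closed form on the
    same grid, and records the sup-norm error max(sup|s-s*|, sup|c-c*|).
    The log-log least-squares slope of error against s0 estimates the
    convergence order (theoretical value 2); C_hat = max(error / s0^2).

    The time grid is rebuilt per s0 from the linearization's slow
    eigenvalue, which does not depend on s0, so all sweeps share the
    same horizon.
    """
    s0_values = np.asarray(list(s0_values), dtype=float)
    if len(s0_values) < 4:
        raise ValueError("need at least 4 s0 values for a reliable slope")
    if np.any(np.diff(s0_values) >= 0):
        raise ValueError("s0_values must be strictly decreasing")
    dc = derived_constants(params_base)
    K_star_half = dc.K / 2.0
    if np.any(s0_values > K_star_half):
        raise ValueError(
            f"all s0 values must be <= K/2 = {K_star_half} for the "
            "second-order error estimate to apply"
        )
    errs_s, errs_c = [], []
    for s0 in s0_values:
        p = params_base.with_s0(float(s0))
        es, ec = approximation_error(p, rtol=rtol, atol=atol)
        errs_s.append(es)
        errs_c.append(ec)
    errs_s = np.array(errs_s)
    errs_c = np.array(errs_c)
    errors = np.maximum(errs_s, errs_c)
    slope = float(np.polyfit(np.log(s0_values), np.log(errors), 1)[0])
    normalized = errors / s0_values**2
    return ConvergenceStudy(
        s0_values=s0_values,
        sup_errors_s=errs_s,
        sup_errors_c=errs_c,
        normalized_errors=normalized,
        slope=slope,
        C_hat=float(np.max(normalized)),
        K_star_half=K_star_half,
    )
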