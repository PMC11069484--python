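"""Timescale separation analysis of the pseudo-first-order system.

The linearized system has two real negative eigenvalues, expressible in
the derived constants as

    lambda_{1,2} = (k1/2)*(K_M + e0) * (-1 +/- sqrt(1 - eta)),
    eta = 4*K*e0 / (K_M + e0)^2.

Linearity alone does not give timescale separation: the timescales (the
inverse absolute eigenvalues) differ strongly only when the separation
index eta is small.  eta is small notably when e0/K_M is small or K/K_M
is small; it approaches 1 when K_S ~ 0 and K_M ~ e0, in which case no
accurate one-dimensional reduction exists.  Under separation the slow
eigenvalue is approximately -k2*e0/(K_M + e0) (first-order Taylor in
eta), the dynamics collapse onto the slow eigenspace, asymptotically
spanned by

    v_hat_1 = (K_M - K*e0/(K_M + e0), e0),

and both concentrations decay as a single exponential at the reduced
rate k2*e0/(K_M + e0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .linear import build_matrices, eigenstructure
from .parameters import ReactionParameters, derived_constants
from .timecourse import TimeCourse, default_time_grid

__all__ = [
    "TimescaleReport",
    "separation_index",
    "slow_eigenvalue_approx",
    "reduced_model",
    "slow_eigenvector_compare",
    "timescale_report",
]

DEFAULT_ETA_THRESHOLD = 0.1


@dataclass(frozen=True)
class TimescaleReport:
    """Everything the eigenvalue analysis yields for one parameter set.

    ``separated`` applies the configurable policy threshold on eta (the
    theory states only "much less than 1").  ``relative_gap`` =
    |lambda_slow| / |lambda_fast| tends to 0 with eta.
    """

    eta: float
    e0_over_KM: float
    K_over_KM: float
    lambda_slow_exact: float
    lambda_fast_exact: float
    lambda_slow_approx: float
    relative_gap: float
    separated: bool
    eta_threshold: float
    v_hat_1: tuple[float, float]
    v_slow_exact: tuple[float, float]
    eigvec_angle: float
    reduced_rate: float


def separation_index(params: ReactionParameters) -> tuple[float, dict[str, float]]:
    """The dimensionless index eta = 4*K*e0/(K_M+e0)^2 plus the two
    sufficient smallness ratios (e0/K_M and K/K_M)."""
    dc = derived_constants(params)
    eta = 4.0 * dc.K * params.e0 / (dc.K_M + params.e0) ** 2
    return eta, {"e0_over_KM": params.e0 / dc.K_M, "K_over_KM": dc.K / dc.K_M}


def slow_eigenvalue_approx(params: ReactionParameters) -> float:
    """First-order slow-eigenvalue approximation -k2*e0/(K_M + e0).

    The error relative to the exact slow eigenvalue shrinks as eta^2
    (Taylor remainder of sqrt(1 - eta)).
    """
    dc = derived_constants(params)
    return -params.k2 * params.e0 / (dc.K_M + params.e0)


def exact_eigenvalues(params: ReactionParameters) -> tuple[float, float]:
    """Slow and fast eigenvalues in the K_M/K/e0 form.

    Algebraically identical to the (alpha, beta, gamma) route through
    the radicand identity (K_M - e0)^2 + 4*K_S*e0 = (K_M + e0)^2 - 4*K*e0.
    """
    dc = derived_constants(params)
    eta, _ = separation_index(params)
    half = 0.5 * params.k1 * (dc.K_M + params.e0)
    root = np.sqrt(1.0 - eta)
    return -half * (1.0 - root), -half * (1.0 + root)


def reduced_model(params: ReactionParameters,
                  t: np.ndarray | None = None,
                  initial: tuple[float, float] | None = None,
                  project_slow: bool = False,
                  eta_threshold: float = DEFAULT_ETA_THRESHOLD) -> TimeCourse:
    """The one-dimensional reduction: exponential decay at the reduced rate.

    Both components decay as exp(-k2*e0/(K_M+e0) * t) from the initial
    point.  With ``project_slow=True`` the initial point is first
    projected onto the slow eigenspace along the fast one — the
    asymptotically correct reduction; the default applies the decay to
    the raw initial data.  A warning (not an error) is emitted when the
    separation index exceeds the threshold, since the reduction is then
    inaccurate.
    """
    eta, _ = separation_index(params)
    if eta > eta_threshold:
        warnings.warn(
            f"separation index eta={eta:.4g} exceeds threshold "
            f"{eta_threshold}; the one-dimensional reduction may be inaccurate",
            stacklevel=2,
        )
    rate = -slow_eigenvalue_approx(params)
    if initial is None:
        initial = (params.s0, params.c0)
    s_init, c_init = initial
    if project_slow:
        eig = eigenstructure(build_matrices(params)["linear"])
        V = np.column_stack([eig.v_slow, eig.v_fast])
        coeffs = np.linalg.solve(V, np.array([s_init, c_init]))
        s_init = coeffs[0] * eig.v_slow[0]
        c_init = coeffs[0] * eig.v_slow[1]
    if t is None:
        t = default_time_grid(-rate)
    t = np.asarray(t, dtype=float)
    decay = np.exp(-rate * t)
    return TimeCourse(t, s_init * decay, c_init * decay, model_label="reduced",
                      meta={**params.to_dict(), "reduced_rate": rate,
                            "project_slow": project_slow, "eta": eta})


def slow_eigenvector_compare(params: ReactionParameters
                             ) -> tuple[np.ndarray, np.ndarray, float]:
    """Approximate vs exact slow eigenvector direction and their angle.

    Returns (v_hat_1, v_slow_exact, angle) with both directions unit-
    normalized.  The exact direction is
    ((K_M - e0) + sqrt((K_M - e0)^2 + 4*K_S*e0), 2*e0); the approximate
    one is v_hat_1 = (K_M - K*e0/(K_M+e0), e0).  The angle tends to 0 as
    eta -> 0.
    """
    dc = derived_constants(params)
    e0 = params.e0
    v_hat = np.array([dc.K_M - dc.K * e0 / (dc.K_M + e0), e0])
    radicand = (dc.K_M - e0) ** 2 + 4.0 * dc.K_S * e0
    v_exact = np.array([(dc.K_M - e0) + np.sqrt(radicand), 2.0 * e0])
    v_hat = v_hat / np.linalg.norm(v_hat)
    v_exact = v_exact / np.linalg.norm(v_exact)
    cosang = float(np.clip(np.dot(v_hat, v_exact), -1.0, 1.0))
    return v_hat, v_exact, float(np.arccos(cosang))


def timescale_report(params: ReactionParameters,
                     eta_threshold: float = DEFAULT_ETA_THRESHOLD
                     ) -> TimescaleReport:
    """Assemble the full timescale-separation report for one parameter set."""
    eta, ratios = separation_index(params)
    lam_slow, lam_fast = exact_eigenvalues(params)
    v_hat, v_exact, angle = slow_eigenvector_compare(params)
    return TimescaleReport(
        eta=eta,
        e0_over_KM=ratios["e0_over_KM"],
        K_over_KM=ratios["K_over_KM"],
        lambda_slow_exact=lam_slow,
        lambda_fast_exact=lam_fast,
        lambda_slow_approx=slow_eigenvalue_approx(params),
        relative_gap=abs(lam_slow) / abs(lam_fast),
        separated=eta <= eta_threshold,
        eta_threshold=eta_threshold,
        v_hat_1=(float(v_hat[0]), float(v_hat[1])),
        v_slow_exact=(float(v_exact[0]), float(v_exact[1])),
        eigvec_angle=angle,
        reduced_rate=-slow_eigenvalue_approx(params),
    )
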