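"""The pseudo-first-order (linear) systems and their closed-form solutions.

Three linear systems matter here, all of the two-dimensional Metzler form

    M = [[-alpha,  beta ],
         [ alpha, -gamma]]       alpha, beta, gamma > 0.

With the derived scales K_S, K_M they are, in units of k1:

* ``linear``  — the Jacobian of the nonlinear system at the origin,
  alpha = k1*e0, beta = k1*K_S, gamma = k1*K_M.  Its flow is the
  pseudo-first-order approximation proper.
* ``lower_G`` — gamma inflated to k1*(K_M + s0); its flow bounds the
  nonlinear solution from below, component-wise.
* ``upper_H`` — beta inflated to k1*(K_S + s0); its flow bounds it from
  above.  H loses stability exactly when s0 > K = k2/k1.

The lower/upper bracketing follows from Kamke's comparison theorem for
cooperative systems: on the invariant region D the off-diagonal Jacobian
entries of the nonlinear field are nonnegative, and the G/H fields bound
it from below/above there.

The discriminant Delta = (alpha-gamma)^2 + 4*alpha*beta is strictly
positive, so the eigenvalues are always real and distinct; the solution
started at (s0, 0) is an explicit two-exponential (bi-exponential)
expression, implemented here from the eigen-decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ReactionParameters, derived_constants
from .timecourse import TimeCourse, default_time_grid

__all__ = [
    "MetzlerMatrix2",
    "EigenStructure",
    "build_matrices",
    "eigenstructure",
    "closed_form_solution",
    "general_linear_solution",
    "linear_time_grid",
]


@dataclass(frozen=True)
class MetzlerMatrix2:
    """A 2x2 Metzler matrix [[-alpha, beta], [alpha, -gamma]] with positive entries."""

    alpha: float
    beta: float
    gamma: float
    label: str = "linear"

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([[-self.alpha, self.beta],
                         [self.alpha, -self.gamma]])

    @property
    def trace(self) -> float:
        return -(self.alpha + self.gamma)

    @property
    def det(self) -> float:
        return self.alpha * (self.gamma - self.beta)


@dataclass(frozen=True)
class EigenStructure:
    """Eigenvalues and eigenvector directions of a MetzlerMatrix2.

    ``lambda_slow`` is the eigenvalue closer to zero (the ``+sqrt(Delta)``
    branch), ``lambda_fast`` the more negative one.  The slow eigenvalue
    is negative iff gamma > beta, i.e. iff the matrix determinant
    alpha*(gamma - beta) is positive.
    """

    Delta: float
    lambda_slow: float
    lambda_fast: float
    v_slow: tuple[float, float]
    v_fast: tuple[float, float]


def build_matrices(params: ReactionParameters) -> dict[str, MetzlerMatrix2]:
    """The linearization Df(0) and its lower/upper comparison matrices G, H.

    As ``s0 -> 0`` both G and H converge entrywise to Df(0), which is the
    mechanism behind the O(s0^2) accuracy of the linear approximation.
    """
    dc = derived_constants(params)
    k1, e0, s0 = params.k1, params.e0, params.s0
    alpha = k1 * e0
    return {
        "linear": MetzlerMatrix2(alpha, k1 * dc.K_S, k1 * dc.K_M, "linear"),
        "lower_G": MetzlerMatrix2(alpha, k1 * dc.K_S, k1 * (dc.K_M + s0), "lower_G"),
        "upper_H": MetzlerMatrix2(alpha, k1 * (dc.K_S + s0), k1 * dc.K_M, "upper_H"),
    }


def eigenstructure(M: MetzlerMatrix2) -> EigenStructure:
    """Closed-form eigenvalues/eigenvectors of the Metzler family.

    Delta = (alpha+gamma)^2 - 4*alpha*(gamma-beta) = (alpha-gamma)^2 +
    4*alpha*beta >= 4*alpha*beta > 0, so both eigenvalues are real and
    distinct and no repeated-root branch is needed.  Eigenvectors follow
    the (beta, (alpha - gamma +/- sqrt(Delta))/2) convention.
    """
    a, b, g = M.alpha, M.beta, M.gamma
    Delta = (a - g) ** 2 + 4.0 * a * b
    if not Delta > 0.0:  # impossible for positive entries; guard loudly
        raise ArithmeticError(f"non-positive discriminant Delta={Delta}")
    sq = np.sqrt(Delta)
    lam_slow = 0.5 * (-(a + g) + sq)
    lam_fast = 0.5 * (-(a + g) - sq)
    v_slow = (b, 0.5 * (a - g + sq))
    v_fast = (b, 0.5 * (a - g - sq))
    return EigenStructure(Delta, lam_slow, lam_fast, v_slow, v_fast)


def linear_time_grid(params: ReactionParameters, n_points: int = 400) -> np.ndarray:
    """Default grid spanning 12 slow e-folds of the linearized system."""
    eig = eigenstructure(build_matrices(params)["linear"])
    return default_time_grid(eig.lambda_slow, n_points=n_points)


def _biexponential_terms(M: MetzlerMatrix2, s0: float):
    """Amplitude vectors (u_slow, u_fast) of the solution started at (s0, 0).

    The solution is u_slow*exp(lambda_slow*t) + u_fast*exp(lambda_fast*t)
    with amplitude pairs proportional to (-alpha+gamma+sqrt(Delta), 2*alpha)
    and (alpha-gamma+sqrt(Delta), -2*alpha), each scaled by s0/(2*sqrt(Delta)).
    """
    a, g = M.alpha, M.gamma
    eig = eigenstructure(M)
    sq = np.sqrt(eig.Delta)
    pref = s0 / (2.0 * sq)
    u_slow = pref * np.array([-a + g + sq, 2.0 * a])
    u_fast = pref * np.array([a - g + sq, -2.0 * a])
    return eig, u_slow, u_fast


def closed_form_solution(M: MetzlerMatrix2, s0: float,
                         t: np.ndarray | None = None,
                         c0: float = 0.0) -> TimeCourse:
    """Exact bi-exponential solution of the linear system started at (s0, 0).

    Parameters
    ----------
    M : MetzlerMatrix2
    s0 : float
        Initial substrate concentration; the initial complex must be 0.
    t : ndarray, optional
        Time grid (defaults to 12 slow e-folds, geometric spacing).
    c0 : float
        Accepted only as 0; a nonzero value raises and points the caller
        at :func:`general_linear_solution`.
    """
    if c0 != 0.0:
        raise ValueError(
            "closed_form_solution is specialised to initial value (s0, 0); "
            "use general_linear_solution for nonzero initial complex"
        )
    eig, u_slow, u_fast = _biexponential_terms(M, s0)
    if t is None:
        t = default_time_grid(eig.lambda_slow)
    t = np.asarray(t, dtype=float)
    e_slow = np.exp(eig.lambda_slow * t)
    e_fast = np.exp(eig.lambda_fast * t)
    s = u_slow[0] * e_slow + u_fast[0] * e_fast
    c = u_slow[1] * e_slow + u_fast[1] * e_fast
    return TimeCourse(t, s, c, model_label=M.label,
                      meta={"matrix": (M.alpha, M.beta, M.gamma), "s0": s0,
                            "method": "closed_form"})


def general_linear_solution(M: MetzlerMatrix2, s_init: float, c_init: float,
                            t: np.ndarray | None = None,
                            params: ReactionParameters | None = None) -> TimeCourse:
    """Exact linear-system trajectory from an arbitrary initial value.

    Extends the bi-exponential formula to any initial point via
    eigen-decomposition; reduces to :func:`closed_form_solution` when
    ``c_init = 0``.  If ``params`` is given and the initial value lies
    outside the invariant region D, a warning is emitted (the comparison
    semantics of the G/H flows are only guaranteed inside D) but the
    trajectory is still exact.
    """
    import warnings

    from .parameters import in_region_D

    if params is not None and not in_region_D(s_init, c_init, params):
        warnings.warn(
            f"initial value ({s_init}, {c_init}) outside region D; the "
            "trajectory is exact but comparison-bound semantics do not apply",
            stacklevel=2,
        )
    eig = eigenstructure(M)
    if t is None:
        t = default_time_grid(eig.lambda_slow)
    t = np.asarray(t, dtype=float)
    V = np.column_stack([eig.v_slow, eig.v_fast])
    coeffs = np.linalg.solve(V, np.array([s_init, c_init]))
    e_slow = np.exp(eig.lambda_slow * t)
    e_fast = np.exp(eig.lambda_fast * t)
    s = coeffs[0] * eig.v_slow[0] * e_slow + coeffs[1] * eig.v_fast[0] * e_fast
    c = coeffs[0] * eig.v_slow[1] * e_slow + coeffs[1] * eig.v_fast[1] * e_fast
    return TimeCourse(t, s, c, model_label=M.label,
                      meta={"matrix": (M.alpha, M.beta, M.gamma),
                            "s_init": s_init, "c_init": c_init,
                            "method": "eigen_decomposition"})
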