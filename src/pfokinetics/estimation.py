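"""Rate-constant estimation from progress curves via the closed form.

Because the pseudo-first-order solution is an explicit bi-exponential,

    s*(t) = A1*exp(lambda1*t) + A2*exp(lambda2*t)
    c*(t) = A *(exp(lambda1*t) - exp(lambda2*t)),   A = s0*alpha/sqrt(Delta)

a measured progress curve can be fitted directly and the microscopic
rate constants recovered algebraically from the fitted rates and
amplitudes — no stiff ODE solving inside the optimization loop.  With
s0 and e0 known (as in a real assay, where both are pipetted), the
inversion is exact on noiseless linear-model data:

    trace:      lambda1 + lambda2 = -(alpha + gamma)
    det:        lambda1 * lambda2 =  alpha * (gamma - beta)
    amplitude:  fixes alpha (for observable c: alpha = A*(lambda1-lambda2)/s0)

then k1 = alpha/e0, k2 = det/alpha, k_minus1 = -(trace) - alpha - k2.

The total-substrate observable s + c (and the product s0 - s - c) has
amplitudes determined by the two rates alone, so it identifies only two
of the three constants; recovery from those observables raises an
identifiability error.

Fitting uses variable projection: the optimizer searches only the two
rates (parametrized to keep lambda2 < lambda1 < 0) while the amplitudes
are solved by linear least squares at each step.  Initialization is by
exponential peeling — a log-linear fit of the tail for the slow rate,
then of the early-time remainder for the fast rate.

The module also generates synthetic progress curves (from either the
linear or the full nonlinear model, plus i.i.d. Gaussian noise) and
exposes the whole pipeline as a Model/Results pair:
:class:`ProgressCurveModel` and :class:`ProgressCurveResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .linear import build_matrices, closed_form_solution, linear_time_grid
from .nonlinear import simulate_nonlinear
from .parameters import ReactionParameters
from .timecourse import TimeCourse

__all__ = [
    "SyntheticDataset",
    "FitResult",
    "IdentifiabilityError",
    "generate_synthetic",
    "fit_biexponential",
    "recover_rate_constants",
    "ProgressCurveModel",
    "ProgressCurveResults",
]

OBSERVABLES = ("s", "c", "total", "product")


class IdentifiabilityError(ValueError):
    """The requested observable does not identify all three rate constants."""


# ---------------------------------------------------------------------------
# synthetic data
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A noisy synthetic progress curve with its generating truth attached.

    The truth is carried for later scoring only; the fitting interface
    (:func:`fit_biexponential`, :class:`ProgressCurveModel`) takes plain
    arrays plus the experimental knowns s0, e0 and never sees it.
    """

    t: np.ndarray
    y: np.ndarray
    observable: str
    noise_sd: float
    seed: int | None
    truth: ReactionParameters
    model: str
    clean: TimeCourse

    @property
    def timecourse(self) -> TimeCourse:
        """The underlying trajectory with noise injected into the
        observed channel (s or c; derived observables leave both clean)."""
        s = self.clean.s.copy()
        c = self.clean.c.copy()
        if self.observable == "s":
            s = self.y.copy()
        elif self.observable == "c":
            c = self.y.copy()
        return TimeCourse(self.t, s, c, model_label=self.clean.model_label,
                          meta={**self.clean.meta, "noise_sd": self.noise_sd,
                                "seed": self.seed, "observable": self.observable})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, self.observable: self.y})


def generate_synthetic(params: ReactionParameters,
                       t: np.ndarray | None = None,
                       observable: str = "c",
                       noise_sd: float = 0.0,
                       seed: int | None = None,
                       model: str = "linear",
                       truncate_at_zero: bool = False) -> SyntheticDataset:
    """Simulate a progress curve and add i.i.d. Gaussian noise.

    Parameters
    ----------
    model : {"linear", "full"}
        Generate from the pseudo-first-order closed form or from the
        full nonlinear system.  Fitting linear-form data back is the
        exact round trip; fitting full-model data probes the
        misspecification bias, which shrinks as s0/K decreases.
    noise_sd : float
        Standard deviation of additive homoscedastic Gaussian noise on
        the observed channel.
    truncate_at_zero : bool
        Clip noisy values at zero (off by default: untruncated noise
        keeps the estimator's statistical behaviour analyzable).
    """
    if observable not in OBSERVABLES:
        raise ValueError(f"unknown observable {observable!r}; one of {OBSERVABLES}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if t is None:
        t = linear_time_grid(params)
    t = np.asarray(t, dtype=float)
    if model == "linear":
        clean = closed_form_solution(build_matrices(params)["linear"],
                                     params.s0, t)
    elif model == "full":
        clean = simulate_nonlinear(params, t)
    else:
        raise ValueError(f"unknown model {model!r}; expected 'linear' or 'full'")
    y = clean.observable(observable, s0=params.s0).copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
        if truncate_at_zero:
            y = np.maximum(y, 0.0)
    return SyntheticDataset(t=t, y=y, observable=observable, noise_sd=noise_sd,
                            seed=seed, truth=params, model=model, clean=clean)


# ---------------------------------------------------------------------------
# bi-exponential fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Fitted rates and amplitudes of the bi-exponential progress curve.

    ``lambda_slow_hat`` is the rate closer to zero.  ``amplitudes`` has
    one entry for the constrained complex form A*(e1 - e2) and two
    (slow, fast) otherwise.  Recovered rate constants are filled in by
    :func:`recover_rate_constants`.
    """

    lambda_slow_hat: float
    lambda_fast_hat: float
    amplitudes: np.ndarray
    residual_rms: float
    converged: bool
    observable: str
    s0: float
    e0: float
    n_obs: int
    message: str = ""
    k1_hat: float | None = None
    k_minus1_hat: float | None = None
    k2_hat: float | None = None
    extras: dict[str, Any] = field(default_factory=dict)


def _design_matrix(t: np.ndarray, lam1: float, lam2: float,
                   observable: str) -> np.ndarray:
    e1 = np.exp(lam1 * t)
    e2 = np.exp(lam2 * t)
    if observable == "c":
        # Eq-structure constraint: amplitudes are +/-A for the two modes
        return (e1 - e2)[:, None]
    return np.column_stack([e1, e2])


def _peel_initial_rates(t: np.ndarray, y: np.ndarray,
                        observable: str) -> tuple[float, float]:
    """Exponential-peeling starting rates (slow, fast).

    Tail log-linear fit -> slow rate; early-time log-linear fit of the
    remainder after subtracting the slow mode -> fast rate.  Falls back
    to scale-based guesses when the data defeat the log fits.
    """
    t_max = t[-1]
    fallback_slow = -3.0 / t_max

    tail = (t > t_max / 3.0) & (np.abs(y) > 1e-12 * np.max(np.abs(y)))
    lam_slow = fallback_slow
    amp_slow = None
    if np.count_nonzero(tail) >= 3:
        sign = np.sign(np.median(y[tail])) or 1.0
        good = tail & (sign * y > 0)
        if np.count_nonzero(good) >= 3:
            slope, intercept = np.polyfit(t[good], np.log(sign * y[good]), 1)
            if slope < 0:
                lam_slow = slope
                amp_slow = sign * np.exp(intercept)

    lam_fast = 10.0 * lam_slow
    if amp_slow is not None:
        r = y - amp_slow * np.exp(lam_slow * t)
        early = (t > 0) & (t < t_max / 10.0) & (np.abs(r) > 1e-10 * np.max(np.abs(y)))
        if np.count_nonzero(early) >= 3:
            sign = np.sign(np.median(r[early])) or 1.0
            good = early & (sign * r > 0)
            if np.count_nonzero(good) >= 3:
                slope, _ = np.polyfit(t[good], np.log(sign * r[good]), 1)
                if slope < lam_slow:
                    lam_fast = slope
    return lam_slow, lam_fast


def fit_biexponential(t: np.ndarray, y: np.ndarray, observable: str,
                      s0: float, e0: float,
                      recover: bool = False) -> FitResult:
    """Least-squares fit of the bi-exponential closed-form shape.

    Variable projection over the two rates, parametrized as
    lambda1 = -exp(p1), lambda2 = lambda1 - exp(p2) so that
    lambda2 < lambda1 < 0 throughout; amplitudes solved linearly at
    each step.  The ``product`` observable is converted to total
    substrate (s0 - y) before fitting.

    Non-convergence is reported through ``converged=False`` with a
    diagnostic message, never as silently wrong numbers.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if observable not in OBSERVABLES:
        raise ValueError(f"unknown observable {observable!r}")
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-d arrays of equal length")
    if len(t) < 8:
        raise ValueError("need at least 8 samples spanning both timescales")
    if np.all(np.abs(y) < 1e-300) or np.ptp(y) == 0:
        raise ValueError("degenerate observable series (constant or zero)")

    fit_obs = observable
    if observable == "product":
        y = s0 - y       # product -> total substrate, a plain bi-exponential
        fit_obs = "total"

    lam_slow0, lam_fast0 = _peel_initial_rates(t, y, fit_obs)

    # rate bounds from the data timescales: the slow rate cannot be much
    # slower than the observation window nor faster than the sampling
    t_pos_min = t[t > 0].min()
    lo_slow, hi_slow = 1e-3 / t[-1], 50.0 / t_pos_min
    lo_gap, hi_gap = 1e-8 * lo_slow, 100.0 / t_pos_min
    bounds = (np.log([lo_slow, lo_gap]), np.log([hi_slow, hi_gap]))

    def rates(p):
        lam1 = -np.exp(p[0])
        lam2 = lam1 - np.exp(p[1])
        return lam1, lam2

    def residuals(p):
        lam1, lam2 = rates(p)
        X = _design_matrix(t, lam1, lam2, fit_obs)
        a, *_ = np.linalg.lstsq(X, y, rcond=None)
        return X @ a - y

    def start_from(lam_slow, lam_fast):
        p = np.array([np.log(-lam_slow), np.log(max(lam_slow - lam_fast, 1e-12))])
        return np.clip(p, bounds[0] + 1e-9, bounds[1] - 1e-9)

    # peeling start plus scale-based fallbacks guard against local minima
    scale = -3.0 / t[-1]
    starts = [start_from(lam_slow0, lam_fast0),
              start_from(scale, 20.0 * scale),
              start_from(scale, 200.0 * scale)]
    sol = None
    for p0 in starts:
        cand = least_squares(residuals, p0, method="trf", bounds=bounds,
                             xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000)
        if sol is None or cand.cost < sol.cost:
            sol = cand
    lam1, lam2 = rates(sol.x)
    X = _design_matrix(t, lam1, lam2, fit_obs)
    amps, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = X @ amps - y
    rms = float(np.sqrt(np.mean(resid**2)))
    converged = bool(sol.status > 0)
    message = sol.message if not converged else ""

    result = FitResult(
        lambda_slow_hat=float(lam1), lambda_fast_hat=float(lam2),
        amplitudes=np.asarray(amps, dtype=float),
        residual_rms=rms, converged=converged, observable=observable,
        s0=float(s0), e0=float(e0), n_obs=len(t),
        message=message,
        extras={"optimizer_status": int(sol.status), "nfev": int(sol.nfev),
                "init_rates": (lam_slow0, lam_fast0), "fit_observable": fit_obs,
                "residuals": resid},
    )
    if recover and result.converged:
        try:
            recover_rate_constants(result, s0, e0, observable)
        except IdentifiabilityError:
            raise
        except ValueError as exc:
            result.converged = False
            result.message = str(exc)
    return result


def recover_rate_constants(fit: FitResult, s0: float, e0: float,
                           observable: str | None = None
                           ) -> tuple[float, float, float]:
    """Algebraic inversion of the fitted bi-exponential to (k1, k_minus1, k2).

    For observable c, the single amplitude fixes alpha = A*(lam1-lam2)/s0;
    for observable s, the amplitude asymmetry does: the slow/fast
    amplitudes are s0*(-alpha+gamma+sqrt(Delta))/(2*sqrt(Delta)) and
    s0*(alpha-gamma+sqrt(Delta))/(2*sqrt(Delta)), whence
    gamma - alpha = (A_slow - A_fast)*(lam1 - lam2)/s0.  Combined with
    trace and determinant this yields all three constants, exactly on
    noiseless linear-model input.  Total/product observables identify
    the two rates but not alpha, and are rejected.
    """
    if observable is None:
        observable = fit.observable
    if not fit.converged:
        raise ValueError("cannot recover constants from a non-converged fit")
    lam1, lam2 = fit.lambda_slow_hat, fit.lambda_fast_hat
    if observable == "c":
        A = float(fit.amplitudes[0])
        alpha = A * (lam1 - lam2) / s0
    elif observable == "s":
        A_slow, A_fast = float(fit.amplitudes[0]), float(fit.amplitudes[1])
        gamma_minus_alpha = (A_slow - A_fast) * (lam1 - lam2) / s0
        alpha = 0.5 * (-(lam1 + lam2) - gamma_minus_alpha)
    else:
        raise IdentifiabilityError(
            f"observable {observable!r} determines only the two rates; "
            "alpha (hence k1) is not identifiable from it — measure s or c"
        )
    if alpha <= 0:
        fit.converged = False
        fit.message = (f"recovered alpha={alpha:.4g} not positive: model "
                       "misspecification or s0 too large for the linear regime")
        raise ValueError(fit.message)
    k1 = alpha / e0
    k2 = lam1 * lam2 / alpha
    k_minus1 = -(lam1 + lam2) - alpha - k2
    if min(k1, k2, k_minus1) <= 0:
        fit.converged = False
        fit.message = (
            f"non-positive recovered constants (k1={k1:.4g}, "
            f"k_minus1={k_minus1:.4g}, k2={k2:.4g}): model misspecification "
            "or s0 too large for the linear regime"
        )
        raise ValueError(fit.message)
    fit.k1_hat, fit.k_minus1_hat, fit.k2_hat = k1, k_minus1, k2
    return k1, k_minus1, k2


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class ProgressCurveModel:
    """Pseudo-first-order progress-curve model for one observed channel.

    Parameters
    ----------
    t, y : array_like
        Sample times and observed concentrations.
    observable : {"s", "c", "total", "product"}
        Which channel ``y`` records.
    s0, e0 : float
        Initial substrate and total enzyme — the experimental knowns.
        Only the three rate constants are estimated.

    Examples
    --------
    >>> ds = generate_synthetic(ReactionParameters(1, 1, 1, 1, 0.1),
    ...                         observable="c", noise_sd=0.001, seed=0)
    >>> res = ProgressCurveModel(ds.t, ds.y, "c", s0=0.1, e0=1.0).fit()
    >>> res.params.round(2)  # doctest: +SKIP
    k1          1.0
    k_minus1    1.0
    k2          1.0
    """

    def __init__(self, t, y, observable: str, s0: float, e0: float):
        self.t = np.asarray(t, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if observable not in OBSERVABLES:
            raise ValueError(f"unknown observable {observable!r}")
        self.observable = observable
        self.s0 = float(s0)
        self.e0 = float(e0)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, observable: str,
                       s0: float, e0: float, time_col: str = "t"
                       ) -> "ProgressCurveModel":
        if time_col not in df.columns:
            raise ValueError(f"missing time column {time_col!r}")
        if observable not in df.columns:
            raise ValueError(f"missing observable column {observable!r}")
        return cls(df[time_col].to_numpy(), df[observable].to_numpy(),
                   observable, s0, e0)

    def fit(self) -> "ProgressCurveResults":
        """Fit the bi-exponential and recover the rate constants.

        For the total/product observables only the two rates are
        estimated (the third constant is not identifiable); ``params``
        then carries NaN for the rate constants.
        """
        fit = fit_biexponential(self.t, self.y, self.observable,
                                self.s0, self.e0)
        identifiable = self.observable in ("s", "c")
        if fit.converged and identifiable:
            try:
                recover_rate_constants(fit, self.s0, self.e0, self.observable)
            except ValueError:
                pass  # converged flag + message already updated on fit
        return ProgressCurveResults(self, fit)

    def predict(self, fit: FitResult, t=None) -> np.ndarray:
        """Evaluate the fitted bi-exponential at the given times."""
        t = self.t if t is None else np.asarray(t, dtype=float)
        fit_obs = "total" if self.observable == "product" else self.observable
        X = _design_matrix(t, fit.lambda_slow_hat, fit.lambda_fast_hat, fit_obs)
        yhat = X @ fit.amplitudes
        if self.observable == "product":
            yhat = self.s0 - yhat
        return yhat


class ProgressCurveResults:
    """Estimates, rough standard errors and diagnostics of a fitted
    progress curve.

    ``params`` holds the recovered rate constants; ``rates`` the two
    exponential rates; ``bse`` residual-based standard errors obtained
    from the local linearization of the fit (delta method for the rate
    constants).  These are rough errors — no small-sample or
    correlated-noise corrections.
    """

    def __init__(self, model: ProgressCurveModel, fit: FitResult):
        self.model = model
        self.fit_result = fit
        self.converged = fit.converged
        self.rates = pd.Series(
            {"lambda_slow": fit.lambda_slow_hat,
             "lambda_fast": fit.lambda_fast_hat})
        self.amplitudes = fit.amplitudes
        self.params = pd.Series(
            {"k1": np.nan if fit.k1_hat is None else fit.k1_hat,
             "k_minus1": np.nan if fit.k_minus1_hat is None else fit.k_minus1_hat,
             "k2": np.nan if fit.k2_hat is None else fit.k2_hat})
        self.fittedvalues = model.predict(fit)
        self.resid = model.y - self.fittedvalues
        self.residual_rms = fit.residual_rms
        self.nobs = fit.n_obs
        self._bse: pd.Series | None = None

    @property
    def bse(self) -> pd.Series:
        if self._bse is None:
            self._bse = self._compute_bse()
        return self._bse

    def _theta(self) -> np.ndarray:
        return np.concatenate([[self.fit_result.lambda_slow_hat,
                                self.fit_result.lambda_fast_hat],
                               self.fit_result.amplitudes])

    def _predict_theta(self, theta: np.ndarray) -> np.ndarray:
        fit_obs = ("total" if self.model.observable == "product"
                   else self.model.observable)
        X = _design_matrix(self.model.t, theta[0], theta[1], fit_obs)
        yhat = X @ theta[2:]
        if self.model.observable == "product":
            yhat = self.model.s0 - yhat
        return yhat

    def _recover_theta(self, theta: np.ndarray) -> np.ndarray:
        stub = FitResult(
            lambda_slow_hat=theta[0], lambda_fast_hat=theta[1],
            amplitudes=theta[2:], residual_rms=0.0, converged=True,
            observable=self.model.observable, s0=self.model.s0,
            e0=self.model.e0, n_obs=self.nobs)
        return np.array(recover_rate_constants(
            stub, self.model.s0, self.model.e0, self.model.observable))

    def _compute_bse(self) -> pd.Series:
        theta = self._theta()
        n, k = self.nobs, len(theta)
        # Jacobian of the prediction wrt (rates, amplitudes)
        J = np.empty((n, k))
        y0 = self._predict_theta(theta)
        for j in range(k):
            h = 1e-7 * max(abs(theta[j]), 1e-3)
            tp = theta.copy()
            tp[j] += h
            J[:, j] = (self._predict_theta(tp) - y0) / h
        dof = max(n - k, 1)
        sigma2 = float(np.sum(self.resid**2)) / dof
        try:
            cov_theta = sigma2 * np.linalg.inv(J.T @ J)
        except np.linalg.LinAlgError:
            cov_theta = np.full((k, k), np.nan)
        out = {"lambda_slow": np.sqrt(abs(cov_theta[0, 0])),
               "lambda_fast": np.sqrt(abs(cov_theta[1, 1]))}
        if self.model.observable in ("s", "c") and self.converged:
            # delta method through the algebraic recovery map
            G = np.empty((3, k))
            base = self._recover_theta(theta)
            for j in range(k):
                h = 1e-7 * max(abs(theta[j]), 1e-3)
                tp = theta.copy()
                tp[j] += h
                try:
                    G[:, j] = (self._recover_theta(tp) - base) / h
                except ValueError:
                    G[:, j] = np.nan
            cov_k = G @ cov_theta @ G.T
            for i, name in enumerate(("k1", "k_minus1", "k2")):
                out[name] = np.sqrt(abs(cov_k[i, i]))
        return pd.Series(out)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "Pseudo-first-order progress-curve fit",
            "=" * 53,
            f"Observable:        {self.model.observable}",
            f"N observations:    {self.nobs}",
            f"Known s0, e0:      {self.model.s0:g}, {self.model.e0:g}",
            f"Converged:         {self.converged}",
            f"Residual RMS:      {self.residual_rms:.4e}",
            "-" * 53,
            f"{'parameter':<14}{'estimate':>16}{'std err':>16}",
            "-" * 53,
        ]
        bse = self.bse
        for name, val in self.rates.items():
            se = bse.get(name, np.nan)
            lines.append(f"{name:<14}{val:>16.6g}{se:>16.3g}")
        for name, val in self.params.items():
            if np.isnan(val):
                continue
            se = bse.get(name, np.nan)
            lines.append(f"{name:<14}{val:>16.6g}{se:>16.3g}")
        if self.fit_result.message:
            lines += ["-" * 53, f"note: {self.fit_result.message}"]
        lines.append("=" * 53)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        status = "converged" if self.converged else "NOT converged"
        return (f"<ProgressCurveResults observable={self.model.observable!r} "
                f"{status} nobs={self.nobs}>")
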