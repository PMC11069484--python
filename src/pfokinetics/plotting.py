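"""Optional matplotlib helpers (requires the ``plot`` extra)."""

from __future__ import annotations

import numpy as np

from .bounds import bounds_envelope
from .linear import build_matrices, closed_form_solution, linear_time_grid
from .nonlinear import simulate_nonlinear
from .parameters import ReactionParameters


def plot_envelope(params: ReactionParameters, axes=None):
    """Two panels (s and c): full solution, pseudo-first-order solution
    and the lower/upper comparison envelopes, on scaled time t/T."""
    import matplotlib.pyplot as plt

    t = linear_time_grid(params)
    full = simulate_nonlinear(params, t)
    lin = closed_form_solution(build_matrices(params)["linear"], params.s0, t)
    env = bounds_envelope(params, t)
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    x = t / t[-1]
    for ax, channel in zip(axes, ("s", "c")):
        ax.plot(x, getattr(full, channel), "k-", lw=2, label="full")
        ax.plot(x, getattr(lin, channel), color="gold", lw=3, alpha=0.8,
                label="linear")
        ax.plot(x, getattr(env, f"{channel}_low"), "b-.", lw=1, label="lower")
        ax.plot(x, getattr(env, f"{channel}_up"), "r:", lw=1.5, label="upper")
        ax.set_xlabel("t / T")
        ax.set_ylabel(channel)
    axes[0].legend(frameon=False)
    axes[0].figure.suptitle(
        f"s0={params.s0:g}, K={params.k2 / params.k1:g}"
        + ("" if env.valid else "  (upper bounds not valid: s0 >= K)"))
    return axes


def plot_fit(results, ax=None):
    """Observed points, fitted bi-exponential and residuals of a
    ProgressCurveResults object."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    m = results.model
    ax.plot(m.t, m.y, ".", ms=3, alpha=0.5, label="observed")
    ax.plot(m.t, results.fittedvalues, "r-", lw=1.5, label="fit")
    ax.set_xlabel("t")
    ax.set_ylabel(m.observable)
    ax.legend(frameon=False)
    return ax
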