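"""Plotting helpers for trajectories and experiment results.

All functions render to a file path with the non-interactive Agg backend
and return the path, so they are safe in headless batch runs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .gillespie import EnsembleSummary, Trajectory  # noqa: E402
from .meanfield import MeanFieldTrajectory  # noqa: E402

__all__ = [
    "plot_mean_decay",
    "plot_trajectory",
    "plot_histogram_evolution",
    "plot_variance_vs_lambda",
    "plot_phase_diagram",
    "plot_absorption_scaling",
]


def _finish(fig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_trajectory(traj, path) -> Path:
    """Mean and variance of the production degree over time."""
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 5))
    ax1.plot(traj.times, traj.means, color="tab:green")
    ax1.set_ylabel(r"$\langle p \rangle$")
    ax2.plot(traj.times, traj.variances, color="tab:orange")
    ax2.set_ylabel(r"$\mathrm{Var}(p)$")
    ax2.set_xlabel("time $t$")
    return _finish(fig, path)


def plot_mean_decay(times, means, path, guide_slope: float = -1.0) -> Path:
    """Log-log decay of <p>(t) with a power-law guide line."""
    times = np.asarray(times, float)
    means = np.asarray(means, float)
    sel = (times > 0) & (means > 0)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.loglog(times[sel], means[sel], label=r"$\langle p \rangle(t)$")
    t0 = times[sel][len(times[sel]) // 2]
    m0 = means[sel][len(means[sel]) // 2]
    ax.loglog(times[sel], m0 * (times[sel] / t0) ** guide_slope, "k--",
              label=rf"$t^{{{guide_slope:g}}}$ guide")
    ax.set_xlabel("time $t$")
    ax.set_ylabel(r"$\langle p \rangle$")
    ax.legend()
    return _finish(fig, path)


def plot_histogram_evolution(result, path) -> Path:
    """Heatmap of the (pooled) production-degree histogram over time."""
    if isinstance(result, (Trajectory,)):
        hists, times = result.histograms, result.times
    elif isinstance(result, EnsembleSummary):
        hists, times = result.pooled_histograms, result.times
    else:
        raise TypeError("expected a Trajectory or EnsembleSummary")
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(np.asarray(hists).T, origin="lower", aspect="auto",
                   extent=(times[0], times[-1], 0.0, 1.0), cmap="Greens")
    fig.colorbar(im, ax=ax, label="count")
    ax.set_xlabel("time $t$")
    ax.set_ylabel("production degree $p$")
    return _finish(fig, path)


def plot_variance_vs_lambda(result, path) -> Path:
    """Simulated quasi-stationary variance against the analytic curve."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(result["lam_grid"], result["analytic_variance"], "k-",
            label=r"$\beta(R(\beta)-\beta)$")
    ax.plot(result["lam_grid"], result["sim_variance"], "ro",
            label="simulation")
    ax.set_xlabel(r"response probability $\lambda$")
    ax.set_ylabel(r"$\mathrm{Var}(p)_\infty$")
    ax.legend()
    return _finish(fig, path)


def plot_phase_diagram(result, path) -> Path:
    """Heterogeneity indicator over the (lambda, kappa) plane."""
    fig, ax = plt.subplots(figsize=(5, 4))
    lam, kap = result["lam_grid"], result["kappa_grid"]
    im = ax.pcolormesh(lam, kap, result["indicator"].T, shading="nearest",
                       cmap="viridis")
    fig.colorbar(im, ax=ax, label="time-averaged Var(p)")
    ax.axvline(result["lambda_up"], color="k",
               label=r"$\lambda_{\mathrm{up}} = s/2$")
    ax.set_xlabel(r"response probability $\lambda$")
    ax.set_ylabel(r"up-regulation magnitude $\kappa$")
    ax.legend(loc="upper right")
    return _finish(fig, path)


def plot_absorption_scaling(fit, path) -> Path:
    """Geometric-mean absorption time vs N on a semilog axis."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(fit.N_values, fit.geometric_means,
                yerr=[fit.geometric_means - fit.spread_low,
                      fit.spread_high - fit.geometric_means],
                fmt="o", color="tab:blue", label=r"$T_{\mathrm{abs}}$")
    ns = np.linspace(fit.N_values[0], fit.N_values[-1], 50)
    ref = fit.geometric_means[0] * np.exp(fit.gamma * (ns - fit.N_values[0]))
    ax.plot(ns, ref, "k--", label=rf"$e^{{\gamma N}}$, $\gamma$={fit.gamma:.2g}")
    ax.set_yscale("log")
    ax.set_xlabel("population size $N$")
    ax.set_ylabel(r"$T_{\mathrm{abs}}$")
    ax.legend()
    return _finish(fig, path)
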