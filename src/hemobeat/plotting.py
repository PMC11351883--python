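"""Comparison plots for estimated vs measured hemodynamic parameters."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .labels import PARAM_NAMES

_UNITS = {"sbp": "mmHg", "dbp": "mmHg", "mrr": "mmHg/s", "mrd": "mmHg/s"}


def plot_beat_traces(estimated: np.ndarray, measured: np.ndarray, path=None):
    """Beat-index traces of estimated vs measured values, one panel per parameter."""
    fig, axes = plt.subplots(4, 1, figsize=(9, 10), sharex=True)
    for j, (ax, name) in enumerate(zip(axes, PARAM_NAMES)):
        ax.plot(measured[:, j], lw=0.8, label="measured")
        ax.plot(estimated[:, j], lw=0.8, label="estimated")
        ax.set_ylabel(f"{name.upper()} ({_UNITS[name]})")
    axes[0].legend(loc="upper right")
    axes[-1].set_xlabel("beat index")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_scatter(estimated: np.ndarray, measured: np.ndarray, path=None):
    """Estimated-vs-measured scatter with the identity line, per parameter."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for j, (ax, name) in enumerate(zip(axes.ravel(), PARAM_NAMES)):
        ax.plot(measured[:, j], estimated[:, j], ".", ms=2, alpha=0.5)
        lims = [min(measured[:, j].min(), estimated[:, j].min()),
                max(measured[:, j].max(), estimated[:, j].max())]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel(f"measured {name.upper()} ({_UNITS[name]})")
        ax.set_ylabel(f"estimated {name.upper()}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_parameter_density(values_by_subject: dict[str, np.ndarray], parameter: str, path=None):
    """Per-subject probability density of one parameter (optional utility)."""
    from scipy.stats import gaussian_kde

    fig, ax = plt.subplots(figsize=(7, 4))
    for subject, vals in values_by_subject.items():
        vals = np.asarray(vals, dtype=float)
        if np.std(vals) == 0:
            continue
        grid = np.linspace(vals.min(), vals.max(), 200)
        ax.plot(grid, gaussian_kde(vals)(grid), label=subject)
    ax.set_xlabel(f"{parameter.upper()} ({_UNITS.get(parameter, '')})")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
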