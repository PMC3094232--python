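"""Deterministic figure rendering: discrepancy/intensity heat maps and z densities."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .io_maps import ArmdynError

# high values light (yellow), low values dark — hot/cold spots read directly off the map
_CMAP = "inferno"

plt.rcParams["svg.hashsalt"] = "armdyn"


def render_heat_map(matrix: np.ndarray, row_labels, col_labels, mode: str = "discrepancy",
                    path=None, title: str | None = None):
    """Heat map of a discrepancy or intensity matrix (rows: species 1 regions)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ArmdynError("empty matrix")
    if not np.isfinite(matrix).all():
        raise ArmdynError("matrix must be finite")
    if matrix.shape != (len(row_labels), len(col_labels)):
        raise ArmdynError("labels do not match matrix shape")
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(col_labels), 1.0 + 0.6 * len(row_labels)))
    vmin, vmax = matrix.min(), matrix.max()
    if vmin == vmax:                       # constant matrix: pin a degenerate scale
        vmin, vmax = vmin - 0.5, vmax + 0.5
    im = ax.imshow(matrix, cmap=_CMAP, vmin=vmin, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(col_labels)), col_labels, rotation=45, ha="right")
    ax.set_yticks(range(len(row_labels)), row_labels)
    default_titles = {"discrepancy": "(O - E)^2 / E", "intensity": "posterior gamma"}
    ax.set_title(title if title is not None else default_titles.get(mode, mode))
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
        plt.close(fig)
    return fig


def render_density(samples_by_arm: dict[str, np.ndarray], path=None,
                   xlabel: str = "z = lambda_diff * gamma_diff / L"):
    """Gaussian-KDE curves of the per-arm z posteriors on one shared axis.

    Bandwidth is Scott's rule (fixed); degenerate constant samples fall back
    to a vertical line at the constant.
    """
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for arm, samples in samples_by_arm.items():
        samples = np.asarray(samples, dtype=float)
        if samples.size < 2:
            raise ArmdynError(f"arm {arm!r}: need >= 2 samples")
        if np.ptp(samples) == 0:
            ax.axvline(samples[0], label=arm)
            continue
        kde = stats.gaussian_kde(samples, bw_method="scott")
        lo, hi = np.percentile(samples, [0.5, 99.5])
        pad = 0.1 * (hi - lo)
        grid = np.linspace(lo - pad, hi + pad, 400)
        ax.plot(grid, kde(grid), label=arm)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("posterior density")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
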