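"""Optional figure writers (heatmaps, radar plots).

Numerical CSVs are the contract; these conveniences render the standard
views — an instances x features attribution heatmap, a per-instance radar
plot, and a pairwise interaction heatmap.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .attribution import Attribution, phi_matrix  # noqa: E402


def attribution_heatmap(attributions: list[Attribution], path) -> None:
    """Instances (rows) x features (columns) heatmap of attribution values,
    rows sorted by the absolute attribution of the 11685 feature when
    present (cosmetic ordering only)."""
    mat = phi_matrix(attributions)
    if "11685" in mat.columns:
        mat = mat.loc[mat["11685"].abs().sort_values().index]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.25 * len(mat))))
    vmax = max(np.abs(mat.to_numpy()).max(), 1e-12)
    im = ax.imshow(mat.to_numpy(), cmap="RdBu", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90)
    ax.set_yticks(range(len(mat)), mat.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="attribution")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def radar_plot(attr: Attribution, path) -> None:
    """Radar plot of one attribution: radial extent is |phi|, color its
    sign (blue positive/Good, red negative/Poor)."""
    n = len(attr.feature_names)
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for angle, name, value in zip(angles, attr.feature_names, attr.phi):
        ax.bar(
            angle,
            abs(value),
            width=2 * np.pi / n * 0.9,
            color="tab:blue" if value >= 0 else "tab:red",
            alpha=0.7,
        )
    ax.set_xticks(angles, attr.feature_names)
    ax.set_title(f"{attr.instance_id} ({attr.method})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def interaction_heatmap(matrix, metric: str, path) -> None:
    """Heatmap of one pairwise interaction matrix (NaN diagonal masked)."""
    data = np.ma.masked_invalid(matrix.to_numpy(dtype=float))
    fig, ax = plt.subplots()
    vmax = max(np.abs(data).max(), 1e-12)
    im = ax.imshow(data, cmap="RdBu", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    ax.set_title(metric)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
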