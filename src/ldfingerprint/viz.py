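"""Contour/heatmap rendering of fingerprints and differential grids.

Rendering is optional and headless-safe (Agg backend); all scientific
outputs of the pipeline are text files.  For display only, the open-ended
first and last ln(L) bins are clamped to finite bounds (default ln(L) = 4.3
and 7.3); binning itself never clamps.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .errors import ValidationError
from .fingerprint import Fingerprint, LDPartition

DEFAULT_CLAMP = (4.3, 7.3)


def _display_edges(partition: LDPartition, clamp: tuple[float, float]) -> np.ndarray:
    lo, hi = clamp
    if not lo < hi:
        raise ValidationError("clamp bounds must satisfy lo < hi")
    edges = partition.ln_edges.copy()
    edges[0] = min(lo, edges[1] - 0.1)
    edges[-1] = max(hi, edges[-2] + 0.1)
    return edges


def render_contour(
    fp_or_grid,
    out_path,
    partition: LDPartition | None = None,
    clamp: tuple[float, float] = DEFAULT_CLAMP,
    title: str | None = None,
):
    """Render a fingerprint (sequential scale) or a differential grid
    (diverging scale centred at 0) to an image file."""
    if isinstance(fp_or_grid, Fingerprint):
        grid = fp_or_grid.density
        partition = fp_or_grid.partition
        title = title or fp_or_grid.name
        cmap, norm = "viridis", None
    else:
        grid = np.asarray(fp_or_grid, dtype=float)
        if partition is None:
            raise ValidationError("a raw grid needs an explicit partition")
        vmax = max(np.abs(grid).max(), 1e-12)
        cmap = "RdBu_r"
        norm = matplotlib.colors.TwoSlopeNorm(vmin=-vmax, vcenter=0.0, vmax=vmax)

    ln_edges = _display_edges(partition, clamp)
    id_edges = partition.id_edges

    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(ln_edges, id_edges, grid.T, cmap=cmap, norm=norm)
    fig.colorbar(mesh, ax=ax, label="protein density")
    ax.set_xlabel("ln(L)")
    ax.set_ylabel("ID")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
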