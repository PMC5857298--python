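"""Euclidean distances between fingerprints and distance-matrix output.

The distance between proteomes A and B is
``r_AB = sqrt(sum_ij (A_ij - B_ij)^2)`` over all M x N density blocks.
Because densities are normalized, r_AB is bounded above by sqrt(2)
(attained by disjointly supported grids).
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix

from .errors import ValidationError
from .fingerprint import Fingerprint

MAX_DISTANCE = float(np.sqrt(2.0))


def fingerprint_distance(a: Fingerprint, b: Fingerprint) -> float:
    if not a.partition.same_as(b.partition):
        raise ValidationError("distance requires identical partitions")
    diff = a.density - b.density
    return float(np.sqrt(np.sum(diff * diff)))


def distance_matrix(fps: list[Fingerprint]) -> DistanceMatrix:
    """All-pairs fingerprint distances as a labelled symmetric matrix."""
    if len(fps) < 2:
        raise ValidationError("need at least 2 fingerprints")
    labels = [fp.name for fp in fps]
    if len(set(labels)) != len(labels):
        raise ValidationError(f"duplicate fingerprint labels in {labels}")
    n = len(fps)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fingerprint_distance(fps[i], fps[j])
    return DistanceMatrix(d, ids=labels)


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for label in dm.ids:
            row = " ".join(f"{v:.10f}" for v in dm[label])
            fh.write(f"{label:<10s} {row}\n")


def write_tsv(dm: DistanceMatrix, path) -> None:
    dm.to_data_frame().to_csv(path, sep="\t", float_format="%.10g")
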