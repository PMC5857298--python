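"""Proteome fingerprints: normalized protein-density grids over LD space.

LD space is the plane spanned by ln(L) (natural-log protein length) and ID
(per-protein disorder content, id_pep).  The space is partitioned into
M x N blocks; the fingerprint of a proteome is the grid of densities
X_ij = n_ij / n_tot, which sums to 1 by construction.

Bins are half-open [lo, hi); the last bin on each axis is closed above, so
id_pep = 1.0 falls into bin N.  The default 10 x 10 partition uses ln(L)
edges 0, 4.6, 4.9, ..., 7.0, +inf (interior step 0.3) and ID edges
0, 0.1, ..., 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import disorder
from .errors import ValidationError
from .records import Proteome

LN_INTERIOR_LO = 4.6
LN_INTERIOR_HI = 7.0


@dataclass(frozen=True)
class LDPartition:
    """Block edges of an M x N partition of LD space."""

    ln_edges: np.ndarray  # M+1 values: 0, interior edges, +inf
    id_edges: np.ndarray  # N+1 values spanning [0, 1]

    def __post_init__(self) -> None:
        ln_e = np.asarray(self.ln_edges, dtype=float)
        id_e = np.asarray(self.id_edges, dtype=float)
        object.__setattr__(self, "ln_edges", ln_e)
        object.__setattr__(self, "id_edges", id_e)
        if ln_e.size < 3 or id_e.size < 3:
            raise ValidationError("partition needs M >= 2 and N >= 2")
        if not (np.all(np.diff(ln_e) > 0) and np.all(np.diff(id_e) > 0)):
            raise ValidationError("partition edges must be strictly ascending")
        if ln_e[0] != 0.0 or not math.isinf(ln_e[-1]):
            raise ValidationError("ln edges must start at 0 and end at +inf")
        if id_e[0] != 0.0 or id_e[-1] != 1.0:
            raise ValidationError("id edges must span [0, 1]")

    @property
    def M(self) -> int:
        return self.ln_edges.size - 1

    @property
    def N(self) -> int:
        return self.id_edges.size - 1

    def same_as(self, other: "LDPartition") -> bool:
        return (
            self.M == other.M
            and self.N == other.N
            and bool(np.array_equal(self.ln_edges, other.ln_edges))
            and bool(np.array_equal(self.id_edges, other.id_edges))
        )


def default_partition(M: int = 10, N: int = 10) -> LDPartition:
    """The standard partition: open-ended first/last ln bins around equally
    spaced interior edges on [4.6, 7.0]; equal-width ID bins on [0, 1].

    For M = N = 10 this reproduces ln edges (0, 4.6, 4.9, ..., 7.0, inf) and
    ID edges 0, 0.1, ..., 1.0.
    """
    if M < 2 or N < 2:
        raise ValidationError("M and N must both be >= 2")
    interior = np.linspace(LN_INTERIOR_LO, LN_INTERIOR_HI, M - 1)
    ln_edges = np.concatenate(([0.0], interior, [np.inf]))
    id_edges = np.linspace(0.0, 1.0, N + 1)
    return LDPartition(ln_edges=ln_edges, id_edges=id_edges)


def integer_length_bound(ln_edge: float) -> int:
    """Smallest integer length L with ln(L) >= ln_edge (= ceil(e^edge))."""
    return int(math.ceil(math.exp(ln_edge)))


@dataclass(frozen=True)
class Fingerprint:
    """Normalized M x N protein-density grid of one proteome."""

    name: str
    partition: LDPartition
    counts: np.ndarray  # (M, N) ints
    n_tot: int

    @property
    def density(self) -> np.ndarray:
        return self.counts / self.n_tot


def _bin_indices(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """0-based half-open binning with the final bin closed above."""
    idx = np.searchsorted(edges, values, side="right") - 1
    # values exactly at the top edge (finite axes only) belong to the last bin
    return np.clip(idx, 0, edges.size - 2)


def bin_protein(L: int, id_frac: float, partition: LDPartition) -> tuple[int, int]:
    """Map one protein to its (i, j) block, 1-based on both axes."""
    if L < 1:
        raise ValidationError("protein length must be >= 1")
    if not 0.0 <= id_frac <= 1.0:
        raise ValidationError("id_pep must lie in [0, 1]")
    i = _bin_indices(np.array([math.log(L)]), partition.ln_edges)[0]
    j = _bin_indices(np.array([id_frac]), partition.id_edges)[0]
    return int(i) + 1, int(j) + 1


def fingerprint_from_pairs(
    name: str, lengths, id_fracs, partition: LDPartition
) -> Fingerprint:
    """Fingerprint directly from per-protein (L, id_pep) pairs."""
    lengths = np.asarray(lengths)
    id_fracs = np.asarray(id_fracs, dtype=float)
    if lengths.size == 0:
        raise ValidationError(f"fingerprint {name!r}: no proteins to bin")
    if lengths.size != id_fracs.size:
        raise ValidationError("lengths and id fractions differ in size")
    i = _bin_indices(np.log(lengths.astype(float)), partition.ln_edges)
    j = _bin_indices(id_fracs, partition.id_edges)
    counts = np.zeros((partition.M, partition.N), dtype=int)
    np.add.at(counts, (i, j), 1)
    return Fingerprint(name=name, partition=partition, counts=counts, n_tot=int(lengths.size))


def compute_fingerprint(proteome: Proteome, partition: LDPartition) -> Fingerprint:
    """Fingerprint of a proteome's scored, X-free view."""
    scored = proteome.scored_records()
    if not scored:
        raise ValidationError(
            f"proteome {proteome.name!r}: empty scored view, cannot fingerprint"
        )
    lengths = np.array([r.length for r in scored])
    ids = np.array([disorder.id_pep(r.scores).id_pep for r in scored])
    return fingerprint_from_pairs(proteome.name, lengths, ids, partition)


def differential(a: Fingerprint, b: Fingerprint) -> np.ndarray:
    """Cell-wise density difference a - b (sums to 0)."""
    if not a.partition.same_as(b.partition):
        raise ValidationError("differential requires identical partitions")
    return a.density - b.density


# -- category counting (short/long x ordered/disordered census) --------------

def short_rule(bound: int = 100):
    """L < bound (default: short proteins, L < 100 i.e. ln(L) < 4.6)."""
    return lambda L: L < bound


def long_rule(bound: int = 1000):
    """L >= bound (default: long proteins, L >= 1000)."""
    return lambda L: L >= bound


def disordered_strict(id_frac: float) -> bool:
    """ID strictly above 0.5 (the census convention)."""
    return id_frac > disorder.DISORDER_THRESHOLD


def disordered_ge(id_frac: float) -> bool:
    """ID at or above 0.5 (the IDP-classification convention)."""
    return id_frac >= disorder.DISORDER_THRESHOLD


def count_category(proteome: Proteome, l_rule, d_rule) -> int:
    """Number of scored proteins satisfying both a length and an ID predicate."""
    n = 0
    for rec in proteome.scored_records():
        if l_rule(rec.length) and d_rule(disorder.id_pep(rec.scores).id_pep):
            n += 1
    return n


# -- serialization ------------------------------------------------------------

def grid_frame(grid: np.ndarray, partition: LDPartition) -> pd.DataFrame:
    """Grid as a DataFrame with ln-bin rows and ID-bin columns."""
    rows = [
        f"ln[{partition.ln_edges[i]:g},{partition.ln_edges[i + 1]:g})"
        for i in range(partition.M)
    ]
    cols = [
        f"id[{partition.id_edges[j]:g},{partition.id_edges[j + 1]:g})"
        for j in range(partition.N)
    ]
    return pd.DataFrame(grid, index=rows, columns=cols)


def write_fingerprint(fp: Fingerprint, path) -> None:
    """TSV with a header block annotating the bin edges."""
    with open(path, "w") as fh:
        fh.write(f"# fingerprint\t{fp.name}\n")
        fh.write(f"# n_tot\t{fp.n_tot}\n")
        fh.write("# ln_edges\t" + "\t".join(f"{e:g}" for e in fp.partition.ln_edges) + "\n")
        fh.write("# id_edges\t" + "\t".join(f"{e:g}" for e in fp.partition.id_edges) + "\n")
        grid_frame(fp.density, fp.partition).to_csv(fh, sep="\t", float_format="%.10g")
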