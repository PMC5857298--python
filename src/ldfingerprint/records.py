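"""Core domain containers: a protein record and a proteome.

A :class:`Proteome` holds the proteins of one organism (or gene set) after
primary-isoform selection.  Two views are exposed:

* the *length view* (:meth:`Proteome.length_view`) — every primary protein,
  including those whose sequence contains unknown ``X`` residues; protein
  length statistics are computed on this view;
* the *disorder view* (``Proteome.records``) — the X-free subset, on which
  all intrinsic-disorder quantities are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_VALID_CHARS = frozenset(STANDARD_AA) | {"X"}


@dataclass
class ProteinRecord:
    """One protein: identifier, gene-locus identifier, sequence and
    (optionally) one disorder score per residue, each in [0, 1]."""

    protein_id: str
    locus_id: str
    sequence: str
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"empty sequence for {self.protein_id!r}")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise ValidationError(
                f"{self.protein_id!r}: invalid residue characters {sorted(bad)}"
            )
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if self.scores.shape != (self.length,):
                raise ValidationError(
                    f"{self.protein_id!r}: {self.scores.size} scores for "
                    f"{self.length} residues"
                )
            if self.scores.size and (
                self.scores.min() < 0.0 or self.scores.max() > 1.0
            ):
                raise ValidationError(
                    f"{self.protein_id!r}: disorder scores must lie in [0, 1]"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def has_x(self) -> bool:
        return "X" in self.sequence

    def with_scores(self, scores) -> "ProteinRecord":
        return replace(self, scores=np.asarray(scores, dtype=float))


@dataclass
class Proteome:
    """A named set of primary proteins with provenance counts.

    ``records`` is the X-free disorder view; ``x_records`` keeps the primary
    proteins that were excluded for containing 'X', so length statistics can
    still cover every primary protein.
    """

    name: str
    records: list[ProteinRecord]
    x_records: list[ProteinRecord] = field(default_factory=list)
    n_alternative_removed: int = 0

    def __post_init__(self) -> None:
        if any(r.has_x for r in self.records):
            raise ValidationError(
                f"proteome {self.name!r}: X-containing record in disorder view"
            )
        loci = [r.locus_id for r in self.length_view()]
        if len(loci) != len(set(loci)):
            raise ValidationError(
                f"proteome {self.name!r}: duplicate locus_id after isoform selection"
            )

    @property
    def n_excluded_x(self) -> int:
        return len(self.x_records)

    @property
    def n_total_loaded(self) -> int:
        return len(self.records) + self.n_excluded_x + self.n_alternative_removed

    def length_view(self) -> list[ProteinRecord]:
        """All primary proteins, X-containing ones included."""
        return self.records + self.x_records

    def scored_records(self) -> list[ProteinRecord]:
        return [r for r in self.records if r.scores is not None]

    def unscored_ids(self) -> list[str]:
        return [r.protein_id for r in self.records if r.scores is None]

    def __len__(self) -> int:
        return len(self.records)
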