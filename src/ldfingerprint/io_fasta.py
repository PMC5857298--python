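"""FASTA and disorder-score file input/output.

Locus identifiers are derived from protein identifiers by a configurable
header rule.  The default strips a trailing isoform suffix of the form
``.<digits>`` (Phytozome-style: ``AT1G01010.2`` -> ``AT1G01010``); when no
suffix matches, the locus id is the protein id itself.

Score files come in two plain-text dialects:

* one protein per line: ``<protein_id> v1 v2 ... vL`` (whitespace- or
  comma-separated values);
* blocks headed by ``><protein_id>`` followed by ``position score`` lines.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .records import ProteinRecord, Proteome

DEFAULT_ISOFORM_SUFFIX = re.compile(r"\.\d+$")

HeaderRule = Callable[[str], str]


def default_header_rule(protein_id: str) -> str:
    """Strip a trailing ``.<digits>`` isoform suffix, if present."""
    return DEFAULT_ISOFORM_SUFFIX.sub("", protein_id)


def regex_header_rule(pattern: str) -> HeaderRule:
    """Build a header rule stripping the given trailing regex from the id."""
    compiled = re.compile(pattern)

    def rule(protein_id: str) -> str:
        return compiled.sub("", protein_id)

    return rule


def read_fasta(path, header_rule: HeaderRule = default_header_rule) -> list[ProteinRecord]:
    """Read an amino-acid FASTA file into protein records.

    Trailing ``*`` stop characters are stripped before the length is taken.
    Characters other than the 20 standard residues, 'X' and '*' raise a
    :class:`ValidationError` naming the offending header.
    """
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().rstrip("*")
        if not seq:
            raise ValidationError(f"empty sequence for header {entry.id!r} in {path}")
        if "*" in seq:
            raise ValidationError(
                f"internal stop '*' in sequence for header {entry.id!r} in {path}"
            )
        try:
            rec = ProteinRecord(
                protein_id=entry.id,
                locus_id=header_rule(entry.id),
                sequence=seq,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
        records.append(rec)
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description="")
        for r in records
    ]
    SeqIO.write(entries, str(path), "fasta-2line")


def select_primary(records: list[ProteinRecord]) -> tuple[list[ProteinRecord], int]:
    """Keep the single longest isoform per locus (the primary protein).

    Equal-length ties keep the lexicographically smallest protein_id.
    Returns the kept records (input order of their first locus occurrence)
    and the number of alternative isoforms removed.
    """
    best: dict[str, ProteinRecord] = {}
    order: list[str] = []
    for rec in records:
        cur = best.get(rec.locus_id)
        if cur is None:
            best[rec.locus_id] = rec
            order.append(rec.locus_id)
        elif rec.length > cur.length or (
            rec.length == cur.length and rec.protein_id < cur.protein_id
        ):
            best[rec.locus_id] = rec
    kept = [best[locus] for locus in order]
    return kept, len(records) - len(kept)


def exclude_unknown(records: list[ProteinRecord]) -> tuple[list[ProteinRecord], int]:
    """Split off records whose sequence contains unknown 'X' residues."""
    kept = [r for r in records if not r.has_x]
    return kept, len(records) - len(kept)


def build_proteome(name: str, records: list[ProteinRecord]) -> Proteome:
    """Assemble a proteome: primary-isoform selection, then X exclusion.

    Length statistics later use all primary proteins; disorder statistics
    use the X-free subset only.
    """
    primary, n_alt = select_primary(records)
    clean, _ = exclude_unknown(primary)
    x_recs = [r for r in primary if r.has_x]
    return Proteome(
        name=name,
        records=clean,
        x_records=x_recs,
        n_alternative_removed=n_alt,
    )


def read_proteome(name: str, path, header_rule: HeaderRule = default_header_rule) -> Proteome:
    return build_proteome(name, read_fasta(path, header_rule))


def _parse_score_file(path) -> dict[str, np.ndarray]:
    """Parse either score-file dialect into id -> per-residue array."""
    table: dict[str, list[float]] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                table.setdefault(current, [])
                continue
            fields = line.replace(",", " ").split()
            if current is not None and len(fields) == 2 and _is_number(fields[0]):
                # position/score block under a ">id" header
                table[current].append(float(fields[1]))
                continue
            current = None
            pid, values = fields[0], fields[1:]
            if not values:
                raise ValidationError(f"{path}:{lineno}: no scores for {pid!r}")
            table[pid] = [float(v) for v in values]
    return {pid: np.asarray(vals, dtype=float) for pid, vals in table.items()}


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def load_scores(proteome: Proteome, path) -> Proteome:
    """Attach per-residue disorder scores from a score file.

    Records without an entry keep ``scores=None`` and are reported through a
    warning.  A score-count mismatch or out-of-range value is an error.
    """
    table = _parse_score_file(path)
    new_records: list[ProteinRecord] = []
    missing: list[str] = []
    for rec in proteome.records:
        scores = table.get(rec.protein_id)
        if scores is None:
            missing.append(rec.protein_id)
            new_records.append(rec)
            continue
        if scores.size != rec.length:
            raise ValidationError(
                f"{rec.protein_id!r}: {scores.size} scores for {rec.length} residues"
            )
        if scores.size and (scores.min() < 0.0 or scores.max() > 1.0):
            raise ValidationError(f"{rec.protein_id!r}: score outside [0, 1]")
        new_records.append(rec.with_scores(scores))
    if missing:
        warnings.warn(
            f"proteome {proteome.name!r}: no scores for {len(missing)} records "
            f"(e.g. {missing[:5]})",
            stacklevel=2,
        )
    return Proteome(
        name=proteome.name,
        records=new_records,
        x_records=list(proteome.x_records),
        n_alternative_removed=proteome.n_alternative_removed,
    )


def write_scores(records: Iterable[ProteinRecord], path) -> None:
    """Write scores in the one-line-per-protein dialect (full repr precision)."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.scores is None:
                continue
            vals = " ".join(repr(float(v)) for v in rec.scores)
            fh.write(f"{rec.protein_id} {vals}\n")


def write_table(df, path) -> None:
    """Write any tabular output as TSV (shared convention for the package)."""
    df.to_csv(Path(path), sep="\t", index=False)
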