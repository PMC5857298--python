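"""Synthetic proteome fixtures with rank-linear ln(L) and ID profiles.

Real proteomes show exponential length distributions: when proteins are
ranked from shortest to longest, ln(L) rises linearly with rank, and the
per-protein disorder content ID shows the same rank-linear shape.  The
generator reproduces exactly that: sorted ln(L) values are equally spaced
over a configurable range, and per-protein ID targets are equally spaced
over ``mean +/- sqrt(3) * sd`` (the rank profile of a uniform distribution
with that mean and standard deviation).  Lengths and ID targets are paired
by a random permutation so the two attributes are unrelated by
construction.

Disorder truth is planted directly in the score file: each protein gets
``N_D = round(id_target * L)`` residues at score 0.9 (one contiguous
stretch, mimicking an intrinsically disordered region) and the rest at 0.1,
so the recovered id_pep equals N_D / L exactly, with no threshold-boundary
ambiguity.  Optional 'X' residues and alternative (shorter) isoforms are
injected at configurable rates, and every planted quantity is recorded in a
truth table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_fasta
from .errors import ValidationError
from .records import ProteinRecord, Proteome

_SQRT3 = math.sqrt(3.0)

# fixed background residue composition (approximate natural frequencies)
BACKGROUND_COMPOSITION = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}
_ALPHABET = np.frombuffer("".join(BACKGROUND_COMPOSITION).encode(), dtype="S1")
_CUM = np.cumsum(np.array(list(BACKGROUND_COMPOSITION.values())))
_CUM /= _CUM[-1]

MIN_PROTEIN_LENGTH = 5  # shortest real protein in the surveyed proteomes


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic proteome."""

    name: str
    n_proteins: int = 1000
    ln_L_range: tuple[float, float] = (3.22, 8.52)
    id_pep_target_mean: float = 0.41
    id_pep_target_sd: float = 0.22
    x_residue_rate: float = 0.0
    isoform_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ln_L_range
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be positive")
        if lo >= hi:
            raise ValidationError("ln_L_range must be increasing")
        if lo < math.log(MIN_PROTEIN_LENGTH) - 1e-9:
            raise ValidationError(
                f"ln_L_range.min must be >= ln({MIN_PROTEIN_LENGTH})"
            )
        for rate in (self.x_residue_rate, self.isoform_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError("rates must lie in [0, 1]")
        half = _SQRT3 * self.id_pep_target_sd
        if self.id_pep_target_mean - half < 0.0 or self.id_pep_target_mean + half > 1.0:
            raise ValidationError(
                "infeasible ID profile: mean +/- sqrt(3)*sd leaves [0, 1]"
            )


def eukaryote_like(name: str, seed: int, n_proteins: int = 1000) -> SynthSpec:
    """Preset emulating a eukaryotic proteome: longer proteins, mean ID 0.41."""
    return SynthSpec(
        name=name, n_proteins=n_proteins, ln_L_range=(3.22, 8.52),
        id_pep_target_mean=0.41, id_pep_target_sd=0.22, seed=seed,
    )


def prokaryote_like(name: str, seed: int, n_proteins: int = 1000) -> SynthSpec:
    """Preset emulating a prokaryotic proteome: shorter proteins, mean ID 0.16."""
    return SynthSpec(
        name=name, n_proteins=n_proteins, ln_L_range=(3.40, 7.78),
        id_pep_target_mean=0.16, id_pep_target_sd=0.09, seed=seed,
    )


@dataclass
class SynthProteome:
    """In-memory fixture: records (primaries + isoforms), scores and truth."""

    spec: SynthSpec
    records: list[ProteinRecord] = field(default_factory=list)
    scores: dict[str, np.ndarray] = field(default_factory=dict)
    truth: pd.DataFrame | None = None

    def proteome(self) -> Proteome:
        """Run the package's own selection/exclusion/scoring pipeline."""
        prot = io_fasta.build_proteome(self.spec.name, self.records)
        new = [
            r.with_scores(self.scores[r.protein_id])
            if r.protein_id in self.scores
            else r
            for r in prot.records
        ]
        return Proteome(
            name=prot.name,
            records=new,
            x_records=prot.x_records,
            n_alternative_removed=prot.n_alternative_removed,
        )


def _random_sequences(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    total = int(lengths.sum())
    draws = np.searchsorted(_CUM, rng.random(total))
    chars = _ALPHABET[draws].tobytes().decode()
    out, pos = [], 0
    for L in lengths:
        out.append(chars[pos:pos + int(L)])
        pos += int(L)
    return out


def _planted_scores(L: int, n_d: int, start: int) -> np.ndarray:
    scores = np.full(L, 0.1)
    scores[start:start + n_d] = 0.9
    return scores


def sample_proteome(spec: SynthSpec) -> SynthProteome:
    """Draw one synthetic proteome (deterministic in the spec's seed)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    lo, hi = spec.ln_L_range

    ln_l = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2])
    lengths = np.maximum(np.rint(np.exp(ln_l)).astype(int), MIN_PROTEIN_LENGTH)

    half = _SQRT3 * spec.id_pep_target_sd
    id_rank = (
        np.linspace(spec.id_pep_target_mean - half, spec.id_pep_target_mean + half, n)
        if n > 1
        else np.array([spec.id_pep_target_mean])
    )
    id_targets = rng.permutation(id_rank)  # decouple length and ID ranks

    n_d = np.rint(id_targets * lengths).astype(int)
    planted_id = n_d / lengths

    seqs = _random_sequences(rng, lengths)

    n_x = int(round(spec.x_residue_rate * n))
    x_idx = set(rng.choice(n, size=n_x, replace=False).tolist()) if n_x else set()

    n_iso = int(round(spec.isoform_rate * n))
    iso_idx = set(rng.choice(n, size=n_iso, replace=False).tolist()) if n_iso else set()

    records: list[ProteinRecord] = []
    scores: dict[str, np.ndarray] = {}
    rows = []
    width = len(str(n))
    for k in range(n):
        locus = f"{spec.name}_g{k + 1:0{width}d}"
        pid = f"{locus}.1"
        seq = seqs[k]
        has_x = k in x_idx
        if has_x:
            pos = int(rng.integers(0, lengths[k]))
            seq = seq[:pos] + "X" + seq[pos + 1:]
        records.append(ProteinRecord(protein_id=pid, locus_id=locus, sequence=seq))
        if not has_x:
            start = int(rng.integers(0, lengths[k] - n_d[k] + 1)) if n_d[k] < lengths[k] else 0
            scores[pid] = _planted_scores(int(lengths[k]), int(n_d[k]), start)
        rows.append(
            {
                "protein_id": pid,
                "locus_id": locus,
                "L": int(lengths[k]),
                "n_d": int(n_d[k]),
                "id_pep": float(planted_id[k]),
                "has_x": has_x,
                "is_primary": True,
            }
        )
        if k in iso_idx:
            iso_len = max(MIN_PROTEIN_LENGTH, int(0.6 * lengths[k]))
            iso_pid = f"{locus}.2"
            iso_seq = seqs[k][:iso_len]
            records.append(
                ProteinRecord(protein_id=iso_pid, locus_id=locus, sequence=iso_seq)
            )
            rows.append(
                {
                    "protein_id": iso_pid,
                    "locus_id": locus,
                    "L": iso_len,
                    "n_d": 0,
                    "id_pep": float("nan"),
                    "has_x": False,
                    "is_primary": False,
                }
            )
    truth = pd.DataFrame(rows)
    return SynthProteome(spec=spec, records=records, scores=scores, truth=truth)


def generate_proteome(spec: SynthSpec, out_dir) -> dict[str, str]:
    """Write FASTA + score file + truth table for one spec; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sp = sample_proteome(spec)
    fasta = out / f"{spec.name}.fasta"
    score_file = out / f"{spec.name}.scores.txt"
    truth_file = out / f"{spec.name}.truth.tsv"
    io_fasta.write_fasta(sp.records, fasta)
    scored = [
        r.with_scores(sp.scores[r.protein_id])
        for r in sp.records
        if r.protein_id in sp.scores
    ]
    io_fasta.write_scores(scored, score_file)
    sp.truth.to_csv(truth_file, sep="\t", index=False, float_format="%.17g")
    return {
        "name": spec.name,
        "fasta": str(fasta),
        "scores": str(score_file),
        "truth": str(truth_file),
    }


def generate_cohort(specs: list[SynthSpec], out_dir) -> dict:
    """Write one fixture set per spec plus a JSON manifest."""
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate cohort names in {names}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"proteomes": []}
    for spec in specs:
        entry = generate_proteome(spec, out / spec.name)
        entry["seed"] = spec.seed
        entry["n_proteins"] = spec.n_proteins
        manifest["proteomes"].append(entry)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
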