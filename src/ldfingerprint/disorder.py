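"""Intrinsic-disorder quantities.

A residue is *disordered* when its predictor score is >= 0.5 (the threshold
is inclusive).  Two proteome-level quantities follow:

* ``id_pep`` — per protein, the fraction of disordered residues
  N_D / L; a protein with id_pep >= 0.5 is classified as an IDP
  (intrinsically disordered protein);
* ``id_res`` — per proteome, the plain mean of all raw residue scores
  (not thresholded).

External predictor output (e.g. PONDR-VSL2) is attached through
:func:`ldfingerprint.io_fasta.load_scores`.  For self-contained runs a
deterministic proxy scorer is provided: a sliding-window average of a frozen
TOP-IDP-style propensity scale, min-max rescaled to [0, 1].  The proxy is
NOT equivalent to PONDR-VSL2; outputs produced with it are labelled
``score_source="proxy"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError
from .records import Proteome

DISORDER_THRESHOLD = 0.5


@dataclass(frozen=True)
class DisorderSummary:
    """Disorder content of one protein."""

    id_pep: float
    n_disordered_residues: int
    is_idp: bool


def id_pep(scores) -> DisorderSummary:
    """Per-protein disorder content: N_D / L with N_D = #{scores >= 0.5}."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValidationError("id_pep requires a non-empty score vector")
    n_d = int(np.count_nonzero(arr >= DISORDER_THRESHOLD))
    frac = n_d / arr.size
    return DisorderSummary(
        id_pep=frac,
        n_disordered_residues=n_d,
        is_idp=frac >= DISORDER_THRESHOLD,
    )


def id_res(proteome: Proteome) -> float:
    """Proteome-level mean raw score over every residue (Eq.-2-style).

    Equals sum_i D_i / X with X the total residue count of the (X-free,
    scored) disorder view.
    """
    missing = proteome.unscored_ids()
    if missing:
        raise ValidationError(
            f"proteome {proteome.name!r}: records without scores: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    if not proteome.records:
        raise ValidationError(f"proteome {proteome.name!r}: empty disorder view")
    total = sum(float(r.scores.sum()) for r in proteome.records)
    n_res = sum(r.length for r in proteome.records)
    return total / n_res


def _load_scale() -> dict[str, float]:
    text = (
        resources.files("ldfingerprint") / "data" / "top_idp_scale.json"
    ).read_text()
    return json.loads(text)["propensity"]


_SCALE = _load_scale()
_SCALE_MIN = min(_SCALE.values())
_SCALE_MAX = max(_SCALE.values())
_RESCALED = {
    aa: (v - _SCALE_MIN) / (_SCALE_MAX - _SCALE_MIN) for aa, v in _SCALE.items()
}


def proxy_scores(sequence: str, window: int = 21) -> np.ndarray:
    """Deterministic stand-in disorder scorer (not a PONDR-VSL2 emulator).

    Maps each residue to its rescaled propensity and smooths with a centred
    sliding window (truncated at the termini).  A window longer than the
    sequence is clamped to the sequence length.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError("window must be a positive odd integer")
    try:
        raw = np.array([_RESCALED[aa] for aa in sequence], dtype=float)
    except KeyError as exc:
        raise ValidationError(
            f"proxy scorer accepts the 20 standard residues only; got {exc}"
        ) from exc
    L = raw.size
    w = min(window, L)
    if w % 2 == 0:
        w -= 1
    half = w // 2
    csum = np.concatenate(([0.0], np.cumsum(raw)))
    idx = np.arange(L)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, L)
    return (csum[hi] - csum[lo]) / (hi - lo)


def attach_proxy_scores(proteome: Proteome, window: int = 21) -> Proteome:
    """Return a copy of the proteome with proxy scores on every record."""
    new = [r.with_scores(proxy_scores(r.sequence, window)) for r in proteome.records]
    return Proteome(
        name=proteome.name,
        records=new,
        x_records=list(proteome.x_records),
        n_alternative_removed=proteome.n_alternative_removed,
    )


def per_protein_table(proteome: Proteome) -> pd.DataFrame:
    """TSV-ready per-protein disorder table: id, L, N_D, id_pep, is_idp."""
    rows = []
    for rec in proteome.scored_records():
        summ = id_pep(rec.scores)
        rows.append(
            {
                "protein_id": rec.protein_id,
                "L": rec.length,
                "n_disordered": summ.n_disordered_residues,
                "id_pep": summ.id_pep,
                "is_idp": summ.is_idp,
            }
        )
    return pd.DataFrame(rows, columns=["protein_id", "L", "n_disordered", "id_pep", "is_idp"])
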