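"""Proteome summary statistics and length/disorder correlation.

Length statistics (average, median, max, min) cover every primary protein,
including those later excluded from disorder analysis for containing 'X';
the disorder percentages cover only the X-free scored view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import disorder
from .errors import ValidationError
from .records import Proteome


@dataclass(frozen=True)
class ProteomeSummary:
    name: str
    gene_number: int
    ave_L: float
    med_L: float
    max_L: int
    min_L: int
    pct_idp: float       # share of proteins with id_pep >= 0.5, in percent
    pct_id_res: float    # 100 x mean raw residue score


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson/Spearman correlation between per-protein ln(L) and id_pep.

    ``defined`` is False when either variable has zero variance; the
    coefficients are then None rather than NaN.
    """

    pearson: float | None
    spearman: float | None
    defined: bool


def summarize(proteome: Proteome) -> ProteomeSummary:
    lengths = np.array([r.length for r in proteome.length_view()], dtype=int)
    if lengths.size == 0:
        raise ValidationError(f"proteome {proteome.name!r} is empty")
    scored = proteome.scored_records()
    if not scored:
        raise ValidationError(
            f"proteome {proteome.name!r}: no scored records for disorder statistics"
        )
    id_fracs = np.array([disorder.id_pep(r.scores).id_pep for r in scored])
    return ProteomeSummary(
        name=proteome.name,
        gene_number=int(lengths.size),
        ave_L=float(lengths.mean()),
        med_L=float(np.median(lengths)),
        max_L=int(lengths.max()),
        min_L=int(lengths.min()),
        pct_idp=100.0 * float(np.mean(id_fracs >= disorder.DISORDER_THRESHOLD)),
        pct_id_res=100.0 * disorder.id_res(proteome),
    )


def summary_table(summaries: list[ProteomeSummary]) -> pd.DataFrame:
    """Summary TSV with percentages displayed to one decimal place."""
    return pd.DataFrame(
        {
            "name": [s.name for s in summaries],
            "gene_number": [s.gene_number for s in summaries],
            "ave_L": [round(s.ave_L, 1) for s in summaries],
            "med_L": [s.med_L for s in summaries],
            "max_L": [s.max_L for s in summaries],
            "min_L": [s.min_L for s in summaries],
            "id_pep_pct": [round(s.pct_idp, 1) for s in summaries],
            "id_res_pct": [round(s.pct_id_res, 1) for s in summaries],
        }
    )


def ld_pairs(proteome: Proteome) -> tuple[np.ndarray, np.ndarray]:
    """Per-protein (ln L, id_pep) pairs over the scored view."""
    scored = proteome.scored_records()
    ln_l = np.array([np.log(r.length) for r in scored])
    ids = np.array([disorder.id_pep(r.scores).id_pep for r in scored])
    return ln_l, ids


def ld_correlation(proteome: Proteome) -> CorrelationResult:
    """Pearson and Spearman correlation between ln(L) and id_pep.

    Spearman uses mid-rank ties.  Degenerate (zero-variance) input yields a
    distinguished undefined result.
    """
    ln_l, ids = ld_pairs(proteome)
    if ln_l.size < 3:
        raise ValidationError("correlation requires at least 3 scored proteins")
    if np.ptp(ln_l) == 0.0 or np.ptp(ids) == 0.0:
        return CorrelationResult(pearson=None, spearman=None, defined=False)
    pear = stats.pearsonr(ln_l, ids).statistic
    spear = stats.spearmanr(ln_l, ids).statistic
    return CorrelationResult(pearson=float(pear), spearman=float(spear), defined=True)


def correlation_table(proteomes: list[Proteome]) -> pd.DataFrame:
    rows = []
    for p in proteomes:
        cc = ld_correlation(p)
        rows.append(
            {
                "name": p.name,
                "pearson": cc.pearson if cc.defined else float("nan"),
                "spearman": cc.spearman if cc.defined else float("nan"),
                "defined": cc.defined,
            }
        )
    return pd.DataFrame(rows, columns=["name", "pearson", "spearman", "defined"])
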