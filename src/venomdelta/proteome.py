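"""Spectral-count proteome integration with the transcriptome.

Protein abundance is quantified as exclusive unique spectral counts
(EUSC), normalized to per-sample fractions — like TPM, a composition.
Both omics layers are clr-transformed, correlated (Spearman's rho and
Pearson's R with an OLS best-fit line), and differenced per toxin to give
a translation-efficiency score: te = clr(protein) - clr(transcript).
Toxins in the lowest TE quantile are candidates for post-transcriptional
repression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .outliers import orthogonal_fit

__all__ = [
    "CorrelationResult",
    "normalize_eusc",
    "correlate_omics",
    "translation_efficiency",
    "low_te_set",
]


@dataclass
class CorrelationResult:
    rho: float       # Spearman's rank correlation
    r: float         # Pearson's correlation
    slope: float     # best-fit line, protein on transcript
    intercept: float
    n: int


def normalize_eusc(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fractions of total spectral counts.

    Idempotent; an all-zero sample has no defined composition and raises.
    """
    arr = table.astype(float)
    totals = arr.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero proteome sample(s): {bad}")
    return arr / totals


def correlate_omics(transcript_clr, protein_clr, line: str = "ols") -> CorrelationResult:
    """Spearman/Pearson correlation and best-fit line between clr-scale
    transcript and protein abundances over shared toxins.

    ``line="ols"`` regresses protein on transcript (default);
    ``line="orthogonal"`` uses the total-least-squares axis instead.
    """
    x = pd.Series(transcript_clr).astype(float)
    y = pd.Series(protein_clr).astype(float)
    shared = x.index.intersection(y.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared toxins")
    x, y = x[shared].to_numpy(), y[shared].to_numpy()
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("zero variance on one axis")
    rho = float(stats.spearmanr(x, y).statistic)
    r = float(stats.pearsonr(x, y).statistic)
    if line == "orthogonal":
        slope, intercept = orthogonal_fit(x, y)
    else:
        slope, intercept = np.polyfit(x, y, 1)
    return CorrelationResult(rho, r, float(slope), float(intercept), len(shared))


def translation_efficiency(transcript_clr: pd.DataFrame,
                           protein_clr: pd.DataFrame,
                           species_of: dict | None = None) -> pd.DataFrame:
    """Per-toxin, per-species translation efficiency.

    Inputs are clr values with toxins as rows and species (or samples
    already pooled to species) as columns; only toxins present in both
    tables are scored.  Returns a long DataFrame with columns
    ``toxin_id, species, te``.
    """
    t = pd.DataFrame(transcript_clr)
    p = pd.DataFrame(protein_clr)
    shared_rows = t.index.intersection(p.index)
    shared_cols = t.columns.intersection(p.columns)
    rows = []
    for col in shared_cols:
        sp = species_of[col] if species_of else col
        for tid in shared_rows:
            rows.append((tid, sp, float(p.loc[tid, col] - t.loc[tid, col])))
    return pd.DataFrame(rows, columns=["toxin_id", "species", "te"])


def low_te_set(te: pd.DataFrame, species: str, quantile: float = 0.25) -> list[str]:
    """Toxins in the lowest TE quantile for one species."""
    sub = te[te.species == species].set_index("toxin_id")["te"]
    if sub.empty:
        return []
    return sorted(sub.index[sub <= sub.quantile(quantile)])
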