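"""Compositional normalization of expression data.

TPM tables are compositional: each sample is a vector of relative
abundances summing to one million, so between-sample comparisons operate
on centered log-ratio (clr) coordinates.  Raw small-RNA count libraries
are instead normalized with trimmed-mean-of-M-values (TMM) scaling
factors, which are robust to composition bias from a few very abundant
genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "clr_transform",
    "tmm_factors",
    "filter_min_tpm",
    "tpm_scale",
]


@dataclass
class ExpressionMatrix:
    """Transcripts x samples abundance table with species and class labels.

    Parameters
    ----------
    values : DataFrame
        Rows are transcripts, columns are samples.  Values are TPM or raw
        counts, always non-negative.
    species : Series
        Species label per sample (indexed by sample id).
    classes : Series
        Class label per transcript: a toxin family name or ``"nontoxin"``.
    """

    values: pd.DataFrame
    species: pd.Series
    classes: pd.Series = field(default=None)

    def __post_init__(self):
        self.species = pd.Series(self.species).reindex(self.values.columns)
        if self.species.isna().any():
            missing = list(self.species.index[self.species.isna()])
            raise ValueError(f"samples without species label: {missing}")
        if self.classes is None:
            self.classes = pd.Series("nontoxin", index=self.values.index)
        else:
            self.classes = pd.Series(self.classes).reindex(self.values.index)
            if self.classes.isna().any():
                raise ValueError("every transcript needs exactly one class label")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")

    # -- convenience -------------------------------------------------------
    @property
    def transcripts(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def samples_of(self, species: str) -> list[str]:
        return list(self.species.index[self.species == species])

    def species_names(self) -> list[str]:
        seen: list[str] = []
        for sp in self.species:
            if sp not in seen:
                seen.append(sp)
        return seen

    def is_toxin(self) -> pd.Series:
        return self.classes != "nontoxin"

    def subset(self, transcripts=None, samples=None) -> "ExpressionMatrix":
        vals = self.values
        if transcripts is not None:
            vals = vals.loc[transcripts]
        if samples is not None:
            vals = vals[samples]
        return ExpressionMatrix(vals, self.species[vals.columns], self.classes[vals.index])

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write TSV: transcript_id, class, one column per sample, plus a
        ``#species`` annotation line under the header."""
        with open(path, "w") as fh:
            fh.write("transcript_id\tclass\t" + "\t".join(self.samples) + "\n")
            fh.write("#species\t-\t" + "\t".join(self.species[s] for s in self.samples) + "\n")
            for tid in self.transcripts:
                row = "\t".join(f"{v:.6g}" for v in self.values.loc[tid])
                fh.write(f"{tid}\t{self.classes[tid]}\t{row}\n")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            species_line = fh.readline().rstrip("\n").split("\t")
            if not species_line or species_line[0] != "#species":
                raise ValueError("expected a '#species' annotation line after the header")
            body = pd.read_csv(fh, sep="\t", header=None, names=header, index_col=0)
        sample_ids = header[2:]
        species = pd.Series(species_line[2:], index=sample_ids)
        classes = body["class"]
        values = body[sample_ids].astype(float)
        return cls(values, species, classes)


def tpm_scale(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale every sample column to sum to 1e6 (TPM convention)."""
    totals = matrix.values.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("cannot TPM-scale an all-zero sample")
    scaled = matrix.values * (1e6 / totals)
    return ExpressionMatrix(scaled, matrix.species, matrix.classes)


def _replace_zeros(col: np.ndarray, zero_policy, pseudocount: float) -> np.ndarray:
    if not (col > 0).any():
        raise ValueError("all-zero sample column: composition undefined")
    out = col.astype(float).copy()
    if (out == 0).any():
        if zero_policy == "multiplicative":
            out[out == 0] = 0.5 * out[out > 0].min()
        elif zero_policy == "pseudocount":
            out = out + pseudocount
        else:
            raise ValueError(f"unknown zero_policy {zero_policy!r}")
    return out


def clr_transform(values, zero_policy: str = "multiplicative",
                  pseudocount: float = 0.5):
    """Centered log-ratio transform, column-wise.

    Per sample column x: ``clr(x) = ln(x') - mean(ln(x'))`` where ``x'`` is
    the zero-replaced column.  Zeros are replaced by half of the smallest
    nonzero value in that column (``zero_policy="multiplicative"``, the
    default) or by adding a flat pseudocount (``zero_policy="pseudocount"``).
    Columns of the result sum to zero, and the transform is invariant to
    rescaling of each column (so TPM and raw proportions give identical
    output).
    """
    if isinstance(values, ExpressionMatrix):
        values = values.values
    squeeze = False
    if isinstance(values, pd.Series):
        values = values.to_frame()
        squeeze = True
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
        squeeze = True
    if (arr < 0).any():
        raise ValueError("clr requires non-negative input")
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = _replace_zeros(arr[:, j], zero_policy, pseudocount)
        logs = np.log(col)
        out[:, j] = logs - logs.mean()
    if isinstance(values, pd.DataFrame):
        res = pd.DataFrame(out, index=values.index, columns=values.columns)
        return res.iloc[:, 0] if squeeze else res
    return out[:, 0] if squeeze else out


def filter_min_tpm(matrix: ExpressionMatrix, threshold: float = 1.0,
                   scope: str = "per-species") -> ExpressionMatrix:
    """Drop transcripts not strictly above ``threshold`` TPM in every
    individual of the scope.

    ``scope="per-species"`` keeps a transcript if, in at least one species,
    all of that species' individuals exceed the threshold; a species name
    restricts the check to that species; ``scope="all"`` requires every
    sample.  The strict inequality means a transcript at exactly the
    threshold in any required individual is removed.
    """
    vals = matrix.values
    if scope == "all":
        keep = (vals > threshold).all(axis=1)
    elif scope == "per-species":
        per_sp = []
        for sp in matrix.species_names():
            cols = matrix.samples_of(sp)
            per_sp.append((vals[cols] > threshold).all(axis=1))
        keep = pd.concat(per_sp, axis=1).any(axis=1)
    else:
        cols = matrix.samples_of(scope)
        if not cols:
            raise ValueError(f"no samples for species {scope!r}")
        keep = (vals[cols] > threshold).all(axis=1)
    return matrix.subset(transcripts=matrix.transcripts[keep])


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Weighted doubly-trimmed mean of M-values of one sample vs the reference.

    Returns the log2 scaling factor.  Only genes nonzero in both samples
    enter; `trim_m` / `trim_a` fractions are trimmed from each tail of the
    M and A distributions, and the surviving M-values are averaged with
    inverse asymptotic (binomial) variance weights.
    """
    both = (obs > 0) & (ref > 0)
    if not both.any():
        raise ValueError("sample shares no nonzero genes with the reference")
    o, r = obs[both], ref[both]
    fo, fr = o / n_obs, r / n_ref
    m = np.log2(fo / fr)
    a = 0.5 * np.log2(fo * fr)
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.isclose(m, m[0]).all():  # identical profiles up to depth
        return float(m[0])
    n = len(m)
    # trim by sort position, not rank: average ranks of large tied blocks
    # can straddle the cut points and empty the kept set, whereas dropping
    # tied members by position leaves the kept mean unchanged
    cut_m = int(np.floor(n * trim_m))
    cut_a = int(np.floor(n * trim_a))
    keep = np.ones(n, dtype=bool)
    order_m = np.argsort(m, kind="stable")
    order_a = np.argsort(a, kind="stable")
    if cut_m:
        keep[order_m[:cut_m]] = False
        keep[order_m[n - cut_m:]] = False
    if cut_a:
        keep[order_a[:cut_a]] = False
        keep[order_a[n - cut_a:]] = False
    if not keep.any():
        return float(np.average(m, weights=1.0 / w))
    return float(np.average(m[keep], weights=1.0 / w[keep]))


def tmm_factors(counts, trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """TMM normalization factors for raw count libraries.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those quantiles across samples.  Factors are
    rescaled so their geometric mean is 1.
    """
    if isinstance(counts, ExpressionMatrix):
        counts = counts.values
    arr = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = arr.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("all-zero library")
    q75 = np.array([np.quantile(arr[:, j][arr[:, j] > 0] / lib[j], 0.75) if (arr[:, j] > 0).any() else 0.0
                    for j in range(arr.shape[1])])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    log_factors = np.array([
        0.0 if j == ref_idx else
        _tmm_pair(arr[:, j], arr[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(arr.shape[1])
    ])
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    cols = counts.columns if isinstance(counts, pd.DataFrame) else range(arr.shape[1])
    return pd.Series(factors, index=cols, name="tmm_factor")


def tmm_normalize(counts, trim_m: float = 0.30, trim_a: float = 0.05):
    """Counts scaled to TMM-adjusted effective library size (counts per
    million of the effective library)."""
    if isinstance(counts, ExpressionMatrix):
        counts = counts.values
    factors = tmm_factors(counts, trim_m=trim_m, trim_a=trim_a)
    lib = counts.sum(axis=0)
    return counts / (lib * factors) * 1e6
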