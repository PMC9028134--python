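"""Weighted coexpression module detection.

A deterministic WGCNA-style stack: log2(TPM+1) variance-stabilizing
transform, a mean-variance-trend filter that keeps transcripts more
variable than expected at their expression level, soft-thresholded
Pearson adjacency (|r|^beta, beta=10 by default), topological-overlap
similarity, average-linkage clustering on 1-TOM with a static cut, and
eigengene-based merging of modules below the minimum size (a no-op at the
default minimum of 1).  With very few samples correlation estimates are
coarse; a warning is emitted below 8 samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "CoexpressionConfig",
    "ModuleAssignment",
    "vst_filter",
    "detect_modules",
    "annotate_modules",
    "topological_overlap",
]


@dataclass
class CoexpressionConfig:
    beta: float = 10.0
    correlation_method: str = "pearson"
    min_module_size: int = 1
    variance_filter_keep: int | float | None = None  # count, fraction, or trend-only
    cut_height: float = 0.25

    def __post_init__(self):
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if self.correlation_method != "pearson":
            raise ValueError("only pearson correlation is supported")


@dataclass
class ModuleAssignment:
    """transcript -> module id partition; module 0 means unassigned."""
    assignment: pd.Series
    modules: dict = field(default_factory=dict)  # module id -> member list

    def __post_init__(self):
        if not self.modules:
            self.modules = {int(m): sorted(self.assignment.index[self.assignment == m])
                            for m in sorted(set(self.assignment)) if m != 0}

    @property
    def n_modules(self) -> int:
        return len(self.modules)


def vst_filter(expr: pd.DataFrame, config: CoexpressionConfig | None = None) -> pd.DataFrame:
    """log2(TPM+1) transform plus a variance-vs-trend filter.

    A lowess trend of per-transcript variance on mean expression is
    fitted; transcripts whose variance exceeds the trend are kept,
    optionally capped at ``variance_filter_keep`` (a count, or a fraction
    of transcripts) ranked by excess variance.  The returned matrix is
    tagged (``attrs["vst_filtered"]``) and passing it back in is a no-op:
    the operation means "ensure filtered", so applying it twice equals
    applying it once, and the tag prevents a second log2 transform from
    corrupting already-transformed values.
    """
    config = config or CoexpressionConfig()
    if getattr(expr, "attrs", {}).get("vst_filtered"):
        return expr
    if expr.shape[1] < 3:
        warnings.warn("fewer than 3 samples: variance filtering is unreliable")
    mat = np.log2(expr.astype(float) + 1.0)
    mean = mat.mean(axis=1)
    var = mat.var(axis=1, ddof=1)
    if np.allclose(var, 0):
        raise ValueError("constant expression matrix: nothing to filter")
    trend = pd.Series(
        lowess(var.to_numpy(), mean.to_numpy(), frac=0.5, return_sorted=False),
        index=mat.index,
    ).clip(lower=0.0)
    excess = var - trend
    keep = excess > 0
    if not keep.any():  # degenerate trend: keep the most variable half
        keep = var > var.median()
    kept = mat.loc[keep]
    cap = config.variance_filter_keep
    if cap is not None:
        n = int(round(cap * len(mat))) if isinstance(cap, float) and cap <= 1 else int(cap)
        kept = kept.loc[excess[keep].sort_values(ascending=False).index[:n]]
    out = kept.loc[[t for t in mat.index if t in kept.index]]
    out.attrs["vst_filtered"] = True
    return out


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned TOM similarity of an adjacency matrix with unit diagonal."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def _eigengene(block: np.ndarray) -> np.ndarray:
    """First principal component of standardized member profiles."""
    z = block - block.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = z / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    return vt[0]


def detect_modules(transformed: pd.DataFrame,
                   config: CoexpressionConfig | None = None) -> ModuleAssignment:
    """Cluster transcripts into coexpression modules.

    Adjacency |pearson r|^beta -> TOM similarity -> average-linkage
    hierarchical clustering on 1-TOM -> static cut at ``cut_height``.
    Modules smaller than ``min_module_size`` are merged into the module
    with the most correlated eigengene.
    """
    config = config or CoexpressionConfig()
    if transformed.shape[0] < 2:
        raise ValueError("need at least 2 transcripts")
    if transformed.shape[1] < 8:
        warnings.warn(f"only {transformed.shape[1]} samples: correlations are coarse")
    mat = transformed.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat)
    corr = np.nan_to_num(corr, nan=0.0)
    adjacency = np.abs(np.clip(corr, -1, 1)) ** config.beta
    np.fill_diagonal(adjacency, 1.0)
    tom = topological_overlap(adjacency)
    dist = 1.0 - tom
    dist = (dist + dist.T) / 2.0
    np.clip(dist, 0.0, None, out=dist)  # float error can push TOM above 1
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.average(squareform(dist, checks=False))
    labels = hierarchy.fcluster(link, t=config.cut_height, criterion="distance")
    assignment = pd.Series(labels, index=transformed.index)

    # merge undersized modules into the nearest module by eigengene correlation
    sizes = assignment.value_counts()
    small = [m for m in sizes.index if sizes[m] < config.min_module_size]
    big = [m for m in sizes.index if sizes[m] >= config.min_module_size]
    if small and big:
        eg = {m: _eigengene(mat[(assignment == m).to_numpy()]) for m in sizes.index}
        for m in small:
            best = max(big, key=lambda b: abs(np.corrcoef(eg[m], eg[b])[0, 1]))
            assignment[assignment == m] = best
    elif small and not big:
        warnings.warn("no module reaches min_module_size; all left unassigned")
        assignment[:] = 0

    # relabel 1..K by decreasing size, deterministically
    sizes = assignment[assignment != 0].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], int(m)))
    remap = {old: new for new, old in enumerate(order, start=1)}
    remap[0] = 0
    assignment = assignment.map(remap)
    return ModuleAssignment(assignment)


def annotate_modules(assignment: ModuleAssignment, classes: pd.Series,
                     tf_list=()) -> pd.DataFrame:
    """Per-module summary: toxin members by family, nontoxin count, and
    transcription-factor co-members.  Modules containing at least one
    toxin are highlighted (``has_toxin``)."""
    tf_set = set(tf_list)
    rows = []
    for mod, members in sorted(assignment.modules.items()):
        fams: dict[str, list] = {}
        n_nontoxin = 0
        tfs = []
        for t in members:
            cls = classes.get(t, "nontoxin")
            if cls == "nontoxin":
                n_nontoxin += 1
            else:
                fams.setdefault(cls, []).append(t)
            if t in tf_set:
                tfs.append(t)
        rows.append({
            "module": mod,
            "size": len(members),
            "toxins": {f: sorted(v) for f, v in sorted(fams.items())},
            "n_toxin": sum(len(v) for v in fams.values()),
            "n_nontoxin": n_nontoxin,
            "tfs": sorted(tfs),
            "has_toxin": bool(fams),
        })
    return pd.DataFrame(rows)
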