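"""Differential-expression outlier calling against a nontoxin null band.

With only two individuals per species, replicate-based count models are
unusable, so divergence in expression is judged against an empirical null:
a total-least-squares (orthogonal) line is fitted through paired clr
values, the 99th percentile of the absolute orthogonal residuals of
*nontoxins* defines a band half-width, and toxins falling outside the band
are called outliers.  The same machinery serves the within-species
(individual vs individual) and between-species (species mean vs species
mean) comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compose import ExpressionMatrix, clr_transform, filter_min_tpm

__all__ = [
    "NullBand",
    "OutlierCall",
    "orthogonal_fit",
    "orthogonal_residuals",
    "build_null_band",
    "call_outliers",
    "intraspecific_divergence",
    "interspecific_divergence",
]


def orthogonal_fit(x, y) -> tuple[float, float]:
    """Total-least-squares line through paired points.

    The line passes through the centroid along the first principal axis of
    the 2x2 covariance matrix, so residuals are perpendicular distances.
    Returns ``(slope, intercept)``.  A perfectly isotropic cloud has no
    preferred axis; the tie is broken toward slope 1 with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("orthogonal fit needs at least 3 points")
    cov = np.cov(x, y)
    if not np.isfinite(cov).all() or np.allclose(cov, 0):
        raise ValueError("zero total variance: no line defined")
    evals, evecs = np.linalg.eigh(cov)
    if np.isclose(evals[0], evals[1]) and not np.isclose(cov[0, 1], 0.0):
        pass  # off-diagonal still orients the axis
    elif np.isclose(evals[0], evals[1]):
        warnings.warn("isotropic point cloud: slope tie broken toward 1")
        slope = 1.0
        return slope, float(y.mean() - slope * x.mean())
    v = evecs[:, np.argmax(evals)]  # principal axis
    if np.isclose(v[0], 0.0):
        raise ValueError("principal axis vertical: slope undefined")
    slope = float(v[1] / v[0])
    intercept = float(y.mean() - slope * x.mean())
    return slope, intercept


def orthogonal_residuals(x, y, slope: float, intercept: float) -> np.ndarray:
    """Signed perpendicular distance of each point from the line.

    Positive residual means the point lies above the line (the y-axis
    member of the pair is higher than the line predicts).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return (y - slope * x - intercept) / np.hypot(1.0, slope)


@dataclass
class NullBand:
    """Orthogonal best-fit line plus the nontoxin-derived 99% band.

    ``half_width`` is the 99th percentile (linear interpolation) of the
    absolute orthogonal residuals of the nontoxins used to build the band
    (``mode="absolute"``, default).  In ``mode="signed"`` the band is the
    pair of one-sided 0.5%/99.5% quantiles of the signed residuals.
    """

    slope: float
    intercept: float
    half_width: float
    n_null: int
    mode: str = "absolute"
    bounds: tuple[float, float] = field(default=None)

    def __post_init__(self):
        if self.half_width < 0:
            raise ValueError("half_width must be >= 0")
        if self.n_null < 50:
            warnings.warn(f"null band built from only {self.n_null} nontoxins")
        if self.mode == "absolute" and self.bounds is None:
            self.bounds = (-self.half_width, self.half_width)

    def contains(self, residual) -> np.ndarray:
        lo, hi = self.bounds
        r = np.asarray(residual, float)
        return (r >= lo) & (r <= hi)


@dataclass
class OutlierCall:
    id: str
    x: float
    y: float
    residual: float
    is_outlier: bool
    direction: str  # which axis member is higher ("x", "y", or "-")


def build_null_band(x, y, percentile: float = 99.0, mode: str = "absolute") -> NullBand:
    """Fit the orthogonal line to nontoxin pairs and set the band width at
    the given percentile of their orthogonal residuals."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 nontoxin points for a null band")
    slope, intercept = orthogonal_fit(x, y)
    res = orthogonal_residuals(x, y, slope, intercept)
    if mode == "absolute":
        hw = float(np.percentile(np.abs(res), percentile))
        return NullBand(slope, intercept, hw, x.size, mode="absolute")
    elif mode == "signed":
        tail = (100.0 - percentile) / 2.0
        lo = float(np.percentile(res, tail))
        hi = float(np.percentile(res, 100.0 - tail))
        return NullBand(slope, intercept, max(abs(lo), abs(hi)), x.size,
                        mode="signed", bounds=(lo, hi))
    raise ValueError(f"unknown mode {mode!r}")


def call_outliers(band: NullBand, x, y, ids=None, labels=("x", "y")) -> list[OutlierCall]:
    """Flag points whose orthogonal residual escapes the null band.

    ``labels`` names the two axes (e.g. the two individuals or the two
    species); ``direction`` in each call reports which is higher.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if ids is None:
        ids = [str(i) for i in range(x.size)]
    res = orthogonal_residuals(x, y, band.slope, band.intercept)
    inside = band.contains(res)
    calls = []
    for i, tid in enumerate(ids):
        flagged = not inside[i]
        direction = "-"
        if flagged:
            direction = labels[1] if res[i] > 0 else labels[0]
        calls.append(OutlierCall(tid, float(x[i]), float(y[i]), float(res[i]),
                                 flagged, direction))
    return calls


def _clr_filtered(matrix: ExpressionMatrix, scope: str, threshold: float,
                  zero_policy: str) -> pd.DataFrame:
    """TPM>threshold filter applied to nontoxins (toxins always retained),
    then clr over the retained composition."""
    nontox = matrix.subset(transcripts=matrix.transcripts[~matrix.is_toxin()])
    kept_nontox = filter_min_tpm(nontox, threshold=threshold, scope=scope)
    keep = matrix.is_toxin() | matrix.transcripts.isin(kept_nontox.transcripts)
    sub = matrix.subset(transcripts=matrix.transcripts[keep])
    return sub, clr_transform(sub.values, zero_policy=zero_policy)


def intraspecific_divergence(matrix: ExpressionMatrix, species: str,
                             percentile: float = 99.0, threshold: float = 1.0,
                             zero_policy: str = "multiplicative",
                             mode: str = "absolute"):
    """Individual-vs-individual outlier calls within one species.

    Returns ``(band, calls)`` where the band is built on nontoxins and the
    calls cover every toxin transcript retained in the species.
    """
    cols = matrix.samples_of(species)
    if len(cols) != 2:
        raise ValueError(f"intraspecific mode needs exactly 2 individuals, got {len(cols)}")
    sub = matrix.subset(samples=cols)
    sub, clr = _clr_filtered(sub, species, threshold, zero_policy)
    toxin = sub.is_toxin()
    x_all, y_all = clr[cols[0]], clr[cols[1]]
    band = build_null_band(x_all[~toxin], y_all[~toxin], percentile, mode)
    calls = call_outliers(band, x_all[toxin], y_all[toxin],
                          ids=list(sub.transcripts[toxin]), labels=tuple(cols))
    return band, calls


def interspecific_divergence(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix,
                             ortholog_pairs, percentile: float = 99.0,
                             threshold: float = 1.0,
                             zero_policy: str = "multiplicative",
                             mode: str = "absolute"):
    """Species-vs-species outlier calls over one-to-one ortholog pairs.

    Each species' individuals are clr-transformed over that species' own
    composition and summarized by the arithmetic mean of clr values (the
    geometric mean of abundances).  Nontoxin pairs build the band; toxin
    pairs are called.  Pairs with an id missing from either table are
    skipped.  ``ortholog_pairs`` is an iterable of ``(id_in_a, id_in_b)``.

    Returns ``(band, calls)``; call ids are ``id_a`` and direction labels
    are the species names.
    """
    sp_a = expr_a.species_names()[0]
    sp_b = expr_b.species_names()[0]
    fa, clr_a = _clr_filtered(expr_a, "per-species", threshold, zero_policy)
    fb, clr_b = _clr_filtered(expr_b, "per-species", threshold, zero_policy)
    mean_a = clr_a.mean(axis=1)
    mean_b = clr_b.mean(axis=1)
    rows = []
    for id_a, id_b in ortholog_pairs:
        if id_a not in mean_a.index or id_b not in mean_b.index:
            continue  # filtered out or unpaired: skipped
        rows.append((id_a, id_b, mean_a[id_a], mean_b[id_b],
                     fa.classes[id_a] != "nontoxin"))
    if not rows:
        raise ValueError("no ortholog pairs survive filtering")
    df = pd.DataFrame(rows, columns=["id_a", "id_b", "x", "y", "is_toxin"])
    null = df[~df.is_toxin]
    band = build_null_band(null.x, null.y, percentile, mode)
    tox = df[df.is_toxin]
    calls = call_outliers(band, tox.x, tox.y, ids=list(tox.id_a),
                          labels=(sp_a, sp_b))
    return band, calls


def calls_to_frame(calls: list[OutlierCall], band: NullBand) -> pd.DataFrame:
    df = pd.DataFrame([c.__dict__ for c in calls])
    if not df.empty:
        df["half_width"] = band.half_width
    return df
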