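"""Genome-free miRNA quantification, novel-duplex detection, and
seed-based target scanning on toxin 3'UTRs.

Without a reference genome, known miRNAs are quantified by similarity to
a curated set of mature sequences, and novel candidates are detected from
read pairs that form a miRNA/miRNA* duplex (reverse-complement pairing
with the characteristic 2-nt 3' overhangs).  Target sites on 3'UTRs use
the canonical seed-match taxonomy (6mer, 7mer-A1, 7mer-m8, 8mer: perfect
Watson–Crick complementarity to miRNA positions 2-7/2-8, optionally with
an adenine opposite position 1), plus a transparent gap-free duplex score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compose import tmm_normalize

__all__ = [
    "MatureMirna",
    "TargetSite",
    "RegulatoryCandidate",
    "collapse_reads",
    "collapse_and_quantify",
    "detect_novel_duplex",
    "seed_scan",
    "build_site",
    "integrate_candidates",
]

_DNA_COMP = str.maketrans("ACGT", "TGCA")
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def _to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


@dataclass
class MatureMirna:
    id: str
    sequence: str  # RNA alphabet
    family: str = ""

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("T", "U")
        if not (18 <= len(self.sequence) <= 26):
            raise ValueError(f"mature miRNA length must be 18-26 nt, got {len(self.sequence)}")
        if set(self.sequence) - set("ACGU"):
            raise ValueError("mature miRNA must be over the RNA alphabet")

    @property
    def seed(self) -> str:
        """Positions 2-8 (1-based), the seed region."""
        return self.sequence[1:8]


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # 0-based half-open interval on the UTR
    end: int
    site_type: str
    duplex_score: float


@dataclass
class RegulatoryCandidate:
    mirna_id: str
    toxin_id: str
    expr_log_ratio: float  # species log2 ratio of TMM-normalized miRNA expression
    te: float              # toxin translation efficiency (clr units)
    n_sites: int


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def collapse_reads(reads) -> dict[str, float]:
    """Collapse identical reads into sequence -> count.  ``reads`` is an
    iterable of sequences or ``(sequence, count)`` pairs."""
    out: dict[str, float] = {}
    for item in reads:
        seq, cnt = (item, 1.0) if isinstance(item, str) else item
        seq = _to_dna(seq)
        out[seq] = out.get(seq, 0.0) + float(cnt)
    return out


def _match_mismatches(read: str, mature: str, end_flex: int = 2) -> int | None:
    """Fewest mismatches of an ungapped full-length alignment of read to
    mature with up to ``end_flex`` nt of slack at each end, or None if no
    such alignment exists."""
    best = None
    for off in range(-end_flex, end_flex + 1):
        # read position i aligns with mature position i + off
        end_off = (off + len(read)) - len(mature)  # 3' slack
        if abs(end_off) > end_flex:
            continue
        lo = max(0, -off)
        hi = min(len(read), len(mature) - off)
        if hi <= lo:
            continue
        mm = sum(1 for i in range(lo, hi) if read[i] != mature[i + off])
        if best is None or mm < best:
            best = mm
    return best


def collapse_and_quantify(reads_by_sample: dict, reference: list[MatureMirna],
                          max_mismatch: int = 1, end_flex: int = 2,
                          min_len: int = 18, max_len: int = 26):
    """Assign collapsed reads to known matures.

    A read is assigned if it matches a mature full-length with at most
    ``max_mismatch`` mismatches under +/- ``end_flex`` nt end slack.
    Ambiguous reads go to the best match (fewest mismatches); exact ties
    are split equally.  Returns ``(counts, unassigned)`` where ``counts``
    is a miRNA x sample DataFrame and ``unassigned`` maps sample ->
    {read -> count}.  Reads outside the length window are dropped.
    """
    if not reference:
        raise ValueError("empty mature miRNA reference")
    matures = [(m.id, _to_dna(m.sequence)) for m in reference]
    samples = list(reads_by_sample)
    counts = pd.DataFrame(0.0, index=[m.id for m in reference], columns=samples)
    unassigned: dict[str, dict[str, float]] = {}
    for sample in samples:
        collapsed = collapse_reads(reads_by_sample[sample])
        un: dict[str, float] = {}
        for seq, cnt in collapsed.items():
            if not (min_len <= len(seq) <= max_len):
                continue
            hits = []
            for mid, mseq in matures:
                mm = _match_mismatches(seq, mseq, end_flex)
                if mm is not None and mm <= max_mismatch:
                    hits.append((mm, mid))
            if not hits:
                un[seq] = un.get(seq, 0.0) + cnt
                continue
            best = min(h[0] for h in hits)
            winners = [mid for mm, mid in hits if mm == best]
            for mid in winners:
                counts.loc[mid, sample] += cnt / len(winners)
        unassigned[sample] = un
    return counts, unassigned


# ---------------------------------------------------------------------------
# Novel miRNA detection from duplexes
# ---------------------------------------------------------------------------

def _pairs_wc_gu(b1: str, b2: str) -> bool:
    """Watson-Crick or G:U wobble pairing (DNA encoding: U==T)."""
    pair = {b1, b2}
    return pair in ({"A", "T"}, {"G", "C"}, {"G", "T"})


def detect_novel_duplex(collapsed: dict[str, float], min_count: float = 5,
                        min_paired: int = 14) -> list[dict]:
    """Candidate novel miRNAs from miRNA/miRNA* duplex read pairs.

    Two reads form a duplex if, when paired antiparallel so that each
    strand carries a 2-nt 3' overhang, at least ``min_paired`` positions
    pair (Watson-Crick or G:U).  Both reads must reach ``min_count``.
    The more abundant member is reported as the candidate mature.
    """
    seqs = sorted(s for s, c in collapsed.items() if c >= min_count)
    out = []
    for i, r1 in enumerate(seqs):
        for r2 in seqs[i + 1:]:
            if len(r1) != len(r2):
                continue  # unequal lengths imply interior bulges, not modeled
            L = len(r1)
            paired = sum(1 for k in range(L - 2) if _pairs_wc_gu(r1[k], r2[L - 3 - k]))
            if paired >= min_paired:
                mature, star = (r1, r2) if collapsed[r1] >= collapsed[r2] else (r2, r1)
                out.append({"mature": mature, "star": star,
                            "mature_count": collapsed[mature],
                            "star_count": collapsed[star],
                            "paired_positions": paired})
    return out


# ---------------------------------------------------------------------------
# Seed-site target scanning
# ---------------------------------------------------------------------------

def seed_scan(mirna: MatureMirna, utr: str, transcript_id: str = "") -> list[TargetSite]:
    """Canonical seed sites of one miRNA on one 3'UTR.

    A 6mer is a perfect Watson-Crick match of the UTR to the reverse
    complement of miRNA positions 2-7; the m8 match extends it one base
    5' on the UTR (opposite position 8) and an adenine one base 3'
    (opposite position 1) gives the A1 variant; both together make an
    8mer.  The most specific type is reported per seed-match position.
    The duplex score counts +5 per Watson-Crick and +2 per G:U pair over
    the full gap-free miRNA:UTR duplex anchored at the seed.
    """
    utr_dna = _to_dna(utr)
    mir_dna = _to_dna(mirna.sequence)
    if len(utr_dna) < 6:
        return []
    match6 = _revcomp_dna(mir_dna[1:7])
    m8_comp = _revcomp_dna(mir_dna[7])  # UTR base opposite miRNA position 8
    sites = []
    pos = utr_dna.find(match6)
    while pos != -1:
        has_m8 = pos > 0 and utr_dna[pos - 1] == m8_comp
        has_a1 = pos + 6 < len(utr_dna) and utr_dna[pos + 6] == "A"
        if has_m8 and has_a1:
            stype, start, end = "8mer", pos - 1, pos + 7
        elif has_m8:
            stype, start, end = "7mer-m8", pos - 1, pos + 6
        elif has_a1:
            stype, start, end = "7mer-A1", pos, pos + 7
        else:
            stype, start, end = "6mer", pos, pos + 6
        score = 0.0
        for m in range(len(mir_dna)):
            u = pos + 6 - m  # UTR index opposite miRNA position m+1
            if 0 <= u < len(utr_dna):
                b_m, b_u = mir_dna[m], utr_dna[u]
                if {b_m, b_u} in ({"A", "T"}, {"G", "C"}):
                    score += 5.0
                elif {b_m, b_u} == {"G", "T"}:
                    score += 2.0
        sites.append(TargetSite(mirna.id, transcript_id, start, end, stype, score))
        pos = utr_dna.find(match6, pos + 1)
    return sites


def build_site(mirna: MatureMirna, site_type: str, rng=None) -> str:
    """UTR (DNA) fragment containing exactly one site of the given type
    for this miRNA, with flanks chosen so the site cannot be upgraded to a
    more specific type."""
    if site_type not in SITE_TYPES:
        raise ValueError(f"unknown site type {site_type!r}")
    mir_dna = _to_dna(mirna.sequence)
    match6 = _revcomp_dna(mir_dna[1:7])
    m8_comp = _revcomp_dna(mir_dna[7])
    not_m8 = next(b for b in "ACGT" if b != m8_comp)
    not_a = "C"
    if site_type == "8mer":
        return m8_comp + match6 + "A"
    if site_type == "7mer-m8":
        return m8_comp + match6 + not_a
    if site_type == "7mer-A1":
        return not_m8 + match6 + "A"
    return not_m8 + match6 + not_a


def scan_all(mirnas: list[MatureMirna], utrs: dict[str, str]) -> list[TargetSite]:
    sites = []
    for m in mirnas:
        for tid, utr in utrs.items():
            sites.extend(seed_scan(m, utr, tid))
    return sites


# ---------------------------------------------------------------------------
# Integration with translation efficiency
# ---------------------------------------------------------------------------

def integrate_candidates(counts: pd.DataFrame, species: pd.Series,
                         sites: list[TargetSite], te: pd.DataFrame,
                         target_species: str, expr_ratio_min: float = 1.0,
                         te_quantile: float = 0.25,
                         normalized: bool = False) -> list[RegulatoryCandidate]:
    """(miRNA, toxin) pairs where an over-expressed miRNA has a seed site
    on a poorly translated toxin.

    A candidate requires all three signals at once: the miRNA's
    TMM-normalized expression log2 ratio (``target_species`` over the
    other species) is at least ``expr_ratio_min``; the toxin's translation
    efficiency in ``target_species`` falls in the lowest ``te_quantile``
    of toxins; and at least one seed site links the two.

    ``te`` is a DataFrame with columns ``toxin_id``, ``species``, ``te``.
    """
    norm = counts if normalized else tmm_normalize(counts)
    sp = pd.Series(species).reindex(norm.columns)
    target_cols = list(sp.index[sp == target_species])
    other_cols = list(sp.index[sp != target_species])
    if not target_cols or not other_cols:
        raise ValueError("need samples from both species")
    eps = 0.5  # stabilizes ratios for dropout miRNAs
    ratio = np.log2((norm[target_cols].mean(axis=1) + eps)
                    / (norm[other_cols].mean(axis=1) + eps))
    te_sp = te[te.species == target_species].set_index("toxin_id")["te"]
    if te_sp.empty:
        return []
    cutoff = te_sp.quantile(te_quantile)
    low_te = set(te_sp.index[te_sp <= cutoff])
    n_sites: dict[tuple[str, str], int] = {}
    for s in sites:
        key = (s.mirna_id, s.transcript_id)
        n_sites[key] = n_sites.get(key, 0) + 1
    out = []
    for (mid, tid), n in sorted(n_sites.items()):
        if mid not in ratio.index or tid not in low_te:
            continue
        if ratio[mid] >= expr_ratio_min:
            out.append(RegulatoryCandidate(mid, tid, float(ratio[mid]),
                                           float(te_sp[tid]), n))
    return out
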