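"""Ortholog pairing and pairwise dN/dS by codon counting.

Orthology between the two species is approximated by reciprocal best hits
(RBH) under global protein alignment: a bijective pairing is exactly what
the downstream per-pair statistics consume, and unpaired sequences surface
as putative duplication/loss candidates.  Each pair is aligned by codon
(protein alignment back-threaded onto the nucleotides) and dS, dN and
omega are estimated with Nei–Gojobori (1986) counting: expected
synonymous/nonsynonymous site fractions per codon, pathway-averaged
difference counts per codon pair, and a Jukes–Cantor multiple-hit
correction.  In the retained divergence regime (dS <= 0.10) counting and
maximum-likelihood estimates agree closely.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "CodingSequence",
    "OrthologPair",
    "DnDsResult",
    "GroupComparison",
    "ng86_sites",
    "ng86_differences",
    "pairwise_dnds",
    "codon_align",
    "rbh_pairs",
    "filter_ds_range",
    "compare_groups",
    "translate",
]

BASES = "ACGT"
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}


def _code_table(table_id: int = 1):
    """Genetic code as codon -> amino acid ('*' for stop).  Only the
    standard code is exercised; the table id is a stub for other codes."""
    table = unambiguous_dna_by_id[table_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code

GENETIC_CODE = _code_table(1)
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]


def translate(cds: str) -> str:
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    prot = str(Seq(cds).translate())
    if "*" in prot[:-1] or prot.endswith("*"):
        # terminal stops are trimmed by callers; internal stops are invalid
        raise ValueError("CDS contains a stop codon")
    return prot


# ---------------------------------------------------------------------------
# NG86 counting primitives
# ---------------------------------------------------------------------------

def ng86_sites(codon: str) -> tuple[float, float]:
    """Expected synonymous and nonsynonymous site counts of one codon.

    At each of the three positions the synonymous fraction is the number
    of synonymous single-nucleotide changes divided by the number of
    non-stop changes (mutations to stop codons are excluded from the
    denominator).  ``s`` sums these fractions and ``n = 3 - s``.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    if codon not in CODON_INDEX:
        raise ValueError(f"invalid codon {codon!r}")
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        viable = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in STOP_CODONS:
                continue
            viable += 1
            if GENETIC_CODE[mut] == aa:
                syn += 1
        if viable:
            s += syn / viable
    return s, 3.0 - s


def _classify_step(c1: str, c2: str) -> str:
    return "syn" if GENETIC_CODE[c1] == GENETIC_CODE[c2] else "nonsyn"


def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts.

    All orderings of the differing positions (1, 2 or 6 pathways) are
    walked; each single-nucleotide step is classified synonymous or
    nonsynonymous; pathways passing through a stop codon are excluded.
    If every pathway is blocked, blocked pathways are included with steps
    to/from stops counted as nonsynonymous (logged).
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if c in STOP_CODONS or c not in CODON_INDEX:
            raise ValueError(f"invalid or stop codon {c!r}")
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    open_paths = []
    blocked_paths = []
    for order in itertools.permutations(diff):
        cur = a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                nd += 1  # only used in the all-blocked fallback
            elif cur in STOP_CODONS:
                blocked = True
                nd += 1
            elif GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked_paths if blocked else open_paths).append((sd, nd))
    paths = open_paths
    if not paths:
        logger.debug("all pathways %s->%s pass through stops; including them", a, b)
        paths = blocked_paths
    sd = float(np.mean([p[0] for p in paths]))
    nd = float(np.mean([p[1] for p in paths]))
    return sd, nd


@lru_cache(maxsize=1)
def _count_tables():
    """Precomputed per-codon site fractions and per-pair difference counts,
    indexed by codon index, for fast whole-alignment counting."""
    s_sites = np.full(64, np.nan)
    for c in SENSE_CODONS:
        s_sites[CODON_INDEX[c]] = ng86_sites(c)[0]
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for ca in SENSE_CODONS:
        for cb in SENSE_CODONS:
            i, j = CODON_INDEX[ca], CODON_INDEX[cb]
            if np.isnan(sd[i, j]):
                d = ng86_differences(ca, cb)
                sd[i, j] = sd[j, i] = d[0]
                nd[i, j] = nd[j, i] = d[1]
    return s_sites, sd, nd


def codon_indices(cds: str) -> np.ndarray:
    return np.array([CODON_INDEX[cds[i:i + 3]] for i in range(0, len(cds), 3)])


# ---------------------------------------------------------------------------
# Sequence containers, alignment, RBH
# ---------------------------------------------------------------------------

@dataclass
class CodingSequence:
    id: str
    species: str
    sequence: str
    class_label: str = "nontoxin"

    def __post_init__(self):
        self.sequence = self.sequence.upper().replace("U", "T")
        if (len(self.sequence) % 3 == 0 and len(self.sequence) >= 6
                and self.sequence[-3:] in STOP_CODONS):
            self.sequence = self.sequence[:-3]  # trim terminal stop
        self.protein = translate(self.sequence)

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3


@dataclass
class OrthologPair:
    id_a: str
    id_b: str
    class_label: str
    codons_a: np.ndarray  # codon indices, gap-free paired columns
    codons_b: np.ndarray
    n_dropped_columns: int = 0

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


def make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def codon_align(seq_a: CodingSequence, seq_b: CodingSequence,
                aligner: PairwiseAligner | None = None) -> OrthologPair:
    """Protein-guided codon alignment: globally align the translations,
    back-thread onto the nucleotides, and drop columns gapped in either
    protein."""
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(seq_a.protein, seq_b.protein)[0]
    idx_a, idx_b = aln.indices  # -1 marks gaps
    keep = (idx_a >= 0) & (idx_b >= 0)
    dropped = int((~keep).sum())
    ca = codon_indices(seq_a.sequence)[idx_a[keep]]
    cb = codon_indices(seq_b.sequence)[idx_b[keep]]
    label = seq_a.class_label if seq_a.class_label == seq_b.class_label else "mixed"
    return OrthologPair(seq_a.id, seq_b.id, label, ca, cb, dropped)


def _kmer_set(protein: str, k: int = 4) -> set:
    return {protein[i:i + k] for i in range(len(protein) - k + 1)}


def _jaccard_topk(kmers_q: list[set], kmers_t: list[set], top: int) -> list[np.ndarray]:
    """Per query, the ``top`` target indices by k-mer Jaccard similarity.

    Computed with a sparse incidence-matrix product instead of per-pair set
    intersections, which is orders of magnitude faster for thousands of
    sequences.
    """
    from scipy import sparse

    vocab: dict[str, int] = {}
    def rows(kmer_sets):
        indptr, indices = [0], []
        for ks in kmer_sets:
            for km in ks:
                indices.append(vocab.setdefault(km, len(vocab)))
            indptr.append(len(indices))
        return indptr, indices

    iq, jq = rows(kmers_q)
    it, jt = rows(kmers_t)
    v = len(vocab)
    mq = sparse.csr_matrix((np.ones(len(jq), np.float32), jq, iq),
                           shape=(len(kmers_q), v))
    mt = sparse.csr_matrix((np.ones(len(jt), np.float32), jt, it),
                           shape=(len(kmers_t), v))
    inter = (mq @ mt.T).toarray()
    size_q = np.array([len(s) for s in kmers_q], np.float32)[:, None]
    size_t = np.array([len(s) for s in kmers_t], np.float32)[None, :]
    union = np.maximum(size_q + size_t - inter, 1.0)
    jac = inter / union
    order = np.argsort(-jac, axis=1, kind="stable")
    return [order[i, :top] for i in range(len(kmers_q))]


def rbh_pairs(seqs_a: list[CodingSequence], seqs_b: list[CodingSequence],
              prescreen_top: int = 8, exact_limit: int = 250_000):
    """Reciprocal-best-hit ortholog pairing under global protein alignment
    (BLOSUM62, gap open -10 / extend -1).

    Sequences are scored within class partitions (toxins against toxins,
    nontoxins against nontoxins).  For large partitions a shared-k-mer
    prescreen keeps the ``prescreen_top`` most k-mer-similar candidates per
    query before alignment; partitions with at most ``exact_limit``
    cross-pairs are aligned exhaustively.  Ties are broken by lexicographic
    id.  Returns ``(pairs, unpaired_a, unpaired_b)`` where unpaired
    sequences are putative duplication/loss candidates.
    """
    if not seqs_a or not seqs_b:
        raise ValueError("both sequence sets must be nonempty")
    aligner = make_aligner()
    pairs: list[OrthologPair] = []
    paired_a, paired_b = set(), set()

    def partition(seqs, toxin):
        return [s for s in seqs if (s.class_label != "nontoxin") == toxin]

    for toxin in (True, False):
        part_a = sorted(partition(seqs_a, toxin), key=lambda s: s.id)
        part_b = sorted(partition(seqs_b, toxin), key=lambda s: s.id)
        if not part_a or not part_b:
            continue
        exhaustive = len(part_a) * len(part_b) <= exact_limit
        if exhaustive:
            cand_a = [range(len(part_b))] * len(part_a)
            cand_b = [range(len(part_a))] * len(part_b)
        else:
            kmers_a = [_kmer_set(s.protein) for s in part_a]
            kmers_b = [_kmer_set(s.protein) for s in part_b]
            cand_a = _jaccard_topk(kmers_a, kmers_b, prescreen_top)
            cand_b = _jaccard_topk(kmers_b, kmers_a, prescreen_top)

        scores: dict[tuple[int, int], float] = {}

        def score(i, j):
            if (i, j) not in scores:
                scores[(i, j)] = aligner.score(part_a[i].protein, part_b[j].protein)
            return scores[(i, j)]

        best_for_a = {}
        for i, sa in enumerate(part_a):
            cand = list(cand_a[i])
            if not cand:
                continue
            sc = [(score(i, j), part_b[j].id, j) for j in cand]
            sc.sort(key=lambda t: (-t[0], t[1]))
            best_for_a[i] = sc[0][2]
        best_for_b = {}
        for j, sb in enumerate(part_b):
            cand = set(cand_b[j]) | {i for i, bj in best_for_a.items() if bj == j}
            sc = [(score(i, j), part_a[i].id, i) for i in cand]
            sc.sort(key=lambda t: (-t[0], t[1]))
            best_for_b[j] = sc[0][2]
        for i, j in best_for_a.items():
            if best_for_b.get(j) == i:
                pairs.append(codon_align(part_a[i], part_b[j], aligner))
                paired_a.add(part_a[i].id)
                paired_b.add(part_b[j].id)

    unpaired_a = [s.id for s in seqs_a if s.id not in paired_a]
    unpaired_b = [s.id for s in seqs_b if s.id not in paired_b]
    return pairs, unpaired_a, unpaired_b


# ---------------------------------------------------------------------------
# Pairwise dN/dS
# ---------------------------------------------------------------------------

@dataclass
class DnDsResult:
    pair_id: str
    class_label: str
    n_codons: int
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float  # NaN when flagged undefined
    filter_flag: str = "pass"


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log1p(-(4.0 / 3.0) * p)


def pairwise_dnds(pair: OrthologPair) -> DnDsResult:
    """NG86 estimate on one gap-free codon alignment.

    Site counts are averaged across the two sequences; proportions are
    Jukes–Cantor corrected.  ``p >= 3/4`` or ``dS == 0`` flag the result
    undefined instead of raising.
    """
    if pair.n_codons < 1:
        raise ValueError("empty codon alignment")
    s_tab, sd_tab, nd_tab = _count_tables()
    s_a = s_tab[pair.codons_a]
    s_b = s_tab[pair.codons_b]
    if np.isnan(s_a).any() or np.isnan(s_b).any():
        raise ValueError("alignment contains stop codons")
    S = float((s_a.sum() + s_b.sum()) / 2.0)
    N = 3.0 * pair.n_codons - S
    Sd = float(sd_tab[pair.codons_a, pair.codons_b].sum())
    Nd = float(nd_tab[pair.codons_a, pair.codons_b].sum())
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    flag = "pass"
    omega = float("nan")
    if np.isnan(dS) or np.isnan(dN):
        flag = "undefined"
    elif dS == 0.0:
        flag = "undefined"
    else:
        omega = dN / dS
    return DnDsResult(f"{pair.id_a}~{pair.id_b}", pair.class_label,
                      pair.n_codons, S, N, Sd, Nd, pS, pN, dS, dN, omega, flag)


def filter_ds_range(results: list[DnDsResult], ds_min: float = 0.001,
                    ds_max: float = 0.10) -> list[DnDsResult]:
    """Flag pairs outside the trusted dS window.

    Very low dS inflates omega (tiny denominator); very high dS marks
    putative misidentified orthologs.  Already-undefined results keep
    their flag.  Returns the same list with flags set.
    """
    for r in results:
        if r.filter_flag == "undefined":
            continue
        if r.dS < ds_min:
            r.filter_flag = "ds_too_low"
        elif r.dS > ds_max:
            r.filter_flag = "ds_too_high"
        else:
            r.filter_flag = "pass"
    return results


@dataclass
class GroupComparison:
    tests: dict            # metric -> (statistic, p-value)
    thresholds: dict       # metric -> nontoxin 95th percentile
    flagged: dict          # metric -> list of toxin pair ids above threshold
    positive_selection: list  # toxin pair ids with omega > 1
    n_toxin: int
    n_nontoxin: int


def compare_groups(results: list[DnDsResult], percentile: float = 95.0,
                   test: str = "ranksums",
                   threshold_source: str = "nontoxin") -> GroupComparison:
    """Toxin-vs-nontoxin comparison of dS, dN and omega over pass-flagged
    pairs.

    Per metric: a two-sample Wilcoxon rank-sum test (``test="ranksums"``;
    ``"signed-rank"`` pairs toxins with nontoxins by rank order and is only
    meaningful for equal group sizes) and a flagging threshold at the 95th
    percentile of the nontoxin (or pooled) distribution.
    """
    passed = [r for r in results if r.filter_flag == "pass"]
    tox = [r for r in passed if r.class_label != "nontoxin"]
    non = [r for r in passed if r.class_label == "nontoxin"]
    if len(tox) < 2 or len(non) < 2:
        raise ValueError("need at least 2 pass-flagged pairs per class")
    tests, thresholds, flagged = {}, {}, {}
    for metric in ("dS", "dN", "omega"):
        tv = np.array([getattr(r, metric) for r in tox])
        nv = np.array([getattr(r, metric) for r in non])
        tv_ok, nv_ok = tv[~np.isnan(tv)], nv[~np.isnan(nv)]
        if test == "ranksums":
            stat, p = stats.ranksums(tv_ok, nv_ok)
        elif test == "signed-rank":
            k = min(len(tv_ok), len(nv_ok))
            stat, p = stats.wilcoxon(np.sort(tv_ok)[:k], np.sort(nv_ok)[:k])
        else:
            raise ValueError(f"unknown test {test!r}")
        pool = nv_ok if threshold_source == "nontoxin" else np.concatenate([tv_ok, nv_ok])
        thr = float(np.percentile(pool, percentile))
        tests[metric] = (float(stat), float(p))
        thresholds[metric] = thr
        flagged[metric] = [r.pair_id for r in tox
                           if not np.isnan(getattr(r, metric)) and getattr(r, metric) > thr]
    pos = [r.pair_id for r in tox if not np.isnan(r.omega) and r.omega > 1.0]
    return GroupComparison(tests, thresholds, flagged, pos, len(tox), len(non))


def results_to_frame(results: list[DnDsResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
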