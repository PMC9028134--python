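"""Synthetic two-species venom-gland cohort with known ground truth.

Emulates the study design the package analyzes: two closely related
pit-viper species, two venom-gland individuals each.  Roughly fifty toxin
orthologs in named families sit on top of a few thousand nontoxin
orthologs; expression is log-normal around shared ortholog baselines with
planted interspecific fold-changes; coding sequences diverge from random
ancestors at controlled dS and omega; spectral counts are drawn
multinomially from the toxin composition with planted translation-
efficiency offsets; and small-RNA libraries carry planted mature-miRNA
counts whose targets have seed sites planted in toxin 3'UTRs.  Every
planted effect is recorded, with its realized value, in a truth record so
downstream recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compose import ExpressionMatrix, clr_transform, tpm_scale
from .evolution import (BASES, CODON_INDEX, GENETIC_CODE, SENSE_CODONS,
                        STOP_CODONS, CodingSequence, _count_tables, translate)
from .mirna import MatureMirna, build_site, seed_scan, SITE_TYPES

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "MirnaPlanEntry",
    "generate_cohort",
    "evolve_ortholog_pair",
    "random_cds",
    "simulate_proteome",
    "simulate_profile_matrix",
    "default_config",
    "write_cohort",
]

# B. cotiara-like venom composition (% of toxin expression) used as the
# default expression plan for species A; species B differs by the planted
# fold-changes.
DEFAULT_FAMILY_PERCENT = {
    "CTL": 46.7, "SVMP": 16.7, "VEGF-F": 11.8, "BPP": 9.0, "SVSP": 8.2,
    "PLA2": 3.6, "CRISP": 1.0, "LAO": 1.5, "NGF": 0.7, "PLB": 0.8,
}

DEFAULT_FAMILY_PLAN = [
    ("CTL", 12), ("SVMP", 14), ("SVSP", 10), ("PLA2", 1), ("BPP", 4),
    ("VEGF-F", 1), ("CRISP", 1), ("LAO", 2), ("NGF", 1), ("PLB", 1),
]


@dataclass
class MirnaPlanEntry:
    id: str
    sequence: str | None          # None: drawn at generation time (22 nt)
    counts: dict                  # species -> mean mature count per sample
    targets: tuple = ()           # toxin base ids carrying a planted site
    site_type: str = "8mer"


@dataclass
class CohortConfig:
    species: tuple = ("cotiara", "fonsecai")
    n_individuals: int = 2
    n_nontoxin_orthologs: int = 3500
    toxin_family_plan: list = field(default_factory=lambda: list(DEFAULT_FAMILY_PLAN))
    toxin_family_percent: dict | None = field(default_factory=lambda: dict(DEFAULT_FAMILY_PERCENT))
    toxin_share: float = 0.6      # expected toxin fraction of total expression
    expr_log_mean: float = 1.0    # natural-log scale, nontoxin baseline
    expr_log_sd: float = 1.5
    individual_noise_sd: float = 0.3
    planted_expression_shifts: list = field(default_factory=list)  # (id, species, fold)
    dnds_plan: list = field(default_factory=list)  # (id, target dS, target omega)
    toxin_ds_median: float = 0.05
    nontoxin_ds_median: float = 0.03
    ds_log_sd: float = 0.5
    toxin_omega_mean: float = 0.67
    nontoxin_omega_mean: float = 0.2
    omega_shape: float = 2.0
    min_codons: int = 100
    max_codons: int = 400
    utr_min_len: int = 80
    utr_max_len: int = 300
    proteome_depth: int = 100_000
    te_offsets: list = field(default_factory=list)  # (toxin id, clr offset, species|None)
    te_noise_sd: dict | float = 0.0  # per-species (or shared) random TE dispersion
    mirna_plan: list = field(default_factory=list)  # MirnaPlanEntry
    coexpression_plan: list = field(default_factory=list)  # (label, member ids)
    module_effect_sd: float = 0.6
    tf_ids: list = field(default_factory=list)
    rng_seed: int = 0
    # layer switches: expression-only cohorts for repeated power simulations
    include_sequences: bool = True
    include_proteome: bool = True
    include_mirna: bool = True

    # -- declared transcript ids ------------------------------------------
    def toxin_ids(self) -> list[str]:
        return [f"{fam}-{i+1}" for fam, n in self.toxin_family_plan for i in range(n)]

    def nontoxin_ids(self) -> list[str]:
        return [f"NT{i+1:05d}" for i in range(self.n_nontoxin_orthologs)]

    def family_of(self) -> dict[str, str]:
        fams = {t: t.rsplit("-", 1)[0] for t in self.toxin_ids()}
        fams.update({t: "nontoxin" for t in self.nontoxin_ids()})
        return fams

    def validate(self) -> None:
        declared = set(self.toxin_ids()) | set(self.nontoxin_ids())
        toxins = set(self.toxin_ids())
        for tid, sp, fold in self.planted_expression_shifts:
            if tid not in declared:
                raise ValueError(f"planted shift on undeclared transcript {tid!r}")
            if sp not in self.species:
                raise ValueError(f"unknown species {sp!r} in expression shift")
            if fold <= 0:
                raise ValueError("fold-changes must be > 0")
        for tid, ds, om in self.dnds_plan:
            if tid not in declared:
                raise ValueError(f"dN/dS plan on undeclared transcript {tid!r}")
            if ds < 0 or om < 0:
                raise ValueError("target dS and omega must be >= 0")
        for tid, _off, sp in self.te_offsets:
            if tid not in toxins:
                raise ValueError(f"TE offset on non-toxin id {tid!r}")
            if sp is not None and sp not in self.species:
                raise ValueError(f"unknown species {sp!r} in TE offset")
        for entry in self.mirna_plan:
            if entry.site_type not in SITE_TYPES:
                raise ValueError(f"invalid site type {entry.site_type!r}")
            for t in entry.targets:
                if t not in toxins:
                    raise ValueError(f"miRNA {entry.id} targets undeclared toxin {t!r}")
        for _label, members in self.coexpression_plan:
            for m in members:
                if m not in declared:
                    raise ValueError(f"coexpression plan names undeclared transcript {m!r}")
        if self.proteome_depth < 0:
            raise ValueError("proteome depth must be >= 0")


@dataclass
class SyntheticCohort:
    config: CohortConfig
    expression: dict        # species -> ExpressionMatrix (TPM)
    cds: dict               # species -> list[CodingSequence]
    utr: dict               # species -> {transcript id -> DNA 3'UTR}
    ortholog_truth: list    # (id in species A, id in species B)
    proteome: dict          # species -> DataFrame (toxin x sample EUSC)
    mirnas: list            # list[MatureMirna]
    mirna_reads: dict       # sample -> list[(sequence, count)]
    tf_ids: list
    truth: dict

    def sample_species(self) -> pd.Series:
        pairs = {}
        for sp, em in self.expression.items():
            for s in em.samples:
                pairs[s] = sp
        return pd.Series(pairs)


def qualify(base_id: str, species: str) -> str:
    return f"{base_id}@{species}"


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random coding sequence: ATG start then random sense codons."""
    if n_codons < 2:
        raise ValueError("need at least 2 codons")
    body = rng.choice([c for c in SENSE_CODONS if c != "ATG"], size=n_codons - 1)
    return "ATG" + "".join(body)


def _expected_p(ds: float) -> float:
    return 0.75 * (1.0 - np.exp(-4.0 * ds / 3.0))


def evolve_ortholog_pair(ancestral_cds: str, target_ds: float,
                         target_omega: float, rng: np.random.Generator):
    """Descend two sequences from a common ancestor at controlled dS/omega.

    Along each branch, uniform random single-nucleotide changes are
    proposed; proposals creating stop codons are rejected outright;
    nonsynonymous proposals are accepted with probability
    ``min(1, omega)`` and synonymous ones with ``min(1, 1/max(omega, 1))``.
    Proposals continue until the branch accumulates its Poisson-drawn
    quota of synonymous events (``target_ds/2 * S`` expected per branch),
    so the expected pairwise dS matches ``target_ds``.  Returns
    ``(cds_a, cds_b, realized_counts)`` with per-branch accepted
    synonymous/nonsynonymous event counts.
    """
    cds = ancestral_cds.upper()
    if len(cds) % 3 or len(cds) < 90:
        raise ValueError("ancestral CDS must be >= 30 codons, in frame")
    translate(cds)  # validates absence of stops
    if target_ds < 0 or target_omega < 0:
        raise ValueError("target dS and omega must be >= 0")
    # expected p_S approaches the 3/4 asymptote where the Jukes-Cantor
    # correction diverges; refuse well before that (p_S >= 0.70, dS ~ 2)
    if _expected_p(target_ds) >= 0.70:
        raise ValueError("target dS saturates the p_S < 3/4 correction domain")
    s_tab, _, _ = _count_tables()
    idx = np.array([CODON_INDEX[cds[i:i + 3]] for i in range(0, len(cds), 3)])
    S = float(s_tab[idx].sum())
    p_syn_acc = min(1.0, 1.0 / max(target_omega, 1.0))
    p_non_acc = min(1.0, target_omega)

    def one_branch(seq: str):
        n_target = rng.poisson(target_ds / 2.0 * S)
        nt = list(seq)
        syn = non = 0
        while syn < n_target:
            pos = int(rng.integers(len(nt)))
            new = BASES[int(rng.integers(4))]
            if new == nt[pos]:
                continue
            c0 = pos - pos % 3
            old_codon = "".join(nt[c0:c0 + 3])
            new_codon = old_codon[:pos - c0] + new + old_codon[pos - c0 + 1:]
            if new_codon in STOP_CODONS:
                continue
            synonymous = GENETIC_CODE[old_codon] == GENETIC_CODE[new_codon]
            p = p_syn_acc if synonymous else p_non_acc
            if p < 1.0 and rng.random() >= p:
                continue
            nt[pos] = new
            if synonymous:
                syn += 1
            else:
                non += 1
        return "".join(nt), syn, non

    cds_a, syn_a, non_a = one_branch(cds)
    cds_b, syn_b, non_b = one_branch(cds)
    N = 3.0 * (len(cds) // 3) - S
    total_syn, total_non = syn_a + syn_b, non_a + non_b
    realized_omega = float("nan")
    if total_syn > 0:
        realized_omega = (total_non / N) / (total_syn / S)
    counts = {"syn_a": syn_a, "nonsyn_a": non_a, "syn_b": syn_b,
              "nonsyn_b": non_b, "S_sites": S, "N_sites": N,
              "realized_omega": realized_omega}
    return cds_a, cds_b, counts


# ---------------------------------------------------------------------------
# Proteome simulation
# ---------------------------------------------------------------------------

def simulate_proteome(expression: ExpressionMatrix, te_offsets, depth: int,
                      rng: np.random.Generator,
                      exclude_families: tuple = ("BPP",)) -> pd.DataFrame:
    """Spectral counts drawn multinomially from the toxin composition.

    Per sample, the protein composition is proportional to
    ``exp(clr(TPM) + offset)`` over toxin transcripts (families in
    ``exclude_families`` — BPPs, which escape proteomic detection — are
    dropped first); ``depth`` spectra are then drawn multinomially.
    ``te_offsets`` is a list of ``(toxin id, clr offset, species|None)``.
    """
    if depth < 0:
        raise ValueError("negative proteome depth")
    toxins = expression.transcripts[expression.is_toxin()
                                    & ~expression.classes.isin(exclude_families)]
    sub = expression.subset(transcripts=toxins)
    if sub.values.empty:
        raise ValueError("no toxin transcripts to simulate a proteome from")
    clr = clr_transform(sub.values)
    counts = pd.DataFrame(0.0, index=sub.transcripts, columns=sub.samples)
    offsets = pd.DataFrame(0.0, index=sub.transcripts, columns=sub.samples)
    for tid, off, sp in te_offsets:
        if tid not in offsets.index:
            continue
        cols = sub.samples if sp is None else [c for c in sub.samples
                                               if sub.species[c] == sp]
        offsets.loc[tid, cols] += off  # entries for the same toxin accumulate
    for col in sub.samples:
        logw = clr[col].to_numpy() + offsets[col].to_numpy()
        w = np.exp(logw - logw.max())
        p = w / w.sum()
        counts[col] = rng.multinomial(int(depth), p).astype(float)
    return counts


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _baselines(config: CohortConfig, rng: np.random.Generator) -> pd.Series:
    """Shared (ancestral) expression baseline per ortholog, linear scale."""
    nontox = config.nontoxin_ids()
    tox = config.toxin_ids()
    base = pd.Series(
        np.exp(rng.normal(config.expr_log_mean, config.expr_log_sd, len(nontox))),
        index=nontox,
    )
    nt_total = float(base.sum())
    tox_total = nt_total * config.toxin_share / (1.0 - config.toxin_share)
    if config.toxin_family_percent:
        pct = config.toxin_family_percent
        total_pct = sum(pct.get(f, 0.0) for f, _n in config.toxin_family_plan)
        vals = {}
        for fam, n in config.toxin_family_plan:
            fam_total = tox_total * pct.get(fam, 0.0) / total_pct
            for i in range(n):
                vals[f"{fam}-{i+1}"] = fam_total / n
        tox_base = pd.Series(vals)
    else:
        raw = np.exp(rng.normal(0.0, config.expr_log_sd, len(tox)))
        tox_base = pd.Series(raw / raw.sum() * tox_total, index=tox)
    return pd.concat([tox_base, base])


def _random_utr(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _random_mirna_seq(rng: np.random.Generator, length: int = 22) -> str:
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, length)])


def _scrub_sites(utr: str, mirnas: list[MatureMirna], keep_for: set,
                 rng: np.random.Generator) -> str:
    """Mutate accidental seed matches of planned miRNAs out of a UTR so
    that planted sites are the only ones, keeping ground truth exact."""
    from .mirna import _revcomp_dna, _to_dna
    for m in mirnas:
        if m.id in keep_for:
            continue
        match6 = _revcomp_dna(_to_dna(m.sequence)[1:7])
        guard = 0
        while match6 in utr and guard < 50:
            pos = utr.find(match6)
            j = pos + int(rng.integers(6))
            repl = "ACGT"[int(rng.integers(4))]
            while repl == utr[j]:
                repl = "ACGT"[int(rng.integers(4))]
            utr = utr[:j] + repl + utr[j + 1:]
            guard += 1
    return utr


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort.  Deterministic for a fixed
    ``config.rng_seed``."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    sp_a, sp_b = config.species
    family_of = config.family_of()
    all_ids = config.toxin_ids() + config.nontoxin_ids()
    truth: dict = {"seed": config.rng_seed, "expression_shifts": [],
                   "dnds": {}, "te_offsets": [], "mirna_targets": [],
                   "coexpression": {}}

    # -- expression --------------------------------------------------------
    base = _baselines(config, rng).reindex(all_ids)
    shift = {(tid, sp): np.log(fold)
             for tid, sp, fold in config.planted_expression_shifts}
    module_of = {}
    for label, members in config.coexpression_plan:
        for m in members:
            module_of[m] = label
    samples = {sp: [f"{sp}_ind{i+1}" for i in range(config.n_individuals)]
               for sp in config.species}
    # Shared per-sample module effects give module members correlated
    # profiles; they are centered within each species so planted species
    # fold-changes and family compositions stay exact in expectation.
    module_effects = {}
    for label, _m in config.coexpression_plan:
        for sp in config.species:
            eff = rng.normal(0.0, config.module_effect_sd, len(samples[sp]))
            eff -= eff.mean()
            for s, e in zip(samples[sp], eff):
                module_effects[(label, s)] = float(e)
    raw = {sp: pd.DataFrame(index=all_ids, columns=samples[sp], dtype=float)
           for sp in config.species}
    for sp in config.species:
        for s in samples[sp]:
            noise = rng.normal(0.0, config.individual_noise_sd, len(all_ids))
            vals = np.log(base.to_numpy()) + noise
            for i, tid in enumerate(all_ids):
                vals[i] += shift.get((tid, sp), 0.0)
                if tid in module_of:
                    vals[i] += module_effects[(module_of[tid], s)]
            raw[sp][s] = np.exp(vals)
    for tid, sp, fold in config.planted_expression_shifts:
        other = sp_b if sp == sp_a else sp_a
        realized = float(np.log2(np.exp(np.log(raw[sp].loc[tid]).mean()
                                        - np.log(raw[other].loc[tid]).mean())))
        if sp == sp_a:  # report as B-over-A convention
            realized = -realized
        truth["expression_shifts"].append(
            {"id": tid, "species": sp, "planted_fold": fold,
             "planted_log2": float(np.log2(fold)), "realized_log2_b_over_a": realized})
    expression = {}
    for sp in config.species:
        classes = pd.Series({qualify(t, sp): family_of[t] for t in all_ids})
        vals = raw[sp].copy()
        vals.index = [qualify(t, sp) for t in all_ids]
        em = ExpressionMatrix(vals, pd.Series({s: sp for s in samples[sp]}), classes)
        expression[sp] = tpm_scale(em)
    truth["coexpression"] = {label: list(members)
                             for label, members in config.coexpression_plan}

    # -- coding sequences --------------------------------------------------
    planned = {tid: (ds, om) for tid, ds, om in config.dnds_plan}
    cds = {sp: [] for sp in config.species}
    ortholog_truth = [(qualify(t, sp_a), qualify(t, sp_b)) for t in all_ids]
    for tid in all_ids if config.include_sequences else []:
        n_codons = int(rng.integers(config.min_codons, config.max_codons + 1))
        anc = random_cds(n_codons, rng)
        if tid in planned:
            ds, om = planned[tid]
        elif family_of[tid] != "nontoxin":
            ds = float(np.exp(rng.normal(np.log(config.toxin_ds_median),
                                         config.ds_log_sd)))
            om = float(rng.gamma(config.omega_shape,
                                 config.toxin_omega_mean / config.omega_shape))
        else:
            ds = float(np.exp(rng.normal(np.log(config.nontoxin_ds_median),
                                         config.ds_log_sd)))
            om = float(rng.gamma(config.omega_shape,
                                 config.nontoxin_omega_mean / config.omega_shape))
        seq_a, seq_b, counts = evolve_ortholog_pair(anc, ds, om, rng)
        id_a, id_b = qualify(tid, sp_a), qualify(tid, sp_b)
        cds[sp_a].append(CodingSequence(id_a, sp_a, seq_a, family_of[tid]))
        cds[sp_b].append(CodingSequence(id_b, sp_b, seq_b, family_of[tid]))
        truth["dnds"][tid] = {"target_ds": ds, "target_omega": om, **counts}

    # -- miRNAs and 3'UTRs -------------------------------------------------
    mirnas = []
    target_plan: dict[str, list] = {}
    mirna_plan = config.mirna_plan if config.include_mirna else []
    for entry in mirna_plan:
        seq = entry.sequence or _random_mirna_seq(rng)
        mirnas.append(MatureMirna(entry.id, seq))
        for t in entry.targets:
            target_plan.setdefault(t, []).append((mirnas[-1], entry.site_type))
    utr = {sp: {} for sp in config.species}
    for tid in config.toxin_ids() if config.include_mirna else []:
        length = int(rng.integers(config.utr_min_len, config.utr_max_len + 1))
        u = _random_utr(length, rng)
        planted_ids = {m.id for m, _st in target_plan.get(tid, [])}
        u = _scrub_sites(u, mirnas, planted_ids, rng)
        for m, stype in target_plan.get(tid, []):
            site = build_site(m, stype)
            pos = int(rng.integers(1, max(2, len(u) - len(site) - 1)))
            u = u[:pos] + site + u[pos + len(site):]
            found = [s for s in seed_scan(m, u, tid) if s.site_type == stype]
            if not found:
                raise RuntimeError(f"failed to plant {stype} site for {m.id} on {tid}")
            truth["mirna_targets"].append(
                {"mirna": m.id, "toxin": tid, "site_type": stype,
                 "utr_position": found[0].start})
        for sp in config.species:
            utr[sp][qualify(tid, sp)] = u

    # -- small-RNA reads ---------------------------------------------------
    mirna_reads = {}
    mature_seq = {m.id: m.sequence.replace("U", "T") for m in mirnas}
    for sp in config.species:
        for s in samples[sp]:
            reads = []
            for entry in mirna_plan:
                mean = float(entry.counts.get(sp, 0.0))
                cnt = int(rng.poisson(mean)) if mean > 0 else 0
                if cnt > 0:
                    reads.append((mature_seq[entry.id], cnt))
            mirna_reads[s] = reads

    # -- proteome ----------------------------------------------------------
    proteome = {}
    truth["te_noise"] = {}
    for sp in config.species if config.include_proteome else []:
        sd = (config.te_noise_sd.get(sp, 0.0)
              if isinstance(config.te_noise_sd, dict) else config.te_noise_sd)
        noise = {t: float(rng.normal(0.0, sd)) if sd > 0 else 0.0
                 for t in config.toxin_ids()}
        truth["te_noise"][sp] = noise
        offsets = [(qualify(t, sp), o, s2) for t, o, s2 in config.te_offsets
                   if s2 in (None, sp)]
        offsets += [(qualify(t, sp), n, sp) for t, n in noise.items() if n != 0.0]
        proteome[sp] = simulate_proteome(expression[sp], offsets,
                                         config.proteome_depth, rng)
    truth["te_offsets"] = [{"toxin": t, "offset": o, "species": sp}
                           for t, o, sp in config.te_offsets]

    return SyntheticCohort(config, expression, cds, utr, ortholog_truth,
                           proteome, mirnas, mirna_reads,
                           list(config.tf_ids), truth)


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """Study-condition defaults: a B. cotiara-like composition for species
    A, interspecific shifts dominated by a 6-fold PLA2 excess in species
    B, positive selection planted on the PLA2 pair (omega 2.41), a pair
    of translationally repressed toxins in species A, and two miRNAs
    over-expressed in species A targeting those toxins with 8mer sites."""
    shifts = [("PLA2-1", "fonsecai", 6.0)]
    shifts += [(f"SVMP-{i}", "fonsecai", 3.0) for i in range(1, 9)]
    shifts += [("SVMP-9", "cotiara", 3.0)]
    shifts += [(f"SVSP-{i}", "fonsecai", 2.5) for i in range(1, 9)]
    shifts += [(f"CTL-{i}", "fonsecai", 2.0) for i in range(1, 5)]
    shifts += [("BPP-1", "cotiara", 2.0), ("NGF-1", "cotiara", 2.0)]
    te_offsets = [("SVMP-10", -2.0, "cotiara"), ("CTL-5", -2.0, "cotiara")]
    mirna_plan = [
        MirnaPlanEntry(f"mir-{i}", None, {"cotiara": 500.0, "fonsecai": 500.0})
        for i in range(1, 11)
    ] + [
        MirnaPlanEntry("mir-rep1", None, {"cotiara": 800.0, "fonsecai": 150.0},
                       targets=("SVMP-10",), site_type="8mer"),
        MirnaPlanEntry("mir-rep2", None, {"cotiara": 900.0, "fonsecai": 200.0},
                       targets=("CTL-5",), site_type="8mer"),
    ]
    tf_ids = ["NT00001", "NT00002", "NT00003", "NT00004", "NT00005"]
    coexpression_plan = [
        ("M1", [t for t, sp, _f in shifts if sp == "fonsecai"] + tf_ids[:2]),
        ("M2", ["SVMP-9", "BPP-1", "NGF-1"] + tf_ids[2:3]),
    ]
    cfg = CohortConfig(
        planted_expression_shifts=shifts,
        dnds_plan=[("PLA2-1", 0.05, 2.41)],
        te_offsets=te_offsets,
        te_noise_sd={"cotiara": 1.4, "fonsecai": 0.6},
        mirna_plan=mirna_plan,
        coexpression_plan=coexpression_plan,
        tf_ids=tf_ids,
        rng_seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# Small planted-profile matrices for module-detection validation
# ---------------------------------------------------------------------------

def simulate_profile_matrix(n_samples: int, blocks: dict, n_noise: int,
                            noise_sd: float, rng: np.random.Generator,
                            profile_sd: float = 2.0):
    """Expression-like matrix with planted coexpression blocks.

    ``blocks`` maps block label -> member count; each block shares one
    random sample profile (sd ``profile_sd``) plus member-level noise;
    ``n_noise`` transcripts are pure noise.  Returns ``(matrix, labels)``
    where labels assigns block names to planted rows only.
    """
    rows, labels = {}, {}
    for label, n in blocks.items():
        profile = rng.normal(0.0, profile_sd, n_samples)
        for i in range(n):
            tid = f"{label}_t{i+1}"
            rows[tid] = profile + rng.normal(0.0, noise_sd, n_samples)
            labels[tid] = label
    for i in range(n_noise):
        rows[f"noise_{i+1}"] = rng.normal(0.0, noise_sd, n_samples)
    mat = pd.DataFrame(rows).T
    mat.columns = [f"s{j+1}" for j in range(n_samples)]
    return mat, pd.Series(labels)


# ---------------------------------------------------------------------------
# On-disk form
# ---------------------------------------------------------------------------

def _write_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write FASTA (CDS, 3'UTR, matures, reads), TSV (expression,
    proteome) and JSON (truth record) under ``outdir``."""
    import os
    os.makedirs(outdir, exist_ok=True)
    for sp in cohort.config.species:
        if cohort.cds.get(sp):
            _write_fasta(os.path.join(outdir, f"cds_{sp}.fasta"),
                         [(c.id, c.sequence) for c in cohort.cds[sp]])
        if cohort.utr.get(sp):
            _write_fasta(os.path.join(outdir, f"utr_{sp}.fasta"),
                         sorted(cohort.utr[sp].items()))
        cohort.expression[sp].to_tsv(os.path.join(outdir, f"expression_{sp}.tsv"))
        if cohort.proteome.get(sp) is not None:
            cohort.proteome[sp].to_csv(os.path.join(outdir, f"proteome_{sp}.tsv"), sep="\t")
    if cohort.mirnas:
        _write_fasta(os.path.join(outdir, "mature_mirnas.fasta"),
                     [(m.id, m.sequence) for m in cohort.mirnas])
    for sample, reads in cohort.mirna_reads.items():
        _write_fasta(os.path.join(outdir, f"smallrna_{sample}.fasta"),
                     [(f"read{i+1}_x{int(c)}", s) for i, (s, c) in enumerate(reads)])
    with open(os.path.join(outdir, "ortholog_truth.tsv"), "w") as fh:
        fh.write("id_a\tid_b\n")
        for a, b in cohort.ortholog_truth:
            fh.write(f"{a}\t{b}\n")
    with open(os.path.join(outdir, "tf_ids.txt"), "w") as fh:
        fh.write("\n".join(cohort.tf_ids) + "\n")
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
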