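"""End-to-end orchestration of the comparative venom-gland analysis.

Stages run in dependency order: normalize -> orthologs -> (outliers, dN/dS,
modules, miRNA, proteome) -> report.  Every stage writes its intermediate
table; the final machine-readable report collects per-species venom
composition, outlier calls, selection statistics, module content, miRNA
regulatory candidates and omics correlations, along with the provenance
(seed and parameters) needed to regenerate it byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import os
from importlib.metadata import version as _pkg_version

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cohort import CohortConfig, MirnaPlanEntry, SyntheticCohort, generate_cohort
from .compose import ExpressionMatrix, clr_transform
from .evolution import (compare_groups, filter_ds_range, pairwise_dnds,
                        rbh_pairs, results_to_frame)
from .mirna import collapse_and_quantify, integrate_candidates, scan_all
from .modules import (CoexpressionConfig, annotate_modules, detect_modules,
                      vst_filter)
from .outliers import (calls_to_frame, interspecific_divergence,
                       intraspecific_divergence)
from .proteome import (correlate_omics, low_te_set,
                       translation_efficiency)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all", "compose_family_summary", "load_config"]


class PipelineConfig:
    """Validated single-config view: a `simulate` block (CohortConfig
    fields) or an `inputs` directory, plus optional per-stage blocks."""

    STAGE_DEFAULTS = {
        "outliers": {"percentile": 99.0, "threshold": 1.0, "mode": "absolute"},
        "dnds": {"ds_min": 0.001, "ds_max": 0.10, "percentile": 95.0},
        "modules": {"beta": 10.0, "min_module_size": 1, "cut_height": 0.25,
                    "variance_filter_keep": None},
        "mirna": {"max_mismatch": 1, "expr_ratio_min": 1.0, "te_quantile": 0.25},
        "proteome": {"line": "ols", "te_quantile": 0.25},
    }

    def __init__(self, raw: dict):
        self.raw = dict(raw)
        self.simulate = raw.get("simulate")
        self.inputs = raw.get("inputs")
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs a 'simulate' or an 'inputs' block")
        if self.inputs is not None and not os.path.isdir(self.inputs.get("dir", "")):
            raise ValueError(f"input directory not found: {self.inputs!r}")
        self.stages = {}
        for stage, defaults in self.STAGE_DEFAULTS.items():
            block = dict(defaults)
            block.update(raw.get("stages", {}).get(stage, {}))
            self.stages[stage] = block
        self.seed = int(raw.get("seed", 0))

    def cohort_config(self) -> CohortConfig:
        block = dict(self.simulate or {})
        block.setdefault("rng_seed", self.seed)
        plan = block.pop("mirna_plan", None)
        if plan is not None:
            block["mirna_plan"] = [
                e if isinstance(e, MirnaPlanEntry) else MirnaPlanEntry(
                    e["id"], e.get("sequence"), e["counts"],
                    tuple(e.get("targets", ())), e.get("site_type", "8mer"))
                for e in plan
            ]
        if block.pop("use_defaults", True):
            return cohort_mod.default_config(block.pop("rng_seed"), **block)
        return CohortConfig(**block)


def load_config(path) -> PipelineConfig:
    import yaml
    with open(path) as fh:
        return PipelineConfig(yaml.safe_load(fh))


def compose_family_summary(expr: ExpressionMatrix) -> pd.Series:
    """Per-family percentage of total toxin TPM, averaged over samples."""
    toxin = expr.is_toxin()
    if not toxin.any():
        raise ValueError("no toxin transcripts")
    vals = expr.values.loc[toxin]
    fams = expr.classes.loc[toxin]
    per_sample = vals.groupby(fams).sum() / vals.sum(axis=0) * 100.0
    return per_sample.mean(axis=1).sort_values(ascending=False)


def _base_id(qualified: str) -> str:
    return qualified.split("@", 1)[0]


def _species_mean_clr(expr: ExpressionMatrix, transcripts) -> pd.Series:
    sub = expr.subset(transcripts=transcripts)
    return clr_transform(sub.values).mean(axis=1)


def _load_cohort(indir: str) -> SyntheticCohort:
    """Read a cohort from the on-disk layout `write_cohort` produces."""
    from Bio import SeqIO
    cfg = CohortConfig()  # species names inferred below
    expr, cds, utr, proteome = {}, {}, {}, {}
    species = sorted({f.split("_", 1)[1].rsplit(".", 1)[0]
                      for f in os.listdir(indir) if f.startswith("expression_")})
    from .evolution import CodingSequence
    for sp in species:
        expr[sp] = ExpressionMatrix.from_tsv(os.path.join(indir, f"expression_{sp}.tsv"))
        em = expr[sp]
        cds[sp] = [CodingSequence(r.id, sp, str(r.seq),
                                  em.classes.get(r.id, "nontoxin"))
                   for r in SeqIO.parse(os.path.join(indir, f"cds_{sp}.fasta"), "fasta")]
        utr_path = os.path.join(indir, f"utr_{sp}.fasta")
        utr[sp] = {r.id: str(r.seq) for r in SeqIO.parse(utr_path, "fasta")} \
            if os.path.exists(utr_path) else {}
        prot_path = os.path.join(indir, f"proteome_{sp}.tsv")
        proteome[sp] = pd.read_csv(prot_path, sep="\t", index_col=0) \
            if os.path.exists(prot_path) else None
    cfg.species = tuple(species)
    from .mirna import MatureMirna
    mat_path = os.path.join(indir, "mature_mirnas.fasta")
    mirnas = [MatureMirna(r.id, str(r.seq))
              for r in SeqIO.parse(mat_path, "fasta")] if os.path.exists(mat_path) else []
    mirna_reads = {}
    for sp in species:
        for s in expr[sp].samples:
            path = os.path.join(indir, f"smallrna_{s}.fasta")
            if os.path.exists(path):
                mirna_reads[s] = [(str(r.seq), float(r.id.rsplit("_x", 1)[1]))
                                  for r in SeqIO.parse(path, "fasta")]
    tf_path = os.path.join(indir, "tf_ids.txt")
    tf_ids = [l.strip() for l in open(tf_path) if l.strip()] if os.path.exists(tf_path) else []
    truth_path = os.path.join(indir, "truth.json")
    truth = json.load(open(truth_path)) if os.path.exists(truth_path) else {}
    return SyntheticCohort(cfg, expr, cds, utr, [], proteome, mirnas,
                           mirna_reads, tf_ids, truth)


def run_all(config: PipelineConfig, outdir: str) -> dict:
    """Execute every stage and return (and write) the comparative report."""
    os.makedirs(outdir, exist_ok=True)
    report: dict = {"provenance": {
        "package": "venomdelta", "version": _pkg_version("venomdelta"),
        "seed": config.seed, "stages": config.stages,
    }}

    def stage(name):
        logger.info("stage: %s", name)

    # -- inputs ------------------------------------------------------------
    stage("inputs")
    if config.simulate is not None:
        cohort = generate_cohort(config.cohort_config())
        cohort_mod.write_cohort(cohort, os.path.join(outdir, "cohort"))
    else:
        cohort = _load_cohort(config.inputs["dir"])
    sp_a, sp_b = cohort.config.species[:2]
    expr_a, expr_b = cohort.expression[sp_a], cohort.expression[sp_b]

    # -- composition summary ----------------------------------------------
    stage("composition")
    report["composition_pct"] = {
        sp: {k: round(v, 3) for k, v in compose_family_summary(cohort.expression[sp]).items()}
        for sp in (sp_a, sp_b)
    }

    # -- intraspecific outliers -------------------------------------------
    stage("outliers-intra")
    opts = config.stages["outliers"]
    report["intraspecific_outliers"] = {}
    for sp in (sp_a, sp_b):
        band, calls = intraspecific_divergence(
            cohort.expression[sp], sp, percentile=opts["percentile"],
            threshold=opts["threshold"], mode=opts["mode"])
        frame = calls_to_frame(calls, band)
        frame.to_csv(os.path.join(outdir, f"outliers_intra_{sp}.tsv"),
                     sep="\t", index=False)
        flagged = [c.id for c in calls if c.is_outlier]
        report["intraspecific_outliers"][sp] = {
            "n_toxins_tested": len(calls), "n_flagged": len(flagged),
            "flagged": sorted(flagged), "half_width": band.half_width,
        }
        logger.info("%s: %d of %d toxins outside the 99%% band",
                    sp, len(flagged), len(calls))

    # -- orthologs ---------------------------------------------------------
    stage("orthologs")
    pairs, unpaired_a, unpaired_b = rbh_pairs(cohort.cds[sp_a], cohort.cds[sp_b])
    pair_map = [(p.id_a, p.id_b) for p in pairs]
    report["orthologs"] = {
        "n_pairs": len(pairs),
        "n_toxin_pairs": sum(1 for p in pairs if p.class_label != "nontoxin"),
        "unpaired": {sp_a: sorted(unpaired_a), sp_b: sorted(unpaired_b)},
    }

    # -- interspecific outliers -------------------------------------------
    stage("outliers-inter")
    band, calls = interspecific_divergence(
        expr_a, expr_b, pair_map, percentile=opts["percentile"],
        threshold=opts["threshold"], mode=opts["mode"])
    calls_to_frame(calls, band).to_csv(
        os.path.join(outdir, "outliers_inter.tsv"), sep="\t", index=False)
    flagged = [c for c in calls if c.is_outlier]
    report["interspecific_outliers"] = {
        "n_toxin_pairs_tested": len(calls), "n_flagged": len(flagged),
        "flagged": sorted([(c.id, c.direction) for c in flagged]),
        "half_width": band.half_width,
    }

    # -- dN/dS -------------------------------------------------------------
    stage("dnds")
    dopts = config.stages["dnds"]
    results = [pairwise_dnds(p) for p in pairs]
    results = filter_ds_range(results, dopts["ds_min"], dopts["ds_max"])
    results_to_frame(results).to_csv(os.path.join(outdir, "dnds.tsv"),
                                     sep="\t", index=False)
    comparison = compare_groups(results, percentile=dopts["percentile"])
    passed = [r for r in results if r.filter_flag == "pass"]
    tox_omega = [r.omega for r in passed
                 if r.class_label != "nontoxin" and not np.isnan(r.omega)]
    report["dnds"] = {
        "n_pairs": len(results),
        "n_pass": len(passed),
        "flags": {f: sum(1 for r in results if r.filter_flag == f)
                  for f in ("pass", "ds_too_low", "ds_too_high", "undefined")},
        "mean_toxin_omega": float(np.mean(tox_omega)) if tox_omega else None,
        "tests": {m: {"statistic": s, "p_value": p}
                  for m, (s, p) in comparison.tests.items()},
        "percentile_95": comparison.thresholds,
        "positive_selection": sorted(comparison.positive_selection),
        "flagged_by_metric": {m: sorted(v) for m, v in comparison.flagged.items()},
    }

    # -- coexpression modules ---------------------------------------------
    stage("modules")
    mopts = config.stages["modules"]
    joint = pd.DataFrame({
        **{s: expr_a.values.loc[[a for a, _b in pair_map], s].to_numpy()
           for s in expr_a.samples},
        **{s: expr_b.values.loc[[b for _a, b in pair_map], s].to_numpy()
           for s in expr_b.samples},
    }, index=[_base_id(a) for a, _b in pair_map])
    classes = pd.Series({_base_id(p.id_a): p.class_label for p in pairs})
    mconfig = CoexpressionConfig(
        beta=mopts["beta"], min_module_size=mopts["min_module_size"],
        cut_height=mopts["cut_height"],
        variance_filter_keep=mopts["variance_filter_keep"])
    filtered = vst_filter(joint, mconfig)
    assignment = detect_modules(filtered, mconfig)
    tf_bases = [_base_id(t) for t in cohort.tf_ids]
    module_report = annotate_modules(assignment, classes, tf_bases)
    assignment.assignment.rename("module").to_csv(
        os.path.join(outdir, "modules.tsv"), sep="\t")
    report["modules"] = {
        "n_transcripts_filtered": int(filtered.shape[0]),
        "n_modules": assignment.n_modules,
        "modules": module_report.to_dict(orient="records"),
    }

    # -- proteome ----------------------------------------------------------
    stage("proteome")
    popts = config.stages["proteome"]
    te_frames, report_prot = [], {}
    if all(cohort.proteome.get(sp) is not None for sp in (sp_a, sp_b)):
        for sp in (sp_a, sp_b):
            prot = cohort.proteome[sp]
            pooled = prot.sum(axis=1)  # species-level pooled spectral counts
            frac = pooled / pooled.sum()
            prot_clr = clr_transform(frac)
            tr_clr = _species_mean_clr(cohort.expression[sp], prot.index)
            corr = correlate_omics(tr_clr, prot_clr, line=popts["line"])
            te = translation_efficiency(tr_clr.to_frame(sp), prot_clr.to_frame(sp))
            te_frames.append(te)
            report_prot[sp] = {
                "rho": round(corr.rho, 4), "r": round(corr.r, 4),
                "slope": round(corr.slope, 4), "intercept": round(corr.intercept, 4),
                "n": corr.n,
                "low_te": low_te_set(te, sp, popts["te_quantile"]),
            }
        te_all = pd.concat(te_frames, ignore_index=True)
        te_all.to_csv(os.path.join(outdir, "translation_efficiency.tsv"),
                      sep="\t", index=False)
        report["proteome"] = report_prot
    else:
        te_all = None
        logger.info("no proteome tables: skipping proteome and miRNA integration")

    # -- miRNA -------------------------------------------------------------
    stage("mirna")
    if cohort.mirnas and cohort.mirna_reads:
        miopts = config.stages["mirna"]
        counts, unassigned = collapse_and_quantify(
            cohort.mirna_reads, cohort.mirnas, max_mismatch=miopts["max_mismatch"])
        counts.to_csv(os.path.join(outdir, "mirna_counts.tsv"), sep="\t")
        utrs = {_base_id(t): u for t, u in cohort.utr[sp_a].items()}
        sites = scan_all(cohort.mirnas, utrs)
        pd.DataFrame([s.__dict__ for s in sites]).to_csv(
            os.path.join(outdir, "mirna_sites.tsv"), sep="\t", index=False)
        report["mirna"] = {
            "n_known_detected": int((counts.sum(axis=1) > 0).sum()),
            "n_sites": len(sites),
        }
        if te_all is not None:
            te_base = te_all.assign(toxin_id=te_all.toxin_id.map(_base_id))
            cands = integrate_candidates(
                counts, cohort.sample_species(), sites, te_base,
                target_species=sp_a, expr_ratio_min=miopts["expr_ratio_min"],
                te_quantile=miopts["te_quantile"])
            report["mirna"]["candidates"] = [
                {"mirna": c.mirna_id, "toxin": c.toxin_id,
                 "log2_ratio": round(c.expr_log_ratio, 3),
                 "te": round(c.te, 3), "n_sites": c.n_sites}
                for c in cands
            ]

    # -- report ------------------------------------------------------------
    stage("report")
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, pd.Series)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
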