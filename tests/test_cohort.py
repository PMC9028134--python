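"""Synthetic cohort generator: determinism, planted-effect readback,
sequence evolution controls, proteome simulation."""

import filecmp
import json
import math
import os

import numpy as np
import pytest

from venomdelta.cohort import (CohortConfig, MirnaPlanEntry, default_config,
                               evolve_ortholog_pair, generate_cohort, qualify,
                               random_cds, simulate_profile_matrix,
                               simulate_proteome, write_cohort)
from venomdelta.compose import ExpressionMatrix, clr_transform
from venomdelta.evolution import (STOP_CODONS, OrthologPair, codon_indices,
                                  pairwise_dnds, translate)
from venomdelta.mirna import seed_scan


def small_config(seed=0, **overrides):
    base = dict(
        n_nontoxin_orthologs=30,
        toxin_family_plan=[("PLA2", 2), ("SVMP", 3), ("CTL", 2)],
        toxin_family_percent={"PLA2": 30.0, "SVMP": 50.0, "CTL": 20.0},
        rng_seed=seed,
    )
    base.update(overrides)
    return CohortConfig(**base)


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = small_config(
            seed=7,
            planted_expression_shifts=[("PLA2-1", "fonsecai", 6.0)],
            mirna_plan=[MirnaPlanEntry("mir-x", None,
                                       {"cotiara": 100.0, "fonsecai": 10.0},
                                       targets=("SVMP-1",))],
            te_offsets=[("SVMP-1", -2.0, None)],
        )
        d1, d2 = tmp_path / "c1", tmp_path / "c2"
        write_cohort(generate_cohort(small_config(
            seed=7,
            planted_expression_shifts=[("PLA2-1", "fonsecai", 6.0)],
            mirna_plan=[MirnaPlanEntry("mir-x", None,
                                       {"cotiara": 100.0, "fonsecai": 10.0},
                                       targets=("SVMP-1",))],
            te_offsets=[("SVMP-1", -2.0, None)],
        )), d1)
        write_cohort(generate_cohort(cfg), d2)
        files = sorted(os.listdir(d1))
        assert files == sorted(os.listdir(d2))
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, files, shallow=False)
        assert not mismatch and not errors

    def test_different_seeds_differ(self):
        c1 = generate_cohort(small_config(seed=1, include_sequences=False,
                                          include_proteome=False,
                                          include_mirna=False))
        c2 = generate_cohort(small_config(seed=2, include_sequences=False,
                                          include_proteome=False,
                                          include_mirna=False))
        assert not c1.expression["cotiara"].values.equals(
            c2.expression["cotiara"].values)


class TestExpressionLayer:
    def test_columns_are_tpm(self):
        c = generate_cohort(small_config(include_sequences=False,
                                         include_proteome=False,
                                         include_mirna=False))
        for em in c.expression.values():
            assert np.allclose(em.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_null_cohort_family_composition_matches_plan(self):
        cfg = small_config(seed=3, n_nontoxin_orthologs=200,
                           individual_noise_sd=0.0, include_sequences=False,
                           include_proteome=False, include_mirna=False)
        c = generate_cohort(cfg)
        em = c.expression["cotiara"]
        tox = em.values[em.is_toxin().to_numpy()]
        fam_pct = tox.groupby(em.classes[em.is_toxin()]).sum().mean(axis=1)
        fam_pct = 100.0 * fam_pct / fam_pct.sum()
        assert abs(fam_pct["SVMP"] - 50.0) < 1e-6
        assert abs(fam_pct["PLA2"] - 30.0) < 1e-6

    def test_toxin_share_respected(self):
        cfg = small_config(seed=4, toxin_share=0.6, individual_noise_sd=0.0,
                           include_sequences=False, include_proteome=False,
                           include_mirna=False)
        c = generate_cohort(cfg)
        em = c.expression["fonsecai"]
        share = em.values[em.is_toxin().to_numpy()].sum().iloc[0] / 1e6
        assert abs(share - 0.6) < 1e-6

    def test_sixfold_shift_readback(self):
        cfg = small_config(seed=5, n_nontoxin_orthologs=300,
                           planted_expression_shifts=[("PLA2-1", "fonsecai", 6.0)],
                           include_sequences=False, include_proteome=False,
                           include_mirna=False)
        c = generate_cohort(cfg)
        rec = c.truth["expression_shifts"][0]
        assert rec["id"] == "PLA2-1"
        assert abs(rec["planted_log2"] - math.log2(6.0)) < 1e-12
        # realized value recorded in the truth must match a direct readback
        la = np.log2(c.expression["cotiara"].values.loc["PLA2-1@cotiara"]).mean()
        lb = np.log2(c.expression["fonsecai"].values.loc["PLA2-1@fonsecai"]).mean()
        # TPM rescaling shifts all transcripts of a species equally;
        # remove it with a reference nontoxin
        ra = np.log2(c.expression["cotiara"].values.loc["NT00001@cotiara"]).mean()
        rb = np.log2(c.expression["fonsecai"].values.loc["NT00001@fonsecai"]).mean()
        direct = (lb - rb) - (la - ra)
        # reference transcript adds its own noise: loose agreement only
        assert abs(direct - rec["realized_log2_b_over_a"]) < 1.5
        assert abs(rec["realized_log2_b_over_a"] - math.log2(6.0)) < 1.0

    def test_zero_noise_shift_exact(self):
        cfg = small_config(seed=6, individual_noise_sd=0.0,
                           planted_expression_shifts=[("SVMP-1", "cotiara", 4.0)],
                           include_sequences=False, include_proteome=False,
                           include_mirna=False)
        c = generate_cohort(cfg)
        rec = c.truth["expression_shifts"][0]
        # shift planted in species A: B-over-A convention flips the sign
        assert abs(rec["realized_log2_b_over_a"] + 2.0) < 1e-9

    def test_validate_rejects_bad_plans(self):
        with pytest.raises(ValueError, match="undeclared"):
            generate_cohort(small_config(
                planted_expression_shifts=[("GHOST-1", "cotiara", 2.0)]))
        with pytest.raises(ValueError, match="unknown species"):
            generate_cohort(small_config(
                planted_expression_shifts=[("PLA2-1", "atrox", 2.0)]))
        with pytest.raises(ValueError, match="non-toxin"):
            generate_cohort(small_config(te_offsets=[("NT00001", -1.0, None)]))


class TestEvolve:
    def test_zero_ds_returns_ancestor(self, rng):
        anc = random_cds(100, rng)
        a, b, counts = evolve_ortholog_pair(anc, 0.0, 1.0, rng)
        assert a == anc and b == anc
        assert counts["syn_a"] == 0 and counts["nonsyn_a"] == 0

    def test_zero_omega_only_synonymous(self, rng):
        anc = random_cds(150, rng)
        a, b, counts = evolve_ortholog_pair(anc, 0.05, 0.0, rng)
        assert counts["nonsyn_a"] == 0 and counts["nonsyn_b"] == 0
        assert translate(a) == translate(anc) == translate(b)

    def test_no_stop_codons_ever(self, rng):
        anc = random_cds(120, rng)
        a, b, _ = evolve_ortholog_pair(anc, 0.08, 2.0, rng)
        for seq in (a, b):
            codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
            assert not codons & STOP_CODONS

    def test_saturating_ds_refused(self, rng):
        anc = random_cds(100, rng)
        with pytest.raises(ValueError, match="3/4"):
            evolve_ortholog_pair(anc, 10.0, 1.0, rng)

    def test_estimator_recovers_target_ds(self, rng):
        # average NG86 dS over replicates tracks the planted dS
        target = 0.05
        est = []
        for _ in range(30):
            anc = random_cds(300, rng)
            a, b, _ = evolve_ortholog_pair(anc, target, 0.5, rng)
            pair = OrthologPair("a", "b", "nontoxin",
                                codon_indices(a), codon_indices(b))
            est.append(pairwise_dnds(pair).dS)
        assert abs(np.mean(est) - target) / target < 0.15

    def test_realized_omega_matches_counts(self, rng):
        anc = random_cds(200, rng)
        _a, _b, c = evolve_ortholog_pair(anc, 0.06, 1.5, rng)
        total_syn = c["syn_a"] + c["syn_b"]
        total_non = c["nonsyn_a"] + c["nonsyn_b"]
        expect = (total_non / c["N_sites"]) / (total_syn / c["S_sites"])
        assert abs(c["realized_omega"] - expect) < 1e-12


class TestProteome:
    def _expr(self, seed=0):
        c = generate_cohort(small_config(seed=seed, include_sequences=False,
                                         include_proteome=False,
                                         include_mirna=False))
        return c.expression["cotiara"]

    def test_zero_depth_all_zero(self, rng):
        counts = simulate_proteome(self._expr(), [], 0, rng)
        assert (counts.to_numpy() == 0).all()

    def test_depth_conserved(self, rng):
        counts = simulate_proteome(self._expr(), [], 5000, rng)
        assert (counts.sum(axis=0) == 5000).all()

    def test_excluded_family_absent(self, rng):
        cfg = small_config(toxin_family_plan=[("BPP", 2), ("SVMP", 3)],
                           toxin_family_percent={"BPP": 40.0, "SVMP": 60.0},
                           include_sequences=False, include_proteome=False,
                           include_mirna=False)
        c = generate_cohort(cfg)
        counts = simulate_proteome(c.expression["cotiara"], [], 1000, rng)
        assert not any(i.startswith("BPP") for i in counts.index)

    def test_te_offset_recovered_at_high_depth(self, rng):
        expr = self._expr(seed=9)
        tid = "SVMP-1@cotiara"
        counts = simulate_proteome(expr, [(tid, -2.0, None)], 2_000_000, rng)
        frac = counts.sum(axis=1)
        prot_clr = clr_transform(frac / frac.sum())
        tox = expr.subset(transcripts=counts.index)
        tr_clr = clr_transform(tox.values).mean(axis=1)
        te = prot_clr - tr_clr
        n = len(counts)
        # clr centering spreads a single offset: expected -2 * (1 - 1/n)
        assert abs((te[tid] - te.drop(tid).mean()) + 2.0) < 0.15

    def test_negative_depth_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_proteome(self._expr(), [], -1, rng)


class TestMirnaLayer:
    def test_planted_sites_exact_ground_truth(self):
        plan = [
            MirnaPlanEntry("mir-a", None, {"cotiara": 200.0, "fonsecai": 20.0},
                           targets=("SVMP-1", "CTL-1"), site_type="8mer"),
            MirnaPlanEntry("mir-b", None, {"cotiara": 150.0, "fonsecai": 150.0},
                           targets=("PLA2-1",), site_type="7mer-m8"),
            MirnaPlanEntry("mir-c", None, {"cotiara": 90.0, "fonsecai": 90.0}),
        ]
        c = generate_cohort(small_config(seed=11, mirna_plan=plan,
                                         include_sequences=False,
                                         include_proteome=False))
        planted = {(t["mirna"], t["toxin"], t["site_type"])
                   for t in c.truth["mirna_targets"]}
        assert planted == {("mir-a", "SVMP-1", "8mer"), ("mir-a", "CTL-1", "8mer"),
                           ("mir-b", "PLA2-1", "7mer-m8")}
        # scanning every UTR finds the planted sites and nothing else
        mirnas = {m.id: m for m in c.mirnas}
        found = set()
        for tid, u in c.utr["cotiara"].items():
            base = tid.split("@")[0]
            for m in c.mirnas:
                for s in seed_scan(m, u, base):
                    found.add((m.id, base, s.site_type))
        assert found == planted

    def test_read_counts_follow_plan(self):
        plan = [MirnaPlanEntry("mir-a", "ACGUACGUACGUACGUACGUAC",
                               {"cotiara": 400.0, "fonsecai": 40.0})]
        c = generate_cohort(small_config(seed=12, mirna_plan=plan,
                                         include_sequences=False,
                                         include_proteome=False))
        cot = [sum(n for _s, n in c.mirna_reads[s])
               for s in c.mirna_reads if s.startswith("cotiara")]
        fon = [sum(n for _s, n in c.mirna_reads[s])
               for s in c.mirna_reads if s.startswith("fonsecai")]
        assert min(cot) > max(fon)


class TestLayerSwitches:
    def test_expression_only(self):
        c = generate_cohort(small_config(include_sequences=False,
                                         include_proteome=False,
                                         include_mirna=False))
        assert not any(c.cds.values()) and not c.proteome and not c.mirnas
        assert len(c.expression) == 2

    def test_sequences_present_by_default(self):
        c = generate_cohort(small_config(seed=13))
        n = 30 + 7
        assert len(c.cds["cotiara"]) == n == len(c.cds["fonsecai"])
        assert len(c.ortholog_truth) == n


class TestWriteCohort:
    def test_layout_and_roundtrip(self, tmp_path):
        cfg = small_config(seed=14, mirna_plan=[
            MirnaPlanEntry("mir-a", None, {"cotiara": 50.0, "fonsecai": 50.0})])
        c = generate_cohort(cfg)
        out = tmp_path / "cohort"
        write_cohort(c, out)
        for sp in ("cotiara", "fonsecai"):
            assert (out / f"expression_{sp}.tsv").exists()
            assert (out / f"cds_{sp}.fasta").exists()
            assert (out / f"proteome_{sp}.tsv").exists()
        em = ExpressionMatrix.from_tsv(out / "expression_cotiara.tsv")
        orig = c.expression["cotiara"]
        assert list(em.transcripts) == list(orig.transcripts)
        assert np.allclose(em.values, orig.values, rtol=1e-5)
        assert (em.classes == orig.classes).all()
        truth = json.loads((out / "truth.json").read_text())
        assert truth["seed"] == 14


class TestDefaultConfig:
    def test_validates_and_is_deterministic(self):
        cfg = default_config(0)
        cfg.validate()
        assert cfg.rng_seed == 0
        assert any(t == ("PLA2-1", "fonsecai", 6.0)
                   for t in cfg.planted_expression_shifts)
        assert cfg.dnds_plan == [("PLA2-1", 0.05, 2.41)]

    def test_overrides_applied(self):
        cfg = default_config(3, n_nontoxin_orthologs=100)
        assert cfg.n_nontoxin_orthologs == 100 and cfg.rng_seed == 3


def test_simulate_profile_matrix_shapes(rng):
    mat, labels = simulate_profile_matrix(6, {"A": 4, "B": 3}, 10, 0.3, rng)
    assert mat.shape == (17, 6)
    assert set(labels) == {"A", "B"} and len(labels) == 7
    # block members correlate strongly with each other
    corr = np.corrcoef(mat.loc[["A_t1", "A_t2"]])[0, 1]
    assert corr > 0.8
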