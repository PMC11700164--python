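"""Annotation windows, LD scores, the stratified regression, FDR, conditioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellherit._utils import stage_rng
from cellherit.config import SimConfig
from cellherit.simulate import HaplotypePanel, generate_gwas, simulate_sumstats, _snp_table
from cellherit.sldsc import (
    EnrichmentResult,
    SnpMembership,
    StratifiedLDRegression,
    build_annotation,
    compute_ld_scores,
    conditional_scan,
    fdr_adjust,
    sldsc_fit,
)


def _snps(positions, chrom="chr1"):
    return pd.DataFrame({
        "snp": [f"rs{i}" for i in range(len(positions))],
        "chrom": chrom,
        "pos": positions,
    })


def _gene_row(gene, chrom, start, end):
    return {"gene": gene, "chrom": chrom, "start": start, "end": end,
            "tss": start, "strand": "+", "biotype": "protein_coding", "emhc": False}


class TestBuildAnnotation:
    def test_window_interval_oracle(self):
        """Gene [1000, 2000) on chr1 with a 100 kb window: membership is the
        half-open interval [0, 102000)."""
        ann = pd.DataFrame([_gene_row("g1", "chr1", 1000, 2000)])
        snps = _snps([500, 101_999, 102_000])
        member = build_annotation({"g1"}, ann, snps, window_kb=100).indicator
        np.testing.assert_array_equal(member, [True, True, False])

    def test_zero_window_half_open_boundaries(self):
        ann = pd.DataFrame([_gene_row("g1", "chr1", 1000, 2000)])
        snps = _snps([999, 1000, 1999, 2000])
        member = build_annotation({"g1"}, ann, snps, window_kb=0).indicator
        np.testing.assert_array_equal(member, [False, True, True, False])

    def test_other_chromosome_not_member(self):
        ann = pd.DataFrame([_gene_row("g1", "chr1", 1000, 2000)])
        snps = _snps([1500], chrom="chr2")
        assert not build_annotation({"g1"}, ann, snps, window_kb=100).indicator[0]

    def test_empty_or_unknown_gene_sets_rejected(self):
        ann = pd.DataFrame([_gene_row("g1", "chr1", 1000, 2000)])
        snps = _snps([1500])
        with pytest.raises(ValueError, match="empty"):
            build_annotation(set(), ann, snps)
        with pytest.raises(ValueError, match="zz"):
            build_annotation({"zz"}, ann, snps)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_bruteforce_interval_scan(self, seed):
        rng = np.random.default_rng(seed)
        genes = pd.DataFrame([
            _gene_row(f"g{i}", f"chr{rng.integers(1, 4)}",
                      s := int(rng.integers(0, 500_000)), s + int(rng.integers(1, 50_000)))
            for i in range(8)
        ])
        snps = pd.DataFrame({
            "snp": [f"rs{i}" for i in range(300)],
            "chrom": [f"chr{c}" for c in rng.integers(1, 4, size=300)],
            "pos": rng.integers(0, 600_000, size=300),
        })
        window = 20_000
        member = build_annotation(set(genes["gene"]), genes, snps,
                                  window_kb=window / 1000).indicator
        brute = np.zeros(len(snps), dtype=bool)
        for j, (chrom, pos) in enumerate(zip(snps["chrom"], snps["pos"])):
            for _, g in genes.iterrows():
                if g["chrom"] == chrom and max(g["start"] - window, 0) <= pos < g["end"] + window:
                    brute[j] = True
        np.testing.assert_array_equal(member, brute)


class TestLdScores:
    def _panel(self, seed, n, m, block=10, rho=0.5):
        cfg = SimConfig(seed=seed, n_snps=m, n_individuals=50, n_panel=n,
                        ld_block_size=block, block_rho=rho)
        _, panel = generate_gwas(cfg, np.zeros(m, dtype=bool))
        return panel

    def test_independent_snps_have_unit_base_scores(self):
        panel = self._panel(seed=1, n=500, m=400, rho=0.0)
        ld = compute_ld_scores(panel, [], window_snps=20)
        assert abs(ld.scores["base"].mean() - 1.0) < 0.05

    def test_equicorrelated_block_closed_form(self):
        """Block of size B with correlation rho: E[l_base] = 1 + (B-1) rho^2."""
        b, rho = 10, 0.6
        panel = self._panel(seed=2, n=800, m=500, block=b, rho=rho)
        ld = compute_ld_scores(panel, [], window_snps=25)
        expected = 1 + (b - 1) * rho**2
        assert abs(ld.scores["base"].mean() - expected) < 0.15

    def test_empty_annotation_scores_zero(self):
        panel = self._panel(seed=3, n=200, m=100)
        ld = compute_ld_scores(
            panel, [SnpMembership("none", np.zeros(100, dtype=bool))], window_snps=10
        )
        assert (ld.scores["none"] == 0).all()

    def test_base_dominates_subannotations(self):
        panel = self._panel(seed=4, n=200, m=200)
        rng = np.random.default_rng(0)
        sub = rng.random(200) < 0.3
        ld = compute_ld_scores(panel, [SnpMembership("sub", sub)], window_snps=15)
        assert (ld.scores["base"] >= ld.scores["sub"] - 1e-9).all()

    def test_monomorphic_snps_warn_and_score_zero(self):
        panel = self._panel(seed=5, n=100, m=50)
        panel.genotypes[:, 7] = 0.0
        with pytest.warns(UserWarning, match="monomorphic"):
            ld = compute_ld_scores(panel, [], window_snps=5)
        assert ld.scores["base"].iloc[7] == 0.0
        assert ld.n_monomorphic == 1

    def test_tiny_panel_rejected(self):
        panel = self._panel(seed=6, n=100, m=20)
        panel.genotypes = panel.genotypes[:2]
        with pytest.raises(ValueError, match="3 samples"):
            compute_ld_scores(panel, [], window_snps=5)


@pytest.fixture(scope="module")
def fitted_inputs():
    cfg = SimConfig(seed=11, n_snps=2000, n_individuals=1000, n_panel=300)
    mem = np.zeros(2000, dtype=bool)
    mem[200:500] = True
    ss, panel = generate_gwas(cfg, mem)
    ld = compute_ld_scores(panel, [SnpMembership("t", mem)], window_snps=25)
    return ss, ld, mem


@pytest.fixture(scope="module")
def cond_setup():
    cfg = SimConfig(seed=14, n_snps=2000, n_individuals=1000, n_panel=300)
    mem_a = np.zeros(2000, dtype=bool)
    mem_a[:400] = True
    mem_b = np.zeros(2000, dtype=bool)
    mem_b[1000:1400] = True
    ss, panel = generate_gwas(cfg, mem_a)
    members = {"a": mem_a, "b": mem_b, "zero": np.zeros(2000, dtype=bool)}

    def ld_builder(names):
        return compute_ld_scores(
            panel, [SnpMembership(n, members[n]) for n in names], window_snps=25
        )

    tdep_sets = {n: {"dummy"} for n in members}
    return ss, ld_builder, tdep_sets


class TestSldscFit:
    def test_too_few_snps_for_jackknife(self, fitted_inputs):
        ss, ld, _ = fitted_inputs
        with pytest.raises(ValueError, match="n_blocks"):
            sldsc_fit(ss, ld, "t", n_blocks=1500)

    def test_collinear_annotations_rejected(self, fitted_inputs):
        ss, ld, mem = fitted_inputs
        ld.scores["t2"] = ld.scores["t"]
        ld.memberships["t2"] = ld.memberships["t"]
        with pytest.raises(ValueError, match="collinear"):
            sldsc_fit(ss, ld, "t", conditional=["t2"], n_blocks=100)

    def test_results_object_summary(self, fitted_inputs):
        ss, ld, _ = fitted_inputs
        model = StratifiedLDRegression(ss, ld, "t", n_blocks=100)
        res = model.fit()
        summ = res.summary()
        assert set(summ["annotation"]) == {"base", "t"}
        assert summ.loc[summ["is_target"], "tau_hat"].iloc[0] == res.tau_hat
        assert 0 < res.p_one_sided <= 1
        assert res.se > 0

    def test_tau_increases_with_planted_enrichment(self):
        """Mean estimated coefficient rises across planted enrichment levels."""
        mem = np.zeros(2000, dtype=bool)
        mem[::4] = True
        mean_taus = []
        for tau_level in (1.0, 5.0, 15.0):
            cfg = SimConfig(seed=12, n_snps=2000, n_individuals=1000,
                            n_panel=300, enrich_tau=tau_level, h2=0.5)
            _, panel = generate_gwas(cfg, mem)
            ld = compute_ld_scores(panel, [SnpMembership("t", mem)], window_snps=25)
            snps = panel.snps.copy()
            taus = []
            for rep in range(10):
                rng = stage_rng(12, "experiment", rep)
                ss = simulate_sumstats(cfg, mem, rng, snps=snps)
                taus.append(sldsc_fit(ss, ld, "t", n_blocks=100).tau_hat)
            mean_taus.append(np.mean(taus))
        assert mean_taus[0] < mean_taus[1] < mean_taus[2]

    def test_jackknife_se_tracks_empirical_sd(self):
        """Jackknife SE within 2x of the replicate SD of tau_hat."""
        cfg = SimConfig(seed=13, n_snps=3000, n_individuals=1500, n_panel=300)
        mem = np.zeros(3000, dtype=bool)
        mem[::5] = True
        _, panel = generate_gwas(cfg, mem)
        ld = compute_ld_scores(panel, [SnpMembership("t", mem)], window_snps=25)
        snps = panel.snps.copy()
        taus, ses = [], []
        for rep in range(30):
            rng = stage_rng(13, "experiment", rep)
            ss = simulate_sumstats(cfg, mem, rng, snps=snps)
            res = sldsc_fit(ss, ld, "t", n_blocks=100)
            taus.append(res.tau_hat)
            ses.append(res.se)
        emp_sd = np.std(taus, ddof=1)
        assert np.mean(ses) < 2 * emp_sd
        assert emp_sd < 2 * np.mean(ses)


class TestFdrAndConditional:
    def _results(self, pvals, trait="t"):
        return [
            EnrichmentResult(trait=trait, annotation=f"a{i}", tau_hat=0.0,
                             se=1.0, z=0.0, p_one_sided=p, enrichment_ratio=1.0)
            for i, p in enumerate(pvals)
        ]

    def test_bh_hand_computation(self):
        res = fdr_adjust(self._results([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose([r.fdr for r in res], [0.04] * 4)

    def test_single_test_fdr_equals_p(self):
        res = fdr_adjust(self._results([0.2]))
        assert res[0].fdr == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        res = fdr_adjust(self._results([1.0, 1.0, 1.0]))
        assert all(r.fdr == 1.0 for r in res)

    def test_fdr_grouped_per_trait(self):
        res = self._results([0.01, 0.04], trait="A") + self._results([0.5], trait="B")
        res = fdr_adjust(res)
        assert res[2].fdr == pytest.approx(0.5)
        assert res[0].fdr == pytest.approx(0.02)

    def test_conditioning_on_empty_annotation_is_noop(self, cond_setup):
        ss, ld_builder, tdep_sets = cond_setup
        res = conditional_scan(ss, ld_builder, tdep_sets,
                               [("a", None), ("a", "zero")], n_blocks=100)
        assert res[0].p_one_sided == pytest.approx(res[1].p_one_sided, rel=1e-9)

    def test_self_conditioning_rejected(self, cond_setup):
        ss, ld_builder, tdep_sets = cond_setup
        with pytest.raises(ValueError, match="itself"):
            conditional_scan(ss, ld_builder, tdep_sets, [("a", "a")])

    def test_overlapping_annotation_loses_signal_when_conditioned(self):
        """Signal planted in annotation A; a 90%-overlapping non-causal copy
        B is significant marginally but not once A is in the model."""
        cfg = SimConfig(seed=15, n_snps=6000, n_individuals=4000,
                        n_panel=400, enrich_tau=12.0, h2=0.5)
        mem_a = np.zeros(6000, dtype=bool)
        mem_a[:600] = True
        mem_b = np.zeros(6000, dtype=bool)
        mem_b[60:660] = True  # 90% overlap with A
        ss, panel = generate_gwas(cfg, mem_a)
        members = {"a": mem_a, "b": mem_b}

        def ld_builder(names):
            return compute_ld_scores(
                panel, [SnpMembership(n, members[n]) for n in names], window_snps=25
            )
        tdep = {n: {"dummy"} for n in members}
        res = conditional_scan(ss, ld_builder, tdep,
                               [("b", None), ("b", "a")], n_blocks=100)
        marginal, conditional = res[0], res[1]
        assert marginal.p_one_sided < 0.05
        assert conditional.p_one_sided > marginal.p_one_sided
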