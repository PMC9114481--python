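"""Association calling, BH adjustment, enrichment, proximity, diff methylation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from lncmeth.annotation import GeneModel
from lncmeth.immune import (bh_adjust, category_enrichment, count_pathways,
                            diff_methylation, interval_gap, link_pathways,
                            spearman_assoc)


class TestBHAdjust:
    def test_hand_value(self):
        """[0.01, 0.02, 0.03, 0.04] -> all 0.04 by the step-up rule."""
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4, atol=1e-12
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03, abs=1e-15)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0] * 3)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_nan_propagates(self):
        q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])


def _assoc_inputs(n=40, n_genes=5, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    pm = pd.DataFrame(rng.uniform(size=(n, n_genes)), index=samples,
                      columns=[f"L{i}" for i in range(n_genes)])
    fractions = pd.DataFrame(rng.dirichlet(np.ones(3), size=n), index=samples,
                             columns=["CD8", "CD4_Eff", "Fib"])
    clusters = pd.Series("C1", index=samples)
    return pm, fractions, clusters


class TestSpearmanAssoc:
    def test_monotone_transform_gives_rho_one(self):
        pm, fractions, clusters = _assoc_inputs()
        fractions["CD8"] = np.exp(3 * pm["L0"])  # strictly increasing map
        res = spearman_assoc(pm, fractions, clusters)
        rec = res[(res.gene_id == "L0") & (res.cell_type == "CD8")].iloc[0]
        assert rec.rho == pytest.approx(1.0)
        assert rec.called

    def test_monotone_invariance(self):
        """Any strictly monotone transform of either variable leaves rho fixed."""
        pm, fractions, clusters = _assoc_inputs(seed=2)
        base = spearman_assoc(pm, fractions, clusters)
        pm2 = pm ** 3
        fractions2 = fractions.copy()
        fractions2["CD8"] = np.log(fractions2["CD8"] + 1e-9)
        res = spearman_assoc(pm2, fractions2, clusters)
        np.testing.assert_allclose(base["rho"], res["rho"], atol=1e-12)

    def test_thresholds_are_conjunctive(self):
        pm, fractions, clusters = _assoc_inputs()
        res = spearman_assoc(pm, fractions, clusters, rho_threshold=0.99)
        # even tiny p cannot rescue a rho below the threshold
        assert not res["called"].any()

    def test_small_cluster_skipped(self):
        pm, fractions, clusters = _assoc_inputs(n=5)
        with pytest.warns(UserWarning, match="skipped"):
            res = spearman_assoc(pm, fractions, clusters)
        assert res.empty

    def test_constant_column_gives_missing_rho(self):
        pm, fractions, clusters = _assoc_inputs()
        pm["L0"] = 0.5
        res = spearman_assoc(pm, fractions, clusters)
        l0 = res[res.gene_id == "L0"]
        assert l0["rho"].isna().all()
        assert not l0["called"].any()

    def test_adjusted_at_least_raw(self):
        pm, fractions, clusters = _assoc_inputs(seed=4)
        res = spearman_assoc(pm, fractions, clusters)
        ok = res.dropna(subset=["p_raw", "p_adj"])
        assert (ok["p_adj"] >= ok["p_raw"] - 1e-15).all()

    def test_planted_copula_pairs_detected(self):
        """Sensitivity to planted rho = 0.5 couplings at n = 100."""
        from lncmeth.synthetic import (SyntheticConfig, generate_annotation,
                                       generate_signature, simulate_beta)
        from lncmeth.annotation import promoters_of
        from lncmeth.methylation import (map_probes_to_promoters,
                                         summarize_promoter)
        hits = trials = 0
        for seed in range(5):
            cfg = SyntheticConfig(n_samples=100, n_lncrna=60, n_pcg=10,
                                  n_assoc_lncrna=10, assoc_rho=0.5, seed=seed)
            ann = generate_annotation(cfg)
            sig = generate_signature(cfg)
            beta, truth = simulate_beta(cfg, ann, sig)
            mapping = map_probes_to_promoters(
                ann.manifest, promoters_of(ann.lncrnas))
            pm = summarize_promoter(beta, mapping).values
            clusters = pd.Series("C1", index=pm.index)
            res = spearman_assoc(pm, truth.mixture_of_sample, clusters)
            idx = res.set_index(["gene_id", "cell_type"])["called"]
            for row in truth.planted_assoc.itertuples():
                trials += 1
                hits += bool(idx.get((row.gene_id, row.cell_type), False))
        assert hits / trials >= 0.9


class TestCategoryEnrichment:
    def test_perfect_association_hand_p(self):
        """2x2 table [[10,0],[0,10]]: two-sided p = 2 / C(20,10)."""
        categories = pd.Series(
            ["hypo"] * 10 + ["inter"] * 10,
            index=[f"g{i}" for i in range(20)],
        )
        called = {f"g{i}" for i in range(10)}
        res = category_enrichment(called, categories).set_index("category")
        assert res.loc["hypo", "p"] == pytest.approx(2 / comb(20, 10, exact=True))

    def test_balanced_table_null(self):
        categories = pd.Series(["hypo"] * 10 + ["inter"] * 10,
                               index=[f"g{i}" for i in range(20)])
        called = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(10, 15)}
        res = category_enrichment(called, categories).set_index("category")
        assert res.loc["hypo", "odds_ratio"] == pytest.approx(1.0)
        assert res.loc["hypo", "p"] == pytest.approx(1.0)

    def test_degenerate_margin_flagged(self):
        categories = pd.Series(["hypo"] * 4, index=list("abcd"))
        res = category_enrichment({"a", "b"}, categories)
        assert res["degenerate"].all()
        assert (res["p"] == 1.0).all()

    def test_null_calls_give_uniform_p(self):
        """Calls independent of category: enrichment p approximately uniform."""
        from scipy.stats import kstest
        rng = np.random.default_rng(0)
        pvals = []
        genes = [f"g{i}" for i in range(60)]
        categories = pd.Series(rng.choice(["hyper", "hypo", "inter"], 60),
                               index=genes)
        for _ in range(300):
            called = set(rng.choice(genes, size=20, replace=False))
            res = category_enrichment(called, categories)
            pvals.extend(res["p"])
        # Fisher p-values are discrete; check the null rejection rate stays
        # near nominal (binomial MC slack for ~300 effective replicates,
        # since the per-rep category tests share one called set)
        slack = 2 * np.sqrt(0.05 * 0.95 / 300)
        assert np.mean(np.array(pvals) < 0.05) <= 0.05 + slack


def _interval_gene(gene_id, start, end, biotype="protein_coding"):
    return GeneModel(gene_id=gene_id, biotype=biotype, chrom="chr1",
                     strand="+", start=start, end=end, exon_count=1)


class TestLinkPathways:
    TABLE = pd.DataFrame({"gene_id": ["P1", "P1", "P2"],
                          "pathway": ["A", "B", "C"]})

    def test_within_window_linked(self):
        lnc = [_interval_gene("L1", 1_000, 5_000, "lncRNA")]
        pcg = [_interval_gene("P1", 12_000, 14_000)]
        links = link_pathways(lnc, pcg, self.TABLE)
        assert len(links) == 1
        assert links.iloc[0]["distance"] == 7_000
        assert links.iloc[0]["pathways"] == "A;B"

    def test_strict_window(self):
        lnc = [_interval_gene("L1", 0, 5_000, "lncRNA")]
        pcg = [_interval_gene("P1", 15_001, 16_000)]
        assert link_pathways(lnc, pcg, self.TABLE).empty  # gap 10001

    def test_overlap_distance_zero(self):
        lnc = [_interval_gene("L1", 1_000, 5_000, "lncRNA")]
        pcg = [_interval_gene("P1", 4_000, 6_000)]
        links = link_pathways(lnc, pcg, self.TABLE)
        assert links.iloc[0]["distance"] == 0

    def test_unannotated_gene_empty_pathways(self):
        lnc = [_interval_gene("L1", 1_000, 5_000, "lncRNA")]
        pcg = [_interval_gene("P9", 6_000, 7_000)]
        links = link_pathways(lnc, pcg, self.TABLE)
        assert links.iloc[0]["pathways"] == ""

    def test_distance_symmetric(self):
        assert interval_gap(0, 10, 20, 30) == interval_gap(20, 30, 0, 10) == 10

    def test_pathway_count_union(self):
        lnc = [_interval_gene("L1", 1_000, 5_000, "lncRNA")]
        pcg = [_interval_gene("P1", 6_000, 7_000), _interval_gene("P2", 8_000, 9_000)]
        table = pd.DataFrame({"gene_id": ["P1", "P1", "P2", "P2"],
                              "pathway": ["A", "B", "B", "C"]})
        links = link_pathways(lnc, pcg, table)
        counts = count_pathways(links, {"L1"})
        assert counts["L1"] == 3  # union {A, B, C}

    def test_no_links_count_zero(self):
        counts = count_pathways(pd.DataFrame(columns=["lncrna_id", "pathways"]),
                                {"L1"})
        assert counts["L1"] == 0

    def test_planted_linkage_truth_recovered(self, small_dataset):
        ds = small_dataset
        links = link_pathways(ds.annotation.lncrnas, ds.annotation.pcgs,
                              ds.pathway_table)
        found = set(map(tuple, links[["lncrna_id", "pcg_id"]].to_numpy()))
        planted = set(map(tuple,
                          ds.annotation.linked_pairs[["lncrna_id", "pcg_id"]].to_numpy()))
        assert found == planted


class TestDiffMethylation:
    def _pm(self, cluster_beta, rest_beta, n=20, sd=0.02, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.concatenate([
            rng.normal(cluster_beta, sd, n), rng.normal(rest_beta, sd, n)
        ]).clip(0, 1)
        pm = pd.DataFrame({"G1": vals}, index=[f"s{i}" for i in range(2 * n)])
        clusters = pd.Series(["C1"] * n + ["C2"] * n, index=pm.index)
        return pm, clusters

    def test_large_shift_called(self):
        pm, clusters = self._pm(0.9, 0.2)
        res = diff_methylation(pm, clusters)
        rec = res[(res.cluster == "C1") & (res.gene_id == "G1")].iloc[0]
        assert rec.delta == pytest.approx(0.7, abs=0.03)
        assert rec.called

    def test_small_delta_not_called_despite_tiny_p(self):
        pm, clusters = self._pm(0.50, 0.35, n=200, sd=0.01)
        res = diff_methylation(pm, clusters)
        rec = res[res.cluster == "C1"].iloc[0]
        assert rec.p < 1e-10 and abs(rec.delta) < 0.2
        assert not rec.called

    def test_identical_groups_not_called(self):
        pm = pd.DataFrame({"G1": [0.5] * 10}, index=[f"s{i}" for i in range(10)])
        clusters = pd.Series(["C1"] * 5 + ["C2"] * 5, index=pm.index)
        res = diff_methylation(pm, clusters)
        assert (res["delta"] == 0).all()
        assert (res["p"] == 1.0).all()
        assert not res["called"].any()

    def test_sign_convention_cluster_minus_rest(self):
        pm, clusters = self._pm(0.2, 0.9)
        res = diff_methylation(pm, clusters).set_index("cluster")
        assert res.loc["C1", "delta"] < 0 < res.loc["C2", "delta"]
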