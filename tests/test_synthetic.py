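"""Synthetic cohort generator: determinism, planted truth, and error paths."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from lncmeth.synthetic import (SyntheticConfig, generate_annotation,
                               generate_pathway_table, generate_signature,
                               simulate_beta, simulate_dataset,
                               simulate_survival, write_dataset)


def _cfg(**kw):
    base = dict(n_samples=30, n_clusters=2, n_lncrna=20, n_pcg=10,
                n_assoc_lncrna=2, seed=1)
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_samples=0),
            dict(n_clusters=31),  # > n_samples
            dict(beta_precision=0),
            dict(frac_hyper=0.7, frac_hypo=0.5),
            dict(assoc_rho=1.0),
            dict(hazard_ratio=0),
            dict(censor_rate=1.0),
            dict(cluster_shift=1.5),
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            _cfg(**kw).validate()


class TestGenerateAnnotation:
    def test_probe_count_near_mean(self):
        ann = generate_annotation(_cfg(n_lncrna=10, n_pcg=1, probes_per_promoter=3))
        lnc_probes = ann.probe_gene[ann.probe_gene.str.startswith("LNC")]
        assert 15 <= len(lnc_probes) <= 50  # ~30 expected, >= 1 per promoter
        assert set(ann.probe_gene[lnc_probes.index]) <= {g.gene_id for g in ann.lncrnas}

    def test_deterministic_under_seed(self):
        a1 = generate_annotation(_cfg())
        a2 = generate_annotation(_cfg())
        pd.testing.assert_frame_equal(a1.manifest, a2.manifest)
        assert [g.gene_id for g in a1.genes] == [g.gene_id for g in a2.genes]

    def test_zero_flag_fraction(self):
        ann = generate_annotation(_cfg(flag_fraction=0.0))
        flags = ann.manifest[["chrXY", "snp_overlap", "non_unique", "not_on_epic"]]
        assert not flags.to_numpy().any()

    def test_promoters_do_not_overlap(self):
        from lncmeth.annotation import promoters_of
        ann = generate_annotation(_cfg(n_lncrna=50, n_pcg=25))
        proms = sorted(promoters_of(ann.genes), key=lambda p: p.start)
        for a, b in zip(proms[:-1], proms[1:]):
            assert a.end <= b.start

    def test_linkage_truth_within_window(self):
        ann = generate_annotation(_cfg(n_pcg=10, frac_near_pcg=0.5))
        assert len(ann.linked_pairs) == 5
        assert (ann.linked_pairs["distance"] <= 10_000).all()
        # genes not in the linkage truth are farther than 10 kb from any lncRNA
        genes = {g.gene_id: g for g in ann.genes}
        linked = set(map(tuple, ann.linked_pairs[["lncrna_id", "pcg_id"]].to_numpy()))
        for lnc in ann.lncrnas:
            for pcg in ann.pcgs:
                gap = max(0, max(lnc.start, pcg.start) - min(lnc.end, pcg.end))
                assert (gap <= 10_000) == ((lnc.gene_id, pcg.gene_id) in linked)

    def test_impossible_geometry_raises(self):
        with pytest.raises(ValueError, match="cannot fit"):
            generate_annotation(_cfg(n_lncrna=100), chrom_length=50_000)


class TestGenerateSignature:
    def test_block_structure_and_rank(self):
        sig = generate_signature(_cfg())
        assert sig.values.shape == (500, 10)
        assert np.linalg.matrix_rank(sig.values.to_numpy()) == 10
        assert list(sig.cell_types)[0] == "CD14"

    def test_pairwise_column_correlation_low(self):
        sig = generate_signature(_cfg())
        corr = np.corrcoef(sig.values.to_numpy().T)
        off = corr[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.5

    def test_identical_profiles_rejected(self):
        from lncmeth.deconvolution import SignatureMatrix
        dup = pd.DataFrame({"A": [0.9, 0.1, 0.5], "B": [0.9, 0.1, 0.5]})
        with pytest.raises(ValueError, match="rank"):
            SignatureMatrix(dup)

    def test_fewer_probes_than_cell_types_rejected(self):
        from lncmeth.deconvolution import SignatureMatrix
        wide = pd.DataFrame(np.full((3, 5), 0.5))
        with pytest.raises(ValueError, match="rank"):
            SignatureMatrix(wide)


class TestSimulateBeta:
    def test_deterministic(self):
        b1, _ = simulate_beta(_cfg())
        b2, _ = simulate_beta(_cfg())
        pd.testing.assert_frame_equal(b1, b2)

    def test_values_in_unit_interval(self):
        beta, _ = simulate_beta(_cfg())
        assert beta.to_numpy().min() >= 0 and beta.to_numpy().max() <= 1

    def test_mixture_rows_sum_to_one(self):
        _, truth = simulate_beta(_cfg())
        sums = truth.mixture_of_sample.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_noiseless_limit_reproduces_signature_mixture(self):
        cfg = _cfg(beta_precision=np.inf)
        ann = generate_annotation(cfg)
        sig = generate_signature(cfg)
        beta, truth = simulate_beta(cfg, ann, sig)
        expected = np.clip(
            truth.mixture_of_sample.to_numpy() @ sig.values.to_numpy().T, 0.01, 0.99
        )
        np.testing.assert_allclose(
            beta[list(sig.probe_ids)].to_numpy(), expected, atol=1e-12
        )

    def test_noiseless_promoter_means_match_planted_categories(self):
        cfg = _cfg(beta_precision=np.inf)
        ann = generate_annotation(cfg)
        beta, truth = simulate_beta(cfg, ann)
        mu = {"hyper": 0.85, "hypo": 0.15}
        for gene, cat in truth.category_of_lncrna.items():
            probes = ann.probe_gene[ann.probe_gene == gene].index
            special = set(truth.planted_assoc["gene_id"]) | set(
                truth.cluster_informative.index
            )
            if cat in mu and gene not in special:
                assert np.allclose(beta[list(probes)].to_numpy(), mu[cat])

    def test_planted_spearman_correlation_close_to_target(self):
        cfg = _cfg(n_samples=150, n_lncrna=60, n_assoc_lncrna=6, assoc_rho=0.6)
        ann = generate_annotation(cfg)
        sig = generate_signature(cfg)
        beta, truth = simulate_beta(cfg, ann, sig)
        from scipy.stats import spearmanr
        rhos = []
        for row in truth.planted_assoc.itertuples():
            probes = list(ann.probe_gene[ann.probe_gene == row.gene_id].index)
            pm = beta[probes].mean(axis=1)
            rho = spearmanr(pm, truth.mixture_of_sample[row.cell_type]).statistic
            rhos.append(rho * np.sign(row.rho))
        assert np.mean(rhos) == pytest.approx(0.6, abs=0.12)


class TestSimulateSurvival:
    def test_zero_censoring_all_events(self):
        cfg = _cfg(censor_rate=0.0)
        _, truth = simulate_beta(cfg)
        surv = simulate_survival(truth, cfg)
        assert (surv["event"] == 1).all()

    def test_censor_rate_approximately_achieved(self):
        cfg = _cfg(n_samples=2000, censor_rate=0.3)
        _, truth = simulate_beta(cfg)
        surv = simulate_survival(truth, cfg)
        assert (surv["event"] == 0).mean() == pytest.approx(0.3, abs=0.05)

    def test_cluster_hazard_ratio_spans_range(self):
        cfg = _cfg(hazard_ratio=3.0, n_clusters=2)
        _, truth = simulate_beta(cfg)
        simulate_survival(truth, cfg)
        hazards = truth.survival_params
        assert hazards[1] / hazards[0] == pytest.approx(3.0)

    def test_invalid_hazard_rejected(self):
        cfg = _cfg()
        _, truth = simulate_beta(cfg)
        bad = dataclasses.replace(cfg, hazard_ratio=-1.0)
        with pytest.raises(ValueError, match="hazard_ratio"):
            simulate_survival(truth, bad)


class TestDatasetSerialization:
    def test_roundtrip_deterministic_bytes(self, tmp_path):
        cfg = _cfg()
        p1 = write_dataset(simulate_dataset(cfg), tmp_path / "a")
        p2 = write_dataset(simulate_dataset(cfg), tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_pathway_table_covers_pcgs(self):
        cfg = _cfg()
        ann = generate_annotation(cfg)
        table = generate_pathway_table(cfg, ann)
        assert set(table["gene_id"]) == {g.gene_id for g in ann.pcgs}
        assert table.groupby("gene_id").size().between(1, 3).all()
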