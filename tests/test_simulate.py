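"""Synthetic study generator: determinism, planted structure, null behaviour."""

import filecmp

import numpy as np
import pytest
from scipy import stats

from regnet.simulate import (
    GroundTruth,
    SimulationConfig,
    export_truth,
    read_truth,
    simulate_study,
    write_study,
)


def _pooled_population_r(study, mirna_id, gene_id, cond="DN"):
    """Pooled (case+control) subject-level correlation from the latent tables."""
    x_df, y_df, _mask = study.latent[cond]
    x = x_df.loc[mirna_id].to_numpy()
    y = y_df.loc[gene_id].to_numpy()
    return np.corrcoef(x, y)[0, 1]


class TestDeterminism:
    def test_same_seed_byte_identical_study(self, tmp_path):
        cfg = dict(seed=7, n_genes=60, n_mirnas=8, repression_edges=4,
                   sponge_edges=8, lnc_mrna_edges=4, targets_per_tf=3,
                   upstream_bp=200, downstream_bp=50)
        f1 = write_study(simulate_study(SimulationConfig(**cfg)), tmp_path / "a")
        f2 = write_study(simulate_study(SimulationConfig(**cfg)), tmp_path / "b")
        for key in f1:
            assert filecmp.cmp(f1[key], f2[key], shallow=False), key

    def test_different_seed_differs(self, tmp_path):
        m1 = simulate_study(SimulationConfig(seed=1, n_genes=50, n_mirnas=6,
                                             repression_edges=3,
                                             upstream_bp=100, downstream_bp=50))
        m2 = simulate_study(SimulationConfig(seed=2, n_genes=50, n_mirnas=6,
                                             repression_edges=3,
                                             upstream_bp=100, downstream_bp=50))
        assert not np.allclose(m1.matrices["mRNA-DN"].values,
                               m2.matrices["mRNA-DN"].values)


class TestPlantedStructure:
    def test_empty_config_gives_empty_truth(self):
        study = simulate_study(SimulationConfig(
            seed=0, n_genes=50, de_fraction=0.0, repression_edges=0,
            sponge_edges=0, lnc_mrna_edges=0, targets_per_tf=0,
            upstream_bp=100, downstream_bp=50,
        ))
        assert not study.truth.de_genes["DN"]
        assert not study.truth.planted_edges

    def test_planted_pairs_population_correlation_negative(self, small_study):
        """Every planted repression pair has negative pooled correlation on
        the full subject-level data, with |r| near the design point 0.9."""
        pairs = small_study.truth.edges_of_kind("miRNA->mRNA")
        assert pairs
        rs = [_pooled_population_r(small_study, m, g) for m, g in pairs]
        assert all(r < -0.7 for r in rs)
        assert np.median(np.abs(rs)) > 0.85

    def test_correlation_magnitude_monotone_in_beta(self):
        base = dict(seed=13, n_genes=80, n_mirnas=8, repression_edges=4,
                    sponge_edges=0, lnc_mrna_edges=0, targets_per_tf=0,
                    upstream_bp=100, downstream_bp=50,
                    mirna_de_log2_effect=1.0, noise_sd=0.5)
        weak = simulate_study(SimulationConfig(repression_beta=0.3, **base))
        strong = simulate_study(SimulationConfig(repression_beta=3.0, **base))
        for study in (weak, strong):
            study.mean_abs_r = np.mean([
                abs(_pooled_population_r(study, m, g))
                for m, g in study.truth.edges_of_kind("miRNA->mRNA")
            ])
        assert strong.mean_abs_r > weak.mean_abs_r

    def test_decoy_records_present_and_weak(self, small_study):
        planted = set(small_study.truth.edges_of_kind("miRNA->mRNA"))
        decoys = [r for r in small_study.catalog.records
                  if r.source_kind == "miRNA"
                  and (r.source_id, r.target_id) not in planted]
        assert len(decoys) == small_study.config.decoy_factor * len(planted)
        assert all(not r.validated and r.n_methods < 4 for r in decoys)

    def test_planted_edges_reference_generated_features(self, small_study):
        genes = set(small_study.matrices["mRNA-DN"].feature_ids)
        mirnas = set(small_study.matrices["miRNA-DN"].feature_ids)
        for e in small_study.truth.edges_of_kind("miRNA->mRNA"):
            assert e[0] in mirnas and e[1] in genes

    def test_planted_sites_in_promoters(self, small_study):
        for s in small_study.truth.planted_sites:
            p = small_study.promoters.promoters[s["gene_id"]]
            motif = small_study.pwms.get(s["motif_id"])
            planted = p.sequence[s["position"]:s["position"] + motif.length]
            from regnet.io import reverse_complement
            expected = motif.consensus if s["strand"] == "+" \
                else reverse_complement(motif.consensus)
            assert planted == expected
            track = small_study.promoters.conservation[s["gene_id"]]
            assert track[s["position"]:s["position"] + motif.length].min() == 0.9


class TestNullBehaviour:
    def test_null_t_statistics_follow_t_distribution(self):
        """With zero effects the per-gene pooled t statistics match their
        null distribution (KS p > 0.01 on 1,000 genes)."""
        study = simulate_study(SimulationConfig(
            seed=21, n_genes=1000, de_fraction=0.0, repression_edges=0,
            sponge_edges=0, lnc_mrna_edges=0, targets_per_tf=0,
            upstream_bp=100, downstream_bp=50,
        ))
        mat = study.matrices["mRNA-DN"]
        case = mat.values[:, [mat.groups[s] == "case" for s in mat.sample_ids]]
        ctl = mat.values[:, [mat.groups[s] == "control" for s in mat.sample_ids]]
        t, _ = stats.ttest_ind(case, ctl, axis=1)
        df = case.shape[1] + ctl.shape[1] - 2
        assert stats.kstest(t, "t", args=(df,)).pvalue > 0.01


class TestValidationAndExport:
    def test_group_size_below_two_rejected(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            SimulationConfig(group_sizes={"mRNA-DN": (1, 4)})

    def test_truth_round_trip(self, tmp_path, small_study):
        export_truth(small_study.truth, tmp_path / "truth.tsv")
        df = read_truth(tmp_path / "truth.tsv")
        planted = df[df["record"] == "miRNA->mRNA"]
        assert {(r.source, r.target) for r in planted.itertuples()} == \
            set(small_study.truth.edges_of_kind("miRNA->mRNA"))

    def test_empty_truth_exports_header_only(self, tmp_path):
        export_truth(GroundTruth(), tmp_path / "t.tsv")
        assert (tmp_path / "t.tsv").read_text().count("\n") == 1
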