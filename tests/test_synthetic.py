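import numpy as np
import pytest
from scipy import stats

from neurospot import (SyntheticConfig, assign_peptides, assign_spots,
                       coexistence, generate_neuron, place_mrnas,
                       place_partner_channel, emit_translation_channels,
                       simulate_null, synthesize_experiment)


class TestMorphology:
    def test_requested_branch_count(self, flat_synth_config):
        cfg = SyntheticConfig(n_branches=4, branch_length_um=40)
        geom, _ = generate_neuron(cfg, np.random.default_rng(0))
        assert len(geom.branches) == 4

    def test_zero_spine_density(self):
        cfg = SyntheticConfig(n_branches=2, branch_length_um=40,
                              spine_density_per_um=0.0)
        _, spines = generate_neuron(cfg, np.random.default_rng(0))
        assert len(spines) == 0

    def test_spine_count_poisson_mean(self, flat_synth_config):
        # density 1/um on one 100 um branch -> mean 100 over seeds
        counts = [len(generate_neuron(flat_synth_config,
                                      np.random.default_rng(s))[1])
                  for s in range(100)]
        assert np.mean(counts) == pytest.approx(100.0, abs=4.0)

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(branch_length_um=1.0, branch_half_width_um=2.0)


class TestPlacement:
    def test_zero_rates_give_empty_table(self, flat_synth_config):
        cfg = SyntheticConfig(
            n_branches=1, branch_length_um=50, mean_mrnas_per_branch=0.0,
            mean_soma_mrnas=0.0, n_transcription_sites=0)
        geom, spines = generate_neuron(cfg, np.random.default_rng(0))
        spots, truth = place_mrnas(geom, spines, cfg,
                                   np.random.default_rng(1))
        assert len(spots) == 0

    def test_flat_density_is_uniform_per_pixel(self, flat_synth_config):
        # pooled per-bin counts across seeds match bin pixel areas (chi2 GOF)
        geom, spines = generate_neuron(flat_synth_config,
                                       np.random.default_rng(0))
        B = 25_000.0
        n_bins = geom.n_bins(B)
        pooled = np.zeros(n_bins)
        for s in range(50):
            _, truth = place_mrnas(geom, spines, flat_synth_config,
                                   np.random.default_rng(100 + s))
            dend = truth[truth["compartment"] == "dendrite"]
            pooled += np.bincount(dend["bin"], minlength=n_bins)
        areas = geom.raster.bin_pixel_counts(B, n_bins).sum(axis=0)
        expected = pooled.sum() * areas / areas.sum()
        _, p = stats.chisquare(pooled, expected)
        assert p > 0.01

    def test_ground_truth_matches_assignment(self, flat_synth_config):
        geom, spines = generate_neuron(flat_synth_config,
                                       np.random.default_rng(3))
        spots, truth = place_mrnas(geom, spines, flat_synth_config,
                                   np.random.default_rng(4))
        recomputed = assign_spots(spots, geom)
        merged = truth.merge(recomputed, on="id", suffixes=("_true", ""))
        agree = (merged["compartment_true"] == merged["compartment"]).mean()
        assert agree > 0.97  # sub-pixel jitter can flip mask-edge spots
        dend = merged[(merged["compartment_true"] == "dendrite")
                      & (merged["compartment"] == "dendrite")]
        assert (dend["bin_true"] == dend["bin"]).mean() > 0.99


class TestCoexistenceChannel:
    def test_kappa_one_noise_free_fraction_is_one(self, flat_synth_config):
        cfg = SyntheticConfig(
            n_branches=1, branch_length_um=100,
            decay_length_um=float("inf"), localization_error_sd_nm=0.0,
            n_transcription_sites=0, mean_soma_mrnas=0.0,
            coexistence_enrichment=1.0, mean_partner_per_branch=40.0)
        geom, spines = generate_neuron(cfg, np.random.default_rng(5))
        mrna, truth = place_mrnas(geom, spines, cfg,
                                  np.random.default_rng(6))
        dend_ids = truth.loc[truth["compartment"] == "dendrite",
                             "id"].to_numpy()
        partner, ptruth = place_partner_channel(
            mrna, geom, cfg, np.random.default_rng(7),
            reference_dendritic_ids=dend_ids)
        # fraction of partner molecules with a reference within 700 nm
        ref_xyz = mrna.xyz[np.isin(mrna.ids, dend_ids)]
        out = coexistence(partner.xyz, np.zeros(len(partner), dtype=int),
                          ref_xyz, 700.0, n_bins=1)
        assert out.loc[0, "frac_coexisting"] == 1.0

    def test_kappa_recovered_from_excess_over_null(self, flat_synth_config):
        kappa = 0.4
        cfg = SyntheticConfig(
            n_branches=2, branch_length_um=100,
            decay_length_um=float("inf"), localization_error_sd_nm=0.0,
            n_transcription_sites=0, mean_soma_mrnas=0.0,
            coexistence_enrichment=kappa, mean_partner_per_branch=250.0)
        geom, spines = generate_neuron(cfg, np.random.default_rng(8))
        mrna, truth = place_mrnas(geom, spines, cfg,
                                  np.random.default_rng(9))
        dend_ids = truth.loc[truth["compartment"] == "dendrite",
                             "id"].to_numpy()
        partner, _ = place_partner_channel(
            mrna, geom, cfg, np.random.default_rng(10),
            reference_dendritic_ids=dend_ids)
        ref_xyz = mrna.xyz[np.isin(mrna.ids, dend_ids)]

        def pooled_frac(par_xyz):
            return coexistence(par_xyz, np.zeros(len(par_xyz), dtype=int),
                               ref_xyz, 700.0, n_bins=1,
                               mode="2d").loc[0, "frac_coexisting"]

        obs = pooled_frac(partner.xyz)
        par_assign = assign_spots(partner, geom)
        ens = simulate_null(par_assign, partner, geom, 100,
                            np.random.default_rng(11), z_mode="zero")
        null_fracs = [pooled_frac(pos) for pos in ens.positions]
        null = np.mean(null_fracs)
        recovered = (obs - null) / (1 - null)
        assert recovered == pytest.approx(kappa, abs=0.05)


class TestTranslationChannel:
    def test_noise_free_round_trip_exact(self):
        cfg = SyntheticConfig(
            n_branches=2, branch_length_um=60, mean_mrnas_per_branch=80,
            mean_soma_mrnas=20, n_transcription_sites=0,
            intensity_cv=0.0, colocalization_sd_nm=0.0,
            mean_free_peptides=0.0, chromatic_offset=(50.0, -30.0, 20.0),
            p_translating=0.3)
        geom, spines = generate_neuron(cfg, np.random.default_rng(12))
        mrna, _ = place_mrnas(geom, spines, cfg, np.random.default_rng(13))
        peptides, truth = emit_translation_channels(
            mrna, geom, cfg, np.random.default_rng(14))
        calls = assign_peptides(
            mrna, peptides, base_threshold=200.0,
            chromatic_offset=cfg.chromatic_offset,
            unit=cfg.unit_peptide_intensity)
        merged = calls.pairs.merge(truth, on="mrna_id")
        assert (merged["peptide_id_x"] >= 0).equals(merged["translating"])
        translating = merged[merged["translating"]]
        assert list(translating["ribosomes_x"]) == \
            list(translating["ribosomes_y"])

    def test_p_zero_yields_only_free_background(self, flat_synth_config):
        cfg = SyntheticConfig(n_branches=1, branch_length_um=50,
                              p_translating=0.0, mean_free_peptides=30.0)
        geom, spines = generate_neuron(cfg, np.random.default_rng(15))
        mrna, _ = place_mrnas(geom, spines, cfg, np.random.default_rng(16))
        peptides, truth = emit_translation_channels(
            mrna, geom, cfg, np.random.default_rng(17))
        assert not truth["translating"].any()
        assert (truth["peptide_id"] == -1).all()


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        cfg = SyntheticConfig(n_branches=2, branch_length_um=50)
        a = synthesize_experiment(cfg, seed=99)
        b = synthesize_experiment(cfg, seed=99)
        for key in ("mrna", "partner", "peptides"):
            np.testing.assert_array_equal(a[key].xyz, b[key].xyz)
            np.testing.assert_array_equal(a[key].intensity, b[key].intensity)
        assert a["mrna_truth"].equals(b["mrna_truth"])
        assert a["translation_truth"].equals(b["translation_truth"])

    def test_different_seeds_differ(self):
        cfg = SyntheticConfig(n_branches=1, branch_length_um=50)
        a = synthesize_experiment(cfg, seed=1)
        b = synthesize_experiment(cfg, seed=2)
        assert len(a["mrna"]) != len(b["mrna"]) or \
            not np.array_equal(a["mrna"].xyz, b["mrna"].xyz)
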