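import numpy as np
import pandas as pd
import pytest

from ribopolya.correction import apply_correction, compute_ratios
from ribopolya.expression import median_profile
from ribopolya.kmers import index_uniqueness
from ribopolya.simulate import (
    SimulationConfig,
    generate_toy_transcriptome,
    generate_truth,
    simulate_lps,
    simulate_libraries,
)
from ribopolya.stats import inducible_set


class TestGenerateTruth:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_genes=500, seed=42)
        assert generate_truth(cfg).table.equals(generate_truth(cfg).table)

    def test_class_fractions_respected(self):
        cfg = SimulationConfig(n_genes=1000, seed=1)
        truth = generate_truth(cfg)
        counts = truth.table["polya_class"].value_counts()
        assert counts.get("polyA_minus", 0) == 80
        assert counts.get("bimorphic", 0) == 50

    def test_no_polya_minus_when_fraction_zero(self):
        cfg = SimulationConfig(n_genes=300, frac_polya_minus=0.0, seed=2)
        truth = generate_truth(cfg)
        assert "polyA_minus" not in set(truth.table["polya_class"])

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_polya_minus=1.2)

    def test_rank_abundance_slope_matches_power_law(self):
        cfg = SimulationConfig(n_genes=10_000, powerlaw_alpha=1.8, seed=3)
        a = np.sort(generate_truth(cfg).table["true_abundance"].to_numpy())[::-1]
        # fit log-abundance vs log-rank over the mid-range (away from the
        # clipped head and the x>=1 floor of the law)
        ranks = np.arange(1, a.size + 1)
        sel = (ranks >= 10) & (ranks <= a.size // 10)
        slope = np.polyfit(np.log10(ranks[sel]), np.log10(a[sel]), 1)[0]
        assert slope == pytest.approx(-1 / (cfg.powerlaw_alpha - 1), abs=0.15)


class TestSimulateLibraries:
    def test_polya_minus_rows_exactly_zero_in_polya(self):
        cfg = SimulationConfig(n_genes=400, seed=4)
        truth = generate_truth(cfg)
        mat = simulate_libraries(truth, "polyA", cfg)
        minus = truth.genes_of_class("polyA_minus")
        assert len(minus) > 0
        assert (mat.values.loc[minus] == 0).all().all()

    def test_columns_are_tpm_normalized(self):
        cfg = SimulationConfig(n_genes=300, seed=5)
        truth = generate_truth(cfg)
        for lib in ("polyA", "ribominus"):
            mat = simulate_libraries(truth, lib, cfg)
            assert mat.is_normalized()

    def test_noiseless_limit_differs_only_by_renormalization(self):
        cfg = SimulationConfig(n_genes=300, noise_sd_log2=0.0,
                               nascent_background_frac=0.0, bimorphic_capture=1.0,
                               seed=6)
        truth = generate_truth(cfg)
        polya = simulate_libraries(truth, "polyA", cfg)
        ribo = simulate_libraries(truth, "ribominus", cfg)
        captured = truth.table.index[truth.table["polya_class"] != "polyA_minus"]
        ratio = polya.values.loc[captured, "P_0h_rep1"] / ribo.values.loc[captured, "R_0h_rep1"]
        assert np.allclose(ratio, ratio.iloc[0], rtol=1e-9)

    def test_ribo_only_mass_in_plausible_range(self):
        cfg = SimulationConfig(n_genes=10_000, seed=0)
        truth = generate_truth(cfg)
        ribo = simulate_libraries(truth, "ribominus", cfg)
        minus = truth.genes_of_class("polyA_minus")
        frac = ribo.values.loc[minus].sum(axis=0).mean() / 1e6
        assert 0.01 <= frac <= 0.10


class TestSimulateLps:
    def test_zero_inducible_fraction_is_identity(self):
        cfg = SimulationConfig(n_genes=200, frac_inducible=0.0, seed=7)
        truth = generate_truth(cfg)
        assert simulate_lps(truth, cfg).table.equals(truth.table)

    def test_relative_abundance_ratio_is_exact_but_tpm_is_compositional(self):
        cfg = SimulationConfig(n_genes=200, noise_sd_log2=0.0, seed=8)
        pre = generate_truth(cfg)
        post = simulate_lps(pre, cfg)
        induced = post.table.index[post.table["lps_log2fc"] > 0]
        ratio = (post.table.loc[induced, "true_abundance"]
                 / pre.table.loc[induced, "true_abundance"])
        assert np.allclose(np.log2(ratio), post.table.loc[induced, "lps_log2fc"])
        # TPM ratios are damped by the renormalization
        pre_m = simulate_libraries(pre, "polyA", cfg)
        post_m = simulate_libraries(post, "polyA", cfg, condition="7h")
        g = induced[pre_m.values.loc[induced, "P_0h_rep1"].gt(0)][0]
        tpm_ratio = post_m.values.loc[g, "P_7h_rep1"] / pre_m.values.loc[g, "P_0h_rep1"]
        true_ratio = float(2 ** post.table.loc[g, "lps_log2fc"])
        assert tpm_ratio < true_ratio

    def test_inducible_set_recovers_strong_responders_noiseless(self):
        cfg = SimulationConfig(n_genes=5000, noise_sd_log2=0.0, seed=9)
        pre = generate_truth(cfg)
        post = simulate_lps(pre, cfg)
        pre_prof = median_profile(simulate_libraries(pre, "polyA", cfg))
        post_prof = median_profile(simulate_libraries(post, "polyA", cfg, condition="7h"))
        called = inducible_set(pre_prof, post_prof)
        strong = {
            g
            for g in post.table.index[post.table["lps_log2fc"] > 2.5]
            if pre_prof[g] > 1 and post_prof[g] > 1
        }
        assert strong
        recovered = len(strong & called) / len(strong)
        assert recovered >= 0.95


class TestToyTranscriptome:
    def test_deterministic(self):
        a = generate_toy_transcriptome(20, 100, 1, seed=3)
        b = generate_toy_transcriptome(20, 100, 1, seed=3)
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]

    def test_duplicated_pair_has_no_unique_kmers(self):
        recs = generate_toy_transcriptome(10, 200, 1, seed=4)
        stats = index_uniqueness(recs)
        assert stats.per_transcript["T0000"].unique_kmers == 0
        assert stats.per_transcript["T0000_dup"].unique_kmers == 0

    def test_random_long_sequences_nearly_all_unique(self):
        recs = generate_toy_transcriptome(30, 500, 0, seed=5)
        stats = index_uniqueness(recs)
        assert stats.index_unique_fraction > 0.999

    def test_length_floor(self):
        with pytest.raises(ValueError):
            generate_toy_transcriptome(5, 30)
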