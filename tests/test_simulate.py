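"""Synthetic-data generators: ground truth consistency, determinism,
distributional targets."""

import numpy as np
import pytest

from piezocomp import (
    SimulationConfig,
    gc_metrics,
    simulate_cds_set,
    simulate_ortholog_proteomes,
    simulate_spot_table,
)
from piezocomp.alphabet import AA_INDEX, encode
from piezocomp.io import write_fasta, write_truth
from piezocomp.simulate import random_proteome


class TestOrthologSimulator:
    def test_zero_rates_give_identical_proteomes(self):
        cfg = SimulationConfig(n_proteins=10, sub_rate=0.0, seed=1)
        pa, pb, truth = simulate_ortholog_proteomes(cfg)
        assert list(pa.values()) == list(pb.values())
        assert truth.n_substitutions == 0

    def test_directional_bias_shows_in_event_log(self):
        cfg = SimulationConfig(
            n_proteins=200, sub_rate=0.2, bias_pairs={("K", "R"): 3.0}, seed=42
        )
        _, _, truth = simulate_ortholog_proteomes(cfg)
        assert truth.directed_count("K", "R") > truth.directed_count("R", "K")
        # directional counts are exactly the event totals
        assert truth.directed_counts.sum() == truth.n_substitutions

    def test_event_log_matches_sitewise_differences(self):
        """Without indels, events equal the Hamming difference per pair."""
        cfg = SimulationConfig(n_proteins=15, sub_rate=0.15, seed=3)
        pa, pb, truth = simulate_ortholog_proteomes(cfg)
        total_hamming = sum(
            int((encode(sa) != encode(sb)).sum())
            for sa, sb in zip(pa.values(), pb.values())
        )
        assert total_hamming == truth.n_substitutions

    def test_seed_determinism_is_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_proteins=8, sub_rate=0.1, indel_rate=0.01, seed=5)
        blobs = []
        for run in ("x", "y"):
            pa, pb, truth = simulate_ortholog_proteomes(cfg)
            write_fasta(pa, tmp_path / f"{run}_a.faa")
            write_fasta(pb, tmp_path / f"{run}_b.faa")
            write_truth(truth, tmp_path / f"{run}_t.tsv")
            blobs.append(
                tuple((tmp_path / f"{run}{s}").read_bytes() for s in ("_a.faa", "_b.faa", "_t.tsv"))
            )
        assert blobs[0] == blobs[1]

    def test_different_seeds_same_marginal_statistics(self):
        """Replicate runs differ in sequence but agree in divergence level."""
        fracs = []
        total = None
        for seed in range(20):
            cfg = SimulationConfig(n_proteins=20, length_sd=0.0, sub_rate=0.1, seed=seed)
            pa, _, truth = simulate_ortholog_proteomes(cfg)
            total = sum(len(s) for s in pa.values())
            fracs.append(truth.n_substitutions / total)
        fracs = np.array(fracs)
        assert np.ptp(fracs) > 0  # seeds actually differ
        sd = fracs.std(ddof=1)
        assert np.all(np.abs(fracs - fracs.mean()) <= 2.5 * sd)

    def test_unbiased_process_is_directionally_symmetric(self):
        """With no bias the mean signed count difference per pair is ~0
        (within 3 standard errors of its 50-replicate estimate)."""
        pairs = [("K", "R"), ("D", "E"), ("A", "S")]
        diffs = {p: [] for p in pairs}
        for seed in range(50):
            cfg = SimulationConfig(
                n_proteins=20, length_mean=100.0, length_sd=0.0, sub_rate=0.2, seed=seed
            )
            _, _, truth = simulate_ortholog_proteomes(cfg)
            for a, b in pairs:
                diffs[(a, b)].append(
                    truth.directed_count(a, b) - truth.directed_count(b, a)
                )
        for p, values in diffs.items():
            values = np.array(values, dtype=float)
            se = values.std(ddof=1) / np.sqrt(len(values))
            assert abs(values.mean()) <= 3.0 * se + 1e-9, p

    def test_paralogs_and_orphans_are_added(self):
        cfg = SimulationConfig(
            n_proteins=10, sub_rate=0.05, paralog_fraction=0.2, orphan_fraction=0.3, seed=1
        )
        pa, pb, truth = simulate_ortholog_proteomes(cfg)
        assert sum("par" in g for g in pb) == 2
        assert sum("orphan" in g for g in pa) == 3
        assert sum("orphan" in g for g in pb) == 3
        assert len(truth.ortholog_map) == 10

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_proteins": 0},
            {"n_proteins": 5, "sub_rate": -0.1},
            {"n_proteins": 5, "sub_rate": float("nan")},
            {"n_proteins": 5, "indel_rate": 1.5},
            {"n_proteins": 5, "paralog_fraction": -0.2},
            {"n_proteins": 5, "orphan_fraction": 2.0},
            {"n_proteins": 5, "bias_pairs": {("K", "K"): 2.0}},
            {"n_proteins": 5, "bias_pairs": {("K", "R"): 0.5}},
            {"n_proteins": 5, "bias_pairs": {("K", "R"): float("inf")}},
        ],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_random_proteome_reproduces_its_composition(self):
        from piezocomp import aa_frequency
        from piezocomp.alphabet import DEFAULT_AA_FREQS

        proteome = random_proteome(500, 200.0, 0.0, seed=6)
        freqs = aa_frequency(proteome).frequencies
        assert np.abs(freqs - DEFAULT_AA_FREQS).max() <= 0.01


class TestCdsSimulator:
    def test_structure(self):
        cds = simulate_cds_set(5, 20, 50.0, seed=1)
        assert len(cds) == 5
        for seq in cds.values():
            assert seq.startswith("ATG")
            assert len(seq) == 60
            assert set(seq) <= set("ACGT")

    def test_no_internal_stop_codons(self):
        cds = simulate_cds_set(20, 100, 30.0, seed=2)
        stops = {"TAA", "TAG", "TGA"}
        for seq in cds.values():
            codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
            assert not (codons & stops)

    @pytest.mark.parametrize("target,expected", [(100.0, "GC"), (0.0, "AT")])
    def test_degenerate_targets_fix_third_positions(self, target, expected):
        cds = simulate_cds_set(10, 30, target, seed=3)
        for seq in cds.values():
            thirds = seq[5::3]  # third positions after the fixed ATG start
            assert set(thirds) <= set(expected)

    def test_gc3_converges_to_target(self):
        cds = simulate_cds_set(200, 300, 55.0, seed=4)
        _, gc3 = gc_metrics(cds)
        assert abs(gc3 - 55.0) <= 1.0

    @pytest.mark.parametrize("bad", [-1.0, 101.0])
    def test_invalid_percent_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_cds_set(5, 20, bad)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            simulate_cds_set(5, 1, 50.0)


class TestSpotSimulator:
    def test_noise_free_null_has_unit_ratios(self):
        table = simulate_spot_table(20, noise_cv=0.0, seed=1)
        wide = table.pivot(index="spot_id", columns="condition", values="volume")
        assert np.allclose(wide["low"], wide["high"])

    def test_noise_free_planted_fold_is_exact_on_raw_volumes(self):
        table = simulate_spot_table(20, planted={"s1": 3.0}, noise_cv=0.0, seed=2)
        wide = table.pivot(index="spot_id", columns="condition", values="volume")
        ratios = wide["low"] / wide["high"]
        assert ratios["s1"] == pytest.approx(3.0)
        assert np.allclose(ratios.drop("s1"), 1.0)

    def test_noisy_planted_fold_recovered_on_average(self):
        """Monte-Carlo mean of the recovered ratio is within 5% of the truth."""
        ratios = []
        for seed in range(100):
            table = simulate_spot_table(100, planted={"s1": 2.0}, noise_cv=0.1, seed=seed)
            wide = table.pivot(index="spot_id", columns="condition", values="volume")
            ratios.append(wide.loc["s1", "low"] / wide.loc["s1", "high"])
        assert abs(np.mean(ratios) - 2.0) <= 0.1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_spot_table(5, planted={"s1": -2.0})
        with pytest.raises(ValueError):
            simulate_spot_table(5, planted={"s99": 2.0})
        with pytest.raises(ValueError):
            simulate_spot_table(5, noise_cv=-0.1)
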