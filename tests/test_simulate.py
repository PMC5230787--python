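"""The synthetic-data generators: determinism, stated structure, recovery."""

import numpy as np
import pandas as pd
import pytest

from kevtools import (
    AnalysisConfig,
    SimulationConfig,
    compute_kevs,
    detect_sd,
    simulate_annotation,
    simulate_start_regions,
    simulate_translatome,
)
from kevtools.config import OperonConfig
from kevtools.pipeline import te_summaries
from kevtools.start_region import score_sd_site


class TestSimulateTranslatome:
    def test_deterministic_under_fixed_seed(self):
        config = SimulationConfig(n_genes=50, seed=42)
        m1, t1 = simulate_translatome(config)
        m2, t2 = simulate_translatome(config)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            SimulationConfig(noise_cv=float("nan"))
        with pytest.raises(ValueError):
            SimulationConfig(missing_prob=1.5)

    def test_noiseless_null_gives_unit_kevs(self):
        config = SimulationConfig(
            n_genes=40, frac_sensitive=0.0, frac_resistant=0.0, log2_kev_sd=0.0,
            noise_cv=0.0, missing_prob=0.0, outlier_prob=0.0, seed=1,
        )
        measurements, _ = simulate_translatome(config)
        analysis = AnalysisConfig()
        _, passing, _ = te_summaries(measurements, analysis)
        records = compute_kevs(passing, analysis)
        assert len(records) == 40
        assert all(r.kev == pytest.approx(1.0, abs=1e-12) for r in records)

    def test_noiseless_recovery_is_exact(self, noiseless_config):
        measurements, truth = simulate_translatome(noiseless_config)
        analysis = AnalysisConfig()
        _, passing, _ = te_summaries(measurements, analysis)
        records = compute_kevs(passing, analysis)
        estimated = {r.gene_id: r.log2_kev for r in records}
        truth_map = dict(zip(truth["gene_id"], truth["true_log2_kev"]))
        assert set(estimated) == set(truth_map)
        for gene_id, value in estimated.items():
            assert value == pytest.approx(truth_map[gene_id], abs=1e-9)

    def test_planted_sensitive_recall_is_one_without_noise(self):
        config = SimulationConfig(
            n_genes=1000, frac_sensitive=0.05, frac_resistant=0.0, effect_log2=2.0,
            noise_cv=0.0, missing_prob=0.0, outlier_prob=0.0, seed=123,
        )
        measurements, truth = simulate_translatome(config)
        analysis = AnalysisConfig()
        _, passing, _ = te_summaries(measurements, analysis)
        called = {r.gene_id for r in compute_kevs(passing, analysis)
                  if r.class_label == "sensitive"}
        planted = set(truth.loc[truth["planted"] == "sensitive", "gene_id"])
        assert planted and planted <= called

    def test_average_class_centers_on_zero(self):
        config = SimulationConfig(n_genes=5000, frac_sensitive=0.0,
                                  frac_resistant=0.0, seed=9)
        _, truth = simulate_translatome(config)
        assert abs(truth["true_log2_kev"].mean()) < 0.03
        assert float(np.median(truth["true_log2_kev"])) == 0.0

    def test_heavy_missingness_flags_genes_downstream(self):
        config = SimulationConfig(n_genes=60, missing_prob=0.6, noise_cv=0.1,
                                  outlier_prob=0.0, seed=2)
        measurements, _ = simulate_translatome(config)
        analysis = AnalysisConfig()
        summaries, passing, excluded = te_summaries(measurements, analysis)
        assert excluded  # some genes must fall under 3 usable replicates
        assert set(excluded) | set(passing) == set(summaries)
        for reason in excluded.values():
            assert "replicate filter" in reason

    def test_expected_ratio_structure(self):
        """Geometric-mean polysomal/free ratio in treated vs untreated
        recovers the true effect within sampling error."""
        config = SimulationConfig(n_genes=300, noise_cv=0.15, missing_prob=0.0,
                                  outlier_prob=0.0, seed=31)
        measurements, truth = simulate_translatome(config)
        wide = measurements.pivot_table(
            index=["gene_id", "condition", "replicate"],
            columns="fraction", values="intensity",
        )
        te = np.log2(wide["polysomal"] / wide["free"])
        per_gene = te.groupby(level=["gene_id", "condition"]).mean().unstack()
        diff = per_gene["treated"] - per_gene["untreated"]
        truth_map = truth.set_index("gene_id")["true_log2_kev"]
        resid = diff - truth_map.loc[diff.index]
        # analytic residual sd: per-measurement log2 noise sigma, doubled
        # in variance by the poly/free quotient, averaged over 5 replicates,
        # differenced across conditions -> sigma * 2 / sqrt(5)
        sigma_log2 = np.sqrt(np.log1p(0.15**2)) / np.log(2)
        expected_sd = sigma_log2 * 2.0 / np.sqrt(5.0)
        assert abs(resid.mean()) < 0.02
        assert resid.std() == pytest.approx(expected_sd, rel=0.15)

    def test_dye_swap_metadata_present(self):
        config = SimulationConfig(n_genes=10, seed=3)
        measurements, _ = simulate_translatome(config)
        by_rep = measurements.groupby("replicate")["dye"].unique()
        assert all(len(v) == 1 for v in by_rep)
        assert set(measurements["dye"]) == {"Cy3/Cy5", "Cy5/Cy3"}


class TestSimulateStartRegions:
    def test_planted_motif_round_trip(self):
        config = SimulationConfig(n_genes=50, sd_plant_prob=1.0,
                                  sd_spacer_range=(5, 5), seed=7)
        windows, truth = simulate_start_regions(config)
        analysis = AnalysisConfig()
        for w in windows:
            call = detect_sd(w.upstream_seq, analysis)
            assert call.present and call.distance_to_aug == 5
        assert truth["sd_planted"].all()

    def test_window_geometry(self):
        config = SimulationConfig(n_genes=5, seed=1)
        windows, _ = simulate_start_regions(config)
        for w in windows:
            assert len(w.upstream_seq) == 40 and len(w.downstream_seq) == 37

    def test_false_positive_rate_matches_enumeration(self):
        """With the scan fixed to a single register, the detector's
        false-positive rate under a uniform background equals the exact
        fraction of qualifying 8-mers among all 4^8."""
        analysis = AnalysisConfig(sd_scan_min=2, sd_scan_max=2)
        bases = "ACGT"
        qualify = 0
        for code in range(4**8):
            site = ""
            x = code
            for _ in range(8):
                site += bases[x % 4]
                x //= 4
            total, run = score_sd_site(site, analysis.sd_consensus)
            qualify += total >= analysis.sd_min_matches or run >= analysis.sd_min_run
        p1 = qualify / 4**8

        config = SimulationConfig(
            n_genes=10_000, sd_plant_prob=0.0,
            base_composition=(0.25, 0.25, 0.25, 0.25), seed=19,
        )
        windows, _ = simulate_start_regions(config, analysis)
        rate = np.mean([detect_sd(w.upstream_seq, analysis).present for w in windows])
        se = np.sqrt(p1 * (1 - p1) / len(windows))
        assert abs(rate - p1) < 4 * se

    def test_base_composition_recovered(self):
        target = (0.29, 0.23, 0.22, 0.26)
        config = SimulationConfig(n_genes=10_000, sd_plant_prob=0.0,
                                  base_composition=target, seed=5)
        windows, _ = simulate_start_regions(config)
        pooled = "".join(w.sequence for w in windows)
        fractions = [pooled.count(b) / len(pooled) for b in "ACGT"]
        assert np.allclose(fractions, target, atol=0.01)

    def test_deterministic(self):
        config = SimulationConfig(n_genes=25, seed=99)
        w1, t1 = simulate_start_regions(config)
        w2, t2 = simulate_start_regions(config)
        assert w1 == w2
        pd.testing.assert_frame_equal(t1, t2)


class TestSimulateAnnotation:
    def test_no_distal_genes_when_fraction_zero(self):
        oc = OperonConfig(frac_single=0.5, frac_first=0.5, frac_distal=0.0)
        config = SimulationConfig(n_genes=200, operon_config=oc, seed=4)
        frame = simulate_annotation(config)
        assert (frame["operon_position"] != "distal").all()

    def test_distal_enrichment_planted_by_class(self):
        oc = OperonConfig(distal_rate_by_class={"sensitive": 0.1, "resistant": 0.7})
        config = SimulationConfig(n_genes=2000, operon_config=oc, seed=6)
        classes = {f"g{i:04d}": ("sensitive" if i % 2 else "resistant")
                   for i in range(1, 2001)}
        frame = simulate_annotation(config, classes=classes)
        frame["cls"] = frame["gene_id"].map(classes)
        rates = frame.groupby("cls")["operon_position"].apply(
            lambda s: (s == "distal").mean()
        )
        assert rates["sensitive"] == pytest.approx(0.1, abs=0.03)
        assert rates["resistant"] == pytest.approx(0.7, abs=0.03)

    def test_distal_distances_are_short(self):
        config = SimulationConfig(n_genes=2000, seed=8)
        frame = simulate_annotation(config)
        distal = frame.loc[frame["operon_position"] == "distal", "intergenic_distance"]
        first = frame.loc[frame["operon_position"] == "first", "intergenic_distance"]
        assert distal.astype(float).median() < 15
        assert first.astype(float).median() > 15
        single = frame.loc[frame["operon_position"] == "single", "intergenic_distance"]
        assert single.isna().all()

    def test_deterministic(self):
        config = SimulationConfig(n_genes=40, seed=12)
        pd.testing.assert_frame_equal(
            simulate_annotation(config), simulate_annotation(config)
        )
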