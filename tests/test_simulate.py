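import numpy as np
import pandas as pd
import pytest

from ecckit.filters import apply_filters
from ecckit.io_formats import CANDIDATE_COLUMNS
from ecckit.prognostic import univariate_cox
from ecckit.simulate import (
    SimulationConfig,
    _placement_index,
    simulate_cohort,
    simulate_genome_and_tracks,
    simulate_sample,
    simulate_survival,
    write_cohort,
)


class TestGenomeAndTracks:
    def test_reproducible_from_seed(self, small_config):
        layout1, tracks1 = simulate_genome_and_tracks(small_config)
        layout2, tracks2 = simulate_genome_and_tracks(small_config)
        assert layout1 == layout2
        for key in tracks1:
            pd.testing.assert_frame_equal(tracks1[key], tracks2[key])

    def test_all_seven_repeat_classes_present(self, small_genome):
        _, tracks = small_genome
        classes = set(tracks["repeats"]["repClass"])
        assert classes >= {"SINE", "LINE", "LTR", "DNA", "Simple_repeat",
                           "Low_complexity", "Satellite"}
        fams = set(tracks["repeats"]["repFamily"])
        assert {"Alu", "MIR"} <= fams

    def test_tracks_lie_within_the_layout(self, small_genome):
        layout, tracks = small_genome
        for key, frame in tracks.items():
            assert (frame["start"] >= 0).all(), key
            limits = frame["chrom"].map(layout.lengths)
            assert (frame["end"] <= limits).all(), key

    def test_too_short_chromosome_is_a_config_error(self):
        with pytest.raises(ValueError, match="too short"):
            SimulationConfig(chrom_length_bp=10_000)


class TestSampleSimulation:
    def test_candidates_within_genome_and_fails_all_rejected(self, small_config, small_genome):
        layout, tracks = small_genome
        placement = _placement_index(tracks, layout)
        rng = np.random.default_rng(9)
        table, mapped = simulate_sample(small_config, "tumor", rng, layout, placement)
        assert mapped > 0
        limits = table["chrom"].map(layout.lengths)
        assert (table["start"] >= 0).all() and (table["end"] <= limits).all()
        # every candidate generated as "fail" violates at least one criterion
        kept, _ = apply_filters(table.loc[:, list(CANDIDATE_COLUMNS)])
        kept_idx = set(kept.index)
        fail_idx = set(table.index[~table["simulated_pass"]])
        assert kept_idx.isdisjoint(fail_idx)
        # and pass-labelled candidates all survive (support drawn above thresholds)
        assert kept_idx == set(table.index[table["simulated_pass"]])

    def test_tumor_lengths_exceed_normal_on_average(self, small_config, small_genome):
        layout, tracks = small_genome
        placement = _placement_index(tracks, layout)
        wins = 0
        for rep in range(20):
            rng_t = np.random.default_rng(100 + rep)
            rng_n = np.random.default_rng(200 + rep)
            t, _ = simulate_sample(small_config, "tumor", rng_t, layout, placement)
            n, _ = simulate_sample(small_config, "normal", rng_n, layout, placement)
            wins += (t["end"] - t["start"]).mean() > (n["end"] - n["start"]).mean()
        assert wins >= 19

    def test_null_config_makes_groups_exchangeable(self, small_genome):
        from scipy.stats import mannwhitneyu

        cfg = SimulationConfig.null(seed=3, n_chroms=2, chrom_length_bp=300_000)
        layout, tracks = small_genome
        placement = _placement_index(tracks, layout)
        pvals = []
        for rep in range(40):
            t, _ = simulate_sample(cfg, "tumor", np.random.default_rng(rep), layout, placement)
            n, _ = simulate_sample(cfg, "normal", np.random.default_rng(1000 + rep), layout, placement)
            pvals.append(
                mannwhitneyu(t["end"] - t["start"], n["end"] - n["start"]).pvalue
            )
        # under exchangeability the rejection rate stays near nominal
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.15


class TestSurvivalSimulation:
    def test_zero_horizon_censors_everything_at_zero(self):
        from dataclasses import replace

        cfg = SimulationConfig()
        cfg = replace(cfg, survival=replace(cfg.survival, horizon_months=0.0,
                                            lost_to_followup=0.0))
        m = pd.DataFrame({"intron_proportion": np.random.default_rng(0).random(30),
                          "repeat_all_proportion": np.zeros(30)})
        out = simulate_survival(m, cfg, np.random.default_rng(1))
        assert (out["dfs_time"] == 0).all() and (out["dfs_event"] == 0).all()

    def test_missing_planted_feature_is_an_error(self):
        m = pd.DataFrame({"other": [1.0, 2.0]})
        with pytest.raises(ValueError, match="absent"):
            simulate_survival(m, SimulationConfig(), np.random.default_rng(0))

    def test_null_hazards_leave_cox_at_one(self):
        from dataclasses import replace

        cfg = SimulationConfig()
        cfg = replace(cfg, survival=replace(cfg.survival, log_hr={},
                                            baseline_hazard=0.02,
                                            lost_to_followup=0.0))
        covered = 0
        for rep in range(30):
            rng = np.random.default_rng(rep)
            grp = rng.random(120) < 0.5
            m = pd.DataFrame({"x": grp.astype(float)})
            out = simulate_survival(m, cfg, rng, standardize=False)
            cox = univariate_cox(grp, out["dfs_time"], out["dfs_event"])
            covered += cox.ci_low <= 1.0 <= cox.ci_high
        assert covered >= 25


class TestCohort:
    def test_cohort_shape_and_truth(self, default_cohort):
        clin = default_cohort.clinical
        assert (clin.tissue_label == "tumor").sum() == 81
        assert (clin.tissue_label == "normal").sum() == 33
        assert default_cohort.truth["n_events"] >= 1
        # normals never carry survival fields
        assert clin.loc[clin.tissue_label == "normal", "dfs_time"].isna().all()

    def test_event_rate_matches_design(self, default_cohort):
        clin = default_cohort.clinical
        tumor = clin[clin.tissue_label == "tumor"]
        followed = tumor["dfs_event"].notna()
        rate = tumor.loc[followed, "dfs_event"].mean()
        assert 0.05 <= rate <= 0.35  # design center ~0.18

    def test_write_is_deterministic(self, tmp_path, small_config):
        import filecmp

        a, b = tmp_path / "a", tmp_path / "b"
        write_cohort(simulate_cohort(small_config), a)
        write_cohort(simulate_cohort(small_config), b)
        for rel in ("clinical.tsv", "truth.json", "tracks/gene_model.tsv",
                    "samples/T001.tsv"):
            assert filecmp.cmp(a / rel, b / rel, shallow=False), rel
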