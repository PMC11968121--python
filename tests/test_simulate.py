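"""Synthetic-data generator: structural identities, missingness, determinism."""

import numpy as np
import pandas as pd
import pytest

import twinpath as tp
from twinpath.simulate import (
    COHORT_INTERVAL_COUNTS,
    MissingnessProfile,
    apply_missingness,
    emit_ordinal_items,
)
from twinpath.zoo import build_autoregression, build_univariate_ace


def _twin_correlations(pairs):
    out = {}
    for zyg in ("MZ", "DZ"):
        sub = pairs[pairs.zygosity == zyg]
        out[zyg] = sub[["y1_t0", "y2_t0"]].corr().iloc[0, 1]
    return out


class TestStructuralIdentities:
    def test_pure_a_rmz_twice_rdz(self):
        """a2=0.6, e2=0.4: empirical rMZ ~ 0.6 and rDZ ~ 0.3 at n=50000."""
        model = build_univariate_ace(drop=("C",))
        truth = {"a_var": 0.6, "e_var": 0.4, "mu_1": 0.0, "beta_sex": 0.0}
        cfg = tp.SimulationConfig(model, truth, n_mz=50_000, n_dz=50_000,
                                  seed=101, missingness=None)
        pairs, _ = tp.simulate_pairs(cfg)
        r = _twin_correlations(pairs)
        assert r["MZ"] == pytest.approx(0.6, abs=0.01)
        assert r["DZ"] == pytest.approx(0.3, abs=0.01)

    def test_e_only_correlations_vanish(self):
        model = build_univariate_ace(drop=("A", "C"))
        truth = {"e_var": 1.0, "mu_1": 0.0, "beta_sex": 0.0}
        cfg = tp.SimulationConfig(model, truth, n_mz=50_000, n_dz=50_000,
                                  seed=102, missingness=None)
        pairs, _ = tp.simulate_pairs(cfg)
        r = _twin_correlations(pairs)
        assert abs(r["MZ"]) < 0.01 and abs(r["DZ"]) < 0.01

    def test_c_only_equal_correlations(self):
        model = build_univariate_ace(drop=("A",))
        truth = {"c_var": 0.5, "e_var": 0.5, "mu_1": 0.0, "beta_sex": 0.0}
        cfg = tp.SimulationConfig(model, truth, n_mz=30_000, n_dz=30_000,
                                  seed=103, missingness=None)
        pairs, _ = tp.simulate_pairs(cfg)
        r = _twin_correlations(pairs)
        assert r["MZ"] == pytest.approx(r["DZ"], abs=0.015)
        assert r["MZ"] == pytest.approx(0.5, abs=0.015)

    def test_mz_same_sex(self, study_pairs):
        mz = study_pairs[study_pairs.zygosity == "MZ"]
        assert (mz["sex_1"] == mz["sex_2"]).all()


class TestMissingness:
    def test_profile_must_be_probability_vector(self):
        with pytest.raises(ValueError):
            MissingnessProfile(probs=(0.5, 0.6))

    def test_profile_incompatible_with_T(self):
        prof = MissingnessProfile(probs=(0.2, 0.2, 0.2, 0.2, 0.1, 0.1))
        with pytest.raises(ValueError, match="T=4"):
            prof.draw_mask(np.random.default_rng(0), 10, 4)

    def test_observe_all_profile_masks_nothing(self, study_model):
        model, truth = study_model
        cfg = tp.SimulationConfig(model, truth, n_mz=200, n_dz=200, seed=1,
                                  missingness=None)
        pairs, _ = tp.simulate_pairs(cfg)
        prof = MissingnessProfile(probs=(0, 0, 0, 0, 0, 1.0))
        masked, audit = apply_missingness(pairs, prof, seed=0, T=6)
        assert masked[[c for c in masked.columns if c.startswith("y")]].notna().all().all()
        assert audit["subjects_at_k_intervals"] == {6: 800}

    def test_histogram_matches_cohort_profile(self, study_model):
        """Default profile: subject counts at 1-4 intervals reproduce the
        cohort proportions within 3 multinomial standard errors."""
        model, truth = study_model
        cfg = tp.SimulationConfig(model, truth, n_mz=943, n_dz=943, seed=8)
        _, audit = tp.simulate_pairs(cfg)
        hist = audit["subjects_at_k_intervals"]
        n_subj = 4 * 943  # two twins per pair
        probs = np.array(COHORT_INTERVAL_COUNTS, float) / sum(COHORT_INTERVAL_COUNTS)
        for k in range(1, 5):
            se = np.sqrt(n_subj * probs[k - 1] * (1 - probs[k - 1]))
            assert abs(hist.get(k, 0) - n_subj * probs[k - 1]) < 3 * se
        assert set(hist) <= {1, 2, 3, 4}  # nobody observed everywhere, nobody removed

    def test_masking_never_removes_a_subject(self, study_model):
        model, truth = study_model
        cfg = tp.SimulationConfig(model, truth, n_mz=500, n_dz=500, seed=9)
        pairs, _ = tp.simulate_pairs(cfg)
        for j in (1, 2):
            cols = [f"y{j}_t{t}" for t in range(6)]
            assert pairs[cols].notna().any(axis=1).all()


class TestOrdinalEmission:
    def test_latent_below_both_thresholds_gives_zero(self):
        items = emit_ordinal_items(np.array([-10.0]), thresholds=(0.5, 1.5),
                                   rng=np.random.default_rng(0), noise_sd=0.01)
        assert (items == 0).all()

    def test_extreme_thresholds_force_single_category(self):
        z = np.random.default_rng(1).standard_normal(500)
        lo = emit_ordinal_items(z, thresholds=(-1e9, 1e9),
                                rng=np.random.default_rng(2))
        assert set(np.unique(lo)) == {1}

    def test_non_increasing_thresholds_rejected(self):
        with pytest.raises(ValueError):
            emit_ordinal_items(np.zeros(3), thresholds=(1.0, 1.0))

    def test_domain_scores_right_skewed(self, study_model):
        """Default thresholds produce mostly-zero items and positively skewed
        0-12 domain sums, like self-report distress screeners."""
        model, truth = study_model
        cfg = tp.SimulationConfig(model, truth, n_mz=1500, n_dz=1500, seed=4)
        panel = tp.simulate_panel(cfg, ordinal=True)
        items = panel[[f"item_{i:02d}" for i in range(1, 7)]].to_numpy()
        assert (items == 0).mean() > 0.55
        sums = items.sum(axis=1)
        skew = ((sums - sums.mean()) ** 3).mean() / sums.std() ** 3
        assert skew > 0.5

    def test_pipeline_closure_continuous_emission(self, study_model):
        """simulate -> score -> bin -> pairs reproduces the pair records the
        generator drew (continuous emission carries the scores exactly)."""
        from twinpath.data import build_pairs, score_panel
        model, truth = study_model
        cfg = tp.SimulationConfig(model, truth, n_mz=300, n_dz=300, seed=12)
        direct, _ = tp.simulate_pairs(cfg)
        panel = tp.simulate_panel(cfg, ordinal=False, age_jitter_sd=0.5)
        scored, audit = score_panel(panel, "psychological")
        assert audit["excluded_age"] == 0 and not audit["collisions"]
        rebuilt, _ = build_pairs(scored, T=6)
        rebuilt = rebuilt.sort_values("family_id").reset_index(drop=True)
        direct = direct.sort_values("family_id").reset_index(drop=True)
        ycols = [c for c in direct.columns if c.startswith("y")]
        assert np.allclose(rebuilt[ycols].to_numpy(float),
                           direct[ycols].to_numpy(float), equal_nan=True)


class TestDeterminism:
    def test_same_config_same_bytes(self, study_model):
        model, truth = study_model
        cfg = tp.SimulationConfig(model, truth, n_mz=150, n_dz=150, seed=77)
        p1, a1 = tp.simulate_pairs(cfg)
        p2, a2 = tp.simulate_pairs(cfg)
        assert p1.to_csv(index=False) == p2.to_csv(index=False)
        assert a1 == a2

    def test_different_seed_different_data(self, study_model):
        model, truth = study_model
        p1, _ = tp.simulate_pairs(tp.SimulationConfig(model, truth, 100, 100, seed=1))
        p2, _ = tp.simulate_pairs(tp.SimulationConfig(model, truth, 100, 100, seed=2))
        assert not p1.equals(p2)

    def test_truth_must_bind_all_labels(self, study_model):
        model, truth = study_model
        bad = {k: v for k, v in truth.items() if k != "beta_a"}
        with pytest.raises(ValueError, match="beta_a"):
            tp.simulate_pairs(tp.SimulationConfig(model, bad, 10, 10, seed=0))
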