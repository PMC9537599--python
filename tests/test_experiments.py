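"""Imbalanced-dataset construction, synthetic augmentation, task configs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiosynth.experiments import (BMI_GAP_BINS, D1_SPEC, D2_SPEC,
                                     ImbalanceSpec, augment_with_synthetic,
                                     balanced_indices,
                                     configure_alternative_task,
                                     imbalanced_indices, phase_rmse,
                                     run_debias_experiment,
                                     synthesize_minority)
from cardiosynth.networks import SynthesisResult


class IdentityGenerator:
    def synthesize(self, x, a_d):
        x = np.asarray(x, dtype=np.float32)
        return SynthesisResult(x=x, mapping=np.zeros_like(x), output=x)


@pytest.fixture(scope="module")
def age_pool():
    rng = np.random.default_rng(0)
    ages = rng.uniform(45, 82, 3000)
    images = (ages[:, None, None] / 100.0
              * np.ones((1, 8, 8), dtype=np.float32)).astype(np.float32)
    return images, ages


class TestImbalancedConstruction:
    def test_d1_counts_match_design(self, age_pool):
        _, ages = age_pool
        idx = imbalanced_indices(ages, D1_SPEC, np.random.default_rng(1))
        sel = ages[idx]
        assert len(sel) == 1000
        assert (sel < 70).sum() == 900
        assert (sel >= 70).sum() == 100

    def test_d2_counts_match_design(self, age_pool):
        _, ages = age_pool
        idx = imbalanced_indices(ages, D2_SPEC, np.random.default_rng(1))
        sel = ages[idx]
        assert (sel >= 60).sum() == 900
        assert (sel < 60).sum() == 100

    def test_same_seed_identical_selection(self, age_pool):
        _, ages = age_pool
        a = imbalanced_indices(ages, D1_SPEC, np.random.default_rng(7))
        b = imbalanced_indices(ages, D1_SPEC, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_insufficient_pool_reports_counts(self):
        ages = np.full(50, 50.0)          # no one older than 70
        with pytest.raises(ValueError, match="minority"):
            imbalanced_indices(ages, D1_SPEC, np.random.default_rng(0))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(40, 400),
           frac=st.floats(0.05, 0.45),
           thresh=st.floats(55, 75))
    def test_counts_exact_for_random_specs(self, n, frac, thresh):
        spec = ImbalanceSpec(n_total=n, threshold=thresh,
                             minority_side="older", minority_fraction=frac)
        ages = np.random.default_rng(0).uniform(45, 82, 5000)
        idx = imbalanced_indices(ages, spec, np.random.default_rng(1))
        n_min = int(round(n * frac))
        assert len(idx) == n
        assert (ages[idx] >= thresh).sum() == n_min

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ImbalanceSpec(minority_fraction=0.6)
        with pytest.raises(ValueError):
            ImbalanceSpec(minority_side="sideways")
        with pytest.raises(ValueError):
            ImbalanceSpec(synth_fractions=(0.0, 0.5))


class TestSyntheticAugmentation:
    def test_fraction_zero_is_noop(self, age_pool):
        images, ages = age_pool
        frame = augment_with_synthetic(images[:100], ages[:100],
                                       IdentityGenerator(), D1_SPEC, 0.0)
        assert len(frame) == 100
        assert frame["synthetic"].sum() == 0

    def test_count_and_flags(self, age_pool):
        images, ages = age_pool
        idx = imbalanced_indices(ages, D1_SPEC, np.random.default_rng(2))
        frame = augment_with_synthetic(images[idx], ages[idx],
                                       IdentityGenerator(), D1_SPEC, 0.10,
                                       seed=3)
        assert len(frame) == 1100
        assert frame["synthetic"].sum() == 100
        assert frame.attrs["images"].shape[0] == 1100

    def test_synthetic_targets_lie_in_minority_region(self, age_pool):
        images, ages = age_pool
        idx = imbalanced_indices(ages, D1_SPEC, np.random.default_rng(2))
        syn_x, syn_a = synthesize_minority(images[idx], ages[idx],
                                           IdentityGenerator(), D1_SPEC,
                                           0.25, np.random.default_rng(4))
        assert len(syn_a) == 250
        assert np.all(syn_a >= 70.0) and np.all(syn_a <= 82.0)
        # D2: minority is the young side
        idx2 = imbalanced_indices(ages, D2_SPEC, np.random.default_rng(2))
        _, syn_a2 = synthesize_minority(images[idx2], ages[idx2],
                                        IdentityGenerator(), D2_SPEC,
                                        0.10, np.random.default_rng(4))
        assert np.all(syn_a2 < 60.0) and np.all(syn_a2 >= 45.0)


class TestDebiasExperiment:
    def test_layout_and_leakage(self, age_pool):
        """One row per (fraction, seed) plus the balanced reference; the
        held-out set never overlaps the training pools."""
        images, ages = age_pool
        spec = ImbalanceSpec(n_total=300, synth_fractions=(0.25,))
        table = run_debias_experiment(
            images, ages, IdentityGenerator(), spec, seeds=(0, 1),
            n_test=64, regressor_config=dict(width=4, epochs=1))
        # fractions 0 and 0.25 plus balanced row, per seed
        assert len(table) == 2 * 3
        assert set(table["fraction"].dropna()) == {0.0, 0.25}
        assert np.isfinite(table["mae"]).all()
        frac_rows = table.dropna(subset=["fraction"])
        assert (frac_rows[frac_rows["fraction"] == 0.25]["n_train"]
                == 300 + 75).all()

    def test_balanced_indices_are_age_uniform(self, age_pool):
        _, ages = age_pool
        idx = balanced_indices(ages, 200, np.random.default_rng(0))
        sel = ages[idx]
        hist, _ = np.histogram(sel, bins=8, range=(45, 82))
        assert hist.min() >= 15          # roughly uniform occupancy


class TestAlternativeTasks:
    def test_bmi_task_exposes_table_gap_bins(self):
        cfg = configure_alternative_task("bmi")
        assert cfg["eval_gaps"] == BMI_GAP_BINS
        assert cfg["gap_min"] == -8.0 and cfg["gap_max"] == 8.0
        assert cfg["covariate"] == "bmi"

    def test_phase_task_uses_unit_gaps(self):
        cfg = configure_alternative_task("phase")
        assert cfg["eval_gaps"] == (-1, 0, 1)

    def test_age_is_default_roundtrip(self):
        cfg = configure_alternative_task("age")
        assert cfg["covariate"] == "age"

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            configure_alternative_task("contrast")

    def test_phase_rmse_zero_for_perfect_generator(self):
        rng = np.random.default_rng(0)
        es = rng.uniform(0, 1, (4, 8, 8)).astype(np.float32)

        class ToES:
            def synthesize(self, x, a_d):
                return SynthesisResult(x=np.asarray(x), mapping=None,
                                       output=es)

        assert phase_rmse(ToES(), np.zeros((4, 8, 8), dtype=np.float32),
                          es) == pytest.approx(0.0)
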