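import numpy as np
import pytest

from gleason_cad.patching import PatchRecord
from gleason_cad.training import (
    TrainingConfig,
    balance_classes,
    random_search,
    split_slides,
    train_scale,
)

SIDE = 46  # smallest side the four conv+pool blocks accept


def make_patch(slide_id, label, rng, side=SIDE):
    """Trivially separable 2-class fixture: solid color vs. noise."""
    if label == 1:
        pixels = np.full((side, side, 3), (40, 80, 200), dtype=np.float64)
        pixels += rng.normal(0, 5, pixels.shape)
    else:
        pixels = rng.uniform(0, 255, (side, side, 3))
    return PatchRecord(
        slide_id=slide_id,
        scale=side,
        origin=(0, 0),
        pixels=np.clip(pixels, 0, 255).astype(np.uint8),
        label=label,
    )


def separable_patches(rng, n_slides=8, per_class=5):
    patches = []
    for s in range(n_slides):
        for label in (1, 2):
            patches += [
                make_patch(f"s{s}", label, rng) for _ in range(per_class)
            ]
    return patches


class TestBalanceClasses:
    def _patches(self, counts, rng):
        patches = []
        for label, n in counts.items():
            for i in range(n):
                patches.append(
                    PatchRecord(f"s{i % 7}", 46, (0, 0), None, label=label)
                )
        return patches

    def test_gp1_subsampled_to_median_of_others(self, rng):
        counts = {1: 1000, 2: 100, 3: 100, 4: 100, 5: 100}
        kept, plan = balance_classes(self._patches(counts, rng), seed=0)
        assert plan.gp1_target == 100
        assert plan.counts_after == {1: 100, 2: 100, 3: 100, 4: 100, 5: 100}

    def test_gp1_below_target_is_untouched(self, rng):
        counts = {1: 50, 2: 100, 3: 120, 4: 80, 5: 100}
        kept, plan = balance_classes(self._patches(counts, rng), seed=0)
        assert plan.counts_after[1] == 50

    def test_other_classes_never_dropped(self, rng):
        counts = {1: 400, 2: 37, 3: 111, 4: 8, 5: 60}
        kept, plan = balance_classes(self._patches(counts, rng), seed=0)
        for label in (2, 3, 4, 5):
            assert plan.counts_after[label] == counts[label]

    def test_same_seed_same_subsample(self, rng):
        patches = self._patches({1: 300, 2: 50, 3: 50, 4: 50, 5: 50}, rng)
        kept_a, _ = balance_classes(patches, seed=9)
        kept_b, _ = balance_classes(patches, seed=9)
        assert [id(p) for p in kept_a] == [id(p) for p in kept_b]

    def test_empty_input_gives_empty_output(self):
        kept, _ = balance_classes([], seed=0)
        assert kept == []


class TestSplitSlides:
    def test_partition_is_disjoint_and_complete(self):
        ids = [f"s{i}" for i in range(10)]
        train, val, test = split_slides(ids, 0.3, seed=1, test_fraction=0.2)
        assert sorted(train + val + test) == sorted(ids)
        assert not (set(train) & set(val)) and not (set(val) & set(test))

    def test_no_heldout_slide_contributes_training_patches(self, rng):
        patches = separable_patches(rng)
        config = TrainingConfig(epochs=1, seed=0, val_fraction=0.25)
        train_ids, val_ids, _ = split_slides(
            [p.slide_id for p in patches], config.val_fraction, config.seed
        )
        assert not (set(train_ids) & set(val_ids))


class TestTrainScale:
    def test_learns_trivially_separable_fixture(self, rng):
        patches = separable_patches(rng)
        config = TrainingConfig(epochs=5, seed=0, batch_size=8)
        model, history = train_scale(patches, config)
        assert history["train_acc"].iloc[-1] > 0.95

    def test_loss_decreases_on_learnable_fixture(self, rng):
        patches = separable_patches(rng)
        config = TrainingConfig(epochs=5, seed=0, batch_size=8)
        _, history = train_scale(patches, config)
        assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]

    def test_reproducible_with_fixed_seed(self, rng):
        patches = separable_patches(rng, n_slides=4, per_class=3)
        config = TrainingConfig(epochs=2, seed=5, batch_size=8)
        model_a, hist_a = train_scale(patches, config)
        model_b, hist_b = train_scale(patches, config)
        for (pa, _), (pb, _) in zip(model_a.parameters(), model_b.parameters()):
            np.testing.assert_array_equal(pa, pb)
        assert hist_a.equals(hist_b)

    def test_mixed_scales_rejected(self, rng):
        patches = separable_patches(rng, n_slides=2, per_class=2)
        patches[0].scale = 100
        with pytest.raises(ValueError, match="mix scales"):
            train_scale(patches, TrainingConfig(epochs=1))

    def test_no_patches_rejected(self):
        with pytest.raises(ValueError, match="no patches"):
            train_scale([], TrainingConfig())


class TestRandomSearch:
    def test_budget_one_returns_single_sampled_config(self, rng):
        patches = separable_patches(rng, n_slides=4, per_class=3)
        base = TrainingConfig(epochs=1, seed=0)
        best, trials = random_search(patches, budget=1, seed=3, base_config=base)
        assert len(trials) == 1
        assert best.learning_rate == trials["learning_rate"].iloc[0]

    def test_same_seed_same_trial_sequence(self, rng):
        patches = separable_patches(rng, n_slides=4, per_class=3)
        base = TrainingConfig(epochs=1, seed=0)
        _, trials_a = random_search(patches, budget=2, seed=4, base_config=base)
        _, trials_b = random_search(patches, budget=2, seed=4, base_config=base)
        assert trials_a.equals(trials_b)

    def test_best_config_maximizes_validation_accuracy(self, rng):
        patches = separable_patches(rng, n_slides=4, per_class=3)
        base = TrainingConfig(epochs=1, seed=0)
        best, trials = random_search(patches, budget=3, seed=0, base_config=base)
        best_row = trials.loc[trials["val_acc"].idxmax()]
        assert best.learning_rate == best_row["learning_rate"]
        assert (trials["val_acc"] <= best_row["val_acc"]).all()

    def test_zero_budget_rejected(self, rng):
        with pytest.raises(ValueError, match="budget"):
            random_search([], budget=0, seed=0)
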