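"""Stratified splitting, CV grid search, class-weight search, bootstrap."""

import numpy as np
import pytest

from rbpsvm import simulate as sim
from rbpsvm.exceptions import TrainingError
from rbpsvm.io import ProteinRecord
from rbpsvm.model_selection import (
    DEFAULT_W_MINUS,
    DEFAULT_W_PLUS,
    SplitSpec,
    bootstrap_balanced,
    class_weight_search,
    grid_search,
    stratified_split,
)


@pytest.fixture(scope="module")
def divisible_dataset():
    """100 positives + 900 negatives -> a 10% split stratifies exactly."""
    records, _, _ = sim.generate(
        sim.SimConfig(
            n_pos=100,
            n_neg=900,
            planted_pos_kmers=sim.POS_KMERS,
            lambda_pos=8.0,
            length_range=(50, 200),
            seed=11,
        )
    )
    return records


def test_stratified_split_exact_on_divisible_counts(divisible_dataset):
    train, test = stratified_split(divisible_dataset, SplitSpec(test_fraction=0.1, seed=0))
    assert len(test) == 100
    assert sum(r.label for r in test) == 10
    assert sum(r.label for r in train) == 90


def test_stratified_split_partition(divisible_dataset):
    train, test = stratified_split(divisible_dataset, SplitSpec(seed=3))
    train_ids = {r.id for r in train}
    test_ids = {r.id for r in test}
    assert train_ids.isdisjoint(test_ids)
    assert train_ids | test_ids == {r.id for r in divisible_dataset}


def test_stratified_split_deterministic(divisible_dataset):
    a = stratified_split(divisible_dataset, SplitSpec(seed=5))
    b = stratified_split(divisible_dataset, SplitSpec(seed=5))
    assert [r.id for r in a[0]] == [r.id for r in b[0]]
    assert [r.id for r in a[1]] == [r.id for r in b[1]]


def test_stratified_split_ratio_invariant(divisible_dataset):
    """Positive ratio in each partition within 2 points of the global ratio."""
    global_ratio = np.mean([r.label for r in divisible_dataset])
    for seed in (0, 1, 2):
        train, test = stratified_split(divisible_dataset, SplitSpec(seed=seed))
        for part in (train, test):
            if len(part) >= 25:
                ratio = np.mean([r.label for r in part])
                assert abs(ratio - global_ratio) <= 0.02


def test_split_requires_both_classes():
    records = [ProteinRecord(id=f"p{i}", sequence="MKRKKR" * 10, label=1) for i in range(10)]
    with pytest.raises(TrainingError):
        stratified_split(records, SplitSpec())


def test_grid_search_single_combination(small_planted):
    records, _ = small_planted
    spec = SplitSpec(n_folds=3, seed=0)
    result = grid_search(records, ks=[3], costs=[1.0], spec=spec)
    assert len(result.frame) == 1
    assert len(result.best["per_fold_bacc"]) == 3
    assert 0.0 <= result.best["mean_bacc"] <= 1.0


def test_grid_search_prefers_k3_on_tripeptide_signal(small_planted):
    """The planted signal lives at k = 3, so k = 3 beats k = 1."""
    records, _ = small_planted
    spec = SplitSpec(n_folds=3, seed=0)
    result = grid_search(records, ks=[1, 3], costs=[1.0], spec=spec)
    frame = result.frame.set_index("k")
    assert frame.loc[3, "mean_bacc"] >= frame.loc[1, "mean_bacc"]


def test_grid_search_deterministic(small_planted):
    records, _ = small_planted
    spec = SplitSpec(n_folds=3, seed=9)
    a = grid_search(records, ks=[2, 3], costs=[1.0], spec=spec)
    b = grid_search(records, ks=[2, 3], costs=[1.0], spec=spec)
    assert a.frame["mean_bacc"].tolist() == b.frame["mean_bacc"].tolist()
    assert a.best_index == b.best_index


def test_grid_search_tie_break_prefers_simpler_model(small_planted):
    """Duplicated combinations tie exactly; smaller k then smaller C wins."""
    records, _ = small_planted
    spec = SplitSpec(n_folds=3, seed=0)
    result = grid_search(records, ks=[3], costs=[10.0, 1.0], spec=spec)
    frame = result.frame
    if frame["mean_bacc"].nunique() == 1:
        assert result.best["C"] == 1.0


def test_default_weight_grid_contains_published_pairs():
    pairs = {(wp, wm) for wp in DEFAULT_W_PLUS for wm in DEFAULT_W_MINUS}
    assert (1.8, 0.2) in pairs
    assert (1.0, 0.1) in pairs


def test_class_weight_search_single_pair(small_planted):
    records, _ = small_planted
    spec = SplitSpec(n_folds=3, seed=0)
    result = class_weight_search(
        records, k=3, cost=1.0, weight_grid=[(1.8, 0.2)], spec=spec
    )
    assert len(result.frame) == 1
    assert result.best["w_plus"] == 1.8


def test_bootstrap_subsample_sizes(small_planted):
    records, _ = small_planted
    positives = [r for r in records if r.label == 1]
    test_records = records[:40]
    result = bootstrap_balanced(records, test_records, k=3, cost=1.0, reps=3, seed=0)
    assert len(result.replicates) == 3
    for model, metrics_dict in result.replicates:
        assert 0.0 <= metrics_dict["bacc"] <= 1.0
    # every replicate trains on all positives + an equal negative subsample:
    # the training set size is fixed at 2 * n_pos, visible via the SV count bound
    for model, _ in result.replicates:
        assert len(model.support_vectors) <= 2 * len(positives)


def test_bootstrap_equal_sizes_uses_full_negative_set():
    records, _, _ = sim.generate(
        sim.SimConfig(
            n_pos=20,
            n_neg=20,
            planted_pos_kmers=("KKR",),
            lambda_pos=10.0,
            length_range=(50, 120),
            seed=5,
        )
    )
    result = bootstrap_balanced(records, records, k=3, cost=1.0, reps=1, seed=0)
    assert len(result.replicates) == 1


def test_bootstrap_more_positives_than_negatives_raises():
    records, _, _ = sim.generate(
        sim.SimConfig(n_pos=30, n_neg=10, length_range=(50, 80), seed=5)
    )
    with pytest.raises(TrainingError):
        bootstrap_balanced(records, records, reps=1)


def test_bootstrap_deterministic(small_planted):
    records, _ = small_planted
    a = bootstrap_balanced(records, records[:30], reps=2, seed=4)
    b = bootstrap_balanced(records, records[:30], reps=2, seed=4)
    assert [m["bacc"] for _, m in a.replicates] == [m["bacc"] for _, m in b.replicates]


def test_grid_result_tsv_round_trip(tmp_path, small_planted):
    import pandas as pd

    records, _ = small_planted
    result = grid_search(records, ks=[3], costs=[1.0], spec=SplitSpec(n_folds=3, seed=0))
    path = tmp_path / "grid.tsv"
    result.to_tsv(path)
    frame = pd.read_csv(path, sep="\t")
    assert frame["selected"].sum() == 1
    assert frame.loc[0, "mean_bacc"] == pytest.approx(result.best["mean_bacc"])
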