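"""SVM core: dual feasibility, KKT conditions, the weight-vector
reconstruction identity, prediction semantics and Platt calibration."""

import numpy as np
import pytest

from rbpsvm import simulate as sim
from rbpsvm import svm as svm_mod
from rbpsvm.exceptions import CalibrationError, TrainingError
from rbpsvm.io import ProteinRecord
from rbpsvm.kernel import KernelConfig, featurize_csr, maybe_normalize


def _separable_toy(n=30, seed=0):
    """Positives rich in KKK, negatives rich in LLL: linearly separable."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        base = "".join(rng.choice(list("ACDEFGHIMNPQSTVWY"), size=60))
        records.append(
            ProteinRecord(id=f"pos{i}", sequence=base[:20] + "KKKKKKKK" + base[20:], label=1)
        )
        records.append(
            ProteinRecord(id=f"neg{i}", sequence=base[:20] + "LLLLLLLL" + base[20:], label=0)
        )
    return records


def test_separable_training_reaches_perfect_accuracy():
    records = _separable_toy()
    model = svm_mod.train(records, KernelConfig(k=3), cost=1.0, weights=(1.0, 1.0))
    scores = svm_mod.decision_values(model, [r.sequence for r in records])
    labels = np.array([r.label for r in records])
    assert np.all((scores >= 0).astype(int) == labels)


def test_single_class_dataset_raises():
    records = [r for r in _separable_toy() if r.label == 1]
    with pytest.raises(TrainingError):
        svm_mod.train(records, KernelConfig(k=3))


def test_class_weighted_box_constraint():
    """Negative dual coefficients are bounded by C * W- under (1.8, 0.2)."""
    records = _separable_toy()
    model = svm_mod.train(records, KernelConfig(k=3), cost=1.0, weights=(1.8, 0.2))
    negatives = model.dual_coefs[model.dual_coefs < 0]
    positives = model.dual_coefs[model.dual_coefs > 0]
    assert np.all(np.abs(negatives) <= 0.2 * (1 + 1e-9))
    assert np.all(positives <= 1.8 * (1 + 1e-9))


def test_dual_feasibility_across_model_bank(model_bank):
    for model, records in model_bank:
        w_plus, w_minus = model.class_weights
        for coef in model.dual_coefs:
            bound = model.cost * (w_plus if coef > 0 else w_minus)
            assert 0 < abs(coef) <= bound * (1 + 1e-9) + 1e-12
        assert abs(float(np.sum(model.dual_coefs))) <= 1e-6


def test_kkt_condition_on_free_support_vectors(model_bank):
    """Free SVs (strictly inside the box) sit on the margin: y f(x) = 1."""
    checked = 0
    for model, records in model_bank:
        w_plus, w_minus = model.class_weights
        gram = model.sv_matrix @ model.sv_matrix.T
        sv_scores = np.asarray(gram @ model.dual_coefs).ravel() + model.bias
        for coef, score in zip(model.dual_coefs, sv_scores):
            bound = model.cost * (w_plus if coef > 0 else w_minus)
            if 1e-6 < abs(coef) < bound * (1 - 1e-6):  # strictly free
                y = 1.0 if coef > 0 else -1.0
                assert y * score == pytest.approx(1.0, abs=1e-4)
                checked += 1
    assert checked > 0  # the bank must actually contain free SVs


def test_unweighted_equals_equal_weights(small_planted):
    records, _ = small_planted
    a = svm_mod.train(records, KernelConfig(k=3), cost=1.0, weights=(1.0, 1.0))
    b = svm_mod.train(records, KernelConfig(k=3), cost=1.0, weights=(2.0, 2.0))
    # W+ = W- = w rescales the effective cost; with w = 1 vs 2 decision values
    # differ, but identical weight pairs must coincide exactly:
    c = svm_mod.train(records, KernelConfig(k=3), cost=1.0, weights=(1.0, 1.0))
    seqs = [r.sequence for r in records[:20]]
    assert np.allclose(
        svm_mod.decision_values(a, seqs), svm_mod.decision_values(c, seqs), atol=1e-6
    )
    assert b is not None


def test_reconstruction_identity(model_bank, heldout_sequences):
    """w . Phi(x) + b reproduces the dual decision function."""
    for model, _ in model_bank:
        weights = svm_mod.feature_weights(model)
        phi = maybe_normalize(
            featurize_csr(heldout_sequences, model.config), model.config
        )
        recon = np.asarray(phi @ weights.as_array()).ravel() + model.bias
        dual = svm_mod.decision_values(model, heldout_sequences)
        assert np.allclose(dual, recon, rtol=1e-8, atol=1e-10)


def test_feature_weight_sign_recovery(toy_model):
    """Planted positive k-mers get w > 0, planted negative k-mers w < 0."""
    weights = svm_mod.feature_weights(toy_model)
    for kmer in sim.POS_KMERS:
        assert weights.value(kmer) > 0
    for kmer in sim.NEG_KMERS:
        assert weights.value(kmer) < 0


def test_decision_on_empty_spectrum_is_bias(toy_model):
    assert svm_mod.decision_value(toy_model, "XXXXXX") == pytest.approx(
        toy_model.bias, abs=1e-12
    )


def test_predict_cutoff_semantics(toy_model, heldout_sequences):
    records = [ProteinRecord(id=f"s{i}", sequence=s) for i, s in enumerate(heldout_sequences)]
    all_in = svm_mod.predict(toy_model, records, cutoff=-np.inf)
    none_in = svm_mod.predict(toy_model, records, cutoff=np.inf)
    assert all_in["predicted_label"].sum() == len(records)
    assert none_in["predicted_label"].sum() == 0
    counts = [
        svm_mod.predict(toy_model, records, cutoff=c)["predicted_label"].sum()
        for c in np.linspace(-2, 2, 9)
    ]
    assert counts == sorted(counts, reverse=True)  # monotone in the cutoff


def test_probability_scale_requires_calibration(toy_model, heldout_sequences):
    records = [ProteinRecord(id="s0", sequence=heldout_sequences[0])]
    with pytest.raises(CalibrationError):
        svm_mod.predict(toy_model, records, cutoff=0.5, scale="probability")


def test_calibration_properties(toy_model, small_planted, heldout_sequences):
    records, _ = small_planted
    calibrated = svm_mod.calibrate(toy_model, records, seed=0)
    probs = svm_mod.probabilities(calibrated, heldout_sequences)
    scores = svm_mod.decision_values(calibrated, heldout_sequences)
    assert np.all((probs > 0) & (probs < 1))
    # ranking by probability equals ranking by decision value
    assert np.array_equal(np.argsort(probs), np.argsort(scores))


def test_calibration_symmetric_balanced_data():
    """On symmetric balanced data the sigmoid crosses ~0.5 at decision 0."""
    records = _separable_toy(n=40, seed=3)
    model = svm_mod.train(records, KernelConfig(k=3), cost=1.0, weights=(1.0, 1.0))
    calibrated = svm_mod.calibrate(model, records, seed=0)
    a, b = calibrated.calibration
    p_at_zero = 1.0 / (1.0 + np.exp(b))
    assert p_at_zero == pytest.approx(0.5, abs=0.1)


def test_calibrate_single_class_raises(toy_model):
    positives = [
        ProteinRecord(id=f"p{i}", sequence="KKRKKRKKR" * 8, label=1) for i in range(5)
    ]
    with pytest.raises((CalibrationError, TrainingError)):
        svm_mod.calibrate(toy_model, positives)


def test_training_determinism(small_planted):
    records, _ = small_planted
    a = svm_mod.train(records, KernelConfig(k=3), cost=1.0, weights=(1.8, 0.2), seed=7)
    b = svm_mod.train(records, KernelConfig(k=3), cost=1.0, weights=(1.8, 0.2), seed=7)
    assert np.array_equal(a.dual_coefs, b.dual_coefs)
    assert a.bias == b.bias
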