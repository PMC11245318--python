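"""Training machinery: contrastive loss vs enumeration oracle, BCE,
metric formulas vs independent oracle, optimisation sanity, persistence."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.metrics import confusion_matrix, matthews_corrcoef

from graphadt import (GraphADTClassifier, SynthConfig, classification_loss,
                      compute_metrics, contrastive_loss, evaluate,
                      generate_dataset, train_model)
from graphadt.errors import BatchTooSmallError, SingleClassDatasetError


def ntxent_oracle(Ho, Hr, tau):
    """Direct pairwise-softmax enumeration of the symmetric NT-Xent loss."""
    n = Ho.shape[0]
    def cos(a, b):
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
    S = np.array([[cos(Ho[i], Hr[j]) / tau for j in range(n)] for i in range(n)])
    loss = 0.0
    for i in range(n):
        loss += -np.log(np.exp(S[i, i]) / np.exp(S[i, :]).sum())
        loss += -np.log(np.exp(S[i, i]) / np.exp(S[:, i]).sum())
    return loss / (2 * n)


class TestContrastiveLoss:
    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_matches_enumeration_oracle(self, n, rng):
        Ho = rng.normal(size=(n, 6))
        Hr = rng.normal(size=(n, 6))
        assert abs(contrastive_loss(Ho, Hr, 0.5) - ntxent_oracle(Ho, Hr, 0.5)) < 1e-6

    def test_orthogonal_identical_views_two_mols(self):
        H = np.array([[1.0, 0.0], [0.0, 1.0]])
        # S = [[1,0],[0,1]]/tau; per-row loss = log(e^1/(e^1+e^0))^-1
        expected = -np.log(np.e / (np.e + 1.0))
        assert abs(contrastive_loss(H, H, 1.0) - expected) < 1e-9

    def test_separated_limit_loss_vanishes(self):
        Ho = np.array([[1.0, 0.0], [-1.0, 0.0]])
        assert contrastive_loss(Ho, Ho, 0.05) < 1e-8

    def test_batch_permutation_invariance(self, rng):
        Ho, Hr = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))
        perm = rng.permutation(5)
        assert abs(contrastive_loss(Ho, Hr, 0.7)
                   - contrastive_loss(Ho[perm], Hr[perm], 0.7)) < 1e-10

    def test_batch_of_one_rejected(self):
        with pytest.raises(BatchTooSmallError):
            contrastive_loss(np.ones((1, 3)), np.ones((1, 3)))


class TestClassificationLoss:
    def test_zero_logits_give_log_two(self):
        assert abs(classification_loss(np.zeros(8), np.ones(8)) - np.log(2)) < 1e-12

    def test_perfect_logits_vanish(self):
        logits = np.array([50.0, -50.0])
        assert classification_loss(logits, np.array([1, 0])) < 1e-12

    def test_confident_mistake_grows(self):
        assert classification_loss(np.array([-30.0]), np.array([1])) > 20


class TestMetrics:
    def test_against_sklearn_oracle(self, rng):
        y = rng.integers(0, 2, size=1000)
        prob = rng.random(1000)
        rep = compute_metrics(y, prob)
        pred = (prob >= 0.5).astype(int)
        tn, fp, fn, tp = confusion_matrix(y, pred).ravel()
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (tp, tn, fp, fn)
        assert abs(rep.acc - (tp + tn) / 1000) < 1e-12
        assert abs(rep.se - tp / (tp + fn)) < 1e-12
        assert abs(rep.sp - tn / (tn + fp)) < 1e-12
        assert abs(rep.mcc - matthews_corrcoef(y, pred)) < 1e-10

    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        rep = compute_metrics(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert rep.auc == 1.0 and rep.mcc == 1.0

    def test_random_predictions_auc_near_half(self, rng):
        y = rng.integers(0, 2, size=2000)
        rep = compute_metrics(y, rng.permutation(y) + rng.normal(0, 1e-6, 2000))
        assert abs(rep.auc - 0.5) < 0.05

    def test_all_positive_predictions(self):
        y = np.array([0, 1, 0, 1])
        rep = compute_metrics(y, np.array([0.9, 0.9, 0.8, 0.8]))
        assert rep.sp == 0.0 and rep.se == 1.0 and rep.mcc == 0.0


class TestTraining:
    def test_loss_decreases_early(self):
        df = generate_dataset(SynthConfig(n_molecules=60, seed=21))
        for seed in (0, 1, 2):
            clf = GraphADTClassifier(epochs=5, hidden_dim=16, batch_size=16,
                                     val_fraction=0.0, random_state=seed)
            clf.fit(df["smiles"].tolist(), df["label"].to_numpy())
            losses = [h["loss"] for h in clf.history_]
            assert losses[-1] < losses[0]

    def test_seeding_gives_identical_first_epoch(self):
        df = generate_dataset(SynthConfig(n_molecules=40, seed=22))
        runs = []
        for _ in range(2):
            clf = GraphADTClassifier(epochs=1, hidden_dim=8, val_fraction=0.0,
                                     random_state=5)
            clf.fit(df["smiles"].tolist(), df["label"].to_numpy())
            runs.append(clf.history_[0]["loss"])
        assert runs[0] == runs[1]

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassDatasetError):
            GraphADTClassifier(epochs=1).fit(["CCO", "CCC", "CCN"] * 7, [1] * 21)

    def test_lambda_zero_and_no_remap_ablation(self):
        df = generate_dataset(SynthConfig(n_molecules=40, seed=23))
        clf = GraphADTClassifier(epochs=2, hidden_dim=8, val_fraction=0.0,
                                 contrastive_weight=0.0, use_remap=False,
                                 random_state=1)
        clf.fit(df["smiles"].tolist(), df["label"].to_numpy())
        assert np.all(np.isfinite(clf.predict_proba(df["smiles"].head(5))))

    def test_save_load_roundtrip(self, tiny_model, tmp_path):
        path = tmp_path / "ckpt"
        tiny_model.save(str(path))
        restored = GraphADTClassifier.load(str(path))
        smiles = ["CCO", "CC(Cl)(Cl)Cl", "CCCC[N+](=O)[O-]"]
        assert np.allclose(restored.predict_proba(smiles),
                           tiny_model.predict_proba(smiles))

    def test_sklearn_protocol(self, tiny_model):
        cloned = clone(tiny_model)
        assert cloned.get_params() == tiny_model.get_params()
        assert not hasattr(cloned, "net_")
        assert list(tiny_model.classes_) == [0, 1]
        assert tiny_model.predict(["CCO"]).shape == (1,)

    def test_heldout_accuracy_bounded_by_bayes_rate(self, trained_model,
                                                    benchmark_split):
        """With label noise p the Bayes-optimal accuracy against the noisy
        held-out labels is 1-p; the fitted model must not appear to beat it
        (overfitting guard)."""
        _, test_df = benchmark_split
        prob = trained_model.predict_proba(test_df["smiles"].tolist())[:, 1]
        rep = compute_metrics(test_df["label"].to_numpy(), prob)
        assert rep.acc <= 0.95 + 0.02

    def test_train_model_and_evaluate_wrappers(self):
        df = generate_dataset(SynthConfig(n_molecules=40, seed=24))
        clf = train_model(df, train_config={"epochs": 2, "hidden_dim": 8,
                                            "val_fraction": 0.0})
        rep = evaluate(clf, df)
        assert 0.0 <= rep.acc <= 1.0
        assert rep.n == 40
        with pytest.raises(ValueError):
            train_model(df.head(5))
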