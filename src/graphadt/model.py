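"""GraphADT classifier: joint contrastive + supervised training of original
and structure-remapped molecular graph representations.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``predict_proba`` on arrays of SMILES strings) so it composes with pipelines
and model selection.  Two :class:`~graphadt.encoder.GraphEncoder` streams —
one over the atom graph, one over the bond (remapped) graph — produce per-
molecule representations; a linear head on their concatenation gives the
toxicity logit.  The loss is binary cross-entropy plus ``lambda`` times a
symmetric NT-Xent contrastive term that aligns each molecule's two views
against in-batch negatives.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from . import autodiff as ad
from .autodiff import Tensor, no_grad
from .encoder import EncoderConfig, GraphEncoder
from .errors import (BatchTooSmallError, EmptyRemapError, NonFiniteLossError,
                     SingleClassDatasetError, UntrainedModelError)
from .featurize import (FeaturizerConfig, MolGraph, bond_edge_arrays,
                        parse_smiles, parse_smiles_batch)
from .metrics import MetricsReport, compute_metrics
from .nn import Adam, Linear, Module
from .remap import RemappedGraph, edge_feature_arrays, remap_graph

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _normalize_rows(H: Tensor) -> Tensor:
    norm = ((H * H).sum(axis=1, keepdims=True) + 1e-12) ** 0.5
    return H / norm


def _contrastive_loss_t(H_orig: Tensor, H_remap: Tensor, tau: float) -> Tensor:
    n = H_orig.shape[0]
    if n < 2:
        raise BatchTooSmallError("contrastive loss needs a batch of >= 2")
    if tau <= 0:
        raise ValueError("temperature must be positive")
    S = (_normalize_rows(H_orig) @ _normalize_rows(H_remap).T) * (1.0 / tau)
    diag_idx = (np.arange(n), np.arange(n))
    pos = S[diag_idx]
    loss_o = (ad.logsumexp(S, axis=1).reshape(n) - pos).mean()
    loss_r = (ad.logsumexp(S.T, axis=1).reshape(n) - pos).mean()
    return (loss_o + loss_r) * 0.5


def contrastive_loss(H_orig, H_remap, tau: float = 0.5) -> float:
    """Symmetric NT-Xent between matched batches of representations.

    Row i of each matrix is the same molecule seen through the original and
    the remapped stream; that pair is the positive, every other row of the
    opposite stream is a negative.  Cosine similarities are scaled by
    ``1/tau`` and the cross-entropy is averaged over both directions.
    """
    with no_grad():
        return float(_contrastive_loss_t(Tensor(np.asarray(H_orig, float)),
                                         Tensor(np.asarray(H_remap, float)),
                                         tau).item())


def _bce_with_logits_t(logits: Tensor, y: np.ndarray,
                       weights: Optional[np.ndarray] = None) -> Tensor:
    # numerically stable: max(x,0) - x*y + log(1 + exp(-|x|))
    y_t = Tensor(np.asarray(y, dtype=float))
    absx = logits.relu() + (-logits).relu()
    per = logits.relu() - logits * y_t + ((-absx).exp() + 1.0).log()
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        return (per * Tensor(w)).sum() / float(w.sum())
    return per.mean()


def classification_loss(logits, y) -> float:
    """Mean binary cross-entropy of ``sigmoid(logits)`` against labels."""
    with no_grad():
        return float(_bce_with_logits_t(Tensor(np.asarray(logits, float)),
                                        np.asarray(y)).item())


# ---------------------------------------------------------------------------
# per-molecule graph pack
# ---------------------------------------------------------------------------

@dataclass
class GraphPack:
    """Featurised original + remapped graph arrays for one molecule."""
    smiles: str
    X: np.ndarray
    A: np.ndarray
    edges: tuple                       # original-graph bond features, COO
    Xr: Optional[np.ndarray]           # None for bond-less molecules
    Ar: Optional[np.ndarray]
    edges_r: Optional[tuple]
    graph: MolGraph = None
    remapped: Optional[RemappedGraph] = None

    @property
    def has_remap(self) -> bool:
        return self.Xr is not None


def build_pack(graph: MolGraph, exclude_backtrack: bool = False) -> GraphPack:
    """Assemble encoder-ready arrays; bond-less molecules get no remapped
    stream (the model falls back to the original representation)."""
    edges = bond_edge_arrays(graph)
    try:
        rg = remap_graph(graph, exclude_backtrack=exclude_backtrack)
        Xr, Ar = rg.Xr, rg.Ar
        edges_r = edge_feature_arrays(rg)
    except EmptyRemapError:
        logger.info("molecule %r has no bonds; remapped stream falls back to "
                    "the original representation", graph.smiles)
        rg, Xr, Ar, edges_r = None, None, None, None
    return GraphPack(smiles=graph.smiles, X=graph.X, A=graph.A, edges=edges,
                     Xr=Xr, Ar=Ar, edges_r=edges_r, graph=graph, remapped=rg)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class _GraphADTNet(Module):
    def __init__(self, d_atom: int, d_bond: int, config: EncoderConfig,
                 rng: np.random.Generator):
        self.enc_orig = GraphEncoder(d_atom, config, rng, edge_dim=d_bond)
        self.enc_remap = GraphEncoder(2 * d_atom + d_bond, config, rng,
                                      edge_dim=2 * d_bond + d_atom)
        self.head = Linear(2 * self.enc_orig.out_dim, 1, rng)


class GraphADTClassifier(BaseEstimator, ClassifierMixin):
    """Acute-dermal-toxicity graph classifier with bond-graph remapping,
    multi-view pooling and contrastive two-stream training.

    Parameters
    ----------
    n_layers : int
        Number of (GIN + MVPool) encoder layers K.
    hidden_dim : int
        Node embedding width.
    pool_ratio : float
        Fraction r of nodes kept per pooling step (``ceil(r*N)``).
    delta : float
        PageRank restart probability in (0, 1].
    k_power : int
        Exponent on the normalised adjacency in the PageRank seed.
    use_edge_features, gin_eps_learnable, exclude_backtrack : bool
        Architecture switches (see the encoder / remap modules).
    use_remap : bool
        If False, the remapped stream is ablated: the original-graph
        representation stands in for both views.
    epochs, batch_size, learning_rate : training schedule.
    contrastive_weight : float
        Weight lambda of the NT-Xent term; 0 disables the contrastive path.
    temperature : float
        NT-Xent temperature tau.
    val_fraction : float
        Fraction of the training data held out for early stopping.
    patience : int
        Early-stopping patience in epochs (on validation AUC).
    class_weight : None or "balanced"
        Optional positive-class reweighting of the BCE term.
    random_state : int
        Seed for parameter init, splitting and shuffling.
    """

    def __init__(self, n_layers: int = 2, hidden_dim: int = 32,
                 pool_ratio: float = 0.8, delta: float = 0.2, k_power: int = 1,
                 use_edge_features: bool = True, gin_eps_learnable: bool = True,
                 exclude_backtrack: bool = False, use_remap: bool = True,
                 epochs: int = 30, batch_size: int = 32,
                 learning_rate: float = 1e-3, contrastive_weight: float = 0.1,
                 temperature: float = 0.5, val_fraction: float = 0.1,
                 patience: int = 20, class_weight=None,
                 random_state: int = 0, verbose: int = 0):
        self.n_layers = n_layers
        self.hidden_dim = hidden_dim
        self.pool_ratio = pool_ratio
        self.delta = delta
        self.k_power = k_power
        self.use_edge_features = use_edge_features
        self.gin_eps_learnable = gin_eps_learnable
        self.exclude_backtrack = exclude_backtrack
        self.use_remap = use_remap
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.contrastive_weight = contrastive_weight
        self.temperature = temperature
        self.val_fraction = val_fraction
        self.patience = patience
        self.class_weight = class_weight
        self.random_state = random_state
        self.verbose = verbose

    # -- internals ------------------------------------------------------------

    def _encoder_config(self) -> EncoderConfig:
        return EncoderConfig(n_layers=self.n_layers, hidden_dim=self.hidden_dim,
                             pool_ratio=self.pool_ratio, delta=self.delta,
                             k_power=self.k_power,
                             gin_eps_learnable=self.gin_eps_learnable,
                             use_edge_features=self.use_edge_features)

    def _encode_pair(self, pack: GraphPack):
        h_o = self.net_.enc_orig(pack.X, pack.A, pack.edges)
        if pack.has_remap and self.use_remap:
            h_r = self.net_.enc_remap(pack.Xr, pack.Ar, pack.edges_r)
        else:
            h_r = h_o
        return h_o, h_r

    def _encode_remap_arrays(self, Xr, Ar, edges_r) -> Tensor:
        return self.net_.enc_remap(Xr, Ar, edges_r)

    def _logit_from_reps(self, h_o: Tensor, h_r: Tensor) -> Tensor:
        h = ad.concatenate([h_o, h_r], axis=0)
        return self.net_.head(h.reshape(1, h.shape[0])).reshape(1)

    def _batch_forward(self, packs: Sequence[GraphPack]):
        hs_o, hs_r = [], []
        for pack in packs:
            h_o, h_r = self._encode_pair(pack)
            hs_o.append(h_o)
            hs_r.append(h_r)
        H_o = ad.stack(hs_o, axis=0)
        H_r = ad.stack(hs_r, axis=0)
        H = ad.concatenate([H_o, H_r], axis=1)
        logits = self.net_.head(H).reshape(len(packs))
        return H_o, H_r, logits

    def _predict_proba_packs(self, packs: Sequence[GraphPack]) -> np.ndarray:
        with no_grad():
            _, _, logits = self._batch_forward(packs)
            return 1.0 / (1.0 + np.exp(-logits.data))

    def _sample_weights(self, y: np.ndarray) -> Optional[np.ndarray]:
        if self.class_weight is None:
            return None
        if self.class_weight != "balanced":
            raise ValueError("class_weight must be None or 'balanced'")
        n, n_pos = len(y), int(np.sum(y))
        w_pos = n / (2.0 * n_pos)
        w_neg = n / (2.0 * (n - n_pos))
        return np.where(np.asarray(y) == 1, w_pos, w_neg)

    # -- sklearn API ----------------------------------------------------------

    def fit(self, X, y) -> "GraphADTClassifier":
        """Fit on SMILES strings ``X`` and binary labels ``y``.

        Invalid SMILES are skipped with a logged warning.  Raises
        :class:`SingleClassDatasetError` if only one class remains.
        """
        smiles = list(X)
        y = np.asarray(y).astype(int)
        if y.ndim != 1 or len(smiles) != len(y):
            raise ValueError("X and y must be matched 1-D sequences")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

        self.featurizer_config_ = FeaturizerConfig()
        graphs, kept = parse_smiles_batch(smiles, self.featurizer_config_)
        y = y[kept]
        if len(np.unique(y)) < 2:
            raise SingleClassDatasetError("training data needs both classes")
        packs = [build_pack(g, self.exclude_backtrack) for g in graphs]

        rng = np.random.default_rng(self.random_state)
        d_atom = self.featurizer_config_.d_atom
        d_bond = self.featurizer_config_.d_bond
        self.encoder_config_ = self._encoder_config()
        self.net_ = _GraphADTNet(d_atom, d_bond, self.encoder_config_, rng)
        self.classes_ = np.array([0, 1])

        idx = np.arange(len(packs))
        if self.val_fraction > 0 and len(packs) >= 10:
            tr_idx, va_idx = train_test_split(
                idx, test_size=self.val_fraction, stratify=y,
                random_state=self.random_state)
        else:
            tr_idx, va_idx = idx, np.array([], dtype=int)
        packs_tr = [packs[i] for i in tr_idx]
        y_tr = y[tr_idx]
        packs_va = [packs[i] for i in va_idx]
        y_va = y[va_idx]

        opt = Adam(self.net_.parameters(), lr=self.learning_rate)
        weights_tr = self._sample_weights(y_tr)
        best_auc, best_state, best_epoch = -np.inf, None, -1
        history: List[dict] = []
        since_best = 0
        for epoch in range(self.epochs):
            order = rng.permutation(len(packs_tr))
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(order), self.batch_size):
                sel = order[start:start + self.batch_size]
                batch = [packs_tr[i] for i in sel]
                yb = y_tr[sel]
                wb = weights_tr[sel] if weights_tr is not None else None
                opt.zero_grad()
                H_o, H_r, logits = self._batch_forward(batch)
                loss = _bce_with_logits_t(logits, yb, wb)
                if self.contrastive_weight > 0 and len(batch) >= 2:
                    loss = loss + self.contrastive_weight * _contrastive_loss_t(
                        H_o, H_r, self.temperature)
                value = loss.item()
                if not np.isfinite(value):
                    raise NonFiniteLossError(
                        f"non-finite loss at epoch {epoch}: {value}")
                loss.backward()
                opt.step()
                epoch_loss += value
                n_batches += 1
            record = {"epoch": epoch, "loss": epoch_loss / max(n_batches, 1)}
            if len(packs_va):
                prob_va = self._predict_proba_packs(packs_va)
                rep = compute_metrics(y_va, prob_va)
                record.update(val_auc=rep.auc, val_acc=rep.acc)
                score = rep.auc if np.isfinite(rep.auc) else rep.acc
                if score > best_auc:
                    best_auc, best_epoch = score, epoch
                    best_state = self.net_.state_dict()
                    since_best = 0
                else:
                    since_best += 1
            history.append(record)
            if self.verbose:
                logger.info("epoch %d: %s", epoch, record)
            if len(packs_va) and since_best > self.patience:
                break
        if best_state is not None:
            self.net_.load_state_dict(best_state)
        self.best_epoch_ = best_epoch if best_state is not None else self.epochs - 1
        self.history_ = history
        self.n_features_in_ = 1
        return self

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise UntrainedModelError("call fit() or load() first")

    def _packs_from_smiles(self, X) -> List[GraphPack]:
        graphs = [parse_smiles(s, self.featurizer_config_) for s in X]
        return [build_pack(g, self.exclude_backtrack) for g in graphs]

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities, column order ``[P(non-toxic), P(toxic)]``."""
        self._check_fitted()
        p1 = self._predict_proba_packs(self._packs_from_smiles(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_function(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, 1]
        return np.log(p / (1.0 - p))

    # -- persistence ----------------------------------------------------------

    def save(self, path: str) -> None:
        """Write weights to ``<path>`` (npz) and configs to ``<path>.json``."""
        self._check_fitted()
        np.savez(path, **self.net_.state_dict())
        sidecar = {
            "params": self.get_params(),
            "featurizer_config": self.featurizer_config_.to_json(),
            "encoder_config": self.encoder_config_.to_dict(),
        }
        with open(str(path) + ".json", "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "GraphADTClassifier":
        with open(str(path) + ".json", encoding="utf-8") as fh:
            sidecar = json.load(fh)
        est = cls(**sidecar["params"])
        est.featurizer_config_ = FeaturizerConfig.from_json(
            sidecar["featurizer_config"])
        est.encoder_config_ = EncoderConfig(**sidecar["encoder_config"])
        rng = np.random.default_rng(est.random_state)
        est.net_ = _GraphADTNet(est.featurizer_config_.d_atom,
                                est.featurizer_config_.d_bond,
                                est.encoder_config_, rng)
        npz_path = str(path) if str(path).endswith(".npz") else str(path) + ".npz"
        with np.load(npz_path) as data:
            est.net_.load_state_dict({k: data[k] for k in data.files})
        est.classes_ = np.array([0, 1])
        est.history_ = []
        est.best_epoch_ = -1
        return est


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def train_model(dataset, train_config: Optional[dict] = None,
                encoder_config: Optional[dict] = None) -> GraphADTClassifier:
    """Fit a :class:`GraphADTClassifier` on a dataset of (smiles, label).

    ``dataset`` is a pandas DataFrame with columns ``smiles``/``label`` or an
    iterable of pairs; config dicts override estimator defaults.
    """
    import pandas as pd

    if isinstance(dataset, pd.DataFrame):
        smiles, y = dataset["smiles"].tolist(), dataset["label"].to_numpy()
    else:
        smiles, y = zip(*dataset)
        y = np.asarray(y)
    if len(smiles) < 20:
        raise ValueError("training requires at least 20 molecules")
    params = dict(train_config or {})
    params.update(encoder_config or {})
    return GraphADTClassifier(**params).fit(smiles, y)


def evaluate(model: GraphADTClassifier, dataset, threshold: float = 0.5) -> MetricsReport:
    """Metrics of a fitted model on a labelled dataset."""
    import pandas as pd

    if isinstance(dataset, pd.DataFrame):
        smiles, y = dataset["smiles"].tolist(), dataset["label"].to_numpy()
    else:
        smiles, y = zip(*dataset)
        y = np.asarray(y)
    prob = model.predict_proba(smiles)[:, 1]
    return compute_metrics(y, prob, threshold=threshold)
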