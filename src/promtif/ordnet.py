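"""Ordinal-regression convolutional model of promoter TIF.

The sorted-library prediction task is ordinal: the 11 classes are ordered
fluorescence gates, and misclassifying by one bin is a smaller error than by
five.  The model therefore projects each one-hot spacer through a shallow
convolutional trunk (4 width-1, 16 width-4, 32 width-2 kernels), dropout
(p = 0.3) and two dense layers (128, 64) onto a single latent score
s = w.x correlated with TIF.  A vector of ten ordered biases b turns the
score into threshold probabilities

    o_hat_i = sigmoid(w.x + b_i)  ~  Pr(y > i | x),   i = 0..9,

trained as ten weighted binary cross-entropy problems against the prefix
targets o_i(y) = 1[i < y].  An auxiliary softplus penalty on adjacent bias
gaps enforces b_i > b_{i+1} (hence monotone thresholds) softly, staying
positive to avoid oscillation of the bias order during training.  Class
probabilities follow by differencing the thresholds.

Public surface is statsmodels-like: build a :class:`PromoterTIFModel` from a
labeled dataset, call ``fit()`` for a :class:`TIFResults` carrying the
parameter snapshot at minimum validation loss, its training history, test
metrics and ``summary()``; ``cross_validate()`` aggregates five folds.
:class:`OrthogonalityModel` is the binary variant (same trunk, single
sigmoid output) predicting loss of orthogonality toward noncognate sigma
factors.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .binfilter import FilteredDataset
from .evalmetrics import EvalReport, roc_auc_binary
from .seqdata import encode_batch

EPS = 1e-7  # probability clamp inside the cross-entropy


@dataclass
class OrdinalNetConfig:
    """Architecture of the trunk + ordinal head."""

    input_length: int = 17
    conv_layers: tuple = ((4, 1), (16, 4), (32, 2))  # (kernels, width)
    dropout_p: float = 0.3
    fc_sizes: tuple = (128, 64)
    n_classes: int = 11

    @property
    def n_thresholds(self) -> int:
        return self.n_classes - 1

    @property
    def feature_dim(self) -> int:
        return self.fc_sizes[-1]

    def conv_output_length(self) -> int:
        L = self.input_length
        for _, width in self.conv_layers:
            L = L - width + 1
        if L < 1:
            raise ValueError("input_length too short for the convolution stack")
        return L


@dataclass
class TrainConfig:
    """Optimisation and data-splitting settings.

    The optimiser is adaptive-moment gradient descent; the stopping rule is
    the minimum of the validation loss with a patience window.  Splits are
    70/10/20 train/validation/test, stratified by class.
    """

    test_fraction: float = 0.20
    val_fraction: float = 0.10
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 10
    folds: int = 5
    seed: int = 0
    verbose: bool = False


def encode_ordinal_target(y: int | np.ndarray, n_classes: int = 11) -> np.ndarray:
    """Prefix-of-ones target: o_i = 1 iff i < y, length n_classes - 1."""
    y_arr = np.asarray(y)
    if ((y_arr < 0) | (y_arr > n_classes - 1)).any():
        raise ValueError("class label out of range")
    thresholds = np.arange(n_classes - 1)
    out = (thresholds[None, :] < y_arr.reshape(-1, 1)).astype(np.float64)
    return out[0] if y_arr.ndim == 0 else out


def forward_head(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Threshold probabilities o_hat_i = sigmoid(w.x + b_i)."""
    x = np.atleast_2d(x)
    s = x @ w
    return nn.sigmoid(s[:, None] + b[None, :])


def class_probabilities(o_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Difference the threshold probabilities into class probabilities.

    Pr(y=0) = 1 - o_hat_0, Pr(y=i) = o_hat_{i-1} - o_hat_i, and
    Pr(y=K-1) = o_hat_{K-2}; the unique assignment that satisfies
    Pr(y > K-1) = 0 and sums to one.  When the thresholds are non-monotone
    (possible early in training) negative differences are clamped to zero
    and the vector renormalised; the returned flag records that this
    happened.  Predicted class is the argmax, ties resolved to the lower
    class.
    """
    o_hat = np.atleast_2d(np.asarray(o_hat, dtype=np.float64))
    n, k1 = o_hat.shape
    probs = np.empty((n, k1 + 1))
    probs[:, 0] = 1.0 - o_hat[:, 0]
    probs[:, 1:-1] = o_hat[:, :-1] - o_hat[:, 1:]
    probs[:, -1] = o_hat[:, -1]
    warn = bool((probs < -1e-12).any())
    np.clip(probs, 0.0, None, out=probs)
    probs /= probs.sum(axis=1, keepdims=True)
    predicted = probs.argmax(axis=1)
    return probs, predicted, warn


def loss_output(o_hat: np.ndarray, o: np.ndarray, sample_weight: np.ndarray | float = 1.0) -> float:
    """Weighted multilabel BCE: mean over samples of w_n * sum_i BCE_i."""
    o_hat = np.clip(np.atleast_2d(o_hat), EPS, 1.0 - EPS)
    o = np.atleast_2d(o)
    bce = -(o * np.log(o_hat) + (1.0 - o) * np.log(1.0 - o_hat)).sum(axis=1)
    return float(np.mean(np.asarray(sample_weight) * bce))


def loss_auxiliary(b: np.ndarray) -> float:
    """Soft ordering penalty: sum over adjacent pairs of softplus(b_{i+1} - b_i)."""
    b = np.asarray(b, dtype=np.float64)
    return float(nn.softplus(np.diff(b)).sum())


@dataclass
class PredictionResult:
    """Model outputs for a batch of spacers."""

    latent_score: np.ndarray        # (n,)
    thresholds: np.ndarray          # (n, K-1)
    class_probs: np.ndarray         # (n, K)
    predicted_class: np.ndarray     # (n,)
    monotonicity_warning: bool = False


class _OrdinalNetwork:
    """Trunk + ordinal head with joint backpropagation."""

    def __init__(self, cfg: OrdinalNetConfig, rng: np.random.Generator):
        self.cfg = cfg
        layers: list[nn.Layer] = []
        c_in = 4
        for c_out, width in cfg.conv_layers:
            layers.append(nn.Conv1D(c_in, c_out, width, rng))
            layers.append(nn.ReLU())
            c_in = c_out
        layers.append(nn.Flatten())
        layers.append(nn.Dropout(cfg.dropout_p, rng))
        d_in = c_in * cfg.conv_output_length()
        for d_out in cfg.fc_sizes:
            layers.append(nn.Dense(d_in, d_out, rng))
            layers.append(nn.ReLU())
            d_in = d_out
        self.trunk = nn.Sequential(layers)
        self.w = rng.normal(0.0, np.sqrt(1.0 / d_in), size=d_in)
        # start the biases strictly decreasing so thresholds begin ordered
        self.b = np.linspace(1.0, -1.0, cfg.n_thresholds)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return self.trunk.params() + [self.w, self.b]

    def grads(self):
        return self.trunk.grads() + [self.dw, self.db]

    def forward(self, X: np.ndarray, train: bool = False):
        feat = self.trunk.forward(X, train=train)
        s = feat @ self.w
        o_hat = nn.sigmoid(s[:, None] + self.b[None, :])
        if train:
            self._feat = feat
        return s, o_hat

    def train_step_grads(self, o_hat, targets, sample_weight) -> None:
        """Fill gradient buffers for zeta = zeta_out + zeta_aux on this batch."""
        n = o_hat.shape[0]
        dlogits = (sample_weight[:, None] * (o_hat - targets)) / n
        self.db[...] = dlogits.sum(axis=0)
        # ordering penalty gradient: softplus'(b_{i+1} - b_i) = sigmoid(gap)
        sig = nn.sigmoid(np.diff(self.b))
        self.db[1:] += sig
        self.db[:-1] -= sig
        ds = dlogits.sum(axis=1)
        self.dw[...] = self._feat.T @ ds
        dfeat = ds[:, None] * self.w[None, :]
        self.trunk.backward(dfeat)


def _stratified_split(y: np.ndarray, test_size: float, seed: int):
    idx = np.arange(len(y))
    try:
        return train_test_split(idx, test_size=test_size, stratify=y, random_state=seed)
    except ValueError:
        warnings.warn("class too small to stratify; falling back to a plain random split")
        return train_test_split(idx, test_size=test_size, random_state=seed)


def split_dataset(y: np.ndarray, cfg: TrainConfig):
    """70/10/20 stratified train/validation/test index split.

    The test set takes ``test_fraction``; the validation set is carved from
    the remainder (0.10 / 0.80 = 1/8 of it), preserving class proportions.
    """
    rest, test = _stratified_split(y, cfg.test_fraction, cfg.seed)
    val_of_rest = cfg.val_fraction / (1.0 - cfg.test_fraction)
    train, val = _stratified_split(y[rest], val_of_rest, cfg.seed + 1)
    return rest[train], rest[val], test


class PromoterTIFModel:
    """Ordinal promoter-TIF model over a labeled spacer dataset.

    Parameters
    ----------
    sequences : list of equal-length spacer strings
    labels : integer ordinal classes, 0..n_classes-1
    net_config, train_config : architecture and optimisation settings;
        ``net_config.input_length`` is inferred from the data when omitted.
    """

    def __init__(
        self,
        sequences: Sequence[str],
        labels: Sequence[int],
        net_config: OrdinalNetConfig | None = None,
        train_config: TrainConfig | None = None,
    ):
        self.sequences = list(sequences)
        self.y = np.asarray(labels, dtype=np.int64)
        if len(self.sequences) != len(self.y):
            raise ValueError("sequences and labels differ in length")
        L = len(self.sequences[0])
        self.net_config = net_config or OrdinalNetConfig(input_length=L)
        if self.net_config.input_length != L:
            raise ValueError("net_config.input_length does not match the data")
        self.train_config = train_config or TrainConfig()
        if len(self.y) < self.net_config.n_classes:
            raise ValueError("dataset smaller than the number of classes")
        if self.y.min() < 0 or self.y.max() > self.net_config.n_classes - 1:
            raise ValueError("labels out of class range")
        self.X = encode_batch(self.sequences)

    @classmethod
    def from_dataset(cls, dataset: FilteredDataset, **kwargs) -> "PromoterTIFModel":
        return cls(dataset.sequences, dataset.labels, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, seq_col: str = "sequence",
                       class_col: str = "class", **kwargs) -> "PromoterTIFModel":
        return cls(list(df[seq_col]), df[class_col].to_numpy(), **kwargs)

    # -- fitting -----------------------------------------------------------

    def _fit_indices(self, train_idx, val_idx, seed: int):
        cfg, net_cfg = self.train_config, self.net_config
        rng = np.random.default_rng(seed)
        net = _OrdinalNetwork(net_cfg, rng)
        opt = nn.Adam(net.params(), net.grads(), lr=cfg.learning_rate)

        y_train = self.y[train_idx]
        counts = np.bincount(y_train, minlength=net_cfg.n_classes)
        present = counts > 0
        w_n = np.ones(net_cfg.n_classes)
        w_n[present] = counts[present].sum() / (present.sum() * counts[present])

        X_train, X_val = self.X[train_idx], self.X[val_idx]
        t_train = encode_ordinal_target(y_train, net_cfg.n_classes)
        t_val = encode_ordinal_target(self.y[val_idx], net_cfg.n_classes)
        sw_train = w_n[y_train]
        sw_val = w_n[self.y[val_idx]]

        history = []
        best_loss, best_epoch, best_params = np.inf, -1, None
        order = np.arange(len(train_idx))
        for epoch in range(cfg.max_epochs):
            rng.shuffle(order)
            for start in range(0, len(order), cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                _, o_hat = net.forward(X_train[sel], train=True)
                net.train_step_grads(o_hat, t_train[sel], sw_train[sel])
                opt.step()
            _, o_val = net.forward(X_val, train=False)
            val_loss = loss_output(o_val, t_val, sw_val) + loss_auxiliary(net.b)
            history.append(val_loss)
            if cfg.verbose:
                print(f"epoch {epoch}: validation loss {val_loss:.5f}")
            if val_loss < best_loss:
                best_loss, best_epoch = val_loss, epoch
                best_params = nn.snapshot(net.params())
            elif epoch - best_epoch >= cfg.patience:
                break
        nn.restore(net.params(), best_params)
        return net, history, best_epoch, w_n

    def fit(self) -> "TIFResults":
        """Train with early stopping; return the minimum-validation-loss model."""
        cfg = self.train_config
        train_idx, val_idx, test_idx = split_dataset(self.y, cfg)
        net, history, best_epoch, w_n = self._fit_indices(train_idx, val_idx, cfg.seed)
        return TIFResults(self, net, history, best_epoch, w_n,
                          train_idx, val_idx, test_idx)

    def cross_validate(self, folds: int | None = None) -> pd.DataFrame:
        """K-fold evaluation: per-fold test metrics, one row per fold.

        Each fold's held-out 20% is the test set; validation is 1/8 of the
        remaining data, stratified.  Aggregate with ``df.mean()`` /
        ``df.std()`` for the mean +/- std presentation.
        """
        cfg = self.train_config
        folds = folds or cfg.folds
        try:
            kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
            splits = list(kf.split(self.X, self.y))
        except ValueError:
            warnings.warn("stratified folding failed; using unstratified folds")
            from sklearn.model_selection import KFold
            kf = KFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
            splits = list(kf.split(self.X))
        rows = []
        for fold, (rest, test_idx) in enumerate(splits):
            val_of_rest = cfg.val_fraction / (1.0 - cfg.test_fraction)
            tr, va = _stratified_split(self.y[rest], val_of_rest, cfg.seed + fold + 1)
            net, history, best_epoch, w_n = self._fit_indices(
                rest[tr], rest[va], cfg.seed + fold)
            res = TIFResults(self, net, history, best_epoch, w_n,
                             rest[tr], rest[va], test_idx)
            rep = res.eval_report()
            row = {"fold": fold, "weighted_acc": rep.weighted_acc,
                   "weighted_mae": rep.weighted_mae, "spearman_rho": rep.spearman_rho}
            for c, v in enumerate(rep.per_class_mae):
                row[f"mae_class_{c}"] = v
            rows.append(row)
        return pd.DataFrame(rows).set_index("fold")


class TIFResults:
    """Fitted ordinal TIF model: parameter snapshot, history, diagnostics."""

    def __init__(self, model: PromoterTIFModel, net: _OrdinalNetwork,
                 history: list[float], best_epoch: int, class_weights_: np.ndarray,
                 train_idx, val_idx, test_idx):
        self.model = model
        self.net = net
        self.history = history
        self.best_epoch = best_epoch
        self.class_weights_ = class_weights_
        self.train_idx = np.asarray(train_idx)
        self.val_idx = np.asarray(val_idx)
        self.test_idx = np.asarray(test_idx)
        self._report: EvalReport | None = None

    @property
    def biases(self) -> np.ndarray:
        return self.net.b.copy()

    def predict_encoded(self, X: np.ndarray, batch_size: int = 4096) -> PredictionResult:
        scores, thresholds = [], []
        for start in range(0, len(X), batch_size):
            s, o_hat = self.net.forward(X[start:start + batch_size], train=False)
            scores.append(s)
            thresholds.append(o_hat)
        s = np.concatenate(scores)
        o_hat = np.concatenate(thresholds)
        probs, pred, warn = class_probabilities(o_hat)
        return PredictionResult(s, o_hat, probs, pred, warn)

    def predict(self, sequences: Sequence[str]) -> PredictionResult:
        """Predict latent score, threshold and class probabilities for spacers."""
        return self.predict_encoded(encode_batch(list(sequences)))

    def eval_report(self) -> EvalReport:
        """Metrics on the held-out test split."""
        if self._report is None:
            pred = self.predict_encoded(self.model.X[self.test_idx]).predicted_class
            truth = self.model.y[self.test_idx]
            self._report = EvalReport.from_predictions(
                pred, truth, self.model.net_config.n_classes)
        return self._report

    def summary(self) -> str:
        rep = self.eval_report()
        cfg = self.model.net_config
        lines = [
            "Ordinal promoter-TIF model",
            "=" * 44,
            f"sequences            {len(self.model.y):>10d}",
            f"input length         {cfg.input_length:>10d} nt",
            f"classes              {cfg.n_classes:>10d}",
            f"train/val/test       {len(self.train_idx)}/{len(self.val_idx)}/{len(self.test_idx)}",
            f"best epoch           {self.best_epoch:>10d}",
            f"min validation loss  {min(self.history):>10.4f}",
            "-" * 44,
            f"weighted accuracy    {rep.weighted_acc:>10.3f}",
            f"weighted MAE         {rep.weighted_mae:>10.3f}",
            f"Spearman rho         {rep.spearman_rho:>10.3f}",
            "-" * 44,
            "per-class MAE:",
        ]
        for c, v in enumerate(rep.per_class_mae):
            lines.append(f"  y = {c:<2d}             {v:>10.3f}")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint with an embedded config copy."""
        payload = {
            "net_config": asdict(self.model.net_config),
            "train_config": asdict(self.model.train_config),
            "params": nn.snapshot(self.net.params()),
            "history": self.history,
            "best_epoch": self.best_epoch,
            "class_weights": self.class_weights_,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @staticmethod
    def load_network(path: str | Path) -> tuple["_OrdinalNetwork", dict]:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        cfg_d = dict(payload["net_config"])
        cfg_d["conv_layers"] = tuple(tuple(c) for c in cfg_d["conv_layers"])
        cfg_d["fc_sizes"] = tuple(cfg_d["fc_sizes"])
        cfg = OrdinalNetConfig(**cfg_d)
        net = _OrdinalNetwork(cfg, np.random.default_rng(0))
        nn.restore(net.params(), payload["params"])
        return net, payload


class OrthogonalityModel:
    """Binary classifier for loss of orthogonality toward noncognate sigmas.

    Same convolutional trunk as the ordinal model; the specialised head and
    ordinal loss are replaced by a single sigmoid output and plain BCE.  The
    positive class is fluorescence under a noncognate sigma factor, i.e.
    loss of orthogonality.
    """

    def __init__(self, sequences: Sequence[str], labels: Sequence[int],
                 net_config: OrdinalNetConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.sequences = list(sequences)
        self.y = np.asarray(labels, dtype=np.int64)
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError("binary model requires labels in {0, 1}")
        L = len(self.sequences[0])
        self.net_config = net_config or OrdinalNetConfig(input_length=L, n_classes=2)
        self.train_config = train_config or TrainConfig()
        self.X = encode_batch(self.sequences)

    def fit(self) -> "OrthogonalityResults":
        cfg = self.train_config
        train_idx, val_idx, test_idx = split_dataset(self.y, cfg)
        rng = np.random.default_rng(cfg.seed)
        net_cfg = self.net_config
        layers: list[nn.Layer] = []
        c_in = 4
        for c_out, width in net_cfg.conv_layers:
            layers.append(nn.Conv1D(c_in, c_out, width, rng))
            layers.append(nn.ReLU())
            c_in = c_out
        layers.append(nn.Flatten())
        layers.append(nn.Dropout(net_cfg.dropout_p, rng))
        d_in = c_in * net_cfg.conv_output_length()
        for d_out in net_cfg.fc_sizes:
            layers.append(nn.Dense(d_in, d_out, rng))
            layers.append(nn.ReLU())
            d_in = d_out
        layers.append(nn.Dense(d_in, 1, rng))
        trunk = nn.Sequential(layers)
        opt = nn.Adam(trunk.params(), trunk.grads(), lr=cfg.learning_rate)

        X_train, y_train = self.X[train_idx], self.y[train_idx].astype(np.float64)
        X_val, y_val = self.X[val_idx], self.y[val_idx].astype(np.float64)

        def val_loss_fn():
            p = nn.sigmoid(trunk.forward(X_val, train=False)[:, 0])
            p = np.clip(p, EPS, 1 - EPS)
            return float(-np.mean(y_val * np.log(p) + (1 - y_val) * np.log(1 - p)))

        history, best_loss, best_epoch, best_params = [], np.inf, -1, None
        order = np.arange(len(train_idx))
        for epoch in range(cfg.max_epochs):
            rng.shuffle(order)
            for start in range(0, len(order), cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                logits = trunk.forward(X_train[sel], train=True)[:, 0]
                p = nn.sigmoid(logits)
                dlogits = ((p - y_train[sel]) / len(sel))[:, None]
                trunk.backward(dlogits)
                opt.step()
            vl = val_loss_fn()
            history.append(vl)
            if vl < best_loss:
                best_loss, best_epoch = vl, epoch
                best_params = nn.snapshot(trunk.params())
            elif epoch - best_epoch >= cfg.patience:
                break
        nn.restore(trunk.params(), best_params)
        return OrthogonalityResults(self, trunk, history, best_epoch,
                                    train_idx, val_idx, test_idx)


class OrthogonalityResults:
    def __init__(self, model, trunk, history, best_epoch, train_idx, val_idx, test_idx):
        self.model = model
        self.trunk = trunk
        self.history = history
        self.best_epoch = best_epoch
        self.train_idx, self.val_idx, self.test_idx = train_idx, val_idx, test_idx

    def predict_proba(self, sequences: Sequence[str]) -> np.ndarray:
        X = encode_batch(list(sequences))
        return nn.sigmoid(self.trunk.forward(X, train=False)[:, 0])

    def roc_auc(self) -> float:
        X = self.model.X[self.test_idx]
        scores = nn.sigmoid(self.trunk.forward(X, train=False)[:, 0])
        return roc_auc_binary(scores, self.model.y[self.test_idx])

    def summary(self) -> str:
        return (
            "Orthogonality (binary) model\n"
            f"sequences      {len(self.model.y)}\n"
            f"best epoch     {self.best_epoch}\n"
            f"test ROC AUC   {self.roc_auc():.3f}"
        )
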