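"""The stacking combiner and the naive ensemble baselines.

The combined model is a fully-connected network that maps the concatenated
probability vectors of the four base predictors (80 inputs, 20 per model)
through two hidden layers of 120 and 60 rectified-linear units to a 20-way
softmax output.  It is trained per site with categorical cross-entropy
against the wildtype residue, using Adam at a fixed learning rate for a
fixed number of epochs (no early stopping).

The two baselines it is compared against are the naive ensembles: the
elementwise mean of the four probability vectors, and copy-the-single-
most-confident-entry across all four models.

Everything here is plain numpy: the forward pass, backpropagation and the
Adam update are written out explicitly so that training is bit-for-bit
deterministic given the seed and the numeric backend.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ALPHABET, PROB_COLUMNS, ValidationError, validate_probability_vector

#: Default concatenation order of the four base models: structure-like
#: first, then sequence-like.  Any fixed order works, but weights are
#: order-dependent, so the order is serialized with the trained model.
DEFAULT_MODEL_ORDER: tuple[str, ...] = ("struct_a", "struct_b", "seq_a", "seq_b")

LAYER_WIDTHS: tuple[int, int, int, int] = (80, 120, 60, 20)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the combiner training run.

    Defaults follow the reference recipe: 150 epochs of Adam at a fixed
    learning rate of 1e-4 with categorical cross-entropy.  Batch size and
    the protein-level validation split are local choices (batching is
    standard for ~1e5-site training sets; the split only monitors
    generalization and never gates training).
    """

    epochs: int = 150
    learning_rate: float = 1e-4
    batch_size: int = 256
    validation_fraction: float = 0.1
    seed: int = 0
    model_order: tuple[str, ...] = DEFAULT_MODEL_ORDER

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning rate must be positive")
        if not (0.0 <= self.validation_fraction < 0.5):
            raise ValidationError("validation_fraction must lie in [0, 0.5)")
        if len(self.model_order) != 4 or len(set(self.model_order)) != 4:
            raise ValidationError("model_order must name exactly four distinct models")


# --------------------------------------------------------------------------
# feature assembly


def assemble_features(
    vectors: Mapping[str, np.ndarray | Sequence[float]],
    order: Sequence[str] = DEFAULT_MODEL_ORDER,
) -> np.ndarray:
    """Concatenate four models' probability vectors into one length-80 input.

    ``vectors`` maps model identifier to that model's 20-way vector for a
    single site; segments appear in ``order``, each in alphabet order.
    """
    if set(vectors) != set(order):
        raise ValidationError(
            f"need exactly the models {sorted(order)}, got {sorted(vectors)}"
        )
    parts = [validate_probability_vector(vectors[m], where=f"model {m}") for m in order]
    return np.concatenate(parts)


def assemble_feature_matrix(
    predictions: pd.DataFrame,
    order: Sequence[str] = DEFAULT_MODEL_ORDER,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Build the (n_sites, 80) feature matrix from a long prediction table.

    Every (protein, site) must have exactly one row per model in ``order``.
    Returns ``(X, y, sites)`` where ``y`` holds wildtype indices into the
    alphabet and ``sites`` is the per-site key frame (protein_id, site,
    wildtype) aligned with the rows of ``X``.
    """
    order = list(order)
    present = set(predictions["model_id"].unique())
    if set(order) - present:
        raise ValidationError(f"prediction table lacks models {sorted(set(order) - present)}")

    sites = (
        predictions[["protein_id", "site", "wildtype"]]
        .drop_duplicates(subset=["protein_id", "site"])
        .sort_values(["protein_id", "site"], kind="stable")
        .reset_index(drop=True)
    )
    base_index = pd.MultiIndex.from_frame(sites[["protein_id", "site"]])
    blocks = []
    for m in order:
        sub = predictions.loc[predictions["model_id"] == m]
        dup = sub.duplicated(subset=["protein_id", "site"])
        if dup.any():
            bad = sub.loc[dup, ["protein_id", "site"]].head(10).to_records(index=False)
            raise ValidationError(f"duplicate rows for model {m}: {list(bad)}")
        indexed = sub.set_index(["protein_id", "site"])[PROB_COLUMNS]
        block = indexed.reindex(base_index).to_numpy(dtype=float)
        if np.isnan(block).any():
            missing = base_index[np.isnan(block).any(axis=1)][:10].tolist()
            raise ValidationError(f"sites missing model {m}'s vector: {missing}")
        blocks.append(block)
    X = np.hstack(blocks)
    aa_index = {aa: i for i, aa in enumerate(ALPHABET)}
    try:
        y = np.array([aa_index[aa] for aa in sites["wildtype"]], dtype=int)
    except KeyError as exc:
        raise ValidationError(f"non-canonical wildtype {exc} in training sites") from None
    return X, y, sites


# --------------------------------------------------------------------------
# the network


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class CombinerNetwork:
    """Weights of the 80-120-60-20 fully-connected stacking network."""

    weights: list[np.ndarray]  # [(80,120), (120,60), (60,20)]
    biases: list[np.ndarray]

    @classmethod
    def initialize(cls, seed: int) -> "CombinerNetwork":
        """Uniform fan-in-scaled initialization, U(-1/sqrt(fan_in), +1/sqrt(fan_in))."""
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(101,)))
        weights, biases = [], []
        for fan_in, fan_out in zip(LAYER_WIDTHS[:-1], LAYER_WIDTHS[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return cls(weights=weights, biases=biases)

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Softmax output probabilities, shape (n, 20)."""
        h = np.maximum(X @ self.weights[0] + self.biases[0], 0.0)
        h = np.maximum(h @ self.weights[1] + self.biases[1], 0.0)
        return _softmax(h @ self.weights[2] + self.biases[2])

    def _forward_cached(self, X):
        h1 = np.maximum(X @ self.weights[0] + self.biases[0], 0.0)
        h2 = np.maximum(h1 @ self.weights[1] + self.biases[1], 0.0)
        p = _softmax(h2 @ self.weights[2] + self.biases[2])
        return h1, h2, p

    def gradients(self, X: np.ndarray, y: np.ndarray):
        """Mean cross-entropy loss and its gradients for one minibatch."""
        n = X.shape[0]
        h1, h2, p = self._forward_cached(X)
        loss = -np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean()
        delta = p.copy()
        delta[np.arange(n), y] -= 1.0
        delta /= n
        gW3 = h2.T @ delta
        gb3 = delta.sum(axis=0)
        d2 = (delta @ self.weights[2].T) * (h2 > 0)
        gW2 = h1.T @ d2
        gb2 = d2.sum(axis=0)
        d1 = (d2 @ self.weights[1].T) * (h1 > 0)
        gW1 = X.T @ d1
        gb1 = d1.sum(axis=0)
        return loss, [gW1, gW2, gW3], [gb1, gb2, gb3]


class _Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedCombiner:
    """A trained stacking network plus everything needed to reproduce it."""

    network: CombinerNetwork
    config: TrainingConfig
    loss_history: pd.DataFrame  # columns: epoch, train_loss[, val_loss]
    provenance: dict = field(default_factory=dict)

    @property
    def model_order(self) -> tuple[str, ...]:
        return tuple(self.config.model_order)

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "maskstack-combiner-v1",
            "alphabet": "".join(ALPHABET),
            "layer_widths": list(LAYER_WIDTHS),
            "model_order": list(self.config.model_order),
            "config": {
                "epochs": self.config.epochs,
                "learning_rate": self.config.learning_rate,
                "batch_size": self.config.batch_size,
                "validation_fraction": self.config.validation_fraction,
                "seed": self.config.seed,
            },
            "weights": [w.tolist() for w in self.network.weights],
            "biases": [b.tolist() for b in self.network.biases],
            "loss_history": self.loss_history.to_dict(orient="list"),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedCombiner":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "maskstack-combiner-v1":
            raise ValidationError(f"{path}: not a combiner file")
        if payload["alphabet"] != "".join(ALPHABET):
            raise ValidationError(f"{path}: alphabet mismatch")
        cfg = TrainingConfig(model_order=tuple(payload["model_order"]), **payload["config"])
        net = CombinerNetwork(
            weights=[np.array(w) for w in payload["weights"]],
            biases=[np.array(b) for b in payload["biases"]],
        )
        return cls(
            network=net,
            config=cfg,
            loss_history=pd.DataFrame(payload["loss_history"]),
            provenance=payload.get("provenance", {}),
        )


def _data_fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train_combiner(
    predictions: pd.DataFrame,
    config: TrainingConfig = TrainingConfig(),
) -> TrainedCombiner:
    """Train the stacking network on a long prediction table.

    Every training site must carry all four models' vectors and a canonical
    wildtype.  A protein-level fraction of the data is held out purely to
    monitor validation loss (site-level splits would leak protein identity).
    Training runs exactly ``config.epochs`` epochs with per-epoch shuffling;
    there is no early stopping.
    """
    X, y, sites = assemble_feature_matrix(predictions, config.model_order)
    if len(X) == 0:
        raise ValidationError("empty training set")

    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(202,)))

    proteins = sites["protein_id"].to_numpy()
    unique_proteins = np.array(sorted(set(proteins)))
    n_val_prot = int(round(config.validation_fraction * len(unique_proteins)))
    val_proteins = set(
        rng.choice(unique_proteins, size=n_val_prot, replace=False).tolist()
        if n_val_prot
        else []
    )
    val_mask = np.isin(proteins, sorted(val_proteins))
    Xtr, ytr = X[~val_mask], y[~val_mask]
    Xval, yval = X[val_mask], y[val_mask]

    net = CombinerNetwork.initialize(config.seed)
    params = net.weights + net.biases
    opt = _Adam(params, config.learning_rate)

    n = len(Xtr)
    history = []
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            loss, gw, gb = net.gradients(Xtr[idx], ytr[idx])
            opt.step(params, gw + gb)
            epoch_loss += loss
            n_batches += 1
        row = {"epoch": epoch, "train_loss": epoch_loss / n_batches}
        if len(Xval):
            pv = net.forward(Xval)
            row["val_loss"] = float(
                -np.log(np.maximum(pv[np.arange(len(yval)), yval], 1e-12)).mean()
            )
        history.append(row)

    return TrainedCombiner(
        network=net,
        config=config,
        loss_history=pd.DataFrame(history),
        provenance={
            "n_sites": int(len(X)),
            "n_proteins": int(len(unique_proteins)),
            "n_validation_proteins": int(len(val_proteins)),
            "data_fingerprint": _data_fingerprint(X, y),
        },
    )


def predict_combined(model: TrainedCombiner | CombinerNetwork, features: np.ndarray) -> np.ndarray:
    """Softmax output of the combiner for length-80 features.

    Accepts one feature vector or a matrix of them; output rows are valid
    probability vectors (softmax normalizes by construction).
    """
    net = model.network if isinstance(model, TrainedCombiner) else model
    arr = np.asarray(features, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if arr.shape[1] != LAYER_WIDTHS[0]:
        raise ValidationError(
            f"expected {LAYER_WIDTHS[0]} features, got {arr.shape[1]}"
        )
    out = net.forward(arr)
    return out[0] if single else out


# --------------------------------------------------------------------------
# naive ensemble baselines


def baseline_mean(vectors: Sequence[np.ndarray | Sequence[float]]) -> np.ndarray:
    """Elementwise arithmetic mean of four probability vectors."""
    if len(vectors) != 4:
        raise ValidationError(f"baseline_mean needs exactly 4 vectors, got {len(vectors)}")
    stacked = np.stack([validate_probability_vector(v) for v in vectors])
    return stacked.mean(axis=0)


def baseline_max(vectors: Sequence[np.ndarray | Sequence[float]]) -> str:
    """Amino acid holding the single highest probability across four models.

    Ties are broken by alphabet order first (which model supplied the
    winning entry does not affect the returned amino acid).
    """
    if len(vectors) != 4:
        raise ValidationError(f"baseline_max needs exactly 4 vectors, got {len(vectors)}")
    stacked = np.stack([validate_probability_vector(v) for v in vectors])
    per_aa_best = stacked.max(axis=0)  # best probability offered for each aa
    return ALPHABET[int(np.argmax(per_aa_best))]


def baseline_predictions(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized mean- and max-ensemble top-1 indices for feature rows.

    ``X`` is the (n, 80) feature matrix; returns ``(mean_top1, max_top1)``
    as alphabet indices (argmax ties resolve to alphabet order, matching
    the scalar baselines).
    """
    cube = X.reshape(len(X), 4, 20)
    mean_top1 = cube.mean(axis=1).argmax(axis=1)
    max_top1 = cube.max(axis=1).argmax(axis=1)
    return mean_top1, max_top1
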