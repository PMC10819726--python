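"""Three-layer sigmoid BP network with genetic-algorithm weight seeding.

The classifier is a classic fully connected input-hidden-output network
with sigmoid activations at both layers and 10 hidden nodes.  Instead of
random initialization, a real-coded genetic algorithm (population 50,
100 generations, crossover 0.5, mutation 0.01, genes in [-1, 1])
searches for initial weights and thresholds that minimize the training
mean squared error; gradient descent then refines them (1000 epochs,
learning rate 0.01, target error 1e-5).

Three input variants mirror the feature-combination experiment:
``raw33`` feeds all 33 fused features, ``pca15`` the retained principal
components, and ``pca15_plus_score`` the components plus the
comprehensive evaluation score as one extra input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import pca as pca_mod
from .audio import CLASS_NAMES, ValidationError
from .features import FEATURE_NAMES
from .metrics import ConfusionMatrix, confusion, report

__all__ = [
    "NetworkParams",
    "GAConfig",
    "TrainConfig",
    "LabeledDataset",
    "ModelBundle",
    "TrainingError",
    "VARIANTS",
    "forward",
    "mse",
    "bp_train",
    "ga_optimize",
    "stratified_split",
    "train_variant",
    "predict",
]

VARIANTS = ("raw33", "pca15", "pca15_plus_score")


class TrainingError(RuntimeError):
    """Raised when gradient training diverges."""


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class NetworkParams:
    """Weights and thresholds of the three-layer sigmoid network."""

    W1: np.ndarray  # n_in x n_hidden
    b1: np.ndarray  # n_hidden
    W2: np.ndarray  # n_hidden x n_out
    b2: np.ndarray  # n_out

    def __post_init__(self) -> None:
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        self.b2 = np.asarray(self.b2, dtype=float)
        n_in, n_hidden = self.W1.shape
        if self.b1.shape != (n_hidden,) or self.W2.shape[0] != n_hidden:
            raise ValidationError("inconsistent hidden-layer dimensions")
        if self.b2.shape != (self.W2.shape[1],):
            raise ValidationError("inconsistent output-layer dimensions")
        for arr in (self.W1, self.b1, self.W2, self.b2):
            if not np.all(np.isfinite(arr)):
                raise ValidationError("network parameters must be finite")

    @property
    def topology(self) -> tuple[int, int, int]:
        return (self.W1.shape[0], self.W1.shape[1], self.W2.shape[1])

    @property
    def n_params(self) -> int:
        n_in, n_hidden, n_out = self.topology
        return n_in * n_hidden + n_hidden + n_hidden * n_out + n_out

    def flatten(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.W2.ravel(), self.b2])

    @classmethod
    def from_flat(cls, genes: np.ndarray, topology: tuple[int, int, int]) -> "NetworkParams":
        n_in, n_hidden, n_out = topology
        sizes = [n_in * n_hidden, n_hidden, n_hidden * n_out, n_out]
        if len(genes) != sum(sizes):
            raise ValidationError(
                f"chromosome length {len(genes)} != parameter count {sum(sizes)}"
            )
        parts = np.split(np.asarray(genes, dtype=float), np.cumsum(sizes)[:-1])
        return cls(
            W1=parts[0].reshape(n_in, n_hidden),
            b1=parts[1],
            W2=parts[2].reshape(n_hidden, n_out),
            b2=parts[3],
        )


@dataclass
class GAConfig:
    """Genetic-algorithm settings for the weight search."""

    population: int = 50
    generations: int = 100
    crossover_prob: float = 0.5
    mutation_prob: float = 0.01
    gene_range: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValidationError("probabilities must lie in [0, 1]")
        if self.population % 2:
            raise ValidationError("population size must be even")


@dataclass
class TrainConfig:
    """Gradient-descent settings for network refinement."""

    max_epochs: int = 1000
    target_error: float = 1e-5
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 0 or self.target_error <= 0 or self.learning_rate < 0:
            raise ValidationError("training settings must be positive")


@dataclass
class LabeledDataset:
    """Network-ready inputs: scaled features and one-hot class targets."""

    X: np.ndarray
    y: np.ndarray  # n x 3 one-hot
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValidationError("X and y row counts differ")
        if self.y.shape[1] > 1 and not np.allclose(self.y.sum(axis=1), 1.0):
            raise ValidationError("multiclass targets must be one-hot rows")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("features must be finite")

    @property
    def class_indices(self) -> np.ndarray:
        return self.y.argmax(axis=1)


def forward(net: NetworkParams, x: np.ndarray) -> np.ndarray:
    """Network outputs: o = sigmoid(sigmoid(x W1 + b1) W2 + b2)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != net.topology[0]:
        raise ValidationError(
            f"input dimension {x.shape[-1]} != network input size {net.topology[0]}"
        )
    hidden = sigmoid(x @ net.W1 + net.b1)
    return sigmoid(hidden @ net.W2 + net.b2)


def mse(net: NetworkParams, data: LabeledDataset) -> float:
    """Mean over samples and output units of squared output error."""
    if data.X.shape[0] == 0:
        raise ValidationError("dataset is empty")
    out = forward(net, data.X)
    return float(np.mean((out - data.y) ** 2))


def bp_train(
    net: NetworkParams, data: LabeledDataset, cfg: TrainConfig
) -> tuple[NetworkParams, np.ndarray]:
    """Incremental (per-pattern) backpropagation on the squared error.

    Each epoch visits every training sample once in a seeded shuffled
    order and applies the delta rule for the sample's squared output
    error (E = 1/2 sum (o - t)^2, so delta_out = (o - t) o (1 - o)).
    The returned history holds the dataset MSE at the end of each
    epoch, starting with the initial parameters' error; training stops
    at ``max_epochs`` or once the error reaches ``target_error``.  The
    parameters of the best epoch are returned, so the final reported
    error never exceeds the initial one.
    """
    rng = np.random.default_rng(cfg.seed)
    W1, b1 = net.W1.copy(), net.b1.copy()
    W2, b2 = net.W2.copy(), net.b2.copy()
    X, y = data.X, data.y
    n = X.shape[0]
    history = [mse(net, data)]
    best_err = history[0]
    best = (W1.copy(), b1.copy(), W2.copy(), b2.copy())
    lr = cfg.learning_rate
    for _ in range(cfg.max_epochs):
        if history[-1] <= cfg.target_error:
            break
        for i in rng.permutation(n):
            x, t = X[i], y[i]
            hidden = sigmoid(x @ W1 + b1)
            out = sigmoid(hidden @ W2 + b2)
            delta_out = (out - t) * out * (1.0 - out)
            delta_hidden = (delta_out @ W2.T) * hidden * (1.0 - hidden)
            W2 -= lr * np.outer(hidden, delta_out)
            b2 -= lr * delta_out
            W1 -= lr * np.outer(x, delta_hidden)
            b1 -= lr * delta_hidden
        err = float(np.mean((sigmoid(sigmoid(X @ W1 + b1) @ W2 + b2) - y) ** 2))
        if not np.isfinite(err):
            raise TrainingError("gradient training diverged (non-finite error)")
        history.append(err)
        if err < best_err:
            best_err = err
            best = (W1.copy(), b1.copy(), W2.copy(), b2.copy())
    trained = NetworkParams(W1=best[0], b1=best[1], W2=best[2], b2=best[3])
    return trained, np.asarray(history)


def ga_optimize(
    topology: tuple[int, int, int],
    data: LabeledDataset,
    cfg: GAConfig,
    return_history: bool = False,
):
    """Search for initial weights/thresholds with a real-coded GA.

    Fitness is 1/(1 + training MSE).  Each generation applies
    roulette-wheel selection, arithmetic blend crossover with
    probability ``crossover_prob`` per pair, per-gene uniform mutation
    within ``gene_range`` with probability ``mutation_prob``, and elitism
    (the single best individual survives unchanged), so the best fitness
    never decreases.
    """
    rng = np.random.default_rng(cfg.seed)
    n_genes = NetworkParams.from_flat(
        np.zeros(
            topology[0] * topology[1]
            + topology[1]
            + topology[1] * topology[2]
            + topology[2]
        ),
        topology,
    ).n_params
    lo, hi = cfg.gene_range
    pop = rng.uniform(lo, hi, size=(cfg.population, n_genes))

    def fitness_of(genes: np.ndarray) -> float:
        return 1.0 / (1.0 + mse(NetworkParams.from_flat(genes, topology), data))

    fitness = np.array([fitness_of(ind) for ind in pop])
    best_history = [fitness.max()]

    for _ in range(cfg.generations):
        elite = pop[fitness.argmax()].copy()
        # roulette-wheel selection proportional to fitness
        probs = fitness / fitness.sum()
        chosen = rng.choice(cfg.population, size=cfg.population, p=probs)
        pop = pop[chosen].copy()
        # arithmetic blend crossover on consecutive pairs
        for i in range(0, cfg.population - 1, 2):
            if rng.random() < cfg.crossover_prob:
                u = rng.random()
                p1, p2 = pop[i].copy(), pop[i + 1].copy()
                pop[i] = u * p1 + (1.0 - u) * p2
                pop[i + 1] = u * p2 + (1.0 - u) * p1
        # uniform per-gene mutation
        mask = rng.random(pop.shape) < cfg.mutation_prob
        pop[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
        fitness = np.array([fitness_of(ind) for ind in pop])
        # elitism: the previous best replaces the current worst
        worst = fitness.argmin()
        if fitness_of(elite) > fitness[worst]:
            pop[worst] = elite
            fitness[worst] = fitness_of(elite)
        best_history.append(fitness.max())

    best = NetworkParams.from_flat(pop[fitness.argmax()], topology)
    if return_history:
        return best, np.asarray(best_history)
    return best


def stratified_split(
    labels: np.ndarray, train_frac: float = 0.7, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class seeded shuffle into train/validation index arrays.

    Each class contributes round((1 - train_frac) * n_c) rows to the
    validation set; the split is disjoint and exhaustive.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in CLASS_NAMES:
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValidationError(f"class {cls!r} needs at least 2 samples to split")
        rng.shuffle(idx)
        n_val = int(np.floor((1.0 - train_frac) * idx.size + 0.5))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def one_hot(labels: np.ndarray) -> np.ndarray:
    index = {c: i for i, c in enumerate(CLASS_NAMES)}
    try:
        rows = [index[l] for l in labels]
    except KeyError as exc:
        raise ValidationError(f"unknown class label {exc.args[0]!r}") from None
    y = np.zeros((len(rows), len(CLASS_NAMES)))
    y[np.arange(len(rows)), rows] = 1.0
    return y


@dataclass
class MinMaxScaler:
    """Per-feature linear map of the training range onto [0, 1]."""

    data_min: np.ndarray
    data_range: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        lo, hi = X.min(axis=0), X.max(axis=0)
        rng = hi - lo
        rng[rng == 0] = 1.0
        return cls(data_min=lo, data_range=rng)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.data_min) / self.data_range


@dataclass
class ModelBundle:
    """A trained variant: network, scalers, optional PCA model, and report."""

    variant: str
    net: NetworkParams
    scaler: MinMaxScaler
    pca_model: pca_mod.PCAModel | None
    seed: int
    validation_cm: ConfusionMatrix
    validation_report: dict
    predictions: pd.DataFrame
    ga_history: np.ndarray | None = None
    bp_history: np.ndarray | None = None

    def save(self, path: str | Path) -> None:
        d = {
            "variant": self.variant,
            "seed": int(self.seed),
            "network": {
                "W1": self.net.W1.tolist(),
                "b1": self.net.b1.tolist(),
                "W2": self.net.W2.tolist(),
                "b2": self.net.b2.tolist(),
            },
            "scaler": {
                "data_min": self.scaler.data_min.tolist(),
                "data_range": self.scaler.data_range.tolist(),
            },
            "pca": None if self.pca_model is None else self.pca_model.to_dict(),
            "validation_report": self.validation_report,
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        d = json.loads(Path(path).read_text())
        net = NetworkParams(
            W1=np.asarray(d["network"]["W1"]),
            b1=np.asarray(d["network"]["b1"]),
            W2=np.asarray(d["network"]["W2"]),
            b2=np.asarray(d["network"]["b2"]),
        )
        cm = ConfusionMatrix(np.asarray(d["validation_report"]["confusion"], dtype=int))
        return cls(
            variant=d["variant"],
            net=net,
            scaler=MinMaxScaler(
                data_min=np.asarray(d["scaler"]["data_min"]),
                data_range=np.asarray(d["scaler"]["data_range"]),
            ),
            pca_model=None if d["pca"] is None else pca_mod.PCAModel.from_dict(d["pca"]),
            seed=d["seed"],
            validation_cm=cm,
            validation_report=d["validation_report"],
            predictions=pd.DataFrame(),
        )


def _variant_inputs(
    variant: str,
    X_train: np.ndarray,
    X_val: np.ndarray,
    threshold: float,
    feature_names=None,
) -> tuple[np.ndarray, np.ndarray, pca_mod.PCAModel | None]:
    """Map raw 33-D rows to the variant's network inputs (train-fit only)."""
    if variant == "raw33":
        return X_train, X_val, None
    model, scored_train = pca_mod.fit_transform(
        pca_mod.FeatureMatrix(X_train, feature_names=feature_names), threshold
    )
    scored_val = model.transform(X_val)
    if variant == "pca15":
        return scored_train.F, scored_val.F, model
    if variant == "pca15_plus_score":
        tr = np.column_stack([scored_train.F, scored_train.f_comprehensive])
        va = np.column_stack([scored_val.F, scored_val.f_comprehensive])
        return tr, va, model
    raise ValidationError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def train_variant(
    features: pd.DataFrame,
    variant: str,
    ga_cfg: GAConfig | None = None,
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
    pca_threshold: float = 0.85,
    train_frac: float = 0.7,
) -> ModelBundle:
    """Run the full experiment for one input variant.

    Splits the feature table 70/30 per class, fits any PCA transform and
    the min-max input scaler on the training rows only, seeds the
    network with the GA, refines with gradient descent, and reports the
    validation confusion matrix and derived metrics.
    """
    ga_cfg = ga_cfg or GAConfig(seed=seed)
    train_cfg = train_cfg or TrainConfig(seed=seed)
    X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    labels = features["label"].to_numpy()
    ids = features["id"].to_numpy()

    train_idx, val_idx = stratified_split(labels, train_frac=train_frac, seed=seed)
    X_train_in, X_val_in, pca_model = _variant_inputs(
        variant, X[train_idx], X[val_idx], pca_threshold, list(FEATURE_NAMES)
    )
    scaler = MinMaxScaler.fit(X_train_in)
    train = LabeledDataset(
        X=scaler.transform(X_train_in), y=one_hot(labels[train_idx]), ids=ids[train_idx]
    )
    val = LabeledDataset(
        X=scaler.transform(X_val_in), y=one_hot(labels[val_idx]), ids=ids[val_idx]
    )

    topology = (train.X.shape[1], 10, len(CLASS_NAMES))
    seeded_net, ga_history = ga_optimize(topology, train, ga_cfg, return_history=True)
    net, bp_history = bp_train(seeded_net, train, train_cfg)

    val_pred_idx = forward(net, val.X).argmax(axis=1)
    predicted = np.array([CLASS_NAMES[i] for i in val_pred_idx])
    cm = confusion(labels[val_idx], predicted)
    bundle = ModelBundle(
        variant=variant,
        net=net,
        scaler=scaler,
        pca_model=pca_model,
        seed=seed,
        validation_cm=cm,
        validation_report=report(cm, variant=variant),
        predictions=pd.DataFrame(
            {"id": ids[val_idx], "true_label": labels[val_idx], "predicted_label": predicted}
        ),
        ga_history=ga_history,
        bp_history=bp_history,
    )
    return bundle


def predict(bundle: ModelBundle, features: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Predict class labels for raw 33-D feature rows.

    Applies the bundle's stored transforms (PCA scoring for the pca
    variants, then min-max scaling) and takes the argmax of the three
    output activations; ties break toward the lowest class index.
    """
    if isinstance(features, pd.DataFrame):
        X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != len(FEATURE_NAMES):
        raise ValidationError(f"expected {len(FEATURE_NAMES)}-D raw feature rows")
    if bundle.pca_model is not None:
        scored = bundle.pca_model.transform(X)
        if bundle.variant == "pca15_plus_score":
            X = np.column_stack([scored.F, scored.f_comprehensive])
        else:
            X = scored.F
    out = forward(bundle.net, bundle.scaler.transform(X))
    return np.array([CLASS_NAMES[i] for i in out.argmax(axis=1)])
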