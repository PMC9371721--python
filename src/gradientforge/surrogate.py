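"""MLP surrogate of the gradient simulator.

A multilayer perceptron maps the four condition inputs (E_appl, P, D, L) to
the 20-point laterally averaged concentration profile.  Two networks are
maintained in practice: one per species (O2 profiles on Pt, H2O2 profiles on
Au), each trained on its own simulated dataset.

Protocol: a random 20% of the data is held out first for final evaluation;
the remainder is split 65%/15% (of the whole) into training and per-epoch
validation.  Accuracy is reported as the per-profile mean-squared error
(MSE, mM^2) averaged over the 20 points, its dataset average (AMSE), the
population standard deviation of per-profile MSEs (SD), and the pooled
coefficient of determination R^2.

The network is a compact fully connected ReLU net trained with Adam under a
cosine learning-rate schedule (annealing the step size is what lets the fit
converge tightly instead of dithering around the optimum).  Training is a
self-contained numpy implementation: it keeps the epoch semantics exact,
makes runs bit-reproducible under a fixed seed, and lets saved models
reproduce their predictions exactly after a save/load round trip.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import DEFAULT_RANGES, GradientDataset
from .geometry import Morphology
from .physchem import PhysicalConstants
from .solver import PROFILE_Z_UM, GradientProfile

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "SurrogateModel",
    "EvalReport",
    "split_dataset",
    "train",
    "predict_profile",
    "evaluate",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (of the whole dataset) and split seed."""

    train: float = 0.65
    val: float = 0.15
    test: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass(frozen=True)
class TrainConfig:
    """MLP architecture and optimization settings.

    The default 10 epochs mirror the reference training protocol; the epoch
    count is a default, not a cap -- extend it until the validation AMSE
    plateaus when chasing production accuracy.
    """

    hidden_layers: tuple[int, ...] = (64, 64)
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    lr_schedule: str = "cosine"  # "cosine" anneals to 0 over the epochs
    seed: int = 0


@dataclass
class SurrogateModel:
    """Trained MLP plus the input/output normalization it was fitted with."""

    species: str
    x_mean: np.ndarray
    x_std: np.ndarray
    y_lo: float  # global min-max output scaling (from the train split)
    y_hi: float
    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    config: TrainConfig
    training_log: pd.DataFrame = field(default_factory=pd.DataFrame)
    input_ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    c_max_mM: float = PhysicalConstants().C_O2_bulk

    def predict_batch(self, X: np.ndarray, warn_out_of_range: bool = True) -> np.ndarray:
        """Predict (N, 20) profiles in mM from (N, 4) raw inputs, clipped to bounds."""
        X = np.atleast_2d(np.asarray(X, float))
        if warn_out_of_range:
            lo = np.array([self.input_ranges[k][0] for k in ("E_appl", "P", "D", "L")])
            hi = np.array([self.input_ranges[k][1] for k in ("E_appl", "P", "D", "L")])
            if ((X < lo) | (X > hi)).any():
                warnings.warn(
                    "surrogate inputs outside the training ranges; predictions "
                    "are extrapolations", stacklevel=2,
                )
        h = (X - self.x_mean) / self.x_std
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        y = h @ self.coefs[-1] + self.intercepts[-1]
        y = y * (self.y_hi - self.y_lo) + self.y_lo
        hi_clip = self.c_max_mM if self.species == "O2" else np.inf
        return np.clip(y, 0.0, hi_clip)

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, (W, b) in enumerate(zip(self.coefs, self.intercepts)):
            arrays[f"W{i}"], arrays[f"b{i}"] = W, b
        np.savez(d / "weights.npz", **arrays)
        scaler = {
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_lo": self.y_lo,
            "y_hi": self.y_hi,
            "c_max_mM": self.c_max_mM,
        }
        (d / "scaler.json").write_text(json.dumps(scaler, indent=2))
        cfg = {
            "species": self.species,
            "hidden_layers": list(self.config.hidden_layers),
            "epochs": self.config.epochs,
            "batch_size": self.config.batch_size,
            "learning_rate": self.config.learning_rate,
            "seed": self.config.seed,
            "input_ranges": {k: list(v) for k, v in self.input_ranges.items()},
        }
        (d / "config.json").write_text(json.dumps(cfg, indent=2))
        self.training_log.to_csv(d / "training_log.csv", index=False)

    @classmethod
    def load(cls, directory) -> "SurrogateModel":
        d = Path(directory)
        npz = np.load(d / "weights.npz")
        n_layers = len(npz.files) // 2
        coefs = [npz[f"W{i}"] for i in range(n_layers)]
        intercepts = [npz[f"b{i}"] for i in range(n_layers)]
        scaler = json.loads((d / "scaler.json").read_text())
        cfg = json.loads((d / "config.json").read_text())
        return cls(
            species=cfg["species"],
            x_mean=np.asarray(scaler["x_mean"]),
            x_std=np.asarray(scaler["x_std"]),
            y_lo=scaler["y_lo"],
            y_hi=scaler["y_hi"],
            coefs=coefs,
            intercepts=intercepts,
            config=TrainConfig(
                hidden_layers=tuple(cfg["hidden_layers"]),
                epochs=cfg["epochs"],
                batch_size=cfg["batch_size"],
                learning_rate=cfg["learning_rate"],
                seed=cfg["seed"],
            ),
            training_log=pd.read_csv(d / "training_log.csv"),
            input_ranges={k: tuple(v) for k, v in cfg["input_ranges"].items()},
            c_max_mM=scaler["c_max_mM"],
        )


@dataclass
class EvalReport:
    """Accuracy summary on a dataset: per-row MSE, AMSE, SD (mM^2) and pooled R^2."""

    row_mse: np.ndarray
    amse: float
    sd: float
    r2: float


def split_dataset(
    ds: GradientDataset, spec: SplitSpec | None = None
) -> tuple[GradientDataset, GradientDataset, GradientDataset]:
    """Disjoint, exhaustive (train, val, test) partition; test drawn first.

    Sizes are round(fraction * N) for test and val, remainder to train.
    """
    spec = spec or SplitSpec()
    n = len(ds)
    if n < 20:
        raise ValueError("dataset must have at least 20 rows to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_test = round(spec.test * n)
    n_val = round(spec.val * n)
    test_idx = np.sort(perm[:n_test])
    val_idx = np.sort(perm[n_test : n_test + n_val])
    train_idx = np.sort(perm[n_test + n_val :])
    return ds.subset(train_idx), ds.subset(val_idx), ds.subset(test_idx)


def _amse(model: SurrogateModel, X: np.ndarray, Y: np.ndarray) -> float:
    pred = model.predict_batch(X, warn_out_of_range=False)
    return float(np.mean((pred - Y) ** 2))


def _init_layers(sizes: tuple[int, ...], rng: np.random.Generator):
    """Glorot-uniform weights, zero biases."""
    coefs, intercepts = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        coefs.append(rng.uniform(-bound, bound, (fan_in, fan_out)))
        intercepts.append(np.zeros(fan_out))
    return coefs, intercepts


class _Adam:
    """Adam with bias correction; one shared step counter for all parameters."""

    def __init__(self, params: list[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / (1 - b1**self.t)) / (np.sqrt(v / (1 - b2**self.t)) + self.eps)


def train(
    train_ds: GradientDataset,
    val_ds: GradientDataset,
    config: TrainConfig | None = None,
) -> SurrogateModel:
    """Fit the MLP surrogate, logging train/val AMSE per epoch.

    Inputs are standardized and outputs min-max scaled with statistics from
    the training split only.  Fully deterministic under a fixed seed.
    """
    config = config or TrainConfig()
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("train and validation datasets must be non-empty")
    X, Y = train_ds.X, train_ds.Y
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0)
    x_std[x_std < 1e-12] = 1.0
    y_lo, y_hi = float(Y.min()), float(Y.max())
    if y_hi - y_lo < 1e-12:
        y_hi = y_lo + 1.0  # constant-target degenerate case
    Xs = (X - x_mean) / x_std
    Ys = (Y - y_lo) / (y_hi - y_lo)

    rng = np.random.default_rng(config.seed)
    sizes = (X.shape[1], *config.hidden_layers, Y.shape[1])
    coefs, intercepts = _init_layers(sizes, rng)
    params = coefs + intercepts
    optimizer = _Adam(params)
    n, n_out = len(Xs), Y.shape[1]
    batch = min(config.batch_size, n)

    model = SurrogateModel(
        species=train_ds.species,
        x_mean=x_mean, x_std=x_std, y_lo=y_lo, y_hi=y_hi,
        coefs=coefs, intercepts=intercepts, config=config,
    )
    logrows = []
    n_layers = len(coefs)
    for epoch in range(1, config.epochs + 1):
        if config.lr_schedule == "cosine":
            lr = config.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * (epoch - 1) / config.epochs))
        else:
            lr = config.learning_rate
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            # forward pass, keeping hidden activations for backprop
            acts = [Xs[idx]]
            h = acts[0]
            for W, b in zip(coefs[:-1], intercepts[:-1]):
                h = np.maximum(h @ W + b, 0.0)
                acts.append(h)
            out = h @ coefs[-1] + intercepts[-1]
            err = out - Ys[idx]
            epoch_loss += float(np.sum(err**2))
            # backward pass of the mean-squared loss
            delta = 2.0 * err / (len(idx) * n_out)
            g_coefs = [None] * n_layers
            g_inter = [None] * n_layers
            for li in range(n_layers - 1, -1, -1):
                g_coefs[li] = acts[li].T @ delta
                g_inter[li] = delta.sum(axis=0)
                if li > 0:
                    delta = (delta @ coefs[li].T) * (acts[li] > 0)
            optimizer.step(params, g_coefs + g_inter, lr)
        if not np.isfinite(epoch_loss):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: loss={epoch_loss} "
                f"(lr={config.learning_rate}, batch={config.batch_size})"
            )
        logrows.append({
            "epoch": epoch,
            "train_amse_mM2": _amse(model, X, Y),
            "val_amse_mM2": _amse(model, val_ds.X, val_ds.Y),
        })
    model.training_log = pd.DataFrame(logrows)
    first, last = logrows[0]["val_amse_mM2"], logrows[-1]["val_amse_mM2"]
    if last > first:
        log.warning(
            "validation AMSE did not improve over training "
            "(epoch 1: %.3e, final: %.3e mM^2)", first, last,
        )
    return model


def predict_profile(model: SurrogateModel, E_appl: float, morph: Morphology) -> GradientProfile:
    """Predict one 20-point gradient profile (mM), clipped to physical bounds."""
    y = model.predict_batch([[E_appl, morph.P, morph.D, morph.L]])[0]
    return GradientProfile(species=model.species, z_um=PROFILE_Z_UM.copy(), c_mM=y)


def evaluate(model: SurrogateModel, test_ds: GradientDataset) -> EvalReport:
    """Score the surrogate: row MSEs over 20 points, AMSE, SD, pooled R^2."""
    if len(test_ds) == 0:
        raise ValueError("test dataset must be non-empty")
    Y = test_ds.Y
    pred = model.predict_batch(test_ds.X, warn_out_of_range=False)
    row_mse = np.mean((pred - Y) ** 2, axis=1)
    amse = float(row_mse.mean())
    sd = float(np.sqrt(np.mean((row_mse - amse) ** 2)))
    ss_res = float(np.sum((pred - Y) ** 2))
    ss_tot = float(np.sum((Y - Y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float(ss_res == 0.0)
    return EvalReport(row_mse=row_mse, amse=amse, sd=sd, r2=r2)
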