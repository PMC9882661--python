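"""Label-budget construction and model optimization.

Two labeling protocols, both built on BP-value binning so that the few
supervised labels cover the whole pressure range rather than clustering
at the resting baseline:

* the *minimal training criterion*: tile [min(BP), max(BP)] with 1-mmHg
  bins (K = ceil(range) bins) and draw exactly one labeled beat per
  non-empty bin — e.g. 1000 beats spanning 120–160 mmHg yield a 40-beat
  training set and a 960-beat test set;
* the *growing-set protocol*: draw one point per non-empty 0.5-mmHg bin
  into a pool of k points, then emit nested training sets of sizes
  1, 3, 5, … (ceil(k/2) splits; each adds two pool points), used to study
  how the learned input–output map stabilizes with the label budget.

Training minimizes ``L_conv + λ·L_phys`` with full-batch Adam and stops
when the supervised loss reaches 0.01 on the standardized scale (the
λ = 0 run is the conventional CNN baseline under the exact same data,
split, seed, and stopping rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DegenerateRangeError, TrainingDivergedError
from .pinn_core import (
    LossBundle,
    ModelConfig,
    ModelParams,
    init_params,
    loss_and_param_grads,
    total_loss,
)
from .signal_features import BeatDataset

__all__ = [
    "SplitSpec",
    "TrainReport",
    "minimal_split",
    "growing_sets",
    "train",
]


@dataclass(frozen=True)
class SplitSpec:
    """A labeled/unlabeled partition of the beats of one dataset."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    bin_width: float
    n_bins: int
    seed: int

    def __post_init__(self):
        tr = np.asarray(self.train_idx, dtype=int)
        te = np.asarray(self.test_idx, dtype=int)
        object.__setattr__(self, "train_idx", tr)
        object.__setattr__(self, "test_idx", te)
        if np.intersect1d(tr, te).size:
            raise ConfigError("train and test indices overlap")

    @property
    def n_labeled(self) -> int:
        return int(self.train_idx.size)


def _bin_indices(labels: np.ndarray, bin_width: float) -> tuple[np.ndarray, int]:
    """Assign each label to a bin tiling [min, max]; K = ceil(range/width)."""
    labels = np.asarray(labels, dtype=float)
    if labels.size == 0 or not np.all(np.isfinite(labels)):
        raise DegenerateRangeError("labels must be a non-empty finite vector")
    lo, hi = float(labels.min()), float(labels.max())
    if hi <= lo:
        raise DegenerateRangeError(f"constant labels ({lo} mmHg): nothing to bin")
    K = int(math.ceil((hi - lo) / bin_width - 1e-9))
    which = np.minimum((labels - lo) // bin_width, K - 1).astype(int)
    return which, K


def minimal_split(
    labels: np.ndarray, bin_width: float = 1.0, seed: int = 0
) -> SplitSpec:
    """One uniformly drawn labeled beat per non-empty ``bin_width``-mmHg bin.

    Bins are anchored at min(labels) and the final bin is closed on the
    right; empty bins contribute no training point. All remaining beats
    form the test set.
    """
    which, K = _bin_indices(labels, bin_width)
    rng = np.random.default_rng(seed)
    train = []
    for b in range(K):
        members = np.flatnonzero(which == b)
        if members.size:
            train.append(int(rng.choice(members)))
    train = np.sort(np.array(train, dtype=int))
    test = np.setdiff1d(np.arange(len(which)), train)
    return SplitSpec(
        train_idx=train, test_idx=test, bin_width=bin_width, n_bins=K, seed=seed
    )


def growing_sets(
    labels: np.ndarray, bin_width: float = 0.5, seed: int = 0
) -> list[SplitSpec]:
    """Nested splits of sizes 1, 3, 5, … drawn from one fixed binned pool.

    The pool holds one seeded draw per non-empty ``bin_width``-mmHg bin
    (k points); the N-th split trains on the first 2N−1 points of a fixed
    random ordering of that pool, so ceil(k/2) splits are emitted and each
    training set contains the previous one plus two new pool points.
    """
    which, K = _bin_indices(labels, bin_width)
    rng = np.random.default_rng(seed)
    pool = []
    for b in range(K):
        members = np.flatnonzero(which == b)
        if members.size:
            pool.append(int(rng.choice(members)))
    pool = np.array(pool, dtype=int)
    pool = pool[rng.permutation(pool.size)]  # fixed growth order
    all_idx = np.arange(len(which))
    splits = []
    for n in range(1, pool.size + 1, 2):
        train = np.sort(pool[:n])
        splits.append(
            SplitSpec(
                train_idx=train,
                test_idx=np.setdiff1d(all_idx, train),
                bin_width=bin_width,
                n_bins=K,
                seed=seed,
            )
        )
    return splits


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

@dataclass
class TrainReport:
    """Outcome of one training run."""

    epochs_run: int
    converged: bool
    final: LossBundle
    seed: int
    lambda_phys: float
    stop_loss: float
    history: np.ndarray = field(repr=False, default=None)  # (epochs, 3) loss rows

    def history_columns(self) -> tuple[str, ...]:
        return ("L_conv", "L_phys", "L_total")


def train(
    ds: BeatDataset,
    split: SplitSpec,
    cfg: ModelConfig | None = None,
    lambda_phys: float = 1.0,
    stop_loss: float = 0.01,
    max_epochs: int = 20000,
    learning_rate: float = 1e-3,
    seed: int = 0,
) -> tuple[ModelParams, TrainReport]:
    """Full-batch Adam on ``L_conv + λ·L_phys`` with supervised-loss stopping.

    The run is declared converged as soon as the supervised loss (on the
    standardized scale) reaches ``stop_loss`` — checked before each
    update, so a lucky initialization returns at epoch 0. Hitting
    ``max_epochs`` first is flagged, not raised; a non-finite loss raises
    :class:`TrainingDivergedError` with the epoch index. Identical seeds
    give identical parameter trajectories.
    """
    if not ds.standardized:
        raise ConfigError("train expects a standardized dataset")
    if cfg is None:
        cfg = ModelConfig(input_len=ds.n_samples)
    if cfg.input_len != ds.n_samples:
        raise ConfigError(
            f"model input_len {cfg.input_len} != waveform length {ds.n_samples}"
        )
    params = init_params(cfg, np.random.default_rng(seed))

    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m = {k: np.zeros_like(v) for k, v in params.values.items()}
    s = {k: np.zeros_like(v) for k, v in params.values.items()}

    history = []
    converged = False
    epochs_run = 0
    for epoch in range(max_epochs):
        bundle, grads = loss_and_param_grads(ds, split, params, lambda_phys)
        history.append((bundle.L_conv, bundle.L_phys, bundle.L_total))
        if not np.isfinite(bundle.L_total):
            raise TrainingDivergedError(
                f"non-finite loss at epoch {epoch}", epoch=epoch
            )
        if bundle.L_conv <= stop_loss:
            converged = True
            epochs_run = epoch
            break
        t = epoch + 1
        corr = np.sqrt(1.0 - beta2**t) / (1.0 - beta1**t)
        for k, g in grads.items():
            m[k] = beta1 * m[k] + (1.0 - beta1) * g
            s[k] = beta2 * s[k] + (1.0 - beta2) * g * g
            params.values[k] = params.values[k] - learning_rate * corr * m[k] / (
                np.sqrt(s[k]) + eps
            )
        epochs_run = epoch + 1

    final = total_loss(ds, split, params, lambda_phys)
    report = TrainReport(
        epochs_run=epochs_run,
        converged=converged,
        final=final,
        seed=seed,
        lambda_phys=lambda_phys,
        stop_loss=stop_loss,
        history=np.array(history) if history else np.empty((0, 3)),
    )
    return params, report
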