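"""Network, feature gradients, Taylor residuals, and the composite loss.

The regression model maps a beat's waveform ``x`` (length-N, standardized)
and its feature vector ``u`` (M=3) to a standardized BP estimate
``y_NN = f_NN(x, u, Θ)``. Architecture: two 1-D convolutions (32 filters
of width 5, then 64 of width 3, ReLU), max-pooling (width 3, stride 1),
flattening, concatenation with ``u``, a 60-unit ReLU layer, and a single
linear output.

The physics-informed part is a first-order Taylor expansion of ``f_NN``
in the features, anchored at beat ``i`` and evaluated at beat ``i+1``:

    P_i(u) = f_NN(x_i, u_i, Θ) + Σ_k ∂f_NN/∂u^k |_i · (u^k − u_i^k)

The residual ``h_i = f_NN(x_{i+1}, u_{i+1}, Θ) − P_i(u_{i+1})`` vanishes
as consecutive beats coincide; its mean square over all within-session
consecutive pairs is the unsupervised physics loss, added to the ordinary
MSE over the labeled subset:

    L_total = L_conventional + λ · L_physics        (λ = 1 by default)

Everything here is plain NumPy. Backpropagation — including the mixed
second-order terms ∂²f/∂u∂Θ that the physics loss needs for weight
optimization — is written out by hand with the usual ReLU almost-
everywhere convention (activation masks are locally constant, so the
second derivative of ReLU is zero). Because ``u`` enters only at the
concatenation, ∂f/∂u flows through the fully connected head alone, which
keeps those terms cheap and exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import (
    ConfigError,
    InsufficientSequenceError,
    NoLabelsError,
)
from .signal_features import BeatDataset

__all__ = [
    "ModelConfig",
    "ModelParams",
    "LossBundle",
    "init_params",
    "forward",
    "feature_gradients",
    "taylor_evaluate",
    "residuals",
    "physics_loss",
    "supervised_loss",
    "total_loss",
    "loss_and_param_grads",
]


# ---------------------------------------------------------------------------
# configuration and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Layer hyperparameters of the beat-to-BP network."""

    input_len: int = 60
    n_features: int = 3
    conv1_filters: int = 32
    conv1_kernel: int = 5
    conv2_filters: int = 64
    conv2_kernel: int = 3
    pool_size: int = 3
    pool_stride: int = 1
    fc1_units: int = 60
    dtype: str = "float64"

    def __post_init__(self):
        sizes = (
            self.input_len, self.n_features, self.conv1_filters,
            self.conv1_kernel, self.conv2_filters, self.conv2_kernel,
            self.pool_size, self.pool_stride, self.fc1_units,
        )
        if any(s <= 0 for s in sizes):
            raise ConfigError(f"all layer sizes must be positive, got {self}")
        if self.pool_len < 1:
            raise ConfigError("input_len too short for the convolution stack")

    @property
    def conv1_len(self) -> int:
        return self.input_len - self.conv1_kernel + 1

    @property
    def conv2_len(self) -> int:
        return self.conv1_len - self.conv2_kernel + 1

    @property
    def pool_len(self) -> int:
        return (self.conv2_len - self.pool_size) // self.pool_stride + 1

    @property
    def flat_len(self) -> int:
        return self.pool_len * self.conv2_filters

    @property
    def concat_len(self) -> int:
        return self.flat_len + self.n_features


@dataclass
class ModelParams:
    """The trainable weights Θ, keyed by layer.

    Shapes: ``Wc1 (k1, c1)``, ``Wc2 (k2, c1, c2)``, ``W1 (fc1, flat+M)``,
    ``w2 (fc1,)``; biases match their layer widths, ``b2`` is scalar.
    """

    config: ModelConfig
    values: dict[str, np.ndarray] = field(default_factory=dict)

    KEYS = ("Wc1", "bc1", "Wc2", "bc2", "W1", "b1", "w2", "b2")

    def __getitem__(self, key: str) -> np.ndarray:
        return self.values[key]

    def copy(self) -> "ModelParams":
        return ModelParams(self.config, {k: v.copy() for k, v in self.values.items()})

    def ravel(self) -> np.ndarray:
        return np.concatenate([self.values[k].ravel() for k in self.KEYS])

    def with_ravel(self, flat: np.ndarray) -> "ModelParams":
        out, pos = {}, 0
        for k in self.KEYS:
            v = self.values[k]
            out[k] = flat[pos : pos + v.size].reshape(v.shape).astype(v.dtype)
            pos += v.size
        return ModelParams(self.config, out)


def init_params(cfg: ModelConfig, seed: int | np.random.Generator = 0) -> ModelParams:
    """He-initialized weights; biases zero. Deterministic given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = np.dtype(cfg.dtype)

    def he(shape, fan_in):
        return (rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)).astype(dt)

    vals = {
        "Wc1": he((cfg.conv1_kernel, cfg.conv1_filters), cfg.conv1_kernel),
        "bc1": np.zeros(cfg.conv1_filters, dtype=dt),
        "Wc2": he(
            (cfg.conv2_kernel, cfg.conv1_filters, cfg.conv2_filters),
            cfg.conv2_kernel * cfg.conv1_filters,
        ),
        "bc2": np.zeros(cfg.conv2_filters, dtype=dt),
        "W1": he((cfg.fc1_units, cfg.concat_len), cfg.concat_len),
        "b1": np.zeros(cfg.fc1_units, dtype=dt),
        "w2": he((cfg.fc1_units,), cfg.fc1_units),
        "b2": np.zeros((), dtype=dt),
    }
    return ModelParams(cfg, vals)


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def _as_batch(x: np.ndarray, u: np.ndarray, cfg: ModelConfig):
    x = np.asarray(x, dtype=cfg.dtype)
    u = np.asarray(u, dtype=cfg.dtype)
    single = x.ndim == 1
    if single:
        x, u = x[None, :], u[None, :]
    if x.ndim != 2 or x.shape[1] != cfg.input_len:
        raise ConfigError(
            f"waveform batch must be (B, {cfg.input_len}), got {x.shape}"
        )
    if u.shape != (x.shape[0], cfg.n_features):
        raise ConfigError(
            f"feature batch must be ({x.shape[0]}, {cfg.n_features}), got {u.shape}"
        )
    return x, u, single


def _maxpool(a: np.ndarray, size: int, stride: int, out_len: int):
    """Window-max along axis 1 with first-max argmax semantics.

    Implemented as an offset loop over contiguous slices — much faster
    than argmax over a strided sliding window.
    """
    best = a[:, : out_len * stride : stride].copy()
    idx = np.zeros(best.shape, dtype=np.int8)
    for o in range(1, size):
        cand = a[:, o : o + out_len * stride : stride]
        better = cand > best
        np.copyto(best, cand, where=better)
        idx[better] = o
    return best, idx


def _maxpool_backward(
    dpooled: np.ndarray, idx: np.ndarray, in_len: int, size: int, stride: int
) -> np.ndarray:
    da = np.zeros((dpooled.shape[0], in_len, dpooled.shape[2]), dtype=dpooled.dtype)
    out_len = dpooled.shape[1]
    for o in range(size):
        da[:, o : o + out_len * stride : stride] += np.where(idx == o, dpooled, 0.0)
    return da


def _forward_cache(params: ModelParams, x: np.ndarray, u: np.ndarray) -> dict:
    """Batched forward pass keeping everything backprop needs."""
    cfg = params.config
    v = params.values
    B = x.shape[0]

    V1 = sliding_window_view(x, cfg.conv1_kernel, axis=1)          # (B, L1, k1)
    p1 = V1 @ v["Wc1"] + v["bc1"]                                  # (B, L1, c1)
    m1 = p1 > 0
    a1 = np.where(m1, p1, 0.0)

    V2 = sliding_window_view(a1, cfg.conv2_kernel, axis=1)         # (B, L2, c1, k2)
    V2f = np.ascontiguousarray(V2).reshape(B * cfg.conv2_len, -1)  # (.., c1*k2)
    W2m = v["Wc2"].transpose(1, 0, 2).reshape(
        cfg.conv1_filters * cfg.conv2_kernel, cfg.conv2_filters
    )
    p2 = (V2f @ W2m).reshape(B, cfg.conv2_len, cfg.conv2_filters) + v["bc2"]
    m2 = p2 > 0
    a2 = np.where(m2, p2, 0.0)

    pooled, pool_idx = _maxpool(a2, cfg.pool_size, cfg.pool_stride, cfg.pool_len)

    flat = pooled.reshape(B, cfg.flat_len)
    z = np.concatenate([flat, u], axis=1)                          # (B, flat+M)
    pf = z @ v["W1"].T + v["b1"]                                   # (B, fc1)
    mf = pf > 0
    af = np.where(mf, pf, 0.0)
    y = af @ v["w2"] + v["b2"]

    return {
        "x": x, "u": u, "V1": V1, "m1": m1, "a1": a1, "V2f": V2f, "W2m": W2m,
        "m2": m2, "pool_idx": pool_idx, "z": z, "mf": mf, "af": af, "y": y,
    }


def forward(params: ModelParams, x: np.ndarray, u: np.ndarray) -> np.ndarray | float:
    """Standardized BP prediction(s) for one beat or a batch of beats."""
    x, u, single = _as_batch(x, u, params.config)
    y = _forward_cache(params, x, u)["y"]
    return float(y[0]) if single else y


def feature_gradients(params: ModelParams, x: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Exact ∂y_NN/∂u (standardized scale), shape (M,) or (B, M).

    The features enter the network only at the concatenation, so the
    gradient is carried entirely by the fully connected head:
    ``g_k = Σ_j w2_j · 1[p_j > 0] · W1[j, flat+k]``.
    """
    if not all(np.all(np.isfinite(v)) for v in params.values.values()):
        raise ConfigError("non-finite weights: gradients undefined")
    x, u, single = _as_batch(x, u, params.config)
    cache = _forward_cache(params, x, u)
    g = _feature_gradients_from_cache(params, cache)
    return g[0] if single else g


def _feature_gradients_from_cache(params: ModelParams, cache: dict) -> np.ndarray:
    cfg = params.config
    W1u = params["W1"][:, cfg.flat_len :]                          # (fc1, M)
    return (cache["mf"] * params["w2"]) @ W1u                      # (B, M)


# ---------------------------------------------------------------------------
# backward pass (gradients with respect to Θ)
# ---------------------------------------------------------------------------

def _backprop_params(params: ModelParams, cache: dict, seed: np.ndarray) -> dict:
    """dL/dΘ for a loss whose per-example output seeds are ``seed`` (B,)."""
    cfg = params.config
    v = params.values
    B = seed.shape[0]

    daf = seed[:, None] * v["w2"]                                  # (B, fc1)
    dpf = np.where(cache["mf"], daf, 0.0)
    grads = {
        "b2": np.asarray(seed.sum(), dtype=v["b2"].dtype),
        "w2": cache["af"].T @ seed,
        "W1": dpf.T @ cache["z"],
        "b1": dpf.sum(axis=0),
    }
    dz = dpf @ v["W1"]                                             # (B, flat+M)
    dflat = dz[:, : cfg.flat_len].reshape(B, cfg.pool_len, cfg.conv2_filters)

    # max-pool backward: route each pooled gradient to its argmax source
    da2 = _maxpool_backward(
        dflat, cache["pool_idx"], cfg.conv2_len, cfg.pool_size, cfg.pool_stride
    )

    dp2 = np.where(cache["m2"], da2, 0.0)
    dp2f = dp2.reshape(B * cfg.conv2_len, cfg.conv2_filters)
    dW2m = cache["V2f"].T @ dp2f                                   # (c1*k2, c2)
    grads["Wc2"] = dW2m.reshape(
        cfg.conv1_filters, cfg.conv2_kernel, cfg.conv2_filters
    ).transpose(1, 0, 2)
    grads["bc2"] = dp2.sum(axis=(0, 1))

    dV2f = dp2f @ cache["W2m"].T
    dV2 = dV2f.reshape(B, cfg.conv2_len, cfg.conv1_filters, cfg.conv2_kernel)
    da1 = np.zeros_like(cache["a1"])
    for o in range(cfg.conv2_kernel):                              # fold windows back
        da1[:, o : o + cfg.conv2_len, :] += dV2[:, :, :, o]
    dp1 = np.where(cache["m1"], da1, 0.0)
    grads["Wc1"] = np.einsum("blk,blc->kc", cache["V1"], dp1)
    grads["bc1"] = dp1.sum(axis=(0, 1))
    return grads


def _taylor_term_grads(
    params: ModelParams,
    cache: dict,
    anchor_idx: np.ndarray,
    delta_u: np.ndarray,
    coef: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of Σ_p coef_p · (g_{anchor_p} · Δu_p) w.r.t. w2 and W1_u.

    ``g·Δu = Σ_j w2_j m_j (W1_u[j]·Δu)``; with the activation masks locally
    constant this expression touches only ``w2`` and the feature columns
    of ``W1`` — every other parameter's contribution is zero almost
    everywhere, exactly as reverse-over-reverse autodiff would give.
    """
    cfg = params.config
    W1u = params["W1"][:, cfg.flat_len :]                          # (fc1, M)
    Mf = cache["mf"][anchor_idx]                                   # (P, fc1)
    Q = delta_u @ W1u.T                                            # (P, fc1)
    cm = coef[:, None] * Mf                                        # (P, fc1)
    dw2 = (cm * Q).sum(axis=0)
    dW1u = (cm * params["w2"]).T @ delta_u                         # (fc1, M)
    return dw2, dW1u


# ---------------------------------------------------------------------------
# Taylor polynomial, residuals, and losses
# ---------------------------------------------------------------------------

def taylor_evaluate(
    params: ModelParams,
    anchor_x: np.ndarray,
    anchor_u: np.ndarray,
    target_u: np.ndarray,
) -> float:
    """First-order Taylor value P_anchor(target_u).

    ``f_NN`` and its feature gradient are evaluated at the anchor beat;
    the polynomial extrapolates linearly in the features only (any change
    in the waveform between beats is absorbed by the residual).
    """
    y0 = forward(params, anchor_x, anchor_u)
    g = feature_gradients(params, anchor_x, anchor_u)
    target_u = np.asarray(target_u, dtype=params.config.dtype)
    return float(y0 + g @ (target_u - np.asarray(anchor_u, dtype=params.config.dtype)))


def _pairs_or_raise(ds: BeatDataset) -> np.ndarray:
    if ds.n_beats < 2:
        raise InsufficientSequenceError(
            f"need at least 2 beats for sequential residuals, got {ds.n_beats}"
        )
    pairs = ds.consecutive_pairs()
    if pairs.shape[0] == 0:
        raise InsufficientSequenceError(
            "no within-session consecutive beat pairs available"
        )
    return pairs


def residuals(ds: BeatDataset, params: ModelParams) -> np.ndarray:
    """Taylor residuals h_i over all within-session consecutive pairs.

    ``h_i = f_NN(x_{i+1}, u_{i+1}, Θ) − P_i(u_{i+1})``; pairs spanning a
    session boundary are excluded (the beat-to-beat locality premise does
    not hold across recording gaps).
    """
    h, _, _ = _residuals_cached(ds, params)
    return h


def _residuals_cached(ds: BeatDataset, params: ModelParams):
    pairs = _pairs_or_raise(ds)
    cache = _forward_cache(
        params,
        np.asarray(ds.waveforms, dtype=params.config.dtype),
        np.asarray(ds.features, dtype=params.config.dtype),
    )
    g = _feature_gradients_from_cache(params, cache)
    i, j = pairs[:, 0], pairs[:, 1]
    du = cache["u"][j] - cache["u"][i]
    h = cache["y"][j] - cache["y"][i] - (g[i] * du).sum(axis=1)
    return h, pairs, cache


def physics_loss(ds: BeatDataset, params: ModelParams) -> float:
    """Mean squared Taylor residual over all evaluated pairs (unsupervised)."""
    h = residuals(ds, params)
    return float(np.mean(h**2))


def _labeled_indices(ds: BeatDataset, labeled_idx) -> np.ndarray:
    if labeled_idx is None:
        raise NoLabelsError("no labeled indices supplied")
    if hasattr(labeled_idx, "train_idx"):
        labeled_idx = labeled_idx.train_idx
    idx = np.asarray(labeled_idx, dtype=int)
    if idx.size == 0:
        raise NoLabelsError("supervised loss needs at least one labeled beat")
    if ds.labels is None:
        raise NoLabelsError("dataset has no labels")
    return idx


def supervised_loss(ds: BeatDataset, labeled_idx, params: ModelParams) -> float:
    """MSE between predictions and labels over the S labeled beats only."""
    idx = _labeled_indices(ds, labeled_idx)
    y = forward(params, ds.waveforms[idx], ds.features[idx])
    return float(np.mean((y - ds.labels[idx]) ** 2))


@dataclass(frozen=True)
class LossBundle:
    """Snapshot of the composite objective at one parameter state."""

    L_conv: float
    L_phys: float
    lambda_phys: float
    residuals: np.ndarray

    @property
    def L_total(self) -> float:
        return self.L_conv + self.lambda_phys * self.L_phys


def total_loss(
    ds: BeatDataset, labeled_idx, params: ModelParams, lambda_phys: float = 1.0
) -> LossBundle:
    """L_total = L_conventional + λ·L_physics (λ = 1 reproduces the plain sum).

    With λ = 0 the objective degenerates exactly to the conventional
    supervised CNN loss; the physics term is still reported.
    """
    h = residuals(ds, params)
    return LossBundle(
        L_conv=supervised_loss(ds, labeled_idx, params),
        L_phys=float(np.mean(h**2)),
        lambda_phys=lambda_phys,
        residuals=h,
    )


# ---------------------------------------------------------------------------
# fused loss + parameter gradients (used by the optimizer)
# ---------------------------------------------------------------------------

def loss_and_param_grads(
    ds: BeatDataset,
    labeled_idx,
    params: ModelParams,
    lambda_phys: float = 1.0,
) -> tuple[LossBundle, dict]:
    """Composite loss and dL_total/dΘ in one batched forward/backward pass.

    The supervised and physics contributions share one output-seed
    backpropagation; the Taylor term adds its analytic (a.e.) extra
    gradients on ``w2`` and the feature columns of ``W1``.
    """
    idx = _labeled_indices(ds, labeled_idx)
    cfg = params.config

    if lambda_phys == 0.0:
        # conventional objective: only the labeled beats matter
        cache = _forward_cache(
            params,
            np.asarray(ds.waveforms[idx], dtype=cfg.dtype),
            np.asarray(ds.features[idx], dtype=cfg.dtype),
        )
        err = cache["y"] - ds.labels[idx]
        grads = _backprop_params(params, cache, 2.0 * err / err.size)
        # the physics term is not evaluated on this fast path (it has zero
        # weight in the objective); total_loss() reports it when wanted
        bundle = LossBundle(
            L_conv=float(np.mean(err**2)),
            L_phys=0.0,
            lambda_phys=0.0,
            residuals=np.empty(0),
        )
        return bundle, grads

    h, pairs, cache = _residuals_cached(ds, params)
    i, j = pairs[:, 0], pairs[:, 1]
    n_pairs = h.size
    err = cache["y"][idx] - ds.labels[idx]

    seed = np.zeros(ds.n_beats, dtype=cfg.dtype)
    np.add.at(seed, idx, 2.0 * err / err.size)
    w = lambda_phys * 2.0 * h / n_pairs
    np.add.at(seed, j, w)
    np.add.at(seed, i, -w)
    grads = _backprop_params(params, cache, seed)

    dw2, dW1u = _taylor_term_grads(
        params, cache, i, cache["u"][j] - cache["u"][i], -w
    )
    grads["w2"] = grads["w2"] + dw2
    grads["W1"] = grads["W1"].copy()
    grads["W1"][:, cfg.flat_len :] += dW1u

    bundle = LossBundle(
        L_conv=float(np.mean(err**2)),
        L_phys=float(np.mean(h**2)),
        lambda_phys=lambda_phys,
        residuals=h,
    )
    return bundle, grads
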