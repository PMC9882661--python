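"""Accuracy statistics and gradient-interpretation analyses.

Metrics are always computed on destandardized (mmHg) values: mean error
(ME), SD of the error (SDE), RMSE, Pearson's r, Bland-Altman bias with
1.96·SDE limits of agreement, and a simplified AAMI flag (|ME| ≤ 5 mmHg
and SDE ≤ 8 mmHg — the classical device criterion, not the standard's
full grading tables).

The interpretation side maps the network's feature gradients ∂y_NN/∂u
back to mmHg per physical feature unit, bins them by the predicted BP
(nearest integer mmHg) per recording session to form trend lines, and
summarizes the consistency of those trends across a group of models with
SD_avg: the across-model SD of the trend at each integer BP value,
averaged over the BP values where at least two models contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, CorrelationUndefined, DataError
from .pinn_core import ModelParams, _feature_gradients_from_cache, _forward_cache
from .signal_features import BeatDataset

__all__ = [
    "MetricsReport",
    "GradientTrace",
    "compute_metrics",
    "predict_mmhg",
    "gradient_trace",
    "sd_avg",
]


@dataclass(frozen=True)
class MetricsReport:
    """Agreement statistics between predicted and reference BP (mmHg)."""

    ME: float
    SDE: float
    RMSE: float
    pearson_r: float | None
    n: int
    bland_altman: tuple[float, float, float]  # (bias, loa_low, loa_high)
    aami_pass: bool

    def to_dict(self) -> dict:
        return {
            "ME_mmHg": self.ME,
            "SDE_mmHg": self.SDE,
            "RMSE_mmHg": self.RMSE,
            "pearson_r": self.pearson_r,
            "n": self.n,
            "bland_altman_bias_mmHg": self.bland_altman[0],
            "bland_altman_loa_low_mmHg": self.bland_altman[1],
            "bland_altman_loa_high_mmHg": self.bland_altman[2],
            "aami_pass_simplified": self.aami_pass,
        }


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """ME / SDE / RMSE / Pearson r / Bland-Altman for one prediction set.

    Errors are ``pred − true``; SDE uses the n−1 denominator, so
    ``RMSE² = ME² + SDE²·(n−1)/n`` holds exactly. With a constant input
    the correlation is undefined: a :class:`CorrelationUndefined` warning
    is emitted and ``pearson_r`` is None while the other metrics are
    still returned.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 2:
        raise DataError(
            f"need two equal-length vectors of >= 2 values, got "
            f"{y_true.shape} and {y_pred.shape}"
        )
    err = y_pred - y_true
    me = float(err.mean())
    sde = float(err.std(ddof=1))
    rmse = float(np.sqrt(np.mean(err**2)))
    if y_true.std() == 0 or y_pred.std() == 0:
        warnings.warn(
            "constant y_true or y_pred: Pearson correlation is undefined",
            CorrelationUndefined,
        )
        r = None
    else:
        r = float(stats.pearsonr(y_true, y_pred).statistic)
    return MetricsReport(
        ME=me,
        SDE=sde,
        RMSE=rmse,
        pearson_r=r,
        n=y_true.size,
        bland_altman=(me, me - 1.96 * sde, me + 1.96 * sde),
        aami_pass=bool(abs(me) <= 5.0 and sde <= 8.0),
    )


def predict_mmhg(params: ModelParams, ds: BeatDataset) -> np.ndarray:
    """Model predictions for every beat, destandardized to mmHg."""
    if not ds.standardized or ds.norm_stats is None:
        raise ConfigError("predict_mmhg expects a standardized dataset")
    cache = _forward_cache(
        params,
        np.asarray(ds.waveforms, dtype=params.config.dtype),
        np.asarray(ds.features, dtype=params.config.dtype),
    )
    return ds.norm_stats.destandardize_y(cache["y"])


# ---------------------------------------------------------------------------
# gradient interpretation
# ---------------------------------------------------------------------------

@dataclass
class GradientTrace:
    """Per-beat feature gradients of one trained model, in physical units.

    ``records`` has one row per beat: predicted BP (mmHg), the three
    gradients (mmHg per feature unit), and the session id. ``trends``
    holds per-session mean gradients at each integer predicted-BP value;
    ``overall_trend`` pools all sessions (used for across-model SD_avg).
    """

    records: pd.DataFrame
    trends: dict[str, pd.DataFrame]
    overall_trend: pd.DataFrame

    GRAD_COLS = ("g1", "g2", "g3")

    def session_sd_avg(self) -> np.ndarray:
        """Across-session trend SD per component, averaged over integer BP."""
        return _trend_sd_avg(list(self.trends.values()))


def _trend(df: pd.DataFrame) -> pd.DataFrame:
    bp_int = df["y_nn_mmhg"].round().astype(int)
    out = df.groupby(bp_int)[list(GradientTrace.GRAD_COLS)].mean()
    out.index.name = "bp_mmhg"
    return out


def _trend_sd_avg(trends: list[pd.DataFrame]) -> np.ndarray:
    if len(trends) < 2:
        raise DataError("need at least 2 trends for an across-group SD")
    stacked = pd.concat(trends, keys=range(len(trends)), names=["trace", "bp_mmhg"])
    counts = stacked.groupby(level="bp_mmhg").size()
    support = counts[counts >= 2].index
    if support.empty:
        raise DataError("no overlapping integer-BP support across traces")
    sd = (
        stacked.loc[(slice(None), support), :]
        .groupby(level="bp_mmhg")
        .std(ddof=1)
    )
    return sd.mean(axis=0).to_numpy()


def gradient_trace(params: ModelParams, ds: BeatDataset) -> GradientTrace:
    """Destandardized ∂y_NN/∂u for every beat, with per-session trends.

    Gradients on the standardized scale are rescaled by sd_y/sd_{u_k}
    (chain rule through the recorded normalization statistics) so they
    read as mmHg per physical feature unit.
    """
    if not ds.standardized or ds.norm_stats is None:
        raise ConfigError("gradient_trace expects a standardized dataset")
    cache = _forward_cache(
        params,
        np.asarray(ds.waveforms, dtype=params.config.dtype),
        np.asarray(ds.features, dtype=params.config.dtype),
    )
    g_std = _feature_gradients_from_cache(params, cache)
    g_phys = g_std * ds.norm_stats.gradient_scale()
    y_mmhg = ds.norm_stats.destandardize_y(cache["y"])
    records = pd.DataFrame(
        {
            "beat_index": np.arange(ds.n_beats),
            "y_nn_mmhg": y_mmhg,
            "g1": g_phys[:, 0],
            "g2": g_phys[:, 1],
            "g3": g_phys[:, 2],
            "session_id": ds.session_ids.astype(str),
        }
    )
    trends = {
        sid: _trend(grp) for sid, grp in records.groupby("session_id", sort=False)
    }
    return GradientTrace(
        records=records, trends=trends, overall_trend=_trend(records)
    )


def sd_avg(traces: list[GradientTrace]) -> np.ndarray:
    """Consistency of the learned input-output map across a model group.

    For each integer predicted-BP value where at least two traces'
    overall trends contribute, the SD of the trend values is taken across
    traces; the result is averaged over those BP values. Returns one
    value per feature component (shape (3,)).
    """
    if len(traces) < 2:
        raise DataError("sd_avg needs at least 2 gradient traces")
    return _trend_sd_avg([t.overall_trend for t in traces])
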