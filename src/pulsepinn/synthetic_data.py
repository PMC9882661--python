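"""Synthetic bioimpedance/BP generator with known ground truth.

Emulates the statistical structure a Taylor-residual-trained network
relies on: a smooth, locally linearizable map between per-beat waveform
features and blood pressure, with the couplings seen in cold-pressor
(CPT) style maneuvers:

* pulse amplitude falls as BP rises (peripheral vasoconstriction):
  ``a(BP) = alpha0 − alpha1·(BP − baseline)``;
* the reflection wave arrives earlier as BP rises (stiffer wall, higher
  pulse wave velocity): ``d(BP) = d0 − d1·(BP − baseline)``;
* heart rate responds biphasically (sympathetic rise, later vagal fall):
  ``HR(BP) = h0 + h1·ΔBP − h2·ΔBP²``.

Each beat's −ΔZ waveform is a two-Gaussian pulse (systolic crest plus a
delayed reflection crest) — deliberately not a hemodynamic solve: the
Gaussian morphology makes the fiducial and gradient ground truth exact,
which is what parameter-recovery tests need. Beat-to-beat BP wanders
around a piecewise-linear CPT-like profile with AR(1) noise, keeping
consecutive beats close (the locality premise behind the sequential
Taylor residual).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasibleConfigError, NonIdentifiableGradientError
from .signal_features import BeatDataset, RawRecording, preprocess_recording

__all__ = ["ProfilePhase", "SimConfig", "SimTruth", "simulate", "true_gradient"]


@dataclass(frozen=True)
class ProfilePhase:
    """One phase of the BP schedule: ramp linearly to ``target_mmhg``."""

    session: str
    duration_s: float
    target_mmhg: float


def default_cpt_profile() -> tuple[ProfilePhase, ...]:
    """Two cold-pressor elevations with recoveries, ~750 s, 44 mmHg span."""
    return (
        ProfilePhase("cpt-1", 60.0, 118.0),
        ProfilePhase("cpt-1", 90.0, 162.0),
        ProfilePhase("cpt-1", 60.0, 162.0),
        ProfilePhase("recovery-1", 120.0, 118.0),
        ProfilePhase("recovery-1", 70.0, 118.0),
        ProfilePhase("cpt-2", 90.0, 162.0),
        ProfilePhase("cpt-2", 60.0, 162.0),
        ProfilePhase("recovery-2", 120.0, 118.0),
        ProfilePhase("recovery-2", 80.0, 118.0),
    )


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; the defaults are the study conditions.

    Amplitude units follow a raw-ΔZ recording (mΩ-scale pulses normalized
    to ~1); couplings are per mmHg relative to ``bp_baseline``.
    """

    n_beats: int = 1000
    bp_baseline: float = 118.0
    bp_profile: tuple[ProfilePhase, ...] = field(default_factory=default_cpt_profile)
    alpha0: float = 1.0          # base pulse amplitude
    alpha1: float = 0.01         # amplitude loss per mmHg (vasoconstriction)
    d0: float = 0.28             # base reflection delay, s
    d1: float = 0.0015           # delay reduction per mmHg (PWV)
    h0: float = 70.0             # base heart rate, bpm
    h1: float = 0.8              # linear HR gain, bpm per mmHg
    h2: float = 0.02             # quadratic HR fall-off, bpm per mmHg^2
    ar1_rho: float = 0.9         # beat-to-beat BP noise persistence
    ar1_sigma: float = 1.0       # BP innovation SD, mmHg
    amp_jitter_sd: float = 0.08  # per-beat amplitude scatter (vasomotion)
    delay_jitter_sd: float = 0.012  # per-beat reflection-delay scatter, s
    hrv_sd: float = 2.5          # per-beat HR scatter, bpm (RSA etc.)
    noise_sd: float = 0.03       # additive waveform noise SD
    sample_rate: float = 100.0   # raw-waveform rate, Hz
    seed: int = 0
    # pulse morphology (systolic crest time/width, reflection ratio/width)
    mu1_s: float = 0.15
    sigma1_s: float = 0.04
    refl_ratio: float = 0.45
    sigma2_s: float = 0.06

    def __post_init__(self):
        if self.n_beats < 2:
            raise InfeasibleConfigError(f"n_beats must be >= 2, got {self.n_beats}")
        if self.alpha0 <= 0 or self.d0 <= 0:
            raise InfeasibleConfigError("alpha0 and d0 must be > 0")
        if self.sample_rate <= 0:
            raise InfeasibleConfigError("sample_rate must be > 0")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise InfeasibleConfigError(f"need 0 <= ar1_rho < 1, got {self.ar1_rho}")
        if min(self.ar1_sigma, self.noise_sd, self.amp_jitter_sd,
               self.delay_jitter_sd, self.hrv_sd) < 0:
            raise InfeasibleConfigError("noise SDs must be >= 0")
        # couplings must stay physical over the whole profile (with noise headroom)
        margin = 5.0 * self._stationary_sd()
        levels = [self.bp_baseline] + [p.target_mmhg for p in self.bp_profile]
        for lv in (min(levels) - margin, max(levels) + margin):
            db = lv - self.bp_baseline
            if self.alpha0 - self.alpha1 * db <= 0:
                raise InfeasibleConfigError(
                    f"amplitude coupling gives a(BP) <= 0 at BP = {lv:.1f} mmHg"
                )
            if self.d0 - self.d1 * db <= 0:
                raise InfeasibleConfigError(
                    f"delay coupling gives d(BP) <= 0 at BP = {lv:.1f} mmHg"
                )
            if self.h0 + self.h1 * db - self.h2 * db * db <= 10.0:
                raise InfeasibleConfigError(
                    f"HR coupling gives HR <= 10 bpm at BP = {lv:.1f} mmHg"
                )

    def _stationary_sd(self) -> float:
        return self.ar1_sigma / np.sqrt(1.0 - self.ar1_rho**2)

    # -- planted couplings -------------------------------------------------

    def amplitude(self, bp):
        return self.alpha0 - self.alpha1 * (np.asarray(bp) - self.bp_baseline)

    def delay(self, bp):
        return self.d0 - self.d1 * (np.asarray(bp) - self.bp_baseline)

    def heart_rate(self, bp):
        db = np.asarray(bp) - self.bp_baseline
        return self.h0 + self.h1 * db - self.h2 * db * db

    def profile_bp(self, t):
        """Noiseless scheduled BP at time t (s), piecewise-linear ramps."""
        t = np.asarray(t, dtype=float)
        out = np.empty(t.shape)
        level = self.bp_baseline
        t0 = 0.0
        remaining = np.ones(t.shape, dtype=bool)
        for ph in self.bp_profile:
            inside = remaining & (t < t0 + ph.duration_s)
            frac = (t[inside] - t0) / ph.duration_s
            out[inside] = level + frac * (ph.target_mmhg - level)
            remaining &= ~inside
            level = ph.target_mmhg
            t0 += ph.duration_s
        out[remaining] = level  # beyond the schedule: hold the last level
        return out

    def session_at(self, t: float) -> str:
        t0 = 0.0
        for ph in self.bp_profile:
            if t < t0 + ph.duration_s:
                return ph.session
            t0 += ph.duration_s
        return self.bp_profile[-1].session


@dataclass(frozen=True)
class SimTruth:
    """Per-beat ground truth: BP, noiseless latent features, analytic ∂BP/∂u.

    ``u_true`` holds the realized latent features of each beat — pulse
    amplitude, inverse reflection delay, heart rate, i.e. the coupling
    values plus the per-beat physiological scatter, free of waveform
    measurement noise — which extraction recovers up to morphology
    constants. ``grad_true`` is the
    implicit-function inverse (∂u/∂BP)⁻¹ per component; it is non-finite
    where a coupling is locally non-invertible (e.g. at the HR vertex).
    """

    bp: np.ndarray
    u_true: np.ndarray
    grad_true: np.ndarray


def true_gradient(cfg: SimConfig, bp) -> np.ndarray:
    """Analytic ∂BP/∂u at blood pressure ``bp`` (shape (3,) or (n, 3)).

    Components: ``−1/alpha1``, ``d(bp)²/d1``, ``1/(h1 − 2·h2·(bp−baseline))``.
    Raises :class:`NonIdentifiableGradientError` when a coupling gain is
    zero (component 1 or 2) or the HR parabola is at its vertex.
    """
    bp = np.asarray(bp, dtype=float)
    if cfg.alpha1 == 0:
        raise NonIdentifiableGradientError(
            "alpha1 = 0: d(BP)/du1 is not identifiable (component 1)"
        )
    if cfg.d1 == 0:
        raise NonIdentifiableGradientError(
            "d1 = 0: d(BP)/du2 is not identifiable (component 2)"
        )
    hr_slope = cfg.h1 - 2.0 * cfg.h2 * (bp - cfg.bp_baseline)
    if np.any(hr_slope == 0):
        raise NonIdentifiableGradientError(
            "HR coupling at its vertex: d(BP)/du3 is not identifiable (component 3)"
        )
    g1 = np.full(bp.shape, -1.0 / cfg.alpha1)
    g2 = cfg.delay(bp) ** 2 / cfg.d1
    g3 = 1.0 / hr_slope
    return np.stack(np.broadcast_arrays(g1, g2, g3), axis=-1)


def _true_gradient_allow_nonfinite(cfg: SimConfig, bp: np.ndarray) -> np.ndarray:
    bp = np.asarray(bp, dtype=float)
    with np.errstate(divide="ignore"):
        g1 = np.full(bp.shape, -1.0 / cfg.alpha1 if cfg.alpha1 else np.inf)
        g2 = (cfg.delay(bp) ** 2 / cfg.d1) if cfg.d1 else np.full(bp.shape, np.inf)
        hr_slope = cfg.h1 - 2.0 * cfg.h2 * (bp - cfg.bp_baseline)
        g3 = np.divide(1.0, hr_slope, out=np.full(bp.shape, np.inf), where=hr_slope != 0)
    return np.stack(np.broadcast_arrays(g1, g2, g3), axis=-1)


def simulate(
    cfg: SimConfig, process: bool = True
) -> tuple[RawRecording, BeatDataset | None, SimTruth]:
    """Generate a recording, its processed dataset, and the ground truth.

    Deterministic given ``cfg.seed``. Beat ``i`` gets BP from the profile
    plus AR(1) noise, a period of ``60/HR(BP_i)`` seconds, and a −ΔZ
    waveform ``a(BP_i)·[G(t;μ1,σ1) + r·G(t;μ1+d(BP_i),σ2)]`` plus white
    noise; stored samples carry the physical ΔZ sign (downward pulses).
    Beat boundaries are exact. With ``process=True`` the returned
    :class:`BeatDataset` is the full preprocessing chain (30 Hz, pad 60,
    3-beat moving average) applied to the recording, labelled with the
    per-beat true BP; otherwise it is None.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate

    bp = np.empty(cfg.n_beats)
    amp = np.empty(cfg.n_beats)
    dly = np.empty(cfg.n_beats)
    hr_arr = np.empty(cfg.n_beats)
    n_samp = np.empty(cfg.n_beats, dtype=int)
    sessions = np.empty(cfg.n_beats, dtype=object)
    t = 0.0
    e = 0.0
    for i in range(cfg.n_beats):
        e = cfg.ar1_rho * e + rng.normal(0.0, cfg.ar1_sigma)
        bp_i = float(cfg.profile_bp(t)) + e
        # per-beat physiological scatter around the couplings: the features
        # are noisy proxies of BP, as they are on real wearables
        amp_i = float(cfg.amplitude(bp_i)) + rng.normal(0.0, cfg.amp_jitter_sd)
        dly_i = float(cfg.delay(bp_i)) + rng.normal(0.0, cfg.delay_jitter_sd)
        hr_i = float(cfg.heart_rate(bp_i)) + rng.normal(0.0, cfg.hrv_sd)
        if hr_i <= 10.0:
            raise InfeasibleConfigError(f"HR coupling gives {hr_i:.1f} bpm at beat {i}")
        if amp_i <= 0 or dly_i <= 0:
            raise InfeasibleConfigError(
                f"realized amplitude or delay non-positive at beat {i}"
            )
        bp[i], amp[i], dly[i], hr_arr[i] = bp_i, amp_i, dly_i, hr_i
        sessions[i] = cfg.session_at(t)
        n_samp[i] = max(8, int(round(60.0 / hr_i * fs)))
        t += n_samp[i] / fs

    boundaries = np.concatenate([[0], np.cumsum(n_samp)])
    samples = np.empty(int(boundaries[-1]))
    bp_trace = np.empty_like(samples)
    for i in range(cfg.n_beats):
        lo, hi = boundaries[i], boundaries[i + 1]
        tau = np.arange(n_samp[i]) / fs
        pulse = amp[i] * (
            np.exp(-0.5 * ((tau - cfg.mu1_s) / cfg.sigma1_s) ** 2)
            + cfg.refl_ratio
            * np.exp(-0.5 * ((tau - cfg.mu1_s - dly[i]) / cfg.sigma2_s) ** 2)
        )
        if cfg.noise_sd > 0:
            pulse = pulse + rng.normal(0.0, cfg.noise_sd, size=n_samp[i])
        samples[lo:hi] = -pulse  # store physical ΔZ (drops with pulse arrival)
        bp_trace[lo:hi] = bp[i]

    rec = RawRecording(
        samples=samples,
        sample_rate=fs,
        beat_boundaries=boundaries,
        session_ids=np.array([str(s) for s in sessions]),
        bp=bp_trace,
    )

    u_true = np.stack([amp, 1.0 / dly, hr_arr], axis=1)
    truth = SimTruth(
        bp=bp, u_true=u_true, grad_true=_true_gradient_allow_nonfinite(cfg, bp)
    )

    ds = preprocess_recording(rec) if process else None
    return rec, ds, truth
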