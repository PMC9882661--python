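"""Bioimpedance waveform preprocessing and per-beat feature extraction.

The pulsatile bioimpedance signal ΔZ drops with every heartbeat as the
arriving pressure pulse expands the artery (blood conducts better than the
surrounding tissue), so all morphological analysis happens on the inverted
waveform −ΔZ. Each beat contributes nine fiducial landmarks, labelled
A..J (letter I unused), from which three physiological features are read:

* ``u1 = (ΔZ)_A − (ΔZ)_C`` — full pulsatile amplitude swing, a proxy for
  arterial volume expansion (vasoconstriction lowers it while BP rises);
* ``u2 = 1/(t_F − t_B)`` — inverse delay between the systolic crest (B)
  and the reflection-wave crest (F), a proxy for pulse wave velocity;
* ``u3 = 60/(t_J − t_A)`` — beat-to-beat heart rate in beats/min.

The preprocessing chain mirrors a standard wearable-BP pipeline: optional
Z0 normalization, beat segmentation, fiducial/feature extraction,
down-sampling to 30 Hz with zero padding, a three-beat moving average, and
whole-dataset standardization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import (
    BeatTooLongError,
    BoundaryError,
    DegenerateChannelError,
    FiducialDetectionError,
    InvalidBaselineError,
    InvalidWindowError,
    NonPhysicalTimingError,
)

FIDUCIAL_LETTERS = ("A", "B", "C", "D", "E", "F", "G", "H", "J")
N_FEATURES = 3

__all__ = [
    "FIDUCIAL_LETTERS",
    "N_FEATURES",
    "RawRecording",
    "BeatRecord",
    "FiducialPoint",
    "FiducialSet",
    "FeatureVector",
    "NormStats",
    "BeatDataset",
    "normalize_delta_z",
    "detect_beat_boundaries",
    "segment_beats",
    "extract_fiducials",
    "compute_features",
    "resample_and_pad",
    "moving_average_smooth",
    "standardize",
    "destandardize",
    "preprocess_recording",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawRecording:
    """A single-channel ΔZ recording with known beat boundaries.

    Parameters
    ----------
    samples:
        ΔZ amplitude series (mΩ, or dimensionless once normalized by Z0).
    sample_rate:
        Sampling rate in Hz.
    z0:
        Baseline impedance in Ω, if available.
    beat_boundaries:
        Strictly increasing sample indices marking beat starts; the last
        boundary closes the final beat.
    session_ids:
        One label per beat (e.g. ``"cpt-1"``), length ``len(boundaries)-1``.
    bp:
        Optional per-sample reference BP trace (mmHg), used to label beats.
    norm_mode:
        ``"z0-normalized"`` or ``"raw-dz"``; set by :func:`normalize_delta_z`.
    """

    samples: np.ndarray
    sample_rate: float
    z0: float | None = None
    beat_boundaries: np.ndarray | None = None
    session_ids: np.ndarray | None = None
    bp: np.ndarray | None = None
    norm_mode: str = "raw-dz"

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.size == 0:
            raise BoundaryError("recording has no samples")
        if self.sample_rate <= 0:
            raise BoundaryError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.z0 is not None and self.z0 <= 0:
            raise InvalidBaselineError(f"Z0 must be > 0, got {self.z0}")
        if self.beat_boundaries is not None:
            b = np.asarray(self.beat_boundaries, dtype=int)
            if b.size >= 2 and not np.all(np.diff(b) > 0):
                raise BoundaryError("beat_boundaries must be strictly increasing")
            object.__setattr__(self, "beat_boundaries", b)


@dataclass(frozen=True)
class BeatRecord:
    """One cardiac cycle: waveform vector plus timing and optional BP label."""

    x: np.ndarray
    sample_rate: float
    duration: float
    t_start: float
    beat_index: int
    session_id: str = "session-0"
    y_true: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        if self.duration <= 0:
            raise BoundaryError(f"beat duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class FiducialPoint:
    """One landmark: time within the beat and the −ΔZ amplitude there."""

    t: float
    neg_dz: float


@dataclass(frozen=True)
class FiducialSet:
    """The nine labelled landmarks of one beat, ordered A..J in time."""

    points: dict[str, FiducialPoint]

    def __post_init__(self):
        if tuple(self.points.keys()) != FIDUCIAL_LETTERS:
            missing = set(FIDUCIAL_LETTERS) - set(self.points)
            raise FiducialDetectionError(
                f"expected exactly the nine landmarks {FIDUCIAL_LETTERS}, "
                f"missing {sorted(missing)}"
            )
        times = [p.t for p in self.points.values()]
        if any(b < a - 1e-12 for a, b in zip(times, times[1:])):
            raise FiducialDetectionError(
                f"fiducial times must be non-decreasing A..J, got {times}"
            )

    def __getitem__(self, letter: str) -> FiducialPoint:
        return self.points[letter]

    def times(self) -> np.ndarray:
        return np.array([p.t for p in self.points.values()])


@dataclass(frozen=True)
class FeatureVector:
    """The three physiological features of one beat (u1, u2, u3)."""

    u1: float
    u2: float
    u3: float

    def __post_init__(self):
        vals = (self.u1, self.u2, self.u3)
        if not all(np.isfinite(vals)):
            raise NonPhysicalTimingError(f"non-finite feature vector {vals}")
        if self.u2 <= 0 or self.u3 <= 0:
            raise NonPhysicalTimingError(f"u2 and u3 must be > 0, got {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.u1, self.u2, self.u3])


@dataclass(frozen=True)
class NormStats:
    """Standardization statistics for waveforms, features, and labels.

    ``x`` uses one scalar mean/SD over the whole waveform matrix (so beat
    morphology is preserved); ``u`` is standardized per component; ``y``
    as a scalar. Storing the statistics makes the transform exactly
    invertible and lets gradients be mapped back to physical units.
    """

    x_mean: float
    x_sd: float
    u_mean: np.ndarray
    u_sd: np.ndarray
    y_mean: float | None = None
    y_sd: float | None = None

    def gradient_scale(self) -> np.ndarray:
        """Factor converting ∂y/∂u from standardized to mmHg per feature unit."""
        if self.y_sd is None:
            raise DegenerateChannelError("no label statistics recorded")
        return self.y_sd / self.u_sd

    def destandardize_y(self, y_std: np.ndarray) -> np.ndarray:
        if self.y_sd is None:
            raise DegenerateChannelError("no label statistics recorded")
        return np.asarray(y_std) * self.y_sd + self.y_mean

    def standardize_y(self, y_mmhg: np.ndarray) -> np.ndarray:
        if self.y_sd is None:
            raise DegenerateChannelError("no label statistics recorded")
        return (np.asarray(y_mmhg) - self.y_mean) / self.y_sd


@dataclass
class BeatDataset:
    """Ordered sequence of R beats stored as dense arrays.

    Waveforms must share a common length N (use :func:`resample_and_pad`),
    features are R×3, labels (mmHg) are optional. ``standardized`` flips to
    True after :func:`standardize`; ``norm_stats`` then records the
    statistics needed to invert the transform.
    """

    waveforms: np.ndarray
    features: np.ndarray
    durations: np.ndarray
    t_start: np.ndarray
    session_ids: np.ndarray
    sample_rate: float
    labels: np.ndarray | None = None
    label_name: str = "SBP"
    standardized: bool = False
    norm_stats: NormStats | None = None

    def __post_init__(self):
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        self.features = np.asarray(self.features, dtype=float)
        R = self.waveforms.shape[0]
        if self.features.shape != (R, N_FEATURES):
            raise BoundaryError(
                f"features must be ({R}, {N_FEATURES}), got {self.features.shape}"
            )
        for name in ("durations", "t_start"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (R,):
                raise BoundaryError(f"{name} must have length {R}")
            setattr(self, name, arr)
        self.session_ids = np.asarray(self.session_ids)
        if self.session_ids.shape != (R,):
            raise BoundaryError(f"session_ids must have length {R}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=float)
            if self.labels.shape != (R,):
                raise BoundaryError(f"labels must have length {R}")
        if np.any(np.diff(self.t_start) < 0):
            raise BoundaryError("beats must be ordered by t_start")

    @property
    def n_beats(self) -> int:
        return self.waveforms.shape[0]

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[1]

    def __len__(self) -> int:
        return self.n_beats

    def __getitem__(self, i: int) -> BeatRecord:
        return BeatRecord(
            x=self.waveforms[i],
            sample_rate=self.sample_rate,
            duration=float(self.durations[i]),
            t_start=float(self.t_start[i]),
            beat_index=i,
            session_id=str(self.session_ids[i]),
            y_true=None if self.labels is None else float(self.labels[i]),
        )

    def session_runs(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (session_id, contiguous index array) in temporal order."""
        ids = self.session_ids
        start = 0
        for i in range(1, len(ids) + 1):
            if i == len(ids) or ids[i] != ids[start]:
                yield str(ids[start]), np.arange(start, i)
                start = i

    def consecutive_pairs(self) -> np.ndarray:
        """Indices (i, i+1) of consecutive beats within the same session."""
        pairs = [
            np.stack([run[:-1], run[1:]], axis=1)
            for _, run in self.session_runs()
            if run.size >= 2
        ]
        if not pairs:
            return np.empty((0, 2), dtype=int)
        return np.concatenate(pairs, axis=0)

    def copy(self) -> "BeatDataset":
        return BeatDataset(
            waveforms=self.waveforms.copy(),
            features=self.features.copy(),
            durations=self.durations.copy(),
            t_start=self.t_start.copy(),
            session_ids=self.session_ids.copy(),
            sample_rate=self.sample_rate,
            labels=None if self.labels is None else self.labels.copy(),
            label_name=self.label_name,
            standardized=self.standardized,
            norm_stats=self.norm_stats,
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def normalize_delta_z(rec: RawRecording) -> RawRecording:
    """Normalize ΔZ by the baseline impedance Z0 when it is available.

    With Z0 present the samples become the dimensionless ratio ΔZ/Z0 and
    ``norm_mode`` is set to ``"z0-normalized"``; without Z0 the samples are
    passed through unchanged and the mode flag records ``"raw-dz"``.
    """
    if rec.z0 is None:
        return replace(rec, norm_mode="raw-dz")
    if rec.z0 <= 0:
        raise InvalidBaselineError(f"Z0 must be > 0, got {rec.z0}")
    return replace(rec, samples=rec.samples / rec.z0, norm_mode="z0-normalized")


def detect_beat_boundaries(
    rec: RawRecording,
    min_period_s: float = 0.4,
    prominence_frac: float = 0.3,
) -> np.ndarray:
    """Locate beat onsets as prominent troughs of −ΔZ (peaks of ΔZ).

    A fallback for recordings without supplied boundaries; prominence is
    relative to the overall signal swing. Returns boundary sample indices.
    """
    s = rec.samples
    swing = float(np.ptp(s))
    if swing <= 0:
        raise BoundaryError("flat recording: cannot detect beats")
    idx, _ = find_peaks(
        s,
        distance=max(1, int(round(min_period_s * rec.sample_rate))),
        prominence=prominence_frac * swing,
    )
    if idx.size < 2:
        raise BoundaryError(f"detected only {idx.size} beat boundaries (need >= 2)")
    return idx


def segment_beats(rec: RawRecording) -> list[BeatRecord]:
    """Cut the recording into beat-to-beat intervals [b_i, b_{i+1}).

    Each boundary pair yields one :class:`BeatRecord` whose duration is the
    boundary spacing in seconds; sample values are retained untouched. The
    per-beat BP label, when a per-sample ``bp`` trace exists, is its mean
    over the beat window.
    """
    b = rec.beat_boundaries
    if b is None or len(b) < 2:
        n = 0 if b is None else len(b)
        raise BoundaryError(f"need at least 2 beat boundaries, got {n}")
    if not np.all(np.diff(b) > 0):
        raise BoundaryError("beat_boundaries must be strictly increasing")
    if b[0] < 0 or b[-1] > len(rec.samples):
        raise BoundaryError("beat boundaries outside the recording")
    n_beats = len(b) - 1
    sessions = rec.session_ids
    if sessions is not None and len(sessions) != n_beats:
        raise BoundaryError(
            f"session_ids length {len(sessions)} != number of beats {n_beats}"
        )
    beats = []
    for i in range(n_beats):
        lo, hi = int(b[i]), int(b[i + 1])
        y = None
        if rec.bp is not None:
            y = float(np.mean(rec.bp[lo:hi]))
        beats.append(
            BeatRecord(
                x=rec.samples[lo:hi],
                sample_rate=rec.sample_rate,
                duration=(hi - lo) / rec.sample_rate,
                t_start=lo / rec.sample_rate,
                beat_index=i,
                session_id="session-0" if sessions is None else str(sessions[i]),
                y_true=y,
            )
        )
    return beats


def _smooth_for_landmarks(s: np.ndarray) -> np.ndarray:
    # light Savitzky-Golay pass: keeps crest timing, suppresses sample noise
    n = len(s)
    win = min(7, n if n % 2 == 1 else n - 1)
    if win < 5:
        return s.copy()
    return savgol_filter(s, window_length=win, polyorder=2)


def extract_fiducials(beat: BeatRecord, prominence_frac: float = 0.10) -> FiducialSet:
    """Place the nine landmarks A..J on the inverted waveform −ΔZ.

    Landmark semantics (times non-decreasing by construction):

    ====== =====================================================
    A      beat onset — foot of the −ΔZ upstroke
    B      systolic-wave crest (first prominent −ΔZ maximum)
    C      global −ΔZ maximum — amplitude reference for u1
    D      inter-wave valley (dicrotic-notch region minimum)
    E      steepest reflection upstroke between D and F
    F      reflection-wave crest
    G      steepest decay after the reflection wave
    H      decay inflection (second-derivative zero crossing)
    J      beat end (t = beat duration)
    ====== =====================================================

    Raises :class:`FiducialDetectionError` (carrying ``beat_index``) when
    the morphology does not show the two required crests.
    """
    s = -beat.x
    n = len(s)
    if n < 8:
        raise FiducialDetectionError(
            f"beat of {n} samples is too short for landmark detection",
            beat_index=beat.beat_index,
        )
    fs = beat.sample_rate
    sm = _smooth_for_landmarks(s)
    swing = float(np.ptp(sm))
    if swing <= 0:
        raise FiducialDetectionError(
            "flat beat: no extrema on -dz", beat_index=beat.beat_index
        )
    peaks, props = find_peaks(sm, prominence=prominence_frac * swing)
    if peaks.size < 2:
        raise FiducialDetectionError(
            f"found {peaks.size} prominent crest(s) on -dz, need the systolic "
            "and reflection waves",
            beat_index=beat.beat_index,
        )
    # systolic crest: the most prominent; reflection crest: the most
    # prominent crest after it
    order = np.argsort(props["prominences"])[::-1]
    i_b = int(peaks[order[0]])
    later = peaks[peaks > i_b]
    if later.size == 0:
        # the dominant crest is the reflection wave; take the most prominent
        # earlier crest as systolic
        earlier = peaks[peaks < i_b]
        if earlier.size == 0:
            raise FiducialDetectionError(
                "no second crest on -dz", beat_index=beat.beat_index
            )
        prom = {int(p): pr for p, pr in zip(peaks, props["prominences"])}
        i_f = i_b
        i_b = int(earlier[np.argmax([prom[int(p)] for p in earlier])])
    else:
        prom = {int(p): pr for p, pr in zip(peaks, props["prominences"])}
        i_f = int(later[np.argmax([prom[int(p)] for p in later])])

    i_a = int(np.argmin(sm[: i_b + 1]))
    i_c = int(np.argmax(sm))
    if i_c < i_b:  # freak early maximum: amplitude reference falls back to B
        i_c = i_b
    i_d = i_b + int(np.argmin(sm[i_b : i_f + 1]))
    ds = np.gradient(sm)
    i_e = i_d + int(np.argmax(ds[i_d : i_f + 1]))
    tail_lo = min(i_f + 1, n - 1)
    i_g = tail_lo + int(np.argmin(ds[tail_lo:]))
    d2 = np.gradient(ds)
    i_h = None
    for j in range(i_g + 1, n - 1):
        if d2[j] == 0 or d2[j] * d2[j + 1] < 0:
            i_h = j
            break
    if i_h is None:
        i_h = (i_g + n - 1) // 2
        i_h = max(i_h, i_g)

    def pt(i: int) -> FiducialPoint:
        return FiducialPoint(t=i / fs, neg_dz=float(s[i]))

    points = {
        "A": pt(i_a),
        "B": pt(i_b),
        "C": pt(i_c),
        "D": pt(i_d),
        "E": pt(i_e),
        "F": pt(i_f),
        "G": pt(i_g),
        "H": pt(i_h),
        "J": FiducialPoint(t=beat.duration, neg_dz=float(s[-1])),
    }
    return FiducialSet(points=points)


def compute_features(fids: FiducialSet, beat: BeatRecord) -> FeatureVector:
    """Read the three features off the fiducial set.

    ``u1 = (ΔZ)_A − (ΔZ)_C`` (equivalently the −ΔZ swing C minus A),
    ``u2 = 1/(t_F − t_B)``, ``u3 = 60/(t_J − t_A)``.
    """
    a, b, c, f, j = (fids[k] for k in "ABCFJ")
    if f.t <= b.t:
        raise NonPhysicalTimingError(
            f"reflection crest must follow systolic crest (t_F={f.t}, t_B={b.t})"
        )
    if j.t <= a.t:
        raise NonPhysicalTimingError(
            f"beat end must follow onset (t_J={j.t}, t_A={a.t})"
        )
    return FeatureVector(
        u1=c.neg_dz - a.neg_dz,  # == (dz)_A - (dz)_C
        u2=1.0 / (f.t - b.t),
        u3=60.0 / (j.t - a.t),
    )


def resample_and_pad(
    beat: BeatRecord, target_rate: float = 30.0, pad_len: int = 60
) -> BeatRecord:
    """Down-sample the beat to ``target_rate`` and zero-pad to ``pad_len``.

    Linear interpolation onto the grid k/target_rate, k = 0..⌈d·rate⌉−1,
    then right-padding with zeros. A beat longer than pad_len/target_rate
    raises :class:`BeatTooLongError`; nothing is ever silently truncated.
    """
    n_out = int(math.ceil(beat.duration * target_rate - 1e-9))
    if n_out > pad_len:
        raise BeatTooLongError(
            f"beat of {beat.duration:.3f} s needs {n_out} samples at "
            f"{target_rate} Hz but pad_len is {pad_len}"
        )
    t_orig = np.arange(len(beat.x)) / beat.sample_rate
    t_new = np.arange(n_out) / target_rate
    resampled = np.interp(t_new, t_orig, beat.x)
    out = np.zeros(pad_len)
    out[:n_out] = resampled
    return replace(beat, x=out, sample_rate=target_rate)


def moving_average_smooth(
    ds: BeatDataset, window: int = 3, overlap: int = 1
) -> BeatDataset:
    """Average waveforms, features, and labels over sliding beat windows.

    Windows of ``window`` beats advance by ``window − overlap`` beats and
    never span a session boundary. With the defaults (3-beat window, one
    shared beat) each session of R beats yields floor((R−3)/2)+1 outputs.
    """
    if overlap >= window:
        raise InvalidWindowError(f"overlap ({overlap}) must be < window ({window})")
    if window < 1:
        raise InvalidWindowError(f"window must be >= 1, got {window}")
    if ds.n_beats < window:
        raise InvalidWindowError(
            f"dataset has {ds.n_beats} beats, fewer than window {window}"
        )
    stride = window - overlap
    wf, feat, dur, t0, sess, lab = [], [], [], [], [], []
    for sid, run in ds.session_runs():
        for start in range(0, run.size - window + 1, stride):
            idx = run[start : start + window]
            wf.append(ds.waveforms[idx].mean(axis=0))
            feat.append(ds.features[idx].mean(axis=0))
            dur.append(ds.durations[idx].mean())
            t0.append(ds.t_start[idx[0]])
            sess.append(sid)
            if ds.labels is not None:
                lab.append(ds.labels[idx].mean())
    return BeatDataset(
        waveforms=np.array(wf),
        features=np.array(feat),
        durations=np.array(dur),
        t_start=np.array(t0),
        session_ids=np.array(sess),
        sample_rate=ds.sample_rate,
        labels=np.array(lab) if ds.labels is not None else None,
        label_name=ds.label_name,
        standardized=ds.standardized,
        norm_stats=ds.norm_stats,
    )


def standardize(ds: BeatDataset) -> BeatDataset:
    """Zero-mean / unit-SD transform of waveforms, features, and labels.

    Statistics are computed over the complete dataset (the transductive
    convention: physics-loss training sees every beat anyway) and stored in
    ``norm_stats`` so that :func:`destandardize` inverts the transform to
    machine precision. To standardize held-out data with training-set
    statistics instead, pass a dataset's ``norm_stats`` through
    :func:`apply_norm_stats`.
    """
    if ds.standardized:
        raise DegenerateChannelError("dataset is already standardized")
    x_mean = float(ds.waveforms.mean())
    x_sd = float(ds.waveforms.std())
    u_mean = ds.features.mean(axis=0)
    u_sd = ds.features.std(axis=0)
    if x_sd <= 0:
        raise DegenerateChannelError("waveform channel has zero variance")
    if np.any(u_sd <= 0):
        k = int(np.argmax(u_sd <= 0)) + 1
        raise DegenerateChannelError(f"feature channel u{k} has zero variance")
    y_mean = y_sd = None
    if ds.labels is not None:
        y_mean = float(ds.labels.mean())
        y_sd = float(ds.labels.std())
        if y_sd <= 0:
            raise DegenerateChannelError("label channel has zero variance")
    stats = NormStats(
        x_mean=x_mean, x_sd=x_sd, u_mean=u_mean, u_sd=u_sd,
        y_mean=y_mean, y_sd=y_sd,
    )
    return apply_norm_stats(ds, stats)


def apply_norm_stats(ds: BeatDataset, stats: NormStats) -> BeatDataset:
    """Standardize ``ds`` with externally supplied statistics."""
    if ds.standardized:
        raise DegenerateChannelError("dataset is already standardized")
    out = ds.copy()
    out.waveforms = (ds.waveforms - stats.x_mean) / stats.x_sd
    out.features = (ds.features - stats.u_mean) / stats.u_sd
    if ds.labels is not None:
        out.labels = stats.standardize_y(ds.labels)
    out.standardized = True
    out.norm_stats = stats
    return out


def destandardize(ds: BeatDataset) -> BeatDataset:
    """Invert :func:`standardize` using the recorded statistics."""
    if not ds.standardized or ds.norm_stats is None:
        raise DegenerateChannelError("dataset is not standardized")
    st = ds.norm_stats
    out = ds.copy()
    out.waveforms = ds.waveforms * st.x_sd + st.x_mean
    out.features = ds.features * st.u_sd + st.u_mean
    if ds.labels is not None:
        out.labels = st.destandardize_y(ds.labels)
    out.standardized = False
    out.norm_stats = None
    return out


def preprocess_recording(
    rec: RawRecording,
    target_rate: float = 30.0,
    pad_len: int = 60,
    smooth_window: int = 3,
    smooth_overlap: int = 1,
    label_name: str = "SBP",
    on_fiducial_error: str = "raise",
) -> BeatDataset:
    """Run the full chain: normalize, segment, features, resample, smooth.

    Returns an *unstandardized* :class:`BeatDataset`; call
    :func:`standardize` before model training. ``on_fiducial_error`` may be
    ``"raise"`` (default) or ``"drop"`` to discard undetectable beats.
    """
    if on_fiducial_error not in ("raise", "drop"):
        raise InvalidWindowError(
            f"on_fiducial_error must be 'raise' or 'drop', got {on_fiducial_error!r}"
        )
    rec = normalize_delta_z(rec)
    if rec.beat_boundaries is None:
        rec = replace(rec, beat_boundaries=detect_beat_boundaries(rec))
    beats = segment_beats(rec)
    wf, feat, dur, t0, sess, lab = [], [], [], [], [], []
    have_labels = all(b.y_true is not None for b in beats)
    for b in beats:
        try:
            fids = extract_fiducials(b)
            u = compute_features(fids, b)
        except FiducialDetectionError:
            if on_fiducial_error == "drop":
                continue
            raise
        padded = resample_and_pad(b, target_rate=target_rate, pad_len=pad_len)
        wf.append(padded.x)
        feat.append(u.as_array())
        dur.append(b.duration)
        t0.append(b.t_start)
        sess.append(b.session_id)
        if have_labels:
            lab.append(b.y_true)
    if not wf:
        raise FiducialDetectionError("no beat survived fiducial extraction")
    ds = BeatDataset(
        waveforms=np.array(wf),
        features=np.array(feat),
        durations=np.array(dur),
        t_start=np.array(t0),
        session_ids=np.array(sess),
        sample_rate=target_rate,
        labels=np.array(lab) if have_labels else None,
        label_name=label_name,
    )
    if smooth_window > 1:
        ds = moving_average_smooth(ds, window=smooth_window, overlap=smooth_overlap)
    return ds
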