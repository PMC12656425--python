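"""Acoustic biomarker extraction from sustained phonation.

Implements the classical MDVP/Praat-style perturbation measures:

* fundamental-frequency statistics (Fo, Fhi, Flo) from per-cycle periods,
* jitter (local %, absolute, RAP, PPQ5) from the period sequence
  ``Jitter_local = 100/(N-1) * sum |T_i - T_{i+1}| / T_i``,
* shimmer (local, dB, APQ3) from per-cycle peak-to-peak amplitudes
  ``Shimmer_local = 1/(N-1) * sum |A_i - A_{i+1}| / A_i``,
* harmonics-to-noise ratio ``HNR = 10 log10(R / (1 - R))`` where R is
  the normalized autocorrelation at the pitch-period lag, and
* mel-frequency cepstral coefficients
  ``MFCC_k = sum_n log(S_n) cos(pi k / M (n - 1/2))`` over M mel-filter
  outputs S_n.

Cycle marks are located at the upward zero crossing preceding each
cycle peak.  This choice matters: a marker placed at any fixed nonzero
phase of the cycle mixes adjacent periods and systematically deflates
jitter, whereas the zero crossing coincides with the cycle boundary.

The module also reads/writes feature tables in the UCI Parkinson's CSV
layout (feature columns + subject id + binary label).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps

from voxfuse.audio import Waveform
from voxfuse.errors import EmptyInputError, NoVoicingError, ValidationError

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class PeriodSequence:
    """Per-cycle periods T_i (s) and their cycle-start times (s)."""

    periods: np.ndarray
    cycle_marks: np.ndarray

    def __post_init__(self) -> None:
        periods = np.asarray(self.periods, dtype=np.float64)
        marks = np.asarray(self.cycle_marks, dtype=np.float64)
        if periods.size and np.any(periods <= 0):
            raise ValidationError("all periods must be positive")
        if marks.size > 1 and np.any(np.diff(marks) <= 0):
            raise ValidationError("cycle marks must be strictly increasing")
        object.__setattr__(self, "periods", periods)
        object.__setattr__(self, "cycle_marks", marks)

    def __len__(self) -> int:
        return self.periods.size


@dataclass(frozen=True)
class AmplitudeSequence:
    """Per-cycle peak-to-peak amplitudes A_i (dimensionless)."""

    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=np.float64)
        if amp.size and np.any(amp <= 0):
            raise ValidationError("all amplitudes must be positive")
        object.__setattr__(self, "amplitudes", amp)

    def __len__(self) -> int:
        return self.amplitudes.size


@dataclass(frozen=True)
class FilterbankEnergies:
    """Per-frame mel-filterbank power outputs S_n (linear scale, floored)."""

    energies: np.ndarray  # (n_frames, M)
    M: int

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=np.float64)
        if e.ndim != 2 or e.shape[1] != self.M:
            raise ValidationError("energies must be (n_frames, M)")
        if np.any(e <= 0):
            raise ValidationError("filterbank energies must be positive after flooring")
        object.__setattr__(self, "energies", e)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, unique feature names defining a biomarker vector layout."""

    name: str
    features: Tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValidationError("schema feature names must be unique")

    def __len__(self) -> int:
        return len(self.features)


#: default audio-extraction schema: 22 features computable from phonation
DEFAULT_SCHEMA = FeatureSchema(
    name="voxfuse-22",
    features=(
        "MDVP:Fo(Hz)", "MDVP:Fhi(Hz)", "MDVP:Flo(Hz)",
        "MDVP:Jitter(%)", "MDVP:Jitter(Abs)", "MDVP:RAP", "MDVP:PPQ5",
        "MDVP:Shimmer", "MDVP:Shimmer(dB)", "Shimmer:APQ3",
        "HNR",
    ) + tuple(f"MFCC{k}" for k in range(1, 12)),
)

#: the published UCI Parkinson's column set, accepted for CSV passthrough
UCI_SCHEMA = FeatureSchema(
    name="uci-parkinsons",
    features=(
        "MDVP:Fo(Hz)", "MDVP:Fhi(Hz)", "MDVP:Flo(Hz)",
        "MDVP:Jitter(%)", "MDVP:Jitter(Abs)", "MDVP:RAP", "MDVP:PPQ",
        "Jitter:DDP", "MDVP:Shimmer", "MDVP:Shimmer(dB)", "Shimmer:APQ3",
        "Shimmer:APQ5", "MDVP:APQ", "Shimmer:DDA", "NHR", "HNR",
        "RPDE", "DFA", "spread1", "spread2", "D2", "PPE",
    ),
)

SCHEMAS = {s.name: s for s in (DEFAULT_SCHEMA, UCI_SCHEMA)}


@dataclass(frozen=True)
class BiomarkerVector:
    """Ordered feature values laid out per a :class:`FeatureSchema`."""

    values: np.ndarray
    schema_id: str = DEFAULT_SCHEMA.name

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(v)):
            raise ValidationError("biomarker vector contains non-finite values")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class StandardizationStats:
    """Per-feature z-score statistics fitted on a training set."""

    mean: np.ndarray
    std: np.ndarray
    fitted: bool = False


# --------------------------------------------------------------------------
# period / amplitude extraction

_VOICING_THRESHOLD = 0.3
_FRAME_S = 0.040
_HOP_S = 0.010


def _normalized_autocorr_peak(
    frame: np.ndarray, lag_min: int, lag_max: int, oversample: int = 8
) -> Tuple[float, float]:
    """(best fractional lag in samples, normalized autocorrelation there).

    The autocorrelation is computed by FFT and oversampled in lag by
    zero-padding the power spectrum (exact band-limited interpolation),
    then corrected for the rectangular-window taper ``(1 - lag/N)``.
    """
    n = frame.size
    x = frame - np.mean(frame)
    power = float(np.dot(x, x))
    if power <= 0:
        return 0.0, 0.0
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.abs(np.fft.rfft(x, nfft)) ** 2
    acf_fine = np.fft.irfft(spec, nfft * oversample) * oversample
    acf0 = acf_fine[0]
    lags = np.arange(int(lag_min * oversample), int(lag_max * oversample) + 1)
    lags = lags[(lags > 0) & (lags < acf_fine.size // 2)]
    if lags.size == 0:
        return 0.0, 0.0
    frac_lags = lags / oversample
    taper = 1.0 - frac_lags / n
    vals = acf_fine[lags] / acf0 / np.maximum(taper, 1e-6)
    vmax = float(np.max(vals))
    if vmax <= 0:
        return 0.0, 0.0
    # octave-robust: take the first contiguous run of near-maximum values
    # (the true period lag; integer multiples score equally high)
    near = np.flatnonzero(vals >= 0.9 * vmax)
    run_end = near[0]
    while run_end + 1 < vals.size and vals[run_end + 1] >= 0.9 * vmax:
        run_end += 1
    run = slice(near[0], run_end + 1)
    best = near[0] + int(np.argmax(vals[run]))
    return float(frac_lags[best]), float(min(vals[best], 1.0))


def _voiced_frames(
    samples: np.ndarray, rate: int, f0_min: float, f0_max: float
) -> List[Tuple[int, float, float]]:
    """Frame-wise pitch candidates: (frame start sample, lag s, r)."""
    n_frame = int(round(_FRAME_S * rate))
    n_hop = int(round(_HOP_S * rate))
    lag_min = max(2, int(np.floor(rate / f0_max)))
    lag_max = int(np.ceil(rate / f0_min))
    n_frame = max(n_frame, 2 * lag_max)  # at least two periods per frame
    out = []
    for start in range(0, max(samples.size - n_frame + 1, 1), n_hop):
        frame = samples[start : start + n_frame]
        if frame.size < n_frame:
            break
        lag, r = _normalized_autocorr_peak(frame, lag_min, lag_max)
        if r >= _VOICING_THRESHOLD and lag > 0:
            out.append((start, lag / rate, r))
    return out


def extract_period_sequence(
    w: Waveform, f0_min: float = 50.0, f0_max: float = 500.0
) -> PeriodSequence:
    """Locate glottal cycles and return the per-cycle period sequence.

    Frame-wise normalized autocorrelation restricted to
    ``[1/f0_max, 1/f0_min]`` gives a coarse period; cycle marks are then
    refined to the upward zero crossing preceding each waveform peak,
    with linear sub-sample interpolation of the crossing time.
    """
    if f0_min >= f0_max:
        raise ValidationError("f0_min must be < f0_max")
    if len(w) == 0:
        raise EmptyInputError("empty waveform")
    voiced = _voiced_frames(w.samples, w.rate, f0_min, f0_max)
    if not voiced:
        raise NoVoicingError("no voiced frames found")
    period_med = float(np.median([p for _, p, _ in voiced]))
    lag_med = period_med * w.rate

    x = w.samples
    peaks, _ = sps.find_peaks(
        x, distance=max(2, int(0.7 * lag_med)), height=0.25 * float(np.max(x))
    )
    if peaks.size < 3:
        raise NoVoicingError("too few cycle peaks for period extraction")

    marks: List[float] = []
    for pk in peaks:
        # walk back from the peak to the preceding non-positive sample
        i = pk
        lo = max(0, pk - int(1.2 * lag_med))
        while i > lo and x[i] > 0:
            i -= 1
        if x[i] > 0:
            continue  # no crossing inside one period: skip
        # upward crossing between i and i+1
        denom = x[i + 1] - x[i]
        fracpos = -x[i] / denom if denom != 0 else 0.0
        t = (i + fracpos) / w.rate
        if not marks or t - marks[-1] > 0.3 * period_med:
            marks.append(t)

    marks_arr = np.asarray(marks)
    periods = np.diff(marks_arr)
    keep = (periods >= 1.0 / f0_max) & (periods <= 1.0 / f0_min)
    periods = periods[keep]
    if periods.size < 2:
        raise NoVoicingError("fewer than two valid glottal cycles found")
    return PeriodSequence(periods=periods, cycle_marks=marks_arr)


def extract_amplitude_sequence(w: Waveform, p: PeriodSequence) -> AmplitudeSequence:
    """Per-cycle peak-to-peak amplitudes between consecutive cycle marks."""
    amps = []
    marks = p.cycle_marks
    for t0, t1 in zip(marks[:-1], marks[1:]):
        i0, i1 = int(round(t0 * w.rate)), int(round(t1 * w.rate))
        if i1 - i0 < 2:
            continue
        seg = w.samples[i0:i1]
        amps.append(float(seg.max() - seg.min()))
    arr = np.asarray(amps)
    arr = arr[arr > 0]
    if arr.size < 2:
        raise NoVoicingError("too few cycles for amplitude extraction")
    return AmplitudeSequence(amplitudes=arr)


# --------------------------------------------------------------------------
# perturbation measures

def f0_statistics(p: PeriodSequence) -> Tuple[float, float, float]:
    """(Fo, Fhi, Flo): mean, max and min of the per-cycle frequencies 1/T_i."""
    if len(p) < 1:
        raise EmptyInputError("empty period sequence")
    freqs = 1.0 / p.periods
    return float(np.mean(freqs)), float(np.max(freqs)), float(np.min(freqs))


def jitter_features(p: PeriodSequence) -> Tuple[float, float, float, float]:
    """(jitter_local_pct, jitter_abs_s, rap, ppq5).

    ``jitter_local_pct = 100/(N-1) * sum_{i=1}^{N-1} |T_i - T_{i+1}| / T_i``;
    RAP and PPQ5 are the 3- and 5-point period perturbation quotients
    (deviation from the moving average, relative to the mean period).
    """
    T = p.periods
    n = T.size
    if n < 2:
        raise ValidationError("jitter requires at least 2 periods")
    diffs = np.abs(np.diff(T))
    jitter_local_pct = float(np.mean(diffs / T[:-1]) * 100.0)
    jitter_abs_s = float(np.mean(diffs))

    rap = _perturbation_quotient(T, 3) if n >= 3 else 0.0
    if n < 3:
        raise ValidationError("RAP requires at least 3 periods")
    if n < 5:
        raise ValidationError("PPQ5 requires at least 5 periods")
    ppq5 = _perturbation_quotient(T, 5)
    return jitter_local_pct, jitter_abs_s, rap, ppq5


def _perturbation_quotient(x: np.ndarray, window: int) -> float:
    """Mean |x_i - w-point moving average| / mean(x)."""
    half = window // 2
    n = x.size
    devs = []
    for i in range(half, n - half):
        win = x[i - half : i + half + 1]
        # exact zero on constant windows (no fp residue from the mean)
        devs.append(0.0 if np.ptp(win) == 0 else abs(x[i] - np.mean(win)))
    return float(np.mean(devs) / np.mean(x))


def shimmer_features(a: AmplitudeSequence) -> Tuple[float, float, float]:
    """(shimmer_local, shimmer_db, apq3).

    ``shimmer_local = 1/(N-1) * sum |A_i - A_{i+1}| / A_i``;
    ``shimmer_db = mean |20 log10(A_{i+1}/A_i)|``; APQ3 is the 3-point
    amplitude perturbation quotient.
    """
    A = a.amplitudes
    n = A.size
    if n < 2:
        raise ValidationError("shimmer requires at least 2 amplitudes")
    diffs = np.abs(np.diff(A))
    shimmer_local = float(np.mean(diffs / A[:-1]))
    shimmer_db = float(np.mean(np.abs(20.0 * np.log10(A[1:] / A[:-1]))))
    if n < 3:
        raise ValidationError("APQ3 requires at least 3 amplitudes")
    apq3 = _perturbation_quotient(A, 3)
    return shimmer_local, shimmer_db, apq3


def hnr_from_r(r: float) -> float:
    """Closed-form HNR (dB) from the normalized autocorrelation R."""
    r = min(max(r, 1e-12), 1.0 - 1e-12)
    return 10.0 * math.log10(r / (1.0 - r))


def harmonics_to_noise_ratio(w: Waveform, p: PeriodSequence) -> float:
    """Mean per-frame HNR (dB) at the pitch-period lag.

    Per voiced frame, the normalized autocorrelation R is evaluated at
    the frame's own pitch-period lag (band-limited fractional-lag
    interpolation) and converted via ``10 log10(R / (1 - R))``; frame
    values are averaged in dB over voiced frames.
    """
    if len(p) < 1:
        raise NoVoicingError("no period estimate for HNR")
    period_med = float(np.median(p.periods))
    f0_est = 1.0 / period_med
    voiced = _voiced_frames(w.samples, w.rate, 0.7 * f0_est, 1.4 * f0_est)
    if not voiced:
        raise NoVoicingError("no voiced frames for HNR")
    vals = [hnr_from_r(r) for _, _, r in voiced]
    return float(np.mean(vals))


# --------------------------------------------------------------------------
# MFCC

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(
    n_filters: int = 26, n_fft: int = 512, rate: int = 16000,
    f_min: float = 0.0, f_max: Optional[float] = None,
) -> np.ndarray:
    """Triangular mel filterbank, (n_filters, n_fft//2 + 1)."""
    f_max = f_max or rate / 2.0
    mel_pts = np.linspace(_hz_to_mel(f_min), _hz_to_mel(f_max), n_filters + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.floor((n_fft + 1) * hz_pts / rate).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for m in range(1, n_filters + 1):
        left, center, right = bins[m - 1], bins[m], bins[m + 1]
        if center == left:
            center += 1
        if right == center:
            right += 1
        for k in range(left, center):
            fb[m - 1, k] = (k - left) / (center - left)
        for k in range(center, min(right, fb.shape[1])):
            fb[m - 1, k] = (right - k) / (right - center)
    return fb


def mel_filterbank_energies(
    w: Waveform, n_filters: int = 26, n_fft: int = 512,
    frame_len: float = 0.025, hop_len: float = 0.010, floor: float = 1e-10,
) -> FilterbankEnergies:
    """Per-frame mel-filterbank power outputs of a waveform."""
    n_frame = int(round(frame_len * w.rate))
    n_hop = int(round(hop_len * w.rate))
    if len(w) < n_frame:
        raise ValidationError("signal shorter than one analysis frame")
    window = np.hanning(n_frame)
    n_frames = 1 + (len(w) - n_frame) // n_hop
    idx = np.arange(n_frame)[None, :] + n_hop * np.arange(n_frames)[:, None]
    frames = w.samples[idx] * window
    spec = np.abs(np.fft.rfft(frames, n_fft, axis=1)) ** 2
    fb = mel_filterbank(n_filters, n_fft, w.rate)
    energies = np.maximum(spec @ fb.T, floor)
    return FilterbankEnergies(energies=energies, M=n_filters)


def mel_cepstral_coefficients(fb: FilterbankEnergies, K: int = 13) -> np.ndarray:
    """MFCC_k = sum_{n=1..M} log(S_n) cos(pi k / M (n - 1/2)), k = 1..K.

    Computed per frame and averaged over frames; returns K coefficients.
    """
    if K >= fb.M:
        raise ValidationError(f"K={K} must be < M={fb.M}")
    M = fb.M
    n = np.arange(1, M + 1)
    k = np.arange(1, K + 1)
    basis = np.cos(np.pi * np.outer(k, (n - 0.5)) / M)  # (K, M)
    per_frame = np.log(fb.energies) @ basis.T           # (n_frames, K)
    return per_frame.mean(axis=0)


# --------------------------------------------------------------------------
# assembly and standardization

def assemble_biomarker_vector(
    w: Waveform, schema: FeatureSchema = DEFAULT_SCHEMA,
    f0_min: float = 50.0, f0_max: float = 500.0,
) -> BiomarkerVector:
    """Run the full extraction chain and order features per ``schema``."""
    p = extract_period_sequence(w, f0_min, f0_max)
    a = extract_amplitude_sequence(w, p)
    fo, fhi, flo = f0_statistics(p)
    jit_pct, jit_abs, rap, ppq5 = jitter_features(p)
    shim, shim_db, apq3 = shimmer_features(a)
    hnr = harmonics_to_noise_ratio(w, p)
    mfcc = mel_cepstral_coefficients(mel_filterbank_energies(w), K=13)

    available = {
        "MDVP:Fo(Hz)": fo, "MDVP:Fhi(Hz)": fhi, "MDVP:Flo(Hz)": flo,
        "MDVP:Jitter(%)": jit_pct, "MDVP:Jitter(Abs)": jit_abs,
        "MDVP:RAP": rap, "MDVP:PPQ5": ppq5,
        "MDVP:Shimmer": shim, "MDVP:Shimmer(dB)": shim_db,
        "Shimmer:APQ3": apq3, "HNR": hnr,
    }
    for i, c in enumerate(mfcc, start=1):
        available[f"MFCC{i}"] = float(c)

    values = []
    for name in schema.features:
        if name not in available:
            raise ValidationError(
                f"schema {schema.name!r} requires feature {name!r}, which the "
                "audio extraction chain does not compute"
            )
        values.append(available[name])
    return BiomarkerVector(values=np.asarray(values), schema_id=schema.name)


def fit_standardization(table: np.ndarray) -> StandardizationStats:
    """Fit per-feature z-score statistics (population sd) on training rows."""
    table = np.asarray(table, dtype=np.float64)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValidationError("standardization needs a 2-D table with >= 2 rows")
    mean = table.mean(axis=0)
    std = table.std(axis=0)  # population (divide-by-N) convention
    if np.any(std == 0):
        logger.warning(
            "%d constant feature column(s): standardized values set to 0",
            int(np.sum(std == 0)),
        )
    return StandardizationStats(mean=mean, std=std, fitted=True)


def apply_standardization(
    v: BiomarkerVector | np.ndarray, s: StandardizationStats
) -> BiomarkerVector | np.ndarray:
    """z = (x - mu) / sigma per feature; constant features map to 0."""
    if not s.fitted:
        raise ValidationError("apply_standardization called before fit")
    x = v.values if isinstance(v, BiomarkerVector) else np.asarray(v, dtype=np.float64)
    safe_std = np.where(s.std == 0, 1.0, s.std)
    z = (x - s.mean) / safe_std
    z = np.where(s.std == 0, 0.0, z)
    if isinstance(v, BiomarkerVector):
        return BiomarkerVector(values=z, schema_id=v.schema_id)
    return z


# --------------------------------------------------------------------------
# UCI-layout CSV I/O

def read_feature_table(
    path, schema: Optional[FeatureSchema] = None,
    id_col: str = "name", label_col: str = "status",
) -> pd.DataFrame:
    """Read a UCI-layout feature CSV; rows with missing/non-numeric cells
    in feature columns are dropped with a logged count."""
    df = pd.read_csv(path, float_precision="round_trip")
    if schema is None:
        feat_cols = [c for c in df.columns if c not in (id_col, label_col)]
    else:
        missing = [c for c in schema.features if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing feature columns {missing}")
        feat_cols = list(schema.features)
    coerced = df[feat_cols].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    if bad.any():
        logger.warning("dropped %d row(s) with missing/non-numeric values", int(bad.sum()))
    df = df.loc[~bad].copy()
    df[feat_cols] = coerced.loc[~bad]
    if label_col in df.columns:
        labels = set(df[label_col].unique())
        if not labels <= {0, 1}:
            raise ValidationError(f"{path}: labels must be binary 0/1, got {labels}")
    return df.reset_index(drop=True)


def write_feature_table(df: pd.DataFrame, path) -> None:
    """Write a feature table as CSV (full float precision round-trips)."""
    df.to_csv(path, index=False, float_format="%.17g")
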