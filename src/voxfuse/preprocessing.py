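"""Audio preprocessing: resampling, energy VAD, spectral gating, duration fitting.

The pipeline mirrors what is standard practice for speech-embedding
front-ends: band-limited resampling to 16 kHz, energy-based voice
activity detection to drop silence, an optional STFT soft-mask gate
against stationary background noise, and normalisation plus tail
padding/truncation to a fixed duration so batches can be formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import List, Tuple

import numpy as np
from scipy import signal as sps

from voxfuse.audio import Waveform
from voxfuse.errors import EmptyInputError, NoVoicingError, ValidationError


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``vad_threshold_db`` is relative to the loudest frame: a frame is
    active when its RMS energy in dB is above ``peak + vad_threshold_db``
    (the threshold is therefore negative).  ``gate_offset`` scales the
    per-bin noise-floor deviation used by the spectral gate.
    """

    target_rate: int = 16000
    frame_len: float = 0.030        # s, VAD analysis window
    hop_len: float = 0.010          # s, VAD hop
    vad_threshold_db: float = -40.0  # dB relative to peak frame energy
    gate_enabled: bool = False       # default off for sustained phonation
    gate_offset: float = 1.5         # multiplier on noise-floor std
    max_duration: float = 30.0       # s
    standardize: bool = True
    min_active_frames: int = 3       # VAD runs shorter than this are dropped

    def __post_init__(self) -> None:
        if not (0 < self.hop_len <= self.frame_len):
            raise ValidationError(
                f"hop_len must satisfy 0 < hop_len <= frame_len "
                f"(hop_len={self.hop_len}, frame_len={self.frame_len})"
            )
        if self.max_duration <= 0:
            raise ValidationError(f"max_duration must be > 0, got {self.max_duration}")
        if self.target_rate <= 0:
            raise ValidationError(f"target_rate must be > 0, got {self.target_rate}")


@dataclass(frozen=True)
class SegmentList:
    """Sorted, non-overlapping half-open [start_s, end_s) intervals."""

    segments: Tuple[Tuple[float, float], ...]

    def __post_init__(self) -> None:
        prev_end = 0.0
        for start, end in self.segments:
            if start < 0 or end <= start:
                raise ValidationError(f"invalid segment ({start}, {end})")
            if start < prev_end:
                raise ValidationError("segments must be sorted and non-overlapping")
            prev_end = end

    def __len__(self) -> int:
        return len(self.segments)

    def total_duration(self) -> float:
        return sum(end - start for start, end in self.segments)


def resample(w: Waveform, target_rate: int) -> Waveform:
    """Band-limited polyphase resampling to ``target_rate``.

    Duration is preserved to within one sample period of the coarser
    rate; a rational up/down factor pair is derived from the two rates.
    """
    if len(w) == 0:
        raise EmptyInputError("cannot resample an empty waveform")
    if target_rate <= 0:
        raise ValidationError(f"target_rate must be > 0, got {target_rate}")
    if target_rate == w.rate:
        return Waveform(w.samples.copy(), w.rate)
    frac = Fraction(target_rate, w.rate).limit_denominator(1000)
    out = sps.resample_poly(w.samples, frac.numerator, frac.denominator)
    return Waveform(out, target_rate)


def _frame_rms(samples: np.ndarray, rate: int, cfg: PreprocessConfig) -> np.ndarray:
    """Per-frame RMS energy; frames of frame_len every hop_len seconds."""
    n_frame = max(1, int(round(cfg.frame_len * rate)))
    n_hop = max(1, int(round(cfg.hop_len * rate)))
    if samples.size < n_frame:
        # a single partial frame
        return np.array([np.sqrt(np.mean(samples**2))]) if samples.size else np.array([])
    n_frames = 1 + (samples.size - n_frame) // n_hop
    idx = np.arange(n_frame)[None, :] + n_hop * np.arange(n_frames)[:, None]
    frames = samples[idx]
    return np.sqrt(np.mean(frames**2, axis=1))


def detect_voice_activity(w: Waveform, cfg: PreprocessConfig) -> SegmentList:
    """Energy-based VAD relative to the loudest frame.

    Frames whose RMS energy exceeds ``peak_db + vad_threshold_db`` are
    active; adjacent active frames are merged and runs shorter than
    ``min_active_frames`` frames are discarded.  Digital silence yields
    an empty list.
    """
    rms = _frame_rms(w.samples, w.rate, cfg)
    if rms.size == 0 or np.max(rms) <= 0:
        return SegmentList(())
    db = 20.0 * np.log10(np.maximum(rms, 1e-12))
    active = db > (np.max(db) + cfg.vad_threshold_db)

    segments: List[Tuple[float, float]] = []
    n_hop = max(1, int(round(cfg.hop_len * w.rate)))
    n_frame = max(1, int(round(cfg.frame_len * w.rate)))
    run_start = None
    for i, flag in enumerate(active):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= cfg.min_active_frames:
                segments.append((run_start, i - 1))
            run_start = None
    if run_start is not None and len(active) - run_start >= cfg.min_active_frames:
        segments.append((run_start, len(active) - 1))

    out = []
    for first, last in segments:
        start_s = first * n_hop / w.rate
        end_s = min((last * n_hop + n_frame) / w.rate, w.duration)
        if out and start_s <= out[-1][1]:
            out[-1] = (out[-1][0], end_s)  # merge touching segments
        else:
            out.append((start_s, end_s))
    return SegmentList(tuple(out))


def spectral_gate(w: Waveform, cfg: PreprocessConfig) -> Waveform:
    """Suppress stationary noise with a soft STFT magnitude mask.

    The noise floor is estimated per frequency bin from the
    lowest-energy decile of frames; bins below
    ``thr = floor_mean + gate_offset * floor_std`` are silenced and bins
    above it pass through a soft linear ramp reaching unity at
    ``2.5 thr``, so gains stay in [0, 1] and total energy never
    increases.  The estimator assumes the noise is stationary and
    present in the quiet frames (pauses); a signal with no pauses has no
    observable noise floor.
    """
    n_frame = max(2, int(round(cfg.frame_len * w.rate)))
    if len(w) < n_frame:
        raise ValidationError(
            f"signal of {len(w)} samples is shorter than one STFT frame ({n_frame})"
        )
    if not np.any(w.samples):
        return Waveform(w.samples.copy(), w.rate)

    n_hop = max(1, int(round(cfg.hop_len * w.rate)))
    nfft = int(2 ** np.ceil(np.log2(n_frame)))
    win = sps.get_window("hann", n_frame)
    stft = sps.ShortTimeFFT(win, hop=n_hop, fs=w.rate, mfft=nfft)
    Z = stft.stft(w.samples)
    mag = np.abs(Z)

    frame_energy = np.sum(mag**2, axis=0)
    k = max(1, int(np.ceil(0.1 * frame_energy.size)))
    quiet = np.argsort(frame_energy)[:k]
    floor_mean = np.mean(mag[:, quiet], axis=1, keepdims=True)
    floor_std = np.std(mag[:, quiet], axis=1, keepdims=True)

    thr = floor_mean + cfg.gate_offset * floor_std
    gain = np.clip((mag - thr) / (1.5 * thr + 1e-12), 0.0, 1.0)
    out = stft.istft(Z * gain, k1=len(w))
    return Waveform(np.asarray(out[: len(w)], dtype=np.float64), w.rate)


def normalize_and_fit_duration(w: Waveform, cfg: PreprocessConfig) -> Waveform:
    """Standardize the signal and pad/truncate the tail to ``max_duration``.

    Standardization statistics are computed on the pre-pad region only;
    the zero pad stays exactly zero.
    """
    if len(w) == 0:
        raise EmptyInputError("cannot normalize an empty waveform")
    n_target = int(round(cfg.max_duration * w.rate))
    content = w.samples[:n_target].copy()
    if cfg.standardize:
        sd = float(np.std(content))
        if sd == 0.0:
            if np.any(content):
                raise ValidationError(
                    "zero-variance non-silent region cannot be standardized"
                )
            # pure silence: leave as zeros
        else:
            content = (content - float(np.mean(content))) / sd
    out = np.zeros(n_target, dtype=np.float64)
    out[: content.size] = content
    return Waveform(out, w.rate)


def _concatenate_active(w: Waveform, segs: SegmentList) -> Waveform:
    parts = []
    for start_s, end_s in segs.segments:
        i0 = int(round(start_s * w.rate))
        i1 = int(round(end_s * w.rate))
        parts.append(w.samples[i0:i1])
    if not parts:
        raise NoVoicingError("no active speech found by VAD")
    return Waveform(np.concatenate(parts), w.rate)


def preprocess_audio(raw: Waveform, cfg: PreprocessConfig) -> Waveform:
    """Full chain: resample -> VAD -> (gate) -> normalize & fit duration."""
    if len(raw) == 0:
        raise EmptyInputError("cannot preprocess an empty waveform")
    w = resample(raw, cfg.target_rate)
    segs = detect_voice_activity(w, cfg)
    w = _concatenate_active(w, segs)
    if cfg.gate_enabled:
        w = spectral_gate(w, cfg)
    return normalize_and_fit_duration(w, cfg)
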