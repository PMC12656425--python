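"""Waveform container and RIFF WAV I/O.

Audio is held as a 1-D float array (nominally in [-1, 1]) plus a sample
rate.  Files are read and written with :mod:`scipy.io.wavfile`; both the
16-bit PCM and 32-bit float dialects are supported.  Multi-channel input
is rejected: the toolkit models mono phonation recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

from voxfuse.errors import EmptyInputError, ValidationError

_PCM16_SCALE = 32768.0


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal.

    Parameters
    ----------
    samples:
        1-D float array of amplitudes, dimensionless, nominally in [-1, 1].
    rate:
        Sampling rate in Hz (samples per second).
    """

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValidationError(
                f"waveform samples must be 1-D (mono); got shape {samples.shape}"
            )
        if self.rate <= 0:
            raise ValidationError(f"sample rate must be positive, got {self.rate}")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValidationError("waveform contains NaN or Inf samples")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.rate

    def __len__(self) -> int:
        return self.samples.size


def read_wav(path) -> Waveform:
    """Read a mono RIFF WAV file (PCM16 or float32) into a :class:`Waveform`."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValidationError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _PCM16_SCALE
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    else:
        raise ValidationError(f"{path}: unsupported WAV sample format {data.dtype}")
    return Waveform(samples=samples, rate=int(rate))


def write_wav(path, w: Waveform, dtype: str = "float32") -> None:
    """Write a :class:`Waveform` as mono WAV (``float32`` or ``pcm16``)."""
    if len(w) == 0:
        raise EmptyInputError("refusing to write an empty waveform")
    if dtype == "float32":
        wavfile.write(path, w.rate, w.samples.astype(np.float32))
    elif dtype == "pcm16":
        clipped = np.clip(w.samples, -1.0, 1.0 - 1.0 / _PCM16_SCALE)
        wavfile.write(path, w.rate, (clipped * _PCM16_SCALE).astype(np.int16))
    else:
        raise ValidationError(f"unsupported WAV dtype {dtype!r}")
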