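"""Mono WAV reading/writing and resampling helpers.

Integer PCM samples are mapped to floats in [-1, 1) by dividing by the
full-scale value of the bit depth, so a write/read round trip at a
given depth reproduces the quantized waveform exactly.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly


class AudioError(ValueError):
    pass


_INT_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def read_wav(path, channel: int | None = None) -> tuple[np.ndarray, int]:
    """Read a WAV file as float64 in [-1, 1], returning (waveform, rate).

    Multi-channel files are refused unless ``channel`` selects one.
    16/24/32-bit PCM and float WAVs are supported (24-bit arrives as
    int32 from the reader and is scaled accordingly).
    """
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        if channel is None:
            raise AudioError(
                f"{path} has {data.shape[1]} channels; select one with "
                "the channel option"
            )
        data = data[:, channel]
    elif channel not in (None, 0):
        raise AudioError(f"{path} is mono; channel {channel} does not exist")
    if data.dtype in _INT_SCALE:
        x = data.astype(np.float64) / _INT_SCALE[data.dtype]
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:
        x = data.astype(np.float64)
    return x, int(rate)


def write_wav(path, waveform, sample_rate_hz: int, bit_depth: int = 16) -> None:
    """Write a float waveform as integer PCM (16- or 32-bit) or float32."""
    x = np.asarray(waveform, dtype=np.float64)
    if bit_depth == 16:
        q = np.clip(np.round(x * 2**15), -(2**15), 2**15 - 1).astype(np.int16)
    elif bit_depth == 32:
        q = np.clip(np.round(x * 2**31), -(2**31), 2**31 - 1).astype(np.int32)
    elif bit_depth == 0:  # float32 passthrough
        q = x.astype(np.float32)
    else:
        raise AudioError(f"unsupported bit depth {bit_depth}")
    wavfile.write(path, int(sample_rate_hz), q)


def quantize(waveform, bit_depth: int = 16) -> np.ndarray:
    """Snap a float waveform onto the integer-PCM grid used by write_wav."""
    if bit_depth == 0:
        return np.asarray(waveform, dtype=np.float32).astype(np.float64)
    scale = 2 ** (bit_depth - 1)
    x = np.asarray(waveform, dtype=np.float64)
    return np.clip(np.round(x * scale), -scale, scale - 1) / scale


def resample_to(waveform, rate_hz: int, target_hz: int) -> np.ndarray:
    """Polyphase resampling to a common analysis rate."""
    if rate_hz == target_hz:
        return np.asarray(waveform, dtype=np.float64)
    frac = Fraction(int(target_hz), int(rate_hz))
    return resample_poly(np.asarray(waveform, dtype=np.float64),
                         frac.numerator, frac.denominator)
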