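"""Spectrograms and normalized spectrogram cross-correlation.

The similarity score between two calls is the Pearson correlation between
their spectrogram matrices computed over the overlapping time frames
(all frequency bins of the overlap flattened into one sample), maximized
over integer frame lags.  A score of 1 means the two sonograms are
identical; 0 means no similarity.  The lag search, overlap rule and
normalization are documented contracts (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import get_window


class SpectroError(ValueError):
    """Base class for spectrogram-domain validation errors."""


class TooShortError(SpectroError):
    """Waveform shorter than a single analysis window."""


class GeometryError(SpectroError):
    """Two spectrograms do not share frequency geometry."""


class NoAdmissibleLagError(SpectroError):
    """No lag satisfies the minimum-overlap requirement."""


@dataclass(frozen=True)
class Spectrogram:
    """Time-frequency magnitude matrix with its analysis geometry.

    ``magnitudes`` has one row per frequency bin (``fft_size // 2 + 1``
    for a full-band transform, fewer after band-limiting) and one column
    per analysis frame.  ``f_min_hz`` is the center frequency of the
    first retained bin (0 for a full-band spectrogram).
    """

    magnitudes: np.ndarray
    freq_bin_hz: float
    time_step_s: float
    fft_size: int
    sample_rate_hz: float
    window_name: str = "hamming"
    f_min_hz: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitudes, dtype=float)
        if m.ndim != 2:
            raise SpectroError("magnitudes must be a 2-D matrix")
        if not np.all(np.isfinite(m)):
            raise SpectroError("magnitudes must be finite")
        if np.any(m < 0):
            raise SpectroError("magnitudes must be nonnegative")
        if self.time_step_s <= 0:
            raise SpectroError("time_step_s must be positive")
        object.__setattr__(self, "magnitudes", m)

    @property
    def n_bins(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[1]

    @property
    def frequencies_hz(self) -> np.ndarray:
        """Center frequency of each retained bin."""
        return self.f_min_hz + self.freq_bin_hz * np.arange(self.n_bins)

    @property
    def frame_times_s(self) -> np.ndarray:
        """Start time of each frame; consecutive frames differ by time_step_s."""
        return self.time_step_s * np.arange(self.n_frames)


@dataclass(frozen=True)
class XcorrScore:
    """Maximum-over-lag spectrogram correlation.

    ``undefined`` is set when every admissible lag has a zero-variance
    overlap (e.g. silence against silence); ``value`` is NaN in that
    case and must never be read as 0.
    """

    value: float
    best_lag_frames: int
    overlap_frames: int
    undefined: bool = False


def compute_spectrogram(
    waveform,
    sample_rate_hz: float,
    fft_size: int = 256,
    time_step_s: float = 0.003,
    window: str = "hamming",
    peak_normalize: bool = False,
    magnitude: str = "linear",
) -> Spectrogram:
    """Short-time Fourier magnitude spectrogram.

    Frames start at sample 0 and advance by ``hop = round(time_step_s *
    sample_rate_hz)`` samples; only complete windows are transformed, so
    the waveform must hold at least one full window.  ``magnitude`` may
    be ``"linear"`` (default; keeps the 0-for-no-similarity anchor of
    the correlation score meaningful) or ``"db"``.
    """
    x = np.asarray(waveform, dtype=float).squeeze()
    if x.ndim != 1:
        raise SpectroError("waveform must be mono (1-D)")
    if not np.all(np.isfinite(x)):
        raise SpectroError("waveform contains non-finite samples")
    if sample_rate_hz <= 0:
        raise SpectroError("sample_rate_hz must be positive")
    if fft_size < 2:
        raise SpectroError("fft_size must be >= 2")
    if x.size < fft_size:
        raise TooShortError(
            f"waveform of {x.size} samples is shorter than one "
            f"{fft_size}-sample analysis window"
        )
    hop = int(round(time_step_s * sample_rate_hz))
    if hop < 1:
        raise SpectroError("time step shorter than one sample")
    if peak_normalize:
        peak = np.max(np.abs(x))
        if peak > 0:
            x = x / peak

    win = get_window(window, fft_size, fftbins=True)
    n_frames = 1 + (x.size - fft_size) // hop
    idx = hop * np.arange(n_frames)[:, None] + np.arange(fft_size)[None, :]
    frames = x[idx] * win
    mags = np.abs(np.fft.rfft(frames, axis=1)).T  # bins x frames
    if magnitude == "db":
        mags = 20.0 * np.log10(mags + 1e-12)
        mags -= mags.min()  # keep nonnegativity invariant
    elif magnitude != "linear":
        raise SpectroError(f"unknown magnitude scale {magnitude!r}")
    return Spectrogram(
        magnitudes=mags,
        freq_bin_hz=sample_rate_hz / fft_size,
        time_step_s=hop / sample_rate_hz,
        fft_size=fft_size,
        sample_rate_hz=sample_rate_hz,
        window_name=window,
    )


def band_limit(spec: Spectrogram, f_lo_hz: float, f_hi_hz: float) -> Spectrogram:
    """Restrict a spectrogram to bins with center frequency in [f_lo, f_hi]."""
    nyquist = spec.sample_rate_hz / 2.0
    if not (0 <= f_lo_hz < f_hi_hz <= nyquist):
        raise SpectroError(
            f"band [{f_lo_hz}, {f_hi_hz}] Hz invalid for Nyquist {nyquist} Hz"
        )
    freqs = spec.frequencies_hz
    keep = (freqs >= f_lo_hz) & (freqs <= f_hi_hz)
    if not np.any(keep):
        raise SpectroError("band contains no frequency bins")
    first = int(np.argmax(keep))
    return replace(
        spec,
        magnitudes=spec.magnitudes[keep, :],
        f_min_hz=float(freqs[first]),
    )


class XcorrPlan:
    """Cached FFT-domain transforms of one spectrogram, reusable across
    many pairwise comparisons at a common circular length ``L``."""

    __slots__ = ("n_frames", "n_bins", "L", "fmat", "fsum", "fsq", "fones")

    def __init__(self, spec: Spectrogram, L: int):
        m = spec.magnitudes
        peak = m.max()
        if peak > 0:
            m = m / peak  # scale out amplitude: score is scale-invariant
        self.n_frames = spec.n_frames
        self.n_bins = spec.n_bins
        self.L = L
        self.fmat = np.fft.rfft(m, n=L, axis=1)
        self.fsum = np.fft.rfft(m.sum(axis=0), n=L)
        self.fsq = np.fft.rfft((m * m).sum(axis=0), n=L)
        self.fones = np.fft.rfft(np.ones(self.n_frames), n=L)


def _score_plans(pa: XcorrPlan, pb: XcorrPlan,
                 max_lag_frames: int | None,
                 min_overlap_frac: float) -> XcorrScore:
    ta, tb = pa.n_frames, pb.n_frames
    L = pa.L
    nb = pa.n_bins
    shorter = min(ta, tb)
    if max_lag_frames is None:
        max_lag_frames = shorter
    min_overlap = max(1, int(math.ceil(min_overlap_frac * shorter)))

    # circular cross-correlation at length L >= ta + tb - 1: lag ell >= 0
    # lives at index ell, lag ell < 0 at index L + ell
    lags = np.concatenate([np.arange(0, ta), np.arange(-(tb - 1), 0)])
    pos = np.where(lags >= 0, lags, L + lags)
    overlap = np.minimum(ta, tb + lags) - np.maximum(0, lags)

    admissible = (overlap >= min_overlap) & (np.abs(lags) <= max_lag_frames)
    if not np.any(admissible):
        raise NoAdmissibleLagError(
            f"no lag within +/-{max_lag_frames} frames reaches the "
            f"minimum overlap of {min_overlap} frames"
        )

    s_xy = np.fft.irfft(np.einsum("ij,ij->j", pa.fmat, np.conj(pb.fmat)),
                        n=L)[pos]
    s_x = np.fft.irfft(pa.fsum * np.conj(pb.fones), n=L)[pos]
    s_xx = np.fft.irfft(pa.fsq * np.conj(pb.fones), n=L)[pos]
    s_y = np.fft.irfft(pa.fones * np.conj(pb.fsum), n=L)[pos]
    s_yy = np.fft.irfft(pa.fones * np.conj(pb.fsq), n=L)[pos]

    n_cells = overlap.astype(float) * nb
    num = n_cells * s_xy - s_x * s_y
    var_x = n_cells * s_xx - s_x * s_x
    var_y = n_cells * s_yy - s_y * s_y
    # zero-variance guard: variances are on peak-normalized magnitudes,
    # so an absolute threshold is scale-free
    tol = 1e-10 * n_cells
    defined = admissible & (var_x > tol) & (var_y > tol)
    if not np.any(defined):
        k = np.flatnonzero(admissible)
        k = k[np.lexsort((lags[k], np.abs(lags[k])))][0]
        return XcorrScore(
            value=float("nan"),
            best_lag_frames=int(lags[k]),
            overlap_frames=int(overlap[k]),
            undefined=True,
        )

    r = np.full(lags.size, -np.inf)
    r[defined] = num[defined] / np.sqrt(var_x[defined] * var_y[defined])
    np.clip(r, -1.0, 1.0, out=r)
    best = r.max()
    ties = np.flatnonzero(r >= best - 1e-12)
    k = ties[np.lexsort((lags[ties], np.abs(lags[ties])))][0]
    return XcorrScore(
        value=float(r[k]),
        best_lag_frames=int(lags[k]),
        overlap_frames=int(overlap[k]),
    )


def _check_geometry(a: Spectrogram, b: Spectrogram) -> None:
    if a.n_bins != b.n_bins or not (
        math.isclose(a.freq_bin_hz, b.freq_bin_hz, rel_tol=1e-9)
        and math.isclose(a.f_min_hz, b.f_min_hz, rel_tol=1e-9, abs_tol=1e-6)
        and math.isclose(a.time_step_s, b.time_step_s, rel_tol=1e-9)
    ):
        raise GeometryError(
            "spectrograms differ in frequency band, bin width or time step"
        )


def xcorr_score(
    a: Spectrogram,
    b: Spectrogram,
    max_lag_frames: int | None = None,
    min_overlap_frac: float = 0.5,
) -> XcorrScore:
    """Pearson correlation of overlapping spectrogram columns, maximized
    over frame lag.

    The lag is the number of frames ``b`` is shifted right relative to
    ``a``.  By default the lag search spans +/- the shorter call's frame
    count, and a lag is admissible only if the overlap covers at least
    ``min_overlap_frac`` of the shorter call.  Several lags tying on the
    maximum resolve to the smallest ``|lag|`` (then the smaller lag).
    The score is exactly invariant to uniform amplitude scaling of
    either input.
    """
    if a.n_frames == 0 or b.n_frames == 0:
        raise SpectroError("empty spectrogram")
    _check_geometry(a, b)
    L = a.n_frames + b.n_frames - 1
    return _score_plans(XcorrPlan(a, L), XcorrPlan(b, L),
                        max_lag_frames, min_overlap_frac)


def xcorr_score_many(specs_a, specs_b, max_lag_frames=None,
                     min_overlap_frac: float = 0.5):
    """Score every (a, b) pair of two spectrogram lists, sharing FFT
    plans; numerically equivalent to calling :func:`xcorr_score` pair
    by pair.  Returns a list of lists of XcorrScore."""
    specs_a = list(specs_a)
    specs_b = list(specs_b)
    if not specs_a or not specs_b:
        raise SpectroError("both spectrogram lists must be non-empty")
    for s in specs_a + specs_b:
        _check_geometry(specs_a[0], s)
    L = max(s.n_frames for s in specs_a) + max(s.n_frames for s in specs_b)
    plans_a = [XcorrPlan(s, L) for s in specs_a]
    plans_b = [XcorrPlan(s, L) for s in specs_b]
    return [[_score_plans(pa, pb, max_lag_frames, min_overlap_frac)
             for pb in plans_b] for pa in plans_a]
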