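"""Temporal preprocessing of registered BOLD series.

The chain applied (in this fixed order) before connectivity mapping:

1. discard the first few volumes (scanner equilibration),
2. per-voxel linear detrend followed by an ideal discrete-Fourier band-pass
   (default 0.01–0.08 Hz),
3. global-signal regression: the mask-average time course is removed from
   every in-mask voxel by ordinary least squares.

The band-pass is realized as a DFT mask — coefficients with frequency inside
the closed band are kept, all others zeroed — which is parameter-free and
exactly reproducible. Out-of-mask voxels pass through untouched and never
enter any statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend as _linear_detrend

from .volumeio import BrainMask, FunctionalImage, require_grid_compatible

logger = logging.getLogger(__name__)

#: slack used when deciding whether a DFT bin lies inside the closed passband,
#: so that band edges landing exactly on a bin are kept despite float rounding.
_FREQ_TOL = 1e-9


@dataclass
class PreprocessConfig:
    """Temporal preprocessing parameters.

    Attributes
    ----------
    discard_volumes : int
        Initial frames dropped before filtering (default 5).
    band_low_hz, band_high_hz : float
        Closed passband in Hz (default 0.01–0.08); must satisfy
        ``0 <= low < high < 1 / (2 * tr_sec)``.
    remove_mean_signal : {"global_regression", "none"}
        Whether the mask-mean time course is regressed out.
    """

    discard_volumes: int = 5
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    remove_mean_signal: str = "global_regression"

    def validate(self, tr_sec: float, n_volumes: int | None = None) -> None:
        if self.discard_volumes < 0:
            raise ValueError("discard_volumes must be >= 0")
        nyquist = 1.0 / (2.0 * tr_sec)
        if not (0.0 <= self.band_low_hz < self.band_high_hz):
            raise ValueError(
                f"need 0 <= band_low_hz < band_high_hz, got "
                f"({self.band_low_hz}, {self.band_high_hz})"
            )
        if self.band_high_hz >= nyquist:
            raise ValueError(
                f"band_high_hz={self.band_high_hz} is at or above Nyquist {nyquist}"
            )
        if self.remove_mean_signal not in ("global_regression", "none"):
            raise ValueError(f"unknown remove_mean_signal={self.remove_mean_signal!r}")
        if n_volumes is not None and self.discard_volumes >= n_volumes:
            raise ValueError(
                f"cannot discard {self.discard_volumes} of {n_volumes} volumes"
            )


def discard_initial(img: FunctionalImage, n: int) -> FunctionalImage:
    """Drop the first ``n`` time frames; spatial metadata is unchanged."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= img.n_volumes:
        raise ValueError(f"cannot discard {n} of {img.n_volumes} volumes")
    return FunctionalImage(data=img.data[..., n:].copy(), affine=img.affine, tr_sec=img.tr_sec)


def bandpass_series(x: np.ndarray, tr_sec: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Detrend + ideal DFT band-pass along the last axis of ``x``.

    Retains real-FFT coefficients whose frequency lies in the closed band
    ``[low_hz, high_hz]`` and zeroes the rest, so the output has (near-)zero
    temporal mean whenever ``low_hz > 0``.
    """
    t = x.shape[-1]
    xd = _linear_detrend(np.asarray(x, dtype=np.float64), axis=-1, type="linear")
    freqs = np.fft.rfftfreq(t, d=tr_sec)
    keep = (freqs >= low_hz - _FREQ_TOL) & (freqs <= high_hz + _FREQ_TOL)
    spec = np.fft.rfft(xd, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=t, axis=-1)


def bandpass(
    img: FunctionalImage,
    low_hz: float,
    high_hz: float,
    mask: BrainMask | None = None,
) -> FunctionalImage:
    """Band-pass each voxel's series; out-of-mask voxels pass through unmodified."""
    nyquist = 1.0 / (2.0 * img.tr_sec)
    if not (0.0 <= low_hz < high_hz):
        raise ValueError(f"need 0 <= low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz={high_hz} is at or above Nyquist {nyquist}")
    out = img.data.copy()
    if mask is None:
        out = bandpass_series(out, img.tr_sec, low_hz, high_hz)
    else:
        require_grid_compatible(img, mask, "image and mask")
        m = mask.data
        out[m] = bandpass_series(out[m], img.tr_sec, low_hz, high_hz)
    return FunctionalImage(data=out, affine=img.affine, tr_sec=img.tr_sec)


def remove_global_mean(img: FunctionalImage, mask: BrainMask) -> FunctionalImage:
    """Regress the mask-average time course out of every in-mask voxel.

    Each in-mask series is replaced by its OLS residual against
    ``[intercept, g(t)]`` where ``g`` is the mask-mean series. When ``g`` has
    zero variance the regression degenerates to intercept-only (demeaning),
    with a warning.
    """
    require_grid_compatible(img, mask, "image and mask")
    m = mask.data
    x = img.data[m]  # (N, T)
    g = x.mean(axis=0)
    gc = g - g.mean()
    xc = x - x.mean(axis=1, keepdims=True)
    gvar = float(gc @ gc)
    if gvar <= 1e-30 * x.shape[1]:
        logger.warning("global signal has zero variance; removing intercept only")
        resid = xc
    else:
        beta = (xc @ gc) / gvar
        resid = xc - np.outer(beta, gc)
    out = img.data.copy()
    out[m] = resid
    return FunctionalImage(data=out, affine=img.affine, tr_sec=img.tr_sec)


def run_preprocess(
    img: FunctionalImage, mask: BrainMask, config: PreprocessConfig | None = None
) -> FunctionalImage:
    """Full temporal chain: discard -> detrend+band-pass -> global regression."""
    config = config or PreprocessConfig()
    config.validate(img.tr_sec, img.n_volumes)
    out = discard_initial(img, config.discard_volumes)
    out = bandpass(out, config.band_low_hz, config.band_high_hz, mask)
    if config.remove_mean_signal == "global_regression":
        out = remove_global_mean(out, mask)
    return out
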