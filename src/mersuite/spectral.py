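"""Oscillation analysis of MUA and LFP signals.

Spectra are Welch estimates at 1 Hz resolution (1 s Hamming window, 50%
overlap, transform length = one window) of z-score-normalized signals, so
power is expressed in z-score^2/Hz. The MUA is rectified (absolute value)
after z-normalization so its spectrum follows the spiking envelope and can
expose oscillations far below the band-pass of the recording; the LFP is not
rectified. Beta-band (13-30 Hz) power is compared against a baseline obtained
by linear interpolation between the flanking 12 Hz and 31 Hz bins.
Spike-field coupling is measured in the time domain by the band-limited
spike-triggered average (STA) of the LFP against a shift predictor in which
each spike time is jittered by uniform(0, 1) s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .sorting import RecordingSegment
from .metrics import SpikeTrain


@dataclass
class PSDEstimate:
    freqs: np.ndarray  # Hz, 1 Hz spacing
    power: np.ndarray  # z-score^2 / Hz
    kind: str  # "MUA" | "LFP"
    n_windows: int


@dataclass
class BetaPower:
    observed: float  # mean power over the 13-30 Hz bins
    baseline: float  # mean of the interpolated line over the same bins
    excess: float  # observed - baseline


@dataclass
class STAResult:
    lags: np.ndarray  # s, lag 0 centered
    average: np.ndarray  # z-score
    band: tuple[float, float] | None
    n_spikes: int
    n_dropped: int = 0
    shift_predictor: np.ndarray | None = None


def znorm(x: np.ndarray) -> np.ndarray:
    """Z-score a signal with its own mean and SD (affine-invariant, idempotent)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0.0:
        raise ValueError("constant signal cannot be z-normalized")
    return (x - x.mean()) / sd


def _welch_1hz(
    x: np.ndarray, fs: float, min_windows: int = 2
) -> tuple[np.ndarray, np.ndarray, int]:
    nper = int(round(fs))  # 1 s window -> 1 Hz resolution
    if x.size < nper + (min_windows - 1) * (nper - nper // 2):
        raise ValueError(f"need at least {min_windows} x 1 s windows of signal")
    step = nper - nper // 2
    n_windows = (x.size - nper) // step + 1
    f, p = sps.welch(
        x, fs=fs, window="hamming", nperseg=nper, noverlap=nper // 2, nfft=nper,
        detrend=False,
    )
    return f, p, n_windows


def mua_psd(seg: RecordingSegment) -> PSDEstimate:
    """PSD of the rectified z-normalized MUA (envelope spectrum).

    Pipeline: z-normalize -> absolute value -> Welch (1 s Hamming window, 50%
    overlap, nfft = fs). Rectification demodulates the spiking envelope so
    that slow periodic modulation of spiking appears as a low-frequency peak.
    """
    if seg.kind != "MUA":
        raise ValueError("mua_psd requires an MUA segment")
    f, p, nw = _welch_1hz(np.abs(znorm(seg.samples)), seg.fs)
    return PSDEstimate(f, p, "MUA", nw)


def lfp_psd(seg: RecordingSegment) -> PSDEstimate:
    """PSD of the z-normalized LFP (no rectification)."""
    if seg.kind != "LFP":
        raise ValueError("lfp_psd requires an LFP segment")
    f, p, nw = _welch_1hz(znorm(seg.samples), seg.fs)
    return PSDEstimate(f, p, "LFP", nw)


def beta_power(
    psd: PSDEstimate,
    band: tuple[float, float] = (13.0, 30.0),
    flanks: tuple[float, float] = (12.0, 31.0),
) -> BetaPower:
    """Observed vs linearly interpolated baseline power over the beta band.

    The baseline is the mean, over the integer bins inside ``band``, of the
    straight line through the two flanking PSD values (12 and 31 Hz by
    default); the observed power is the mean of the measured values over the
    same bins.
    """
    f = psd.freqs
    lo_fl, hi_fl = flanks

    def _bin(freq: float) -> int:
        i = int(np.argmin(np.abs(f - freq)))
        if abs(f[i] - freq) > 1e-6:
            raise ValueError(f"PSD grid does not contain the {freq} Hz bin")
        return i

    i_lo, i_hi = _bin(lo_fl), _bin(hi_fl)
    in_band = (f >= band[0] - 1e-9) & (f <= band[1] + 1e-9)
    if not np.any(in_band):
        raise ValueError("PSD does not cover the requested band")
    p_lo, p_hi = psd.power[i_lo], psd.power[i_hi]
    slope = (p_hi - p_lo) / (f[i_hi] - f[i_lo])
    line = p_lo + slope * (f[in_band] - f[i_lo])
    observed = float(psd.power[in_band].mean())
    baseline = float(line.mean())
    return BetaPower(observed=observed, baseline=baseline, excess=observed - baseline)


def _band_filter(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    # 4-pole Butterworth band-pass (2nd-order design -> 4 poles), applied
    # forward-backward for zero phase
    sos = sps.butter(2, list(band), btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def sta_lfp(
    train: SpikeTrain,
    lfp: RecordingSegment,
    band: tuple[float, float] | None = (13.0, 30.0),
    window: float = 0.5,
) -> STAResult:
    """Spike-triggered average of the band-limited z-normalized LFP.

    Averages +/- ``window`` s snippets of the (optionally band-passed)
    z-normalized LFP centered on each spike; spikes whose window would run
    off the record are dropped and counted.
    """
    if lfp.kind != "LFP":
        raise ValueError("sta_lfp requires an LFP segment")
    # a constant (e.g. all-zero) LFP yields a flat zero STA rather than an error
    x = znorm(lfp.samples) if lfp.samples.std() > 0 else lfp.samples - lfp.samples.mean()
    if band is not None:
        x = _band_filter(x, lfp.fs, band)
    half = int(round(window * lfp.fs))
    idx = np.round((train.timestamps - lfp.t0) * lfp.fs).astype(int)
    ok = (idx - half >= 0) & (idx + half + 1 <= x.size)
    used = idx[ok]
    if used.size < 1:
        raise ValueError("no spikes with a full STA window inside the LFP")
    snippets = np.stack([x[i - half : i + half + 1] for i in used])
    lags = np.arange(-half, half + 1) / lfp.fs
    return STAResult(
        lags=lags, average=snippets.mean(axis=0), band=band,
        n_spikes=int(used.size), n_dropped=int(np.sum(~ok)),
    )


def shift_predictor(
    train: SpikeTrain,
    lfp: RecordingSegment,
    band: tuple[float, float] | None = (13.0, 30.0),
    seed: int | np.random.Generator = 0,
    window: float = 0.5,
) -> STAResult:
    """STA control with spike timing destroyed by uniform(0, 1) s jitter.

    Each spike time gets an independent uniform random shift in [0, 1) s,
    wrapped at the record end (preserving the spike count); any residual STA
    structure then reflects the LFP's own statistics, not spike-field locking.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    shifted = (train.timestamps + rng.uniform(0.0, 1.0, train.n_spikes)) % train.duration
    jittered = SpikeTrain(np.sort(shifted), train.duration)
    return sta_lfp(jittered, lfp, band, window)


def sta_psd(sta: STAResult, fs: float) -> PSDEstimate:
    """Welch PSD of the STA curve itself (same estimator as the LFP PSD)."""
    f, p, nw = _welch_1hz(sta.average, fs, min_windows=1)
    return PSDEstimate(f, p, "LFP", nw)
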