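"""Seeded generators of ground-truth spike trains, extracellular signals and LFPs.

Every downstream stage of the pipeline (detection, sorting, quality control,
burst and oscillation statistics) is exercised against recordings produced
here, for which the true spike times, burst intervals, drift slopes and
spike–field locking parameters are known exactly.

The generators emulate the statistical structure of human striatal
microelectrode recordings: sparse (~1–5 Hz) and fast (~30 Hz) renewal spike
trains, burst episodes, slow linear drift of firing rate and spike amplitude
("injury" units), biphasic extracellular waveforms embedded in Gaussian
background noise (plus optional sub-threshold multi-unit "hash"), and 1/f
local field potentials carrying discrete 8–30 Hz oscillations to which
spiking can be phase-locked with von Mises concentration kappa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps
from scipy.special import i0

__all__ = [
    "BurstParams",
    "DriftParams",
    "LockingParams",
    "UnitSpec",
    "SyntheticRecording",
    "gen_spike_train",
    "inject_bursts",
    "apply_drift",
    "synth_lfp",
    "lock_spikes_to_lfp",
    "spike_template",
    "render_extracellular",
    "write_recording",
    "read_recording",
]


@dataclass
class BurstParams:
    """Parameters of injected burst episodes."""

    bursts_per_s: float
    spikes_per_burst: int
    intra_burst_isi: float

    def __post_init__(self) -> None:
        if self.spikes_per_burst < 2:
            raise ValueError("spikes_per_burst must be >= 2")
        if self.intra_burst_isi <= 0:
            raise ValueError("intra_burst_isi must be > 0")
        if self.bursts_per_s < 0:
            raise ValueError("bursts_per_s must be >= 0")


@dataclass
class DriftParams:
    """Linear drift of rate and spike amplitude over the whole segment.

    Slopes are fractional changes across the segment duration: a
    ``rate_slope`` of -0.5 means the instantaneous rate at the end of the
    segment is lower than at the start by 50% of the mean rate.
    """

    rate_slope: float = 0.0
    amp_slope: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.rate_slope) and np.isfinite(self.amp_slope)):
            raise ValueError("drift slopes must be finite")


@dataclass
class LockingParams:
    """Spike–LFP phase locking: von Mises concentration about a preferred phase."""

    lfp_freq: float
    kappa: float
    pref_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass
class UnitSpec:
    """Ground-truth description of one simulated unit."""

    rate: float
    process: str = "poisson"  # "poisson" | "gamma"
    kappa_shape: float = 1.0  # gamma renewal shape; np.inf = periodic limit
    burst: BurstParams | None = None
    drift: DriftParams | None = None
    template_id: int = 0
    peak_amp: float = 1.0
    locking: LockingParams | None = None

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.process not in ("poisson", "gamma"):
            raise ValueError(f"unknown renewal process {self.process!r}")


@dataclass
class SyntheticRecording:
    """A rendered extracellular (MUA) + LFP recording with its ground truth."""

    mua_signal: np.ndarray
    lfp_signal: np.ndarray
    fs_mua: float
    fs_lfp: float
    duration: float
    truth: dict
    seed: int


def _draw_isis(rng: np.random.Generator, spec: UnitSpec, n: int) -> np.ndarray:
    if spec.process == "poisson":
        return rng.exponential(1.0 / spec.rate, n)
    if np.isinf(spec.kappa_shape):  # periodic limit of the gamma renewal process
        return np.full(n, 1.0 / spec.rate)
    return rng.gamma(spec.kappa_shape, 1.0 / (spec.rate * spec.kappa_shape), n)


def gen_spike_train(spec: UnitSpec, duration: float, seed: int | np.random.Generator) -> np.ndarray:
    """Generate a renewal spike train (timestamps in seconds, sorted).

    Poisson trains have exponential inter-spike intervals; gamma trains use a
    gamma ISI with shape ``spec.kappa_shape`` (mean preserved), recovering a
    periodic train in the shape -> infinity limit.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    expected = spec.rate * duration
    chunk = int(expected + 10.0 * np.sqrt(expected) + 20)
    isis = _draw_isis(rng, spec, chunk)
    t = np.cumsum(isis)
    while t[-1] < duration:
        isis = _draw_isis(rng, spec, chunk)
        t = np.concatenate([t, t[-1] + np.cumsum(isis)])
    return t[t < duration]


def inject_bursts(
    train: np.ndarray,
    burst: BurstParams,
    duration: float,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Superimpose stereotyped burst episodes on a baseline train.

    Returns the augmented (sorted) train and the list of ``(t_start, t_end)``
    intervals that exactly bracket the injected spikes. Episodes are placed
    uniformly at random without mutual overlap; placement failure (density too
    high) raises ``ValueError``.
    """
    train = np.asarray(train, dtype=float)
    n_bursts = int(round(burst.bursts_per_s * duration))
    if n_bursts == 0:
        return train.copy(), []
    span = (burst.spikes_per_burst - 1) * burst.intra_burst_isi
    if span >= duration:
        raise ValueError("burst span exceeds segment duration")
    if n_bursts * 2.0 * span > duration:
        raise ValueError("burst density too high to place without overlap")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    placed: list[float] = []
    attempts = 0
    while len(placed) < n_bursts:
        attempts += 1
        if attempts > 1000 * n_bursts:
            raise ValueError("burst density too high to place without overlap")
        t0 = rng.uniform(0.0, duration - span)
        if all(abs(t0 - p) > 2.0 * span for p in placed):
            placed.append(t0)
    placed.sort()
    intervals = [(t0, t0 + span) for t0 in placed]
    burst_spikes = np.concatenate(
        [t0 + np.arange(burst.spikes_per_burst) * burst.intra_burst_isi for t0 in placed]
    )
    out = np.sort(np.concatenate([train, burst_spikes]))
    return out, intervals


def apply_drift(
    train: np.ndarray,
    amps: np.ndarray,
    rate_slope: float,
    amp_slope: float,
    duration: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Impose linear firing-rate and amplitude drift on a train.

    Rate drift is realised by time-dependent thinning with acceptance
    probability proportional to ``1 + rate_slope * (t/duration - 1/2)``;
    amplitude drift scales each spike by ``1 + amp_slope * (t/duration - 1/2)``.
    A ``rate_slope`` with \\|slope\\| >= 2 would drive the instantaneous rate
    to zero or below and is rejected.
    """
    if not (np.isfinite(rate_slope) and np.isfinite(amp_slope)):
        raise ValueError("slopes must be finite")
    if abs(rate_slope) >= 2.0:
        raise ValueError("rate_slope would drive the instantaneous rate <= 0")
    train = np.asarray(train, dtype=float)
    amps = np.asarray(amps, dtype=float)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = train / duration - 0.5
    p = 1.0 + rate_slope * x
    keep = rng.random(train.size) < p / p.max()
    scale = 1.0 + amp_slope * x[keep]
    return train[keep], amps[keep] * scale


def synth_lfp(
    duration: float,
    fs_lfp: float,
    components: list[tuple[float, float]],
    noise_exponent: float = 1.0,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 1.0,
) -> np.ndarray:
    """Synthesize an LFP: 1/f^a background noise plus discrete oscillations.

    ``components`` is a list of ``(freq_hz, amplitude)`` sinusoids with random
    phases. Component frequencies at or above Nyquist are rejected.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration * fs_lfp))
    t = np.arange(n) / fs_lfp
    x = np.zeros(n)
    if noise_sd > 0:
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, 1.0 / fs_lfp)
        shape = np.zeros_like(f)
        shape[1:] = f[1:] ** (-noise_exponent / 2.0)
        noise = np.fft.irfft(spec * shape, n)
        x += noise_sd * noise / noise.std()
    for freq, amp in components:
        if freq >= fs_lfp / 2.0:
            raise ValueError(f"component at {freq} Hz is at or above Nyquist")
        x += amp * np.sin(2.0 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    return x


def lock_spikes_to_lfp(
    lfp: np.ndarray,
    fs_lfp: float,
    rate: float,
    kappa: float,
    pref_phase: float = 0.0,
    seed: int | np.random.Generator = 0,
    freq: float | None = None,
) -> np.ndarray:
    """Generate spikes whose phases w.r.t. an LFP oscillation are von Mises.

    The instantaneous LFP phase phi(t) comes from the analytic signal (after a
    narrow band-pass around ``freq`` when given); spikes are drawn from an
    inhomogeneous Poisson process with intensity

        lambda(t) = rate * exp(kappa * cos(phi(t) - pref_phase)) / I0(kappa)

    so the mean rate is preserved and kappa = 0 reduces to a homogeneous
    Poisson train independent of the LFP.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lfp = np.asarray(lfp, dtype=float)
    duration = lfp.size / fs_lfp
    if kappa == 0.0:
        spec = UnitSpec(rate=rate, process="poisson")
        return gen_spike_train(spec, duration, rng)
    x = lfp
    if freq is not None:
        lo, hi = max(freq - 2.0, 0.5), min(freq + 2.0, fs_lfp / 2.0 * 0.95)
        sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs_lfp, output="sos")
        x = sps.sosfiltfilt(sos, lfp)
    phase = np.unwrap(np.angle(sps.hilbert(x)))
    t_grid = np.arange(lfp.size) / fs_lfp
    lam_max = rate * np.exp(kappa) / i0(kappa)
    # thinning of a homogeneous Poisson process at the peak intensity
    n_cand = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n_cand))
    phi = np.interp(cand, t_grid, phase)
    lam = rate * np.exp(kappa * np.cos(phi - pref_phase)) / i0(kappa)
    keep = rng.random(n_cand) < lam / lam_max
    return cand[keep]


def spike_template(template_id: int, fs: float, support_s: float = 1.2e-3) -> np.ndarray:
    """One of a fixed library of biphasic extracellular waveform templates.

    Shapes are a sharp negative deflection (trough) followed by a slower
    positive rebound, normalized to a trough amplitude of -1. The trough falls
    one third into the support so a 0.4 ms pre / 0.8 ms post alignment window
    captures it.
    """
    n = int(round(support_s * fs))
    if n < 12:
        raise ValueError("sampling rate too low for the template support")
    # (trough width, rebound width, rebound height) in fractions of support
    shapes = [
        (0.06, 0.18, 0.45),
        (0.09, 0.25, 0.30),
        (0.05, 0.14, 0.60),
        (0.08, 0.30, 0.40),
    ]
    w1, w2, h = shapes[template_id % len(shapes)]
    x = np.linspace(0.0, 1.0, n)
    trough_pos = 1.0 / 3.0
    rebound_pos = trough_pos + 1.8 * w1
    w = -np.exp(-0.5 * ((x - trough_pos) / w1) ** 2) + h * np.exp(
        -0.5 * ((x - rebound_pos) / w2) ** 2
    )
    w -= w[0]  # start at baseline
    return w / abs(w.min())


def _unit_truth_train(
    spec: UnitSpec,
    duration: float,
    rng: np.random.Generator,
    lfp: np.ndarray | None,
    fs_lfp: float,
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    """Spike times + per-spike amplitudes + burst intervals for one unit spec."""
    if spec.locking is not None and spec.locking.kappa > 0 and lfp is not None:
        train = lock_spikes_to_lfp(
            lfp, fs_lfp, spec.rate, spec.locking.kappa, spec.locking.pref_phase,
            seed=rng, freq=spec.locking.lfp_freq,
        )
    else:
        train = gen_spike_train(spec, duration, rng)
    intervals: list[tuple[float, float]] = []
    if spec.burst is not None and spec.burst.bursts_per_s > 0:
        train, intervals = inject_bursts(train, spec.burst, duration, rng)
    amps = np.full(train.size, spec.peak_amp)
    if spec.drift is not None and (spec.drift.rate_slope or spec.drift.amp_slope):
        train, amps = apply_drift(
            train, amps, spec.drift.rate_slope, spec.drift.amp_slope, duration, rng
        )
    return train, amps, intervals


def render_extracellular(
    units: list[UnitSpec],
    duration: float,
    fs_mua: float = 20_000.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    fs_lfp: float = 1375.0,
    lfp_components: list[tuple[float, float]] | None = None,
    lfp_noise_exponent: float = 1.0,
    hash_rate: float = 0.0,
) -> SyntheticRecording:
    """Render a band-pass-like MUA trace with embedded spike templates + an LFP.

    Each unit's waveform template is scaled by its (possibly drifting) peak
    amplitude and added at the ground-truth spike times on top of white
    Gaussian noise; ``hash_rate`` > 0 adds sub-threshold background spikes
    (amplitude 1.5 x noise_sd) mimicking distant multi-unit hash. The spike
    trough lands on the sample nearest each truth timestamp.
    """
    rng = np.random.default_rng(seed)
    n_mua = int(round(duration * fs_mua))
    lfp = synth_lfp(
        duration, fs_lfp, lfp_components or [], lfp_noise_exponent, rng
    )
    mua = noise_sd * rng.standard_normal(n_mua) if noise_sd > 0 else np.zeros(n_mua)

    truth_units = []
    for spec in units:
        template = spike_template(spec.template_id, fs_mua)
        trough_idx = int(np.argmin(template))
        train, amps, intervals = _unit_truth_train(spec, duration, rng, lfp, fs_lfp)
        # drop spikes whose template would spill past either record edge
        lo = trough_idx / fs_mua
        hi = duration - (template.size - trough_idx + 1) / fs_mua
        keep = (train >= lo) & (train < hi)
        train, amps = train[keep], amps[keep]
        for t, a in zip(train, amps):
            i0_ = int(round(t * fs_mua)) - trough_idx
            mua[i0_ : i0_ + template.size] += a * template
        truth_units.append(
            {
                "timestamps": train.tolist(),
                "amplitudes": amps.tolist(),
                "burst_intervals": [list(iv) for iv in intervals],
                "rate_slope": spec.drift.rate_slope if spec.drift else 0.0,
                "amp_slope": spec.drift.amp_slope if spec.drift else 0.0,
                "template_id": spec.template_id,
                "peak_amp": spec.peak_amp,
                "locking": asdict(spec.locking) if spec.locking else None,
            }
        )
    if hash_rate > 0 and noise_sd > 0:
        hash_train = gen_spike_train(UnitSpec(rate=hash_rate), duration, rng)
        for t in hash_train:
            tpl = spike_template(int(rng.integers(4)), fs_mua)
            i0_ = int(round(t * fs_mua)) - int(np.argmin(tpl))
            if 0 <= i0_ and i0_ + tpl.size <= n_mua:
                mua[i0_ : i0_ + tpl.size] += 1.5 * noise_sd * tpl

    truth = {"units": truth_units, "hash_rate": hash_rate, "noise_sd": noise_sd}
    return SyntheticRecording(
        mua_signal=mua, lfp_signal=lfp, fs_mua=fs_mua, fs_lfp=fs_lfp,
        duration=duration, truth=truth, seed=seed,
    )


# ---------------------------------------------------------------------------
# on-disk format: raw little-endian float32 + plain-text header + truth files


def _write_channel(path: Path, samples: np.ndarray, fs: float, kind: str, duration: float) -> None:
    samples.astype("<f4").tofile(path)
    path.with_suffix(".hdr").write_text(
        f"fs={fs}\nduration={duration}\nkind={kind}\ndtype=float32-le\n"
    )


def write_recording(rec: SyntheticRecording, outdir: str | Path) -> Path:
    """Write a recording as float32 raw files + sidecar headers + truth CSV/JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_channel(outdir / "mua.f32", rec.mua_signal, rec.fs_mua, "MUA", rec.duration)
    _write_channel(outdir / "lfp.f32", rec.lfp_signal, rec.fs_lfp, "LFP", rec.duration)
    lines = ["unit_id,t_s"]
    for uid, u in enumerate(rec.truth["units"]):
        lines += [f"{uid},{t:.6f}" for t in u["timestamps"]]
    (outdir / "truth_spikes.csv").write_text("\n".join(lines) + "\n")
    manifest = {"seed": rec.seed, "duration": rec.duration, "fs_mua": rec.fs_mua,
                "fs_lfp": rec.fs_lfp, "truth": rec.truth}
    (outdir / "truth.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def read_recording(indir: str | Path) -> SyntheticRecording:
    """Read back a recording written by :func:`write_recording`."""
    indir = Path(indir)
    hdrs = {}
    for name in ("mua", "lfp"):
        hdr = dict(
            line.split("=", 1)
            for line in (indir / f"{name}.hdr").read_text().strip().splitlines()
        )
        hdrs[name] = hdr
    mua = np.fromfile(indir / "mua.f32", dtype="<f4").astype(float)
    lfp = np.fromfile(indir / "lfp.f32", dtype="<f4").astype(float)
    manifest = json.loads((indir / "truth.json").read_text())
    return SyntheticRecording(
        mua_signal=mua, lfp_signal=lfp,
        fs_mua=float(hdrs["mua"]["fs"]), fs_lfp=float(hdrs["lfp"]["fs"]),
        duration=float(hdrs["mua"]["duration"]),
        truth=manifest["truth"], seed=int(manifest["seed"]),
    )
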