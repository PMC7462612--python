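"""Pipeline orchestration, configuration, and tabular I/O.

One `run_pipeline` call takes a config through synth -> sort -> qc ->
discharge metrics -> spectra -> population stats, writing every stage's
tables under a single run directory with a JSON manifest (seed, config hash,
library versions, stage tallies) so any artifact is regenerable from config +
seed alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import synth
from .metrics import SpikeTrain, detect_bursts_surprise, isi_cv
from .population import FEATURE_COLUMNS, central_moments, cluster_units_k2
from .quality import SortedUnit, classify_stationarity, isolation_score, stationarity_slopes
from .sorting import RecordingSegment, detect_spikes, extract_features, kmeans_scan
from .spectral import beta_power, lfp_psd, mua_psd, shift_predictor, sta_lfp, sta_psd

log = logging.getLogger("mersuite")


class SchemaError(ValueError):
    """A feature table is missing mandatory columns."""


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; round-trips losslessly through YAML."""

    out_dir: str = "run"
    seed: int = 0
    duration: float = 60.0
    fs_mua: float = 20_000.0
    fs_lfp: float = 1375.0
    noise_sd: float = 0.1
    units: list[dict] = field(default_factory=lambda: [
        {"rate": 3.0, "template_id": 0, "peak_amp": 1.0},
        {"rate": 8.0, "template_id": 2, "peak_amp": 0.8},
    ])
    lfp_components: list[list[float]] = field(default_factory=lambda: [[21.0, 1.0]])
    iso_min: float = 0.6
    stationarity_percentile: float = 70.0
    burst_min_len: int = 3
    burst_s_threshold: float = 10.0
    beta_band: list[float] = field(default_factory=lambda: [13.0, 30.0])
    beta_flanks: list[float] = field(default_factory=lambda: [12.0, 31.0])
    min_segment_duration: float = 0.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _unit_specs(cfg: PipelineConfig) -> list[synth.UnitSpec]:
    specs = []
    for u in cfg.units:
        u = dict(u)
        if "burst" in u and u["burst"]:
            u["burst"] = synth.BurstParams(**u["burst"])
        else:
            u.pop("burst", None)
        if "drift" in u and u["drift"]:
            u["drift"] = synth.DriftParams(**u["drift"])
        else:
            u.pop("drift", None)
        if "locking" in u and u["locking"]:
            u["locking"] = synth.LockingParams(**u["locking"])
        else:
            u.pop("locking", None)
        specs.append(synth.UnitSpec(**u))
    return specs


def read_feature_table(path: str | Path, schema_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a per-unit feature table from CSV or XLSX with header auto-detection.

    Column names are matched case/space/punctuation-insensitively against
    known aliases (e.g. "Firing rate (Hz)" -> firing_rate); an explicit
    ``schema_map`` of {file column -> canonical column} overrides detection.
    Unknown columns are preserved. Missing mandatory columns raise
    :class:`SchemaError` listing the recognised candidates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature table not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)

    aliases = {
        "firing_rate": ["firing_rate", "firingrate", "rate", "discharge_rate",
                        "firing_rate_hz", "fr", "firingratehz"],
        "isolation_score": ["isolation_score", "isolationscore", "iso_score",
                            "isoscore", "isolation", "iso_sc", "isosc"],
        "cv_isi": ["cv_isi", "cv", "cv_of_isi", "cvisi", "cv_of_the_isi"],
        "mua_beta": ["mua_beta", "beta_power_mua", "mua_beta_power", "betamua"],
        "sta_beta": ["sta_beta", "beta_power_sta", "sta_lfp_beta", "betasta"],
        "unit_id": ["unit_id", "unit", "id", "unitid"],
        "disease": ["disease", "group", "diagnosis", "cohort"],
        "stationary": ["stationary", "is_stationary", "stationarity"],
        "segment_duration": ["segment_duration", "duration", "seg_duration",
                             "duration_s", "segment_duration_s"],
    }

    def norm(name: str) -> str:
        return "".join(c for c in str(name).lower().strip() if c.isalnum() or c == "_")

    rename: dict[str, str] = {}
    if schema_map:
        rename.update(schema_map)
    for col in df.columns:
        if col in rename:
            continue
        n = norm(col).replace("__", "_")
        for canon, names in aliases.items():
            if n in names or norm(col).replace("_", "") in [a.replace("_", "") for a in names]:
                rename[col] = canon
                break
    df = df.rename(columns=rename)
    mandatory = ["firing_rate"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(
            f"missing mandatory columns {missing}; recognised aliases: "
            + "; ".join(f"{k}: {v}" for k, v in aliases.items() if k in missing)
        )
    log.info("read %d rows from %s (mapping %s)", len(df), path, rename)
    return df


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full chain on a synthetic recording; returns the run dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tallies: dict[str, int] = {}

    # -- synth -------------------------------------------------------------
    rec = synth.render_extracellular(
        _unit_specs(cfg), cfg.duration, cfg.fs_mua, cfg.noise_sd, cfg.seed,
        fs_lfp=cfg.fs_lfp,
        lfp_components=[tuple(c) for c in cfg.lfp_components],
    )
    synth.write_recording(rec, out / "synth")
    tallies["truth_units"] = len(rec.truth["units"])

    # -- sort --------------------------------------------------------------
    seg = RecordingSegment(rec.mua_signal, rec.fs_mua, "MUA")
    wf = detect_spikes(seg)
    tallies["detected_events"] = int(wf.timestamps.size)
    feats = extract_features(wf)
    sort = kmeans_scan(feats, timestamps=wf.timestamps, seed=cfg.seed)
    sort_dir = out / "sort"
    sort_dir.mkdir(exist_ok=True)
    pd.DataFrame(
        {"unit_id": sort.labels, "t_s": wf.timestamps}
    ).to_csv(sort_dir / "spikes.csv", index=False)
    with h5py.File(sort_dir / "waveforms.h5", "w") as h5:
        h5.create_dataset("waveforms", data=wf.waveforms)
        h5.create_dataset("timestamps", data=wf.timestamps)
        h5.create_dataset("labels", data=sort.labels)
        h5.attrs["align_index"] = wf.align_index
        h5.attrs["fs"] = wf.fs
    (sort_dir / "report.json").write_text(json.dumps({
        "chosen_k": sort.chosen_k,
        "pseudo_f": {str(k): (None if not np.isfinite(v) else v)
                     for k, v in sort.pseudo_f.items()},
    }, indent=1))
    tallies["sorted_units"] = sort.chosen_k

    # -- qc ----------------------------------------------------------------
    amp = wf.waveforms[:, wf.align_index]
    units: list[SortedUnit] = []
    for uid in np.unique(sort.labels):
        mask = sort.labels == uid
        su = SortedUnit(
            timestamps=wf.timestamps[mask], amplitudes=amp[mask],
            segment_duration=cfg.duration, unit_id=int(uid),
        )
        if mask.sum() >= 2 and (~mask).sum() >= 1:
            try:
                su.isolation_score = isolation_score(feats[mask], feats[~mask])
            except ValueError:
                su.isolation_score = np.nan
        else:
            su.isolation_score = 1.0
        if mask.sum() >= 10:
            # stationarity uses the magnitude of the (negative) trough
            su.m_rate, su.m_amp = stationarity_slopes(su.timestamps, -su.amplitudes)
        units.append(su)
    with_slopes = [u for u in units if np.isfinite(u.m_rate)]
    if len(with_slopes) >= 2:
        classify_stationarity(with_slopes, cfg.stationarity_percentile)
    pd.DataFrame([
        {"unit_id": u.unit_id, "iso_score": u.isolation_score, "m_rate": u.m_rate,
         "m_amp": u.m_amp, "stationary": u.stationary}
        for u in units
    ]).to_csv(out / "qc.csv", index=False)

    # -- discharge metrics -------------------------------------------------
    rows, brows = [], []
    for u in units:
        train = SpikeTrain(u.timestamps, cfg.duration)
        rate = train.n_spikes / cfg.duration
        mean_isi = cv = np.nan
        if train.n_spikes >= 3:
            mean_isi, cv = isi_cv(train)
        bursts = detect_bursts_surprise(
            train, min_len=cfg.burst_min_len, s_threshold=cfg.burst_s_threshold
        )
        for e in bursts.episodes:
            brows.append({"unit_id": u.unit_id, "t_start": e.t_start,
                          "t_end": e.t_end, "n_spikes": e.n_spikes, "S": e.surprise})
        rows.append({"unit_id": u.unit_id, "rate": rate, "mean_isi": mean_isi,
                     "cv": cv, "prevalence": bursts.prevalence})
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
    pd.DataFrame(brows, columns=["unit_id", "t_start", "t_end", "n_spikes", "S"]
                 ).to_csv(out / "bursts.csv", index=False)
    tallies["bursts"] = len(brows)

    # -- spectra -----------------------------------------------------------
    mpsd = mua_psd(seg)
    mbeta = beta_power(mpsd, tuple(cfg.beta_band), tuple(cfg.beta_flanks))
    lseg = RecordingSegment(rec.lfp_signal, rec.fs_lfp, "LFP")
    lpsd = lfp_psd(lseg)
    spec_dir = out / "spectra"
    spec_dir.mkdir(exist_ok=True)
    pd.DataFrame({"freq": mpsd.freqs, "power": mpsd.power}).to_csv(
        spec_dir / "mua_psd.csv", index=False)
    pd.DataFrame({"freq": lpsd.freqs, "power": lpsd.power}).to_csv(
        spec_dir / "lfp_psd.csv", index=False)
    sta_betas: dict[int, float] = {}
    for u in units:
        train = SpikeTrain(u.timestamps, cfg.duration)
        if train.n_spikes < 10:
            continue
        sta = sta_lfp(train, lseg, tuple(cfg.beta_band))
        pred = shift_predictor(train, lseg, tuple(cfg.beta_band), seed=cfg.seed)
        pd.DataFrame({"lag": sta.lags, "sta": sta.average,
                      "predictor": pred.average}).to_csv(
            spec_dir / f"sta_unit{u.unit_id}.csv", index=False)
        sta_betas[u.unit_id] = beta_power(
            sta_psd(sta, rec.fs_lfp), tuple(cfg.beta_band), tuple(cfg.beta_flanks)
        ).observed

    # -- population stats --------------------------------------------------
    met = pd.DataFrame(rows)
    table = pd.DataFrame({
        "unit_id": [u.unit_id for u in units],
        "disease": "SYNTH",
        "firing_rate": met["rate"],
        "cv_isi": met["cv"],
        "mua_beta": mbeta.observed,
        "sta_beta": [sta_betas.get(u.unit_id, np.nan) for u in units],
        "isolation_score": [u.isolation_score for u in units],
        "stationary": [u.stationary for u in units],
        "segment_duration": cfg.duration,
    })[FEATURE_COLUMNS]
    write_feature_table(table, out / "unit_features.csv")
    good = table.dropna(subset=["firing_rate", "cv_isi"])
    if len(good) >= 3:
        cl = cluster_units_k2(good, seed=cfg.seed)
        good.assign(cluster=cl.labels, silhouette=cl.silhouette).to_csv(
            out / "clusters.csv", index=False)
    rates = table["firing_rate"].dropna().to_numpy()
    summary = asdict(central_moments(rates)) if rates.size else {}

    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "tallies": tallies,
        "rate_summary": summary,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("pipeline run complete: %s", tallies)
    return out
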