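"""End-to-end orchestration: simulate/load → preprocess → ERS → phase
locking → propagation, with a serializable run configuration.

The stage order mirrors standard SSVEP practice: line-noise notch, then
downsampling, then (optionally) the surface Laplacian, then stimulus-locked
epoching; all analysis stages consume the resulting epochs.  A run is fully
determined by its :class:`RunConfig` — identical config and seed give
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .montage import Montage, default_montage, load_montage
from .recording import ContinuousRecording, read_recording
from .simulate import (
    NoiseModel,
    StimulationProtocol,
    WavePropagationModel,
    simulate_recording,
)
from . import preprocess as pre
from . import phase_locking as pl
from . import propagation as prop
from .spectral import ers_map, stft_power

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "preprocess_recording"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on, serializable to YAML."""

    seed: int = 0
    rate: float = 2048.0
    protocol: StimulationProtocol = field(default_factory=StimulationProtocol)
    wave: WavePropagationModel = field(default_factory=WavePropagationModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    montage_path: str | None = None          # None = built-in 32-channel 10-20
    recording_path: str | None = None        # None = simulate

    # preprocessing
    notch_freq: float = 50.0
    notch_q: float = 45.0
    target_rate: float = 256.0
    laplacian: bool = True
    epoch_window: tuple[float, float] = (-1.0, 3.0)

    # analysis
    compute_ers: bool = True
    compute_pls: bool = True
    plv_min: float = 0.5
    pls_max: float = 0.05
    n_surrogates: int = 200
    source_override: str | None = "Pz"
    electrode_subset: tuple[str, ...] = prop.GRADIENT_ELECTRODES
    lag_window_center: float = 0.25
    lag_n_cycles: int = 5
    folding_factor: float | None = None

    def montage(self) -> Montage:
        if self.montage_path is None:
            return default_montage()
        return load_montage(self.montage_path)

    def validate(self) -> None:
        montage = self.montage()
        missing = [ch for ch in self.electrode_subset if ch not in montage]
        if missing:
            raise ValueError(f"electrode_subset channels not in montage: {missing}")
        if self.source_override is not None and self.source_override not in montage:
            raise ValueError(f"source_override {self.source_override!r} not in montage")
        if self.wave.source not in montage:
            raise ValueError(f"wave source {self.wave.source!r} not in montage")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "protocol" in d and isinstance(d["protocol"], dict):
            p = dict(d["protocol"])
            for k in ("frequencies", "isi_range"):
                if k in p:
                    p[k] = tuple(p[k])
            d["protocol"] = StimulationProtocol(**p)
        if "wave" in d and isinstance(d["wave"], dict):
            w = dict(d["wave"])
            if "harmonic_weights" in w:
                w["harmonic_weights"] = tuple(w["harmonic_weights"])
            d["wave"] = WavePropagationModel(**w)
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseModel(**d["noise"])
        for k in ("epoch_window", "electrode_subset"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        payload = json.dumps(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _plain(obj):
    """Recursively convert tuples to lists so YAML/JSON stay plain."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


@dataclass
class PipelineResult:
    """Report bundle of a full run."""

    config: RunConfig
    ers: dict[float, "pd.DataFrame | None"]
    plv_tables: pd.DataFrame | None
    locking_delays: dict[float, dict[str, float]]
    selected_source: str
    estimates: list[prop.VelocityEstimate]
    trend: prop.FrequencyTrend | None

    def velocity_table(self) -> pd.DataFrame:
        rows = []
        for e in self.estimates:
            rows.append(
                {
                    "condition_hz": e.condition,
                    "slope_rad_per_cm": e.gradient.slope,
                    "intercept_rad": e.gradient.intercept,
                    "r": e.gradient.r,
                    "p": e.gradient.p,
                    "velocity_m_s": e.velocity,
                    "wavelength_cm": e.wavelength,
                    "folding_factor": e.folding_factor_applied or 1.0,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        out = {
            "version": __version__,
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "selected_source": self.selected_source,
            "n_conditions": len(self.estimates),
            "velocities_m_s": {
                str(e.condition): e.velocity for e in self.estimates
            },
            "wavelengths_cm": {
                str(e.condition): e.wavelength for e in self.estimates
            },
        }
        if self.trend is not None:
            out["trend"] = dataclasses.asdict(self.trend)
        return out


def get_recording(config: RunConfig) -> ContinuousRecording:
    if config.recording_path is not None:
        return read_recording(config.recording_path)
    noise = dataclasses.replace(config.noise, seed=config.seed)
    return simulate_recording(
        config.protocol, config.wave, noise, config.montage(), config.rate
    )


def preprocess_recording(rec: ContinuousRecording, config: RunConfig, montage: Montage):
    """Notch → downsample → (Laplacian) → epoch, in that order."""
    rec = pre.notch_filter(rec, config.notch_freq, config.notch_q)
    rec = pre.downsample(rec, config.target_rate)
    if config.laplacian:
        rec = pre.surface_laplacian(rec, montage)
    epochs = pre.epoch_extract(rec, config.epoch_window)
    stim_epochs = pre.epoch_stimulus(rec, config.epoch_window)
    return rec, epochs, stim_epochs


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute all stages and (optionally) write the report bundle."""
    config.validate()
    montage = config.montage()
    logger.info("pipeline start: seed=%d hash=%s", config.seed, config.config_hash())

    rec = get_recording(config)
    rec, epochs, stim_epochs = preprocess_recording(rec, config, montage)

    conditions = sorted(epochs)
    ers: dict[float, pd.DataFrame | None] = {}
    phases: dict[float, pl.PhaseSeries] = {}
    stim_phases: dict[float, np.ndarray] = {}
    for f in conditions:
        if config.compute_ers:
            ers[f] = ers_map(stft_power(epochs[f])).to_frame()
        ps = pl.epoch_phases(epochs[f], stim_trials=stim_epochs[f])
        phases[f] = ps
        stim_phases[f] = ps.stim_phase

    # --- stimulus-locked PLV / PLS / locking delays ----------------------
    plv_rows: list[pd.DataFrame] = []
    delays: dict[float, dict[str, float]] = {}
    if config.compute_pls:
        ss = np.random.SeedSequence([config.seed, 0x5015])
        child = {f: s for f, s in zip(conditions, ss.spawn(len(conditions)))}
        for f in conditions:
            others = [stim_phases[g] for g in conditions if g != f]
            series = pl.pls_surrogate(
                phases[f], others, config.n_surrogates,
                rng=np.random.default_rng(child[f]),
            )
            series.plv_min, series.pls_max = config.plv_min, config.pls_max
            delays[f] = pl.locking_delays(series)
            tbl = pd.DataFrame(
                {
                    "condition_hz": f,
                    "channel": np.repeat(series.channel_names, series.plv.shape[1]),
                    "time_ms": np.tile(series.times * 1000.0, len(series.channel_names)),
                    "plv": series.plv.ravel(),
                    "pls": series.pls.ravel(),
                }
            )
            plv_rows.append(tbl)

    if config.compute_pls and delays:
        source = pl.select_source(delays, montage, override=config.source_override)
    else:
        source = config.source_override or config.wave.source

    # --- propagation -----------------------------------------------------
    estimates = []
    for f in conditions:
        lag_map = prop.windowed_phase_lag(
            phases[f], source, config.lag_window_center, config.lag_n_cycles
        )
        estimates.append(
            prop.estimate_velocity(
                lag_map, montage, config.electrode_subset, config.folding_factor
            )
        )
    trend = (
        prop.velocity_frequency_trend(estimates) if len(estimates) >= 3 else None
    )

    result = PipelineResult(
        config=config,
        ers=ers,
        plv_tables=pd.concat(plv_rows, ignore_index=True) if plv_rows else None,
        locking_delays=delays,
        selected_source=source,
        estimates=estimates,
        trend=trend,
    )
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    logger.info("pipeline done: %d conditions, source %s", len(estimates), source)
    return result


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out_dir / "config.yaml")
    result.velocity_table().to_csv(out_dir / "velocity.csv", index=False)
    if result.ers:
        pd.concat(result.ers.values(), ignore_index=True).to_csv(
            out_dir / "ers.csv", index=False
        )
    if result.plv_tables is not None:
        result.plv_tables.to_csv(out_dir / "plv.csv", index=False, float_format="%.6g")
    if result.locking_delays:
        rows = [
            {"condition_hz": f, "channel": ch, "delay_s": d}
            for f, dd in result.locking_delays.items()
            for ch, d in dd.items()
        ]
        pd.DataFrame(rows).to_csv(out_dir / "locking_delays.csv", index=False)
    (out_dir / "summary.json").write_text(json.dumps(result.summary(), indent=2))
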