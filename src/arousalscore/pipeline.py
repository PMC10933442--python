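"""End-to-end orchestration: simulate/ingest -> score -> features -> train -> report.

One :class:`PipelineConfig` (optionally loaded from YAML) drives every stage;
the global seed propagates to each stochastic step, so a run is reproducible
down to the report bytes. Recordings are processed one at a time from disk,
so memory stays flat in the number of recordings.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as asio
from .features import DEFAULT_PSI_BANDS, build_feature_matrix
from .intensity import (
    BinningThresholds,
    REFERENCE_THRESHOLDS,
    ScoredEvent,
    amplitude_distance,
    assign_level,
    fit_quartile_thresholds,
    select_sham_windows,
)
from .io import ArousalEvent, read_annotations, read_recording
from .models import ArousalIntensityModel, ArousalIntensityResults, TrainConfig
from .preprocess import (
    DEFAULT_COMPOSITE_MAP,
    SegmentOutOfBounds,
    extract_segment_pair,
    make_composites,
    preprocess_recording,
)
from .synthetic import SyntheticConfig, simulate_dataset

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


class StageFailure(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """All settings of an end-to-end run.

    Exactly one input source must be set: ``synthetic`` (generate data) or
    ``data_dir`` (read existing EDF + CSV annotations). The global ``seed``
    overrides the seeds of every stochastic stage.
    """

    synthetic: SyntheticConfig | None = None
    data_dir: str | None = None
    highpass_hz: float = 0.3
    target_fs: float = 128.0
    threshold_mode: str = "fit"          # "fit" (from data) or "fixed" (reference edges)
    fixed_thresholds: BinningThresholds | None = None
    sham_min: int = 10
    sham_max: int = 14
    sham_len_s: float = 9.0
    sham_clearance_s: float = 10.0
    psi_bands: tuple = DEFAULT_PSI_BANDS
    normalize_aux: bool = True
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.synthetic is None) == (self.data_dir is None):
            raise ConfigError("exactly one of 'synthetic' and 'data_dir' must be set")
        if self.threshold_mode not in ("fit", "fixed"):
            raise ConfigError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "fixed" and self.fixed_thresholds is None:
            object.__setattr__(self, "fixed_thresholds", REFERENCE_THRESHOLDS)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        try:
            kwargs = dict(raw)
            if "synthetic" in kwargs and kwargs["synthetic"] is not None:
                syn = dict(kwargs["synthetic"])
                if "stage_transition" in syn:
                    syn["stage_transition"] = np.asarray(syn["stage_transition"], float)
                if "amplitude_law" in syn:
                    fam, params = syn["amplitude_law"]
                    syn["amplitude_law"] = (fam, dict(params))
                if "event_duration_range" in syn:
                    syn["event_duration_range"] = tuple(syn["event_duration_range"])
                kwargs["synthetic"] = SyntheticConfig(**syn)
            if "train" in kwargs and kwargs["train"] is not None:
                kwargs["train"] = TrainConfig(**dict(kwargs["train"]))
            if "fixed_thresholds" in kwargs and kwargs["fixed_thresholds"] is not None:
                kwargs["fixed_thresholds"] = BinningThresholds(**kwargs["fixed_thresholds"])
            if "psi_bands" in kwargs and kwargs["psi_bands"] is not None:
                kwargs["psi_bands"] = tuple(tuple(b) for b in kwargs["psi_bands"])
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid pipeline configuration: {exc}") from exc


def _recording_names(data_dir: Path) -> list[str]:
    names = sorted(p.stem for p in data_dir.glob("*.edf"))
    if not names:
        raise StageFailure(f"ingest: no EDF recordings found in {data_dir}")
    return names


def _load_one(data_dir: Path, name: str):
    rec = read_recording(data_dir / f"{name}.edf", list(asio.CHANNELS))
    hyp, events = read_annotations(
        data_dir / f"{name}_hypnogram.csv", data_dir / f"{name}_events.csv"
    )
    return rec, hyp, events


def score_directory(data_dir, config: PipelineConfig) -> pd.DataFrame:
    """Score every recording in a directory: amplitudes, shams, levels.

    Returns one row per event (real and sham): ``event_id, recording,
    onset_s, duration_s, stage, is_sham, amplitude_v, level``.
    """
    data_dir = Path(data_dir)
    rows = []
    for idx, name in enumerate(_recording_names(data_dir)):
        rec, hyp, events = _load_one(data_dir, name)
        proc = preprocess_recording(
            rec.subset(["C3", "C4"]), config.highpass_hz, config.target_fs
        )
        sham_rng = np.random.default_rng((config.seed * 1_000_003 + idx) % 2**31)
        shams = select_sham_windows(
            hyp,
            events,
            sham_rng,
            n_range=(config.sham_min, config.sham_max),
            length_s=config.sham_len_s,
            clearance_s=config.sham_clearance_s,
        )
        n_skipped = 0
        for e in list(events) + shams:
            try:
                pair = extract_segment_pair(proc, e, ["C3", "C4"])
            except SegmentOutOfBounds as exc:
                logger.info("scoring: skipping event in %s: %s", name, exc)
                n_skipped += 1
                continue
            rows.append(
                {
                    "event_id": f"{name}:{e.onset:.3f}",
                    "recording": name,
                    "onset_s": e.onset,
                    "duration_s": e.duration,
                    "stage": e.stage_at_onset,
                    "is_sham": e.is_sham,
                    "amplitude_v": amplitude_distance(pair),
                }
            )
        logger.info(
            "scored %s: %d arousals, %d shams, %d skipped",
            name, len(events), len(shams), n_skipped,
        )
    scored = pd.DataFrame(rows)
    if scored.empty:
        raise StageFailure("scoring: no scorable events")
    real = scored[~scored["is_sham"]]
    if config.threshold_mode == "fixed":
        thresholds = config.fixed_thresholds or REFERENCE_THRESHOLDS
    else:
        thresholds = fit_quartile_thresholds(real["amplitude_v"].to_numpy())
    scored["level"] = [
        assign_level(a, thresholds, sham)
        for a, sham in zip(scored["amplitude_v"], scored["is_sham"])
    ]
    return scored


def extract_features_directory(
    data_dir, scored: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, list[dict]]:
    """Build the 136-feature matrix for every scored event in a directory."""
    data_dir = Path(data_dir)
    matrices, drops = [], []
    for name, group in scored.groupby("recording", sort=True):
        rec, _, _ = _load_one(data_dir, name)
        proc = make_composites(
            preprocess_recording(rec, config.highpass_hz, config.target_fs),
            DEFAULT_COMPOSITE_MAP,
        )
        scored_events = [
            ScoredEvent(
                event=ArousalEvent(
                    onset=row.onset_s,
                    duration=row.duration_s,
                    stage_at_onset=row.stage,
                    is_sham=bool(row.is_sham),
                ),
                amplitude=row.amplitude_v,
                level=int(row.level),
            )
            for row in group.itertuples(index=False)
        ]
        matrix, drop_log = build_feature_matrix(
            {name: proc}, {name: scored_events}, config.psi_bands, config.normalize_aux
        )
        matrices.append(matrix)
        drops.extend(drop_log)
        logger.info("features %s: %d rows, %d dropped", name, len(matrix), len(drop_log))
    features = pd.concat(matrices, ignore_index=True)
    return features, drops


def run_pipeline(config: PipelineConfig, out_dir) -> ArousalIntensityResults:
    """Run every stage and write all artifacts under ``out_dir``.

    Artifacts: ``data/`` (when simulating), ``scored.csv``, ``features.csv``,
    ``drops.csv``, ``models/``, ``report.json``, ``summary.txt``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        data_dir = out / "data"
        try:
            simulate_dataset(syn, data_dir)
        except Exception as exc:
            raise StageFailure(f"simulate: {exc}") from exc
        logger.info("simulated %d recordings into %s", syn.n_recordings, data_dir)
    else:
        data_dir = Path(config.data_dir)

    try:
        scored = score_directory(data_dir, config)
    except StageFailure:
        raise
    except Exception as exc:
        raise StageFailure(f"score: {exc}") from exc
    scored.to_csv(out / "scored.csv", index=False)
    logger.info(
        "scoring: %d events (%d sham)", len(scored), int(scored["is_sham"].sum())
    )

    try:
        features, drops = extract_features_directory(data_dir, scored, config)
    except Exception as exc:
        raise StageFailure(f"features: {exc}") from exc
    asio.write_feature_table(features, out / "features.csv")
    pd.DataFrame(drops, columns=["event_id", "reason"]).to_csv(
        out / "drops.csv", index=False
    )
    if len(features) + len(drops) != len(scored):
        raise StageFailure(
            f"features: row accounting broken ({len(features)} kept + "
            f"{len(drops)} dropped != {len(scored)} scored)"
        )

    try:
        train_cfg = dataclasses.replace(config.train, seed=config.seed)
        results = ArousalIntensityModel(features, train_cfg).fit()
    except Exception as exc:
        raise StageFailure(f"train: {exc}") from exc

    results.save(out / "models")
    asio.write_report(results.report, out / "report.json")
    (out / "summary.txt").write_text(results.summary() + "\n")
    logger.info("pipeline complete; report at %s", out / "report.json")
    return results
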