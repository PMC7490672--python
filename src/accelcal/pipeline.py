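"""End-to-end orchestration: simulate/ingest → preprocess → hip-label →
calibrate (three methods) → validate → report.

A single :class:`PipelineConfig` (one master seed) fully determines a
run when the source is the simulator.  Stages draw from named seed
substreams so they can be re-run independently; per-stage row counts
(enrolled → analyzable → matched epochs) are recorded in the
:class:`RunRecord` and reconcile with every downstream table.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import (
    CalibrationResult,
    kmeans_calibrate,
    olr_calibrate,
    roc_calibrate,
)
from .cutpoints import (
    BUTTE_HIP,
    LEVEL_NAMES,
    CutPointSet,
    JohanssonWrist,
    group_mvpa,
    label_series,
)
from .preprocess import ChoiParams, align_pairs, detect_nonwear_choi, exclude_participants, reintegrate
from .simulate import SimulationConfig, StudyData, simulate_study
from .validate import AgreementReport, agreement_report, estimate_table, summarize_tally
from .io import read_manifest

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunRecord", "Bundle", "PipelineStageError", "run", "report"]

_REFERENCES = {"butte_hip": BUTTE_HIP}


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the partial run record."""

    def __init__(self, stage: str, record: "RunRecord", cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.record = record
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything needed for one deterministic run."""

    simulation: Optional[SimulationConfig] = None
    manifest: Optional[str] = None  # ingest instead of simulate
    analysis_epoch_length: int = 15  # 15 or 60
    choi: ChoiParams = field(default_factory=ChoiParams)
    reference: str = "butte_hip"
    johansson_sb_upper: Optional[int] = None  # enables the Johansson column
    olr_ridge: float = 1e-6
    kmeans_method: str = "dp"
    kmeans_seed: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None and self.manifest is None:
            self.simulation = SimulationConfig(seed=self.seed)
        if self.simulation is not None and self.manifest is not None:
            raise ValueError("choose one input source: simulate or ingest")
        if self.reference not in _REFERENCES:
            raise ValueError(
                f"unknown reference {self.reference!r}; options: {sorted(_REFERENCES)}"
            )
        if self.analysis_epoch_length not in (15, 60):
            raise ValueError("analysis_epoch_length must be 15 or 60")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        choi = raw.pop("choi", None)
        cfg = cls(
            simulation=SimulationConfig(**sim) if sim else None,
            choi=ChoiParams(**choi) if choi else ChoiParams(),
            **raw,
        )
        return cfg


@dataclass
class RunRecord:
    config: dict
    version: str = __version__
    n_enrolled: int = 0
    n_analyzable: int = 0
    n_matched_epochs: int = 0
    excluded: list = field(default_factory=list)
    started: float = 0.0
    finished: float = 0.0
    stage_seconds: dict = field(default_factory=dict)


@dataclass
class Bundle:
    """All run outputs: the four study-table analogues plus provenance."""

    tally: dict  # epoch tally of hip-reference labels
    calibrations: dict[str, CalibrationResult]
    agreements: dict[str, AgreementReport]
    johansson: Optional[pd.DataFrame]  # 3-level per-class block, or None
    daily: pd.DataFrame
    matched: pd.DataFrame
    record: RunRecord


def _config_snapshot(config: PipelineConfig) -> dict:
    def enc(obj):
        if hasattr(obj, "__dict__"):
            return {k: enc(v) for k, v in vars(obj).items() if not callable(v)}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    return enc(config)


def _preprocess_study(study: StudyData, config: PipelineConfig):
    """Wear masks, optional re-integration, alignment and pooling."""
    tables, roster_rows = [], []
    for day in study.days:
        hip, wrist = day.hip, day.wrist
        if config.analysis_epoch_length != hip.epoch_length:
            hip = reintegrate(hip, config.analysis_epoch_length)
            wrist = reintegrate(wrist, config.analysis_epoch_length)
        hip_wear = detect_nonwear_choi(hip, config.choi)
        wrist_wear = detect_nonwear_choi(wrist, config.choi)
        tables.append(align_pairs(hip, wrist, hip_wear, wrist_wear))
        roster_rows.append({"participant_id": day.hip.participant_id, "day": day.hip.day_index})
    matched = pd.concat(tables, ignore_index=True)
    roster = pd.DataFrame(roster_rows).drop_duplicates()
    return matched, roster


def run(config: PipelineConfig) -> Bundle:
    """Execute the full study and return the output bundle."""
    record = RunRecord(config=_config_snapshot(config), started=time.time())
    stage = "input"
    try:
        t0 = time.time()
        if config.simulation is not None:
            study = simulate_study(config.simulation)
            days = study.days
        else:
            series = read_manifest(config.manifest)
            by_key: dict = {}
            for s in series:
                by_key.setdefault((s.participant_id, s.day_index), {})[s.placement] = s
            from .simulate import ParticipantDay  # reuse the container

            days = [
                ParticipantDay(pid, day, pair["hip"], pair["wrist"], pd.DataFrame())
                for (pid, day), pair in sorted(by_key.items())
                if "hip" in pair and "wrist" in pair
            ]
            study = StudyData(config=None, days=days)  # type: ignore[arg-type]
        record.n_enrolled = len({d.hip.participant_id for d in days})
        record.stage_seconds[stage] = time.time() - t0

        stage = "preprocess"
        t0 = time.time()
        matched, roster = _preprocess_study(study, config)
        matched, exclusion_log = exclude_participants(matched, roster)
        record.excluded = exclusion_log.to_dict("records")
        record.n_analyzable = matched["participant_id"].nunique()
        record.n_matched_epochs = len(matched)
        record.stage_seconds[stage] = time.time() - t0
        logger.info(
            "preprocess: %d enrolled -> %d analyzable, %d matched epochs",
            record.n_enrolled, record.n_analyzable, record.n_matched_epochs,
        )

        stage = "hip-label"
        t0 = time.time()
        reference = _REFERENCES[config.reference]
        matched = matched.copy()
        matched["hip_label"] = label_series(matched["hip_cpm"].to_numpy(), reference)
        counts = np.bincount(matched["hip_label"], minlength=4)
        tally = summarize_tally(counts)
        record.stage_seconds[stage] = time.time() - t0

        stage = "calibrate"
        t0 = time.time()
        wrist = matched["wrist_cpm"].to_numpy()
        labels = matched["hip_label"].to_numpy()
        calibrations = {
            "roc": roc_calibrate(wrist, labels),
            "olr": olr_calibrate(wrist, labels, ridge=config.olr_ridge),
            "kmeans": kmeans_calibrate(
                wrist, method=config.kmeans_method, seed=config.kmeans_seed
            ),
        }
        record.stage_seconds[stage] = time.time() - t0

        stage = "validate"
        t0 = time.time()
        agreements = {
            name: agreement_report(labels, label_series(wrist, res.cuts), method=name)
            for name, res in calibrations.items()
        }
        johansson_block = None
        day_label_frames = [
            matched.assign(method="hip", label=matched["hip_label"])
        ]
        for name, res in calibrations.items():
            day_label_frames.append(
                matched.assign(method=name, label=label_series(wrist, res.cuts))
            )
        if config.johansson_sb_upper is not None:
            jw = JohanssonWrist(config.johansson_sb_upper)
            comp3 = jw.label_series_3(wrist)
            ref3 = group_mvpa(labels)
            from .validate import _per_class_block, cohen_kappa, confusion, overall_agreement

            block = _per_class_block(ref3, comp3, ("SB", "LPA", "MVPA"))
            m3 = confusion(ref3, comp3, 3)
            johansson_block = block.assign(
                overall_accuracy=overall_agreement(m3),
                overall_kappa=cohen_kappa(ref3, comp3, 3),
            )
            # daily estimates on the 3-level scale: MVPA mapped onto code 2
            day_label_frames.append(matched.assign(method="johansson", label=comp3))
        else:
            logger.info("johansson SB bound not supplied; Johansson column skipped")
        day_labels = pd.concat(day_label_frames, ignore_index=True)[
            ["participant_id", "day", "method", "label"]
        ]
        daily = estimate_table(day_labels, config.analysis_epoch_length)
        if config.johansson_sb_upper is not None:
            # the partial Johansson set cannot split MPA from VPA
            mask = (daily["method"] == "johansson") & daily["class"].isin(["MPA", "VPA"])
            daily.loc[mask, ["mean_minutes", "sd_minutes", "pct_of_wear"]] = np.nan
        record.stage_seconds[stage] = time.time() - t0
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        record.finished = time.time()
        raise PipelineStageError(stage, record, exc) from exc

    record.finished = time.time()
    return Bundle(
        tally=tally,
        calibrations=calibrations,
        agreements=agreements,
        johansson=johansson_block,
        daily=daily,
        matched=matched,
        record=record,
    )


# --------------------------------------------------------------------------
# Reporting
# --------------------------------------------------------------------------

def _tally_frame(tally: dict) -> pd.DataFrame:
    rows = [
        {"class": name, "n": tally["counts"][name], "percent": tally["percent"][name]}
        for name in LEVEL_NAMES
    ]
    rows.append({"class": "MVPA", "n": tally["mvpa"], "percent": tally["mvpa_percent"]})
    rows.append({"class": "total", "n": tally["total"], "percent": 100.0})
    return pd.DataFrame(rows)


def _cutpoint_frame(calibrations: dict[str, CalibrationResult]) -> pd.DataFrame:
    frames = []
    for name, res in calibrations.items():
        df = res.per_class.copy()
        df.insert(0, "method", name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return "undefined"
    if isinstance(v, float):
        return f"{v:.2f}"
    return str(v)


def _markdown(bundle: Bundle) -> str:
    lines = ["# Calibration run report", ""]
    lines += ["## Epoch tally (hip reference)", ""]
    tf = _tally_frame(bundle.tally)
    lines += ["| Class | n | % |", "|---|---|---|"]
    lines += [f"| {r['class']} | {r['n']} | {_fmt(r['percent'])} |" for _, r in tf.iterrows()]
    lines += ["", "## Derived wrist cut points", ""]
    lines += ["| Method | Class | n | Lower | Upper | Mean (SD) |", "|---|---|---|---|---|---|"]
    for name, res in bundle.calibrations.items():
        for _, r in res.per_class.iterrows():
            upper = "inf" if r["class"] == "VPA" else _fmt(r["upper"])
            lines.append(
                f"| {name} | {r['class']} | {r['n']} | {_fmt(r['lower'])} | {upper} | "
                f"{_fmt(r['mean'])} ({_fmt(r['sd'])}) |"
            )
    lines += ["", "## Agreement with the hip reference", ""]
    lines += ["| Method | Scale | Class | Metric | Value |", "|---|---|---|---|---|"]
    for name, rep in bundle.agreements.items():
        for _, r in rep.to_frame().iterrows():
            lines.append(
                f"| {r['method']} | {r['scale']} | {r['class']} | {r['metric']} | {_fmt(r['value'])} |"
            )
    if bundle.johansson is not None:
        for _, r in bundle.johansson.iterrows():
            for metric in ("sensitivity", "specificity", "fpr", "fnr", "kappa"):
                lines.append(
                    f"| johansson | 3-level | {r['class']} | {metric} | {_fmt(r[metric])} |"
                )
    else:
        lines.append("| johansson | - | - | not computed (SB bound not supplied) | - |")
    lines += ["", "## Daily time in each intensity level", ""]
    lines += [
        "| Method | Class | Mean min (SD) | % of wear |",
        "|---|---|---|---|",
    ]
    for _, r in bundle.daily.iterrows():
        lines.append(
            f"| {r['method']} | {r['class']} | {_fmt(r['mean_minutes'])} "
            f"({_fmt(r['sd_minutes'])}) | {_fmt(r['pct_of_wear'])} |"
        )
    lines.append("")
    return "\n".join(lines)


def report(bundle: Bundle, out_dir, formats: tuple[str, ...] = ("csv", "md")) -> list[Path]:
    """Render the bundle to CSV and/or markdown; byte-stable per bundle."""
    unknown = [f for f in formats if f not in ("csv", "md")]
    if unknown:
        raise ValueError(f"unknown formats {unknown}; supported: ['csv', 'md']")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "csv" in formats:
        paths = {
            "tally.csv": _tally_frame(bundle.tally),
            "cutpoints.csv": _cutpoint_frame(bundle.calibrations),
            "agreement.csv": pd.concat(
                [rep.to_frame() for rep in bundle.agreements.values()], ignore_index=True
            ),
            "daily.csv": bundle.daily,
        }
        if bundle.johansson is not None:
            paths["johansson.csv"] = bundle.johansson
        for fname, df in paths.items():
            p = out / fname
            df.to_csv(p, index=False)
            written.append(p)
        rec = out / "run_record.json"
        rec.write_text(json.dumps(vars(bundle.record), indent=2, default=str))
        written.append(rec)
    if "md" in formats:
        p = out / "report.md"
        p.write_text(_markdown(bundle))
        written.append(p)
    return written
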