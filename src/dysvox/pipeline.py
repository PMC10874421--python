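"""End-to-end pipeline: simulate -> extract -> train UBMs -> adapt -> classify.

Every stage reads and writes plain files under the configured output
directory, records a provenance JSON (config hash, seeds, input hashes) and
is individually re-runnable.  A full run is reproducible from the master
seed: identical configuration gives byte-identical result tables.

Layout under ``out_dir``::

    audio/            WAV files + manifest.csv
    features/         per-dimension frame/segment tables (CSV, Parquet)
    ubm/              GMM bundles per dimension and mixture size
    supervectors/     per-recording supervector tables per M
    results/          result tables, confusion matrices, plots
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from . import features as feat
from . import synth
from .adaptation import AdaptationConfig, adapt_recording
from .classification import (
    C_GRID,
    GAMMA_GRID,
    M_GRID,
    CVResult,
    ExperimentSpec,
    lda_project,
    plot_lda_scatter,
    plot_score_histogram,
    sweep_m,
)
from .gmm import em_fit, load_gmm, save_gmm

log = logging.getLogger("dysvox")

DIMENSIONS = ("articulation", "phonation", "prosody")
REPRESENTATIONS = ("articulation", "phonation", "prosody", "fusion", "fusion_pca")


@dataclass
class PipelineConfig:
    """Single document of every tunable pipeline parameter."""

    out_dir: str = "dysvox_out"
    seed: int = 0
    # cohort
    n_per_class: int = 50
    subject_sd: float = 0.10
    profile_overrides: dict = field(default_factory=dict)  # class tag -> params
    # segmentation / F0
    f0_min: float = 60.0
    f0_max: float = 400.0
    voicing_threshold: float = 0.45
    # UBM
    hc_only_ubm: bool = True
    ubm_class: str = "HC"
    m_grid: tuple = M_GRID
    # adaptation
    relevance_factor: float = 16.0
    # evaluation
    folds: int = 10
    repetitions: int = 10
    inner_folds: int = 5
    C_grid: tuple = C_GRID
    gamma_grid: tuple = GAMMA_GRID
    var_kept: float = 0.90
    tasks: tuple = ("PD_vs_ET", "PD_vs_HC", "ET_vs_HC", "triclass")
    representations: tuple = REPRESENTATIONS
    positive_class: str = "PD"

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("m_grid", "C_grid", "gamma_grid", "tasks", "representations"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for k in ("m_grid", "C_grid", "gamma_grid", "tasks", "representations"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_provenance(cfg: PipelineConfig, stage: str, extra: dict | None = None) -> None:
    out = Path(cfg.out_dir) / f"provenance_{stage}.json"
    doc = {"stage": stage, "config_hash": cfg.config_hash(), "seed": cfg.seed}
    if extra:
        doc.update(extra)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(doc, indent=2, sort_keys=True))


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage: simulate
# ---------------------------------------------------------------------------

def cmd_simulate(cfg: PipelineConfig, force: bool = False) -> Path:
    """Generate the synthetic cohort; write WAVs and a manifest CSV."""
    audio_dir = Path(cfg.out_dir) / "audio"
    if audio_dir.exists() and any(audio_dir.iterdir()):
        if not force:
            raise FileExistsError(f"{audio_dir} is not empty (use force=True)")
        shutil.rmtree(audio_dir)
    audio_dir.mkdir(parents=True, exist_ok=True)

    profiles = {}
    for tag in synth.CLASS_TAGS:
        overrides = cfg.profile_overrides.get(tag, {})
        profiles[tag] = synth.PROFILE_FACTORIES[tag](**overrides)
    waves, labels, subj_profiles = synth.synth_cohort(
        cfg.n_per_class, profiles, seed=cfg.seed, subject_sd=cfg.subject_sd
    )
    rows = []
    for w, lab, sp in zip(waves, labels, subj_profiles):
        path = audio_dir / f"{w.source_id}.wav"
        wavfile.write(path, w.sample_rate, (w.samples * 32767).astype(np.int16))
        rows.append(
            {"subject_id": w.source_id, "class": lab, "path": path.name,
             **{f"profile_{k}": v for k, v in synth.profile_dict(sp).items()}}
        )
    manifest = audio_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    log.info("simulate: wrote %d recordings to %s", len(rows), audio_dir)
    _write_provenance(cfg, "simulate", {"n_recordings": len(rows)})
    return manifest


# ---------------------------------------------------------------------------
# stage: extract
# ---------------------------------------------------------------------------

def cmd_extract(cfg: PipelineConfig, strict: bool = False) -> dict[str, Path]:
    """Extract all three feature dimensions for every manifest recording."""
    from . import audio_prep

    audio_dir = Path(cfg.out_dir) / "audio"
    manifest = pd.read_csv(audio_dir / "manifest.csv")
    feat_dir = Path(cfg.out_dir) / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)

    tables: dict[str, list[pd.DataFrame]] = {d: [] for d in DIMENSIONS}
    skipped = 0
    for _, row in manifest.iterrows():
        try:
            w = audio_prep.load_and_preprocess(
                audio_dir / row["path"], source_id=row["subject_id"]
            )
            mats = feat.extract_all(
                w, fmin=cfg.f0_min, fmax=cfg.f0_max,
                voicing_threshold=cfg.voicing_threshold,
            )
        except Exception:
            if strict:
                raise
            log.warning("extract: skipping unreadable recording %s", row["path"])
            skipped += 1
            continue
        for dim, fm in mats.items():
            df = pd.DataFrame(fm.values, columns=fm.column_labels)
            df.insert(0, "source_id", fm.source_id)
            tables[dim].append(df)

    paths = {}
    for dim in DIMENSIONS:
        df = pd.concat(tables[dim], ignore_index=True) if tables[dim] else pd.DataFrame()
        csv_path = feat_dir / f"{dim}.csv"
        df.to_csv(csv_path, index=False)
        try:
            df.to_parquet(feat_dir / f"{dim}.parquet")
        except (ImportError, ValueError):
            pass
        paths[dim] = csv_path
    labels = manifest.set_index("subject_id")["class"]
    labels.to_csv(feat_dir / "labels.csv")
    _write_provenance(
        cfg, "extract",
        {"skipped": skipped, "input_hash": _file_hash(audio_dir / "manifest.csv")},
    )
    if skipped and strict:
        raise RuntimeError(f"{skipped} recordings failed extraction")
    return paths


# ---------------------------------------------------------------------------
# stage: train UBMs
# ---------------------------------------------------------------------------

def cmd_train_ubm(cfg: PipelineConfig) -> dict[tuple[str, int], Path]:
    """Fit one UBM per (dimension, M); by default on healthy-control frames only."""
    feat_dir = Path(cfg.out_dir) / "features"
    labels = pd.read_csv(feat_dir / "labels.csv", index_col=0)["class"]
    ubm_dir = Path(cfg.out_dir) / "ubm"
    ubm_dir.mkdir(parents=True, exist_ok=True)
    out = {}
    for dim in DIMENSIONS:
        df = pd.read_csv(feat_dir / f"{dim}.csv")
        if cfg.hc_only_ubm:
            keep = df["source_id"].map(labels) == cfg.ubm_class
            excluded = int((~keep).sum())
            df = df[keep]
            log.info("train_ubm[%s]: %s-only cohort, excluded %d patient frames",
                     dim, cfg.ubm_class, excluded)
        X = df.drop(columns="source_id").to_numpy(dtype=np.float64)
        for M in cfg.m_grid:
            params = em_fit(X, M, seed=cfg.seed + M)
            path = ubm_dir / f"{dim}_M{M}"
            save_gmm(params, path, dimension_name=dim, hc_only=cfg.hc_only_ubm,
                     n_frames=int(X.shape[0]))
            out[(dim, M)] = path
            log.info("train_ubm[%s, M=%d]: %d frames, %d EM iterations",
                     dim, M, X.shape[0], params.meta.get("n_iter", -1))
    _write_provenance(cfg, "train_ubm", {"m_grid": list(cfg.m_grid)})
    return out


# ---------------------------------------------------------------------------
# stage: adapt
# ---------------------------------------------------------------------------

def cmd_adapt(cfg: PipelineConfig) -> dict[tuple[str, int], Path]:
    """MAP-adapt every recording against each UBM; write supervector tables."""
    feat_dir = Path(cfg.out_dir) / "features"
    ubm_dir = Path(cfg.out_dir) / "ubm"
    sv_dir = Path(cfg.out_dir) / "supervectors"
    sv_dir.mkdir(parents=True, exist_ok=True)
    acfg = AdaptationConfig(relevance_factor=cfg.relevance_factor)
    out = {}
    for dim in DIMENSIONS:
        df = pd.read_csv(feat_dir / f"{dim}.csv")
        grouped = dict(tuple(df.groupby("source_id", sort=True)))
        for M in cfg.m_grid:
            ubm = load_gmm(ubm_dir / f"{dim}_M{M}")
            rows = {}
            for sid, g in grouped.items():
                X = g.drop(columns="source_id").to_numpy(dtype=np.float64)
                if X.shape[0] == 0:
                    log.warning("adapt[%s, M=%d]: %s has no frames", dim, M, sid)
                    continue
                sv = adapt_recording(X, ubm, acfg, dimension_name=dim, source_id=sid)
                rows[sid] = sv.values
            table = pd.DataFrame.from_dict(rows, orient="index")
            table.index.name = "source_id"
            path = sv_dir / f"{dim}_M{M}.csv"
            table.to_csv(path)
            out[(dim, M)] = path
    _write_provenance(cfg, "adapt", {"relevance_factor": cfg.relevance_factor})
    return out


# ---------------------------------------------------------------------------
# stage: classify
# ---------------------------------------------------------------------------

def _task_mask(task: str, labels: pd.Series) -> pd.Series:
    if task == "triclass":
        return pd.Series(True, index=labels.index)
    a, _, b = task.partition("_vs_")
    return labels.isin([a, b])


def _representation_matrix(
    rep: str, sv_tables: dict[str, pd.DataFrame], ids: list[str]
) -> np.ndarray:
    if rep in DIMENSIONS:
        return sv_tables[rep].loc[ids].to_numpy(dtype=np.float64)
    # early fusion in fixed dimension order
    return np.hstack(
        [sv_tables[d].loc[ids].to_numpy(dtype=np.float64) for d in DIMENSIONS]
    )


def cmd_classify(cfg: PipelineConfig, make_plots: bool = True) -> pd.DataFrame:
    """Run every (task, representation) experiment with an M sweep.

    Writes ``results/results.csv`` (one row per cell, best M only, mirroring
    the per-task/per-dimension table layout), pooled confusion matrices as
    JSON, and score-histogram / LDA plots.
    """
    feat_dir = Path(cfg.out_dir) / "features"
    sv_dir = Path(cfg.out_dir) / "supervectors"
    res_dir = Path(cfg.out_dir) / "results"
    res_dir.mkdir(parents=True, exist_ok=True)
    labels = pd.read_csv(feat_dir / "labels.csv", index_col=0)["class"]

    sv_by_m: dict[int, dict[str, pd.DataFrame]] = {}
    for M in cfg.m_grid:
        sv_by_m[M] = {
            dim: pd.read_csv(sv_dir / f"{dim}_M{M}.csv", index_col="source_id")
            for dim in DIMENSIONS
        }
    # recordings present in all three dimensions for every M
    common = None
    for M, tables in sv_by_m.items():
        ids = set.intersection(*(set(t.index) for t in tables.values()))
        common = ids if common is None else common & ids
    excluded = sorted(set(labels.index) - common)
    if excluded:
        log.warning("classify: excluding %d recording(s) missing a dimension: %s",
                    len(excluded), excluded[:5])
    ids_all = sorted(common)

    records = []
    confusions = {}
    for task in cfg.tasks:
        mask = _task_mask(task, labels.loc[ids_all])
        ids = [i for i in ids_all if mask.loc[i]]
        y = labels.loc[ids].to_numpy()
        for rep in cfg.representations:
            use_pca = rep == "fusion_pca"
            spec = ExperimentSpec(
                task=task, C_grid=cfg.C_grid, gamma_grid=cfg.gamma_grid,
                M_grid=cfg.m_grid, folds=cfg.folds, repetitions=cfg.repetitions,
                inner_folds=cfg.inner_folds, use_pca=use_pca, var_kept=cfg.var_kept,
                positive_class=cfg.positive_class, seed=cfg.seed,
            )
            base = rep if rep in DIMENSIONS else "fusion"
            X_by_m = {
                M: _representation_matrix(base, sv_by_m[M], ids) for M in cfg.m_grid
            }
            best, _ = sweep_m(X_by_m, y, spec)
            log.info("classify[%s, %s]: acc %.1f +/- %.1f %% (M=%d, C=%g, gamma=%g)",
                     task, rep, best.accuracy_mean, best.accuracy_sd,
                     best.selected_M, best.selected_C, best.selected_gamma)
            records.append({
                "task": task, "representation": rep, "M": best.selected_M,
                "accuracy_mean": round(best.accuracy_mean, 4),
                "accuracy_sd": round(best.accuracy_sd, 4),
                "sensitivity": round(best.sensitivity, 4),
                "specificity": round(best.specificity, 4),
                "C": best.selected_C, "gamma": best.selected_gamma,
                "n_samples": len(ids), "n_excluded": len(excluded),
            })
            confusions[f"{task}/{rep}"] = {
                "classes": best.classes,
                "matrix": best.confusion.tolist(),
            }
            if make_plots:
                _plots_for_cell(cfg, res_dir, task, rep, best,
                                X_by_m[best.selected_M], y)

    results = pd.DataFrame.from_records(records)
    results.to_csv(res_dir / "results.csv", index=False)
    (res_dir / "confusion_matrices.json").write_text(
        json.dumps(confusions, indent=2, sort_keys=True)
    )
    _write_provenance(cfg, "classify", {"n_cells": len(records)})
    return results


def _plots_for_cell(cfg, res_dir, task, rep, best: CVResult, X, y) -> None:
    try:
        if len(best.classes) == 2 and best.scores is not None:
            plot_score_histogram(
                best.scores.mean(axis=0), y, res_dir / f"scores_{task}_{rep}.png"
            )
        if task == "triclass" and rep == "fusion":
            plot_lda_scatter(lda_project(X, y), y, res_dir / f"lda_{task}_{rep}.png")
    except Exception:  # plotting must never fail the pipeline
        log.warning("classify: plot for %s/%s failed", task, rep, exc_info=True)


def run_all(cfg: PipelineConfig, force: bool = False) -> pd.DataFrame:
    """Full pipeline from one config; reproducible from the master seed."""
    cmd_simulate(cfg, force=force)
    cmd_extract(cfg)
    cmd_train_ubm(cfg)
    cmd_adapt(cfg)
    return cmd_classify(cfg)
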