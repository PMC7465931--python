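"""End-to-end orchestration: simulate or ingest -> features -> network ->
statistics -> prediction, from a single validated configuration.

Feature extraction is blind by construction: the extraction stage receives
only recordings, never the clinical table; clinical metadata is joined onto
feature rows afterwards by subject id.  Every run writes a manifest listing
inputs, seeds, per-stage outputs and their SHA-256 checksums, so identical
configurations with identical seeds yield identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import classify_responders, summarize, write_clinical_table
from .connectivity import coherence_feature_row, pairwise_coherence
from .exceptions import RettNetError
from .io import PreprocessConfig, preprocess, read_recording, write_recording
from .montage import MONTAGE, PAIR_LABELS, normalize_pair
from .network import FeatureTable, NetworkPCA, architecture
from .predict import (PredictorSpec, ResponsePredictor, select_features,
                      sequential_elimination)
from .simulate import CohortDesign, Effect, generate_cohort
from .spectral import compute_psd, spectral_feature_row
from .stats import MixedAnova, posthoc_pairs

log = logging.getLogger("rettnet")


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str
    mode: str = "simulate"  # "simulate" | "real"
    recordings_dir: str | None = None  # real mode: matrix/EDF files
    clinical_path: str | None = None
    fs: float | None = None  # for matrix files without an fs header
    seed: int = 0
    # simulate mode
    design: dict = field(default_factory=dict)
    # preprocessing
    epoch_s: float = 2.0
    artifact_threshold: float = 100.0
    bandpass_hz: tuple[float, float] = (0.5, 40.0)
    notch_hz: float | None = None
    # analysis
    pca_retention: float = 0.9
    alpha: float = 0.05
    cv_folds: int = 5
    predict_contrast: tuple[str, str] = ("responder", "nonresponder")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.mode not in ("simulate", "real"):
            raise RettNetError(f"unknown mode {self.mode!r}")
        if self.mode == "real" and not self.recordings_dir:
            raise RettNetError("real mode requires recordings_dir")
        if self.mode == "simulate":
            self.build_design()  # raises on invalid designs
        if not 0 < self.pca_retention <= 1:
            raise RettNetError("pca_retention must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise RettNetError("alpha must be in (0, 1)")

    def build_design(self) -> CohortDesign:
        d = dict(self.design)
        effects = [Effect(**e) for e in d.pop("effects", [])]
        for eff in effects:
            normalize_pair(eff.pair)  # raises MontageError on bad labels
        d.setdefault("seed", self.seed)
        if "groups" in d:
            d["groups"] = tuple(d["groups"])
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        if isinstance(d.get("n_per_cell"), list):
            d["n_per_cell"] = tuple(d["n_per_cell"])
        return CohortDesign(effects=effects, **d)

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(epoch_s=self.epoch_s,
                                artifact_threshold=self.artifact_threshold,
                                bandpass_hz=tuple(self.bandpass_hz),
                                notch_hz=self.notch_hz)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_simulate(cfg: RunConfig, out: Path) -> dict:
    """Write synthetic recordings and the clinical table."""
    design = cfg.build_design()
    rec_dir = out / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    recs, table = generate_cohort(design, lazy=True)
    paths = []
    for subject_id, timepoint, rec in recs:
        p = write_recording(rec, rec_dir / f"{subject_id}_{timepoint}.csv")
        paths.append(p)
    table = classify_responders(table)
    clin = write_clinical_table(table, out / "clinical.csv")
    log.info("simulate: %d recordings, %d subjects", len(paths), len(table))
    return {"recordings": [str(p) for p in paths], "clinical": str(clin)}


def stage_extract(cfg: RunConfig, out: Path, recording_paths: list[str]
                  ) -> dict:
    """Preprocess recordings and write spectral + coherence feature rows.

    Deliberately takes no clinical information (blind processing).
    """
    pp = cfg.preprocess_config()
    spec_rows, coh_rows = [], []
    for path in sorted(recording_paths):
        rec = read_recording(path, fs=cfg.fs)
        stem = Path(path).stem
        subject_id, _, timepoint = stem.rpartition("_")
        ep = preprocess(rec, pp)
        ps = compute_psd(ep)
        cm = pairwise_coherence(ep)
        meta = {"subject_id": subject_id, "timepoint": timepoint}
        spec_rows.append(meta | spectral_feature_row(ps))
        coh_rows.append(meta | coherence_feature_row(cm)
                        | {"n_segments": cm.n_segments,
                           "n_epochs_kept": ep.n_kept,
                           "n_epochs_dropped": ep.n_epochs - ep.n_kept})
        log.info("extract %s: %d/%d epochs kept, %d segments", stem,
                 ep.n_kept, ep.n_epochs, cm.n_segments)
    spec_path = out / "spectral_features.csv"
    coh_path = out / "coherence_features.csv"
    pd.DataFrame(spec_rows).to_csv(spec_path, index=False)
    pd.DataFrame(coh_rows).to_csv(coh_path, index=False)
    return {"spectral_features": str(spec_path),
            "coherence_features": str(coh_path)}


def _feature_table(coh_path: str, clinical_path: str) -> FeatureTable:
    feats = pd.read_csv(coh_path)
    feats["subject_id"] = feats["subject_id"].astype(str)
    clin = pd.read_csv(clinical_path)
    clin["subject_id"] = clin["subject_id"].astype(str)
    merged = feats.merge(clin, on="subject_id", how="left", validate="m:1")
    return FeatureTable(merged)


def stage_network(cfg: RunConfig, out: Path, coh_path: str,
                  clinical_path: str) -> dict:
    ft = _feature_table(coh_path, clinical_path)
    results = NetworkPCA(ft, retention=cfg.pca_retention).fit()
    scores_path = out / "network_scores.csv"
    results.retained_scores().to_csv(scores_path, index=False)
    loadings_path = out / "network_loadings.csv"
    pd.DataFrame(results.loadings, columns=results.feature_names).to_csv(
        loadings_path, index=False)
    ev_path = out / "explained_variance.csv"
    pd.DataFrame({"explained_variance": results.explained_variance,
                  "ratio": results.explained_variance_ratio}).to_csv(
        ev_path, index=False)
    outputs = {"scores": str(scores_path), "loadings": str(loadings_path),
               "explained_variance": str(ev_path)}
    from .viz import plot_architecture
    for group in ft.df["group"].dropna().unique():
        for tp in ft.df["timepoint"].dropna().unique():
            try:
                arch = architecture(ft, group=group, timepoint=tp)
            except RettNetError:
                continue
            base = out / f"architecture_{group}_{tp}"
            arch.to_frame().to_csv(base.with_suffix(".csv"))
            plot_architecture(arch, base.with_suffix(".png"))
            outputs[f"architecture_{group}_{tp}"] = str(
                base.with_suffix(".csv"))
    return outputs


def _between_column(df: pd.DataFrame) -> str | None:
    """Between-subjects factor: treatment group when both levels are
    present, otherwise the responder label (responder-only cohorts)."""
    for col in ("group", "responder", "design_group"):
        if col in df.columns and df[col].dropna().nunique() == 2:
            return col
    return None


def stage_stats(cfg: RunConfig, out: Path, coh_path: str,
                clinical_path: str, scores_path: str) -> dict:
    scores = pd.read_csv(scores_path)
    ft = _feature_table(coh_path, clinical_path)
    timepoints = sorted(ft.df["timepoint"].dropna().unique())
    between = _between_column(scores)
    if between is None:
        raise RettNetError("no two-level between-subjects factor found")
    pc_cols = [c for c in scores.columns if c.startswith("PC")]
    anova_rows = []
    for pc in pc_cols:
        wide = scores.pivot_table(index="subject_id", columns="timepoint",
                                  values=pc)[list(timepoints)]
        grp = scores.groupby("subject_id")[between].first().reindex(
            wide.index)
        res = MixedAnova(wide.to_numpy(), grp.to_numpy(),
                         timepoint_labels=tuple(timepoints)).fit()
        for term in ("group", "time", "group:time"):
            row = res.table.loc[term]
            anova_rows.append({"component": pc, "term": term,
                               "between": between,
                               "sum_sq": row["sum_sq"], "df": row["df"],
                               "F": row["F"], "p": row["p"]})
    anova_path = out / "anova_network_loadings.csv"
    pd.DataFrame(anova_rows).to_csv(anova_path, index=False)

    outputs = {"anova": str(anova_path)}
    bcol = _between_column(ft.df)
    groups = sorted(ft.df[bcol].dropna().unique()) if bcol else []
    if len(groups) == 2:
        for tp in timepoints:
            try:
                ph = posthoc_pairs(ft, alpha=cfg.alpha,
                                   between=(groups[0], groups[1]),
                                   group_column=bcol, timepoint=tp)
            except RettNetError:
                continue
            p = out / f"posthoc_{groups[0]}_vs_{groups[1]}_{tp}.csv"
            ph.table.to_csv(p, index=False)
            outputs[f"posthoc_{tp}"] = str(p)
    summary = summarize(classify_responders(pd.read_csv(clinical_path)))
    sum_path = out / "cohort_summary.csv"
    summary.table.to_csv(sum_path)
    outputs["cohort_summary"] = str(sum_path)
    return outputs


def stage_predict(cfg: RunConfig, out: Path, coh_path: str,
                  clinical_path: str) -> dict:
    ft = _feature_table(coh_path, clinical_path)
    treated = FeatureTable(ft.df[ft.df["responder"].notna()],
                           ft.feature_columns)
    ph = posthoc_pairs(treated, alpha=cfg.alpha,
                       between=cfg.predict_contrast,
                       group_column="responder", timepoint="baseline")
    ph_path = out / "posthoc_baseline_responder.csv"
    ph.table.to_csv(ph_path, index=False)
    feats = select_features(ph, cfg.alpha)
    spec = PredictorSpec(features=feats, seed=cfg.seed)
    predictor = ResponsePredictor(treated, alpha=cfg.alpha, spec=spec)
    report = predictor.fit(k=cfg.cv_folds)
    x, y = predictor._baseline_xy()
    curve = sequential_elimination(x, y, feats, k=cfg.cv_folds, spec=spec)
    report_path = out / "prediction_report.txt"
    report_path.write_text(report.summary() + "\n")
    curve_path = out / "elimination_curve.csv"
    curve.to_csv(curve_path, index=False)
    from .viz import plot_confusion
    png = out / "confusion_matrix.png"
    plot_confusion(report, png)
    return {"report": str(report_path), "elimination_curve": str(curve_path),
            "confusion_matrix": str(png),
            "posthoc_baseline": str(ph_path),
            "accuracy": report.accuracy}


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage in order; returns (and writes) the manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in asdict(cfg).items()},
                      "seed": cfg.seed, "version": __version__,
                      "numpy": np.__version__, "stages": {}}
    try:
        if cfg.mode == "simulate":
            sim = stage_simulate(cfg, out)
            recording_paths = sim["recordings"]
            clinical_path = sim["clinical"]
            manifest["stages"]["simulate"] = sim
        else:
            rec_dir = Path(cfg.recordings_dir)
            recording_paths = sorted(
                str(p) for p in rec_dir.iterdir()
                if p.suffix.lower() in (".csv", ".edf", ".txt"))
            clinical_path = cfg.clinical_path
        ext = stage_extract(cfg, out, recording_paths)
        manifest["stages"]["extract"] = ext
        net = stage_network(cfg, out, ext["coherence_features"],
                            clinical_path)
        manifest["stages"]["network"] = net
        st = stage_stats(cfg, out, ext["coherence_features"], clinical_path,
                         net["scores"])
        manifest["stages"]["stats"] = st
        try:
            pred = stage_predict(cfg, out, ext["coherence_features"],
                                 clinical_path)
            manifest["stages"]["predict"] = pred
        except RettNetError as err:
            manifest["stages"]["predict"] = {"skipped": str(err)}
    except RettNetError as err:
        raise RettNetError(f"pipeline aborted: {err}") from err

    checksums = {}
    for stage, outputs in manifest["stages"].items():
        for key, val in outputs.items():
            paths = val if isinstance(val, list) else [val]
            for p in paths:
                if isinstance(p, str) and Path(p).is_file():
                    checksums[str(Path(p).relative_to(out))] = _sha256(
                        Path(p))
    manifest["checksums"] = dict(sorted(checksums.items()))
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
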