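"""End-to-end orchestration: simulate -> extract -> select -> evaluate.

A run is described by a :class:`RunConfig` (loadable from YAML), executed by
:func:`run`, and leaves a self-contained run directory: feature tables on
request, the selection result with its trajectory, the cross-validation
report, a metric summary and a manifest with the config hash and seeds so
that identical configs reproduce identical numbers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .features import extract_roi_matrix, feature_names
from .metrics import report as metric_report
from .naive_bayes import cross_validate
from .phantom import PhantomConfig, PhantomJitter, TextureSpec, generate_dataset
from .selection import (
    KSFilter,
    RandomForestImportanceSelector,
    SelectionResult,
    SequentialBackwardEliminator,
    SequentialForwardSelector,
    pca_reduce,
    random_subset_null,
)
from .volume_io import (
    SubjectVolume,
    extract_roi,
    load_subject,
    make_folds,
    normalize_intensity,
    save_subject,
)

__all__ = ["RunConfig", "run", "load_config", "build_cohort_matrix"]

_METHODS = ("ks", "sfs", "sbe", "rf", "pca", "random-null", "none")


@dataclass
class RunConfig:
    """Flat description of one experiment run."""

    seed: int = 0
    out_dir: str = "runs/run-000"
    # input source: exactly one of phantom | files
    n_subjects: int = 6
    phantom: dict = field(default_factory=dict)  # PhantomConfig overrides
    jitter: dict | None = None  # PhantomJitter overrides
    volume_paths: list[str] | None = None
    mask_paths: list[str] | None = None
    roi_margin: int = 2
    # features
    glcm_levels: int = 8
    # selection
    method: str = "sfs"
    method_params: dict = field(default_factory=dict)
    # evaluation
    k: int = 3
    write_features: bool = False
    write_niftis: bool = False

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        phantom_source = self.volume_paths is None
        if not phantom_source and self.mask_paths is None:
            raise ValueError("mask_paths are required with volume_paths")
        if phantom_source and self.n_subjects < self.k:
            raise ValueError(f"k={self.k} exceeds the number of subjects ({self.n_subjects})")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _phantom_config(cfg: RunConfig) -> PhantomConfig:
    over = dict(cfg.phantom)
    for key in ("fg_texture", "bg_texture"):
        if key in over:
            over[key] = TextureSpec(**over[key])
    for key in ("shape", "semiaxes", "center", "intensity_range"):
        if key in over and over[key] is not None:
            over[key] = tuple(over[key])
    over.setdefault("seed", cfg.seed)
    return PhantomConfig(**over)


def _load_cohort(cfg: RunConfig) -> list[SubjectVolume]:
    if cfg.volume_paths is None:
        base = _phantom_config(cfg)
        jit = PhantomJitter(**cfg.jitter) if cfg.jitter is not None else None
        ds = generate_dataset(cfg.n_subjects, base, jit)
        return [
            SubjectVolume(subject_id=sid, intensities=vol, mask=msk)
            for sid, vol, msk in zip(ds.subject_ids, ds.volumes, ds.masks)
        ]
    return [
        load_subject(v, m, subject_id=f"sub-{i:03d}")
        for i, (v, m) in enumerate(zip(cfg.volume_paths, cfg.mask_paths))
    ]


def build_cohort_matrix(subjects: list[SubjectVolume], roi_margin: int, levels: int):
    """Stacked per-voxel feature matrix, labels and subject ids of a cohort."""
    Xs, ys, gs = [], [], []
    for sv in subjects:
        roi = normalize_intensity(extract_roi(sv, margin=roi_margin))
        X, y = extract_roi_matrix(roi, levels=levels)
        Xs.append(X)
        ys.append(y)
        gs.append(np.repeat(sv.subject_id, X.shape[0]))
    return np.vstack(Xs), np.concatenate(ys), np.concatenate(gs)


def _select(cfg: RunConfig, X, y, groups, folds):
    params = dict(cfg.method_params)
    if cfg.method == "none":
        return SelectionResult(method="none", selected=list(range(X.shape[1]))), None
    if cfg.method == "ks":
        return KSFilter(alpha=params.get("alpha", 0.05)).fit(X, y).result(), None
    if cfg.method == "sfs":
        sel = SequentialForwardSelector(
            cv=folds,
            max_steps=params.get("max_steps"),
            candidate_pool=params.get("candidate_pool"),
            seed=cfg.seed,
        )
        return sel.fit(X, y, groups=groups).result(), None
    if cfg.method == "sbe":
        sel = SequentialBackwardEliminator(
            cv=folds,
            min_features=params.get("min_features", 1),
            candidate_pool=params.get("candidate_pool"),
            seed=cfg.seed,
        )
        return sel.fit(X, y, groups=groups).result(), None
    if cfg.method == "rf":
        sel = RandomForestImportanceSelector(
            cv=folds,
            n_estimators=params.get("n_estimators", 100),
            n_thresholds=params.get("n_thresholds", 10),
            seed=cfg.seed,
        )
        return sel.fit(X, y, groups=groups).result(), None
    if cfg.method == "pca":
        frac = params.get("variance_fraction", 0.99)
        Z, fractions = pca_reduce(X, variance_fraction=frac)
        res = SelectionResult(
            method="pca",
            selected=list(range(Z.shape[1])),
            parameters={"variance_fraction": frac, "n_components": Z.shape[1]},
        )
        return res, Z
    # random-null
    values, p = random_subset_null(
        X,
        y,
        groups,
        folds,
        subset_size=params.get("subset_size", 36),
        n_draws=params.get("n_draws", 200),
        seed=cfg.seed,
        reference=params.get("reference"),
    )
    res = SelectionResult(
        method="random-null",
        selected=[],
        criterion_history=[float(v) for v in values],
        parameters={"empirical_p": p, **params},
    )
    return res, None


def run(cfg: RunConfig) -> Path:
    """Execute one full run; returns the run directory.

    On failure the manifest is left with status "incomplete" so partial runs
    are recognizable.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "status": "incomplete",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    try:
        subjects = _load_cohort(cfg)
        if cfg.write_niftis:
            for sv in subjects:
                save_subject(
                    sv,
                    out / f"{sv.subject_id}_vol.nii.gz",
                    out / f"{sv.subject_id}_mask.nii.gz",
                )
        X, y, groups = build_cohort_matrix(subjects, cfg.roi_margin, cfg.glcm_levels)
        if cfg.write_features:
            import pandas as pd

            df = pd.DataFrame(X, columns=feature_names())
            df["class"] = np.where(y == 1, "A", "B")
            df["subject"] = groups
            df.to_csv(out / "features.csv", index=False)
        folds = make_folds(np.unique(groups), cfg.k, seed=cfg.seed)
        folds.to_json(out / "folds.json")

        result, projected = _select(cfg, X, y, groups, folds)
        result.to_json(out / "selection.json", feature_names=feature_names())
        if result.trajectory:
            (out / "trajectory.tsv").write_text(result.trajectory_table())

        if cfg.method == "pca":
            report = cross_validate(projected, y, groups, folds)
        elif cfg.method == "random-null":
            report = cross_validate(X, y, groups, folds)
        else:
            report = cross_validate(X, y, groups, folds, feature_idx=result.selected)
        report.to_json(out / "cv_report.json")

        from .metrics import ConfusionMatrix

        pooled = ConfusionMatrix(
            n_aa=sum(s.cm.n_aa for s in report.scores),
            n_ab=sum(s.cm.n_ab for s in report.scores),
            n_ba=sum(s.cm.n_ba for s in report.scores),
            n_bb=sum(s.cm.n_bb for s in report.scores),
        )
        summary = {
            "method": cfg.method,
            "n_selected": len(result.selected),
            "mean_dice": report.mean_dice,
            "sd_dice": report.sd_dice if len(report.scores) > 1 else None,
            "pooled": metric_report(pooled),
        }
        (out / "metrics.json").write_text(json.dumps(summary, indent=2))

        manifest["status"] = "complete"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except Exception:
        manifest["status"] = "incomplete"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    return out
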