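"""Aggregation arithmetic and the end-to-end experiment driver.

The experiment mirrors a negative-sample injection study: a family of
detector variants — a baseline trained without not-polyp images plus
variants "trained" with increasing negative injections (modelled here as
profiles with progressively smaller false-positive rates on negative
imagery) — is pushed through

1. threshold selection on a validation partition (maximum-F1 operating
   point on the PR curve);
2. an intra-dataset evaluation on the test partition augmented with 0%, 2%,
   5%, 10% and 15% injected not-polyp images;
3. an inter-dataset evaluation over a panel of independent synthetic
   datasets, some containing negatives and some not, with unweighted
   grouped F1 averages;
4. a frame-level analysis of a polyp video and a not-polyp video.

Every displayed number in the emitted TSVs is recomputable from the bundled
raw counts; display rounding is 3 decimals for metrics and 2 for
percentages, half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .errors import UndefinedMetricError, ValidationError
from .evaluation import MatchCriterion, evaluate, pr_curve, select_threshold
from .injection import materialize_partition, plan_injection
from .rounding import metric_round, percent_round
from .synthetic_detector import (
    DatasetSpec,
    DetectorProfile,
    generate_dataset,
    profile_from_metrics,
    simulate_detections,
    simulate_video,
)
from .video_frames import RECALL_PROXY_NOTE, relative_change, summarize_video

# ---------------------------------------------------------------------------
# Grouped averages
# ---------------------------------------------------------------------------


@dataclass
class GroupedF1Report:
    """Unweighted per-group and global means of per-dataset F1 scores."""

    per_dataset: dict[str, float]
    groups: dict[str, str]
    group_averages: dict[str, float | None]
    global_average: float

    def display(self) -> dict[str, float | None]:
        """Averages rounded at 3 decimals for table display."""
        out = {
            group: (None if avg is None else metric_round(avg))
            for group, avg in self.group_averages.items()
        }
        out["global"] = metric_round(self.global_average)
        return out


def grouped_average(
    f1_by_dataset: Mapping[str, float],
    groups: Mapping[str, str],
) -> GroupedF1Report:
    """Unweighted arithmetic means of F1 per group and globally.

    Every dataset must carry a group label. A group with no member datasets
    is reported as ``None`` (absent), never as zero.
    """
    if not f1_by_dataset:
        raise ValidationError("no datasets to average")
    missing = [d for d in f1_by_dataset if d not in groups]
    if missing:
        raise ValidationError(f"datasets without a group: {missing}")

    group_values: dict[str, list[float]] = {g: [] for g in set(groups.values())}
    for dataset, f1 in f1_by_dataset.items():
        group_values[groups[dataset]].append(f1)
    group_averages = {
        g: (sum(vals) / len(vals) if vals else None)
        for g, vals in group_values.items()
    }
    global_average = sum(f1_by_dataset.values()) / len(f1_by_dataset)
    return GroupedF1Report(
        per_dataset=dict(f1_by_dataset),
        groups={d: groups[d] for d in f1_by_dataset},
        group_averages=group_averages,
        global_average=global_average,
    )


def relative_f1_change(baseline_f1: float, model_f1: float) -> float:
    """Signed percentage change of a model's F1 w.r.t. a baseline's."""
    if baseline_f1 <= 0:
        raise UndefinedMetricError("relative F1 change undefined for baseline 0")
    return 100.0 * (model_f1 - baseline_f1) / baseline_f1


# ---------------------------------------------------------------------------
# Experiment configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """One detector variant: a label, its simulator profile, and the
    injection level whose validation partition selects its threshold."""

    label: str
    profile: DetectorProfile
    train_level: float = 0.0


@dataclass
class ExperimentConfig:
    dataset: DatasetSpec
    models: list[ModelSpec]
    levels: list[float] = field(default_factory=lambda: [2.0, 5.0, 10.0, 15.0])
    public_datasets: list[tuple[str, DatasetSpec]] = field(default_factory=list)
    criterion: MatchCriterion = field(default_factory=MatchCriterion)
    injection_seed: int = 0
    video_polyp_frames: int = 450
    video_negative_frames: int = 350

    def __post_init__(self) -> None:
        labels = [m.label for m in self.models]
        if len(set(labels)) != len(labels):
            raise ValidationError("model labels must be unique")
        if not self.models:
            raise ValidationError("at least one model is required")


# Measured operating points of the five detector variants the default
# experiment emulates: (recall, precision on the polyp-only test set,
# precision after 15% negative injection). The simulator profiles are
# calibrated so their expected metrics reproduce these points.
DEFAULT_OPERATING_POINTS: dict[str, tuple[float, float, float]] = {
    "baseline": (0.872, 0.890, 0.836),
    "injection_2": (0.867, 0.894, 0.871),
    "injection_5": (0.875, 0.902, 0.881),
    "injection_10": (0.850, 0.904, 0.895),
    "injection_15": (0.880, 0.910, 0.901),
}

DEFAULT_TRAIN_LEVELS: dict[str, float] = {
    "baseline": 0.0,
    "injection_2": 2.0,
    "injection_5": 5.0,
    "injection_10": 10.0,
    "injection_15": 15.0,
}

# Inter-dataset panel: ten independent datasets, four containing not-polyp
# images (negative fractions mirror public colonoscopy collections, which
# carry between ~1% and ~16% not-polyp frames) and six polyp-only.
DEFAULT_PUBLIC_PANEL: list[tuple[str, float]] = [
    ("public_neg_a", 0.1614),
    ("public_neg_b", 0.0125),
    ("public_neg_c", 0.0508),
    ("public_neg_d", 0.1570),
    ("public_pos_a", 0.0),
    ("public_pos_b", 0.0),
    ("public_pos_c", 0.0),
    ("public_pos_d", 0.0),
    ("public_pos_e", 0.0),
    ("public_pos_f", 0.0),
]


def default_experiment_config(
    seed: int = 0,
    *,
    n_polyp_images: int = 2000,
    n_negative_pool: int = 1200,
    n_public_polyp: int = 250,
) -> ExperimentConfig:
    """Build the default experiment: five calibrated detector variants, a
    49/21/30-split development dataset, nested 2/5/10/15% injections, and a
    ten-dataset inter-dataset panel.

    ``seed`` drives every source of randomness (dataset content, injection
    plan, simulated detections).
    """
    dataset = DatasetSpec(
        n_polyp_images=n_polyp_images,
        n_negative_images=n_negative_pool,
        seed=seed,
    )
    models = []
    for i, (label, (recall, p_clean, p_at15)) in enumerate(
            DEFAULT_OPERATING_POINTS.items()):
        profile = profile_from_metrics(
            recall, p_clean, p_at15, 15.0,
            jitter_frac=0.05, seed=seed * 1000 + i + 1,
        )
        models.append(ModelSpec(label=label, profile=profile,
                                train_level=DEFAULT_TRAIN_LEVELS[label]))
    public = []
    for j, (name, neg_frac) in enumerate(DEFAULT_PUBLIC_PANEL):
        n_neg = int(round(neg_frac * n_public_polyp))
        public.append((name, DatasetSpec(
            n_polyp_images=n_public_polyp,
            n_negative_images=n_neg,
            id_prefix=f"{name}_",
            seed=seed * 1000 + 100 + j,
        )))
    return ExperimentConfig(
        dataset=dataset,
        models=models,
        public_datasets=public,
        injection_seed=seed,
    )


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------


@dataclass
class ExperimentReport:
    """All tables produced by :func:`run_experiment`, as DataFrames."""

    validation: pd.DataFrame        # per model: threshold, recall, precision, f1, ap
    intra: pd.DataFrame             # per model x level: counts + metrics
    precision_matrix: pd.DataFrame  # models x injection levels (precision)
    public_f1: pd.DataFrame         # per dataset x model: f1 + group
    public_averages: pd.DataFrame   # group / global averages per model
    video: pd.DataFrame             # per model: frame summary + relative changes
    summary: pd.DataFrame           # per model: mean F1 over the 5 test partitions
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.validation.to_csv(out_dir / "validation_models.tsv", sep="\t", index=False)
        self.intra.to_csv(out_dir / "intra_dataset.tsv", sep="\t", index=False)
        self.precision_matrix.to_csv(out_dir / "precision_matrix.tsv", sep="\t")
        self.public_f1.to_csv(out_dir / "public_f1.tsv", sep="\t")
        self.public_averages.to_csv(out_dir / "public_f1_averages.tsv", sep="\t")
        self.video.to_csv(out_dir / "video_summary.tsv", sep="\t", index=False)
        self.summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)
        (out_dir / "provenance.yaml").write_text(
            yaml.safe_dump(self.provenance, sort_keys=True))


def run_experiment(
    config: ExperimentConfig,
    out_dir: str | Path | None = None,
) -> ExperimentReport:
    """Run the full injection experiment; deterministic given the config's
    seeds. Writes the report bundle to ``out_dir`` when given."""
    manifest = generate_dataset(config.dataset)
    base = {
        part: [img.image_id for img in manifest.images
               if img.partition == part and img.has_polyp]
        for part in ("training", "validation", "test")
    }
    pool = [img.image_id for img in manifest.images if not img.has_polyp]
    plan = plan_injection(base, pool, config.levels, config.injection_seed)

    all_levels = [0.0] + [float(l) for l in config.levels]
    criterion = config.criterion
    baseline_label = config.models[0].label

    validation_rows = []
    intra_rows = []
    video_rows = []
    thresholds: dict[str, float] = {}

    for model in config.models:
        # --- threshold selection on the model's validation partition
        val_part = materialize_partition(plan, "validation", model.train_level,
                                         manifest)
        val_manifest = val_part.as_manifest()
        val_dets = simulate_detections(val_manifest, model.profile)
        curve = pr_curve(val_manifest, val_dets, criterion)
        thr = select_threshold(curve)
        thresholds[model.label] = thr
        _, val_metrics = evaluate(val_manifest, val_dets, thr, criterion)
        validation_rows.append({
            "model": model.label,
            "train_level": model.train_level,
            "threshold": thr,
            "recall": _r3(val_metrics.recall),
            "precision": _r3(val_metrics.precision),
            "f1": _r3(val_metrics.f1),
            "ap": metric_round(curve.ap),
        })

        # --- intra-dataset evaluation over augmented test partitions
        for level in all_levels:
            part = materialize_partition(plan, "test", level, manifest)
            part_manifest = part.as_manifest()
            dets = simulate_detections(part_manifest, model.profile)
            counts, metrics = evaluate(part_manifest, dets, thr, criterion)
            intra_rows.append({
                "model": model.label,
                "level": level,
                "tp": counts.tp, "fp": counts.fp, "fn": counts.fn,
                "recall": _r3(metrics.recall),
                "precision": _r3(metrics.precision),
                "f1": _r3(metrics.f1),
            })

        # --- frame-level video analysis
        polyp_frames = simulate_video(
            config.video_polyp_frames, True, model.profile,
            id_prefix="polypvideo")
        neg_frames = simulate_video(
            config.video_negative_frames, False, model.profile,
            id_prefix="negvideo")
        polyp_summary = summarize_video(polyp_frames,
                                        config.video_polyp_frames, thr)
        neg_summary = summarize_video(neg_frames,
                                      config.video_negative_frames, thr)
        video_rows.append({
            "model": model.label,
            "polyp_frames": polyp_summary.n_frames,
            "polyp_frames_with_box": polyp_summary.frames_with_box,
            "polyp_frames_with_box_pct": polyp_summary.frames_with_box_pct,
            "negative_total_boxes": neg_summary.total_boxes,
        })

    # relative changes on the video metrics w.r.t. the first (baseline) model
    ref = video_rows[0]
    for row in video_rows:
        row["polyp_frames_rel_change_pct"] = (
            0.0 if row is ref else percent_round(relative_change(
                ref["polyp_frames_with_box"], row["polyp_frames_with_box"]))
        )
        row["negative_boxes_rel_change_pct"] = (
            0.0 if row is ref else percent_round(relative_change(
                ref["negative_total_boxes"], row["negative_total_boxes"]))
            if ref["negative_total_boxes"] > 0 else None
        )

    intra = pd.DataFrame(intra_rows)
    precision_matrix = intra.pivot(index="model", columns="level",
                                   values="precision").reindex(
        [m.label for m in config.models])

    # --- inter-dataset evaluation
    public_f1_rows = []
    groups: dict[str, str] = {}
    for name, spec in config.public_datasets:
        ds = generate_dataset(spec, name=name)
        groups[name] = ("with_negatives" if ds.contains_negatives
                        else "polyp_only")
        row = {"dataset": name, "group": groups[name]}
        for model in config.models:
            dets = simulate_detections(ds, model.profile)
            _, metrics = evaluate(ds, dets, thresholds[model.label], criterion)
            row[model.label] = _r3(metrics.f1)
        public_f1_rows.append(row)
    public_f1 = pd.DataFrame(public_f1_rows).set_index("dataset") \
        if public_f1_rows else pd.DataFrame()

    avg_rows = []
    if public_f1_rows:
        for model in config.models:
            f1s = {r["dataset"]: r[model.label] for r in public_f1_rows}
            report = grouped_average(f1s, groups)
            disp = report.display()
            avg_rows.append({
                "model": model.label,
                "with_negatives": disp.get("with_negatives"),
                "polyp_only": disp.get("polyp_only"),
                "global": disp["global"],
            })
    public_averages = pd.DataFrame(avg_rows).set_index("model") \
        if avg_rows else pd.DataFrame()

    # --- headline summary: mean F1 over the original + four augmented test
    # partitions (five values per model)
    summary_rows = []
    for model in config.models:
        f1s = intra.loc[intra["model"] == model.label, "f1"].tolist()
        summary_rows.append({
            "model": model.label,
            "threshold": thresholds[model.label],
            "mean_f1_test_partitions": metric_round(sum(f1s) / len(f1s)),
        })

    provenance = {
        "package_version": __version__,
        "criterion": criterion.describe(),
        "dataset_seed": config.dataset.seed,
        "injection_seed": config.injection_seed,
        "model_seeds": {m.label: m.profile.seed for m in config.models},
        "levels": [float(l) for l in config.levels],
        "notes": [
            RECALL_PROXY_NOTE,
            "metrics display at 3 decimals, percentages at 2, "
            "half away from zero",
            "mean_f1_test_partitions averages the original test partition "
            "and the four negative-augmented test partitions",
        ],
    }

    report = ExperimentReport(
        validation=pd.DataFrame(validation_rows),
        intra=intra,
        precision_matrix=precision_matrix,
        public_f1=public_f1,
        public_averages=public_averages,
        video=pd.DataFrame(video_rows),
        summary=pd.DataFrame(summary_rows),
        provenance=provenance,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def _r3(value: float | None) -> float | None:
    return None if value is None else metric_round(value)
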