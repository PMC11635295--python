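"""End-to-end orchestration: raw cohort -> QC -> FC -> networks -> stats -> classification.

Per-subject processing follows the acquisition-analysis order: MBLL
conversion, channel QC on the unfiltered data, 0.01-0.1 Hz band-pass, PCA
motion correction, 5-min stable segment, Pearson FC on HbT, ROI means,
sparsity-grid graph metrics with AUCs.  Cohort-level processing adds the
two-sample comparisons (6 ROI means + 4 graph AUCs) and the leave-one-out
KNN/LDA feature-set evaluation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, connectivity, groupstats, network, preprocess, quality
from .montage import Montage, default_montage
from .optics import OpticalModel, default_optics
from .recording import RawRecording

__all__ = ["PipelineParams", "SubjectResult", "CohortResult",
           "process_subject", "run_cohort", "write_results"]


@dataclass(frozen=True)
class PipelineParams:
    """Every decision knob of the pipeline, serialisable alongside outputs."""

    band: tuple[float, float] = (0.01, 0.1)
    filter_order: int = 3
    pca_components: int = 1
    segment_length: float = 300.0
    segment_offset: int | None = None
    snr_threshold: float = 2.0
    cardiac_band: tuple[float, float] = (0.8, 1.6)
    cardiac_ratio_threshold: float = 0.05
    sparsity_grid: tuple[float, ...] = tuple(network.default_sparsity_grid())
    metrics: tuple[str, ...] = network.METRIC_NAMES
    edge_threshold: float = 0.35
    knn_k: int = 3
    n_repeats: int = 20
    lda_ridge: float | None = 1e-8
    feature_sets: tuple[str, ...] = tuple(classify.FEATURE_SETS)

    def to_json(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(self).items()}
        return json.dumps(d, indent=1)


@dataclass
class SubjectResult:
    subject_id: str
    qc: quality.QCReport
    fc: connectivity.FCMatrix
    roi: dict[str, tuple[float, int]]
    metrics: network.NetworkMetrics

    def feature_row(self) -> dict[str, float]:
        row = {m: self.metrics.auc[m] for m in self.metrics.auc}
        row.update({region: v[0] for region, v in self.roi.items()})
        return row


def process_subject(
    raw: RawRecording,
    montage: Montage | None = None,
    optics: OpticalModel | None = None,
    params: PipelineParams | None = None,
) -> SubjectResult:
    """Run the full single-subject chain and collect all stage outputs."""
    montage = montage or default_montage()
    optics = optics or default_optics()
    p = params or PipelineParams()

    hemo = preprocess.mbll_convert(raw, optics)
    qc = quality.prune_channels(
        raw, hemo,
        snr_threshold=p.snr_threshold,
        cardiac_band=p.cardiac_band,
        cardiac_ratio_threshold=p.cardiac_ratio_threshold,
    )
    if not np.any(qc.active_mask()):
        raise ValueError(f"subject {raw.subject_id}: all channels failed QC")
    hemo = preprocess.bandpass(hemo, *p.band, order=p.filter_order)
    if p.pca_components:
        hemo, _ = preprocess.pca_motion_correct(hemo, n_components=p.pca_components)
    hemo = preprocess.select_stable_segment(hemo, p.segment_length, offset=p.segment_offset)
    fc = connectivity.fc_matrix(hemo, qc)
    roi = connectivity.roi_mean(fc, montage)
    met = network.metrics_over_grid(fc, np.asarray(p.sparsity_grid), metrics=p.metrics)
    return SubjectResult(subject_id=raw.subject_id, qc=qc, fc=fc, roi=roi, metrics=met)


@dataclass
class CohortResult:
    subjects: list[SubjectResult]
    labels: list[str]
    features: pd.DataFrame
    comparisons: pd.DataFrame
    classification: pd.DataFrame | None
    group_mean_fc: dict[str, connectivity.FCMatrix]
    excluded: list[str] = field(default_factory=list)


def run_cohort(
    recordings: list[RawRecording],
    labels: list[str],
    montage: Montage | None = None,
    optics: OpticalModel | None = None,
    params: PipelineParams | None = None,
    classify_features: bool = True,
    group_a: str = "MCS",
) -> CohortResult:
    """Process every subject, then compare groups and classify.

    A subject whose channels all fail QC is excluded with a warning rather
    than aborting the cohort.
    """
    montage = montage or default_montage()
    p = params or PipelineParams()
    results, kept_labels, excluded = [], [], []
    for raw, lab in zip(recordings, labels, strict=True):
        try:
            results.append(process_subject(raw, montage, optics, p))
            kept_labels.append(lab)
        except ValueError as e:
            if "failed QC" in str(e):
                warnings.warn(str(e) + "; subject excluded", stacklevel=2)
                excluded.append(raw.subject_id)
            else:
                raise ValueError(f"subject {raw.subject_id}: {e}") from e

    features = pd.DataFrame(
        [r.feature_row() for r in results], index=[r.subject_id for r in results]
    )
    if len(set(kept_labels)) == 2:
        comparisons = groupstats.compare_all(features, kept_labels, group_a=group_a)
    else:  # single-group cohort (e.g. a null pool): nothing to compare
        comparisons = pd.DataFrame()
    classification = None
    if classify_features:
        sets = {n: classify.FEATURE_SETS[n] for n in p.feature_sets}
        classification = classify.classification_report(
            features, kept_labels, feature_sets=sets,
            k=p.knn_k, n_repeats=p.n_repeats, ridge=p.lda_ridge,
        )
    mean_fc = {
        lab: connectivity.group_mean_fc(
            [r.fc for r, l in zip(results, kept_labels) if l == lab]
        )
        for lab in dict.fromkeys(kept_labels)
    }
    return CohortResult(
        subjects=results, labels=kept_labels, features=features,
        comparisons=comparisons, classification=classification,
        group_mean_fc=mean_fc, excluded=excluded,
    )


def write_results(
    out_dir: str | Path,
    res: CohortResult,
    montage: Montage | None = None,
    params: PipelineParams | None = None,
    edge_threshold: float = 0.35,
) -> Path:
    """Write stage-by-stage tidy CSV/JSON outputs under ``out_dir``."""
    out = Path(out_dir)
    montage = montage or default_montage()
    for sub in ("qc", "fc", "network", "edges"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for r in res.subjects:
        (out / "qc" / f"{r.subject_id}.csv").write_text(r.qc.to_csv())
        (out / "fc" / f"{r.subject_id}.csv").write_text(r.fc.to_csv())
    curves = pd.DataFrame(
        [row for r in res.subjects for row in r.metrics.to_rows()]
    )
    curves.to_csv(out / "network" / "metric_curves.csv", index=False)
    res.features.to_csv(out / "features.csv", index_label="subject")
    res.comparisons.to_csv(out / "group_comparisons.csv", index=False)
    if res.classification is not None:
        res.classification.to_csv(out / "classification.csv", index=False)
    for lab, fc in res.group_mean_fc.items():
        node, edge = connectivity.export_node_edge(fc, montage, threshold=edge_threshold)
        (out / "edges" / f"{lab}.node").write_text(node)
        (out / "edges" / f"{lab}.edge").write_text(edge)
        (out / "fc" / f"group_mean_{lab}.csv").write_text(fc.to_csv())
    meta = {
        "labels": res.labels,
        "excluded_subjects": res.excluded,
        "auc_rule": "trapezoid",
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=1))
    if params is not None:
        (out / "effective_params.json").write_text(params.to_json())
    return out
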