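"""Whole-brain functional connectivity on HbT and its summaries.

Each channel is a node; the subject-level FC matrix is the 48 x 48 Pearson
correlation of the (preprocessed, 5-min segment) HbT series.  Summaries:
within-region mean correlations over the six ROIs, pooled FC-value
histograms per group, and suprathreshold edge lists of the group-mean matrix
(default r > 0.35) exported as BrainNet-Viewer-style .node/.edge text.
ROI means average raw r (no Fisher z) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .montage import Montage
from .quality import QCReport
from .recording import HemoRecording

__all__ = [
    "FCMatrix",
    "fc_matrix",
    "roi_mean",
    "group_mean_fc",
    "mean_connectivity_strength",
    "fc_distribution",
    "suprathreshold_edges",
    "export_node_edge",
]


@dataclass
class FCMatrix:
    """Symmetric Pearson correlation matrix with an active-channel mask."""

    r: np.ndarray
    active: np.ndarray
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.active = np.asarray(self.active, dtype=bool)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("FC matrix must be square")
        if self.active.shape != (self.r.shape[0],):
            raise ValueError("active mask length must match matrix size")

    @property
    def n_channels(self) -> int:
        return self.r.shape[0]

    def active_values(self) -> np.ndarray:
        """Off-diagonal upper-triangle r values over active pairs."""
        i, j = np.triu_indices(self.n_channels, k=1)
        ok = self.active[i] & self.active[j] & np.isfinite(self.r[i, j])
        return self.r[i, j][ok]

    def to_csv(self) -> str:
        lines = [",".join(f"ch{c + 1}" for c in range(self.n_channels))]
        for row in self.r:
            lines.append(",".join("" if not np.isfinite(v) else repr(v) for v in row))
        return "\n".join(lines) + "\n"


def fc_matrix(hemo: HemoRecording, qc: QCReport | None = None) -> FCMatrix:
    """Pearson FC of the HbT series; QC-pruned channels are masked missing.

    Zero-variance channels cannot carry a correlation; they are flagged
    inactive with a warning rather than raising.
    """
    if hemo.n_samples < 2:
        raise ValueError("need at least 2 samples to correlate")
    x = hemo.hbt
    active = np.ones(hemo.n_channels, dtype=bool)
    if qc is not None:
        if qc.n_channels != hemo.n_channels:
            raise ValueError("QC report channel count does not match recording")
        active &= qc.active_mask()
    sd = x.std(axis=1)
    zero_var = (sd == 0) | ~np.isfinite(sd)
    if np.any(zero_var & active):
        warnings.warn(
            f"zero-variance channel(s) {np.flatnonzero(zero_var & active) + 1}: "
            "correlations undefined, marked missing",
            stacklevel=2,
        )
        active &= ~zero_var
    if active.sum() < 2:
        raise ValueError("fewer than 2 active channels; FC undefined")
    r = np.full((hemo.n_channels, hemo.n_channels), np.nan)
    idx = np.flatnonzero(active)
    with np.errstate(invalid="ignore"):
        sub = np.corrcoef(x[idx])
    r[np.ix_(idx, idx)] = np.clip(sub, -1.0, 1.0)
    return FCMatrix(r=r, active=active, subject_id=hemo.subject_id)


def roi_mean(
    fc: FCMatrix, montage: Montage, fisher_z: bool = False
) -> dict[str, tuple[float, int]]:
    """Mean within-region off-diagonal correlation per ROI.

    Averages the unordered within-region channel pairs whose both channels
    are active; returns {region: (mean r, n_pairs)}.  A region with fewer
    than 2 active channels gets (nan, 0).  ``fisher_z`` averages arctanh(r)
    and transforms back (off by default; raw-r averaging is the reference
    behaviour).
    """
    out: dict[str, tuple[float, int]] = {}
    for name in montage.regions:
        idx = [i for i in montage.region_indices(name) if fc.active[i]]
        vals = []
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                v = fc.r[idx[a], idx[b]]
                if np.isfinite(v):
                    vals.append(v)
        if len(idx) < 2 or not vals:
            out[name] = (float("nan"), 0)
            continue
        arr = np.asarray(vals)
        if fisher_z:
            m = float(np.tanh(np.mean(np.arctanh(np.clip(arr, -0.999999, 0.999999)))))
        else:
            m = float(arr.mean())
        out[name] = (m, len(vals))
    return out


def group_mean_fc(fcs: list[FCMatrix], min_subjects: int = 1) -> FCMatrix:
    """Entrywise mean FC over subjects where both channels are active.

    Entries supported by fewer than ``min_subjects`` subjects are missing.
    """
    if not fcs:
        raise ValueError("empty FC matrix list")
    n = fcs[0].n_channels
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    for fc in fcs:
        if fc.n_channels != n:
            raise ValueError("FC matrices differ in size")
        ok = np.outer(fc.active, fc.active) & np.isfinite(fc.r)
        total[ok] += fc.r[ok]
        count[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count >= max(min_subjects, 1), total / np.maximum(count, 1), np.nan)
    active = np.isfinite(np.diagonal(mean))
    return FCMatrix(r=mean, active=active, subject_id="group_mean")


def mean_connectivity_strength(fc: FCMatrix) -> float:
    """Mean off-diagonal r over active pairs (whole-brain FC strength)."""
    vals = fc.active_values()
    return float(vals.mean()) if len(vals) else float("nan")


def fc_distribution(
    fcs: list[FCMatrix], bin_edges: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of off-diagonal upper-triangle FC values pooled over subjects.

    Default edges run from -1 to 1 in steps of 0.1, placing a boundary at
    0.1 (the weak-connectivity cut used in group summaries).
    """
    if not fcs:
        raise ValueError("empty FC matrix list")
    if bin_edges is None:
        bin_edges = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    vals = np.concatenate([fc.active_values() for fc in fcs])
    counts, _ = np.histogram(vals, bins=bin_edges)
    return counts, bin_edges


def suprathreshold_edges(
    mean_fc: FCMatrix, threshold: float = 0.35
) -> list[tuple[int, int, float]]:
    """Channel pairs of a group-mean FC with mean r above threshold.

    Returns (i, j, r) with 1-based channel ids, i < j, sorted by (i, j).
    """
    edges = []
    n = mean_fc.n_channels
    for i in range(n):
        for j in range(i + 1, n):
            v = mean_fc.r[i, j]
            if np.isfinite(v) and v > threshold:
                edges.append((i + 1, j + 1, float(v)))
    return edges


def export_node_edge(
    mean_fc: FCMatrix,
    montage: Montage,
    threshold: float = 0.35,
    coords: np.ndarray | None = None,
) -> tuple[str, str]:
    """BrainNet-Viewer-style .node/.edge text for a group-mean FC matrix.

    Without measured optode coordinates the nodes are laid out on a circle
    (sufficient for the text interchange format; columns are x y z color
    size label).  Node color encodes the module index of the channel's
    region.
    """
    n = mean_fc.n_channels
    if coords is None:
        ang = 2 * np.pi * np.arange(n) / n
        coords = np.column_stack([np.cos(ang) * 80, np.sin(ang) * 80, np.zeros(n)])
    modules = montage.module_assignment()
    node_lines = []
    for i in range(n):
        x, y, z = coords[i]
        node_lines.append(
            f"{x:.2f}\t{y:.2f}\t{z:.2f}\t{modules[i] + 1}\t1\tch{i + 1}"
        )
    adj = np.zeros((n, n))
    for i, j, v in suprathreshold_edges(mean_fc, threshold):
        adj[i - 1, j - 1] = adj[j - 1, i - 1] = v
    edge_lines = ["\t".join(f"{v:.4f}" for v in row) for row in adj]
    return "\n".join(node_lines) + "\n", "\n".join(edge_lines) + "\n"
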