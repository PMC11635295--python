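"""Two-sample group comparisons of FC and network features.

Student's pooled-variance two-sample t-test (Welch selectable), two-tailed
p values, Cohen's d effect sizes pooled over df = n1 + n2 - 2, and a batch
comparator over a subject x feature table.  No multiple-testing correction
is applied by default (an explicit Benjamini-Hochberg FDR option exists and
its absence is flagged in the report).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["two_sample_t", "cohens_d", "GroupComparison", "compare_all"]


def _as_sample(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("each sample needs >= 2 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    return x


def two_sample_t(x, y, welch: bool = False) -> tuple[float, float]:
    """Two-sample t statistic (sign follows x - y) and two-tailed p value.

    Default is the classical pooled-variance Student test with
    df = n1 + n2 - 2; ``welch=True`` selects the unequal-variance variant.
    Degenerate zero-variance input follows a documented contract: equal
    means give (0, 1); unequal means give (+/-inf, 0).
    """
    x, y = _as_sample(x), _as_sample(y)
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def cohens_d(x, y) -> float:
    """Cohen's d = (mean_x - mean_y) / pooled SD (pooled over n1 + n2 - 2).

    Returns nan when the pooled SD is zero (effect size undefined).
    """
    x, y = _as_sample(x), _as_sample(y)
    n1, n2 = len(x), len(y)
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


@dataclass
class GroupComparison:
    feature: str
    t: float
    p: float
    d: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    significant: bool


def compare_all(
    features: pd.DataFrame,
    labels,
    group_a: str | None = None,
    alpha: float = 0.05,
    welch: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Compare every feature column between the two label groups.

    ``features`` is a subjects x features table; ``labels`` assigns each row
    to one of exactly two groups.  ``group_a`` names the group whose mean
    enters the t and d statistics with positive sign (defaults to the first
    label encountered).  Features containing missing values are excluded
    with a warning column rather than poisoning the table.  With
    ``fdr=True`` the significance flag uses Benjamini-Hochberg adjusted
    p values; otherwise raw p < alpha (no correction, which is flagged in
    the ``corrected`` column).
    """
    labels = np.asarray(labels)
    if len(labels) != len(features):
        raise ValueError("labels length must match feature table rows")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    a = group_a if group_a is not None else uniq[0]
    b = [u for u in uniq if u != a][0]
    xa_mask, xb_mask = labels == a, labels == b
    if xa_mask.sum() < 2 or xb_mask.sum() < 2:
        raise ValueError("each group needs >= 2 subjects")

    rows, skipped = [], []
    for col in features.columns:
        va = features.loc[xa_mask, col].to_numpy(dtype=float)
        vb = features.loc[xb_mask, col].to_numpy(dtype=float)
        if not (np.all(np.isfinite(va)) and np.all(np.isfinite(vb))):
            skipped.append(col)
            continue
        t, p = two_sample_t(va, vb, welch=welch)
        d = cohens_d(va, vb)
        rows.append(
            GroupComparison(
                feature=str(col), t=t, p=p, d=d,
                mean_a=float(va.mean()), sd_a=float(va.std(ddof=1)),
                mean_b=float(vb.mean()), sd_b=float(vb.std(ddof=1)),
                n_a=int(len(va)), n_b=int(len(vb)),
                significant=bool(p < alpha),
            )
        )
    if skipped:
        import warnings

        warnings.warn(f"features with missing values excluded: {skipped}", stacklevel=2)
    out = pd.DataFrame([vars(r) for r in rows])
    if len(out):
        if fdr:
            out["p_adj"] = _bh_adjust(out["p"].to_numpy())
            out["significant"] = out["p_adj"] < alpha
        out["corrected"] = "BH" if fdr else "none"
    return out


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
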