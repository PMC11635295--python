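"""Monte-Carlo evaluation suites for the pipeline's statistical guarantees.

These routines quantify, by simulation with the synthetic cohort generator,
the properties the pipeline claims: graph metrics agree with brute-force
enumeration, planted bad channels are detected without false positives, the
two-sample t-test is calibrated under the null and powered against the
planted global-efficiency effect, and leave-one-out classification behaves
sanely (perfect on separable features, at chance under permuted labels,
and not hurt by combining discriminative features).

Problem sizes default to reduced study conditions (330-600 s recordings,
small groups where the check does not require the 8/10 split) so every
suite runs in minutes on one CPU; see the methods note for the choices.
"""

from __future__ import annotations

import numpy as np

from . import classify, groupstats, network, preprocess, quality
from .pipeline import PipelineParams, run_cohort
from .synthcohort import SynthConfig, generate_cohort

__all__ = [
    "brute_force_metrics",
    "graph_oracle_agreement",
    "qc_detection",
    "ttest_null_calibration",
    "eg_effect_power",
    "classification_sanity",
    "hybrid_feature_ordering",
]

_EXPECT_REASON = {"low_snr": "snr", "no_cardiac": "cardiac", "anticorrelated": "corr"}


# ---------------------------------------------------------------------------
# suite 1: graph metrics vs exhaustive enumeration

def brute_force_metrics(adj: np.ndarray) -> tuple[float, float, float, float]:
    """(Lp, Cp, Eg, Eloc) by Floyd-Warshall and exhaustive enumeration.

    Deliberately independent of the package implementation (which uses
    breadth-first search via scipy.sparse.csgraph and adjacency algebra).
    """
    n = len(adj)

    def fw(a):
        d = np.where(a, 1.0, np.inf)
        np.fill_diagonal(d, 0.0)
        for k in range(len(a)):
            for i in range(len(a)):
                for j in range(len(a)):
                    if d[i, k] + d[k, j] < d[i, j]:
                        d[i, j] = d[i, k] + d[k, j]
        return d

    def eg_of(d):
        m = len(d)
        off = ~np.eye(m, dtype=bool)
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
        return float(inv[off].mean())

    d = fw(adj)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    lp = float(d[finite].mean()) if finite.any() else float("nan")
    eg = eg_of(d)
    cp_terms, eloc_terms = [], []
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        k = len(nb)
        if k < 2:
            cp_terms.append(0.0)
            eloc_terms.append(0.0)
            continue
        e_i = sum(adj[u, v] for ai, u in enumerate(nb) for v in nb[ai + 1:])
        cp_terms.append(e_i / (k * (k - 1) / 2))
        eloc_terms.append(eg_of(fw(adj[np.ix_(nb, nb)])))
    return lp, float(np.mean(cp_terms)), eg, float(np.mean(eloc_terms))


def graph_oracle_agreement(n_graphs: int = 100, max_nodes: int = 12,
                           seed: int = 0) -> dict:
    """Compare Lp/Cp/Eg/Eloc with the brute-force oracle on random graphs."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    n_compared = 0
    for _ in range(n_graphs):
        n = int(rng.integers(4, max_nodes + 1))
        p = rng.uniform(0.1, 0.9)
        a = np.triu(rng.random((n, n)) < p, 1)
        a = a | a.T
        net = network.BinaryNetwork(adjacency=a, node_ids=np.arange(1, n + 1),
                                    sparsity=0.5)
        lp_o, cp_o, eg_o, eloc_o = brute_force_metrics(a)
        lp, _ = network.char_path_length(net)
        pairs = [
            (lp, lp_o),
            (network.clustering_coeff(net), cp_o),
            (network.global_efficiency(net), eg_o),
            (network.local_efficiency(net), eloc_o),
        ]
        for got, want in pairs:
            if np.isnan(want):
                assert np.isnan(got)
                continue
            max_err = max(max_err, abs(got - want))
            n_compared += 1
    return {"n_graphs": n_graphs, "n_values_compared": n_compared,
            "max_abs_error": max_err}


# ---------------------------------------------------------------------------
# suite 2: QC detection on planted defects

def qc_detection(n_cohorts: int = 100, seed: int = 0,
                 duration: float = 600.0) -> dict:
    """Sensitivity / false-positive count of channel pruning on planted defects."""
    rng = np.random.default_rng(seed)
    n_planted = n_detected = n_clean = n_false = 0
    for _ in range(n_cohorts):
        cfg = SynthConfig(n_group_a=2, n_group_b=2, duration=duration,
                          seed=int(rng.integers(2**31)))
        recordings, gt = generate_cohort(cfg)
        planted = dict(gt.planted_bad_channels)
        for rec in recordings:
            hemo = preprocess.mbll_convert(rec)
            qc = quality.prune_channels(rec, hemo)
            for ch, defect in planted.items():
                n_planted += 1
                if _EXPECT_REASON[defect] in qc.reasons[ch]:
                    n_detected += 1
            for ch in range(rec.n_channels):
                if ch not in planted:
                    n_clean += 1
                    if qc.reasons[ch]:
                        n_false += 1
    return {
        "n_cohorts": n_cohorts,
        "sensitivity": n_detected / n_planted,
        "false_positives": n_false,
        "n_clean_channels": n_clean,
    }


# ---------------------------------------------------------------------------
# suite 3: t-test calibration and power on Eg AUC

def _null_pool_features(pool_size: int, seed: int, duration: float) -> np.ndarray:
    """Eg-AUC features for a pool of subjects drawn from one null condition."""
    cfg = SynthConfig(n_group_a=0, n_group_b=pool_size, duration=duration,
                      seed=seed)
    recordings, gt = generate_cohort(cfg)
    params = PipelineParams(metrics=("Eg",))
    res = run_cohort(recordings, gt.labels, params=params, classify_features=False)
    return res.features["Eg"].to_numpy()


def ttest_null_calibration(n_replicates: int = 2000, pool_size: int = 200,
                           n_a: int = 8, n_b: int = 10, seed: int = 0,
                           duration: float = 330.0, alpha: float = 0.05) -> dict:
    """Type-I error of the two-sample t-test under the null generator.

    All pool subjects come from one generator condition, so group labels
    are exchangeable; each replicate draws disjoint pseudo-groups of 8 and
    10 from the pool and tests them.
    """
    pool = _null_pool_features(pool_size, seed, duration)
    rng = np.random.default_rng(seed + 1)
    rejections = 0
    for _ in range(n_replicates):
        idx = rng.choice(pool_size, size=n_a + n_b, replace=False)
        _, p = groupstats.two_sample_t(pool[idx[:n_a]], pool[idx[n_a:]])
        rejections += p < alpha
    return {"n_replicates": n_replicates, "rejection_rate": rejections / n_replicates}


def eg_effect_power(n_cohorts: int = 200, seed: int = 0,
                    duration: float = 420.0, alpha: float = 0.05) -> dict:
    """Detection rate of the planted Eg-AUC group effect over fresh cohorts.

    Every cohort uses the generator's default study conditions (8 vs 10
    subjects, planted bad channels and all) at a reduced recording length.
    """
    rng = np.random.default_rng(seed)
    params = PipelineParams(metrics=("Eg",))
    detected = 0
    ds = []
    for _ in range(n_cohorts):
        cfg = SynthConfig(duration=duration, seed=int(rng.integers(2**31)))
        recordings, gt = generate_cohort(cfg)
        res = run_cohort(recordings, gt.labels, params=params,
                         classify_features=False)
        row = res.comparisons[res.comparisons.feature == "Eg"].iloc[0]
        detected += (row.p < alpha) and (row.d > 0)
        ds.append(row.d)
    return {
        "n_cohorts": n_cohorts,
        "detection_rate": detected / n_cohorts,
        "mean_cohens_d": float(np.mean(ds)),
    }


def group_separation(
    density_a: float,
    density_b: float,
    coupling: float,
    n_replicates: int = 50,
    n_per_group: int = 4,
    duration: float = 330.0,
    seed: int = 0,
) -> dict:
    """Replicate-level Eg-AUC separation between the two generated groups.

    For each replicate cohort the group means of the Eg AUC are compared;
    returns the fraction of replicates with mean(A) > mean(B) and the mean
    difference.
    """
    rng = np.random.default_rng(seed)
    params = PipelineParams(metrics=("Eg",))
    wins = 0
    diffs = []
    for _ in range(n_replicates):
        cfg = SynthConfig(n_group_a=n_per_group, n_group_b=n_per_group,
                          duration=duration, latent_density_a=density_a,
                          latent_density_b=density_b, coupling_strength=coupling,
                          seed=int(rng.integers(2**31)))
        recordings, gt = generate_cohort(cfg)
        res = run_cohort(recordings, gt.labels, params=params,
                         classify_features=False)
        lab = np.asarray(res.labels)
        eg = res.features["Eg"].to_numpy()
        diff = eg[lab == "MCS"].mean() - eg[lab == "UWS"].mean()
        wins += diff > 0
        diffs.append(diff)
    return {
        "n_replicates": n_replicates,
        "fraction_a_gt_b": wins / n_replicates,
        "mean_difference": float(np.mean(diffs)),
    }


# ---------------------------------------------------------------------------
# suite 4: classification sanity

def classification_sanity(seed: int = 0, n_permutations: int = 200) -> dict:
    """LOOCV on separable features and the permuted-label null."""
    rng = np.random.default_rng(seed)
    x_sep = np.vstack([rng.normal(0, 0.2, (8, 2)), rng.normal(6, 0.2, (10, 2))])
    y = np.array(["MCS"] * 8 + ["UWS"] * 10)
    sep_acc = {
        kind: classify.loocv(x_sep, y, classify.ClassifierSpec(kind=kind,
                                                               ridge=1e-8)).accuracy
        for kind in ("knn", "lda")
    }
    x_null = rng.normal(0, 1, (18, 2))
    null_accs = []
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        null_accs.append(
            classify.loocv(x_null, perm,
                           classify.ClassifierSpec(kind="knn", n_repeats=1)).accuracy
        )
    return {
        "separable_accuracy_knn": sep_acc["knn"],
        "separable_accuracy_lda": sep_acc["lda"],
        "permuted_mean_accuracy": float(np.mean(null_accs)),
        "majority_rate": 10 / 18,
    }


def hybrid_feature_ordering(n_cohorts: int = 50, seed: int = 0,
                            duration: float = 330.0) -> dict:
    """Mean LOOCV accuracy of (Eg, Lp, L_OC) vs its constituent sets.

    Runs the full pipeline on replicate cohorts with planted Eg separation
    and compares the discriminative hybrid against (Eg, Lp) and (L_OC)
    for both classifiers.
    """
    rng = np.random.default_rng(seed)
    sets = {k: classify.FEATURE_SETS[k] for k in ("graph2", "roi1", "graph2+roi1")}
    params = PipelineParams(metrics=("Eg", "Lp"))
    accs: dict[tuple[str, str], list[float]] = {}
    for _ in range(n_cohorts):
        cfg = SynthConfig(duration=duration, seed=int(rng.integers(2**31)))
        recordings, gt = generate_cohort(cfg)
        res = run_cohort(recordings, gt.labels, params=params,
                         classify_features=False)
        report = classify.classification_report(
            res.features, res.labels, feature_sets=sets, n_repeats=1, ridge=1e-8
        )
        for _, row in report.iterrows():
            accs.setdefault((row.feature_set, row.classifier), []).append(row.accuracy)
    return {
        f"{fs}_{clf.lower()}": float(np.mean(v)) for (fs, clf), v in accs.items()
    }
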