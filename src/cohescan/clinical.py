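"""Patient-level statistics: sample clustering by gene lists with adjusted
Rand index evaluation, gene-set sample scoring with Kaplan-Meier / log-rank
survival stratification, and hypergeometric over-representation tests."""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from cohescan.genome import ValidationError
from cohescan.stats import bh_adjust, fisher_exact_2x2, hypergeom_enrichment_p


def _standardize_submatrix(expr: pd.DataFrame, gene_list) -> pd.DataFrame:
    genes = [g for g in gene_list if g in expr.index]
    if not genes:
        raise ValidationError("gene list shares no genes with the expression matrix")
    sub = expr.loc[genes]
    sd = sub.std(axis=1, ddof=0).replace(0, 1.0)
    return sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)


def cluster_patients(
    expr: pd.DataFrame,
    gene_list,
    k: int,
    method: str = "hierarchical",
    seed: int = 0,
) -> pd.Series:
    """Cluster samples on a per-gene standardized gene-list submatrix.

    ``hierarchical`` uses correlation distance (1 - Pearson between sample
    profiles) with average linkage; ``kmeans`` runs scikit-learn k-means
    with 50 restarts and a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > expr.shape[1]:
        raise ValueError("k exceeds the number of samples")
    z = _standardize_submatrix(expr, gene_list)
    if method == "hierarchical":
        corr = np.corrcoef(z.to_numpy().T)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2
        link = hierarchy.linkage(squareform(dist, checks=False), method="average")
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    elif method == "kmeans":
        km = KMeans(n_clusters=k, n_init=50, random_state=seed)
        labels = km.fit_predict(z.to_numpy().T)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return pd.Series(labels, index=expr.columns, name="cluster")


def adjusted_rand_index(truth, predicted) -> float:
    """Chance-corrected agreement between two labelings of the same samples.

    Computed from the contingency table n_ij with row sums a_i, column
    sums b_j and total n:

        ARI = (sum_ij C(n_ij,2) - E) / (0.5 * [sum_i C(a_i,2) + sum_j C(b_j,2)] - E),
        E   = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2).
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("label vectors differ in length")
    n = len(truth)
    cont = pd.crosstab(pd.Series(truth), pd.Series(predicted)).to_numpy()
    sum_ij = sum(comb(int(x), 2) for x in cont.ravel())
    sum_a = sum(comb(int(x), 2) for x in cont.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in cont.sum(axis=0))
    expected = sum_a * sum_b / comb(n, 2)
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0:  # degenerate partitions (e.g. everything in one cluster)
        return 0.0 if sum_ij != 0.5 * (sum_a + sum_b) else 1.0
    return float((sum_ij - expected) / denom)


def gene_set_sample_score(expr: pd.DataFrame, gene_set) -> pd.Series:
    """Per-sample gene-set score: mean over set genes of the sample's
    per-gene z-score.

    A deterministic, linear stand-in for sample-level set scoring (the
    stratification contract — two patient groups from a set-level score —
    is what downstream survival analysis consumes; the scorer is pluggable).
    """
    z = _standardize_submatrix(expr, gene_set)
    return z.mean(axis=0).rename("score")


@dataclass
class KmResult:
    curves: dict[str, pd.DataFrame]
    statistic: float
    p_value: float
    groups: pd.Series
    undefined: bool = False


def km_logrank(
    surv: pd.DataFrame,
    scores: pd.Series | None = None,
    split: str = "median",
) -> KmResult:
    """Kaplan-Meier curves for two groups and the two-group log-rank test.

    Groups come from the ``group`` column, or from a median split of
    ``scores`` (ties to the low group).  Zero observed events yields an
    undefined-result flag rather than a p-value.
    """
    surv = surv.copy()
    if scores is not None:
        if split != "median":
            raise ValueError("only the median split is supported")
        aligned = scores.reindex(surv["sample_id"]).to_numpy()
        surv["group"] = np.where(aligned > np.median(aligned), "high", "low")
    if "group" not in surv.columns:
        raise ValidationError("no grouping available: pass scores or a group column")
    names = sorted(surv["group"].unique())
    if len(names) != 2 or (surv["event"] == 1).sum() == 0:
        return KmResult({}, np.nan, np.nan, surv.set_index("sample_id")["group"], undefined=True)
    curves = {}
    for name in names:
        sub = surv[surv["group"] == name]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        curves[name] = kmf.survival_function_.rename(columns={"KM_estimate": "survival"})
    a, b = (surv[surv["group"] == name] for name in names)
    res = logrank_test(a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"])
    return KmResult(
        curves, float(res.test_statistic), float(res.p_value), surv.set_index("sample_id")["group"]
    )


def ora_enrichment(query, gene_sets: dict[str, list], universe) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query gene list in
    each gene set, BH-adjusted across sets."""
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValidationError("empty query gene list")
    if not query <= universe:
        raise ValidationError("query genes must be a subset of the universe")
    rows = []
    for name, genes in gene_sets.items():
        genes = set(genes) & universe
        k = len(query & genes)
        p = hypergeom_enrichment_p(k, len(universe), len(genes), len(query))
        rows.append((name, k, len(genes), p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"]).set_index("set")
    out["q"] = bh_adjust(out["p"]) if len(out) else []
    return out


def two_list_ratio_fisher(k1: int, n1: int, k2: int, n2: int) -> float:
    """2x2 Fisher p for comparing hit ratios of two gene lists (e.g.
    oncogene ratio of gained-CAS-DEGs vs other DEGs)."""
    return fisher_exact_2x2(k1, n1 - k1, k2, n2 - k2)
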