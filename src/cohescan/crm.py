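"""Cis-regulatory and orthogonal-evidence statistics around CASs:
TF-binding enrichment, chromatin-state proportions, cohesin-depletion
response, per-locus methylation differential with a resampled cohesin
background, and mutation-rate comparisons across site classes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

from cohescan.genome import ValidationError, overlap_query, overlaps_any
from cohescan.stats import fisher_exact_2x2
from cohescan.tracks import aggregate_signal_profile, counts_track

# Roadmap-style 15-state model: states called active promoter/enhancer here
DEFAULT_ACTIVE_STATES = frozenset({1, 2, 6, 7})


def tf_enrichment(
    cas_sites: pd.DataFrame, all_sites: pd.DataFrame, tf_peaks: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Per-TF overlap proportion of CASs and one-sided Fisher enrichment
    against non-CAS cohesin sites (same site universe)."""
    non_cas = all_sites.loc[all_sites.index.difference(cas_sites.index)]
    rows = []
    for tf, peaks in tf_peaks.items():
        if not len(peaks):
            continue
        k_cas = int(overlaps_any(cas_sites, peaks).sum())
        k_non = int(overlaps_any(non_cas, peaks).sum())
        p = fisher_exact_2x2(
            k_cas, len(cas_sites) - k_cas, k_non, len(non_cas) - k_non, alternative="greater"
        )
        rows.append((tf, k_cas / len(cas_sites), k_non / max(len(non_cas), 1), p, -np.log10(max(p, 1e-300))))
    return pd.DataFrame(
        rows, columns=["tf", "prop_cas", "prop_background", "fisher_p", "neg_log10_p"]
    ).set_index("tf")


def majority_state(sites: pd.DataFrame, segmentation: pd.DataFrame) -> pd.Series:
    """Per-site majority-bp chromatin state label; NaN when uncovered."""
    labels = pd.Series(np.nan, index=sites.index, dtype=float)
    pairs = overlap_query(sites, segmentation, same_namespace=False)
    if not len(pairs):
        return labels
    pairs = pairs.assign(state=segmentation.loc[pairs["b_index"], "state"].to_numpy())
    best = (
        pairs.groupby(["a_index", "state"])["overlap_bp"].sum().reset_index()
        .sort_values(["a_index", "overlap_bp", "state"], ascending=[True, False, True])
        .drop_duplicates("a_index")
    )
    labels.loc[best["a_index"].to_numpy()] = best["state"].to_numpy()
    return labels


def chromatin_state_compare(
    sites: pd.DataFrame,
    seg_normal: pd.DataFrame,
    seg_cancer: pd.DataFrame,
    active_states: frozenset = DEFAULT_ACTIVE_STATES,
    n_states: int = 15,
) -> dict:
    """Per-state site proportions per condition and a Fisher test on the
    active-vs-inactive counts between conditions."""
    out = {}
    counts = {}
    for cond, seg in (("normal", seg_normal), ("cancer", seg_cancer)):
        states = majority_state(sites, seg)
        covered = states.dropna().astype(int)
        out[f"n_missing_{cond}"] = int(states.isna().sum())
        props = covered.value_counts(normalize=True).reindex(range(1, n_states + 1), fill_value=0.0)
        out[f"proportions_{cond}"] = props
        n_active = int(covered.isin(active_states).sum())
        counts[cond] = (n_active, len(covered) - n_active)
    out["fisher_p"] = fisher_exact_2x2(*counts["cancer"], *counts["normal"])
    return out


def depletion_response_test(groups: dict[str, list], dep: pd.DataFrame) -> dict:
    """Decreased-gene ratio per gene group under cohesin depletion, with
    pairwise Fisher tests.

    Decreased = negative log2fc AND significant.  A group with no genes in
    the table is an error.
    """
    dep = dep.set_index("gene_id") if "gene_id" in dep.columns else dep
    decreased = (dep["log2fc"] < 0) & dep["significant"].astype(bool)
    counts = {}
    for name, genes in groups.items():
        present = [g for g in genes if g in dep.index]
        if not present:
            raise ValidationError(f"group {name!r} has no genes in the depletion table")
        k = int(decreased.loc[present].sum())
        counts[name] = (k, len(present))
    ratios = {name: k / n for name, (k, n) in counts.items()}
    names = list(groups)
    pairwise = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ka, na = counts[a]
            kb, nb = counts[b]
            p = fisher_exact_2x2(ka, na - ka, kb, nb - kb)
            pairwise.loc[a, b] = pairwise.loc[b, a] = p
    return {"ratios": ratios, "counts": counts, "pairwise_fisher_p": pairwise}


@dataclass
class MethylationResult:
    per_locus_p: np.ndarray
    hyper: np.ndarray  # cancer median above normal median
    significant: np.ndarray
    cas_ratio: float
    random_ratios: np.ndarray

    @property
    def envelope(self) -> dict[str, float]:
        q = np.quantile(self.random_ratios, [0.025, 0.5, 0.975])
        return {"q2.5": float(q[0]), "q50": float(q[1]), "q97.5": float(q[2])}


def methylation_differential(
    loci: pd.DataFrame,
    beta_cancer: np.ndarray,
    beta_normal: np.ndarray,
    cas_sites: pd.DataFrame,
    background_sites: pd.DataFrame,
    p_cut: float = 1e-7,
    direction: str | None = None,
    n_draws: int = 500,
    seed: int | np.random.Generator = 0,
) -> MethylationResult:
    """Per-locus Mann-Whitney beta-value comparison, then the ratio of CAS
    sites overlapping significantly altered loci against size-matched
    random cohesin-site draws.

    ``direction`` restricts significance to hyper- or hypomethylated loci
    (cancer median above / below normal) for the lost/gained asymmetry
    analysis.
    """
    beta_cancer = np.asarray(beta_cancer, dtype=float)
    beta_normal = np.asarray(beta_normal, dtype=float)
    for arr in (beta_cancer, beta_normal):
        if ((arr < 0) | (arr > 1)).any():
            raise ValidationError("beta values must lie in [0, 1]")
        if arr.shape[1] < 2:
            raise ValidationError("need >= 2 samples per population")
    p = sps.mannwhitneyu(beta_cancer, beta_normal, axis=1, alternative="two-sided").pvalue
    hyper = np.median(beta_cancer, axis=1) > np.median(beta_normal, axis=1)
    significant = p < p_cut
    if direction == "hyper":
        significant = significant & hyper
    elif direction == "hypo":
        significant = significant & ~hyper
    sig_loci = loci[significant]

    def ratio(site_set: pd.DataFrame) -> float:
        if not len(site_set):
            return np.nan
        return float(overlaps_any(site_set, sig_loci).mean()) if len(sig_loci) else 0.0

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bg_index = background_sites.index.to_numpy()
    draws = np.array(
        [
            ratio(background_sites.loc[rng.choice(bg_index, size=len(cas_sites), replace=False)])
            for _ in range(n_draws)
        ]
    )
    return MethylationResult(p, hyper, significant, ratio(cas_sites), draws)


def conserved_sites(occ_presence: pd.DataFrame, manifest: pd.DataFrame, min_fraction: float = 0.9) -> pd.Index:
    """Sites present in at least ``min_fraction`` of cancer AND of normal
    datasets."""
    cancer = manifest.loc[manifest["condition"] == "cancer", "sample_id"]
    normal = manifest.loc[manifest["condition"] == "normal", "sample_id"]
    frac_c = occ_presence[list(cancer)].mean(axis=1)
    frac_n = occ_presence[list(normal)].mean(axis=1)
    return occ_presence.index[(frac_c >= min_fraction) & (frac_n >= min_fraction)]


def mutation_conserved_comparison(
    mutations: pd.DataFrame,
    site_classes: dict[str, pd.DataFrame],
    chrom_lengths: dict[str, int],
    flank_bp: int = 10_000,
    bin_bp: int = 1_000,
) -> dict:
    """Mutation-density profiles around each site class plus per-class
    per-bp mutation rates with pairwise two-proportion tests."""
    tracks = {
        chrom: counts_track(
            mutations.loc[mutations["chrom"] == chrom, "pos"].to_numpy(), chrom, length, bin_bp
        )
        for chrom, length in chrom_lengths.items()
    }
    profiles = {
        name: aggregate_signal_profile(sites, tracks, flank_bp, bin_bp).mean_profile()
        for name, sites in site_classes.items()
    }
    counts, totals = {}, {}
    mut_by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in mutations.groupby("chrom")}
    for name, sites in site_classes.items():
        bp = int((sites["end"] - sites["start"]).sum())
        if bp == 0:
            raise ValidationError(f"site class {name!r} covers zero bp")
        k = 0
        for row in sites.itertuples(index=False):
            pos = mut_by_chrom.get(row.chrom)
            if pos is not None:
                k += int(np.searchsorted(pos, row.end) - np.searchsorted(pos, row.start))
        counts[name], totals[name] = k, bp
    names = list(site_classes)
    rates = {name: counts[name] / totals[name] for name in names}
    pairwise = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            _, p = proportions_ztest([counts[a], counts[b]], [totals[a], totals[b]])
            pairwise.loc[a, b] = pairwise.loc[b, a] = float(p)
    return {"profiles": profiles, "rates": rates, "counts": counts, "total_bp": totals, "pairwise_p": pairwise}
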