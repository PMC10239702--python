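"""Enrichment of differentially expressed genes (DEGs) around CASs.

Two models: the *nearby* model integrates the DEG-ratio-vs-distance curve
f(x) over 0-200 kb into S and scores CASs against resampled cohesin-site
backgrounds with the DEG ratio score

    DRS = (S_CAS - S_B) / max(S_CAS, S_B),   DRS in [-1, 1];

the *loop* model compares the DEG ratio among loop-connected genes between
CASs and size-matched random cohesin sites by a rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from cohescan.genome import ValidationError, midpoints, nearest_tss_distance
from cohescan.stats import rank_biserial_from_u

DEG_LOG2FC_CUT = 1.0
DEG_FDR_CUT = 0.01


def label_degs(de: pd.DataFrame) -> pd.DataFrame:
    """Add is_deg/direction columns by the |log2FC|>1, FDR<0.01 convention
    when the table is not already labeled."""
    de = de.copy()
    if "is_deg" not in de.columns:
        de["is_deg"] = (de["log2fc"].abs() > DEG_LOG2FC_CUT) & (de["fdr"] < DEG_FDR_CUT)
    if "direction" not in de.columns:
        de["direction"] = np.where(
            ~de["is_deg"], "none", np.where(de["log2fc"] > 0, "up", "down")
        )
    return de


@dataclass
class DistanceProfile:
    """Per-distance-bin DEG ratio f(x); the raw material of S and DRS."""

    bin_edges: np.ndarray  # bp, len n_bins + 1
    ratio: np.ndarray  # DEG fraction per bin, NaN when the bin holds no gene
    n_genes: np.ndarray

    @property
    def s_integral(self) -> float:
        """Discrete integral S = sum_bins f(x) * bin_width over 0-200 kb.

        Empty bins contribute 0.  Constant bin width cancels in DRS."""
        widths = np.diff(self.bin_edges)
        r = np.where(np.isfinite(self.ratio), self.ratio, 0.0)
        return float((r * widths).sum())


@dataclass
class DrsResult:
    drs: float
    s_cas: float
    s_background: np.ndarray
    n_draws: int

    @property
    def background_quantiles(self) -> dict[str, float]:
        q = np.quantile(self.s_background, [0.025, 0.5, 0.975])
        return {"q2.5": float(q[0]), "q50": float(q[1]), "q97.5": float(q[2])}

    @property
    def drs_background_quantiles(self) -> dict[str, float]:
        """Envelope of DRS values each single draw would score (draw vs mean
        of the others) — used for the exceeds-envelope checks."""
        s_b = self.s_background
        n = len(s_b)
        others_mean = (s_b.sum() - s_b) / (n - 1)
        drs_draws = _drs(s_b, others_mean)
        q = np.quantile(drs_draws, [0.025, 0.975])
        return {"q2.5": float(q[0]), "q97.5": float(q[1])}


def _drs(s_cas, s_b):
    s_cas = np.asarray(s_cas, dtype=float)
    s_b = np.asarray(s_b, dtype=float)
    denom = np.maximum(s_cas, s_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (s_cas - s_b) / denom, 0.0)
    return out


def gene_site_distances(sites: pd.DataFrame, genes: pd.DataFrame, max_bp: int) -> pd.Series:
    """Distance from each gene's TSS to its *nearest* site, NaN beyond max_bp.

    Nearest-site assignment: a gene counts once, for its closest site.
    Vectorized midpoint search (resampling backgrounds calls this per
    draw); a TSS inside a site scores 0, consistent with
    :func:`cohescan.genome.nearest_tss_distance`.
    """
    out = np.full(len(genes), np.nan)
    for chrom, g_sub in genes.groupby("chrom", sort=False):
        s_sub = sites[sites["chrom"] == chrom]
        if not len(s_sub):
            continue
        mids = midpoints(s_sub)
        order = np.argsort(mids)
        mids = mids[order]
        starts = s_sub["start"].to_numpy()[order]
        ends = s_sub["end"].to_numpy()[order]
        tss = g_sub["tss"].to_numpy()
        pos = np.searchsorted(mids, tss)
        left = np.clip(pos - 1, 0, len(mids) - 1)
        right = np.clip(pos, 0, len(mids) - 1)
        d_left = np.abs(tss - mids[left])
        d_right = np.abs(tss - mids[right])
        use_left = d_left <= d_right
        best = np.where(use_left, left, right)
        d = np.where(use_left, d_left, d_right)
        inside = (tss >= starts[best]) & (tss < ends[best])
        d = np.where(inside, 0, d).astype(float)
        d[d > max_bp] = np.nan
        out[genes.index.get_indexer(g_sub.index)] = d
    return pd.Series(out, index=genes["gene_id"].to_numpy())


def deg_ratio_profile(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    de: pd.DataFrame,
    max_bp: int = 200_000,
    bin_bp: int = 10_000,
    direction_filter: str | None = None,
    cumulative: bool = False,
) -> DistanceProfile:
    """DEG ratio as a function of distance to the nearest selected site.

    Per bin, ratio = (#DEGs with nearest-site distance in the bin) /
    (#genes in the bin); with ``cumulative`` the ratio at x is taken over
    all genes with nearest-site distance <= x.  ``direction_filter``
    restricts the numerator to up- or down-regulated DEGs for the
    gained/lost analyses.
    """
    if max_bp % bin_bp:
        raise ValueError("bin_bp must divide max_bp")
    de = label_degs(de)
    dist = gene_site_distances(sites, genes, max_bp)
    in_range = dist.notna()
    if not in_range.any():
        raise ValidationError("no genes within max_bp of the site set")
    deg_flag = de.set_index("gene_id")["is_deg"].reindex(dist.index).fillna(False)
    if direction_filter is not None:
        dir_ser = de.set_index("gene_id")["direction"].reindex(dist.index)
        deg_flag = deg_flag & (dir_ser == direction_filter)
    edges = np.arange(0, max_bp + bin_bp, bin_bp)
    which = np.clip(np.digitize(dist[in_range], edges) - 1, 0, len(edges) - 2)
    n_genes = np.bincount(which, minlength=len(edges) - 1)
    n_degs = np.bincount(which, weights=deg_flag[in_range].astype(float), minlength=len(edges) - 1)
    if cumulative:
        n_genes, n_degs = np.cumsum(n_genes), np.cumsum(n_degs)
    with np.errstate(invalid="ignore"):
        ratio = np.where(n_genes > 0, n_degs / np.maximum(n_genes, 1), np.nan)
    return DistanceProfile(edges, ratio, n_genes)


def drs_score(
    cas_sites: pd.DataFrame,
    background_sites: pd.DataFrame,
    genes: pd.DataFrame,
    de: pd.DataFrame,
    max_bp: int = 200_000,
    bin_bp: int = 10_000,
    direction_filter: str | None = None,
    n_draws: int = 500,
    seed: int | np.random.Generator = 0,
) -> DrsResult:
    """DEG ratio score of a CAS set against resampled cohesin backgrounds.

    Each draw samples |CAS| sites from the background without replacement;
    DRS is computed against the mean background S, and the full draw vector
    is retained for envelopes.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    if len(background_sites) < len(cas_sites):
        raise ValidationError("background must hold at least as many sites as the CAS set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s_cas = deg_ratio_profile(cas_sites, genes, de, max_bp, bin_bp, direction_filter).s_integral
    s_draws = np.empty(n_draws)
    bg_index = background_sites.index.to_numpy()
    for d in range(n_draws):
        take = rng.choice(len(bg_index), size=len(cas_sites), replace=False)
        try:
            prof = deg_ratio_profile(
                background_sites.loc[bg_index[take]], genes, de, max_bp, bin_bp, direction_filter
            )
            s_draws[d] = prof.s_integral
        except ValidationError:
            s_draws[d] = 0.0
    return DrsResult(float(_drs(s_cas, s_draws.mean())), s_cas, s_draws, n_draws)


@dataclass
class LoopEnrichmentResult:
    r_cas: float
    r_background: np.ndarray
    wilcoxon_p: float
    effect_size: float
    n_connected: int
    undefined: bool = False


def connected_genes_per_site(
    sites: pd.DataFrame,
    loops: pd.DataFrame,
    genes: pd.DataFrame,
    span_bp: tuple[int, int] = (200_000, 5_000_000),
    anchor_pad: int = 5_000,
) -> dict:
    """Map each site index to the set of gene_ids it reaches through loops.

    A site connects to a gene when the site overlaps one padded loop anchor
    and the gene's TSS falls in the other padded anchor, for loops whose
    anchor-to-anchor span lies inside ``span_bp``.
    """
    lo, hi = span_bp
    mid1 = (loops["start1"] + loops["end1"]) // 2
    mid2 = (loops["start2"] + loops["end2"]) // 2
    span = (mid2 - mid1).abs()
    usable = loops[(span >= lo) & (span <= hi) & (loops["chrom1"] == loops["chrom2"])]
    out = {idx: set() for idx in sites.index}
    if not len(usable):
        return out
    s_mid = midpoints(sites)
    for row in usable.itertuples(index=False):
        for a_s, a_e, b_s, b_e in (
            (row.start1, row.end1, row.start2, row.end2),
            (row.start2, row.end2, row.start1, row.end1),
        ):
            near_a = (
                (sites["chrom"] == row.chrom1)
                & (sites["end"] > a_s - anchor_pad)
                & (sites["start"] < a_e + anchor_pad)
            )
            if not near_a.any():
                continue
            g_hit = genes[
                (genes["chrom"] == row.chrom1)
                & (genes["tss"] >= b_s - anchor_pad)
                & (genes["tss"] < b_e + anchor_pad)
            ]["gene_id"]
            if not len(g_hit):
                continue
            for idx in sites.index[near_a]:
                out[idx].update(g_hit)
    return out


def loop_model_enrichment(
    cas_sites: pd.DataFrame,
    background_sites: pd.DataFrame,
    loops: pd.DataFrame,
    genes: pd.DataFrame,
    de: pd.DataFrame,
    span_bp: tuple[int, int] = (200_000, 5_000_000),
    anchor_pad: int = 5_000,
    n_draws: int = 500,
    seed: int | np.random.Generator = 0,
    site_genes: dict | None = None,
) -> LoopEnrichmentResult:
    """Loop-model enrichment: R_CAS vs size-matched random cohesin sites.

    R is the DEG fraction among the union of loop-connected genes; the
    observed R is ranked against the draw distribution by a two-sided
    Mann-Whitney test (one observation vs draws — an empirical permutation
    p), with rank-biserial effect size.  ``site_genes`` may carry a
    precomputed :func:`connected_genes_per_site` map (loops and sites fixed
    across repeated calls).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    de = label_degs(de)
    if site_genes is None:
        universe = pd.concat([background_sites, cas_sites]).drop_duplicates()
        site_genes = connected_genes_per_site(universe, loops, genes, span_bp, anchor_pad)
    # boolean site x gene connectivity for vectorized draw unions
    gene_ids = de["gene_id"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    deg_vec = de["is_deg"].to_numpy().astype(bool)
    all_index = background_sites.index.union(cas_sites.index)
    row_pos = {idx: i for i, idx in enumerate(all_index)}
    conn = np.zeros((len(all_index), len(gene_ids)), dtype=bool)
    for idx, gset in site_genes.items():
        i = row_pos.get(idx)
        if i is None:
            continue
        for g in gset:
            j = gene_pos.get(g)
            if j is not None:
                conn[i, j] = True

    def union_ratio(rows) -> float | None:
        u = conn[rows].any(axis=0)
        n = int(u.sum())
        return float(deg_vec[u].sum() / n) if n else None

    cas_rows = np.array([row_pos[i] for i in cas_sites.index])
    r_cas = union_ratio(cas_rows)
    if r_cas is None:
        return LoopEnrichmentResult(np.nan, np.array([]), np.nan, np.nan, 0, undefined=True)
    n_connected = int(conn[cas_rows].any(axis=0).sum())
    bg_rows = np.array([row_pos[i] for i in background_sites.index])
    draws = []
    for _ in range(n_draws):
        take = rng.choice(len(bg_rows), size=min(len(cas_rows), len(bg_rows)), replace=False)
        r = union_ratio(bg_rows[take])
        if r is not None:
            draws.append(r)
    draws = np.asarray(draws)
    if len(draws) < 2:
        return LoopEnrichmentResult(r_cas, draws, np.nan, np.nan, n_connected, undefined=True)
    # exact rank test of one observation vs the draw distribution: the
    # Wilcoxon rank-sum with n1=1 reduces to this permutation p (asymptotic
    # formulas are useless at n1=1)
    n = len(draws)
    r_le = 1 + int((draws <= r_cas).sum())
    r_ge = 1 + int((draws >= r_cas).sum())
    p = min(1.0, 2.0 * min(r_le, r_ge) / (n + 1))
    u = float((draws < r_cas).sum()) + 0.5 * float((draws == r_cas).sum())
    return LoopEnrichmentResult(
        r_cas, draws, float(p), rank_biserial_from_u(u, 1, n), n_connected
    )


@dataclass
class CasDegPartition:
    cas_degs: pd.DataFrame
    other_degs: pd.DataFrame
    mannwhitney_p: float
    undefined: bool = False


def casdeg_partition(
    cas_sites: pd.DataFrame,
    de: pd.DataFrame,
    genes: pd.DataFrame,
    near_bp: int = 5_000,
) -> CasDegPartition:
    """Split DEGs into CAS-DEGs (within ``near_bp`` of a CAS) and other-DEGs
    and compare |log2FC| between the partitions (two-sided Mann-Whitney U)."""
    de = label_degs(de)
    degs = de[de["is_deg"]].copy()
    dist = gene_site_distances(cas_sites, genes, max_bp=near_bp)
    near = set(dist[dist <= near_bp].index)
    is_near = degs["gene_id"].isin(near)
    cas_degs, other_degs = degs[is_near], degs[~is_near]
    if not len(cas_degs) or not len(other_degs):
        return CasDegPartition(cas_degs, other_degs, np.nan, undefined=True)
    _, p = sps.mannwhitneyu(
        cas_degs["log2fc"].abs(), other_degs["log2fc"].abs(), alternative="two-sided"
    )
    return CasDegPartition(cas_degs, other_degs, float(p))
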