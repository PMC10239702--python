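"""Site-level 3D-genome statistics.

Compartment switches from replicate-averaged PC1 tracks (sign flip with
|delta E| > 0.05), insulation scores from dense contact matrices
(log2 diamond-over-expected), TAD boundaries from insulation minima,
cancer-minus-normal insulation change (ISC) stratified by boundary
proximity, aggregate peak analysis (APA) over loop pixels, and
CAS-anchor loop-overlap ratios across tissues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from cohescan.genome import ValidationError, midpoints, overlaps_any
from cohescan.tracks import SignalTrack, mean_track

SWITCH_CLASSES = ("A-to-B", "B-to-A", "stable-A", "stable-B", "undefined")


@dataclass
class ContactMatrix:
    """Dense symmetric non-negative Hi-C contact matrix for one region."""

    chrom: str
    start_bp: int
    resolution: int
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, m = self.matrix.shape
        if n != m:
            raise ValidationError("contact matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValidationError("contact matrix must be symmetric")
        if (self.matrix < 0).any():
            raise ValidationError("contact matrix must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


def vc_sqrt_normalize(m: ContactMatrix) -> ContactMatrix:
    """Square-root vanilla-coverage balancing of a single-region raw matrix."""
    cov = m.matrix.sum(axis=0)
    scale = np.sqrt(cov)
    scale[scale == 0] = np.nan
    norm = m.matrix / np.outer(scale, scale)
    norm = np.nan_to_num(norm, nan=0.0)
    return ContactMatrix(m.chrom, m.start_bp, m.resolution, norm)


def _site_bin(site_row, track: SignalTrack) -> int | None:
    mid = (site_row.start + site_row.end) // 2
    return track.bin_index(mid)


def compartment_switch_classify(
    sites: pd.DataFrame,
    pc1_cancer: list[dict[str, SignalTrack]],
    pc1_normal: list[dict[str, SignalTrack]],
    delta: float = 0.05,
) -> pd.DataFrame:
    """Classify each site's compartment behaviour between conditions.

    E per condition is the mean PC1 across replicate tracks at the site's
    midpoint bin.  A switch requires E_cancer * E_normal < 0 and
    |E_cancer - E_normal| > delta; otherwise the site is stable in the
    compartment of its cancer sign.  Missing PC1 -> undefined.
    """
    chroms = set().union(*(rep.keys() for rep in pc1_cancer))
    mean_c = {c: mean_track([rep[c] for rep in pc1_cancer if c in rep]) for c in chroms}
    mean_n = {c: mean_track([rep[c] for rep in pc1_normal if c in rep]) for c in chroms}
    rows = []
    for site in sites.itertuples():
        tc = mean_c.get(site.chrom)
        tn = mean_n.get(site.chrom)
        mid = (site.start + site.end) // 2
        e_c = tc.value_at(mid) if tc else float("nan")
        e_n = tn.value_at(mid) if tn else float("nan")
        if not (np.isfinite(e_c) and np.isfinite(e_n)):
            label = "undefined"
        elif e_c * e_n < 0 and abs(e_c - e_n) > delta:
            label = "B-to-A" if e_c > 0 else "A-to-B"
        else:
            label = "stable-A" if e_c > 0 else "stable-B"
        rows.append((site.Index, label, e_c, e_n))
    return pd.DataFrame(rows, columns=["site_id", "class", "e_cancer", "e_normal"]).set_index("site_id")


def switch_class_proportions(calls: pd.DataFrame) -> pd.Series:
    """Class proportions over classifiable (non-undefined) sites."""
    defined = calls[calls["class"] != "undefined"]
    return defined["class"].value_counts(normalize=True).reindex(
        [c for c in SWITCH_CLASSES if c != "undefined"], fill_value=0.0
    )


def insulation_score(m: ContactMatrix, window_bins: int = 10) -> SignalTrack:
    """Insulation score: log2 of each bin's diamond mean over the
    chromosome-wide mean of same-geometry diamonds.

    The diamond at bin i is the submatrix {i-w..i-1} x {i+1..i+w}; bins
    within w of either edge are missing.
    """
    w = window_bins
    if w < 1:
        raise ValueError("window_bins must be >= 1")
    n = m.n_bins
    if n < 2 * w + 1:
        raise ValidationError("matrix too small for the insulation window")
    if not m.matrix.any():
        raise ValidationError("all-zero contact matrix")
    diamonds = np.full(n, np.nan)
    for i in range(w, n - w):
        diamonds[i] = m.matrix[i - w : i, i + 1 : i + w + 1].mean()
    mean_d = np.nanmean(diamonds)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2(diamonds / mean_d)
    values[~np.isfinite(values)] = np.nan
    return SignalTrack(m.chrom, m.resolution, values, start_offset=m.start_bp)


def boundary_call(
    is_track: SignalTrack, depth_sd: float = 1.0, min_sep_bins: int = 3
) -> pd.DataFrame:
    """TAD boundaries at insulation local minima below mean - depth_sd * sd,
    greedily keeping the deepest within ``min_sep_bins``."""
    v = is_track.values
    if len(v) < 2 * min_sep_bins:
        raise ValidationError("track too short for boundary calling")
    finite = np.isfinite(v)
    cut = np.nanmean(v) - depth_sd * np.nanstd(v)
    candidates = []
    for i in range(1, len(v) - 1):
        if not (finite[i - 1] and finite[i] and finite[i + 1]):
            continue
        if v[i] <= v[i - 1] and v[i] <= v[i + 1] and v[i] < cut:
            candidates.append((v[i], i))
    kept = []
    for depth, i in sorted(candidates):
        if all(abs(i - j) > min_sep_bins for _, j in kept):
            kept.append((depth, i))
    kept.sort(key=lambda t: t[1])
    rows = [
        (
            is_track.chrom,
            is_track.start_offset + i * is_track.bin_size,
            is_track.start_offset + (i + 1) * is_track.bin_size,
            float(depth),
        )
        for depth, i in kept
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"])


def isc_site_stats(
    is_cancer: dict[str, SignalTrack] | SignalTrack,
    is_normal: dict[str, SignalTrack] | SignalTrack,
    sites: pd.DataFrame,
    boundaries: pd.DataFrame | None = None,
    boundary_pad_bins: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site insulation-score change (cancer - normal) with stratification.

    Sites are labeled ``boundary`` when their midpoint bin lies within one
    bin of a called boundary, else ``within-TAD``; each stratum gets a mean
    ISC and a two-sided Wilcoxon signed-rank test against zero.  Sites with
    missing IS are excluded and counted.
    """
    if isinstance(is_cancer, SignalTrack):
        is_cancer = {is_cancer.chrom: is_cancer}
    if isinstance(is_normal, SignalTrack):
        is_normal = {is_normal.chrom: is_normal}
    rows, n_missing = [], 0
    for site in sites.itertuples():
        tc, tn = is_cancer.get(site.chrom), is_normal.get(site.chrom)
        mid = (site.start + site.end) // 2
        v_c = tc.value_at(mid) if tc else float("nan")
        v_n = tn.value_at(mid) if tn else float("nan")
        if not (np.isfinite(v_c) and np.isfinite(v_n)):
            n_missing += 1
            continue
        stratum = "within-TAD"
        if boundaries is not None and len(boundaries):
            bin_size = tc.bin_size
            b_sub = boundaries[boundaries["chrom"] == site.chrom]
            b_mids = ((b_sub["start"] + b_sub["end"]) // 2).to_numpy()
            if len(b_mids) and np.min(np.abs(b_mids - mid)) <= boundary_pad_bins * bin_size + bin_size // 2:
                stratum = "boundary"
        rows.append((site.Index, v_c - v_n, stratum))
    per_site = pd.DataFrame(rows, columns=["site_id", "isc", "stratum"]).set_index("site_id")
    per_site.attrs["n_missing"] = n_missing
    summaries = []
    for stratum, sub in per_site.groupby("stratum"):
        nonzero = sub["isc"][sub["isc"] != 0]
        if len(nonzero) >= 5:
            p = float(sps.wilcoxon(nonzero).pvalue)
        else:
            p = np.nan
        summaries.append((stratum, len(sub), float(sub["isc"].mean()), p))
    summary = pd.DataFrame(summaries, columns=["stratum", "n_sites", "mean_isc", "wilcoxon_p"])
    return per_site, summary


@dataclass
class ApaResult:
    aggregate: np.ndarray
    apa_score: float
    n_pairs_used: int
    n_pairs_skipped: int


def _loop_pixels(m: ContactMatrix, pairs: pd.DataFrame) -> list[tuple[int, int]]:
    pixels = []
    for row in pairs.itertuples(index=False):
        if row.chrom1 != m.chrom or row.chrom2 != m.chrom:
            continue
        bi = ((row.start1 + row.end1) // 2 - m.start_bp) // m.resolution
        bj = ((row.start2 + row.end2) // 2 - m.start_bp) // m.resolution
        pixels.append((int(min(bi, bj)), int(max(bi, bj))))
    return pixels


def apa_score(m: ContactMatrix, pairs: pd.DataFrame, flank_bins: int = 10) -> ApaResult:
    """Aggregate peak analysis over loop pixels.

    The aggregate is the mean of (2*flank+1)^2 submatrices centered on each
    loop pixel; the score is the center value over the mean of the 3x3
    lower-left corner (the near-diagonal background).  Pixels too close to
    the matrix edge or to the diagonal are skipped and counted.
    """
    f = flank_bins
    n = m.n_bins
    subs, skipped = [], 0
    for bi, bj in _loop_pixels(m, pairs):
        if bi - f < 0 or bj + f >= n or bi + f >= n or bj - f < 0 or (bj - bi) <= 2 * f:
            skipped += 1
            continue
        subs.append(m.matrix[bi - f : bi + f + 1, bj - f : bj + f + 1])
    if not subs:
        raise ValidationError("no usable loop pixels for APA")
    agg = np.mean(subs, axis=0)
    corner = agg[2 * f - 2 : 2 * f + 1, 0:3].mean()
    return ApaResult(agg, float(agg[f, f] / corner), len(subs), skipped)


def apa_compare(
    matrices: dict[str, list[ContactMatrix]],
    pairs: pd.DataFrame,
    flank_bins: int = 10,
    reference: str = "normal",
) -> pd.DataFrame:
    """Per-sample APA scores with ratios normalised to the reference mean
    (reference condition == 1) and a one-sided Welch t-test vs reference."""
    per = {
        cond: np.array([apa_score(m, pairs, flank_bins).apa_score for m in ms])
        for cond, ms in matrices.items()
    }
    ref_mean = per[reference].mean()
    rows = []
    for cond, scores in per.items():
        if cond == reference:
            p = np.nan
        else:
            p = float(
                sps.ttest_ind(scores, per[reference], equal_var=False, alternative="greater").pvalue
            )
        rows.append((cond, scores.mean(), scores.mean() / ref_mean, len(scores), p))
    return pd.DataFrame(rows, columns=["condition", "mean_apa", "normalized_ratio", "n_samples", "p_greater"])


def loop_anchor_frame(loops: pd.DataFrame, pad_bp: int = 0) -> pd.DataFrame:
    """Both anchors of a BEDPE loop set as one padded interval set."""
    a1 = loops[["chrom1", "start1", "end1"]].rename(
        columns={"chrom1": "chrom", "start1": "start", "end1": "end"}
    )
    a2 = loops[["chrom2", "start2", "end2"]].rename(
        columns={"chrom2": "chrom", "start2": "start", "end2": "end"}
    )
    anchors = pd.concat([a1, a2], ignore_index=True)
    anchors["start"] = (anchors["start"] - pad_bp).clip(lower=0)
    anchors["end"] = anchors["end"] + pad_bp
    return anchors


def loop_overlap_ratio(
    cas_by_tissue: dict[str, pd.DataFrame],
    loops_by_tissue: dict[str, pd.DataFrame],
    pad_bp: int = 5_000,
) -> pd.DataFrame:
    """Cross-tissue CAS / loop-anchor overlap, normalised within tissue.

    Entry (i, j) = #CAS_i overlapping anchors of loops_j, divided by the
    same count against loops_i; the diagonal is 1 by construction.  Rows
    with zero same-tissue overlap are NaN (flagged undefined).
    """
    tissues = list(cas_by_tissue)
    anchors = {t: loop_anchor_frame(loops_by_tissue[t], pad_bp) for t in tissues}
    counts = pd.DataFrame(
        {
            tj: {ti: float(overlaps_any(cas_by_tissue[ti], anchors[tj]).sum()) for ti in tissues}
            for tj in tissues
        }
    )
    ratios = counts.copy()
    for ti in tissues:
        own = counts.loc[ti, ti]
        ratios.loc[ti] = counts.loc[ti] / own if own > 0 else np.nan
    return ratios
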