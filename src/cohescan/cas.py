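"""Consensus cohesin-site construction and cancer-aberrant site (CAS) calling.

A CAS is a consensus site whose peak occupancy (fraction of cohort samples
with a peak, compared by Fisher's exact test) *and* read intensity
(log2 mean difference, compared by Welch's t-test) both change
significantly between cancer and normal cohorts, with concordant sign:
gained when both point up in cancer, lost when both point down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cohescan.genome import ValidationError, merge_intervals, overlap_query, overlaps_any
from cohescan.stats import bh_adjust, fisher_exact_2x2, welch_t_rows

DEFAULT_THRESHOLDS = {"min_abs_poc": 0.5, "max_q_occ": 0.01, "min_abs_logfc": 1.0, "max_q_int": 0.01}
EXCLUDED_CHROMS = frozenset({"chrY", "chrM", "Y", "M", "MT"})


@dataclass
class OccupancyMatrix:
    """Sites x samples boolean peak presence."""

    sites: pd.DataFrame  # chrom/start/end, index = site_id
    presence: pd.DataFrame  # bool, index = site_id, columns = sample_id

    def __post_init__(self):
        if not self.sites.index.equals(self.presence.index):
            raise ValidationError("site ids of sites table and presence matrix differ")
        if self.presence.columns.duplicated().any() or self.sites.index.duplicated().any():
            raise ValidationError("duplicate sample or site ids")


@dataclass
class IntensityMatrix:
    """Sites x samples log2 read intensity (paired with an OccupancyMatrix)."""

    sites: pd.DataFrame
    log2_intensity: pd.DataFrame

    def __post_init__(self):
        if not np.isfinite(self.log2_intensity.to_numpy()).all():
            raise ValidationError("intensity matrix contains non-finite values")


def normalize_intensity(raw_counts: pd.DataFrame, target_library_size: float = 1e6) -> pd.DataFrame:
    """Library-size normalisation to a fixed constant then log2(x+1).

    Only for raw count matrices; pre-normalised log2 matrices pass straight
    into :func:`intensity_differential`.
    """
    scaled = raw_counts / raw_counts.sum(axis=0) * target_library_size
    return np.log2(scaled + 1.0)


def build_consensus_sites(
    peak_sets: list[tuple[str, pd.DataFrame]],
    min_occupancy: int = 2,
    exclude_chroms: frozenset = EXCLUDED_CHROMS,
) -> OccupancyMatrix:
    """Merge per-sample peaks into consensus sites and count occupancy.

    Peaks overlapping by >=1 bp merge across samples; each merged site's
    occupancy is the number of samples contributing an overlapping peak,
    and sites seen in fewer than ``min_occupancy`` samples are dropped.
    Chromosomes Y and M are excluded by default.
    """
    if len(peak_sets) < 2:
        raise ValidationError("need at least two peak sets to build consensus sites")
    kept = [(sid, df[~df["chrom"].isin(exclude_chroms)]) for sid, df in peak_sets]
    pooled = pd.concat([df.assign(_sample=sid) for sid, df in kept], ignore_index=True)
    if not len(pooled):
        raise ValidationError("no peaks left after chromosome filtering")
    consensus = merge_intervals(pooled[["chrom", "start", "end"]])
    consensus.index = [f"site_{i:06d}" for i in range(len(consensus))]
    presence = pd.DataFrame(False, index=consensus.index, columns=[sid for sid, _ in kept])
    for sid, df in kept:
        if len(df):
            presence.loc[:, sid] = overlaps_any(consensus, df)
    occupancy = presence.sum(axis=1)
    keep = occupancy >= min_occupancy
    return OccupancyMatrix(consensus[keep].copy(), presence[keep].copy())


def _split_samples(manifest: pd.DataFrame, tissue: str | None = None) -> tuple[list, list]:
    sub = manifest if tissue is None else manifest[manifest["tissue"] == tissue]
    cancer = list(sub.loc[sub["condition"] == "cancer", "sample_id"])
    normal = list(sub.loc[sub["condition"] == "normal", "sample_id"])
    if not cancer or not normal:
        raise ValidationError("both cancer and normal samples are required")
    return cancer, normal


def occupancy_differential(
    occ: OccupancyMatrix, manifest: pd.DataFrame, tissue: str | None = None
) -> pd.DataFrame:
    """Per-site PO (cancer / normal), POC and Fisher/BH occupancy test.

    PO = N_observed / N_all per condition; the 2x2 is (with, without) peak
    for cancer vs normal; p-values are two-sided and BH-adjusted across all
    sites in the comparison.
    """
    cancer, normal = _split_samples(manifest, tissue)
    if len(cancer) < 2 or len(normal) < 2:
        raise ValidationError("need >=2 samples per condition")
    pc = occ.presence[cancer].to_numpy()
    pn = occ.presence[normal].to_numpy()
    n_c, n_n = pc.shape[1], pn.shape[1]
    with_c = pc.sum(axis=1)
    with_n = pn.sum(axis=1)
    po_c = with_c / n_c
    po_n = with_n / n_n
    p_occ = np.array(
        [fisher_exact_2x2(int(a), int(n_c - a), int(b), int(n_n - b)) for a, b in zip(with_c, with_n)]
    )
    return pd.DataFrame(
        {
            "po_cancer": po_c,
            "po_normal": po_n,
            "poc": po_c - po_n,
            "p_occ": p_occ,
            "q_occ": bh_adjust(p_occ),
        },
        index=occ.presence.index,
    )


def intensity_differential(
    intens: IntensityMatrix, manifest: pd.DataFrame, tissue: str | None = None
) -> pd.DataFrame:
    """Per-site log2 fold change and Welch t-test with BH adjustment.

    logFC = mean(log2 cancer) - mean(log2 normal).
    """
    cancer, normal = _split_samples(manifest, tissue)
    if len(cancer) < 2 or len(normal) < 2:
        raise ValidationError("need >=2 samples per condition")
    x = intens.log2_intensity[cancer].to_numpy()
    y = intens.log2_intensity[normal].to_numpy()
    t, p = welch_t_rows(x, y)
    return pd.DataFrame(
        {
            "logfc": x.mean(axis=1) - y.mean(axis=1),
            "t_int": t,
            "p_int": p,
            "q_int": bh_adjust(p),
        },
        index=intens.log2_intensity.index,
    )


def differential_table(occ_diff: pd.DataFrame, int_diff: pd.DataFrame) -> pd.DataFrame:
    if not occ_diff.index.equals(int_diff.index):
        raise ValidationError("occupancy and intensity tables cover different sites")
    return occ_diff.join(int_diff)


def call_cas(diff: pd.DataFrame, thresholds: dict | None = None) -> pd.DataFrame:
    """Apply the dual CAS filter and assign direction.

    A site is a CAS iff |POC| > 0.5 with q_occ < 0.01 AND |logFC| > 1 with
    q_int < 0.01, and the two effects agree in sign; direction is gained
    when positive, lost when negative.  Discordant sites are excluded.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    occ_pass = (diff["poc"].abs() > th["min_abs_poc"]) & (diff["q_occ"] < th["max_q_occ"])
    int_pass = (diff["logfc"].abs() > th["min_abs_logfc"]) & (diff["q_int"] < th["max_q_int"])
    concordant = np.sign(diff["poc"]) == np.sign(diff["logfc"])
    is_cas = occ_pass & int_pass & concordant
    out = diff[is_cas].copy()
    out["direction"] = np.where(out["poc"] > 0, "gained", "lost")
    return out


def simpson_index(x: pd.DataFrame, y: pd.DataFrame) -> float:
    """Overlap coefficient |X n Y| / min(|X|, |Y|), intersecting by >=1 bp.

    |X n Y| is counted on the smaller set (sites of the smaller set that
    overlap any site of the larger), making the index symmetric.
    """
    if not len(x) or not len(y):
        raise ValidationError("Simpson index undefined for empty sets")
    small, large = (x, y) if len(x) <= len(y) else (y, x)
    n_int = int(overlaps_any(small, large).sum())
    return n_int / len(small)


def simpson_matrix(cas_by_tissue: dict[str, pd.DataFrame]) -> pd.DataFrame:
    tissues = list(cas_by_tissue)
    m = pd.DataFrame(1.0, index=tissues, columns=tissues)
    for i, a in enumerate(tissues):
        for b in tissues[i + 1 :]:
            v = simpson_index(cas_by_tissue[a], cas_by_tissue[b])
            m.loc[a, b] = m.loc[b, a] = v
    return m


def ctcf_change_classify(
    sites: pd.DataFrame, ctcf_normal: pd.DataFrame, ctcf_cancer: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Label sites by CTCF colocalisation change between conditions.

    Returns (per-site labels, class proportions).  Labels: non-CTCF (no
    overlap either condition), stable-CTCF (both), gained-CTCF (cancer
    only), lost-CTCF (normal only).
    """
    in_n = overlaps_any(sites, ctcf_normal)
    in_c = overlaps_any(sites, ctcf_cancer)
    labels = np.select(
        [in_n & in_c, ~in_n & in_c, in_n & ~in_c],
        ["stable-CTCF", "gained-CTCF", "lost-CTCF"],
        default="non-CTCF",
    )
    ser = pd.Series(labels, index=sites.index, name="ctcf_class")
    props = ser.value_counts(normalize=True)
    return ser, props
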