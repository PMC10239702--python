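"""Interval algebra and gene-model utilities shared by every stage.

Coordinates are 0-based half-open throughout (BED convention).  Interval
sets are plain pandas DataFrames with columns ``chrom``, ``start``, ``end``
and optionally ``name`` and ``strand``; single intervals and gene models
get small dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


class ValidationError(ValueError):
    """Raised when an interval set violates its invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    id: str | None = None
    strand: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GenomeLayout:
    """Ordered chromosome name -> length (bp) map."""

    lengths: dict[str, int]

    def __post_init__(self):
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValidationError(f"chromosome {name} has non-positive length {length}")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
        return cls(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))

    def to_tsv(self, path) -> None:
        pd.DataFrame({"chrom": self.chroms, "length": [self.lengths[c] for c in self.chroms]}).to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class GeneModel:
    """A gene with its TSS (strand-aware) and exon structure."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(f"gene {self.gene_id}: invalid span")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValidationError(f"gene {self.gene_id}: exon [{s},{e}) outside gene body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def validate_intervals(df: pd.DataFrame, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Check interval-set invariants; returns the frame untouched."""
    for col in INTERVAL_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"interval set missing column {col!r}")
    if len(df) and not (df["start"] < df["end"]).all():
        bad = df.loc[df["start"] >= df["end"]].index[0]
        raise ValidationError(f"interval at index {bad} has start >= end")
    if len(df) and (df["start"] < 0).any():
        raise ValidationError("negative start coordinate")
    if layout is not None:
        unknown = set(df["chrom"].unique()) - set(layout.chroms)
        if unknown:
            raise ValidationError(f"chromosomes not in layout: {sorted(unknown)}")
    return df


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def overlap_query(
    a: pd.DataFrame,
    b: pd.DataFrame,
    min_overlap_bp: int = 1,
    same_namespace: bool = True,
) -> pd.DataFrame:
    """All (a, b) index pairs overlapping by >= ``min_overlap_bp`` bp.

    Half-open semantics: [100,200) and [200,300) do not overlap.  Returns a
    DataFrame with columns ``a_index``, ``b_index``, ``overlap_bp`` (original
    row labels of each input).
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    if same_namespace:
        only_a = set(a["chrom"]) - set(b["chrom"])
        only_b = set(b["chrom"]) - set(a["chrom"])
        # disjoint namespaces indicate mismatched genomes, not mere absence
        if len(a) and len(b) and not (set(a["chrom"]) & set(b["chrom"])) and (only_a or only_b):
            raise ValidationError("interval sets share no chromosome names")
    out_a, out_b, out_o = [], [], []
    for chrom, a_sub in a.groupby("chrom", sort=False):
        b_sub = b[b["chrom"] == chrom]
        if not len(b_sub):
            continue
        b_start = b_sub["start"].to_numpy()
        b_end = b_sub["end"].to_numpy()
        b_idx = b_sub.index.to_numpy()
        order = np.argsort(b_start, kind="stable")
        b_start, b_end, b_idx = b_start[order], b_end[order], b_idx[order]
        # sweep: candidates have b.start < a.end; filter on b.end > a.start
        max_end = np.maximum.accumulate(b_end)
        for ai, a_start, a_end in zip(a_sub.index, a_sub["start"], a_sub["end"]):
            hi = np.searchsorted(b_start, a_end, side="left")
            if hi == 0 or max_end[hi - 1] <= a_start:
                continue
            sel = slice(0, hi)
            ov = np.minimum(b_end[sel], a_end) - np.maximum(b_start[sel], a_start)
            keep = ov >= min_overlap_bp
            if keep.any():
                n = int(keep.sum())
                out_a.extend([ai] * n)
                out_b.extend(b_idx[sel][keep])
                out_o.extend(ov[keep])
    return pd.DataFrame({"a_index": out_a, "b_index": out_b, "overlap_bp": out_o})


def overlaps_any(a: pd.DataFrame, b: pd.DataFrame, min_overlap_bp: int = 1) -> np.ndarray:
    """Boolean per row of ``a``: does it overlap anything in ``b``."""
    flags = np.zeros(len(a), dtype=bool)
    if not len(a) or not len(b):
        return flags
    pairs = overlap_query(a, b, min_overlap_bp=min_overlap_bp, same_namespace=False)
    pos = {label: i for i, label in enumerate(a.index)}
    for label in pairs["a_index"].unique():
        flags[pos[label]] = True
    return flags


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge intervals overlapping by >= 1 bp into maximal runs per chromosome."""
    if not len(df):
        return df.copy()
    pieces = []
    for chrom, sub in sort_intervals(df).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        run_start, run_end = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s < run_end:  # half-open: touching intervals do not merge
                run_end = max(run_end, e)
            else:
                pieces.append((chrom, run_start, run_end))
                run_start, run_end = s, e
        pieces.append((chrom, run_start, run_end))
    return pd.DataFrame(pieces, columns=INTERVAL_COLUMNS)


def midpoints(df: pd.DataFrame) -> np.ndarray:
    return ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)


def nearest_tss_distance(
    sites: pd.DataFrame,
    genes: list[GeneModel] | pd.DataFrame,
    cap_bp: int = 200_000,
) -> pd.DataFrame:
    """All (site, gene) pairs with |site midpoint - TSS| <= cap_bp.

    Distance is 0 when the TSS lies inside the site interval.  Returns
    columns ``site_index``, ``gene_id``, ``distance``.
    """
    if cap_bp < 0:
        raise ValueError("cap_bp must be >= 0")
    genes_df = genes_to_frame(genes)
    if not len(genes_df):
        raise ValidationError("empty gene set")
    rows = []
    mids = midpoints(sites)
    for chrom, g_sub in genes_df.groupby("chrom", sort=False):
        mask = (sites["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        tss = g_sub["tss"].to_numpy()
        order = np.argsort(tss, kind="stable")
        tss_sorted = tss[order]
        gid_sorted = g_sub["gene_id"].to_numpy()[order]
        s_idx = sites.index.to_numpy()[mask]
        s_mid = mids[mask]
        s_start = sites["start"].to_numpy()[mask]
        s_end = sites["end"].to_numpy()[mask]
        for i, m in enumerate(s_mid):
            lo = np.searchsorted(tss_sorted, m - cap_bp, side="left")
            hi = np.searchsorted(tss_sorted, m + cap_bp, side="right")
            for j in range(lo, hi):
                t = tss_sorted[j]
                d = 0 if s_start[i] <= t < s_end[i] else abs(int(m) - int(t))
                if d <= cap_bp:
                    rows.append((s_idx[i], gid_sorted[j], d))
    return pd.DataFrame(rows, columns=["site_index", "gene_id", "distance"])


def genes_to_frame(genes: list[GeneModel] | pd.DataFrame) -> pd.DataFrame:
    """Normalise a gene collection to a frame with gene_id/chrom/start/end/strand/tss."""
    if isinstance(genes, pd.DataFrame):
        df = genes.copy()
        if "tss" not in df.columns:
            df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
        return df
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
        }
    )


def annotate_context(
    site: GenomicInterval,
    genes: list[GeneModel],
    promoter_window: tuple[int, int] = (2000, 500),
) -> str:
    """Classify a site as promoter / exonic / intronic / intergenic.

    Precedence promoter > exonic > intronic > intergenic.  The promoter is
    the strand-aware window [TSS - upstream, TSS + downstream) around each
    TSS; a site takes a label when it overlaps the corresponding feature.
    """
    up, down = promoter_window
    hit_exon = hit_body = False
    for g in genes:
        if g.chrom != site.chrom:
            continue
        if g.strand == "+":
            p_lo, p_hi = g.tss - up, g.tss + down
        else:
            p_lo, p_hi = g.tss - down + 1, g.tss + up + 1
        if site.start < p_hi and p_lo < site.end:
            return "promoter"
        if site.start < g.end and g.start < site.end:
            hit_body = True
            for es, ee in g.exons:
                if site.start < ee and es < site.end:
                    hit_exon = True
                    break
    if hit_exon:
        return "exonic"
    if hit_body:
        return "intronic"
    return "intergenic"
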