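"""Seeded synthetic cohorts with planted ground truth.

Emulates the statistical structure of a multi-tissue cohesin ChIP-seq
cohort study: binary peak presence with condition-dependent occupancy,
log-intensity shifts at planted gained/lost sites, distance-linked
differentially expressed genes, compartment flips and insulation
perturbations at planted bins, loop-strength changes, and group-dependent
survival hazards.  Every generator is fully determined by one root seed;
each data modality draws from a named substream so modalities stay
decoupled.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cohescan.cas import IntensityMatrix, OccupancyMatrix
from cohescan.genome import GenomeLayout
from cohescan.tracks import SignalTrack

TISSUE_NAMES = ("liver", "lung", "breast", "brain", "blood")

DEFAULT_GENOME = GenomeLayout({"chr1": 100_000_000, "chr2": 80_000_000, "chr3": 60_000_000})


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, decoupled random substream derived from the root seed."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(name.encode())])


@dataclass
class CohortConfig:
    """Study conditions for the synthetic ChIP-seq cohort.

    Defaults: 3 tissues, 10,000 sites, 20 cancer + 20 normal samples per
    tissue, 2% gained + 2% lost planted sites, occupancy effect 0.7 over a
    baseline presence probability of 0.15, intensity effect 1.5 log2 units
    with per-sample noise sd 0.5 — chosen so planted sites clear the
    |POC|>0.5 and |logFC|>1 calling thresholds with realistic noise.
    """

    seed: int = 0
    n_sites: int = 10_000
    n_tissues: int = 3
    n_cancer: int = 20
    n_normal: int = 20
    fraction_gained: float = 0.02
    fraction_lost: float = 0.02
    occupancy_effect: float = 0.7
    intensity_effect: float = 1.5
    intensity_noise_sd: float = 0.5
    p_base: float = 0.15
    site_width: int = 400
    genome: GenomeLayout = field(default_factory=lambda: DEFAULT_GENOME)

    def __post_init__(self):
        if self.fraction_gained < 0 or self.fraction_lost < 0:
            raise ValueError("planted fractions must be >= 0")
        if self.fraction_gained + self.fraction_lost >= 1:
            raise ValueError("planted fractions must sum to < 1")
        if self.occupancy_effect < 0 or self.intensity_effect < 0:
            raise ValueError("effects must be >= 0")
        if self.p_base + self.occupancy_effect > 1:
            raise ValueError(
                f"infeasible occupancy: p_base {self.p_base} + effect {self.occupancy_effect} > 1"
            )
        if self.n_tissues > len(TISSUE_NAMES):
            raise ValueError(f"at most {len(TISSUE_NAMES)} tissues supported")

    @property
    def tissues(self) -> list[str]:
        return list(TISSUE_NAMES[: self.n_tissues])


@dataclass
class TruthLabels:
    """Planted ground truth — the acceptance surface for recovery tests."""

    sites: pd.DataFrame  # chrom/start/end, index site_id
    site_classes: pd.DataFrame  # index site_id, one column per tissue: gained/lost/stable
    genes: pd.DataFrame | None = None
    de_truth: dict[str, pd.DataFrame] | None = None  # per tissue: gene_id, is_deg, direction, log2fc
    switch_bins: dict[str, np.ndarray] | None = None  # per chrom: per-bin class string
    loop_truth: pd.DataFrame | None = None
    survival_groups: pd.Series | None = None

    def planted_sites(self, tissue: str, direction: str | None = None) -> pd.Index:
        cls = self.site_classes[tissue]
        mask = cls.isin(["gained", "lost"]) if direction is None else cls == direction
        return self.site_classes.index[mask]


def _place_sites(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Non-overlapping site intervals on an even grid with jitter."""
    total = sum(config.genome.lengths.values())
    rows = []
    allotted = 0
    chroms = config.genome.chroms
    for k, chrom in enumerate(chroms):
        frac = config.genome[chrom] / total
        n = int(round(config.n_sites * frac)) if k < len(chroms) - 1 else config.n_sites - allotted
        allotted += n
        spacing = config.genome[chrom] // (n + 1)
        jitter = rng.integers(0, max(1, spacing - config.site_width - 1), size=n)
        starts = spacing * (1 + np.arange(n)) + jitter - spacing // 2
        for s in starts:
            rows.append((chrom, int(s), int(s) + config.site_width))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df.index = [f"site_{i:06d}" for i in range(len(df))]
    return df


def generate_cohort_chip(
    config: CohortConfig,
) -> tuple[OccupancyMatrix, IntensityMatrix, pd.DataFrame, TruthLabels]:
    """Multi-tissue occupancy and intensity matrices with planted CASs.

    Stable sites have Bernoulli(p_base) presence in both conditions;
    planted gained (lost) sites have cancer (normal) presence probability
    raised by the occupancy effect and cancer log2 intensity shifted by
    +/- the intensity effect.  Site classes are planted independently per
    tissue.
    """
    rng_sites = substream(config.seed, "sites")
    sites = _place_sites(config, rng_sites)

    rng_classes = substream(config.seed, "site_classes")
    classes = pd.DataFrame("stable", index=sites.index, columns=config.tissues)
    n_g = int(round(config.n_sites * config.fraction_gained))
    n_l = int(round(config.n_sites * config.fraction_lost))
    for tissue in config.tissues:
        chosen = rng_classes.choice(config.n_sites, size=n_g + n_l, replace=False)
        classes.iloc[chosen[:n_g], classes.columns.get_loc(tissue)] = "gained"
        classes.iloc[chosen[n_g:], classes.columns.get_loc(tissue)] = "lost"

    manifest_rows = []
    for tissue in config.tissues:
        for i in range(config.n_cancer):
            manifest_rows.append((f"{tissue}_cancer_{i:02d}", tissue, "cancer"))
        for i in range(config.n_normal):
            manifest_rows.append((f"{tissue}_normal_{i:02d}", tissue, "normal"))
    manifest = pd.DataFrame(manifest_rows, columns=["sample_id", "tissue", "condition"])

    rng_occ = substream(config.seed, "occupancy")
    rng_int = substream(config.seed, "intensity")
    base_log2 = 3.5 + 0.8 * rng_int.standard_normal(config.n_sites)  # log2 of a lognormal draw

    presence = np.zeros((config.n_sites, len(manifest)), dtype=bool)
    intensity = np.zeros((config.n_sites, len(manifest)))
    for j, (sid, tissue, condition) in enumerate(manifest.itertuples(index=False)):
        cls = classes[tissue].to_numpy()
        p = np.full(config.n_sites, config.p_base)
        shift = np.zeros(config.n_sites)
        if condition == "cancer":
            p[cls == "gained"] += config.occupancy_effect
            shift[cls == "gained"] = config.intensity_effect
            shift[cls == "lost"] = -config.intensity_effect
        else:
            p[cls == "lost"] += config.occupancy_effect
        presence[:, j] = rng_occ.random(config.n_sites) < p
        intensity[:, j] = base_log2 + shift + config.intensity_noise_sd * rng_int.standard_normal(
            config.n_sites
        )

    occ = OccupancyMatrix(sites, pd.DataFrame(presence, index=sites.index, columns=manifest["sample_id"]))
    intens = IntensityMatrix(
        sites, pd.DataFrame(intensity, index=sites.index, columns=manifest["sample_id"])
    )
    truth = TruthLabels(sites=sites, site_classes=classes)
    return occ, intens, manifest, truth


def generate_genes(
    config: CohortConfig, n_genes: int = 10_000, min_len: int = 5_000, max_len: int = 80_000
) -> pd.DataFrame:
    """Random gene models (TSS positions drive all distance statistics)."""
    rng = substream(config.seed, "genes")
    total = sum(config.genome.lengths.values())
    rows = []
    for chrom in config.genome.chroms:
        n = int(round(n_genes * config.genome[chrom] / total))
        lengths = rng.integers(min_len, max_len, size=n)
        starts = rng.integers(0, config.genome[chrom] - max_len, size=n)
        strands = rng.choice(["+", "-"], size=n)
        for s, ln, st in zip(starts, lengths, strands):
            rows.append((chrom, int(s), int(s + ln), st))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    df.insert(0, "gene_id", [f"gene_{i:05d}" for i in range(len(df))])
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df


def generate_expression(
    truth: TruthLabels,
    genes: pd.DataFrame,
    config: CohortConfig,
    decay_bp: int = 100_000,
    prob_near: float = 0.6,
    prob_far: float = 0.2,
    concordance: float = 0.9,
    expr_noise_sd: float = 0.5,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Distance-linked differential expression plus an expression matrix.

    The probability that a gene is differentially expressed decays linearly
    with the distance from its TSS to the nearest planted CAS, from
    ``prob_near`` at distance 0 to ``prob_far`` at ``decay_bp`` and beyond;
    DE direction follows the CAS direction (gained -> up, lost -> down)
    with the given concordance.  The genes x samples matrix applies each
    tissue's planted log2 fold changes to that tissue's cancer samples.
    """
    if prob_near <= prob_far:
        raise ValueError("prob_near must exceed prob_far")
    rng = substream(config.seed, "expression")
    de_truth: dict[str, pd.DataFrame] = {}
    for tissue in config.tissues:
        planted = truth.planted_sites(tissue)
        site_pos = truth.sites.loc[planted]
        site_mid = ((site_pos["start"] + site_pos["end"]) // 2).to_numpy()
        site_dir = truth.site_classes.loc[planted, tissue].to_numpy()
        dist = np.full(len(genes), np.inf)
        nearest_dir = np.full(len(genes), "", dtype=object)
        for chrom in truth.sites["chrom"].unique():
            gm = (genes["chrom"] == chrom).to_numpy()
            sm = (site_pos["chrom"] == chrom).to_numpy()
            if not gm.any() or not sm.any():
                continue
            mids = site_mid[sm]
            dirs = site_dir[sm]
            order = np.argsort(mids)
            mids, dirs = mids[order], dirs[order]
            tss = genes.loc[gm, "tss"].to_numpy()
            pos = np.searchsorted(mids, tss)
            left = np.clip(pos - 1, 0, len(mids) - 1)
            right = np.clip(pos, 0, len(mids) - 1)
            d_left = np.abs(tss - mids[left])
            d_right = np.abs(tss - mids[right])
            use_left = d_left <= d_right
            dist[gm] = np.where(use_left, d_left, d_right)
            nearest_dir[gm] = np.where(use_left, dirs[left], dirs[right])
        p_de = prob_far + (prob_near - prob_far) * np.clip(1 - dist / decay_bp, 0, 1)
        is_deg = rng.random(len(genes)) < p_de
        concordant = rng.random(len(genes)) < concordance
        base_dir = np.where(nearest_dir == "gained", "up", np.where(nearest_dir == "lost", "down", ""))
        rand_dir = rng.choice(["up", "down"], size=len(genes))
        direction = np.where(
            (base_dir != "") & concordant & (dist < decay_bp), base_dir, rand_dir
        )
        direction = np.where(is_deg, direction, "none")
        magnitude = 1.1 + rng.exponential(0.6, size=len(genes))
        log2fc = np.where(
            is_deg,
            np.where(direction == "up", magnitude, -magnitude),
            np.clip(0.3 * rng.standard_normal(len(genes)), -0.99, 0.99),
        )
        fdr = np.where(is_deg, 10.0 ** -rng.uniform(3, 8, len(genes)), rng.uniform(0.02, 1, len(genes)))
        de_truth[tissue] = pd.DataFrame(
            {
                "gene_id": genes["gene_id"].to_numpy(),
                "log2fc": log2fc,
                "fdr": fdr,
                "is_deg": is_deg,
                "direction": direction,
                "dist_to_planted": dist,
            }
        )
    # expression matrix over all cohort samples
    n_samples_per = config.n_cancer + config.n_normal
    sample_ids, shifts = [], []
    baseline = 5.0 + rng.standard_normal(len(genes))
    cols = {}
    for tissue in config.tissues:
        fc = de_truth[tissue]["log2fc"].to_numpy() * de_truth[tissue]["is_deg"].to_numpy()
        for i in range(config.n_cancer):
            cols[f"{tissue}_cancer_{i:02d}"] = (
                baseline + fc + expr_noise_sd * rng.standard_normal(len(genes))
            )
        for i in range(config.n_normal):
            cols[f"{tissue}_normal_{i:02d}"] = baseline + expr_noise_sd * rng.standard_normal(len(genes))
    expr = pd.DataFrame(cols, index=genes["gene_id"])
    truth.genes = genes
    truth.de_truth = de_truth
    return de_truth, expr


def generate_3d_tracks(
    truth: TruthLabels,
    config: CohortConfig,
    tissue: str | None = None,
    bin_size: int = 50_000,
    n_replicates: int = 2,
    pc1_noise_sd: float = 0.02,
    is_noise_sd: float = 0.05,
    isc_effect: float = 0.4,
) -> dict:
    """PC1 and insulation tracks for cancer and normal with planted changes.

    Baseline PC1 is a smooth alternating (sinusoidal) compartment profile
    clamped away from zero; bins holding planted gained (lost) CASs flip
    B->A (A->B) with |delta E| > 0.05.  Insulation tracks share boundary
    minima every 1 Mb, with positive (negative) cancer-minus-normal
    perturbations of ``isc_effect`` at gained (lost) CAS bins.
    """
    tissue = tissue or config.tissues[0]
    rng = substream(config.seed, f"tracks3d_{tissue}")
    cls = truth.site_classes[tissue]
    out = {"pc1_cancer": [], "pc1_normal": [], "is_cancer": [], "is_normal": []}
    switch_bins: dict[str, np.ndarray] = {}
    base_by_chrom: dict[str, dict[str, np.ndarray]] = {}
    for chrom in config.genome.chroms:
        n = config.genome[chrom] // bin_size
        pos = bin_size * (np.arange(n) + 0.5)
        phase = rng.uniform(0, 2 * np.pi)
        base = 0.5 * np.sin(2 * np.pi * pos / 2_000_000 + phase)
        base = np.where(np.abs(base) < 0.08, np.sign(base + 1e-12) * 0.08, base)

        site_sub = truth.sites[truth.sites["chrom"] == chrom]
        site_bins = ((site_sub["start"] + site_sub["end"]) // 2 // bin_size).to_numpy()
        site_cls = cls.loc[site_sub.index].to_numpy()
        bin_class = np.full(n, "none", dtype=object)
        for b, c in zip(site_bins, site_cls):
            if c == "lost" and bin_class[b] == "none":
                bin_class[b] = "lost"
            elif c == "gained":  # gained wins rare collisions
                bin_class[b] = "gained"
        switch_bins[chrom] = bin_class

        mag = np.maximum(np.abs(base), 0.15)
        pc1_n = np.where(bin_class == "gained", -mag, np.where(bin_class == "lost", mag, base))
        pc1_c = np.where(bin_class == "gained", mag, np.where(bin_class == "lost", -mag, base))

        is_base = np.zeros(n)
        for b in range(10, n, 20):  # boundary dip every 1 Mb at 50 kb bins
            lo, hi = max(0, b - 3), min(n, b + 4)
            is_base[lo:hi] -= 1.5 * np.exp(-0.5 * ((np.arange(lo, hi) - b) / 1.2) ** 2)
        is_n = is_base.copy()
        is_c = is_base + np.where(
            bin_class == "gained", isc_effect, np.where(bin_class == "lost", -isc_effect, 0.0)
        )
        base_by_chrom[chrom] = {"pc1_c": pc1_c, "pc1_n": pc1_n, "is_c": is_c, "is_n": is_n}

    for _ in range(n_replicates):
        for key, src, sd in (
            ("pc1_cancer", "pc1_c", pc1_noise_sd),
            ("pc1_normal", "pc1_n", pc1_noise_sd),
            ("is_cancer", "is_c", is_noise_sd),
            ("is_normal", "is_n", is_noise_sd),
        ):
            rep = {
                chrom: SignalTrack(
                    chrom,
                    bin_size,
                    base_by_chrom[chrom][src]
                    + sd * rng.standard_normal(len(base_by_chrom[chrom][src])),
                )
                for chrom in config.genome.chroms
            }
            out[key].append(rep)
    truth.switch_bins = switch_bins
    out["bin_size"] = bin_size
    return out


def generate_contacts_and_loops(
    truth: TruthLabels,
    config: CohortConfig,
    tissue: str | None = None,
    chrom: str = "chr1",
    region_bp: int = 10_000_000,
    resolution: int = 50_000,
    loop_fold: float = 5.0,
    cas_loop_ratio: float = 2.0,
    n_loops: int = 20,
    n_replicates: int = 3,
    noise_sd: float = 0.05,
) -> dict:
    """Dense symmetric contact matrices per condition with planted loops.

    Distance-decay background with TAD blocks; each loop pixel is set to
    ``fold`` times its local background, where the cancer fold is
    ``loop_fold * cas_loop_ratio`` at loops anchored on planted gained CASs
    (and ``loop_fold / cas_loop_ratio`` at lost-CAS anchors).
    """
    from cohescan.structure3d import ContactMatrix

    if region_bp % resolution:
        raise ValueError("region_bp must be a multiple of resolution")
    tissue = tissue or config.tissues[0]
    rng = substream(config.seed, f"contacts_{tissue}")
    n = region_bp // resolution
    i_idx, j_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    dist = np.abs(i_idx - j_idx)
    background = 100.0 / (1.0 + dist)
    tad_edges = np.arange(0, n + 1, 25)
    tad_id = np.searchsorted(tad_edges, np.arange(n), side="right")
    background = background * np.where(tad_id[:, None] == tad_id[None, :], 2.0, 1.0)

    # loop anchors: planted CAS bins in-region where available, random otherwise
    cls = truth.site_classes[tissue]
    sub = truth.sites[(truth.sites["chrom"] == chrom) & (truth.sites["end"] < region_bp)]
    cas_bins = {
        d: (((sub["start"] + sub["end"]) // 2 // resolution)[cls.loc[sub.index] == d])
        .unique()
        .tolist()
        for d in ("gained", "lost")
    }
    loops = []
    kinds = ["gained", "lost", "neutral"]
    sep_hi = min(60, n - 26)  # keep both anchors a flank away from the edges
    if sep_hi <= 20:
        raise ValueError("region too small for loop placement: need >= 47 bins")
    for k in range(n_loops):
        kind = kinds[k % 3]
        sep = int(rng.integers(20, sep_hi))
        pool = [b for b in cas_bins.get(kind, []) if 12 <= b < n - sep - 12]
        if kind != "neutral" and pool:
            bi = int(pool[int(rng.integers(len(pool)))])
        else:
            kind = kind if kind == "neutral" else f"{kind}-synthetic"
            bi = int(rng.integers(12, n - sep - 12))
        bj = bi + sep
        if kind.startswith("gained"):
            fold_c, fold_n = loop_fold * cas_loop_ratio, loop_fold
        elif kind.startswith("lost"):
            fold_c, fold_n = loop_fold / cas_loop_ratio, loop_fold
        else:
            fold_c = fold_n = loop_fold
        loops.append((bi, bj, kind.split("-")[0], fold_c, fold_n))
    loop_df = pd.DataFrame(loops, columns=["bin1", "bin2", "kind", "fold_cancer", "fold_normal"])
    loop_df["chrom1"] = loop_df["chrom2"] = chrom
    loop_df["start1"] = loop_df["bin1"] * resolution
    loop_df["end1"] = loop_df["start1"] + resolution
    loop_df["start2"] = loop_df["bin2"] * resolution
    loop_df["end2"] = loop_df["start2"] + resolution

    def build(fold_col: str) -> list[ContactMatrix]:
        mats = []
        for _ in range(n_replicates):
            m = background.copy()
            for row in loop_df.itertuples(index=False):
                fold = getattr(row, fold_col)
                m[row.bin1, row.bin2] = background[row.bin1, row.bin2] * fold
                m[row.bin2, row.bin1] = m[row.bin1, row.bin2]
            noise = 1.0 + noise_sd * rng.standard_normal((n, n))
            noise = np.clip((noise + noise.T) / 2, 0.1, None)  # symmetric multiplicative noise
            mats.append(ContactMatrix(chrom, 0, resolution, m * noise))
        return mats

    truth.loop_truth = loop_df
    return {"cancer": build("fold_cancer"), "normal": build("fold_normal"), "loops": loop_df}


def generate_loops_to_genes(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    n_loops: int = 200,
    span_range: tuple[int, int] = (250_000, 3_000_000),
    anchor_width: int = 10_000,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """BEDPE loops joining random site anchors to random gene-TSS anchors
    within the span range — the loop universe for the loop-model tests."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    site_arr = sites.reset_index(drop=True)
    genes_by_chrom = {c: g for c, g in genes.groupby("chrom")}
    while len(rows) < n_loops:
        s = site_arr.iloc[int(rng.integers(len(site_arr)))]
        g_sub = genes_by_chrom.get(s["chrom"])
        if g_sub is None:
            continue
        mid = (s["start"] + s["end"]) // 2
        span = int(rng.integers(*span_range)) * (1 if rng.random() < 0.5 else -1)
        target = mid + span
        cand = g_sub[(g_sub["tss"] - target).abs() < span_range[0] // 2]
        if not len(cand):
            continue
        tss = int(cand.iloc[int(rng.integers(len(cand)))]["tss"])
        a1 = (s["chrom"], max(0, mid - anchor_width // 2), mid + anchor_width // 2)
        a2 = (s["chrom"], max(0, tss - anchor_width // 2), tss + anchor_width // 2)
        if a1[1] > a2[1]:
            a1, a2 = a2, a1
        rows.append((*a1, *a2))
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"])


def plant_loop_linked_degs(
    genes: pd.DataFrame,
    connected_gene_ids,
    prob_connected: float = 0.5,
    prob_background: float = 0.1,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """DE table with an excess of DEGs among loop-connected genes."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    connected = genes["gene_id"].isin(set(connected_gene_ids)).to_numpy()
    p = np.where(connected, prob_connected, prob_background)
    is_deg = rng.random(len(genes)) < p
    magnitude = 1.1 + rng.exponential(0.6, size=len(genes))
    sign = np.where(rng.random(len(genes)) < 0.5, 1.0, -1.0)
    log2fc = np.where(is_deg, sign * magnitude, np.clip(0.3 * rng.standard_normal(len(genes)), -0.99, 0.99))
    fdr = np.where(is_deg, 10.0 ** -rng.uniform(3, 8, len(genes)), rng.uniform(0.02, 1, len(genes)))
    return pd.DataFrame(
        {"gene_id": genes["gene_id"].to_numpy(), "log2fc": log2fc, "fdr": fdr, "is_deg": is_deg}
    )


def generate_survival(
    n_patients: int,
    hazard_ratio: float,
    baseline_hazard: float = 1 / 1000.0,
    censor_max_days: float = 2000.0,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Exponential survival with a planted high-hazard half and uniform
    administrative censoring."""
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    groups = np.array(["high"] * (n_patients // 2) + ["low"] * (n_patients - n_patients // 2))
    hazards = np.where(groups == "high", baseline_hazard * hazard_ratio, baseline_hazard)
    times = rng.exponential(1.0 / hazards)
    censor = rng.uniform(censor_max_days * 0.25, censor_max_days, size=n_patients)
    return pd.DataFrame(
        {
            "sample_id": [f"patient_{i:03d}" for i in range(n_patients)],
            "time": np.minimum(times, censor),
            "event": (times <= censor).astype(int),
            "group": groups,
        }
    )


def generate_clinical_aux(
    truth: TruthLabels,
    config: CohortConfig,
    n_patients: int = 200,
    hazard_ratio: float = 3.0,
    baseline_hazard: float = 1 / 1000.0,
    censor_max_days: float = 2000.0,
    n_meth_samples: int = 20,
    beta_low: tuple[float, float] = (2.0, 8.0),
    beta_high: tuple[float, float] = (8.0, 2.0),
    n_tfs: int = 6,
    tf_cas_prob: float = 0.5,
    tf_background_prob: float = 0.05,
    n_mutations: int = 20_000,
    mutation_enrich_fold: float = 3.0,
    mutation_enrich_class: str | None = None,
    depletion_group_prob: float = 0.6,
    depletion_background_prob: float = 0.25,
    tissue: str | None = None,
) -> dict:
    """Survival, methylation, TF-peak, mutation and depletion-response data.

    Survival times are exponential with a ``hazard_ratio``-fold hazard in
    the planted high-risk half of patients, censored administratively.
    Methylation betas are Beta-distributed in [0,1] with planted
    hypermethylation (cancer) at lost-CAS loci only — the asymmetric truth.
    TF peaks prefer CASs with probability ``tf_cas_prob`` for the first
    half of factors.  Mutations are uniform, optionally enriched inside one
    site class.  Depletion tables plant an excess of decreased genes in the
    named group.
    """
    if not (0 < min(beta_low) and 0 < min(beta_high)):
        raise ValueError("beta distribution parameters must be positive")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    tissue = tissue or config.tissues[0]
    rng = substream(config.seed, f"clinical_{tissue}")
    cls = truth.site_classes[tissue]

    surv = generate_survival(n_patients, hazard_ratio, baseline_hazard, censor_max_days, rng)
    truth.survival_groups = surv.set_index("sample_id")["group"]

    # --- methylation: loci are the site intervals ---
    n_loci = len(truth.sites)
    a0, b0 = beta_low
    beta_normal = rng.beta(a0, b0, size=(n_loci, n_meth_samples))
    beta_cancer = rng.beta(a0, b0, size=(n_loci, n_meth_samples))
    lost_mask = (cls == "lost").to_numpy()
    a1, b1 = beta_high
    beta_cancer[lost_mask] = rng.beta(a1, b1, size=(int(lost_mask.sum()), n_meth_samples))
    methylation = {
        "loci": truth.sites.copy(),
        "beta_cancer": beta_cancer,
        "beta_normal": beta_normal,
        "planted_hyper": truth.sites.index[lost_mask],
    }

    # --- TF peaks over the site universe ---
    cas_mask = cls.isin(["gained", "lost"]).to_numpy()
    tf_peaks = {}
    for t in range(n_tfs):
        enriched = t < n_tfs // 2
        p = np.where(cas_mask, tf_cas_prob if enriched else tf_background_prob, tf_background_prob)
        take = rng.random(n_loci) < p
        tf_peaks[f"TF{t + 1}{'e' if enriched else 'n'}"] = truth.sites[take].copy()

    # --- mutations ---
    chrom = config.genome.chroms[0]
    chrom_len = config.genome[chrom]
    positions = rng.integers(0, chrom_len, size=n_mutations)
    if mutation_enrich_class is not None:
        target = truth.sites[(truth.sites["chrom"] == chrom) & cls.isin([mutation_enrich_class]).to_numpy()] \
            if mutation_enrich_class in ("gained", "lost") else None
        if mutation_enrich_class == "conserved" or target is None:
            target = truth.sites[(truth.sites["chrom"] == chrom) & (cls == "stable").to_numpy()].head(200)
        site_bp = int((target["end"] - target["start"]).sum())
        base_rate = n_mutations / chrom_len
        n_extra = rng.poisson((mutation_enrich_fold - 1.0) * base_rate * site_bp)
        if n_extra and len(target):
            rows = rng.integers(0, len(target), size=n_extra)
            offs = rng.integers(0, config.site_width, size=n_extra)
            extra = target["start"].to_numpy()[rows] + offs
            positions = np.concatenate([positions, extra])
    mutations = pd.DataFrame({"chrom": chrom, "pos": np.sort(positions)})

    # --- cohesin-depletion response tables ---
    depletion = {}
    if truth.de_truth is not None:
        de = truth.de_truth[tissue]
        genes_all = de["gene_id"].to_numpy()
        gained_deg = de[(de["is_deg"]) & (de["direction"] == "up") & (de["dist_to_planted"] <= 5000)][
            "gene_id"
        ]
        for context in ("cancer", "normal"):
            in_group = np.isin(genes_all, gained_deg) & (context == "cancer")
            p_dec = np.where(in_group, depletion_group_prob, depletion_background_prob)
            decreased = rng.random(len(genes_all)) < p_dec
            log2fc = np.where(decreased, -np.abs(rng.normal(1, 0.4, len(genes_all))),
                              np.abs(rng.normal(0.3, 0.3, len(genes_all))))
            depletion[context] = pd.DataFrame(
                {
                    "gene_id": genes_all,
                    "log2fc": log2fc,
                    "significant": decreased | (rng.random(len(genes_all)) < 0.05),
                    "context": context,
                }
            )
        depletion_group = {"group": "gained-CAS-DEG", "genes": list(gained_deg)}
    else:
        depletion_group = None

    return {
        "survival": surv,
        "methylation": methylation,
        "tf_peaks": tf_peaks,
        "mutations": mutations,
        "depletion": depletion,
        "depletion_group": depletion_group,
    }


@dataclass
class SyntheticCohort:
    """One fully generated cohort: all modalities from a single config."""

    config: CohortConfig
    occupancy: OccupancyMatrix
    intensity: IntensityMatrix
    manifest: pd.DataFrame
    truth: TruthLabels
    genes: pd.DataFrame
    de_tables: dict[str, pd.DataFrame]
    expression: pd.DataFrame

    @classmethod
    def generate(cls, config: CohortConfig, n_genes: int = 10_000) -> "SyntheticCohort":
        occ, intens, manifest, truth = generate_cohort_chip(config)
        genes = generate_genes(config, n_genes=n_genes)
        de_tables, expr = generate_expression(truth, genes, config)
        return cls(config, occ, intens, manifest, truth, genes, de_tables, expr)

    def peak_bed_frames(self) -> dict[str, pd.DataFrame]:
        """Per-sample peak interval sets (sites where presence is True)."""
        out = {}
        for sid in self.occupancy.presence.columns:
            mask = self.occupancy.presence[sid].to_numpy()
            out[sid] = self.occupancy.sites[mask].reset_index(names="name")[
                ["chrom", "start", "end", "name"]
            ]
        return out
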