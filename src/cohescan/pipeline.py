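"""End-to-end orchestration: simulate -> call CAS -> DEG enrichment ->
3D statistics -> regulatory tests -> clinical statistics, from one config
and one seed, with a provenance manifest sufficient to reproduce every
number in the report."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cohescan import __version__
from cohescan.cas import (
    DEFAULT_THRESHOLDS,
    call_cas,
    differential_table,
    intensity_differential,
    occupancy_differential,
    simpson_matrix,
)
from cohescan.clinical import adjusted_rand_index, cluster_patients, gene_set_sample_score, km_logrank
from cohescan.crm import depletion_response_test, methylation_differential, tf_enrichment
from cohescan.deg import casdeg_partition, drs_score
from cohescan.io import ensure_dir, write_bed, write_table
from cohescan.simulate import (
    CohortConfig,
    SyntheticCohort,
    generate_3d_tracks,
    generate_clinical_aux,
    generate_contacts_and_loops,
    substream,
)
from cohescan.structure3d import apa_compare, compartment_switch_classify, switch_class_proportions

log = logging.getLogger("cohescan.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All stage thresholds plus the synthetic cohort configuration."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    n_draws: int = 500
    near_bp: int = 5_000
    switch_delta: float = 0.05
    n_genes: int = 10_000
    outdir: str = "results/pipeline"
    seed: int | None = None  # overrides cohort.seed when set

    def __post_init__(self):
        if self.seed is not None:
            self.cohort.seed = self.seed
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        return cls(cohort=cohort, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in dependency order and write the report bundle.

    Returns the report dict; all outputs land under ``config.outdir`` with
    a run manifest carrying version, seed and thresholds.  Any stage error
    aborts with the stage name; prior outputs are preserved.
    """
    out = ensure_dir(config.outdir)
    report: dict = {}
    timings: dict = {}
    stage = "simulate"
    try:
        t0 = time.time()
        cohort = SyntheticCohort.generate(config.cohort, n_genes=config.n_genes)
        write_table(cohort.manifest, out / "manifest_samples.tsv")
        write_bed(cohort.occupancy.sites.reset_index(names="name"), out / "consensus_sites.bed")
        timings[stage] = time.time() - t0
        log.info("simulate: %d sites, %d samples", len(cohort.occupancy.sites), len(cohort.manifest))

        stage = "cas_calling"
        t0 = time.time()
        cas_by_tissue, diff_by_tissue = {}, {}
        for tissue in config.cohort.tissues:
            occ_d = occupancy_differential(cohort.occupancy, cohort.manifest, tissue)
            int_d = intensity_differential(cohort.intensity, cohort.manifest, tissue)
            diff = differential_table(occ_d, int_d)
            cas = call_cas(diff, config.thresholds)
            diff_by_tissue[tissue] = diff
            cas_by_tissue[tissue] = cohort.occupancy.sites.loc[cas.index].join(cas)
            write_table(cas.reset_index(names="site_id"), out / f"cas_{tissue}.tsv")
        report["cas"] = _cas_recovery(cohort, cas_by_tissue)
        if len(cas_by_tissue) > 1:
            simpson = simpson_matrix({t: df for t, df in cas_by_tissue.items() if len(df)})
            simpson.to_csv(out / "simpson_matrix.tsv", sep="\t")
            report["cas"]["simpson_offdiag_max"] = float(
                simpson.where(~np.eye(len(simpson), dtype=bool)).max().max()
            )
        timings[stage] = time.time() - t0

        stage = "deg_enrichment"
        t0 = time.time()
        tissue = config.cohort.tissues[0]
        rng = substream(config.cohort.seed, "pipeline_drs")
        de = cohort.de_tables[tissue]
        all_sites = cohort.occupancy.sites
        report["drs"] = {}
        for direction, de_dir in (("gained", "up"), ("lost", "down")):
            cas_set = cas_by_tissue[tissue]
            sub = cas_set[cas_set["direction"] == direction][["chrom", "start", "end"]]
            if not len(sub):
                report["drs"][direction] = None
                continue
            res = drs_score(
                sub, all_sites, cohort.genes, de,
                direction_filter=de_dir, n_draws=config.n_draws, seed=rng,
            )
            report["drs"][direction] = {
                "drs": res.drs,
                "s_cas": res.s_cas,
                **res.background_quantiles,
                "drs_q97.5": res.drs_background_quantiles["q97.5"],
            }
        part = casdeg_partition(
            cas_by_tissue[tissue][["chrom", "start", "end"]], de, cohort.genes, config.near_bp
        )
        report["casdeg"] = {
            "n_cas_degs": len(part.cas_degs),
            "n_other_degs": len(part.other_degs),
            "mannwhitney_p": part.mannwhitney_p,
        }
        timings[stage] = time.time() - t0

        stage = "structure_3d"
        t0 = time.time()
        tracks = generate_3d_tracks(cohort.truth, config.cohort, tissue)
        cas_sites_t = cas_by_tissue[tissue][["chrom", "start", "end"]]
        switch = compartment_switch_classify(
            cas_sites_t, tracks["pc1_cancer"], tracks["pc1_normal"], config.switch_delta
        )
        switch_all = compartment_switch_classify(
            all_sites, tracks["pc1_cancer"], tracks["pc1_normal"], config.switch_delta
        )
        write_table(switch.reset_index(), out / "compartment_switch_cas.tsv")
        report["compartments"] = {
            "cas": switch_class_proportions(switch).to_dict(),
            "all_sites": switch_class_proportions(switch_all).to_dict(),
        }
        contacts = generate_contacts_and_loops(cohort.truth, config.cohort, tissue)
        apa = apa_compare({"cancer": contacts["cancer"], "normal": contacts["normal"]},
                          contacts["loops"][contacts["loops"]["kind"] == "gained"])
        report["apa"] = apa.set_index("condition")["normalized_ratio"].to_dict()
        timings[stage] = time.time() - t0

        stage = "crm_regulation"
        t0 = time.time()
        clinical = generate_clinical_aux(cohort.truth, config.cohort, tissue=tissue)
        cas_idx = cohort.truth.planted_sites(tissue).intersection(cas_by_tissue[tissue].index)
        tf = tf_enrichment(all_sites.loc[cas_idx] if len(cas_idx) else cas_sites_t,
                           all_sites, clinical["tf_peaks"])
        write_table(tf.reset_index(), out / "tf_enrichment.tsv")
        report["tf_enrichment"] = {
            "n_significant": int((tf["fisher_p"] < 0.01).sum()),
            "n_tfs": len(tf),
        }
        lost_idx = cohort.truth.site_classes.index[cohort.truth.site_classes[tissue] == "lost"]
        meth = methylation_differential(
            clinical["methylation"]["loci"],
            clinical["methylation"]["beta_cancer"],
            clinical["methylation"]["beta_normal"],
            all_sites.loc[lost_idx],
            all_sites,
            direction="hyper",
            n_draws=min(config.n_draws, 200),
            seed=substream(config.cohort.seed, "pipeline_meth"),
        )
        report["methylation"] = {
            "lost_cas_ratio": meth.cas_ratio,
            **{f"random_{k}": v for k, v in meth.envelope.items()},
        }
        if clinical["depletion"]:
            groups = {
                "gained-CAS-DEG": clinical["depletion_group"]["genes"],
                "other-DEG": list(
                    set(de.loc[de["is_deg"], "gene_id"]) - set(clinical["depletion_group"]["genes"])
                ),
            }
            depl = depletion_response_test(groups, clinical["depletion"]["cancer"])
            report["depletion"] = {
                "ratios": depl["ratios"],
                "fisher_p": float(depl["pairwise_fisher_p"].iloc[0, 1]),
            }
        timings[stage] = time.time() - t0

        stage = "clinical_stats"
        t0 = time.time()
        cancer_samples = cohort.manifest.loc[cohort.manifest["condition"] == "cancer", "sample_id"]
        expr_cancer = cohort.expression[list(cancer_samples)]
        truth_labels = [s.split("_")[0] for s in expr_cancer.columns]
        casdeg_genes = sorted(
            set().union(
                *(
                    set(part.cas_degs["gene_id"])
                    for part in [
                        casdeg_partition(
                            cas_by_tissue[t][["chrom", "start", "end"]],
                            cohort.de_tables[t],
                            cohort.genes,
                            config.near_bp,
                        )
                        for t in config.cohort.tissues
                        if len(cas_by_tissue[t])
                    ]
                )
            )
        )
        ari = np.nan
        if len(casdeg_genes) >= 2:
            pred = cluster_patients(
                expr_cancer, casdeg_genes, k=config.cohort.n_tissues, seed=config.cohort.seed
            )
            ari = adjusted_rand_index(truth_labels, pred.to_numpy())
        surv = clinical["survival"]
        km = km_logrank(surv)
        report["clinical"] = {
            "ari_casdeg": float(ari),
            "n_casdeg_genes": len(casdeg_genes),
            "logrank_p": km.p_value,
        }
        timings[stage] = time.time() - t0
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise StageError(stage, exc) from exc

    manifest = {
        "version": __version__,
        "seed": config.cohort.seed,
        "thresholds": config.thresholds,
        "n_draws": config.n_draws,
        "near_bp": config.near_bp,
        "switch_delta": config.switch_delta,
        "cohort": {k: v for k, v in asdict(config.cohort).items() if k != "genome"},
        "genome": config.cohort.genome.lengths,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report


def _cas_recovery(cohort: SyntheticCohort, cas_by_tissue: dict) -> dict:
    """Sensitivity / empirical FDR / direction accuracy against the planted
    truth, pooled over tissues."""
    tp = fp = fn = correct_dir = 0
    for tissue, cas in cas_by_tissue.items():
        truth_cls = cohort.truth.site_classes[tissue]
        called = set(cas.index)
        planted = set(truth_cls.index[truth_cls != "stable"])
        tp_sites = called & planted
        tp += len(tp_sites)
        fp += len(called - planted)
        fn += len(planted - called)
        for s in tp_sites:
            if cas.loc[s, "direction"] == truth_cls.loc[s]:
                correct_dir += 1
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "empirical_fdr": fp / (tp + fp) if tp + fp else 0.0,
        "direction_accuracy": correct_dir / tp if tp else np.nan,
        "n_called": tp + fp,
        "n_planted": tp + fn,
    }
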