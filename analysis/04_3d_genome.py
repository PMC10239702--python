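#!/usr/bin/env python
"""3D-genome statistics at planted CASs: compartment switches, insulation
score change (ISC), TAD boundaries and aggregate peak analysis (APA) of
loop strength between conditions.

Writes switch calls, ISC summaries and APA ratios under results/3d/.
"""

import json
import sys

sys.path.insert(0, "src")

from cohescan import io as cio
from cohescan.simulate import CohortConfig, generate_3d_tracks, generate_cohort_chip, generate_contacts_and_loops
from cohescan.structure3d import (
    apa_compare,
    boundary_call,
    compartment_switch_classify,
    insulation_score,
    isc_site_stats,
    switch_class_proportions,
)
from cohescan.tracks import mean_track

SEED = 1


def main():
    cfg = CohortConfig(seed=SEED)
    _, _, _, truth = generate_cohort_chip(cfg)
    out = cio.ensure_dir("results/3d")
    tracks = generate_3d_tracks(truth, cfg)
    report = {}

    cas = truth.sites.loc[truth.site_classes["liver"] != "stable"]
    calls = compartment_switch_classify(cas, tracks["pc1_cancer"], tracks["pc1_normal"])
    calls_all = compartment_switch_classify(truth.sites, tracks["pc1_cancer"], tracks["pc1_normal"])
    cio.write_table(calls.reset_index(), out / "switch_cas.tsv")
    report["switch_proportions_cas"] = switch_class_proportions(calls).round(4).to_dict()
    report["switch_proportions_all"] = switch_class_proportions(calls_all).round(4).to_dict()
    print("switch classes at CASs:", report["switch_proportions_cas"])
    print("switch classes at all sites:", report["switch_proportions_all"])

    is_c = {c: mean_track([rep[c] for rep in tracks["is_cancer"]]) for c in cfg.genome.chroms}
    is_n = {c: mean_track([rep[c] for rep in tracks["is_normal"]]) for c in cfg.genome.chroms}
    boundaries = None
    gained = truth.sites.loc[truth.site_classes["liver"] == "gained"]
    lost = truth.sites.loc[truth.site_classes["liver"] == "lost"]
    for name, sites in (("gained", gained), ("lost", lost)):
        per_site, summary = isc_site_stats(is_c, is_n, sites, boundaries)
        report[f"isc_{name}"] = summary.round(4).to_dict(orient="records")
        print(f"mean ISC at {name} CASs: {per_site['isc'].mean():+.3f}")

    contacts = generate_contacts_and_loops(truth, cfg)
    for kind in ("gained", "lost", "neutral"):
        loops = contacts["loops"][contacts["loops"]["kind"] == kind]
        if not len(loops):
            continue
        apa = apa_compare({"cancer": contacts["cancer"], "normal": contacts["normal"]}, loops)
        ratio = apa.set_index("condition").loc["cancer", "normalized_ratio"]
        report[f"apa_cancer_ratio_{kind}_loops"] = round(float(ratio), 3)
        print(f"APA cancer/normal ratio at {kind}-CAS loops: {ratio:.2f}")

    ist = insulation_score(contacts["cancer"][0])
    cio.write_bedgraph(ist, out / "insulation_cancer_rep1.bedgraph")
    bounds = boundary_call(ist)
    report["n_boundaries_region"] = len(bounds)
    print(f"{len(bounds)} TAD boundaries called in the simulated region")
    (out / "report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
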