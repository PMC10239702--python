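#!/usr/bin/env python
"""Call cancer-aberrant cohesin sites (CASs) per tissue on the simulated
cohort and report recovery of the planted truth plus tissue specificity
(Simpson index).

Writes per-tissue differential tables and CAS calls under results/cas/.
"""

import sys

sys.path.insert(0, "src")

import numpy as np

from cohescan import io as cio
from cohescan.cas import (
    call_cas,
    differential_table,
    intensity_differential,
    occupancy_differential,
    simpson_matrix,
)
from cohescan.simulate import CohortConfig, SyntheticCohort

SEED = 1


def main():
    cohort = SyntheticCohort.generate(CohortConfig(seed=SEED))
    out = cio.ensure_dir("results/cas")
    cas_sets = {}
    for tissue in cohort.config.tissues:
        diff = differential_table(
            occupancy_differential(cohort.occupancy, cohort.manifest, tissue),
            intensity_differential(cohort.intensity, cohort.manifest, tissue),
        )
        cas = call_cas(diff)
        cio.write_table(diff.round(6).reset_index(names="site_id"), out / f"differential_{tissue}.tsv")
        cio.write_table(cas.round(6).reset_index(names="site_id"), out / f"cas_{tissue}.tsv")
        truth = cohort.truth.site_classes[tissue]
        planted = set(truth.index[truth != "stable"])
        called = set(cas.index)
        tp = len(called & planted)
        sens = tp / len(planted)
        fdr = len(called - planted) / max(len(called), 1)
        n_gained = int((cas["direction"] == "gained").sum())
        print(f"{tissue}: {len(cas)} CASs ({n_gained} gained, {len(cas) - n_gained} lost); "
              f"sensitivity {sens:.3f}, empirical FDR {fdr:.3f}")
        cas_sets[tissue] = cohort.truth.sites.loc[cas.index]
    sm = simpson_matrix(cas_sets)
    sm.round(4).to_csv(out / "simpson_matrix.tsv", sep="\t")
    off = sm.to_numpy()[~np.eye(len(sm), dtype=bool)]
    print(f"Simpson index off-diagonal max {off.max():.3f} "
          f"(independently planted tissue CAS sets are highly specific)")


if __name__ == "__main__":
    main()
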