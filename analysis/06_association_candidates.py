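#!/usr/bin/env python
"""Allelic association of shortlisted variants and the candidate MAF table.

Computes per-variant allelic odds ratios, Wald CIs and chi-square p-values
between the two populations for every shortlisted variant, and rebuilds the
published nine-candidate MAF-difference table from its printed cohort and
African-reference MAF pairs.  Writes results/association.tsv and
results/candidates.tsv.
"""

from pathlib import Path

import pandas as pd

import pygmyscan as pg

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    manifest = pg.PopulationManifest.from_tsv(ROOT / "cohort" / "manifest.tsv")
    records = pg.read_vcf(ROOT / "cohort" / "cohort.vcf", manifest)
    gm = pg.filter_variants(records, manifest)

    short = pd.read_csv(ROOT / "shortlist.tsv", sep="\t")
    rows = [int(gm.variants.index[gm.variants["id"] == vid][0])
            for vid in short["variant_id"]]
    table = pg.association_table(gm.take_variants(rows), manifest)
    table.to_csv(ROOT / "association.tsv", sep="\t", index=False,
                 float_format="%.6g")
    print(f"association table: {len(table)} shortlisted variants")
    print(table[["id", "OR", "CI_5", "CI_95", "p"]].head(10)
          .to_string(index=False))

    pub = pg.PUBLISHED_CANDIDATES
    cohort_maf = pd.Series(pub["maf_cohort"].values, index=pub["snp_id"])
    ref_maf = pd.Series(pub["maf_reference"].values, index=pub["snp_id"])
    ann = pub.set_index("snp_id")[["gene", "localization"]]
    candidates = pg.candidate_table(cohort_maf, ref_maf, ann)
    candidates.to_csv(ROOT / "candidates.tsv", sep="\t", index=False,
                      float_format="%.6g")
    print("\npublished candidate MAF differences (cohort vs African panel):")
    print(candidates.to_string(index=False))
    print(f"wrote {ROOT / 'association.tsv'}, candidates.tsv")


if __name__ == "__main__":
    main()
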