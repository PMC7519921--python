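#!/usr/bin/env python
"""Ingest the cohort VCF, apply quality filters, and summarize variants.

Reads results/cohort/, filters at QUAL >= 30 and locus depth >= 5 (biallelic,
autosomes only), and writes the per-population variant summary to
results/variant_summary.tsv.
"""

from pathlib import Path

import pygmyscan as pg

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    manifest = pg.PopulationManifest.from_tsv(ROOT / "cohort" / "manifest.tsv")
    records = pg.read_vcf(ROOT / "cohort" / "cohort.vcf", manifest)
    gm = pg.filter_variants(records, manifest, min_qual=30, min_depth=5)
    print(f"records read: {len(records)}; after filtering: {gm.n_variants}")

    pops = pg.split_by_population(gm, manifest)
    summary = pg.summarize_variants(pops)
    summary.to_tsv(ROOT / "variant_summary.tsv")
    print(summary.per_population.to_string())
    print(f"shared: {summary.shared}  unique: {summary.unique}  "
          f"union: {summary.union}")
    print(f"wrote {ROOT / 'variant_summary.tsv'}")


if __name__ == "__main__":
    main()
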