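#!/usr/bin/env python
"""Hierarchical clustering of sPLS-selected variants and the gene shortlist.

Builds per-variant frequency profiles over the two populations, clusters them
(complete linkage, Euclidean), cuts at up to 29 clusters, and keeps one
gene-annotated maximum-contrast representative per cluster.  Planted variants
carry the synthetic gene annotation.  Writes results/shortlist.tsv and
results/dendrogram.nwk.
"""

from pathlib import Path

import pandas as pd

import pygmyscan as pg

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    manifest = pg.PopulationManifest.from_tsv(ROOT / "cohort" / "manifest.tsv")
    records = pg.read_vcf(ROOT / "cohort" / "cohort.vcf", manifest)
    gm = pg.filter_variants(records, manifest)
    freqs = pg.allele_frequencies(gm, manifest)

    selected = list(pd.read_csv(ROOT / "spls_selection.tsv",
                                sep="\t")["variant_id"].drop_duplicates())
    profiles = pg.build_profiles(freqs, selected)
    dendro = pg.cluster_variants(profiles, linkage="complete",
                                 metric="euclidean")
    (ROOT / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    profiles.profiles.rename_axis("variant_id").to_csv(
        ROOT / "heatmap_profiles.tsv", sep="\t", float_format="%.6g")

    truth = pd.read_csv(ROOT / "cohort" / "truth.tsv", sep="\t")
    planted = truth.loc[truth["planted"]]
    annotation = pd.DataFrame(
        {"gene": [f"GENE{i:03d}" for i in range(len(planted))],
         "localization": "CDS"},
        index=pd.Index(planted["variant_id"], name="variant_id"),
    )
    k = min(29, profiles.profiles.shape[0])
    short = pg.shortlist(dendro, profiles, annotation, n_clusters=k)
    short.to_csv(ROOT / "shortlist.tsv", sep="\t", index=False,
                 float_format="%.6g")
    print(f"clustered {profiles.profiles.shape[0]} variants, cut at k = {k}")
    print(f"shortlist: {len(short)} gene-annotated representatives")
    print(short.head(10).to_string(index=False))
    print(f"wrote {ROOT / 'shortlist.tsv'}, dendrogram.nwk, "
          "heatmap_profiles.tsv")


if __name__ == "__main__":
    main()
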