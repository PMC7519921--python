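"""End-to-end discovery funnel: ingest -> filter -> F_st -> sPLS -> cluster ->
associate.

A single configuration (optionally loaded from YAML) drives the fixed stage
order; every stage writes its TSV artifact and the funnel report records each
stage's input/output cardinality and parameters.  All randomness flows from
one top-level seed, so a run is fully deterministic: the same config produces
byte-identical artifacts.

Stages after filtering are individually skippable for testing; the funnel
order itself is fixed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import assoc, cluster, popgen, spls
from .errors import PygmyscanError, ValidationError
from .genotype_io import (
    GenotypeMatrix,
    PopulationManifest,
    filter_variants,
    read_vcf,
)
from .simulate import SimulationConfig, simulate_cohort, write_fixture

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full funnel.

    Inputs are either a simulation spec (``simulation`` set) or paths to an
    existing VCF + manifest.  Annotation (variant id -> gene, localization) is
    optional; without it the clustering shortlist is empty by construction.
    """

    simulation: SimulationConfig | None = None
    vcf: str | None = None
    manifest: str | None = None
    annotation: str | None = None

    min_qual: float = 30.0
    min_depth: float = 5.0
    exclude_xy: bool = True

    fst_estimator: str = "weir_cockerham"
    fst_threshold: float = 0.30
    top_quantiles: tuple[float, ...] = (0.001, 0.0001)

    n_components: int = 2
    keep_x: tuple[int, ...] = (400, 400)
    response_type: str = "binary_population"

    cluster_linkage: str = "complete"
    cluster_metric: str = "euclidean"
    n_clusters: int = 29

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "planted_freqs" in sim:
                sim["planted_freqs"] = tuple(sim["planted_freqs"])
            sim = SimulationConfig(**sim)
        for key in ("keep_x", "top_quantiles"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)


@dataclass
class StageRecord:
    stage: str
    n_in: int
    n_out: int
    parameters: dict = field(default_factory=dict)


@dataclass
class FunnelReport:
    """Ordered per-stage cardinalities of one funnel run."""

    stages: list[StageRecord] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int, **parameters) -> None:
        logger.info("stage %s: %d -> %d", stage, n_in, n_out)
        self.stages.append(StageRecord(stage, int(n_in), int(n_out), parameters))

    def to_json(self, path: str | Path) -> None:
        payload = [dataclasses.asdict(s) for s in self.stages]
        with open(path, "w", newline="\n") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def counts(self) -> dict[str, int]:
        return {s.stage: s.n_out for s in self.stages}


def _planted_annotation(truth: pd.DataFrame) -> pd.DataFrame:
    """Synthetic gene annotation: every planted variant gets a gene label."""
    planted = truth.loc[truth["planted"]]
    return pd.DataFrame(
        {
            "gene": [f"GENE{i:03d}" for i in range(len(planted))],
            "localization": "CDS",
        },
        index=pd.Index(planted["variant_id"], name="variant_id"),
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> FunnelReport:
    """Execute the funnel, writing one TSV artifact per stage under ``out_dir``.

    Returns the :class:`FunnelReport`; artifacts of completed stages are
    retained even if a later stage aborts (the raised error names the stage).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = FunnelReport()

    stage = "ingest"
    try:
        annotation = None
        truth = None
        if config.simulation is not None:
            cohort = simulate_cohort(config.simulation)
            paths = write_fixture(cohort, out_dir / "cohort")
            manifest = cohort.manifest
            records = read_vcf(paths["vcf"], manifest)
            truth = cohort.truth
            annotation = _planted_annotation(truth)
        else:
            if not config.vcf or not config.manifest:
                raise ValidationError("need a simulation spec or vcf + manifest")
            manifest = PopulationManifest.from_tsv(config.manifest)
            records = read_vcf(config.vcf, manifest)
        if config.annotation:
            annotation = pd.read_csv(
                config.annotation, sep="\t", index_col="variant_id"
            )
        report.add(stage, len(records), len(records))

        stage = "filter"
        gm = filter_variants(
            records,
            manifest,
            min_qual=config.min_qual,
            min_depth=config.min_depth,
            biallelic_only=True,
            exclude_xy=config.exclude_xy,
        )
        report.add(
            stage,
            len(records),
            gm.n_variants,
            min_qual=config.min_qual,
            min_depth=config.min_depth,
            exclude_xy=config.exclude_xy,
        )

        stage = "frequencies"
        freqs = popgen.allele_frequencies(gm, manifest)
        freq_out = freqs.freq.copy()
        freq_out.insert(0, "variant_id", gm.variants["id"].to_numpy())
        freq_out.to_csv(out_dir / "frequencies.tsv", sep="\t", index=False,
                        float_format="%.6g", lineterminator="\n")
        report.add(stage, gm.n_variants, gm.n_variants)

        stage = "fst_scan"
        fst = popgen.fst_scan(gm, manifest, estimator=config.fst_estimator)
        fst.to_tsv(out_dir / "fst.tsv")
        popgen.manhattan_table(fst).to_csv(
            out_dir / "fst_manhattan.tsv", sep="\t", index=False,
            float_format="%.6g", lineterminator="\n",
        )
        n_defined = int(fst.table["defined"].sum())
        report.add(stage, gm.n_variants, n_defined,
                   estimator=config.fst_estimator)

        stage = "fst_tier"
        tiers = popgen.select_tiers(
            fst, thresholds=[config.fst_threshold],
            top_quantiles=list(config.top_quantiles),
        )
        tier_rows = []
        for t in tiers:
            for i in t.indices:
                tier_rows.append(
                    {
                        "tier": f"{t.kind}:{t.spec:g}",
                        "realized_threshold": t.realized_threshold,
                        "variant_id": gm.variants["id"].iloc[i],
                        "fst": fst.table["fst"].iloc[i],
                    }
                )
        pd.DataFrame(
            tier_rows,
            columns=["tier", "realized_threshold", "variant_id", "fst"],
        ).to_csv(out_dir / "fst_tiers.tsv", sep="\t", index=False,
                 float_format="%.6g", lineterminator="\n")
        primary = tiers[0]
        report.add(stage, n_defined, primary.n_selected,
                   threshold=config.fst_threshold)
        gm_tier = gm.take_variants(primary.indices)

        stage = "spls"
        if gm_tier.n_variants == 0:
            logger.warning("empty F_st tier: funnel ends with no candidates")
            selected_ids: list = []
            report.add(stage, 0, 0)
        else:
            gm_imp = spls.impute_missing(gm_tier)
            keep_x = tuple(
                min(k, gm_imp.n_variants) for k in config.keep_x
            )
            spls_cfg = spls.SplsConfig(
                n_components=config.n_components,
                keep_x=keep_x,
                response_type=config.response_type,
            )
            response = (
                manifest.table["population"]
                if config.response_type == "binary_population"
                else manifest.table["height_sds"]
            )
            fit = spls.fit_spls(gm_imp, response.to_numpy(), spls_cfg)
            spls.selection_table(fit).to_csv(
                out_dir / "spls_selection.tsv", sep="\t", index=False,
                float_format="%.6g", lineterminator="\n",
            )
            selected_ids = spls.selected_variants(fit, "all")
            report.add(stage, gm_imp.n_variants, len(selected_ids),
                       keep_x=list(keep_x), n_components=config.n_components)

        stage = "cluster"
        if len(selected_ids) < 2 or annotation is None:
            short = pd.DataFrame(
                columns=["variant_id", "cluster", "gene", "localization",
                         "contrast"]
            )
            n_cl_in = len(selected_ids)
        else:
            profiles = cluster.build_profiles(freqs, selected_ids)
            dendro = cluster.cluster_variants(
                profiles, linkage=config.cluster_linkage,
                metric=config.cluster_metric,
            )
            (out_dir / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
            profiles.profiles.rename_axis("variant_id").to_csv(
                out_dir / "heatmap_profiles.tsv", sep="\t",
                float_format="%.6g", lineterminator="\n",
            )
            k = min(config.n_clusters, profiles.profiles.shape[0])
            short = cluster.shortlist(dendro, profiles, annotation, n_clusters=k)
            n_cl_in = profiles.profiles.shape[0]
        short.to_csv(out_dir / "shortlist.tsv", sep="\t", index=False,
                     float_format="%.6g", lineterminator="\n")
        report.add(stage, n_cl_in, len(short),
                   linkage=config.cluster_linkage,
                   metric=config.cluster_metric,
                   n_clusters=config.n_clusters)

        stage = "association"
        if len(short):
            rows = [
                int(gm.variants.index[gm.variants["id"] == vid][0])
                for vid in short["variant_id"]
            ]
            gm_short = gm.take_variants(rows)
            ann = annotation if annotation is not None else None
            table = assoc.association_table(gm_short, manifest, annotation=ann)
        else:
            table = pd.DataFrame(
                columns=["chrom", "pos", "id", "gene", "ref", "alt",
                         "OR", "CI_5", "CI_95", "p"]
            )
        table.to_csv(out_dir / "association.tsv", sep="\t", index=False,
                     float_format="%.6g", lineterminator="\n")
        report.add(stage, len(short), len(table))

        if truth is not None:
            truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False,
                         lineterminator="\n")
    except PygmyscanError as exc:
        report.to_json(out_dir / "funnel.json")
        raise PygmyscanError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report.to_json(out_dir / "funnel.json")
    return report
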