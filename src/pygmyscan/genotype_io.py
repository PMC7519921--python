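"""VCF + manifest ingestion into a filtered genotype dosage matrix.

The central container is :class:`GenotypeMatrix`: a variants x samples matrix of
alternate-allele dosages (0, 1, 2, or :data:`MISSING`) with a variant index
(chrom, pos, id, ref, alt) and an ordered sample list.  Reading goes through
cyvcf2; coordinates stay 1-based VCF throughout.

Quality filtering follows exome variant-calling practice: a Phred-scaled site
quality floor (QUAL >= 30), a site read-depth floor (locus DP >= 5), restriction
to biallelic records, and exclusion of the sex chromosomes.  "Total read depth
at the locus" is taken from INFO/DP when present and otherwise from the sum of
per-sample FORMAT/DP values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]

_SEX_CHROMS = {"X", "Y"}


def _is_sex_chrom(chrom: str) -> bool:
    return str(chrom).removeprefix("chr").upper() in _SEX_CHROMS


@dataclass
class PopulationManifest:
    """Per-sample population labels, sex, and optional anthropometric SDS.

    ``table`` is indexed by sample id and carries at least a ``population``
    column; ``sex`` and ``height_sds`` (standard-deviation score, dimensionless)
    are optional.  A two-cohort analysis expects exactly two population labels.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            raise ValidationError("manifest sample ids must be unique")
        if "population" not in self.table.columns:
            raise ValidationError("manifest must have a 'population' column")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def populations(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        return list(dict.fromkeys(self.table["population"]))

    def samples_of(self, population: str) -> list[str]:
        if population not in set(self.table["population"]):
            raise ValidationError(f"unknown population label: {population!r}")
        return list(self.table.index[self.table["population"] == population])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationManifest":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        if "sample_id" not in df.columns:
            raise ParseError(f"{path}: manifest lacks a 'sample_id' column")
        return cls(df.set_index("sample_id"))

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("sample_id").reset_index().to_csv(
            path, sep="\t", index=False, lineterminator="\n"
        )


@dataclass
class VariantRecord:
    """One VCF record with dosages aligned to the manifest sample order."""

    chrom: str
    pos: int  # 1-based, VCF convention
    id: str | None
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    depth: float | None  # site-level DP (INFO DP, else sum of sample DPs)
    dosages: np.ndarray  # int8, MISSING for uncalled

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)


@dataclass
class GenotypeMatrix:
    """Variants x samples alternate-allele dosage matrix.

    ``dosages`` is an int8 array with entries in {0, 1, 2, MISSING}.  ``variants``
    is a DataFrame with columns chrom, pos, id, ref, alt (one row per matrix
    row); ``samples`` names the columns.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValidationError("dosage matrix must be 2-D")
        if len(self.variants) != self.dosages.shape[0]:
            raise ValidationError("variant table length != dosage rows")
        if len(self.samples) != self.dosages.shape[1]:
            raise ValidationError("sample list length != dosage columns")

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of called (non-missing) entries."""
        return self.dosages != MISSING

    def variant_ids(self) -> pd.Series:
        return self.variants["id"]

    def take_variants(self, rows: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows, dtype=int)
        return GenotypeMatrix(
            self.dosages[rows],
            self.variants.iloc[rows].reset_index(drop=True),
            list(self.samples),
        )

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in names]
        return GenotypeMatrix(
            self.dosages[:, idx], self.variants.copy(), list(names)
        )


def read_vcf(path: str | Path, manifest: PopulationManifest) -> list[VariantRecord]:
    """Read a VCF 4.x file into records aligned to the manifest sample order.

    Missing calls ("./.") are preserved as :data:`MISSING`.  Raises
    :class:`ValidationError` if a manifest sample is absent from the VCF and
    :class:`ParseError` on an unreadable file.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc

    vcf_samples = list(vcf.samples)
    missing_samples = [s for s in manifest.samples if s not in vcf_samples]
    if missing_samples:
        raise ParseError(
            f"manifest samples absent from VCF {path}: {missing_samples}"
        )
    order = np.array([vcf_samples.index(s) for s in manifest.samples])

    records: list[VariantRecord] = []
    for line_no, v in enumerate(vcf, start=1):
        try:
            gts = np.asarray(v.genotype.array())[:, :2]  # alleles per sample
            dos = gts.sum(axis=1).astype(np.int8)
            dos[(gts < 0).any(axis=1)] = MISSING
            dos = dos[order]

            info_dp = v.INFO.get("DP")
            if info_dp is not None:
                depth = float(info_dp)
            else:
                fmt_dp = v.format("DP")
                depth = float(np.nansum(fmt_dp)) if fmt_dp is not None else None
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    id=v.ID,
                    ref=v.REF,
                    alts=tuple(v.ALT),
                    qual=v.QUAL,
                    depth=depth,
                    dosages=dos,
                )
            )
        except Exception as exc:
            raise ParseError(f"{path}: malformed record #{line_no}: {exc}") from exc
    return records


def filter_variants(
    records: Iterable[VariantRecord],
    manifest: PopulationManifest,
    min_qual: float = 30.0,
    min_depth: float = 5.0,
    biallelic_only: bool = True,
    exclude_xy: bool = True,
) -> GenotypeMatrix:
    """Apply site-quality filters and emit a dosage matrix over survivors.

    Retains records with QUAL >= ``min_qual`` (records without QUAL pass) and
    site depth >= ``min_depth`` (records without depth pass); drops
    multi-allelic records when ``biallelic_only`` and chrX/chrY records when
    ``exclude_xy``.  Zero survivors produce an empty matrix with a warning,
    not an error.
    """
    kept: list[VariantRecord] = []
    for rec in records:
        if rec.qual is not None and rec.qual < min_qual:
            continue
        if rec.depth is not None and rec.depth < min_depth:
            continue
        if biallelic_only and not rec.is_biallelic:
            continue
        if exclude_xy and _is_sex_chrom(rec.chrom):
            continue
        kept.append(rec)

    if not kept:
        warnings.warn("filter_variants: no records survived filtering", stacklevel=2)
        return GenotypeMatrix(
            np.zeros((0, len(manifest.samples)), dtype=np.int8),
            pd.DataFrame(columns=VARIANT_COLUMNS),
            manifest.samples,
        )

    variants = pd.DataFrame(
        {
            "chrom": [r.chrom for r in kept],
            "pos": [r.pos for r in kept],
            "id": [r.id for r in kept],
            "ref": [r.ref for r in kept],
            "alt": [r.alts[0] for r in kept],
        }
    )
    dosages = np.vstack([r.dosages for r in kept])
    return GenotypeMatrix(dosages, variants, manifest.samples)


@dataclass
class VariantSummary:
    """Cohort-level variant counts per population plus shared/unique partition.

    A variant is scored in a population when at least one alternate allele is
    called there.  "Novel" means the record lacks a database id (external
    membership lookup is out of scope here).
    """

    per_population: pd.DataFrame  # rows: count categories, cols: populations
    shared: int
    unique: dict[str, int]
    union: int

    def to_tsv(self, path: str | Path) -> None:
        out = self.per_population.copy()
        out.loc["shared (both populations)"] = self.shared
        out.loc["union"] = self.union
        out.rename_axis("category").to_csv(path, sep="\t", lineterminator="\n")


def _presence(gm: GenotypeMatrix) -> np.ndarray:
    """Variants with >= 1 called alternate allele."""
    return (gm.dosages > 0).any(axis=1)


def summarize_variants(matrices: Mapping[str, GenotypeMatrix]) -> VariantSummary:
    """Per-population variant counts (Table-2 shape) over a shared variant universe.

    Each matrix holds the same variant rows but the samples of one population.
    """
    pops = list(matrices)
    first = matrices[pops[0]]
    for gm in matrices.values():
        if gm.n_variants != first.n_variants:
            raise ValidationError("population matrices must share a variant universe")

    variants = first.variants
    ids = variants["id"]
    novel_mask = ids.isna() | (ids == ".") | (ids == "")
    snp_mask = (variants["ref"].str.len() == 1) & (variants["alt"].str.len() == 1)
    autosomal_mask = ~variants["chrom"].map(_is_sex_chrom).to_numpy(dtype=bool)

    presence = {p: _presence(matrices[p]) for p in pops}
    rows = {}
    for p in pops:
        pr = presence[p]
        rows[p] = {
            "total variants": int(pr.sum()),
            "variants (w/o XY)": int((pr & autosomal_mask).sum()),
            "SNPs": int((pr & snp_mask.to_numpy()).sum()),
            "In/Del": int((pr & ~snp_mask.to_numpy()).sum()),
            "novel variants": int((pr & novel_mask.to_numpy()).sum()),
            "mean variants per sample": float(
                (matrices[p].dosages > 0).sum(axis=0).mean()
            )
            if matrices[p].n_samples
            else 0.0,
        }

    any_mask = np.zeros(first.n_variants, dtype=bool)
    for pr in presence.values():
        any_mask |= pr
    union = int(any_mask.sum())
    if len(pops) == 2:
        shared = int((presence[pops[0]] & presence[pops[1]]).sum())
        unique = {
            pops[0]: int((presence[pops[0]] & ~presence[pops[1]]).sum()),
            pops[1]: int((presence[pops[1]] & ~presence[pops[0]]).sum()),
        }
    else:
        shared = int(np.logical_and.reduce([presence[p] for p in pops]).sum())
        unique = {
            p: int((presence[p] & ~np.logical_or.reduce(
                [presence[q] for q in pops if q != p])).sum())
            for p in pops
        }
    return VariantSummary(pd.DataFrame(rows), shared, unique, union)


def split_by_population(
    gm: GenotypeMatrix, manifest: PopulationManifest
) -> dict[str, GenotypeMatrix]:
    """One matrix per population, sharing the variant universe."""
    return {p: gm.take_samples(manifest.samples_of(p)) for p in manifest.populations}
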