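"""Per-variant allelic association and MAF-difference candidate tables.

Association between two cohorts is computed on the 2x2 allele-count table
(population x ref/alt allele): the allelic odds ratio with a Wald log-OR 95%
confidence interval (Haldane-Anscombe 0.5 correction when a cell is zero) and
a Pearson chi-square test with one degree of freedom.  A genotypic
(per-individual) counting mode is exposed but allelic counting is the
default.  No multiple-testing correction is applied for selection; adjusted
p-value columns are emitted for transparency only.

The module also builds candidate tables contrasting a cohort's minor-allele
frequencies with an externally supplied reference panel's, sorted by the
frequency difference — the shape in which prioritized variants are reported.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .genotype_io import MISSING, GenotypeMatrix, PopulationManifest
from .popgen import FrequencyTable

logger = logging.getLogger(__name__)

#: Published minor-allele frequencies of the nine validated short-stature
#: candidate variants in the Baka Pygmy cohort versus an African reference
#: panel (gene, dbSNP id, gene localization, cohort MAF, reference MAF).
#: These printed values serve as worked-example inputs for candidate tables.
PUBLISHED_CANDIDATES: pd.DataFrame = pd.read_csv(
    io.StringIO(
        "gene\tsnp_id\tlocalization\tmaf_cohort\tmaf_reference\n"
        "SHISA5\trs3135955\t3'-UTR\t0.570\t0.130\n"
        "HYAL2\trs7629425\t5'-UTR\t0.440\t0.030\n"
        "ABCC12\trs9925287\tCDS\t0.620\t0.300\n"
        "DIRAS3\trs11801053\t3'-UTR\t0.590\t0.270\n"
        "DIRAS\trs61736596\tCDS\t0.550\t0.280\n"
        "STX3\trs472177\t5'-UTR\t0.650\t0.480\n"
        "PLA2G4C\trs9226\t3'-UTR\t0.650\t0.500\n"
        "DBT\trs12021720\tCDS\t0.320\t0.250\n"
        "GPR116\trs572248\tCDS\t0.620\t0.550\n"
    ),
    sep="\t",
)


@dataclass
class AllelicCounts:
    """2x2 population x allele (ref/alt) count table for one variant.

    ``table[i] = (ref_count, alt_count)`` for population i; row sums equal
    2 x called samples.  ``undefined`` flags a population with zero called
    samples.
    """

    table: np.ndarray  # shape (2, 2), ints
    populations: tuple[str, str]
    undefined: bool = False

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.int64)
        if self.table.shape != (2, 2) or (self.table < 0).any():
            raise ValidationError("allele count table must be 2x2 non-negative")


def allelic_counts(
    gm: GenotypeMatrix, manifest: PopulationManifest, variant_row: int
) -> AllelicCounts:
    """Allele counts for one biallelic variant, split by population.

    alt = sum of dosages over called samples; ref = 2 x called - alt.
    Missing genotypes are excluded from both numerator and denominator.
    """
    pops = manifest.populations
    if len(pops) != 2:
        raise ValidationError("allelic counts need exactly two populations")
    rows = []
    undefined = False
    for pop in pops:
        cols = [gm.samples.index(s) for s in manifest.samples_of(pop)]
        d = gm.dosages[variant_row, cols]
        obs = d != MISSING
        called = int(obs.sum())
        alt = int(d[obs].sum())
        ref = 2 * called - alt
        if called == 0:
            undefined = True
        rows.append((ref, alt))
    return AllelicCounts(np.array(rows), (pops[0], pops[1]), undefined)


def genotypic_counts(
    gm: GenotypeMatrix, manifest: PopulationManifest, variant_row: int,
    mode: str = "dominant",
) -> AllelicCounts:
    """Carrier-based 2x2 counts: dominant (dosage > 0) or recessive (== 2)."""
    if mode not in ("dominant", "recessive"):
        raise ValidationError(f"unknown genotypic mode: {mode!r}")
    pops = manifest.populations
    rows = []
    undefined = False
    for pop in pops:
        cols = [gm.samples.index(s) for s in manifest.samples_of(pop)]
        d = gm.dosages[variant_row, cols]
        obs = d != MISSING
        carrier = (d[obs] > 0) if mode == "dominant" else (d[obs] == 2)
        if obs.sum() == 0:
            undefined = True
        rows.append((int(obs.sum() - carrier.sum()), int(carrier.sum())))
    return AllelicCounts(np.array(rows), (pops[0], pops[1]), undefined)


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_5: float
    ci_95: float
    corrected: bool  # Haldane-Anscombe 0.5 applied


def odds_ratio_ci(
    counts: AllelicCounts, correction: bool = True
) -> OddsRatioResult:
    """Allelic odds ratio with Wald 95% CI on the log scale.

    OR = (a d)/(b c) on the table ((a, b), (c, d)); when any cell is zero and
    ``correction`` is on, 0.5 is added to every cell first (Haldane-Anscombe),
    keeping OR and CI finite.  CI = exp(ln OR +/- 1.96 sqrt(1/a+1/b+1/c+1/d))
    on the (corrected) cells.
    """
    if counts.undefined:
        return OddsRatioResult(float("nan"), float("nan"), float("nan"), False)
    t = counts.table.astype(float)
    corrected = False
    if correction and (t == 0).any():
        t = t + 0.5
        corrected = True
    (a, b), (c, d) = t
    if b * c == 0 or a * d == 0:
        return OddsRatioResult(float("nan"), float("nan"), float("nan"), corrected)
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(or_) - 1.959963984540054 * se))
    hi = float(np.exp(np.log(or_) + 1.959963984540054 * se))
    return OddsRatioResult(float(or_), lo, hi, corrected)


def chisq_test(counts: AllelicCounts, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square of homogeneity on the 2x2 table, df = 1.

    Yates continuity correction optional (default off).  If any expected cell
    is zero the test is undefined: (nan, nan) with a warning.
    """
    if counts.undefined:
        warnings.warn("chi-square undefined: empty population", stacklevel=2)
        return float("nan"), float("nan")
    t = counts.table.astype(float)
    total = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    if (expected == 0).any():
        warnings.warn("chi-square undefined: zero expected cell", stacklevel=2)
        return float("nan"), float("nan")
    diff = np.abs(t - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def association_table(
    gm: GenotypeMatrix,
    manifest: PopulationManifest,
    annotation: pd.DataFrame | None = None,
    yates: bool = False,
    correction: bool = True,
) -> pd.DataFrame:
    """Allelic OR / Wald CI / chi-square p for every variant in the matrix.

    Adds Bonferroni- and Benjamini-Hochberg-adjusted p-value columns for
    transparency; they are never used for selection here.
    """
    rows = []
    for i in range(gm.n_variants):
        counts = allelic_counts(gm, manifest, i)
        orr = odds_ratio_ci(counts, correction=correction)
        stat, p = chisq_test(counts, yates=yates)
        v = gm.variants.iloc[i]
        gene = ""
        if annotation is not None and v["id"] in annotation.index:
            gene = annotation.loc[v["id"], "gene"]
        rows.append(
            {
                "chrom": v["chrom"],
                "pos": v["pos"],
                "id": v["id"],
                "gene": gene,
                "ref": v["ref"],
                "alt": v["alt"],
                "OR": orr.odds_ratio,
                "CI_5": orr.ci_5,
                "CI_95": orr.ci_95,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["p_bonferroni"] = np.nan
    out["p_bh"] = np.nan
    if ok.any():
        from statsmodels.stats.multitest import multipletests

        pvals = out.loc[ok, "p"].to_numpy()
        out.loc[ok, "p_bonferroni"] = multipletests(pvals, method="bonferroni")[1]
        out.loc[ok, "p_bh"] = multipletests(pvals, method="fdr_bh")[1]
    return out


def candidate_table(
    cohort_maf: pd.Series | FrequencyTable,
    reference_maf: pd.Series,
    annotation: pd.DataFrame,
    cohort_population: str | None = None,
) -> pd.DataFrame:
    """MAF-difference candidate table, sorted by difference descending.

    ``cohort_maf`` is either a Series of MAF indexed by variant id or a
    :class:`~pygmyscan.popgen.FrequencyTable` (then ``cohort_population``
    names the column to use).  ``reference_maf`` supplies per-variant
    reference-panel MAF (externally typed values); variants without one get
    an undefined difference and are logged, never dropped.  ``annotation``
    maps variant id to gene and localization.
    """
    if isinstance(cohort_maf, FrequencyTable):
        if cohort_population is None:
            raise ValidationError("cohort_population required with a FrequencyTable")
        ser = cohort_maf.maf[cohort_population].copy()
        ser.index = pd.Index(cohort_maf.variants["id"])
        cohort_maf = ser

    rows = []
    for vid, maf in cohort_maf.items():
        ref = reference_maf.get(vid, np.nan)
        if pd.isna(ref):
            logger.info("candidate_table: no reference MAF for %s", vid)
        ann = annotation.loc[vid] if vid in annotation.index else None
        rows.append(
            {
                "gene": "" if ann is None else ann.get("gene", ""),
                "snp_id": vid,
                "localization": "" if ann is None else ann.get("localization", ""),
                "maf_cohort": float(maf),
                "maf_reference": float(ref) if pd.notna(ref) else np.nan,
                "frequency_difference": float(maf - ref)
                if pd.notna(ref)
                else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        "frequency_difference", ascending=False, kind="stable", na_position="last"
    ).reset_index(drop=True)
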