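"""Allele frequencies, MAF correlation, and per-variant fixation-index scans.

Two F_st-type estimators of population differentiation are provided:

* Weir & Cockerham's (1984) per-site estimator, built from three variance
  components per biallelic locus — a (among populations), b (among
  individuals within populations) and c (within individuals) — with
  theta = a / (a + b + c).  Aggregation over loci follows the two standard
  conventions: the "mean" F_st averages the per-site ratios, the "weighted"
  F_st is the ratio of summed components, sum(a) / sum(a + b + c).
* Nei's G_st, (Ht - Hs) / Ht, computed from the population sample
  frequencies only (Ht from the unweighted mean frequency, Hs as the mean
  within-population expected heterozygosity).

Per-site estimates may be negative (a property of the estimator around
F_st = 0, not an error) and are kept in the aggregates unclamped; sites whose
denominator is zero (monomorphic everywhere) are flagged undefined and
excluded.  Candidate tiers are cut either at a fixed value (strictly
greater-than) or at a top quantile of the defined per-site distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError
from .genotype_io import MISSING, GenotypeMatrix, PopulationManifest


@dataclass
class FrequencyTable:
    """Per variant x population alternate-allele frequency, MAF and call counts.

    ``freq`` and ``maf`` are variants x populations DataFrames; entries are NaN
    where no allele was called (undefined, flagged via :meth:`defined`).
    ``called_alleles`` counts 2 x non-missing samples.
    """

    freq: pd.DataFrame
    maf: pd.DataFrame
    called_alleles: pd.DataFrame
    variants: pd.DataFrame = field(repr=False, default=None)

    def defined(self) -> pd.DataFrame:
        return self.freq.notna()


def allele_frequencies(
    gm: GenotypeMatrix, manifest: PopulationManifest
) -> FrequencyTable:
    """Per-population alternate-allele frequency and MAF from a dosage matrix.

    frequency = sum(dosage) / (2 x called samples); MAF = min(f, 1 - f).
    All-missing variant/population cells are NaN (flagged undefined).
    """
    unknown = set(manifest.populations) - set(manifest.table["population"])
    if unknown:
        raise ValidationError(f"unknown population labels: {unknown}")
    freq = {}
    called = {}
    for pop in manifest.populations:
        cols = [gm.samples.index(s) for s in manifest.samples_of(pop)]
        if not cols:
            raise ValidationError(f"population {pop!r} has no samples")
        d = gm.dosages[:, cols]
        obs = d != MISSING
        n_alleles = 2 * obs.sum(axis=1)
        alt = np.where(obs, d, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        freq[pop] = f
        called[pop] = n_alleles
    freq_df = pd.DataFrame(freq)
    maf_df = pd.DataFrame({p: np.minimum(f, 1.0 - f) for p, f in freq.items()})
    return FrequencyTable(freq_df, maf_df, pd.DataFrame(called), gm.variants)


@dataclass
class CorrelationResult:
    """Squared Pearson correlation of two allele-frequency vectors."""

    r_squared: float
    n_snps: int
    p: float
    df: int
    ci_low: float
    ci_high: float


def maf_correlation(
    freqs_a: np.ndarray | pd.Series, freqs_b: np.ndarray | pd.Series
) -> CorrelationResult:
    """Cross-population correlation of allele frequencies over shared SNPs.

    Reports r^2, a p-value from the t distribution with n - 2 degrees of
    freedom, and a 95% CI on r^2 obtained by Fisher z-transforming r,
    squaring the bounds, and ordering them.  NaN pairs are dropped first.
    """
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("frequency vectors must have equal length")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    n = a.size
    if n < 3:
        raise ValidationError("need >= 3 shared defined SNPs")
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValidationError("zero-variance frequency vector: correlation undefined")

    r = float(np.corrcoef(a, b)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))

    # Fisher z CI on r, then squared and order-normalized for r^2.
    if abs(r) >= 1.0 or n <= 3:
        lo = hi = r * r
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        r_lo, r_hi = np.tanh(z - 1.959963984540054 * se), np.tanh(
            z + 1.959963984540054 * se
        )
        lo, hi = sorted((r_lo**2, r_hi**2))
        if min(r_lo, r_hi) < 0 < max(r_lo, r_hi):
            lo = 0.0  # CI on r straddles zero
    return CorrelationResult(r * r, n, p, df, float(lo), float(hi))


@dataclass
class FstTable:
    """Per-variant differentiation estimates.

    ``table`` has one row per variant with columns depending on the estimator:
    Weir-Cockerham adds the variance components a, b, c; Nei's G_st adds the
    heterozygosities ht, hs.  The ``fst`` column always carries the per-site
    estimate and ``defined`` flags rows with a usable denominator.
    """

    table: pd.DataFrame
    estimator: str
    variants: pd.DataFrame = field(repr=False, default=None)

    @property
    def fst(self) -> pd.Series:
        return self.table["fst"]

    def defined_fst(self) -> pd.Series:
        return self.table.loc[self.table["defined"], "fst"]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        if self.variants is not None:
            out = pd.concat(
                [self.variants.reset_index(drop=True), out.reset_index(drop=True)],
                axis=1,
            )
        # negative per-site estimates are kept, undefined sites excluded from
        # aggregates (flag column documents the convention)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g",
                   lineterminator="\n")


def weir_cockerham_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) per-site variance components for r populations.

    Parameters are arrays of shape (loci, r): ``n`` sample sizes in
    individuals, ``p`` alternate-allele sample frequencies and ``h`` observed
    heterozygote proportions.  Returns the per-locus components (a, b, c).
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[1]
    if r < 2:
        raise ValidationError("need >= 2 populations")

    n_tot = n.sum(axis=1)
    n_bar = n_tot / r
    n_c = (n_tot - (n**2).sum(axis=1) / n_tot) / (r - 1)
    p_bar = (n * p).sum(axis=1) / n_tot
    s2 = (n * (p - p_bar[:, None]) ** 2).sum(axis=1) / ((r - 1) * n_bar)
    h_bar = (n * h).sum(axis=1) / n_tot

    with np.errstate(divide="ignore", invalid="ignore"):
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - s2 * (r - 1.0) / r
            - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
    c = h_bar / 2.0
    return a, b, c


def _pop_stats(
    gm: GenotypeMatrix, manifest: PopulationManifest
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (n, p, h) arrays of shape (loci, populations)."""
    ns, ps, hs = [], [], []
    for pop in manifest.populations:
        cols = [gm.samples.index(s) for s in manifest.samples_of(pop)]
        d = gm.dosages[:, cols]
        obs = d != MISSING
        n_i = obs.sum(axis=1)
        alt = np.where(obs, d, 0).sum(axis=1)
        het = np.where(obs, d == 1, False).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i = np.where(n_i > 0, alt / np.maximum(2 * n_i, 1), np.nan)
            h_i = np.where(n_i > 0, het / np.maximum(n_i, 1), np.nan)
        ns.append(n_i)
        ps.append(p_i)
        hs.append(h_i)
    return (np.column_stack(ns).astype(float), np.column_stack(ps),
            np.column_stack(hs))


def nei_gst_from_frequencies(
    freqs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nei's G_st per locus from sample frequencies of shape (loci, pops).

    Ht = 2 p_bar (1 - p_bar) with p_bar the unweighted mean across
    populations; Hs = mean of 2 p_i (1 - p_i).  Returns (ht, hs, gst) with
    gst NaN where Ht = 0.
    """
    freqs = np.asarray(freqs, dtype=float)
    p_bar = freqs.mean(axis=1)
    ht = 2.0 * p_bar * (1.0 - p_bar)
    hs = (2.0 * freqs * (1.0 - freqs)).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        gst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), np.nan)
    return ht, hs, gst


def fst_scan(
    gm: GenotypeMatrix,
    manifest: PopulationManifest,
    estimator: str = "weir_cockerham",
) -> FstTable:
    """Per-variant fixation-index scan across the manifest's populations.

    ``estimator`` is ``"weir_cockerham"`` (variance components from sample
    sizes, frequencies and observed heterozygosity) or ``"nei_gst"``
    (frequencies only).  Sites that are monomorphic everywhere (zero
    denominator) are flagged undefined rather than propagating NaN into
    aggregates.
    """
    if len(manifest.populations) < 2:
        raise ValidationError("fst_scan needs >= 2 populations")
    n, p, h = _pop_stats(gm, manifest)
    any_empty = (n == 0).any(axis=1)

    if estimator == "weir_cockerham":
        # guard empty populations so the component algebra stays finite
        n_safe = np.where(n == 0, 1.0, n)
        a, b, c = weir_cockerham_components(
            n_safe, np.nan_to_num(p), np.nan_to_num(h)
        )
        denom = a + b + c
        defined = (~any_empty) & np.isfinite(denom) & (denom != 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = np.where(defined, a / np.where(denom != 0, denom, 1.0), np.nan)
        a = np.where(any_empty, np.nan, a)
        b = np.where(any_empty, np.nan, b)
        c = np.where(any_empty, np.nan, c)
        table = pd.DataFrame(
            {"a": a, "b": b, "c": c, "fst": fst, "defined": defined}
        )
    elif estimator == "nei_gst":
        ht, hs, gst = nei_gst_from_frequencies(p)
        defined = (~any_empty) & np.isfinite(gst)
        gst = np.where(defined, gst, np.nan)
        table = pd.DataFrame({"ht": ht, "hs": hs, "fst": gst, "defined": defined})
    else:
        raise ConfigurationError(f"unknown estimator: {estimator!r}")
    return FstTable(table, estimator, gm.variants)


@dataclass
class FstAggregate:
    """Mean (average of per-site ratios) and weighted (ratio of sums) F_st."""

    mean_fst: float
    weighted_fst: float
    n_sites: int


def aggregate_fst(table: FstTable) -> FstAggregate:
    """Aggregate a per-site scan into mean and weighted F_st.

    mean = average of defined per-site estimates (negatives kept); weighted =
    sum(a) / sum(a + b + c) for Weir-Cockerham, (sum Ht - sum Hs) / sum Ht
    for Nei's G_st.
    """
    defined = table.table["defined"].to_numpy(dtype=bool)
    if not defined.any():
        raise ValidationError("no defined sites to aggregate")
    per_site = table.table.loc[defined, "fst"].to_numpy(dtype=float)
    mean = float(per_site.mean())
    if table.estimator == "weir_cockerham":
        sub = table.table.loc[defined]
        num = float(sub["a"].sum())
        den = float((sub["a"] + sub["b"] + sub["c"]).sum())
    else:
        sub = table.table.loc[defined]
        ht_sum = float(sub["ht"].sum())
        num = ht_sum - float(sub["hs"].sum())
        den = ht_sum
    if den == 0:
        raise ValidationError("aggregate denominator is zero")
    return FstAggregate(mean, float(num / den), int(defined.sum()))


@dataclass
class SelectionTier:
    """One candidate tier: a threshold or top-quantile cut of the scan."""

    kind: str  # "threshold" | "quantile"
    spec: float
    realized_threshold: float
    indices: np.ndarray  # row indices into the scan table, ascending
    overflow: int = 0  # ties beyond the nominal quantile count

    @property
    def n_selected(self) -> int:
        return int(self.indices.size)


def select_tiers(
    table: FstTable,
    thresholds: list[float] = (0.30,),
    top_quantiles: list[float] = (0.001, 0.0001),
) -> list[SelectionTier]:
    """Cut the per-site distribution into candidate tiers.

    Threshold tiers select strictly greater-than.  Quantile tiers select the
    top fraction q of the defined per-site values: the realized threshold is
    the k-th largest defined value (k = round(q * n), at least 1) and all
    sites >= it are selected, so boundary ties are included and reported as
    ``overflow``.
    """
    if len(table.table) == 0:
        raise ValidationError("empty scan table")
    fst = table.table["fst"].to_numpy(dtype=float)
    defined = table.table["defined"].to_numpy(dtype=bool)
    tiers: list[SelectionTier] = []
    for thr in thresholds:
        sel = np.flatnonzero(defined & (fst > thr))
        tiers.append(SelectionTier("threshold", float(thr), float(thr), sel))
    n_def = int(defined.sum())
    for q in top_quantiles:
        if not (0.0 < q < 1.0):
            raise ConfigurationError(f"top quantile must lie in (0, 1): {q}")
        if n_def == 0:
            tiers.append(SelectionTier("quantile", float(q), float("nan"),
                                       np.array([], dtype=int)))
            continue
        k = max(1, int(round(q * n_def)))
        vals = np.sort(fst[defined])[::-1]
        realized = float(vals[k - 1])
        sel = np.flatnonzero(defined & (fst >= realized))
        tiers.append(
            SelectionTier("quantile", float(q), realized, sel, int(sel.size - k))
        )
    return tiers


def manhattan_table(table: FstTable) -> pd.DataFrame:
    """Scan table with a cumulative genome position column, ready to plot."""
    if table.variants is None:
        raise ValidationError("scan carries no variant index")
    df = table.variants.reset_index(drop=True).copy()
    df["fst"] = table.table["fst"].to_numpy()
    offset = 0
    cum = np.zeros(len(df), dtype=float)
    for chrom, grp in df.groupby("chrom", sort=False):
        cum[grp.index] = grp["pos"].to_numpy(dtype=float) + offset
        offset += float(grp["pos"].max())
    df["cumulative_pos"] = cum
    return df
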