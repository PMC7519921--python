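"""Two-population synthetic cohorts under the Balding-Nichols model.

The generator emulates a small exome-sequenced discovery cohort drawn from two
diverged populations (a short-statured forest forager group and a sympatric
farmer control group).  Background loci follow the Balding-Nichols model:
an ancestral allele frequency p ~ Uniform(0.05, 0.95) and, independently per
population, a present-day frequency drawn from
Beta(p (1-F)/F, (1-p)(1-F)/F), whose variance across populations is
F p (1-p) — so the drift parameter F is the expected fixation index of the
pair.  A small number of "planted" loci instead take explicit per-population
frequencies, giving strongly differentiated variants with known truth.

Phenotype (height standard-deviation score) is generated directly on the SDS
scale: each alternate allele at a planted locus lowers height by
``effect_size`` SDS, plus Gaussian residual noise.  Genotype missingness is
uniform at random.

A companion generator produces dual-luciferase reporter readings with
log-normal multiplicative noise for the functional-assay arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .genotype_io import MISSING, GenotypeMatrix, PopulationManifest
from .reporter import LuciferaseExperiment

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a two-population cohort simulation.

    Defaults describe the study conditions the package targets: an 84 + 20
    two-population cohort, 2000 exome loci at a background divergence of
    F = 0.03 (the weighted fixation index observed between the two sympatric
    Cameroonian populations), and 20 strongly differentiated loci at
    frequencies 0.9 / 0.1 each lowering height by 0.1 SDS per allele — which
    sums, over the expected ~32-allele load difference, to the roughly 3 SDS
    height gap seen between the two groups.
    """

    n_pop1: int = 84
    n_pop2: int = 20
    n_variants: int = 2000
    fst_background: float = 0.03
    n_planted: int = 20
    planted_freqs: tuple[float, float] = (0.9, 0.1)
    effect_size: float = 0.1
    phenotype_sd: float = 1.0
    missing_rate: float = 0.02
    seed: int = 0
    pop1_label: str = "baka"
    pop2_label: str = "bantu"

    def validate(self) -> None:
        for name in ("n_pop1", "n_pop2", "n_variants", "n_planted"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer")
        if self.n_planted > self.n_variants:
            raise ConfigurationError("n_planted cannot exceed n_variants")
        if not (0.0 < self.fst_background < 1.0) or not math.isfinite(
            self.fst_background
        ):
            raise ConfigurationError("fst_background must lie in (0, 1)")
        if len(self.planted_freqs) != 2 or any(
            not (0.0 <= f <= 1.0) or not math.isfinite(f) for f in self.planted_freqs
        ):
            raise ConfigurationError("planted_freqs must be a pair in [0, 1]")
        for name in ("effect_size", "phenotype_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        if self.phenotype_sd < 0:
            raise ConfigurationError("phenotype_sd must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must lie in [0, 1)")


@dataclass
class SyntheticCohort:
    """A simulated cohort: genotypes, manifest, and per-variant truth table.

    The truth table has one row per variant (ancestral and per-population
    allele frequencies, planted flag, effect size), so every downstream
    estimate can be checked against the generating values.
    """

    genotypes: GenotypeMatrix
    manifest: PopulationManifest
    truth: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def planted_ids(self) -> list[str]:
        return list(self.truth.loc[self.truth["planted"], "variant_id"])


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a two-population cohort under the configured model.

    Deterministic: the same config (including seed) yields a bit-identical
    cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m, n1, n2 = config.n_variants, config.n_pop1, config.n_pop2
    n = n1 + n2
    F = config.fst_background

    p_anc = rng.uniform(0.05, 0.95, size=m)
    shape_a = p_anc * (1.0 - F) / F
    shape_b = (1.0 - p_anc) * (1.0 - F) / F
    p1 = rng.beta(shape_a, shape_b)
    p2 = rng.beta(shape_a, shape_b)

    planted_idx = np.sort(rng.choice(m, size=config.n_planted, replace=False))
    planted = np.zeros(m, dtype=bool)
    planted[planted_idx] = True
    p1[planted] = config.planted_freqs[0]
    p2[planted] = config.planted_freqs[1]

    g1 = rng.binomial(2, p1[:, None], size=(m, n1))
    g2 = rng.binomial(2, p2[:, None], size=(m, n2))
    dosages = np.concatenate([g1, g2], axis=1).astype(np.int8)

    # Phenotype is computed on the complete genotypes, before masking.
    planted_load = dosages[planted].sum(axis=0) if config.n_planted else np.zeros(n)
    height_sds = (
        -config.effect_size * planted_load
        + rng.normal(0.0, config.phenotype_sd, size=n)
    )

    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = MISSING

    ref = rng.choice(4, size=m)
    alt = (ref + rng.integers(1, 4, size=m)) % 4
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, m + 1) * 100,
            "id": [f"v{i:06d}" for i in range(m)],
            "ref": _BASES[ref],
            "alt": _BASES[alt],
        }
    )

    samples = [f"{config.pop1_label}{i:03d}" for i in range(n1)] + [
        f"{config.pop2_label}{i:03d}" for i in range(n2)
    ]
    manifest = PopulationManifest(
        pd.DataFrame(
            {
                "population": [config.pop1_label] * n1 + [config.pop2_label] * n2,
                "sex": rng.choice(["M", "F"], size=n),
                "height_sds": np.round(height_sds, 4),
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )

    truth = pd.DataFrame(
        {
            "variant_id": variants["id"],
            "ancestral_freq": np.round(p_anc, 6),
            f"freq_{config.pop1_label}": np.round(p1, 6),
            f"freq_{config.pop2_label}": np.round(p2, 6),
            "planted": planted,
            "effect_size": np.where(planted, config.effect_size, 0.0),
        }
    )

    gm = GenotypeMatrix(dosages, variants, samples)
    return SyntheticCohort(gm, manifest, truth, config)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_fixture(
    cohort: SyntheticCohort,
    out_dir: str | Path,
    qual: float = 60.0,
    sample_depth: int = 20,
) -> dict[str, Path]:
    """Write a cohort as VCF + manifest TSV + truth TSV under ``out_dir``.

    The VCF is VCF 4.2 with QUAL, INFO/DP, and per-sample GT:DP populated;
    missing dosages become "./." calls with DP 0.  Round-trips through
    :func:`pygmyscan.genotype_io.read_vcf` without loss.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gm = cohort.genotypes
    vcf_path = out_dir / "cohort.vcf"
    manifest_path = out_dir / "manifest.tsv"
    truth_path = out_dir / "truth.tsv"

    contigs = list(dict.fromkeys(gm.variants["chrom"]))
    with open(vcf_path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pygmyscan-simulate\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i, row in enumerate(gm.variants.itertuples(index=False)):
            dos = gm.dosages[i]
            depths = np.where(dos == MISSING, 0, sample_depth)
            calls = "\t".join(
                f"{_GT[int(d)]}:{dp}" for d, dp in zip(dos, depths)
            )
            vid = row.id if row.id not in (None, "") else "."
            fh.write(
                f"{row.chrom}\t{row.pos}\t{vid}\t{row.ref}\t{row.alt}\t"
                f"{qual:g}\t.\tDP={int(depths.sum())}\tGT:DP\t{calls}\n"
            )

    cohort.manifest.to_tsv(manifest_path)
    cohort.truth.to_csv(truth_path, sep="\t", index=False, lineterminator="\n")
    return {"vcf": vcf_path, "manifest": manifest_path, "truth": truth_path}


def simulate_luciferase(
    n_replicates: int,
    construct_means: dict[str, float],
    cv: float,
    seed: int,
) -> LuciferaseExperiment:
    """Simulate dual-luciferase readings with multiplicative log-normal noise.

    Renilla readings are drawn per replicate around 5e5 RLU; the firefly
    reading is ``mean * renilla * noise`` where the noise is log-normal with
    unit mean and coefficient of variation ``cv``, so the normalized ratio has
    expectation equal to the configured construct mean, and equals it exactly
    at cv = 0.
    """
    if n_replicates < 2:
        raise ConfigurationError("n_replicates must be >= 2")
    if cv < 0 or not math.isfinite(cv):
        raise ConfigurationError("cv must be a finite non-negative fraction")
    if not construct_means or any(v <= 0 for v in construct_means.values()):
        raise ConfigurationError("construct means must be positive")

    rng = np.random.default_rng(seed)
    rows = []
    for label, mean in construct_means.items():
        renilla = rng.lognormal(math.log(5e5), 0.15, size=n_replicates)
        if cv > 0:
            sigma = math.sqrt(math.log(1.0 + cv**2))
            noise = rng.lognormal(-0.5 * sigma**2, sigma, size=n_replicates)
        else:
            noise = np.ones(n_replicates)
        firefly = mean * renilla * noise
        for f, r in zip(firefly, renilla):
            rows.append({"construct": label, "firefly": f, "renilla": r})
    data = pd.DataFrame(rows)
    data["ratio"] = data["firefly"] / data["renilla"]
    return LuciferaseExperiment(data)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["planted_freqs"] = list(d["planted_freqs"])
    return d
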