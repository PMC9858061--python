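"""Synthetic cohort generator: LD-block genotypes and a liability-threshold
categorical phenotype.

The generator emulates the statistical structure of a WGS case/control-style
cohort of unrelated individuals:

* **Genotypes** come from a Gaussian-copula haplotype model. Each LD block
  has a latent equicorrelated multivariate normal; each of the two haplotypes
  per individual is drawn independently and thresholded at the SNP's
  allele-frequency quantile, and the two haplotypes are summed to a 0/1/2
  dosage. The latent correlation is calibrated numerically so that the
  *dosage* correlation within a block matches the configured target.
  Different blocks are independent.
* **Phenotype** follows a liability-threshold model: liability is a weighted
  sum of standardized causal-SNP dosages plus Gaussian noise, scaled so the
  genetic share of liability variance equals the configured heritability.
  Samples are ranked by liability and cut into the five ordered disease
  categories (resistant < control < benign < mild < severe) at exact counts
  given by the configured proportions.
* **Covariates** (age, sex) are drawn independently of liability by default;
  an optional confounding coefficient adds standardized age into liability.

Default group proportions reproduce a cohort of 1076 with 306 resistant and
235 severe individuals.
"""

from __future__ import annotations

import functools
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix, write_vcf

CATEGORIES = ("resistant", "control", "benign", "mild", "severe")

#: default category proportions: 306 resistant / 161 control / 216 benign /
#: 158 mild / 235 severe out of 1076
DEFAULT_PROPORTIONS = (306 / 1076, 161 / 1076, 216 / 1076, 158 / 1076, 235 / 1076)


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults emulate the target study size."""

    n_samples: int = 1076
    n_snps: int = 5000
    ld_block_size: int = 10
    within_block_r: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int = 10
    causal_effect_sd: float = 1.0
    causal_effect_dist: str = "normal"  # "normal" draws N(0, sd); "equal"
    # gives every causal SNP magnitude sd with random sign (large-effect
    # oligogenic scenario)
    heritability: float = 0.3
    category_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    age_range: tuple[float, float] = (18.0, 85.0)
    missing_rate: float = 0.0
    age_liability_coef: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_snps < 0 or self.ld_block_size < 1:
            raise InvalidConfigError("dimensions must be positive")
        if not 0.0 <= self.within_block_r < 1.0:
            raise InvalidConfigError("within_block_r must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must lie within (0, 0.5]")
        if self.n_causal > self.n_snps:
            raise InvalidConfigError("n_causal exceeds n_snps")
        if not 0.0 <= self.heritability < 1.0:
            raise InvalidConfigError("heritability must be in [0, 1)")
        props = np.asarray(self.category_proportions, dtype=float)
        if props.size != 5 or (props < 0).any():
            raise InvalidConfigError("five nonnegative proportions required")
        if abs(props.sum() - 1.0) > 1e-12:
            raise InvalidConfigError("category proportions must sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidConfigError("missing_rate must be in [0, 1)")
        if self.causal_effect_dist not in ("normal", "equal"):
            raise InvalidConfigError(
                "causal_effect_dist must be 'normal' or 'equal'"
            )

    @property
    def category_thresholds(self) -> tuple[float, ...]:
        """Four ascending standard-normal liability quantiles implied by the
        category proportions (degenerate proportions collapse thresholds)."""
        cum = np.cumsum(self.category_proportions)[:4]
        cum = np.clip(cum, 1e-12, 1 - 1e-12)
        return tuple(stats.norm.ppf(cum))


@dataclass
class SimulatedCohort:
    genotypes: GenotypeMatrix
    truth: pd.DataFrame  # snp_id, is_causal, effect (liability scale)
    cohort_table: pd.DataFrame  # sample_id, category, age, sex
    liability: np.ndarray

    def __post_init__(self) -> None:
        if not self.cohort_table["category"].isin(CATEGORIES).all():
            raise ValueError("unknown category literal in cohort table")


@functools.lru_cache(maxsize=4096)
def _latent_correlation(target_r: float, p: float) -> float:
    """Latent Gaussian correlation giving allele (hence dosage) Pearson
    correlation ``target_r`` for two loci thresholded at frequency ``p``.

    Dosage correlation equals single-haplotype allele correlation because
    the two haplotypes are independent with identical structure.
    """
    if target_r <= 0.0:
        return 0.0
    # ultra-rare frequencies make the bivariate normal orthant mass
    # numerically unstable (and the target correlation unattainable anyway);
    # calibrate at a clamped frequency
    p = min(max(p, 1e-4), 0.5)
    z = stats.norm.ppf(p)

    def phi(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [z, z], mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        )
        return (p11 - p * p) / (p * (1.0 - p))

    hi = 0.9999
    if phi(hi) <= target_r:
        return hi
    return float(optimize.brentq(lambda r: phi(r) - target_r, 0.0, hi, xtol=1e-8))


def _variant_table(n_snps: int, ld_block_size: int, rng: np.random.Generator) -> pd.DataFrame:
    """Deterministic variant metadata: blocks laid contiguously on up to 22
    chromosomes, positions ascending within each chromosome."""
    n_blocks = max(1, -(-n_snps // ld_block_size))
    n_chrom = min(22, n_blocks)
    block_chrom = np.repeat(
        np.arange(n_chrom), -(-n_blocks // n_chrom)
    )[:n_blocks]
    chrom = np.empty(n_snps, dtype=object)
    pos = np.empty(n_snps, dtype=int)
    counter = np.zeros(n_chrom, dtype=int)
    for j in range(n_snps):
        c = block_chrom[j // ld_block_size]
        counter[c] += 1
        chrom[j] = str(c + 1)
        pos[j] = 1000 * counter[c]
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n_snps)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_snps)) % 4
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"snp_{j + 1:06d}" for j in range(n_snps)],
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "multiallelic": False,
        }
    )


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw an LD-structured dosage matrix; reproducible under the seed."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    dosages = np.zeros((n, m))
    for start in range(0, m, config.ld_block_size):
        stop = min(start + config.ld_block_size, m)
        width = stop - start
        block_maf = mafs[start:stop]
        rho = _latent_correlation(
            config.within_block_r, round(float(block_maf.mean()), 3)
        )
        z_thresh = stats.norm.ppf(block_maf)
        for _hap in range(2):
            shared = rng.standard_normal(n)[:, None]
            noise = rng.standard_normal((n, width))
            latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
            dosages[:, start:stop] += latent < z_thresh
    if config.missing_rate > 0.0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages[mask] = np.nan
    variants = _variant_table(m, config.ld_block_size, rng)
    samples = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


def _category_counts(proportions: np.ndarray, n: int) -> np.ndarray:
    """Exact integer partition of ``n`` by cumulative rounding; proportions
    that are exact k/n fractions yield exactly k."""
    bounds = np.round(np.cumsum(proportions) * n).astype(int)
    bounds[-1] = n
    return np.diff(np.concatenate([[0], bounds]))


def simulate_phenotype(
    genotypes: GenotypeMatrix, config: SimulationConfig
) -> SimulatedCohort:
    """Assign liability, categories and covariates to a genotype matrix."""
    if np.isnan(genotypes.dosages).any():
        raise ValueError("phenotype simulation requires complete genotypes")
    rng = np.random.default_rng(config.seed + 1)  # independent of genotype draw
    n, m = genotypes.n_samples, genotypes.n_snps

    causal_idx = np.sort(rng.choice(m, size=config.n_causal, replace=False))
    if config.causal_effect_dist == "equal":
        effects = config.causal_effect_sd * rng.choice(
            [-1.0, 1.0], size=config.n_causal
        )
    else:
        effects = rng.normal(0.0, config.causal_effect_sd, size=config.n_causal)
    is_causal = np.zeros(m, dtype=bool)
    is_causal[causal_idx] = True
    effect_col = np.zeros(m)
    effect_col[causal_idx] = effects

    h2 = config.heritability
    noise = rng.standard_normal(n)
    score = np.zeros(n)
    if config.n_causal > 0 and h2 > 0.0:
        d = genotypes.dosages[:, causal_idx]
        sd = d.std(axis=0)
        poly = sd > 0  # monomorphic causal SNPs contribute nothing
        z = (d[:, poly] - d[:, poly].mean(axis=0)) / sd[poly]
        score = z @ effects[poly]
        s_sd = score.std()
        if s_sd > 0:
            score *= np.sqrt(h2) / s_sd
        else:
            h2 = 0.0
    else:
        h2 = 0.0
    liability = score + np.sqrt(1.0 - h2) * noise
    age = rng.integers(
        int(config.age_range[0]), int(config.age_range[1]) + 1, size=n
    ).astype(float)
    if config.age_liability_coef != 0.0:
        age_z = (age - age.mean()) / (age.std() or 1.0)
        liability = liability + config.age_liability_coef * age_z

    counts = _category_counts(
        np.asarray(config.category_proportions, dtype=float), n
    )
    order = np.argsort(liability, kind="stable")
    category = np.empty(n, dtype=object)
    start = 0
    for cat, k in zip(CATEGORIES, counts):
        category[order[start:start + k]] = cat
        start += k

    sex = rng.choice(["M", "F"], size=n)
    cohort_table = pd.DataFrame(
        {
            "sample_id": genotypes.samples,
            "category": category,
            "age": age,
            "sex": sex,
        }
    )
    truth = pd.DataFrame(
        {
            "snp_id": genotypes.variants["id"],
            "is_causal": is_causal,
            "effect": effect_col,
        }
    )
    return SimulatedCohort(
        genotypes=genotypes,
        truth=truth,
        cohort_table=cohort_table,
        liability=liability,
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Genotypes + phenotype in one call (genotypes drawn complete; the
    missingness mask, if any, is applied to the genotype matrix only)."""
    gm = simulate_genotypes(replace(config, missing_rate=0.0))
    cohort = simulate_phenotype(gm, config)
    if config.missing_rate > 0.0:
        rng = np.random.default_rng(config.seed + 2)
        dosages = gm.dosages.copy()
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
        cohort.genotypes = GenotypeMatrix(
            dosages, gm.variants.copy(), list(gm.samples)
        )
    return cohort


def write_cohort(cohort: SimulatedCohort, out_prefix: str | os.PathLike) -> dict:
    """Write VCF + phenotype TSV + truth TSV; returns the path map."""
    prefix = str(out_prefix)
    os.makedirs(os.path.dirname(prefix) or ".", exist_ok=True)
    paths = {
        "vcf": prefix + ".vcf",
        "pheno": prefix + ".pheno.tsv",
        "truth": prefix + ".truth.tsv",
    }
    write_vcf(cohort.genotypes, paths["vcf"])
    tbl = cohort.cohort_table.copy()
    tbl["age"] = tbl["age"].map(lambda a: format(a, "g"))
    tbl.to_csv(paths["pheno"], sep="\t", index=False)
    truth = cohort.truth.copy()
    truth["is_causal"] = truth["is_causal"].astype(int)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
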