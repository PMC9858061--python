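"""Variant-level quality control for bi-allelic SNP genotypes.

The filter cascade mirrors standard WGS pre-processing: drop multi-allelic
records, then sites with call rate < 95%, then sites failing the exact
Hardy-Weinberg equilibrium test at p < 1e-4, then sites with minor allele
frequency < 0.001. Thresholds are strict inequalities, so boundary values
survive. Each removed variant is attributed to the first filter it fails,
in that order, and the report totals reconcile exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

FILTER_ORDER = ["multiallelic", "callrate", "hwe", "maf"]


@dataclass
class QCThresholds:
    """Strict lower bounds: a variant is removed when its statistic falls
    strictly below the threshold."""

    min_call_rate: float = 0.95
    hwe_p_min: float = 1e-4
    maf_min: float = 0.001

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "hwe_p_min", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    n_input: int
    n_removed_multiallelic: int
    n_removed_callrate: int
    n_removed_hwe: int
    n_removed_maf: int
    n_pass: int
    table: pd.DataFrame = field(repr=False)
    """Per-variant audit: snp_id, chrom, pos, status, fail_reason,
    call_rate, maf, hwe_p (NaN where a stat was never evaluated)."""

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_multiallelic
            + self.n_removed_callrate
            + self.n_removed_hwe
            + self.n_removed_maf
        )
        if self.n_input != self.n_pass + removed:
            raise ValueError("QC report counts do not reconcile")


def call_rate(snp_column: np.ndarray) -> float:
    """Fraction of non-missing genotypes at a site."""
    col = np.asarray(snp_column, dtype=float)
    if col.size == 0:
        raise ValueError("call rate undefined for an empty column")
    return float(np.mean(~np.isnan(col)))


def maf(snp_column: np.ndarray) -> float:
    """Minor allele frequency over observed alleles (2 per called genotype)."""
    col = np.asarray(snp_column, dtype=float)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    p_alt = obs.sum() / (2.0 * obs.size)
    return float(min(p_alt, 1.0 - p_alt))


def genotype_counts(snp_column: np.ndarray) -> tuple[int, int, int]:
    """Counts of (hom-ref, het, hom-alt) among observed genotypes."""
    col = np.asarray(snp_column, dtype=float)
    obs = col[~np.isnan(col)]
    return (
        int(np.sum(obs == 0)),
        int(np.sum(obs == 1)),
        int(np.sum(obs == 2)),
    )


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int, midp: bool = False) -> float:
    """Two-sided exact Hardy-Weinberg equilibrium test.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed count. Probabilities are built by the standard two-term
    recurrence from the modal heterozygote count and normalised, which stays
    finite for sample sizes well beyond 1e5.

    With ``midp=True`` only half the observed configuration's probability is
    counted (mid-p variant).
    """
    for name, v in (("n_AA", n_AA), ("n_Aa", n_Aa), ("n_aa", n_aa)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name}={v} must be a nonnegative integer")
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")

    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # minor allele count
    if n_rare == 0:
        return 1.0  # single attainable configuration

    # attainable het counts share the parity of the rare allele count
    het_min = n_rare % 2
    het_max = n_rare if n_rare <= n else 2 * n - n_rare
    hets = np.arange(het_min, het_max + 1, 2)

    # unnormalised probs via P(h+2)/P(h) = 4*nAA(h)*naa(h) / ((h+2)(h+1))
    # starting at the modal het count to avoid under/overflow before
    # normalisation
    probs = np.empty(hets.size)
    mode_idx = int(np.searchsorted(hets, n_rare * (2.0 * n - n_rare) / (2.0 * n)))
    mode_idx = min(mode_idx, hets.size - 1)
    probs[mode_idx] = 1.0
    if mode_idx < hets.size - 1:  # upward: P(h+2)/P(h) = 4ab/((h+2)(h+1))
        h = hets[mode_idx:-1].astype(float)
        a = (n_rare - h) // 2  # rare homozygotes at h
        b = n - h - a  # common homozygotes at h
        probs[mode_idx + 1:] = np.cumprod(4.0 * a * b / ((h + 2.0) * (h + 1.0)))
    if mode_idx > 0:  # downward: P(h-2)/P(h) = h(h-1)/(4(a+1)(b+1))
        h = hets[mode_idx:0:-1].astype(float)
        a = (n_rare - h) // 2
        b = n - h - a
        probs[mode_idx - 1::-1] = np.cumprod(
            h * (h - 1.0) / (4.0 * (a + 1.0) * (b + 1.0))
        )
    probs /= probs.sum()

    p_obs = probs[np.searchsorted(hets, n_Aa)]
    tail = probs <= p_obs * (1.0 + 1e-10)  # tolerate float ties
    p = float(probs[tail].sum())
    if midp:
        p -= 0.5 * float(p_obs)
    return min(p, 1.0)


def apply_qc(
    gm: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    hwe_sample_mask: np.ndarray | None = None,
    midp: bool = False,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the four-filter cascade, attributing first-failing reasons.

    ``hwe_sample_mask`` optionally restricts the HWE test to a subset of
    samples (e.g. controls only); all other statistics use every sample.
    """
    thr = thresholds or QCThresholds()
    n_in = gm.n_snps
    status = np.full(n_in, "pass", dtype=object)
    reason = np.full(n_in, "", dtype=object)
    cr = np.full(n_in, np.nan)
    mafs = np.full(n_in, np.nan)
    hwe_p = np.full(n_in, np.nan)

    hwe_rows = (
        np.asarray(hwe_sample_mask, dtype=bool)
        if hwe_sample_mask is not None
        else slice(None)
    )
    multi = gm.variants["multiallelic"].to_numpy(dtype=bool)
    D = gm.dosages
    observed = ~np.isnan(D)
    n_obs = observed.sum(axis=0)

    # stage 1: multi-allelic
    status[multi], reason[multi] = "removed", "multiallelic"
    alive = ~multi

    # stage 2: call rate (strict <); a fully missing column also stops here
    if D.shape[0] == 0:
        raise ValueError("call rate undefined without samples")
    cr[alive] = n_obs[alive] / D.shape[0]
    fail = alive & ((cr < thr.min_call_rate) | (n_obs == 0))
    status[fail], reason[fail] = "removed", "callrate"
    alive &= ~fail

    # stage 3: exact HWE (strict <), on the configured sample subset
    D_hwe = D[hwe_rows]
    n0 = (D_hwe == 0).sum(axis=0)
    n1 = (D_hwe == 1).sum(axis=0)
    n2 = (D_hwe == 2).sum(axis=0)
    for j in np.flatnonzero(alive):
        if n0[j] + n1[j] + n2[j] == 0:  # untestable in the HWE subset
            hwe_p[j] = 1.0
        else:
            hwe_p[j] = hwe_exact_p(int(n0[j]), int(n1[j]), int(n2[j]), midp=midp)
    fail = alive & (hwe_p < thr.hwe_p_min)
    status[fail], reason[fail] = "removed", "hwe"
    alive &= ~fail

    # stage 4: MAF (strict <)
    with np.errstate(invalid="ignore"):
        p_alt = np.nansum(D, axis=0) / (2.0 * np.maximum(n_obs, 1))
    mafs[alive] = np.minimum(p_alt, 1.0 - p_alt)[alive]
    fail = alive & (mafs < thr.maf_min)
    status[fail], reason[fail] = "removed", "maf"

    table = pd.DataFrame(
        {
            "snp_id": gm.variants["id"],
            "chrom": gm.variants["chrom"],
            "pos": gm.variants["pos"],
            "status": status,
            "fail_reason": reason,
            "call_rate": cr,
            "maf": mafs,
            "hwe_p": hwe_p,
        }
    )
    keep = np.flatnonzero(status == "pass")
    report = QCReport(
        n_input=n_in,
        n_removed_multiallelic=int(np.sum(reason == "multiallelic")),
        n_removed_callrate=int(np.sum(reason == "callrate")),
        n_removed_hwe=int(np.sum(reason == "hwe")),
        n_removed_maf=int(np.sum(reason == "maf")),
        n_pass=keep.size,
        table=table,
    )
    return gm.take_variants(keep), report


def impute_missing_mean(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the SNP's mean observed dosage."""
    dosages = gm.dosages.copy()
    miss = np.isnan(dosages)
    if not miss.any():
        return GenotypeMatrix(dosages, gm.variants.copy(), list(gm.samples))
    all_missing = miss.all(axis=0)
    if all_missing.any():
        raise ValueError(
            f"cannot impute all-missing SNP column(s) "
            f"{np.flatnonzero(all_missing).tolist()}"
        )
    col_means = np.nanmean(dosages, axis=0)
    dosages[miss] = np.broadcast_to(col_means, dosages.shape)[miss]
    return GenotypeMatrix(dosages, gm.variants.copy(), list(gm.samples))
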