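"""Conventional single-SNP association scan and multi- vs single-SNP
comparison.

Each SNP is tested one at a time by ordinary least squares of the binarised
response on (intercept, age, sex, dosage), with a two-sided t test on the
dosage coefficient at n - 4 degrees of freedom. The scan is vectorised over
SNPs by residualising the response and every dosage column on the covariates
(Frisch-Waugh-Lovell), which reproduces the per-SNP OLS coefficient, its
standard error and p-value exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix
from .model import AssociationResult, _P_FLOOR
from .phenotype import BinaryPhenotype


@dataclass
class SingleSnpResult:
    table: pd.DataFrame  # snp_id, chrom, pos, ref, alt, beta, se, t, p, degenerate
    m_tests: int
    alpha: float
    threshold: float


def single_snp_scan(
    gm: GenotypeMatrix, pheno: BinaryPhenotype, alpha: float = 0.05
) -> SingleSnpResult:
    """Covariate-adjusted OLS scan over all SNPs.

    SNPs collinear with the covariates (e.g. monomorphic) are flagged
    degenerate and reported with beta = 0, p = 1.
    """
    Z = gm.dosages
    if np.isnan(Z).any():
        raise ValueError("scan requires complete genotypes (impute first)")
    y = pheno.y
    n = y.size
    if Z.shape[0] != n:
        raise ValueError("genotype and phenotype sample counts differ")
    X = pheno.design_matrix()
    k = X.shape[1] + 1  # + dosage column
    if n <= k:
        raise ValueError(f"need more than {k} samples, got {n}")
    if np.allclose(y, y[0]):
        raise ValueError("constant response")

    # residualise on covariates: Q from thin QR of X
    Q, _ = np.linalg.qr(X)
    y_res = y - Q @ (Q.T @ y)
    Z_res = Z - Q @ (Q.T @ Z)

    zz = np.einsum("ij,ij->j", Z_res, Z_res)
    degenerate = zz <= 1e-10 * n
    zz_safe = np.where(degenerate, 1.0, zz)
    beta = (Z_res.T @ y_res) / zz_safe
    df = n - k
    ssr = np.maximum(y_res @ y_res - beta**2 * zz_safe, 0.0)
    sigma2 = ssr / df
    se = np.sqrt(np.maximum(sigma2 / zz_safe, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), df), _P_FLOOR)
    beta = np.where(degenerate, 0.0, beta)
    se = np.where(degenerate, np.nan, se)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)

    m = Z.shape[1]
    threshold = alpha / m if m else np.nan
    table = pd.DataFrame(
        {
            "snp_id": gm.variants["id"].to_numpy(),
            "chrom": gm.variants["chrom"].to_numpy(),
            "pos": gm.variants["pos"].to_numpy(),
            "ref": gm.variants["ref"].to_numpy(),
            "alt": gm.variants["alt"].to_numpy(),
            "beta": beta,
            "se": se,
            "t": t,
            "p": p,
            "significant": p < threshold,
            "degenerate": degenerate,
        }
    )
    return SingleSnpResult(table=table, m_tests=m, alpha=alpha,
                           threshold=threshold)


def compare_models(
    multi: AssociationResult, single: SingleSnpResult
) -> tuple[pd.DataFrame, dict]:
    """Pair the two scans SNP-by-SNP.

    Returns the per-SNP table (p_multi, p_single, -log10 transforms, rank
    difference) and summary counts of SNPs significant under exactly one
    approach. Ranks are ascending in p (1 = most significant), ties averaged.
    """
    mt = multi.table.set_index("snp_id")
    st = single.table.set_index("snp_id")
    sym_diff = set(mt.index).symmetric_difference(st.index)
    if sym_diff:
        raise ValueError(
            f"SNP universes differ; symmetric difference: {sorted(sym_diff)[:10]}"
            f"{'...' if len(sym_diff) > 10 else ''}"
        )
    st = st.reindex(mt.index)
    table = pd.DataFrame(
        {
            "snp_id": mt.index,
            "chrom": mt["chrom"].to_numpy(),
            "pos": mt["pos"].to_numpy(),
            "p_multi": mt["p"].to_numpy(),
            "p_single": st["p"].to_numpy(),
        }
    )
    table["neg_log10_p_multi"] = -np.log10(table["p_multi"])
    table["neg_log10_p_single"] = -np.log10(table["p_single"])
    table["rank_multi"] = table["p_multi"].rank(method="average")
    table["rank_single"] = table["p_single"].rank(method="average")
    table["rank_diff"] = table["rank_multi"] - table["rank_single"]
    sig_m = mt["significant"].to_numpy(dtype=bool)
    sig_s = st["significant"].to_numpy(dtype=bool)
    summary = {
        "n_snps": int(len(table)),
        "n_significant_multi": int(sig_m.sum()),
        "n_significant_single": int(sig_s.sum()),
        "n_multi_only": int((sig_m & ~sig_s).sum()),
        "n_single_only": int((sig_s & ~sig_m).sum()),
        "n_both": int((sig_m & sig_s).sum()),
    }
    return table.reset_index(drop=True), summary
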