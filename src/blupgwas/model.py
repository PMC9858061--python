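"""All-SNP mixed linear model (SNP-BLUP / generalized ridge) with Wald tests.

The model is

    y = X beta + Z g + e,    g ~ N(0, I sigma_g^2),   e ~ N(0, I sigma_e^2)

with y the binarised disease status, X the fixed-effects design (intercept,
age, sex), and Z the raw 0/1/2 SNP dosage design. Both variance components
are treated as *known*: sigma_g^2 = 0.3 sigma_y^2 and
sigma_e^2 = 0.7 sigma_y^2, where sigma_y^2 is the sample variance of y
("literal" mode; a conventional per-SNP rescaling by 2*sum p_j(1-p_j) is
available as "scaled" mode). Estimates solve Henderson's mixed-model
equations

    [X'X   X'Z       ] [beta]   [X'y]
    [Z'X   Z'Z + lam*I] [g   ] = [Z'y],     lam = sigma_e^2 / sigma_g^2,

either by dense Cholesky factorization or matrix-free Jacobi-preconditioned
conjugate gradients. Each SNP effect is tested with W_i = g_hat_i / sigma_g
against the standard normal, with Bonferroni family-wise control. Note the
Wald denominator is the *prior* SD of SNP effects, not a standard error of
the estimate; under ridge shrinkage this is conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats
from scipy.sparse.linalg import LinearOperator, cg

#: SNP count above which the auto solver switches from direct to PCG
DIRECT_SOLVER_MAX_SNPS = 5000

_P_FLOOR = np.finfo(float).tiny  # p-values are never reported as exactly 0


class DegeneratePhenotypeError(ValueError):
    pass


class CollinearityError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, rel_residual: float):
        super().__init__(message)
        self.rel_residual = rel_residual


@dataclass(frozen=True)
class MixedModelSpec:
    """Fixed variance components of the model."""

    sigma_y2: float
    sigma_g2: float
    sigma_e2: float
    genetic_share: float = 0.3
    residual_share: float = 0.7
    variance_mode: str = "literal"

    def __post_init__(self) -> None:
        if abs(self.genetic_share + self.residual_share - 1.0) > 1e-12:
            raise ValueError("variance shares must sum to 1")
        if min(self.sigma_y2, self.sigma_g2, self.sigma_e2) <= 0:
            raise ValueError("all variances must be positive")

    @property
    def lam(self) -> float:
        """Ridge parameter sigma_e^2 / sigma_g^2 (7/3 in literal mode)."""
        return self.sigma_e2 / self.sigma_g2

    @property
    def sigma_g(self) -> float:
        return float(np.sqrt(self.sigma_g2))


def estimate_variances(
    y: np.ndarray,
    genetic_share: float = 0.3,
    residual_share: float = 0.7,
    variance_mode: str = "literal",
    allele_freqs: np.ndarray | None = None,
) -> MixedModelSpec:
    """Derive the fixed variance components from the phenotypic variance.

    literal mode: sigma_g^2 = share_g * var(y) exactly as the model states.
    scaled mode: the genetic share is spread over SNPs by dividing by
    2 * sum_j p_j (1 - p_j) (the variance sum of the dosage columns under
    Hardy-Weinberg), which is how genomic-prediction software conventionally
    turns a total genetic variance into a per-SNP prior.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3 or np.allclose(y, y[0]):
        raise DegeneratePhenotypeError("y must be non-constant with n >= 3")
    sigma_y2 = float(np.var(y, ddof=1))
    sigma_g2 = genetic_share * sigma_y2
    sigma_e2 = residual_share * sigma_y2
    if variance_mode == "scaled":
        if allele_freqs is None:
            raise ValueError("scaled mode requires allele frequencies")
        p = np.asarray(allele_freqs, dtype=float)
        denom = 2.0 * np.sum(p * (1.0 - p))
        if denom <= 0:
            raise ValueError("allele frequencies give zero scaling mass")
        sigma_g2 /= denom
    elif variance_mode != "literal":
        raise ValueError(f"unknown variance_mode {variance_mode!r}")
    return MixedModelSpec(
        sigma_y2=sigma_y2,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        genetic_share=genetic_share,
        residual_share=residual_share,
        variance_mode=variance_mode,
    )


@dataclass
class MMESystem:
    """Henderson's equations held in factored (X, Z, y, lam) form; the dense
    coefficient matrix is assembled only for the direct solver."""

    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        n = self.y.size
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("X, Z, y row counts disagree")
        if self.lam <= 0:
            raise ValueError("lam must be positive")

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_snps(self) -> int:
        return self.Z.shape[1]

    def coefficient_matrix(self) -> np.ndarray:
        """Dense [[X'X, X'Z], [Z'X, Z'Z + lam I]]."""
        A = np.hstack([self.X, self.Z])
        C = A.T @ A
        q = self.n_snps
        C[self.n_fixed:, self.n_fixed:] += self.lam * np.eye(q)
        return C

    def rhs(self) -> np.ndarray:
        return np.concatenate([self.X.T @ self.y, self.Z.T @ self.y])

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """Apply the coefficient matrix without forming it."""
        p = self.n_fixed
        u = self.X @ v[:p] + self.Z @ v[p:]
        return np.concatenate(
            [self.X.T @ u, self.Z.T @ u + self.lam * v[p:]]
        )


def build_mme(
    X: np.ndarray, Z: np.ndarray, y: np.ndarray, spec: MixedModelSpec
) -> MMESystem:
    """Assemble the mixed-model equations; X must be full column rank."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if np.isnan(X).any() or np.isnan(np.asarray(Z, dtype=float)).any():
        raise ValueError("design matrices must be complete (no NaN)")
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name the first column linearly dependent on its predecessors
        offending = X.shape[1] - 1
        for k in range(1, X.shape[1] + 1):
            if np.linalg.matrix_rank(X[:, :k]) < k:
                offending = k - 1
                break
        raise CollinearityError(
            f"fixed-effects design is rank deficient (column {offending})"
        )
    return MMESystem(X=X, Z=Z, y=y, lam=spec.lam)


@dataclass
class ModelFit:
    beta_hat: np.ndarray
    g_hat: np.ndarray
    solver: str
    iterations: int
    rel_residual: float


def _split(system: MMESystem, sol: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = system.n_fixed
    return sol[:p], sol[p:]


def solve_mme(
    system: MMESystem,
    method: str = "auto",
    tol: float = 1e-8,
    max_iter: int | None = None,
) -> ModelFit:
    """Solve Henderson's equations.

    ``direct`` factorises the dense SPD coefficient matrix (Cholesky);
    ``pcg`` runs Jacobi-preconditioned conjugate gradients on the matrix-free
    operator from a zero start, to relative residual <= tol. ``auto`` picks
    direct for systems of up to ``DIRECT_SOLVER_MAX_SNPS`` SNPs.
    """
    if method == "auto":
        method = "direct" if system.n_snps <= DIRECT_SOLVER_MAX_SNPS else "pcg"
    b = system.rhs()
    b_norm = float(np.linalg.norm(b))
    size = system.n_fixed + system.n_snps
    if b_norm == 0.0:
        return ModelFit(
            *_split(system, np.zeros(size)), solver=method, iterations=0,
            rel_residual=0.0,
        )

    if method == "direct":
        C = system.coefficient_matrix()
        try:
            sol = sla.cho_solve(sla.cho_factor(C, lower=True), b)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError(f"singular mixed-model system: {exc}") from exc
        rel = float(np.linalg.norm(b - C @ sol) / b_norm)
        return ModelFit(*_split(system, sol), solver="direct", iterations=1,
                        rel_residual=rel)

    if method != "pcg":
        raise ValueError(f"unknown solver {method!r}")

    diag = np.concatenate(
        [
            np.einsum("ij,ij->j", system.X, system.X),
            np.einsum("ij,ij->j", system.Z, system.Z) + system.lam,
        ]
    )
    diag[diag <= 0] = 1.0
    op = LinearOperator((size, size), matvec=system.matvec, dtype=float)
    precond = LinearOperator(
        (size, size), matvec=lambda v: v / diag, dtype=float
    )
    if max_iter is None:
        max_iter = 10 * size
    n_iter = 0

    def _count(_xk: np.ndarray) -> None:
        nonlocal n_iter
        n_iter += 1

    sol, info = cg(
        op, b, x0=np.zeros(size), rtol=tol, atol=0.0, maxiter=max_iter,
        M=precond, callback=_count,
    )
    rel = float(np.linalg.norm(b - system.matvec(sol)) / b_norm)
    if info != 0 and rel > tol:
        raise ConvergenceError(
            f"PCG did not reach tol={tol} in {max_iter} iterations "
            f"(relative residual {rel:.3e})",
            rel_residual=rel,
        )
    return ModelFit(*_split(system, sol), solver="pcg", iterations=n_iter,
                    rel_residual=rel)


@dataclass
class AssociationResult:
    """Per-SNP Wald tests with the Bonferroni family-wise threshold."""

    table: pd.DataFrame  # snp_id, chrom, pos, ref, alt, g_hat, W, p, significant
    m_tests: int
    alpha: float
    threshold: float


def wald_test(
    fit: ModelFit,
    spec: MixedModelSpec,
    variants: pd.DataFrame,
    alpha: float = 0.05,
) -> AssociationResult:
    """W_i = g_hat_i / sigma_g, referred to the standard normal, two-sided;
    significance flags use the Bonferroni threshold alpha / m."""
    if spec.sigma_g2 <= 0:
        raise ValueError("sigma_g2 must be positive")
    g_hat = np.asarray(fit.g_hat, dtype=float)
    if len(variants) != g_hat.size:
        raise ValueError("variant table and g_hat length mismatch")
    W = g_hat / spec.sigma_g
    p = np.maximum(2.0 * stats.norm.sf(np.abs(W)), _P_FLOOR)
    m = g_hat.size
    if m == 0:
        raise ValueError("no SNPs to test")
    threshold = alpha / m
    table = pd.DataFrame(
        {
            "snp_id": variants["id"].to_numpy(),
            "chrom": variants["chrom"].to_numpy(),
            "pos": variants["pos"].to_numpy(),
            "ref": variants["ref"].to_numpy(),
            "alt": variants["alt"].to_numpy(),
            "g_hat": g_hat,
            "W": W,
            "p": p,
            "significant": p < threshold,
        }
    )
    return AssociationResult(table=table, m_tests=m, alpha=alpha,
                             threshold=threshold)


def bonferroni(result: AssociationResult, alpha: float = 0.05) -> AssociationResult:
    """Re-flag significance at family-wise level alpha over m_tests."""
    if result.m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    threshold = alpha / result.m_tests
    table = result.table.copy()
    table["significant"] = table["p"] < threshold
    return AssociationResult(
        table=table, m_tests=result.m_tests, alpha=alpha, threshold=threshold
    )


def rank_hits(result: AssociationResult) -> pd.DataFrame:
    """Rows sorted by ascending p, ties broken by (chrom, pos); stable."""
    if result.table.empty:
        raise ValueError("empty association result")
    return (
        result.table.sort_values(
            ["p", "chrom", "pos"], kind="mergesort"
        ).reset_index(drop=True)
    )
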