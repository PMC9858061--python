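"""Binarisation of the five disease categories into the two analysed
contrasts.

For the *resistant* contrast the resistant group is coded 1; for the *severe*
contrast the severe group is coded 1. In both cases the control group is
dropped entirely and every remaining category is coded 0. Covariates are age
in years and sex coded M=0 / F=1 (the reference level only flips the sign of
the sex effect).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import CATEGORIES

CONTRASTS = ("severe", "resistant")
SEX_CODES = {"M": 0.0, "F": 1.0}


class DegeneratePhenotypeError(ValueError):
    """The binarised response is constant and cannot be analysed."""


@dataclass
class BinaryPhenotype:
    y: np.ndarray
    kept_samples: list[str]
    covariates: pd.DataFrame  # columns: age, sex_code
    contrast: str

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("y must be 0/1")
        if len(self.kept_samples) != self.y.size or len(self.covariates) != self.y.size:
            raise ValueError("phenotype components have mismatched lengths")

    @property
    def n(self) -> int:
        return self.y.size

    def design_matrix(self) -> np.ndarray:
        """Fixed-effects design X = [intercept, age, sex_code]."""
        return np.column_stack(
            [
                np.ones(self.n),
                self.covariates["age"].to_numpy(float),
                self.covariates["sex_code"].to_numpy(float),
            ]
        )


def read_cohort_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a phenotype TSV (sample_id, category, age, sex) with validation."""
    tbl = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = {"sample_id", "category", "age", "sex"} - set(tbl.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    return tbl


def encode(
    cohort: pd.DataFrame,
    contrast: str,
    impute_covariates: bool = False,
) -> BinaryPhenotype:
    """Binarise a cohort table for one contrast, dropping controls.

    Parameters
    ----------
    cohort
        Table with columns sample_id, category, age, sex; sample ids unique,
        categories from {control, resistant, benign, mild, severe}.
    contrast
        ``"severe"`` or ``"resistant"``: which category is coded 1.
    impute_covariates
        If True, missing age/sex are mean/mode-imputed instead of raising.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {CONTRASTS}, got {contrast!r}")
    if cohort.empty:
        raise ValueError("empty cohort")
    if cohort["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in cohort table")
    bad = set(cohort["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown category literal(s): {sorted(bad)}")

    kept = cohort.loc[cohort["category"] != "control"].copy()
    age = pd.to_numeric(kept["age"], errors="coerce")
    sex_code = kept["sex"].map(SEX_CODES)
    if age.isna().any() or sex_code.isna().any():
        if not impute_covariates:
            n_bad = int((age.isna() | sex_code.isna()).sum())
            raise ValueError(
                f"{n_bad} samples have missing/invalid age or sex "
                "(pass impute_covariates=True to mean-impute)"
            )
        age = age.fillna(age.mean())
        sex_code = sex_code.fillna(
            sex_code.mode().iloc[0] if not sex_code.mode().empty else 0.0
        )

    y = (kept["category"] == contrast).to_numpy(dtype=float)
    if y.size == 0 or y.min() == y.max():
        raise DegeneratePhenotypeError(
            f"contrast {contrast!r} yields a constant response"
        )
    covariates = pd.DataFrame(
        {"age": age.to_numpy(float), "sex_code": sex_code.to_numpy(float)}
    )
    return BinaryPhenotype(
        y=y,
        kept_samples=kept["sample_id"].tolist(),
        covariates=covariates,
        contrast=contrast,
    )


def write_encoded(pheno: BinaryPhenotype, path: str | os.PathLike) -> None:
    out = pd.DataFrame(
        {
            "sample_id": pheno.kept_samples,
            "y": pheno.y.astype(int),
            "age": pheno.covariates["age"].map(lambda a: format(a, "g")),
            "sex_code": pheno.covariates["sex_code"].astype(int),
        }
    )
    out.to_csv(path, sep="\t", index=False)
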