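"""Genotype matrix container and VCF input/output.

Genotypes are stored as a dense samples x SNPs dosage matrix with entries
0/1/2 (count of alternate alleles) and ``NaN`` for missing calls, alongside
a per-variant metadata table (chromosome, 1-based position, id, ref, alt).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "multiallelic"]


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


class EmptyCohortError(ValueError):
    """Raised when a VCF contains no sample columns."""


@dataclass
class GenotypeMatrix:
    """Dense samples x SNPs alt-allele dosage matrix with variant metadata.

    Parameters
    ----------
    dosages
        Array of shape ``(n_samples, n_snps)``; entries in {0, 1, 2} or NaN
        for missing genotypes (mean imputation may later introduce fractional
        dosages).
    variants
        DataFrame with columns chrom, pos (1-based), id, ref, alt and a
        boolean ``multiallelic`` flag; one row per matrix column.
    samples
        Ordered sample identifiers, one per matrix row.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D samples x SNPs array")
        if len(self.variants) != self.dosages.shape[1]:
            raise ValueError(
                f"variant table has {len(self.variants)} rows but dosage "
                f"matrix has {self.dosages.shape[1]} columns"
            )
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError(
                f"{len(self.samples)} sample ids for "
                f"{self.dosages.shape[0]} matrix rows"
            )
        if "multiallelic" not in self.variants.columns:
            self.variants = self.variants.assign(multiallelic=False)
        key = self.variants[["chrom", "pos", "ref", "alt"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos, ref, alt) variant keys")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.dosages[:, j]

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given variant (column) indices, order preserved."""
        idx = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            samples=list(self.samples),
        )

    def alt_allele_frequencies(self) -> np.ndarray:
        """Per-SNP alt-allele frequency over observed alleles (2 per call)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a VCF (v4.2, plain or bgzipped) into a :class:`GenotypeMatrix`.

    Multi-allelic records are carried with ``multiallelic=True`` (removal is
    the QC stage's job, they are never split). ``./.`` and half-calls such as
    ``0/.`` are treated as missing. Dosage is the count of alt alleles.
    """
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        vcf.close()
        raise EmptyCohortError(f"VCF {path} has no sample columns")

    rows = []
    cols = []
    for record in vcf:
        alts = record.ALT
        multi = len(alts) > 1
        alt = ",".join(alts) if alts else "."
        rows.append(
            (record.CHROM, record.POS, record.ID or ".", record.REF, alt, multi)
        )
        gts = np.asarray(record.genotypes, dtype=int)[:, :2]
        missing = (gts < 0).any(axis=1)
        dose = (gts == 1).sum(axis=1).astype(float)
        dose[missing] = np.nan
        cols.append(dose)
    vcf.close()

    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


_GT_STRINGS = np.array(["0/0", "0/1", "1/1", "./."])


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a bi-allelic GT-only VCF v4.2; round-trips through read_vcf.

    Fractional (imputed) dosages are rounded to the nearest genotype.
    """
    variants = gm.variants
    chroms = list(dict.fromkeys(variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=blupgwas\n')
        for chrom in chroms:
            max_pos = int(variants.loc[variants["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        codes = gm.dosages.T.copy()  # variants x samples
        miss = np.isnan(codes)
        codes[miss] = 3
        gt_rows = _GT_STRINGS[np.rint(codes).astype(int)]
        for j, var in enumerate(variants.itertuples(index=False)):
            fh.write(
                f"{var.chrom}\t{var.pos}\t{var.id}\t{var.ref}\t{var.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gt_rows[j]) + "\n"
            )
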