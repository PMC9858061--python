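"""End-to-end orchestration: simulate -> qc -> encode -> associate ->
compare -> summarize, with a reproducible run directory and manifest.

Every stage is usable on its own; :func:`run_pipeline` composes them.
Association tables are written as TSV with ``##`` comment lines echoing the
full run configuration, so a result file is self-describing. Outputs are
deterministic given (config, inputs): the manifest records input checksums
and per-stage row counts but no timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baseline import SingleSnpResult, compare_models, single_snp_scan
from .genotypes import GenotypeMatrix, read_vcf, write_vcf
from .model import (
    AssociationResult,
    build_mme,
    estimate_variances,
    solve_mme,
    wald_test,
)
from .phenotype import BinaryPhenotype, encode, read_cohort_table, write_encoded
from .qc import QCThresholds, apply_qc, impute_missing_mean
from .report import (
    consequence_summary,
    gene_hit_list,
    manhattan_export,
    read_annotation,
)
from .simulate import (
    DEFAULT_PROPORTIONS,
    SimulationConfig,
    simulate_cohort,
    write_cohort,
)

log = logging.getLogger("blupgwas")


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    vcf: str = ""
    pheno: str = ""
    annotation: str = ""
    out_dir: str = "blupgwas_run"
    contrast: str = "severe"
    variance_mode: str = "literal"
    alpha: float = 0.05
    solver: str = "auto"
    tol: float = 1.0e-8
    run_single: bool = True
    min_call_rate: float = 0.95
    hwe_p_min: float = 1.0e-4
    maf_min: float = 0.001
    seed: int = 0
    simulate: bool = False
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(
            min_call_rate=self.min_call_rate,
            hwe_p_min=self.hwe_p_min,
            maf_min=self.maf_min,
        )

    def sim_config(self) -> SimulationConfig:
        kw = dict(self.sim)
        for key in ("maf_range", "age_range", "category_proportions"):
            if key in kw:
                kw[key] = tuple(kw[key])
        kw.setdefault("seed", self.seed)
        return SimulationConfig(**kw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def header_lines(self) -> list[str]:
        d = dataclasses.asdict(self)
        lines = [f"##blupgwas_version={__version__}"]
        for key in sorted(d):
            lines.append(f"##{key}={json.dumps(d[key], sort_keys=True)}")
        return lines


def write_association_tsv(
    table: pd.DataFrame, path: str | os.PathLike, config: RunConfig | None = None,
    extra_header: dict | None = None,
) -> None:
    """TSV with '##' config-echo comment lines, rows ordered (chrom, pos)."""
    tab = table.sort_values(["chrom", "pos"], kind="mergesort")
    with open(path, "w") as fh:
        if config is not None:
            fh.write("\n".join(config.header_lines()) + "\n")
        for k, v in (extra_header or {}).items():
            fh.write(f"##{k}={json.dumps(v)}\n")
        tab.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_association_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def associate_multi(
    gm: GenotypeMatrix,
    pheno: BinaryPhenotype,
    variance_mode: str = "literal",
    alpha: float = 0.05,
    solver: str = "auto",
    tol: float = 1e-8,
) -> AssociationResult:
    """QC'd genotypes + encoded phenotype -> multi-SNP association table."""
    gm = impute_missing_mean(gm)
    spec = estimate_variances(
        pheno.y,
        variance_mode=variance_mode,
        allele_freqs=gm.alt_allele_frequencies(),
    )
    system = build_mme(pheno.design_matrix(), gm.dosages, pheno.y, spec)
    fit = solve_mme(system, method=solver, tol=tol)
    return wald_test(fit, spec, gm.variants, alpha=alpha)


def _align_to_phenotype(gm: GenotypeMatrix, pheno: BinaryPhenotype) -> GenotypeMatrix:
    idx = [gm.samples.index(s) for s in pheno.kept_samples]
    return GenotypeMatrix(
        dosages=gm.dosages[idx, :],
        variants=gm.variants.copy(),
        samples=list(pheno.kept_samples),
    )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline into ``config.out_dir``; returns the manifest.

    Stages: (simulate) -> qc -> encode -> assoc multi (and single) ->
    compare -> summarize. Any stage failure raises :class:`StageError`
    naming the stage.
    """
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
        "inputs": {},
    }

    vcf_path, pheno_path = config.vcf, config.pheno
    if config.simulate:
        try:
            cohort = simulate_cohort(config.sim_config())
            paths = write_cohort(cohort, os.path.join(out, "cohort"))
        except Exception as exc:
            raise StageError("simulate", exc) from exc
        vcf_path, pheno_path = paths["vcf"], paths["pheno"]
        manifest["stages"]["simulate"] = {
            "n_samples": cohort.genotypes.n_samples,
            "n_snps": cohort.genotypes.n_snps,
        }
        log.info("simulated cohort: %s", manifest["stages"]["simulate"])
    for name, path in (("vcf", vcf_path), ("pheno", pheno_path)):
        if not path or not os.path.exists(path):
            raise StageError(
                "validate", FileNotFoundError(f"{name} input not found: {path!r}")
            )
        manifest["inputs"][name] = {"path": path, "sha256": _sha256(path)}
    if config.annotation:
        if not os.path.exists(config.annotation):
            raise StageError(
                "validate",
                FileNotFoundError(f"annotation not found: {config.annotation!r}"),
            )
        manifest["inputs"]["annotation"] = {
            "path": config.annotation,
            "sha256": _sha256(config.annotation),
        }

    try:
        gm = read_vcf(vcf_path)
        gm_qc, qc_report = apply_qc(gm, config.qc_thresholds())
        qc_report.table.to_csv(
            os.path.join(out, "qc_report.tsv"), sep="\t", index=False,
            float_format="%.10g",
        )
        write_vcf(gm_qc, os.path.join(out, "filtered.vcf"))
    except Exception as exc:
        raise StageError("qc", exc) from exc
    manifest["stages"]["qc"] = {
        "n_input": qc_report.n_input,
        "n_pass": qc_report.n_pass,
        "n_removed_multiallelic": qc_report.n_removed_multiallelic,
        "n_removed_callrate": qc_report.n_removed_callrate,
        "n_removed_hwe": qc_report.n_removed_hwe,
        "n_removed_maf": qc_report.n_removed_maf,
    }
    log.info("qc: %s", manifest["stages"]["qc"])

    try:
        cohort_table = read_cohort_table(pheno_path)
        pheno = encode(cohort_table, config.contrast)
        write_encoded(pheno, os.path.join(out, "encoded_phenotype.tsv"))
    except Exception as exc:
        raise StageError("encode", exc) from exc
    manifest["stages"]["encode"] = {
        "n_cohort": int(len(cohort_table)),
        "n_kept": pheno.n,
        "n_cases": int(pheno.y.sum()),
        "contrast": config.contrast,
    }
    log.info("encode: %s", manifest["stages"]["encode"])

    try:
        gm_aligned = _align_to_phenotype(gm_qc, pheno)
        gm_complete = impute_missing_mean(gm_aligned)
        multi = associate_multi(
            gm_complete,
            pheno,
            variance_mode=config.variance_mode,
            alpha=config.alpha,
            solver=config.solver,
            tol=config.tol,
        )
        write_association_tsv(
            multi.table, os.path.join(out, "assoc_multi.tsv"), config,
            extra_header={
                "m_tests": multi.m_tests, "threshold": multi.threshold
            },
        )
    except Exception as exc:
        raise StageError("assoc_multi", exc) from exc
    manifest["stages"]["assoc_multi"] = {
        "m_tests": multi.m_tests,
        "n_significant": int(multi.table["significant"].sum()),
    }
    log.info("assoc_multi: %s", manifest["stages"]["assoc_multi"])

    if config.run_single:
        try:
            single = single_snp_scan(gm_complete, pheno, alpha=config.alpha)
            write_association_tsv(
                single.table, os.path.join(out, "assoc_single.tsv"), config,
                extra_header={
                    "m_tests": single.m_tests, "threshold": single.threshold
                },
            )
            comparison, summary = compare_models(multi, single)
            write_association_tsv(
                comparison, os.path.join(out, "comparison.tsv"), config,
                extra_header=summary,
            )
        except Exception as exc:
            raise StageError("assoc_single", exc) from exc
        manifest["stages"]["assoc_single"] = {
            "m_tests": single.m_tests,
            "n_significant": int(single.table["significant"].sum()),
        }
        manifest["stages"]["compare"] = summary
        log.info("compare: %s", summary)

    try:
        manhattan = manhattan_export(
            multi,
            read_annotation(config.annotation) if config.annotation else None,
        )
        manhattan.to_csv(
            os.path.join(out, "manhattan.tsv"), sep="\t", index=False,
            float_format="%.10g",
        )
        if config.annotation:
            ann = read_annotation(config.annotation)
            summ = consequence_summary(multi, ann)
            _write_consequence_summary(summ, os.path.join(out, "consequences"))
            genes = gene_hit_list(multi, ann)
            genes.to_csv(
                os.path.join(out, "gene_hits.tsv"), sep="\t", index=False,
                float_format="%.10g",
            )
            manifest["stages"]["summarize"] = {
                "n_significant": summ.n_significant,
                "n_genes": int(len(genes)),
            }
    except Exception as exc:
        raise StageError("summarize", exc) from exc

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _write_consequence_summary(summ, prefix: str) -> None:
    rows = []
    for cls, cnt in summ.class_counts.items():
        rows.append(
            ("class", cls, int(cnt), float(summ.class_percent.get(cls, np.nan)))
        )
    for sub, cnt in summ.subclass_counts.items():
        rows.append(
            ("coding_subclass", sub, int(cnt),
             float(summ.subclass_percent.get(sub, np.nan)))
        )
    tbl = pd.DataFrame(rows, columns=["level", "category", "count", "percent"])
    tbl.to_csv(prefix + ".tsv", sep="\t", index=False, float_format="%.2f")
    with open(prefix + ".txt", "w") as fh:
        fh.write(f"Significant SNPs: {summ.n_significant}\n")
        for _, r in tbl.iterrows():
            fh.write(
                f"  {r['level']:>16} {r['category']:<12} "
                f"{r['count']:>8} {r['percent']:6.2f}%\n"
            )
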