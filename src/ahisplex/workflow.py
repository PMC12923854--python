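"""Three-step pipeline: (optional external imputation) -> translate -> p-values -> classify.

The hosted phenotyping web service's role is played by the local p-value
model by default; a downloaded batch-result file can be classified instead
via the classification entry points.  An external imputation engine can be
hooked in as a command template run before translation; a template
containing a ``{region}`` placeholder is invoked once per imputation window
and the per-region outputs are combined.
"""

from __future__ import annotations

import json
import shlex
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .catalog import (
    load_catalog,
    load_chrom_lengths,
    default_catalog_path,
    default_chrom_lengths_path,
    build_chrom,
)
from .classify import classify_sample, load_rules, write_phenotype_tsv
from .model import compute_pvalues, load_model, write_pvalue_csv
from .translate import vcf_to_rows, write_upload_csv
from .windows import build_windows

__all__ = [
    "WorkflowConfig",
    "WorkflowError",
    "ExternalCommandError",
    "default_model_path",
    "default_rules_path",
    "run_pipeline",
]

_DATA = Path(__file__).parent / "data"


class WorkflowError(ValueError):
    """Configuration invalid; nothing was computed."""


class ExternalCommandError(RuntimeError):
    """The configured external imputation command failed."""


def default_model_path() -> Path:
    return _DATA / "demo_model.yaml"


def default_rules_path() -> Path:
    return _DATA / "rules_default.yaml"


@dataclass
class WorkflowConfig:
    build: str = "GRCh38"
    catalog_path: Path = None
    rules_path: Path = None
    model_path: Path = None
    chrom_lengths_path: Path = None
    external_impute_command: str = None   # template with {input} {output} [{region}]
    out_dir: Path = Path("ahisplex_out")
    seed: int = 0
    log_level: str = "INFO"

    @staticmethod
    def from_yaml(path) -> "WorkflowConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in WorkflowConfig.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise WorkflowError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = WorkflowConfig(**raw)
        for attr in ("catalog_path", "rules_path", "model_path",
                     "chrom_lengths_path", "out_dir"):
            value = getattr(cfg, attr)
            if value is not None:
                setattr(cfg, attr, Path(value))
        return cfg

    def resolved(self) -> "WorkflowConfig":
        cfg = WorkflowConfig(**{f: getattr(self, f) for f in self.__dataclass_fields__})
        if cfg.catalog_path is None:
            cfg.catalog_path = default_catalog_path(cfg.build)
        if cfg.chrom_lengths_path is None:
            cfg.chrom_lengths_path = default_chrom_lengths_path(cfg.build)
        if cfg.rules_path is None:
            cfg.rules_path = default_rules_path()
        if cfg.model_path is None:
            cfg.model_path = default_model_path()
        return cfg

    def validate(self) -> None:
        for attr in ("catalog_path", "rules_path", "model_path", "chrom_lengths_path"):
            path = getattr(self, attr)
            if path is None or not Path(path).exists():
                raise WorkflowError(f"{attr} does not exist: {path}")
        cmd = self.external_impute_command
        if cmd and cmd != "none":
            if "{input}" not in cmd or "{output}" not in cmd:
                raise WorkflowError(
                    "external_impute_command must contain {input} and {output} placeholders"
                )


def _run_external(template: str, input_vcf: Path, out_dir: Path, regions) -> list:
    """Invoke the external command (per region when templated); return output VCFs."""
    outputs = []
    per_region = "{region}" in template
    jobs = regions if per_region else [None]
    for idx, region in enumerate(jobs):
        out_path = out_dir / f"imputed_{idx:03d}.vcf"
        cmd = template.format(
            input=str(input_vcf), output=str(out_path),
            region=region or "",
        )
        proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
        if proc.returncode != 0:
            raise ExternalCommandError(
                f"external imputation command failed (exit {proc.returncode}): "
                f"{cmd}\nstderr: {proc.stderr.strip()}"
            )
        if not out_path.exists():
            raise ExternalCommandError(f"external command produced no output: {out_path}")
        outputs.append(out_path)
    return outputs


def _combine_rows(row_sets):
    """Merge per-region upload rows: later non-NA counts fill earlier NAs."""
    combined = {}
    order = []
    for rows in row_sets:
        for row in rows:
            if row.sample_id not in combined:
                combined[row.sample_id] = row
                order.append(row.sample_id)
            else:
                target = combined[row.sample_id]
                for col, value in row.counts.items():
                    if value is not None:
                        target.counts[col] = value
    return [combined[s] for s in order]


def run_pipeline(config: WorkflowConfig, vcf_path) -> dict:
    """Run translate -> p-values -> classify; returns the artifact paths.

    Outputs (upload CSV, p-value CSV, phenotype TSV, run log) are
    deterministic given identical inputs and seed; the run log carries
    versions and parameters but no timestamps, so reruns are byte-identical.
    """
    config = config.resolved()
    config.validate()
    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise WorkflowError(f"input VCF does not exist: {vcf_path}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = load_catalog(config.catalog_path, config.build)
    lengths = load_chrom_lengths(config.chrom_lengths_path, config.build)
    rules = load_rules(config.rules_path)
    model = load_model(config.model_path, catalog)

    cmd = config.external_impute_command
    if cmd and cmd != "none":
        ws = build_windows(catalog, lengths)
        regions = [
            f"{build_chrom(chrom, config.build)}:{start + 1}-{end}"
            for chrom, start, end in ws
        ]
        imputed = _run_external(cmd, vcf_path, out_dir, regions)
        row_sets = [vcf_to_rows(p, catalog, config.build) for p in imputed]
        rows = _combine_rows(row_sets)
    else:
        rows = vcf_to_rows(vcf_path, catalog, config.build)

    upload_path = out_dir / "HISplex41_upload.csv"
    write_upload_csv(rows, upload_path, catalog)

    results = [(row.sample_id, compute_pvalues(row, model)) for row in rows]
    pvalue_path = out_dir / "pvalues.csv"
    write_pvalue_csv(results, pvalue_path, model)

    calls = [classify_sample(sid, pv, rules) for sid, pv in results]
    pheno_path = out_dir / "phenotypes.tsv"
    write_phenotype_tsv(calls, pheno_path)

    log_path = out_dir / "run_log.json"
    log = {
        "ahisplex_version": __version__,
        "build": config.build,
        "catalog": str(config.catalog_path),
        "rules": str(config.rules_path),
        "rules_version": rules.version,
        "model": str(config.model_path),
        "model_version": model.version,
        "external_impute_command": cmd or "none",
        "seed": config.seed,
        "input_vcf": str(vcf_path),
        "n_samples": len(rows),
        "n_markers": len(catalog),
    }
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return {
        "upload_csv": upload_path,
        "pvalue_csv": pvalue_path,
        "phenotype_tsv": pheno_path,
        "run_log": log_path,
    }
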