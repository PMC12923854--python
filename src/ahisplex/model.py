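"""The 14 phenotype p-values from probe-based allele counts.

The phenotyping system is a set of multinomial logistic regressions over the
probe allele counts, one per trait group: eye colour (3 categories), hair
colour (4), hair shade (2) and skin tone (5) — 14 probabilities in total.
For each group with categories k (one designated the reference with
eta_ref = 0):

    eta_k = alpha_k + sum_i beta_{k,i} * dosage_i
    p_k   = exp(eta_k) / sum_j exp(eta_j)

where dosage_i is the probe allele count (0/1/2) of marker i.  Missing
markers are dropped from the linear predictor (the system accepts partial
information) and their number is reported alongside the probabilities.
When all 11 MC1R markers are missing the system does not predict hair at
all, so both hair groups are undefined and flagged.

Coefficients are configuration, not code: the published model is entered by
the user in the documented YAML schema, and the repository ships a clearly
synthetic demo model for the test suite.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .catalog import mc1r_subset, probe_name
from .translate import NA_TOKEN, SAMPLE_COLUMN, HisplexRow

__all__ = [
    "GROUPS",
    "ModelError",
    "GroupCoefficients",
    "ModelCoefficients",
    "PValueVector",
    "load_model",
    "compute_pvalues",
    "pvalue_columns",
    "write_pvalue_csv",
    "read_pvalue_csv",
]

#: trait group name -> expected category count (3 + 4 + 2 + 5 = 14 p-values)
GROUPS = {"eye": 3, "hair_colour": 4, "hair_shade": 2, "skin": 5}


class ModelError(ValueError):
    """Invalid or catalog-inconsistent model coefficient file."""


@dataclass(frozen=True)
class GroupCoefficients:
    name: str
    categories: tuple            # category labels, model order
    reference: str               # reference category (eta = 0)
    intercepts: dict             # non-reference category -> alpha
    coefficients: dict           # non-reference category -> {probe name -> beta}

    @property
    def probes(self) -> set:
        used = set()
        for coeffs in self.coefficients.values():
            used.update(coeffs)
        return used


@dataclass(frozen=True)
class ModelCoefficients:
    version: str
    groups: dict                 # group name -> GroupCoefficients
    mc1r_probes: tuple           # probe names of the 11 MC1R markers


@dataclass
class PValueVector:
    """The 14 trait probabilities for one sample (groups may be undefined)."""

    probs: dict                  # group -> {category -> p} or None when undefined
    n_missing_markers: int
    hair_prediction_available: bool

    def group(self, name: str):
        return self.probs[name]


def load_model(path, catalog) -> ModelCoefficients:
    """Load and validate a model coefficient YAML against the catalog."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "groups" not in raw:
        raise ModelError(f"{path}: expected a mapping with a 'groups' section")
    known_probes = {probe_name(m) for m in catalog}
    groups = {}
    for gname, n_cat in GROUPS.items():
        if gname not in raw["groups"]:
            raise ModelError(f"group missing from model: {gname}")
        spec = raw["groups"][gname]
        categories = tuple(spec.get("categories", ()))
        if len(categories) != n_cat:
            raise ModelError(
                f"group {gname}: expected {n_cat} categories, got {len(categories)}"
            )
        reference = spec.get("reference")
        if reference not in categories:
            raise ModelError(f"group {gname}: reference {reference!r} not a category")
        intercepts, coefficients = {}, {}
        for cat in categories:
            if cat == reference:
                continue
            cat_spec = dict(spec.get("coefficients", {}).get(cat, {}))
            alpha = float(cat_spec.pop("intercept", 0.0))
            betas = {}
            for probe, beta in cat_spec.items():
                if probe not in known_probes:
                    raise ModelError(
                        f"group {gname}/{cat}: unknown marker probe {probe!r}"
                    )
                beta = float(beta)
                if not math.isfinite(beta):
                    raise ModelError(f"group {gname}/{cat}/{probe}: non-finite coefficient")
                betas[probe] = beta
            if not math.isfinite(alpha):
                raise ModelError(f"group {gname}/{cat}: non-finite intercept")
            intercepts[cat] = alpha
            coefficients[cat] = betas
        groups[gname] = GroupCoefficients(gname, categories, reference, intercepts, coefficients)
    mc1r_probes = tuple(probe_name(m) for m in mc1r_subset(catalog))
    return ModelCoefficients(str(raw.get("version", "unversioned")), groups, mc1r_probes)


def _softmax_group(group: GroupCoefficients, counts: dict):
    """Stable softmax over the group's linear predictors; None when undefined."""
    used = group.probes
    if used and all(counts.get(p) is None for p in used):
        return None
    etas = []
    for cat in group.categories:
        if cat == group.reference:
            etas.append(0.0)
            continue
        eta = group.intercepts[cat]
        for probe, beta in group.coefficients[cat].items():
            dose = counts.get(probe)
            if dose is not None:
                eta += beta * dose
        etas.append(eta)
    etas = np.asarray(etas, dtype=float)
    etas -= etas.max()  # overflow guard
    expd = np.exp(etas)
    p = expd / expd.sum()
    return dict(zip(group.categories, p.tolist()))


def compute_pvalues(row: HisplexRow, model: ModelCoefficients) -> PValueVector:
    """Evaluate all four trait groups for one sample's probe counts."""
    n_missing = sum(1 for v in row.counts.values() if v is None)
    hair_ok = not all(row.counts.get(p) is None for p in model.mc1r_probes)
    probs = {}
    for gname, group in model.groups.items():
        if gname in ("hair_colour", "hair_shade") and not hair_ok:
            probs[gname] = None
            continue
        probs[gname] = _softmax_group(group, row.counts)
    return PValueVector(probs=probs, n_missing_markers=n_missing,
                        hair_prediction_available=hair_ok)


# --- p-value table I/O (native dialect) -------------------------------------

def pvalue_columns(model: ModelCoefficients) -> list:
    cols = [SAMPLE_COLUMN]
    for gname in GROUPS:
        cols += [f"p_{gname}_{cat}" for cat in model.groups[gname].categories]
    cols += ["n_missing_markers", "hair_available"]
    return cols


def write_pvalue_csv(results, path, model: ModelCoefficients) -> None:
    """Write one row per sample: 14 named probability columns + missing count.

    *results* is an iterable of ``(sample_id, PValueVector)``.  Undefined
    groups are written as NA cells so downstream classification can flag them
    rather than silently defaulting.
    """
    cols = pvalue_columns(model)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(cols)
        for sample_id, pv in results:
            rec = [sample_id]
            for gname in GROUPS:
                group = model.groups[gname]
                gp = pv.probs.get(gname)
                if gp is None:
                    rec += [NA_TOKEN] * len(group.categories)
                else:
                    rec += [f"{gp[cat]:.10g}" for cat in group.categories]
            rec += [pv.n_missing_markers, int(pv.hair_prediction_available)]
            writer.writerow(rec)


def read_pvalue_csv(path, model: ModelCoefficients):
    """Read a native-dialect p-value CSV back into ``(sample_id, PValueVector)``."""
    cols = pvalue_columns(model)
    results = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != cols:
            raise ModelError(
                f"{path}: unexpected p-value columns; expected {cols}, got {reader.fieldnames}"
            )
        for rec in reader:
            probs = {}
            for gname in GROUPS:
                group = model.groups[gname]
                values = [rec[f"p_{gname}_{cat}"] for cat in group.categories]
                if all(v == NA_TOKEN for v in values):
                    probs[gname] = None
                else:
                    probs[gname] = {
                        cat: float(v) for cat, v in zip(group.categories, values)
                    }
            pv = PValueVector(
                probs=probs,
                n_missing_markers=int(rec["n_missing_markers"]),
                hair_prediction_available=bool(int(rec["hair_available"])),
            )
            results.append((rec[SAMPLE_COLUMN], pv))
    return results
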