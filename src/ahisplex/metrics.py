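"""Evaluation machinery for imputed genotypes and phenotypes.

Two genotype-error notions are distinguished by their phenotypic impact:
*total error* counts every imputed diploid genotype differing from the
truth, while *opposite error* counts only homozygote flips
(HOMREF <-> HOMALT), the mismatch class with the largest effect on a
prediction under any inheritance model.  On top of these the module
provides replicate phenotype concordance (exact-match fractions), red-hair
false-positive/false-negative rates, per-site imputation variability
(minor-genotype frequency across replicates), and flagging of sample/marker
combinations whose error rate stays high at high coverage — the signature
of reference-panel bias rather than of missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .translate import GTClass

__all__ = [
    "ErrorSummary",
    "ReplicateDesign",
    "MetricsError",
    "calls_to_frame",
    "compare_genotypes",
    "exact_match_fraction",
    "red_hair_confusion",
    "flag_high_error_combinations",
    "imputation_variability",
    "RED_HAIR_CATEGORY",
]

RED_HAIR_CATEGORY = "red"

_OPPOSITE = {(GTClass.HOMREF, GTClass.HOMALT), (GTClass.HOMALT, GTClass.HOMREF)}


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ErrorSummary:
    """Total / opposite genotype error counts over one comparison group."""

    n_compared: int
    n_total_error: int
    n_opposite_error: int
    group: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.n_opposite_error <= self.n_total_error <= self.n_compared:
            raise MetricsError(
                f"inconsistent counts: opposite {self.n_opposite_error} <= "
                f"total {self.n_total_error} <= compared {self.n_compared} violated"
            )

    @property
    def frac_total(self) -> float:
        return self.n_total_error / self.n_compared if self.n_compared else float("nan")

    @property
    def frac_opposite(self) -> float:
        return self.n_opposite_error / self.n_compared if self.n_compared else float("nan")


@dataclass(frozen=True)
class ReplicateDesign:
    """Replicate layout of a downsampling/imputation validation run."""

    coverages: tuple = (10.0, 2.0, 1.0, 0.5, 0.1)
    n_downsample_reps: int = 10
    n_imputation_reps: int = 10
    seeds: tuple = ()

    def __post_init__(self):
        if self.n_downsample_reps < 1 or self.n_imputation_reps < 1:
            raise MetricsError("replicate counts must be >= 1")
        if len(set(self.seeds)) != len(self.seeds):
            raise MetricsError("seeds must be unique")

    @staticmethod
    def coverage_label(coverage: float) -> str:
        return f"{coverage:g}x"


def calls_to_frame(calls) -> pd.DataFrame:
    """Normalize call input (GenotypeCall iterable or DataFrame) to a frame."""
    if isinstance(calls, pd.DataFrame):
        df = calls.copy()
    else:
        df = pd.DataFrame(
            {
                "sample": [c.sample_id for c in calls],
                "rsid": [c.rsid for c in calls],
                "gt_class": [c.gt_class for c in calls],
            }
        )
    missing = {"sample", "rsid", "gt_class"} - set(df.columns)
    if missing:
        raise MetricsError(f"call table lacks columns {sorted(missing)}")
    return df


def compare_genotypes(truth, test, group_by=()):
    """Total/opposite error summaries of *test* calls against *truth*.

    Truth is indexed by (sample, rsid); the test side may carry replicate
    columns (coverage, replicate, ...).  Truth-MISSING sites are excluded
    from the denominator; a test-MISSING genotype at a defined truth site
    counts as a total (never opposite) error.  Returns a single
    :class:`ErrorSummary` when *group_by* is empty, else a DataFrame with
    one summary row per group; test entries without a truth entry are
    excluded and reported in the ``unmatched`` attribute of the result.
    """
    truth_df = calls_to_frame(truth)
    test_df = calls_to_frame(test)
    dup = truth_df.duplicated(["sample", "rsid"])
    if dup.any():
        raise MetricsError("truth table has duplicate (sample, rsid) entries")

    merged = test_df.merge(
        truth_df[["sample", "rsid", "gt_class"]].rename(columns={"gt_class": "truth_class"}),
        on=["sample", "rsid"], how="left",
    )
    unmatched = merged[merged["truth_class"].isna()]
    matched = merged[merged["truth_class"].notna()]
    matched = matched[matched["truth_class"] != GTClass.MISSING]

    is_total = matched["gt_class"] != matched["truth_class"]
    is_opposite = [
        (t, g) in _OPPOSITE for t, g in zip(matched["truth_class"], matched["gt_class"])
    ]
    matched = matched.assign(_total=is_total.to_numpy(), _opposite=is_opposite)

    def summarize(frame, group):
        return ErrorSummary(
            n_compared=len(frame),
            n_total_error=int(frame["_total"].sum()),
            n_opposite_error=int(frame["_opposite"].sum()),
            group=dict(group),
        )

    if not group_by:
        summary = summarize(matched, {})
        object.__setattr__(summary, "unmatched", unmatched.drop(columns=["_total", "_opposite"], errors="ignore"))
        return summary

    group_by = list(group_by)
    records = []
    for keys, frame in matched.groupby(group_by, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        s = summarize(frame, dict(zip(group_by, keys)))
        records.append(
            dict(zip(group_by, keys))
            | {
                "n_compared": s.n_compared,
                "n_total_error": s.n_total_error,
                "n_opposite_error": s.n_opposite_error,
                "frac_total": s.frac_total,
                "frac_opposite": s.frac_opposite,
            }
        )
    out = pd.DataFrame(records)
    out.attrs["unmatched"] = unmatched
    return out


def exact_match_fraction(truth_pheno, replicate_phenos, trait: str):
    """Fraction of replicate calls whose *trait* category equals the truth's.

    Returns None (undefined) when the truth trait is unavailable/undefined.
    """
    truth_value = getattr(truth_pheno, trait)
    if truth_value in (None, "unavailable", "undefined"):
        return None
    if not replicate_phenos:
        raise MetricsError("need at least one replicate phenotype")
    matches = sum(1 for p in replicate_phenos if getattr(p, trait) == truth_value)
    return matches / len(replicate_phenos)


def red_hair_confusion(truth_phenos: dict, test_phenos):
    """(false-positive rate, false-negative rate) of red-hair classification.

    *truth_phenos* maps sample -> truth hair category; *test_phenos* is a
    DataFrame with columns sample, hair (replicates pooled as comparisons).
    FN = truth-red comparisons classified non-red / truth-red comparisons;
    FP = truth-non-red comparisons classified red / truth-non-red ones.
    A zero denominator yields None for that rate.
    """
    df = test_phenos.copy()
    missing = {"sample", "hair"} - set(df.columns)
    if missing:
        raise MetricsError(f"test phenotype table lacks columns {sorted(missing)}")
    unknown = set(df["sample"]) - set(truth_phenos)
    if unknown:
        raise MetricsError(f"samples without truth hair phenotype: {sorted(unknown)}")
    df = df.assign(truth_hair=df["sample"].map(truth_phenos))
    if (df["truth_hair"].isin(("unavailable", "undefined"))).any() or df["truth_hair"].isna().any():
        raise MetricsError("hair categories must be defined for all entries")

    truth_red = df["truth_hair"] == RED_HAIR_CATEGORY
    test_red = df["hair"] == RED_HAIR_CATEGORY
    n_red = int(truth_red.sum())
    n_nonred = int((~truth_red).sum())
    fn_rate = float((truth_red & ~test_red).sum() / n_red) if n_red else None
    fp_rate = float((~truth_red & test_red).sum() / n_nonred) if n_nonred else None
    return fp_rate, fn_rate


def flag_high_error_combinations(per_combo_errors: pd.DataFrame,
                                 high_coverages=("original", "2x", "1x"),
                                 threshold: float = 0.15):
    """Flag (sample, rsid) combinations with high error at high coverage.

    *per_combo_errors* needs columns sample, rsid, coverage, mean_error and,
    for error attribution, n_errors (error count at that combination and
    coverage).  A combination is flagged when its mean error across the high
    coverages is >= *threshold*; combinations missing one of the high
    coverage levels are skipped with a warning entry.  Returns
    ``(flagged, attribution, skipped)`` where attribution is the fraction of
    all errors (across every coverage) carried by the flagged set, or None
    when no ``n_errors`` column is present.
    """
    df = per_combo_errors
    missing = {"sample", "rsid", "coverage", "mean_error"} - set(df.columns)
    if missing:
        raise MetricsError(f"per-combination table lacks columns {sorted(missing)}")
    high = set(high_coverages)
    flagged, skipped = set(), []
    for (sample, rsid), frame in df.groupby(["sample", "rsid"], sort=True):
        present = set(frame["coverage"])
        if not high <= present:
            skipped.append((sample, rsid, sorted(high - present)))
            continue
        mean_high = frame.loc[frame["coverage"].isin(high), "mean_error"].mean()
        if mean_high >= threshold:
            flagged.add((sample, rsid))
    attribution = None
    if "n_errors" in df.columns:
        total = df["n_errors"].sum()
        if total > 0:
            in_flagged = df.apply(
                lambda r: (r["sample"], r["rsid"]) in flagged, axis=1
            )
            attribution = float(df.loc[in_flagged, "n_errors"].sum() / total)
    return flagged, attribution, skipped


def imputation_variability(replicate_calls) -> pd.DataFrame:
    """Per-(sample, rsid) minor-genotype frequency across imputation replicates.

    1 - frequency of the modal genotype class; 0 when replicates agree, at
    most 1 - 1/k for k observed classes.
    """
    df = calls_to_frame(replicate_calls)
    records = []
    for (sample, rsid), frame in df.groupby(["sample", "rsid"], sort=True):
        if len(frame) < 2:
            raise MetricsError(
                f"{sample}/{rsid}: imputation variability needs >= 2 replicates"
            )
        counts = frame["gt_class"].value_counts()
        records.append(
            {
                "sample": sample,
                "rsid": rsid,
                "n_replicates": len(frame),
                "variability": 1.0 - counts.iloc[0] / len(frame),
            }
        )
    return pd.DataFrame(records)
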