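"""Genotype/phenotype error metrics: definitions, oracles, invariants."""

import numpy as np
import pandas as pd
import pytest

from ahisplex.classify import PhenotypeCall
from ahisplex.metrics import (
    ErrorSummary,
    MetricsError,
    ReplicateDesign,
    compare_genotypes,
    exact_match_fraction,
    flag_high_error_combinations,
    imputation_variability,
    red_hair_confusion,
)
from ahisplex.translate import GTClass

CLASSES = [GTClass.HOMREF, GTClass.HET, GTClass.HOMALT]


def frame(entries, **extra_cols):
    df = pd.DataFrame(entries, columns=["sample", "rsid", "gt_class"])
    for k, v in extra_cols.items():
        df[k] = v
    return df


def test_homozygote_flip_counts_total_and_opposite():
    truth = frame([("s1", "r1", GTClass.HOMREF)])
    test = frame([("s1", "r1", GTClass.HOMALT)])
    s = compare_genotypes(truth, test)
    assert (s.n_compared, s.n_total_error, s.n_opposite_error) == (1, 1, 1)


def test_het_mismatch_counts_total_only():
    truth = frame([("s1", "r1", GTClass.HOMREF)])
    test = frame([("s1", "r1", GTClass.HET)])
    s = compare_genotypes(truth, test)
    assert (s.n_total_error, s.n_opposite_error) == (1, 0)


def test_perfect_concordance_over_41_markers():
    truth = frame([("s1", f"r{i}", CLASSES[i % 3]) for i in range(41)])
    s = compare_genotypes(truth, truth.copy())
    assert s.n_compared == 41
    assert s.frac_total == 0.0


def test_truth_missing_excluded_and_unmatched_reported():
    truth = frame([("s1", "r1", GTClass.MISSING), ("s1", "r2", GTClass.HET)])
    test = frame([
        ("s1", "r1", GTClass.HOMREF),   # truth MISSING -> excluded
        ("s1", "r2", GTClass.HET),
        ("s2", "r2", GTClass.HET),      # no truth entry -> unmatched
    ])
    s = compare_genotypes(truth, test)
    assert s.n_compared == 1
    assert len(s.unmatched) == 1
    assert s.unmatched.iloc[0]["sample"] == "s2"


def test_test_missing_counts_total_not_opposite():
    truth = frame([("s1", "r1", GTClass.HOMALT)])
    test = frame([("s1", "r1", GTClass.MISSING)])
    s = compare_genotypes(truth, test)
    assert (s.n_total_error, s.n_opposite_error) == (1, 0)


def test_compare_matches_brute_force_oracle_with_grouping():
    rng = np.random.default_rng(9)
    samples = [f"s{i}" for i in range(6)]
    rsids = [f"r{i}" for i in range(15)]
    truth_rows = [(s, r, CLASSES[rng.integers(0, 3)]) for s in samples for r in rsids]
    truth = frame(truth_rows)
    truth_map = {(s, r): g for s, r, g in truth_rows}
    test_rows = []
    for cov in ("0.1x", "2x"):
        for rep in range(3):
            for s in samples:
                for r in rsids:
                    test_rows.append(
                        {"sample": s, "rsid": r,
                         "gt_class": CLASSES[rng.integers(0, 3)],
                         "coverage": cov, "replicate": rep}
                    )
    test = pd.DataFrame(test_rows)
    out = compare_genotypes(truth, test, group_by=["coverage"])

    for cov in ("0.1x", "2x"):
        sub = [row for row in test_rows if row["coverage"] == cov]
        n_total = sum(1 for row in sub if row["gt_class"] != truth_map[(row["sample"], row["rsid"])])
        n_opp = sum(
            1 for row in sub
            if {row["gt_class"], truth_map[(row["sample"], row["rsid"])]}
            == {GTClass.HOMREF, GTClass.HOMALT}
        )
        got = out[out["coverage"] == cov].iloc[0]
        assert got["n_compared"] == len(sub)
        assert got["n_total_error"] == n_total
        assert got["n_opposite_error"] == n_opp
        assert got["n_opposite_error"] <= got["n_total_error"] <= got["n_compared"]


def test_rates_invariant_under_replicate_permutation():
    rng = np.random.default_rng(3)
    truth = frame([("s1", f"r{i}", CLASSES[rng.integers(0, 3)]) for i in range(20)])
    test = frame(
        [("s1", f"r{i}", CLASSES[rng.integers(0, 3)]) for i in range(20)] * 3,
        replicate=[r for r in range(3) for _ in range(20)],
    )
    s1 = compare_genotypes(truth, test)
    shuffled = test.sample(frac=1.0, random_state=1).reset_index(drop=True)
    s2 = compare_genotypes(truth, shuffled)
    assert (s1.n_compared, s1.n_total_error, s1.n_opposite_error) == (
        s2.n_compared, s2.n_total_error, s2.n_opposite_error
    )


def test_error_summary_rejects_inconsistent_counts():
    with pytest.raises(MetricsError):
        ErrorSummary(n_compared=5, n_total_error=2, n_opposite_error=3)


def test_replicate_design_defaults_and_validation():
    d = ReplicateDesign()
    assert d.coverages == (10.0, 2.0, 1.0, 0.5, 0.1)
    assert d.n_downsample_reps == d.n_imputation_reps == 10
    assert ReplicateDesign.coverage_label(0.5) == "0.5x"
    with pytest.raises(MetricsError):
        ReplicateDesign(seeds=(1, 1))


def make_pheno(sample, eye="blue", hair="blonde", skin="pale"):
    return PhenotypeCall(sample, eye, hair, skin, [])


def test_exact_match_fraction():
    truth = make_pheno("s1", eye="blue")
    reps = [make_pheno("s1", eye="blue")] * 91 + [make_pheno("s1", eye="brown")] * 9
    assert exact_match_fraction(truth, reps, "eye") == pytest.approx(0.91)
    assert exact_match_fraction(truth, reps[:91], "eye") == 1.0
    assert exact_match_fraction(truth, reps[91:], "eye") == 0.0
    unavailable = PhenotypeCall("s1", "blue", "unavailable", "pale", [])
    assert exact_match_fraction(unavailable, reps, "hair") is None


def test_red_hair_confusion_table_semantics():
    """8 red individuals x 10 replicates with 31 non-red calls -> FN 38.75%."""
    truth = {f"red{i}": "red" for i in range(8)}
    truth |= {f"nr{i}": "blonde" for i in range(85)}
    rows = []
    miss = 31
    for i in range(8):
        for rep in range(10):
            call = "blonde" if miss > 0 else "red"
            miss -= call == "blonde"
            rows.append({"sample": f"red{i}", "hair": call})
    for i in range(85):
        for rep in range(10):
            rows.append({"sample": f"nr{i}", "hair": "blonde"})
    # two false-positive red calls among the 850 non-red comparisons
    rows[-1]["hair"] = "red"
    rows[-2]["hair"] = "red"
    fp, fn = red_hair_confusion(truth, pd.DataFrame(rows))
    assert fn == pytest.approx(31 / 80)
    assert fp == pytest.approx(2 / 850)


def test_red_hair_confusion_edge_cases():
    truth = {"a": "blonde"}
    fp, fn = red_hair_confusion(truth, pd.DataFrame([{"sample": "a", "hair": "blonde"}]))
    assert fn is None          # no red-truth individuals
    assert fp == 0.0
    truth = {"a": "red", "b": "blonde"}
    df = pd.DataFrame([{"sample": "a", "hair": "red"}, {"sample": "b", "hair": "black"}])
    assert red_hair_confusion(truth, df) == (0.0, 0.0)


def test_high_error_flagging_criterion():
    rows = [
        # flagged: mean(0.30, 0.25, 0.20) = 0.25 >= 0.15
        {"sample": "s1", "rsid": "r1", "coverage": c, "mean_error": e, "n_errors": n}
        for c, e, n in [("original", 0.30, 30), ("2x", 0.25, 25), ("1x", 0.20, 20),
                        ("0.5x", 0.40, 40), ("0.1x", 0.50, 50)]
    ] + [
        # clean combination
        {"sample": "s2", "rsid": "r1", "coverage": c, "mean_error": 0.0, "n_errors": 0}
        for c in ("original", "2x", "1x", "0.5x", "0.1x")
    ] + [
        # missing a high coverage level -> skipped
        {"sample": "s3", "rsid": "r1", "coverage": c, "mean_error": 0.9, "n_errors": 9}
        for c in ("original", "2x")
    ]
    flagged, attribution, skipped = flag_high_error_combinations(pd.DataFrame(rows))
    assert flagged == {("s1", "r1")}
    assert skipped == [("s3", "r1", ["1x"])]
    assert attribution == pytest.approx(165 / (165 + 18))


def test_high_error_attribution_engineered_to_47_percent():
    """Flagged combinations constructed to carry 47% of all errors."""
    rows = []
    rows += [{"sample": "bad", "rsid": "r1", "coverage": c, "mean_error": 0.2,
              "n_errors": 47} for c in ("original",)]
    rows += [{"sample": "bad", "rsid": "r1", "coverage": c, "mean_error": 0.2,
              "n_errors": 0} for c in ("2x", "1x")]
    rows += [{"sample": "ok", "rsid": "r2", "coverage": c, "mean_error": 0.01,
              "n_errors": n} for c, n in [("original", 13), ("2x", 20), ("1x", 20)]]
    flagged, attribution, skipped = flag_high_error_combinations(pd.DataFrame(rows))
    assert flagged == {("bad", "r1")}
    assert attribution == pytest.approx(0.47)


def test_imputation_variability():
    reps = frame([("s1", "r1", GTClass.HET)] * 10)
    out = imputation_variability(reps)
    assert out.iloc[0]["variability"] == 0.0
    reps = frame([("s1", "r1", GTClass.HET)] * 7 + [("s1", "r1", GTClass.HOMREF)] * 3)
    out = imputation_variability(reps)
    assert out.iloc[0]["variability"] == pytest.approx(0.3)


def test_imputation_variability_bound():
    rng = np.random.default_rng(7)
    for _ in range(20):
        k_classes = int(rng.integers(1, 4))
        picks = rng.integers(0, k_classes, size=10)
        reps = frame([("s1", "r1", CLASSES[p]) for p in picks])
        out = imputation_variability(reps)
        observed_k = len(set(picks.tolist()))
        assert 0.0 <= out.iloc[0]["variability"] <= 1 - 1 / observed_k + 1e-12
    with pytest.raises(MetricsError, match=">= 2 replicates"):
        imputation_variability(frame([("s1", "r1", GTClass.HET)]))
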