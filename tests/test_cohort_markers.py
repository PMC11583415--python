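import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ginet.cohort_markers import (
    EFFECTIVE_GENOME_MB,
    IFNG_GENES,
    M1M2_GENES,
    MarkerConfig,
    TwoByTwo,
    call_msi_scores,
    compare_groups,
    compute_tmb,
    cytolytic_score,
    fisher_exact_2x2,
    infer_msi_from_panel,
    logrank_test,
    signature_mean_score,
    two_proportion_test,
)
from ginet.genotyping import MutationRecord


# --- TMB --------------------------------------------------------------------


def test_tmb_zero_and_division():
    assert compute_tmb(0) == 0.0
    assert compute_tmb(29348) == pytest.approx(29348 / 2934.876451)


def test_tmb_linear_and_panel_denominator():
    assert compute_tmb(200) == pytest.approx(2 * compute_tmb(100))
    # panel mode: same formula over the panel footprint
    assert compute_tmb(12, genome_size_mb=1.2) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        compute_tmb(5, genome_size_mb=0.0)


# --- MSI --------------------------------------------------------------------


@pytest.mark.parametrize(
    "msisensor,mantis,expected",
    [
        (10.0, 0.4, "MSI"),  # inclusive boundary on both scores
        (9.9, 0.9, "MSS"),
        (40.0, 0.39, "MSS"),
        (None, None, "unknown"),
        (10.0, None, "MSI"),  # single-score fallback
        (None, 0.2, "MSS"),
    ],
)
def test_msi_score_calls(msisensor, mantis, expected):
    assert call_msi_scores(msisensor, mantis) == expected


def test_msi_call_monotone_in_scores(rng):
    """Raising either score never flips an MSI call back to MSS."""
    for _ in range(50):
        s, m = rng.uniform(0, 20), rng.uniform(0, 0.8)
        base = call_msi_scores(s, m)
        if base == "MSI":
            assert call_msi_scores(s + rng.uniform(0, 10), m) == "MSI"
            assert call_msi_scores(s, m + rng.uniform(0, 1)) == "MSI"


def test_panel_msi_inference():
    assert infer_msi_from_panel([MutationRecord("S1", "MSH2", "Frame_Shift_Del")]) == "MSI"
    assert infer_msi_from_panel([MutationRecord("S1", "MLH1", "Missense_Mutation")]) == "MSS"
    assert infer_msi_from_panel([MutationRecord("S1", "TP53", "Nonsense_Mutation")]) == "MSS"
    assert infer_msi_from_panel([]) == "MSS"


# --- immune signatures ------------------------------------------------------


def test_cytolytic_values():
    assert cytolytic_score(4.0, 9.0) == pytest.approx(6.0)
    assert cytolytic_score(7.3, 7.3) == pytest.approx(7.3)
    assert cytolytic_score(0.0, 100.0) == 0.0


def test_cytolytic_scale_equivariance(rng):
    a, b = rng.uniform(0.1, 50, size=2)
    assert cytolytic_score(2 * a, 2 * b) == pytest.approx(2 * cytolytic_score(a, b))


def test_signature_means():
    assert signature_mean_score({g: 5.0 for g in M1M2_GENES}, M1M2_GENES) == pytest.approx(5.0)
    fpkm = {g: 0.0 for g in M1M2_GENES}
    fpkm["IDO1"] = 10.0
    assert signature_mean_score(fpkm, M1M2_GENES) == pytest.approx(1.0)
    incomplete = {g: 1.0 for g in IFNG_GENES if g != "STAT1"}
    with pytest.raises(KeyError, match="STAT1"):
        signature_mean_score(incomplete, IFNG_GENES)


# --- Fisher -----------------------------------------------------------------


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full enumeration of fixed-margin tables,
    summing the probability of every table no more likely than observed."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total


def test_fisher_table3_counts():
    p, odds = fisher_exact_2x2(TwoByTwo(10, 0, 0, 3))
    assert p == pytest.approx(1 / 286, rel=1e-9)
    assert math.isinf(odds)


def test_fisher_balanced_table():
    p, odds = fisher_exact_2x2(TwoByTwo(5, 5, 5, 5))
    assert p == pytest.approx(1.0)
    assert odds == pytest.approx(1.0)


def test_fisher_matches_enumeration_for_small_tables(rng):
    for _ in range(40):
        a, b, c, d = rng.integers(0, 8, size=4)
        if a + b + c + d == 0:
            continue
        p, _ = fisher_exact_2x2(TwoByTwo(int(a), int(b), int(c), int(d)))
        assert p == pytest.approx(_fisher_oracle(int(a), int(b), int(c), int(d)), abs=1e-9)


def test_fisher_rejects_all_zero():
    with pytest.raises(ValueError):
        fisher_exact_2x2(TwoByTwo(0, 0, 0, 0))


# --- proportions ------------------------------------------------------------


def test_equal_proportions_give_p_one():
    assert two_proportion_test(5, 10, 50, 100, correction=False) == pytest.approx(1.0)


def test_reported_proportion_contrast_significant():
    assert two_proportion_test(10, 67, 4, 301) < 1e-4


def test_extreme_proportions_agree_with_exact_oracle():
    """20/20 vs 0/20: chi-square approximation must land in the same
    deep-significance regime as the conditional exact enumeration."""
    p_chi = two_proportion_test(20, 20, 0, 20)
    p_exact, _ = fisher_exact_2x2(TwoByTwo(20, 0, 0, 20))
    assert p_chi < 1e-6 and p_exact < 1e-9


def test_proportion_validation():
    with pytest.raises(ValueError):
        two_proportion_test(1, 0, 1, 10)
    with pytest.raises(ValueError):
        two_proportion_test(11, 10, 1, 10)


# --- group comparisons ------------------------------------------------------


def _marker_frame():
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        {"m1": rng.normal(0, 1, 24), "m2": rng.normal(0, 1, 24)},
        index=[f"S{i}" for i in range(24)],
    )
    labels = pd.Series(["A"] * 12 + ["B"] * 12, index=values.index)
    return values, labels


def test_identical_groups_welch_p_one():
    values, labels = _marker_frame()
    values.iloc[12:] = values.iloc[:12].to_numpy()  # group B copies group A
    res = compare_groups(values, labels)
    assert res["tests"]["welch_p"].round(6).eq(1.0).all()


def test_small_group_not_analysed():
    values, labels = _marker_frame()
    labels.iloc[12:] = "B"
    labels.iloc[:2] = "C"
    labels.iloc[2:12] = "A"
    res = compare_groups(values, labels)
    assert res["not_analysed"] == ["C"]
    assert set(res["groups"]) == {"A", "B"}


def test_three_groups_add_anova_and_tukey(rng):
    values = pd.DataFrame(
        {"m": np.concatenate([rng.normal(0, 1, 8), rng.normal(0, 1, 8), rng.normal(3, 1, 8)])},
        index=[f"S{i}" for i in range(24)],
    )
    labels = pd.Series(["A"] * 8 + ["B"] * 8 + ["C"] * 8, index=values.index)
    res = compare_groups(values, labels)
    assert res["tests"]["anova_p"].iloc[0] < 0.01
    assert len(res["tukey"]["m"]) == 3  # three pairwise contrasts


def test_bh_within_family_monotone(rng):
    values = pd.DataFrame(
        rng.normal(0, 1, size=(20, 4)),
        index=[f"S{i}" for i in range(20)],
        columns=list("wxyz"),
    )
    labels = pd.Series(["A"] * 10 + ["B"] * 10, index=values.index)
    tests = compare_groups(values, labels)["tests"].sort_values("welch_p")
    assert (tests["bh_q"] >= tests["welch_p"] - 1e-12).all()
    assert (tests["bh_q"].diff().dropna() >= -1e-12).all()


# --- log-rank ---------------------------------------------------------------


def _logrank_oracle(times, events, groups):
    """Observed-minus-expected log-rank chi-square over pooled risk sets."""
    df = pd.DataFrame({"t": times, "e": events, "g": groups})
    g1 = sorted(df["g"].unique())[0]
    O = E = V = 0.0
    for t in sorted(df.loc[df["e"] == 1, "t"].unique()):
        at_risk = df[df["t"] >= t]
        n = len(at_risk)
        n1 = (at_risk["g"] == g1).sum()
        d = ((df["t"] == t) & (df["e"] == 1)).sum()
        d1 = ((df["t"] == t) & (df["e"] == 1) & (df["g"] == g1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def test_identical_survival_gives_null_statistic():
    times = [5, 10, 15, 20, 25, 30, 35, 40, 45, 50] * 2
    events = [1, 0] * 10
    groups = ["A"] * 10 + ["B"] * 10
    res = logrank_test(times, events, groups)
    assert res["analysed"]
    assert res["chi_sq"] == pytest.approx(0.0, abs=1e-9)
    assert res["pval"] == pytest.approx(1.0)


def test_undersized_group_not_analysed():
    res = logrank_test([1.0] * 19, [1] * 19, ["A"] * 9 + ["B"] * 10)
    assert not res["analysed"]
    assert res["not_analysed"] == ["A"]
    assert res["pval"] is None


def test_logrank_matches_manual_risk_set_oracle(rng):
    times = list(rng.exponential(20, 12)) + list(rng.exponential(8, 12))
    events = list(rng.random(24) < 0.8)
    groups = ["A"] * 12 + ["B"] * 12
    events = [int(e) for e in events]
    res = logrank_test(times, events, groups)
    assert res["chi_sq"] == pytest.approx(_logrank_oracle(times, events, groups), rel=1e-6)
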