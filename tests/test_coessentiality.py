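import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ginet.coessentiality import (
    call_essentiality_network,
    correlate_all,
    find_inflection,
    map_essentiality_network,
    permutation_adjust_correlations,
)


def _pearson_oracle(x, y):
    """Closed-form Pearson r, written independently of the implementation."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def _toy_matrix():
    return pd.DataFrame(
        {
            "Q": [0.1, -0.5, 0.9, -1.2, 0.4],
            "A": [0.2, -0.3, 1.1, -0.9, 0.0],
            "B": [-0.1, 0.5, -0.9, 1.2, -0.4],  # exact negation of Q
            "C": [1.0, 1.0, 1.0, 1.0, 1.0],  # zero variance -> dropped
        },
        index=[f"L{i}" for i in range(5)],
    )


def test_self_correlation_rank_one():
    rows = correlate_all(_toy_matrix(), "Q").set_index("gene")
    assert rows.loc["Q", "r"] == pytest.approx(1.0)
    assert rows.loc["Q", "rank"] == 1


def test_exact_negation_gives_minus_one():
    rows = correlate_all(_toy_matrix(), "Q").set_index("gene")
    assert rows.loc["B", "r"] == pytest.approx(-1.0)


def test_matches_closed_form_oracle_to_1e12():
    df = _toy_matrix()
    rows = correlate_all(df, "Q").set_index("gene")
    expected = _pearson_oracle(df["Q"], df["A"])
    assert rows.loc["A", "r"] == pytest.approx(expected, abs=1e-12)


def test_zero_variance_gene_dropped():
    rows = correlate_all(_toy_matrix(), "Q")
    assert "C" not in set(rows["gene"])


def test_complete_case_line_sets(rng):
    """Missing entries shrink n_used per gene without breaking r."""
    df = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("QABC"))
    df.iloc[:5, 1] = np.nan
    rows = correlate_all(df, "Q").set_index("gene")
    assert rows.loc["A", "n_used"] == 25
    sub = df.iloc[5:]
    assert rows.loc["A", "r"] == pytest.approx(_pearson_oracle(sub["Q"], sub["A"]), abs=1e-12)


def test_query_absent_or_all_missing():
    df = _toy_matrix()
    with pytest.raises(KeyError):
        correlate_all(df, "ZZZ")
    df["Q"] = np.nan
    with pytest.raises(ValueError):
        correlate_all(df, "Q")


# --- permutation null -------------------------------------------------------


def test_p_perm_bounds_monotone_and_deterministic(rng):
    df = pd.DataFrame(rng.standard_normal((40, 25)), columns=[f"G{i}" for i in range(25)])
    rows = correlate_all(df, "G0")
    a = permutation_adjust_correlations(df, "G0", rows, n_perm=500, seed=4)
    b = permutation_adjust_correlations(df, "G0", rows, n_perm=500, seed=4)
    pd.testing.assert_frame_equal(a, b)
    p = a.set_index("gene")["p_perm"]
    assert (p >= 1 / 501).all() and (p <= 1).all()
    # shared null: larger |r| never gets a larger p
    ordered = a.sort_values("r", key=lambda s: s.abs(), ascending=False)["p_perm"]
    assert (ordered.diff().dropna() >= 0).all()


def test_near_zero_r_gets_p_near_one(rng):
    df = pd.DataFrame(rng.standard_normal((60, 20)), columns=[f"G{i}" for i in range(20)])
    rows = correlate_all(df, "G0")
    adj = permutation_adjust_correlations(df, "G0", rows, n_perm=400, seed=1).set_index("gene")
    weakest = adj["r"].abs().idxmin()
    assert adj.loc[weakest, "p_perm"] > 0.8


def test_sampled_null_agrees_with_exhaustive_enumeration(rng):
    """Tiny 6-line panel: the sampled p sits inside the binomial 99% CI of
    the exact probability enumerated over all (gene, permutation) pairs."""
    df = pd.DataFrame(rng.standard_normal((6, 3)), columns=["Q", "A", "B"])
    rows = correlate_all(df, "Q")
    q = df["Q"].to_numpy()
    null = []
    for col in ["Q", "A", "B"]:
        vals = df[col].to_numpy()
        for perm in itertools.permutations(range(6)):
            null.append(abs(np.corrcoef(q, vals[list(perm)])[0, 1]))
    null = np.array(null)
    n_perm = 4000
    adj = permutation_adjust_correlations(df, "Q", rows, n_perm=n_perm, seed=2).set_index("gene")
    for gene in ["A", "B"]:
        r_obs = abs(adj.loc[gene, "r"])
        p_exact = null[null >= r_obs - 1e-12].size / null.size
        p_hat = adj.loc[gene, "p_perm"]
        half_width = 2.58 * math.sqrt(p_exact * (1 - p_exact) / n_perm) + 2 / n_perm
        assert abs(p_hat - p_exact) <= half_width


# --- knee detection ---------------------------------------------------------


def _piecewise_curve():
    shallow = 3.0 - 0.001 * np.arange(1, 101)  # ranks 1..100
    steep = shallow[-1] - 0.1 * np.arange(1, 21)  # ranks 101..120, all positive
    return np.concatenate([shallow, steep])


def test_knee_found_at_constructed_vertex():
    pos = _piecewise_curve()
    assert pos.min() > 0
    ranked = np.concatenate([pos, -pos[::-1]])
    thr = find_inflection(ranked)
    assert thr.idx_pos == 100
    assert thr.r_pos == pytest.approx(pos[99])
    # mirrored negative segment: knee mirrors the positive one
    assert thr.idx_neg == len(ranked) - 100 + 1
    assert thr.r_neg == pytest.approx(-pos[99])


def test_linear_segment_ties_break_to_first_rank():
    # binary-fraction slope keeps the chord distances exactly zero
    pos = 1.0 - np.arange(50) / 64.0
    neg = -pos[::-1]
    assert pos.min() > 0
    thr = find_inflection(np.concatenate([pos, neg]))
    assert thr.idx_pos == 1


def test_undefined_side_flagged():
    with pytest.warns(UserWarning, match="negative"):
        thr = find_inflection(np.array([0.9, 0.5, 0.2, 0.1]))
    assert thr.pos_defined and not thr.neg_defined


# --- network calls ----------------------------------------------------------


def test_call_rules_and_strict_boundary():
    from ginet.coessentiality import InflectionThresholds

    thr = InflectionThresholds(r_pos=0.2, r_neg=-0.2, idx_pos=5, idx_neg=15)
    rows = pd.DataFrame(
        {
            "gene": ["a", "b", "c", "d"],
            "r": [0.5, 0.5, 0.2, -0.5],
            "n_used": [10] * 4,
            "rank": [1, 2, 3, 4],
            "p_perm": [0.001, 0.2, 0.001, 0.01],
        }
    )
    called = call_essentiality_network(rows, thr).set_index("gene")["call"]
    assert called["a"] == "coessential"
    assert called["b"] == "none"  # fails alpha
    assert called["c"] == "none"  # r == r_pos is not strictly above
    assert called["d"] == "antiessential"


def test_planted_pair_called_on_study_panel(screen_panel):
    rows, _ = map_essentiality_network(
        screen_panel.gene_effect, "G0002", n_perm=2000, seed=3
    )
    row = rows.set_index("gene").loc["G0003"]
    assert row["call"] == "coessential"
    assert row["rank"] == 1
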