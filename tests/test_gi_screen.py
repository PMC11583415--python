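import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ginet.gi_screen import (
    interaction_score,
    permutation_adjust_screen,
    rank_sum_test,
    run_gi_screen,
)
from ginet.simulate import SimulationConfig, simulate_dependency_panel


def _mwu_exact_oracle(x, y):
    """Brute-force two-sided Mann-Whitney p by enumerating every way the
    pooled values could have been split between the groups."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(a, b):
        return sum(1 for i in a for j in b if i > j)

    u_obs = u_stat(x, y)
    mu = n1 * (len(pooled) - n1) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_stat(a, b) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def test_identical_groups_give_p_one():
    _, p = rank_sum_test([0.2, 0.4, 0.6], [0.2, 0.4, 0.6])
    assert p == pytest.approx(1.0)


def test_fully_separated_three_vs_three():
    u, p = rank_sum_test([0.9, 0.8, 0.7], [0.1, 0.2, 0.3])
    assert u == 9.0
    assert p == pytest.approx(0.1)  # 2 / C(6,3)


def test_empty_group_rejected():
    with pytest.raises(ValueError):
        rank_sum_test([], [0.1])


@pytest.mark.parametrize("n1,n2,seed", [(3, 3, 0), (4, 4, 1), (5, 3, 2), (7, 6, 3), (2, 7, 4)])
def test_exact_p_matches_enumeration_oracle(n1, n2, seed):
    rng = np.random.default_rng(seed)
    x = list(rng.random(n1))
    y = list(rng.random(n2))
    _, p = rank_sum_test(x, y)
    assert p == pytest.approx(_mwu_exact_oracle(x, y), abs=1e-12)


# --- interaction score ------------------------------------------------------


def test_interaction_score_values():
    assert interaction_score(1.0, 0.9, 0.1) == 0.0
    assert interaction_score(0.001, 0.5, 0.5) == 0.0
    assert interaction_score(0.01, 0.8, 0.2) == pytest.approx(4.0)


def test_interaction_score_floor_and_validation():
    # zero control median is floored rather than dividing by zero
    s = interaction_score(0.01, 0.5, 0.0, median_floor=1e-4)
    assert s == pytest.approx(2 * math.log2(0.5 / 1e-4))
    with pytest.raises(ValueError):
        interaction_score(0.0, 0.5, 0.1)


# --- permutation adjustment -------------------------------------------------


def _leth_frame(rng, n_lines, n_genes):
    return pd.DataFrame(
        rng.random((n_lines, n_genes)),
        index=[f"L{i}" for i in range(n_lines)],
        columns=[f"G{i}" for i in range(n_genes)],
    )


def test_adjustment_bounds_monotone_deterministic(rng):
    leth = _leth_frame(rng, 20, 15)
    lof, wt = list(leth.index[:8]), list(leth.index[8:])
    obs = pd.Series(np.linspace(0.001, 1.0, 15), index=leth.columns)
    a = permutation_adjust_screen(leth, lof, wt, obs, n_perm=300, seed=5)
    b = permutation_adjust_screen(leth, lof, wt, obs, n_perm=300, seed=5)
    pd.testing.assert_series_equal(a, b)
    assert (a >= 1 / 301).all() and (a <= 1).all()
    assert (a.diff().dropna() >= 0).all()  # monotone in the observed p
    assert a.iloc[-1] == pytest.approx(1.0)  # observed p = 1 -> adjusted 1


def test_small_groups_rejected(rng):
    leth = _leth_frame(rng, 5, 3)
    with pytest.raises(ValueError):
        permutation_adjust_screen(
            leth, [leth.index[0]], list(leth.index[1:]), pd.Series(0.5, index=leth.columns)
        )


def test_sampled_null_matches_exhaustive_relabelling(rng):
    """Single-gene screen, 3 vs 3: the sampled label-shuffle null must agree
    with the exhaustive 20-relabelling null within the binomial 99% CI."""
    vals = np.array([0.1, 0.9, 0.3, 0.7, 0.2, 0.8])
    leth = pd.DataFrame({"G0": vals}, index=[f"L{i}" for i in range(6)])
    lof, wt = ["L0", "L1", "L2"], ["L3", "L4", "L5"]

    def approx_p(a, b):
        # same tie-corrected normal machinery as the null path
        from scipy import stats

        n1, n2 = len(a), len(b)
        ranks = stats.rankdata(np.concatenate([a, b]))
        u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        sigma = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        return min(1.0, 2 * stats.norm.sf((abs(u1 - n1 * n2 / 2) - 0.5) / sigma))

    null = []
    for idx in itertools.combinations(range(6), 3):
        a = vals[list(idx)]
        b = vals[[i for i in range(6) if i not in idx]]
        null.append(approx_p(a, b))
    null = np.array(null)

    obs_p = pd.Series({"G0": 0.3})
    n_perm = 4000
    adj = permutation_adjust_screen(leth, lof, wt, obs_p, n_perm=n_perm, seed=9)
    p_exact = np.mean(null <= 0.3)
    half_width = 2.58 * math.sqrt(p_exact * (1 - p_exact) / n_perm) + 2 / n_perm
    assert abs(adj["G0"] - p_exact) <= half_width


def test_per_gene_and_marginal_strategies_run(rng):
    leth = _leth_frame(rng, 16, 6)
    lof, wt = list(leth.index[:6]), list(leth.index[6:])
    obs = pd.Series(np.linspace(0.01, 0.9, 6), index=leth.columns)
    for strategy in ("pooled_marginal", "per_gene"):
        adj = permutation_adjust_screen(
            leth, lof, wt, obs, n_perm=200, seed=1, strategy=strategy
        )
        assert ((adj > 0) & (adj <= 1)).all()


# --- full screen ------------------------------------------------------------


def test_screen_recovers_planted_sl(screen_panel):
    res = run_gi_screen(screen_panel, "G0001", n_perm=500, seed=11)
    top = res.iloc[0]
    assert top["gene"] == "G0010"
    assert top["direction"] == "SL"
    assert top["interaction_score"] > 0
    assert top["mutant_median"] > top["control_median"]


def test_screen_sign_coherence_and_ordering(screen_panel):
    res = run_gi_screen(screen_panel, "G0001", n_perm=300, seed=2)
    informative = res[res["adj_pval"] < 1]
    pos = informative["interaction_score"] > 0
    assert (pos == (informative["mutant_median"] > informative["control_median"])).all()
    assert (res["interaction_score"].diff().dropna() <= 1e-12).all()


def test_screen_rejects_single_mutant_line():
    cfg = SimulationConfig(
        n_lines=30, n_genes=20, seed=1, n_lof_lines=1,
        planted_gi=(("G01", "G05", 0.8, 0.2),), missing_rate=0.0,
    )
    panel = simulate_dependency_panel(cfg)
    with pytest.raises(ValueError, match="mutant"):
        run_gi_screen(panel, "G01", n_perm=100, seed=0)


def test_screen_context_restriction(screen_panel):
    context = screen_panel.annotations["disease"].iloc[0]
    sub = screen_panel.annotations.query("disease == @context")
    lof_ids = set(screen_panel.lethality.index[:40])
    n_mut = len(set(sub["DepMap_ID"]) & lof_ids)
    if n_mut >= 2:
        res = run_gi_screen(screen_panel, "G0001", n_perm=200, seed=3, context=context)
        assert len(res) == screen_panel.lethality.shape[1] - 1
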