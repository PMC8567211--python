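import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hehrisk import discovery as D
from hehrisk.simulate import Block, SimulationConfig, default_config, generate_cohort


def test_enumerate_subsets_counts_and_order():
    assert sum(1 for _ in D.enumerate_subsets([str(i) for i in range(1, 11)], 4)) == math.comb(10, 4)
    cands = ("5", "17", "18", "20")
    assert list(D.enumerate_subsets(cands, 4)) == [cands]
    assert list(D.enumerate_subsets(cands, 1)) == [("5",), ("17",), ("18",), ("20",)]
    with pytest.raises(ValueError):
        list(D.enumerate_subsets(cands, 5))
    with pytest.raises(ValueError):
        list(D.enumerate_subsets(cands, 0))


def test_plateau_choice_stopping_rule():
    cs = [0.60, 0.62, 0.635, 0.640, 0.641, 0.641]
    assert D.plateau_choice(cs, 0.005) == 4
    assert D.plateau_choice(cs, 1.0) == 1
    assert D.plateau_choice([0.6, 0.7, 0.8], 0.005) == 3  # never plateaus


def _toy_gains(n=400, p=5, seed=0):
    rng = np.random.default_rng(seed)
    cols = {f"gain_{i}": rng.binomial(1, 0.4, n) for i in ["5", "11", "17", "18", "20"][:p]}
    return pd.DataFrame(cols), rng


def test_mallows_cp_full_subset_identity():
    gains, rng = _toy_gains()
    y = rng.binomial(1, 0.3, len(gains))
    cands = ["5", "11", "17", "18", "20"]
    ranked = D.best_subset_cp(gains, y, k=5, candidates=cands)
    assert len(ranked) == 1
    assert ranked.loc[0, "cp"] == pytest.approx(len(cands) + 1)


def test_best_subset_cp_recovers_planted_signal():
    gains, rng = _toy_gains(n=600, seed=1)
    x5 = gains["gain_5"].to_numpy()
    x18 = gains["gain_18"].to_numpy()
    y = np.clip(x5 + x18 + rng.normal(0, 0.1, len(gains)), None, None)
    ranked = D.best_subset_cp(gains, y, k=2, candidates=["5", "11", "17", "18", "20"])
    assert tuple(ranked.loc[0, "subset"]) == ("5", "18")


def test_best_subset_cp_singular_full_model_errors():
    gains, rng = _toy_gains(n=200, seed=2)
    gains["gain_11"] = gains["gain_5"]  # aliased column
    y = rng.binomial(1, 0.3, len(gains))
    with pytest.raises(ValueError, match="aliased"):
        D.best_subset_cp(gains, y, k=2, candidates=["5", "11", "17", "18", "20"])


def test_screen_trisomies_skips_constant_and_flags_planted(cohort2000):
    cohort, _ = cohort2000
    df = cohort.copy()
    df["gain_Y"] = 1  # constant column
    with pytest.warns(UserWarning, match="constant"):
        tab = D.screen_trisomies(df, df, which=("relapse",))
    assert "Y" not in set(tab["chromosome"])
    sig = set(tab.loc[tab["significant"], "chromosome"])
    assert {"17", "18"} <= sig  # strongest planted effects


def test_stepwise_bic_equals_exhaustive_oracle(cohort2000):
    cohort, _ = cohort2000
    cands = ["5", "11", "17", "18", "20"]
    step = D.stepwise_bic(cohort, cohort, candidates=cands)
    exhaustive_subset, exhaustive_bic = D.exhaustive_best_bic(cohort, cohort, cands)
    assert step.chosen_subset == exhaustive_subset
    assert step.bic_trace[-1][1] == pytest.approx(exhaustive_bic, abs=1e-6)


def test_stepwise_bic_null_simulation_is_parsimonious():
    rng = np.random.default_rng(11)
    n = 800
    gains = pd.DataFrame({f"gain_{c}": rng.binomial(1, 0.3, n) for c in ["5", "17", "18", "20"]})
    gains["time_relapse"] = rng.exponential(20, n)
    gains["ind_relapse"] = rng.binomial(1, 0.4, n)
    with pytest.warns(UserWarning, match="null"):
        res = D.stepwise_bic(gains, gains, candidates=["5", "17", "18", "20"])
    assert res.chosen_subset == ()


def test_select_subset_size_invariant_to_column_order(cohort2000):
    cohort, _ = cohort2000
    cands = ["5", "11", "17", "18", "20"]
    a = D.select_subset_size(cohort, cohort, candidates=cands)
    shuffled = cohort[list(cohort.columns[::-1])]
    b = D.select_subset_size(shuffled, shuffled, candidates=cands[::-1])
    assert a.chosen_k == b.chosen_k
    assert a.chosen_subset == b.chosen_subset


def test_cluster_gains_identical_columns_cluster_together():
    rng = np.random.default_rng(4)
    n = 500
    base = rng.binomial(1, 0.5, n)
    df = pd.DataFrame({
        "gain_4": base, "gain_10": base,  # always co-gained
        "gain_5": rng.binomial(1, 0.5, n),
        "gain_20": rng.binomial(1, 0.5, n),
    })
    for g in (2, 3):
        res = D.cluster_gains(df, None, n_groups=g)
        assert res.assignment["4"] == res.assignment["10"]
    with pytest.raises(ValueError):
        D.cluster_gains(df, None, n_groups=10)


def test_cluster_gains_recovers_planted_blocks():
    from sklearn.metrics import adjusted_rand_score

    chroms = [str(i) for i in range(1, 13)]
    blocks = tuple(Block(tuple(chroms[i * 4:(i + 1) * 4]), 0.6) for i in range(3))
    gp = {c: 0.35 for c in chroms}
    cfg = SimulationConfig(n=1500, seed=21, gain_prob=gp, blocks=blocks,
                           modal_range=(46, 70))
    cohort, _ = generate_cohort(cfg)
    sub = cohort[[f"gain_{c}" for c in chroms] + ["time_relapse", "ind_relapse"]]
    res = D.cluster_gains(sub, sub, n_groups=3)
    truth = [i // 4 for i in range(12)]
    pred = [res.assignment[c] for c in chroms]
    assert adjusted_rand_score(truth, pred) >= 0.9
    assert res.stable


def test_derive_rule_recovers_published_profile(cohort5000):
    cohort, _ = cohort5000
    derived = D.derive_rule(cohort, cohort)
    assert D.rule_equivalent_to_published(derived.rule)
    # the pattern table partitions the cohort
    assert derived.pattern_table["n"].sum() == len(cohort)


def test_derive_rule_degenerate_inputs():
    n = 200
    rng = np.random.default_rng(9)
    df = pd.DataFrame({f"gain_{c}": rng.binomial(1, 0.5, n) for c in ("5", "17", "18", "20")})
    df["time_relapse"] = rng.uniform(5, 12, n)
    df["ind_relapse"] = 0  # no events: every pattern rate is exactly 0
    with pytest.raises(ValueError, match="no discriminating rule"):
        D.derive_rule(df, df)

    single = pd.DataFrame({f"gain_{c}": np.ones(50, dtype=int) for c in ("5", "17", "18", "20")})
    single["time_relapse"] = 1.0
    single["ind_relapse"] = 1
    with pytest.raises(ValueError, match="one trisomy pattern"):
        D.derive_rule(single, single)


def test_published_rule_object_matches_classifier():
    assert D.rule_equivalent_to_published(D.PUBLISHED_RULE)


def test_poisson_two_cluster_prefers_likelihood_over_distance():
    # a mid-size pattern whose crude rate sits below the arithmetic
    # midpoint but is far more likely under the high-rate regime
    events = np.array([5, 40, 9, 30])
    ptime = np.array([1000, 8000, 520, 1800])  # rates .005 .005 .017 .017
    high = D._poisson_two_cluster(events, ptime)
    assert list(high) == [False, False, True, True]


def test_boolean_rule_evaluation_and_dnf():
    rule = D.PUBLISHED_RULE
    assert rule.evaluate({"17", "18", "5"})
    assert not rule.evaluate({"17", "5"})
    assert "+17" in rule.to_dnf()
    assert rule.n_literals == 8
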