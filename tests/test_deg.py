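"""DEG calling, priority score, concordance partition, cell-fraction ANOVA."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hyp

from scdimorph.deg import (cell_fraction_anova, classify_concordance,
                           priority_score, wilcoxon_deg)
from scdimorph.preprocess import lognormalize
from .conftest import make_cohort


def _two_group_cohort(xa: np.ndarray, xb: np.ndarray):
    counts = np.vstack([xa, xb])
    cohort = make_cohort(counts)
    norm = lognormalize(cohort)
    ga = np.arange(counts.shape[0]) < xa.shape[0]
    return norm, ga, ~ga


def test_priority_score_formula():
    assert priority_score(2.0, 1e-10) == pytest.approx(20.0)
    assert priority_score(1.0, 1.0) == pytest.approx(0.0, abs=1e-12)
    assert priority_score(1.5, 0.0) == pytest.approx(450.0)


def test_low_expression_genes_are_not_tested():
    rng = np.random.default_rng(0)
    n = 100
    counts = rng.poisson(2.0, size=(2 * n, 3)).astype(float)
    counts[:, 1] = 0.0
    counts[rng.choice(2 * n, size=8, replace=False), 1] = 1.0  # 4% expressed
    counts[:, 2] += 1  # keep totals positive
    norm, ga, gb = _two_group_cohort(counts[:n], counts[n:])
    table = wilcoxon_deg(norm, ga, gb)
    assert "g1" not in set(table["gene"])
    assert table.attrs["n_tested"] == len(table)


def test_exclusion_list_is_dropped_before_testing():
    rng = np.random.default_rng(1)
    counts = rng.poisson(3.0, size=(40, 4)).astype(float) + 1
    cohort = make_cohort(counts)
    cohort.var_names = ["Gm42418", "AY036118", "Actb", "Lifr"]
    norm = lognormalize(cohort)
    ga = np.arange(40) < 20
    table = wilcoxon_deg(norm, ga, ~ga)
    assert set(table["gene"]) == {"Actb", "Lifr"}
    assert table.attrs["n_tested"] == 2  # Bonferroni n counts tested genes only


def test_fully_separated_3v3_gets_exact_two_sided_p():
    """All C(6,3)=20 assignments; only the true split and its mirror are as
    extreme, so the exact two-sided p is 2/20 = 0.1."""
    xa = np.array([[10.0], [11.0], [12.0]]) * np.ones((1, 1))
    xb = np.array([[1.0], [2.0], [3.0]])
    pad = np.ones((3, 1))  # second gene to keep normalization sane
    norm, ga, gb = _two_group_cohort(np.hstack([xa, pad]), np.hstack([xb, pad]))
    table = wilcoxon_deg(norm, ga, gb, min_pct=0.0)
    assert table.set_index("gene").at["g0", "p"] == pytest.approx(2 / 20)


def test_null_p_values_are_uniform_large_groups():
    rng = np.random.default_rng(3)
    counts = rng.poisson(4.0, size=(200, 150)).astype(float)
    norm, ga, gb = _two_group_cohort(counts[:100], counts[100:])
    table = wilcoxon_deg(norm, ga, gb)
    assert st.kstest(table["p"], "uniform").pvalue > 0.01


def test_wilcoxon_invariant_under_monotone_transform():
    rng = np.random.default_rng(4)
    counts = rng.poisson(5.0, size=(60, 10)).astype(float)
    norm, ga, gb = _two_group_cohort(counts[:30], counts[30:])
    p1 = wilcoxon_deg(norm, ga, gb)["p"].to_numpy()
    monotone = norm.copy()
    monotone.X = norm.X.copy()
    monotone.X.data = monotone.X.data / (1 + monotone.X.data)  # strictly increasing
    p2 = wilcoxon_deg(monotone, ga, gb)["p"].to_numpy()
    np.testing.assert_allclose(p1, p2, atol=1e-12)


def test_direction_is_treatment_minus_vehicle():
    up = np.hstack([np.full((20, 1), 9.0), np.ones((20, 1))])
    down = np.hstack([np.full((20, 1), 1.0), np.ones((20, 1))])
    norm, ga, gb = _two_group_cohort(up, down)
    table = wilcoxon_deg(norm, ga, gb, min_pct=0.0).set_index("gene")
    assert table.at["g0", "direction"] == "up"
    assert table.at["g0", "avg_log2fc"] > 0


def _deg_frame(rows):
    df = pd.DataFrame(rows, columns=["gene", "direction", "priority"])
    df["significant"] = True
    return df


def test_concordance_partition_examples():
    xx = _deg_frame([("a", "up", 5.0), ("b", "down", 4.0), ("c", "up", 3.0),
                     ("d", "down", 2.0)])
    xy = _deg_frame([("a", "up", 1.0), ("d", "up", 9.0), ("e", "down", 2.0)])
    sets = classify_concordance(xx, xy).sets
    assert sets["concordant_up"] == ["a"]
    assert sets["xx_only_down"] == ["b"]
    assert sets["xx_only_up"] == ["c"]
    assert sets["discordant_down_xx_up_xy"] == ["d"]
    assert sets["xy_only_down"] == ["e"]


def test_concordance_orders_by_max_priority_and_reports_top_k():
    xx = _deg_frame([(f"g{i}", "up", float(i)) for i in range(15)])
    xy = _deg_frame([(f"g{i}", "up", 100.0 if i == 0 else 0.0) for i in range(15)])
    cs = classify_concordance(xx, xy)
    assert cs.sets["concordant_up"][0] == "g0"       # max across sexes wins
    assert len(cs.top["concordant_up"]) == 10


def test_concordance_rejects_duplicate_gene():
    xx = _deg_frame([("a", "up", 1.0), ("a", "down", 2.0)])
    with pytest.raises(ValueError, match="duplicated gene 'a'"):
        classify_concordance(xx, _deg_frame([]))


@settings(max_examples=40, deadline=None)
@given(hyp.lists(hyp.tuples(hyp.sampled_from("abcdefgh"),
                            hyp.sampled_from(["up", "down"])),
                 unique_by=lambda t: t[0], max_size=8),
       hyp.lists(hyp.tuples(hyp.sampled_from("abcdefgh"),
                            hyp.sampled_from(["up", "down"])),
                 unique_by=lambda t: t[0], max_size=8))
def test_concordance_partition_is_exhaustive_and_disjoint(xx_rows, xy_rows):
    xx = _deg_frame([(g, d, 1.0) for g, d in xx_rows])
    xy = _deg_frame([(g, d, 1.0) for g, d in xy_rows])
    sets = classify_concordance(xx, xy).sets
    everything = list(itertools.chain.from_iterable(sets.values()))
    assert len(everything) == len(set(everything))
    assert set(everything) == {g for g, _ in xx_rows} | {g for g, _ in xy_rows}


def _fractions(arm_means, sd=0.0, n=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for (sex, trt), mu in arm_means.items():
        for i in range(n):
            rows.append({"sample_id": f"{sex}{trt}{i}", "sex": sex, "treatment": trt,
                         "cell_type": "A",
                         "fraction": mu + (rng.normal(0, sd) if sd else 0.0)})
    return pd.DataFrame(rows)


def test_anova_identical_fractions_give_f_zero_p_one():
    frac = _fractions({("XX", "E2"): 10, ("XX", "V"): 10,
                       ("XY", "E2"): 10, ("XY", "V"): 10})
    anova, _ = cell_fraction_anova(frac)
    assert (anova["F"] == 0).all()
    assert (anova["p"] == 1).all()


def test_anova_pure_interaction_recovers_large_f_and_eta():
    frac = _fractions({("XX", "E2"): 20, ("XX", "V"): 10,
                       ("XY", "E2"): 10, ("XY", "V"): 10}, sd=1e-3, seed=1)
    anova, tukey = cell_fraction_anova(frac)
    inter = anova[anova["effect"] == "sex:treatment"].iloc[0]
    assert inter["p"] < 1e-6
    assert inter["partial_eta_sq"] > 0.99
    # the lone elevated arm drives its pairwise Tukey comparisons
    xxe = tukey[(tukey["group1"] == "XXE2") | (tukey["group2"] == "XXE2")]
    assert (xxe["p_adj"] < 0.01).all()


def test_anova_interaction_null_when_effect_is_additive():
    ps = []
    for seed in range(40):
        frac = _fractions({("XX", "E2"): 15, ("XX", "V"): 10,
                           ("XY", "E2"): 15, ("XY", "V"): 10}, sd=2.0, seed=seed)
        anova, _ = cell_fraction_anova(frac)
        ps.append(anova.set_index("effect").at["sex:treatment", "p"])
    assert st.kstest(ps, "uniform").pvalue > 0.01


def test_anova_rejects_missing_arm():
    frac = _fractions({("XX", "E2"): 10, ("XX", "V"): 10, ("XY", "E2"): 10})
    with pytest.raises(ValueError, match="arms"):
        cell_fraction_anova(frac)
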