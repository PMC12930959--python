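"""The synthetic generators must honour their planted ground truth."""

import numpy as np
import pytest
import scipy.stats as st

from scdimorph.simulate import (DegEffect, ShiftSpec, SimConfig, generate_cohort,
                                generate_grn, generate_marker_table)


def test_same_seed_gives_bit_identical_cohorts():
    cfg = SimConfig(seed=5, cell_types=("A",), cells_per_group=20, n_genes=100)
    a, b = generate_cohort(cfg), generate_cohort(cfg)
    assert (a.X != b.X).nnz == 0
    assert a.obs.equals(b.obs)


def test_different_seeds_differ():
    a = generate_cohort(SimConfig(seed=1, cell_types=("A",), cells_per_group=20, n_genes=100))
    b = generate_cohort(SimConfig(seed=2, cell_types=("A",), cells_per_group=20, n_genes=100))
    assert (a.X != b.X).nnz > 0


def test_null_cohort_group_means_differ_only_by_noise():
    """With no planted effect, per-gene t-tests between arms give uniform p."""
    cfg = SimConfig(seed=3, cell_types=("A",), cells_per_group=100, n_genes=300,
                    nb_mean_range=(1, 10), mito_gene_fraction=0.0,
                    damaged_cell_fraction=0.0)
    c = generate_cohort(cfg)
    x = np.log1p(c.X.toarray())
    e2 = (c.obs["treatment"] == "E2").to_numpy() & (c.obs["sex"] == "XX").to_numpy()
    v = (c.obs["treatment"] == "V").to_numpy() & (c.obs["sex"] == "XX").to_numpy()
    p = st.ttest_ind(x[e2], x[v], axis=0).pvalue
    assert st.kstest(p, "uniform").pvalue > 0.01


def test_planted_shift_moves_log_means_by_delta_sd():
    """E2-V mean log-expression gap over shifted genes matches delta*SD within 10%;
    the untargeted sex stays at zero."""
    cfg = SimConfig(seed=4, cell_types=("ASPC",), cells_per_group=500, n_genes=400,
                    nb_mean_range=(10, 50), mito_gene_fraction=0.0,
                    damaged_cell_fraction=0.0, library_size_cv=0.0,
                    shift=ShiftSpec(cell_types=("ASPC",), sex="XX",
                                    n_genes=200, delta=1.0))
    c = generate_cohort(cfg)
    truth = c.uns["truth"]["shift"]
    gidx = c.var_names.get_indexer(truth["gene"])
    x = np.log1p(c.X.toarray())

    def gap(sex):
        a = (c.obs["sex"] == sex) & (c.obs["treatment"] == "E2")
        b = (c.obs["sex"] == sex) & (c.obs["treatment"] == "V")
        return (x[a.to_numpy()][:, gidx].mean(0) - x[b.to_numpy()][:, gidx].mean(0))

    planted = truth["delta"].to_numpy() * truth["log_sd"].to_numpy()
    assert gap("XX").mean() == pytest.approx(planted.mean(), rel=0.10)
    assert abs(gap("XY").mean()) < 0.1 * planted.mean()


def test_truth_records_count_matches_applied_effects():
    effects = tuple(DegEffect(f"g{i:05d}", "A", "XX", 1.0) for i in range(10, 20))
    cfg = SimConfig(seed=1, cell_types=("A", "B"), cells_per_group=10, n_genes=100,
                    deg_effects=effects,
                    shift=ShiftSpec(cell_types=("A",), sex="XY", n_genes=7, delta=0.5))
    c = generate_cohort(cfg)
    assert len(c.uns["truth"]["deg"]) == len(effects)
    assert len(c.uns["truth"]["shift"]) == 7


def test_conflicting_deg_effects_rejected():
    dup = (DegEffect("g00010", "A", "XX", 1.0), DegEffect("g00010", "A", "XX", -1.0))
    with pytest.raises(ValueError, match="g00010"):
        SimConfig(cell_types=("A",), deg_effects=dup)


@pytest.mark.parametrize("bad", [
    dict(cells_per_group=0),
    dict(mito_gene_fraction=1.5),
    dict(nb_dispersion=-1.0),
])
def test_invalid_config_rejected(bad):
    with pytest.raises(ValueError):
        SimConfig(cell_types=("A",), **bad)


def test_grn_hub_degree_and_planted_enrichment():
    """Neighbour DEG count behaves as Binomial(n_neighbors, p_hub) across seeds."""
    hits = []
    for seed in range(30):
        g, degs, hub = generate_grn(
            300, {"n_neighbors": 50, "deg_fraction_in_neighborhood": 0.8,
                  "background_deg_fraction": 0.1}, seed=seed)
        assert g.degree(hub) == 50
        hits.append(len(set(g.neighbors(hub)) & degs))
    # mean within 4 SE of 40, variance sane for Binomial(50, 0.8)
    se = np.sqrt(50 * 0.8 * 0.2 / len(hits))
    assert abs(np.mean(hits) - 40) < 4 * se


def test_grn_no_enrichment_when_rates_equal():
    g, degs, hub = generate_grn(
        400, {"n_neighbors": 60, "deg_fraction_in_neighborhood": 0.25,
              "background_deg_fraction": 0.25}, seed=7)
    rate_nb = len(set(g.neighbors(hub)) & degs) / 60
    # binomial 99% CI around 0.25 at n=60
    assert abs(rate_nb - 0.25) < 2.6 * np.sqrt(0.25 * 0.75 / 60)


def test_grn_rejects_hub_as_large_as_graph():
    with pytest.raises(ValueError):
        generate_grn(50, {"n_neighbors": 50, "deg_fraction_in_neighborhood": 0.5,
                          "background_deg_fraction": 0.1}, seed=0)


def test_marker_table_null_scores_indistinguishable():
    mt = generate_marker_table(100, 5, 1, enriched_set=[f"g{i:05d}" for i in range(30)],
                               enrichment_shift=0.0, seed=2)
    t = mt.table
    enriched = t["gene"].isin({f"g{i:05d}" for i in range(30)})
    ks = st.ks_2samp(t.loc[enriched, "score"], t.loc[~enriched, "score"])
    assert ks.pvalue > 0.01


def test_marker_table_planted_enrichment_raises_median():
    enriched = [f"g{i:05d}" for i in range(50)]
    mt = generate_marker_table(200, 4, 2, enriched_set=enriched,
                               enrichment_shift=4.0, seed=3)
    t = mt.table
    m = t["gene"].isin(set(enriched))
    assert t.loc[m, "score"].median() > t.loc[~m, "score"].median()


def test_marker_table_ld_blocks_have_high_r2():
    mt = generate_marker_table(20, 4, 2, seed=1)
    assert all(v > 0.7 for v in mt.r2.values())
    # singleton blocks carry no pairs
    mt1 = generate_marker_table(20, 3, 1, seed=1)
    assert not mt1.r2


def test_marker_table_rejects_bad_block_size():
    with pytest.raises(ValueError):
        generate_marker_table(10, 2, 0, seed=0)
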