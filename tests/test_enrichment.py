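"""Hypergeometric enrichment, ER-target partition, LD pruning, and MSEA."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from scdimorph.enrichment import (GeneSetLibrary, er_target_partition,
                                  hypergeom_enrich, mdf_prune, msea, msea_scan)
from scdimorph.simulate import MarkerTable, generate_marker_table


def tail_oracle(k, n, big_k, little_n):
    return sum(comb(big_k, i) * comb(n - big_k, little_n - i)
               for i in range(k, min(big_k, little_n) + 1)) / comb(n, little_n)


def _library(universe_size, set_sizes):
    genes = [f"g{i}" for i in range(universe_size)]
    sets = {f"s{j}": genes[:size] for j, size in enumerate(set_sizes)}
    return genes, GeneSetLibrary(sets=sets, background=universe_size,
                                 universe=set(genes))


def test_hypergeom_p_matches_enumeration_oracle():
    genes, lib = _library(20, [5])
    query = genes[:3] + [genes[10]]          # k=3 of K=5, n=4, N=20
    rec = hypergeom_enrich(query, lib, mode="pathway").iloc[0]
    expected = (comb(5, 3) * comb(15, 1) + comb(5, 4)) / comb(20, 4)
    assert rec["p"] == pytest.approx(expected, abs=1e-12)
    assert rec["p"] == pytest.approx(tail_oracle(3, 20, 5, 4), abs=1e-12)
    assert rec["enrichment_score"] == pytest.approx(3.0)


def test_hypergeom_random_instances_match_oracle():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(5, 31))
        big_k = int(rng.integers(1, n + 1))
        little_n = int(rng.integers(1, n + 1))
        k = int(rng.integers(max(0, little_n + big_k - n), min(big_k, little_n) + 1))
        genes = [f"g{i}" for i in range(n)]
        lib = GeneSetLibrary(sets={"s": genes[:big_k]}, background=n,
                             universe=set(genes))
        query = genes[:k] + genes[big_k:big_k + (little_n - k)]
        rec = hypergeom_enrich(query, lib, mode="tf").iloc[0]
        assert rec["overlap"] == k
        assert rec["p"] == pytest.approx(tail_oracle(k, n, big_k, little_n),
                                         abs=1e-12)


def test_hypergeom_monotone_in_overlap():
    genes = [f"g{i}" for i in range(30)]
    lib = GeneSetLibrary(sets={"s": genes[:10]}, background=30,
                         universe=set(genes))
    ps = []
    for k in range(0, 9):
        query = genes[:k] + genes[10:10 + (8 - k)]
        ps.append(hypergeom_enrich(query, lib, mode="tf").iloc[0]["p"])
    assert all(ps[i + 1] <= ps[i] + 1e-15 for i in range(len(ps) - 1))


def test_pathway_pass_requires_min_overlap_even_when_significant():
    genes, lib = _library(2000, [12])
    rec = hypergeom_enrich(genes[:12], lib, mode="pathway").iloc[0]
    assert rec["p_adj"] < 1e-6 and rec["overlap"] == 12
    assert not rec["pass"]                       # k < 20 blocks the call
    tf = hypergeom_enrich(genes[:12], lib, mode="tf").iloc[0]
    assert tf["pass"]                            # TF mode has no overlap floor


def test_query_outside_universe_dropped_with_warning():
    genes, lib = _library(20, [5])
    with pytest.warns(UserWarning, match="dropped 2"):
        out = hypergeom_enrich(genes[:3] + ["alien1", "alien2"], lib, mode="tf")
    assert out.iloc[0]["query_size"] == 3
    with pytest.raises(ValueError, match="empty query"):
        hypergeom_enrich([], lib)


def test_er_target_partition_fractions():
    assert er_target_partition(["a", "b"], ["x"])["fraction_direct"] == 0.0
    assert er_target_partition(["a", "b"], ["a", "b", "c"])["fraction_direct"] == 1.0
    enriched = [f"tf{i}" for i in range(235)]
    res = er_target_partition(enriched, enriched[:38])
    assert res["fraction_direct"] == pytest.approx(38 / 235)
    assert len(res["direct"]) + len(res["indirect"]) == 235


def _two_marker_table(r2):
    table = pd.DataFrame({
        "marker_id": ["m1", "m2"], "gene": ["gA", "gA"],
        "score": [3.0, 1.0], "block_id": ["b0", "b0"]})
    return MarkerTable(table=table, r2={frozenset(("m1", "m2")): r2})


def test_mdf_prune_drops_linked_keeps_unlinked():
    kept = mdf_prune(_two_marker_table(0.8)).table
    assert list(kept["marker_id"]) == ["m1"]     # higher score wins
    kept = mdf_prune(_two_marker_table(0.5)).table
    assert sorted(kept["marker_id"]) == ["m1", "m2"]


def test_mdf_prune_identity_on_singleton_blocks():
    mt = generate_marker_table(30, 3, 1, seed=0)
    assert len(mdf_prune(mt).table) == len(mt.table)


def test_mdf_prune_order_invariant_and_errors_on_missing_r2():
    mt = generate_marker_table(40, 4, 2, seed=5)
    shuffled = MarkerTable(table=mt.table.sample(frac=1, random_state=1), r2=mt.r2)
    a = sorted(mdf_prune(mt).table["marker_id"])
    b = sorted(mdf_prune(shuffled).table["marker_id"])
    assert a == b
    broken = MarkerTable(table=mt.table, r2={})
    with pytest.raises(ValueError, match="missing r2"):
        mdf_prune(broken)


def test_msea_self_comparison_is_exactly_zero():
    mt = generate_marker_table(100, 3, 1, seed=2)
    res = msea(sorted(set(mt.table["gene"])), mt, n_perm=10, seed=0)
    assert res.statistic == 0.0


def test_msea_p_respects_add_one_floor():
    enriched = [f"g{i:05d}" for i in range(40)]
    mt = generate_marker_table(150, 4, 1, enriched_set=enriched,
                               enrichment_shift=6.0, seed=3)
    res = msea(enriched, mt, n_perm=200, seed=1)
    assert res.p >= 1 / 201
    assert res.p < 0.05
    assert res.statistic > 0


def test_msea_null_statistic_centred_and_p_uniform_ish():
    stats, ps = [], []
    for seed in range(25):
        mt = generate_marker_table(120, 3, 1, seed=seed)
        rng = np.random.default_rng(seed + 1000)
        genes = sorted(set(mt.table["gene"]))
        pick = sorted(rng.choice(genes, size=30, replace=False))
        res = msea(pick, mt, n_perm=200, seed=seed)
        stats.append(res.statistic)
        ps.append(res.p)
    assert abs(np.mean(stats)) < 1.0            # X ~ 0 in expectation
    assert 0.3 < np.mean(ps) < 0.7


def test_msea_scan_applies_bh_across_sets():
    enriched = [f"g{i:05d}" for i in range(40)]
    mt = generate_marker_table(150, 4, 1, enriched_set=enriched,
                               enrichment_shift=6.0, seed=9)
    rng = np.random.default_rng(0)
    genes = sorted(set(mt.table["gene"]))
    sets = {"planted": enriched}
    for j in range(4):
        sets[f"rand{j}"] = sorted(rng.choice(genes, size=40, replace=False))
    out = msea_scan(sets, mt, n_perm=300, seed=4)
    assert bool(out.set_index("gene_set").at["planted", "significant"])


def test_msea_errors_when_no_genes_map():
    mt = generate_marker_table(20, 2, 1, seed=0)
    with pytest.raises(ValueError, match="marker mapping"):
        msea(["nope"], mt, n_perm=10)
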