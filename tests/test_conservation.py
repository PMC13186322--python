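"""Rank-sum marker testing, BH correction, and multi-species intersections."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from orthocell import (OrthogroupTable, conserved_deg_orthogroups,
                       ingroup_outgroup_test, marker_intersections,
                       rank_sum_test, shared_markers)
from orthocell.conservation import group_pvalues


class TestRankSum:
    def test_exact_p_on_separated_3v3(self):
        # U = 9, exact two-sided p = 2 * 1/20 = 0.1
        assert rank_sum_test([5, 6, 7], [1, 2, 3]) == pytest.approx(0.1)

    def test_exact_matches_enumeration_oracle(self):
        # enumerate all C(6,3)=20 assignments of ranks to the ingroup
        x, y = [5.0, 6.0, 7.0], [1.0, 2.0, 3.0]
        pooled = sorted(x + y)
        u_obs = sum(1 for xi in x for yi in y if xi > yi)
        n = len(pooled)
        count_extreme = 0
        total = 0
        for combo in itertools.combinations(range(n), 3):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(n) if i not in combo]
            u = sum(1 for xi in xs for yi in ys if xi > yi)
            total += 1
            if abs(u - 4.5) >= abs(u_obs - 4.5):
                count_extreme += 1
        assert rank_sum_test(x, y) == pytest.approx(count_extreme / total)

    def test_all_tied_returns_one(self):
        assert rank_sum_test([2, 2, 2], [2, 2, 2]) == 1.0

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(400):
            x = rng.normal(size=12)
            y = rng.normal(size=15)
            pvals.append(rank_sum_test(x, y))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3

    def test_anndata_wrapper(self, adata_factory):
        counts = np.array([[5.0, 6.0, 7.0, 1.0, 2.0, 3.0]])
        adata = adata_factory(counts, genes=["OG1"],
                              cell_types=["in"] * 3 + ["out"] * 3)
        assert ingroup_outgroup_test(adata, "OG1", ["in"]) == pytest.approx(0.1)


class TestSharedMarkers:
    @pytest.fixture
    def two_species(self, adata_factory):
        rng = np.random.default_rng(23)
        ogs = [f"OG{i}" for i in range(30)]
        mats, fcs = {}, {}
        for s in ("spA", "spB"):
            base = rng.poisson(5.0, size=(30, 40)).astype(float)
            base[:5, :20] += 30.0  # OG0..OG4 strongly up in type P
            adata = adata_factory(base, genes=ogs,
                                  cell_types=["P"] * 20 + ["Q"] * 20)
            mats[s] = adata
            means = pd.DataFrame(
                {ct: base[:, np.array(adata.obs["cell_type"] == ct)].mean(axis=1)
                 for ct in ("P", "Q")}, index=ogs)
            fcs[s] = (means + 0.05).div(means.median(axis=1) + 0.05, axis=0)
        return mats, fcs

    def test_planted_markers_called_shared(self, two_species):
        mats, fcs = two_species
        calls = shared_markers(fcs["spA"], fcs["spB"], ("P", "P"),
                               mats["spA"], mats["spB"])
        shared = set(calls.loc[calls["shared"], "og"])
        assert {"OG0", "OG1", "OG2", "OG3", "OG4"} <= shared

    def test_one_sided_fc_failure_never_shared(self, two_species):
        mats, fcs = two_species
        fcs = {k: v.copy() for k, v in fcs.items()}
        fcs["spB"].loc["OG0", "P"] = 1.05
        calls = shared_markers(fcs["spA"], fcs["spB"], ("P", "P"),
                               mats["spA"], mats["spB"])
        row = calls.set_index("og").loc["OG0"]
        assert not row["shared"]

    def test_shrinks_as_thresholds_tighten(self, two_species):
        mats, fcs = two_species
        loose = shared_markers(fcs["spA"], fcs["spB"], ("P", "P"),
                               mats["spA"], mats["spB"], fc_min=1.1, fdr=0.05)
        tight_fc = shared_markers(fcs["spA"], fcs["spB"], ("P", "P"),
                                  mats["spA"], mats["spB"], fc_min=3.0,
                                  fdr=0.05)
        tight_fdr = shared_markers(fcs["spA"], fcs["spB"], ("P", "P"),
                                   mats["spA"], mats["spB"], fc_min=1.1,
                                   fdr=1e-6)
        s0 = set(loose.loc[loose["shared"], "og"])
        assert set(tight_fc.loc[tight_fc["shared"], "og"]) <= s0
        assert set(tight_fdr.loc[tight_fdr["shared"], "og"]) <= s0


def test_bh_qvalues_monotone_in_pvalue_rank():
    rng = np.random.default_rng(31)
    p = rng.random(200)
    q = multipletests(p, method="fdr_bh")[1]
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()


def test_group_pvalues_match_scalar_path(adata_factory):
    rng = np.random.default_rng(37)
    counts = rng.poisson(3.0, size=(6, 50)).astype(float)
    adata = adata_factory(counts, genes=[f"OG{i}" for i in range(6)],
                          cell_types=["in"] * 25 + ["out"] * 25)
    vec = group_pvalues(adata, ["in"])
    for og in adata.var_names:
        assert vec[og] == pytest.approx(
            ingroup_outgroup_test(adata, og, ["in"]), rel=1e-9)


class TestIntersections:
    def test_core_of_three_sets(self):
        report = marker_intersections(
            {"s1": {"a", "b", "c"}, "s2": {"b", "c"}, "s3": {"b", "c", "d"}}
        )
        assert report.core_set == {"b", "c"}

    def test_disjoint_sets_empty_core(self):
        report = marker_intersections({"s1": {"a"}, "s2": {"b"}})
        assert report.core_set == frozenset()

    def test_upset_counts_match_pattern_oracle_and_sum_to_union(self):
        rng = np.random.default_rng(41)
        universe = [f"OG{i}" for i in range(60)]
        sets = {
            f"s{j}": {og for og in universe if rng.random() < 0.4}
            for j in range(6)
        }
        report = marker_intersections(sets)
        union = set().union(*sets.values())
        # brute-force per-element pattern tally
        tally: dict[frozenset, int] = {}
        for og in union:
            pat = frozenset(s for s, v in sets.items() if og in v)
            tally[pat] = tally.get(pat, 0) + 1
        assert {k: len(v) for k, v in report.combinations.items()} == tally
        assert sum(len(v) for v in report.combinations.values()) == len(union)


class TestConservedDEGs:
    @pytest.fixture
    def table(self):
        return OrthogroupTable(
            og_ids=("OG1", "OG2"),
            membership={
                "OG1": {"s1": ("a1",), "s2": ("b1",), "s3": ("c1",)},
                "OG2": {"s1": ("a2",), "s2": ("b2",), "s3": ("c2",)},
            },
            species=("s1", "s2", "s3"),
        )

    def test_min_species_counting(self, table):
        degs = {"s1": ["a1"], "s2": ["b1"], "s3": []}
        assert conserved_deg_orthogroups(degs, table, 2) == {"OG1"}
        assert conserved_deg_orthogroups(degs, table, 3) == frozenset()

    def test_empty_lists_empty_set(self, table):
        degs = {"s1": [], "s2": [], "s3": []}
        assert conserved_deg_orthogroups(degs, table, 1) == frozenset()

    def test_matches_counting_oracle_on_random_fixture(self):
        rng = np.random.default_rng(43)
        species = tuple(f"s{j}" for j in range(4))
        og_ids = tuple(f"OG{i}" for i in range(25))
        membership = {
            og: {s: (f"{s}_{og}",) for s in species} for og in og_ids
        }
        table = OrthogroupTable(og_ids, membership, species)
        degs = {
            s: [f"{s}_OG{i}" for i in range(25) if rng.random() < 0.3]
            + ["unmapped_gene"]
            for s in species
        }
        for min_species in (1, 2, 3, 4):
            expected = set()
            for og in og_ids:
                n = sum(f"{s}_{og}" in degs[s] for s in species)
                if n >= min_species:
                    expected.add(og)
            got = conserved_deg_orthogroups(degs, table, min_species)
            assert got == expected
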