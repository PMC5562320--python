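import numpy as np
import pytest

from chemscreen.index import ScreenInputs, build_index
from chemscreen.screening import (
    CompoundAssessment,
    PermutationConfig,
    apply_thresholds,
    association_test,
    assess,
    permute_pvalue,
    preliminary_screen,
    rating_score,
    select_thresholds,
)
from chemscreen.stitch_io import ChemicalLink, InteractionTables

from conftest import random_tables


def _link(a, b, combined):
    return ChemicalLink(a, b, 0, 0, 0, 0, combined)


class TestPreliminaryScreen:
    def test_union_of_drug_neighbors_minus_drugs(self):
        links = [_link(10, 1, 500), _link(10, 2, 500), _link(11, 2, 500), _link(11, 10, 500)]
        idx = build_index(InteractionTables(chemical_links=links))
        assert preliminary_screen(idx, {10, 11}) == {1, 2}

    def test_no_drug_neighbors_gives_empty_set(self):
        idx = build_index(InteractionTables(chemical_links=[_link(1, 2, 500)]))
        assert preliminary_screen(idx, {9}) == set()

    def test_empty_drug_set_rejected(self, index):
        with pytest.raises(ValueError):
            preliminary_screen(index, set())

    def test_matches_brute_force_scan(self):
        tables = random_tables(np.random.default_rng(21), n_compounds=50)
        idx = build_index(tables)
        drugs = {1, 2, 3}
        expected = {
            (l.chem_b if l.chem_a in drugs else l.chem_a)
            for l in tables.chemical_links
            if (l.chem_a in drugs) != (l.chem_b in drugs) and l.combined > 0
        }
        assert preliminary_screen(idx, drugs) == expected - drugs


class TestRatingScore:
    def test_mean_of_existing_links(self):
        links = [_link(9, 1, 300), _link(9, 2, 700), _link(9, 3, 800)]
        idx = build_index(InteractionTables(chemical_links=links))
        assert rating_score(9, {1, 2, 3}, idx) == 600.0

    def test_single_link(self):
        idx = build_index(InteractionTables(chemical_links=[_link(9, 1, 500)]))
        assert rating_score(9, {1, 2}, idx) == 500.0

    def test_no_links_is_zero(self):
        idx = build_index(InteractionTables(chemical_links=[_link(1, 2, 500)]))
        assert rating_score(9, {1, 2}, idx) == 0.0


class TestAssociationTest:
    def test_requires_both_channels(self, bundle, inputs, index):
        no_gene = bundle.compounds_with_fate("decoy_no_gene")
        kept = {a.compound for a in association_test(no_gene, inputs, index)}
        assert kept == set()

    def test_scores_recorded(self, bundle, inputs, index):
        pos = sorted(bundle.compounds_with_fate("positive"))
        out = association_test(pos, inputs, index)
        assert {a.compound for a in out} == set(pos)
        assert all(a.rs_chemicals > 0 and a.rs_genes > 0 for a in out)

    def test_planted_fates_drive_retention(self, bundle, inputs, index):
        cands = preliminary_screen(index, inputs.drugs)
        kept = {a.compound for a in association_test(cands, inputs, index)}
        assert bundle.compounds_with_fate("positive") <= kept
        assert not kept & bundle.compounds_with_fate("decoy_no_gene")

    def test_inert_drug_dropped_from_cohort(self, bundle, inputs, index):
        cohort = {a.compound for a in association_test(inputs.drugs, inputs, index)}
        inert = {d for d, role in bundle.drug_roles.items() if role == "inert"}
        assert cohort == set(inputs.drugs) - inert


class TestPermutePvalue:
    def _universe_index(self, scores):
        links = [_link(99, 1 + i, s) for i, s in enumerate(scores)]
        # connect universe members so they all appear in chemical_universe
        links += [_link(1 + i, 2 + i, 200) for i in range(len(scores) - 1)]
        return build_index(InteractionTables(chemical_links=links))

    def test_no_set_can_beat_uniform_maximum(self):
        idx = self._universe_index([700] * 8)
        cfg = PermutationConfig(universe=frozenset(range(1, 9)), n_permutations=500)
        assert permute_pvalue(99, 700.0, 3, cfg, idx) == 0.0

    def test_pvalue_is_multiple_of_permutation_fraction(self, index, inputs):
        cfg = PermutationConfig(universe=index.chemical_universe, n_permutations=200, seed=5)
        obs = rating_score(1101, inputs.disease_chemicals, index)
        p = permute_pvalue(1101, obs, len(inputs.disease_chemicals), cfg, index)
        assert abs(p * 200 - round(p * 200)) < 1e-9

    def test_fixed_seed_reproducible(self, index, inputs):
        cfg = PermutationConfig(universe=index.chemical_universe, n_permutations=300, seed=9)
        obs = rating_score(1001, inputs.disease_chemicals, index)
        p1 = permute_pvalue(1001, obs, 30, cfg, index)
        p2 = permute_pvalue(1001, obs, 30, cfg, index)
        assert p1 == p2

    def test_oversized_reference_rejected(self):
        idx = self._universe_index([500] * 5)
        cfg = PermutationConfig(universe=frozenset(range(1, 6)))
        with pytest.raises(ValueError, match="reference_size"):
            permute_pvalue(99, 1.0, 10, cfg, idx)

    def test_exhaustive_matches_monte_carlo(self):
        rng = np.random.default_rng(17)
        scores = [int(s) for s in rng.integers(150, 1000, size=12)]
        idx = self._universe_index(scores)
        universe = frozenset(range(1, 13))
        obs = rating_score(99, {1, 2, 3}, idx)
        p_ex = permute_pvalue(99, obs, 3, PermutationConfig(universe=universe, exhaustive=True), idx)
        p_mc = permute_pvalue(
            99, obs, 3,
            PermutationConfig(universe=universe, n_permutations=50_000, seed=2), idx,
        )
        se = np.sqrt(max(p_ex * (1 - p_ex), 1e-9) / 50_000)
        assert abs(p_mc - p_ex) <= 3 * se + 1e-9

    def test_observed_above_table_maximum_gives_zero(self, index, inputs):
        cfg = PermutationConfig(universe=index.chemical_universe, n_permutations=300)
        p = permute_pvalue(1001, 1000.5, len(inputs.disease_chemicals), cfg, index)
        assert p == 0.0

    def test_null_pvalues_center_near_half(self):
        """Compounds with i.i.d. link scores have P-values averaging ~0.5."""
        rng = np.random.default_rng(42)
        pvals = []
        for trial in range(150):
            scores = [int(s) for s in rng.integers(150, 1000, size=30)]
            idx = self._universe_index(scores)
            universe = frozenset(range(1, 31))
            ref = set(range(1, 9))
            obs = rating_score(99, ref, idx)
            cfg = PermutationConfig(universe=universe, n_permutations=200, seed=trial)
            pvals.append(permute_pvalue(99, obs, len(ref), cfg, idx))
        assert abs(float(np.mean(pvals)) - 0.5) < 0.05


class TestThresholds:
    def test_single_drug_is_identity(self):
        a = CompoundAssessment(1, 5.0, 5.0, 0.1, 0.2)
        assert select_thresholds([a]) == (0.1, 0.2)

    def test_all_zero_pvalues(self):
        rows = [CompoundAssessment(i, 5.0, 5.0, 0.0, 0.0) for i in range(3)]
        assert select_thresholds(rows) == (0.0, 0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_thresholds([])

    def test_boundary_is_inclusive(self):
        rows = [
            CompoundAssessment(1, 5.0, 5.0, 0.469, 0.292),
            CompoundAssessment(2, 5.0, 5.0, 0.470, 0.100),
        ]
        kept = apply_thresholds(rows, (0.469, 0.292))
        assert [a.compound for a in kept] == [1]

    def test_matches_brute_force_double_filter(self):
        rng = np.random.default_rng(8)
        rows = [
            CompoundAssessment(i, 5.0, 5.0,
                               float(rng.integers(0, 1001)) / 1000,
                               float(rng.integers(0, 1001)) / 1000)
            for i in range(200)
        ]
        thr = (0.3, 0.6)
        expected = [a for a in rows
                    if a.pvalue_chemicals <= thr[0] and a.pvalue_genes <= thr[1]]
        assert apply_thresholds(rows, thr) == expected


def test_pipeline_stage_monotonicity(bundle, inputs, index):
    """Each stage's survivors are a subset of the previous stage's."""
    step1 = preliminary_screen(index, inputs.drugs)
    step2a = {a.compound for a in association_test(step1, inputs, index)}
    assert step2a <= step1
    drugs = association_test(inputs.drugs, inputs, index)
    from chemscreen.screening import permute_assessments

    assessed = permute_assessments(
        association_test(step1, inputs, index), inputs, index,
        n_permutations=200, seed=1,
    )
    drugs = permute_assessments(drugs, inputs, index, n_permutations=200, seed=1)
    kept = {a.compound for a in apply_thresholds(assessed, select_thresholds(drugs))}
    assert kept <= step2a


def test_assess_matches_manual_means(index, inputs):
    c = sorted(inputs.disease_chemicals)[0]
    a = assess(1001, inputs, index)
    neigh = index.neighbors(1001)
    chem_scores = [neigh[s].combined for s in inputs.disease_chemicals if s in neigh]
    assert a.rs_chemicals == pytest.approx(np.mean(chem_scores))
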