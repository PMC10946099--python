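"""Index formulas: examples with independently computed expectations, plus
the structural invariants each index must satisfy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethnogarden import (
    CitationMatrix,
    Inventory,
    LandUseTable,
    SpeciesNotFoundError,
    jaccard_index,
    jaccard_matrix,
    land_use_degree,
    relative_importance,
    relative_importance_table,
    shannon_wiener,
    use_value,
    use_value_table,
)

from conftest import make_record

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


def _matrix(counts, species=None):
    counts = np.asarray(counts)
    return CitationMatrix(
        informants=tuple(f"i{r}" for r in range(counts.shape[0])),
        species=tuple(species or (f"s{c}" for c in range(counts.shape[1]))),
        counts=counts,
    )


class TestUseValue:
    def test_mean_citation_frequency(self):
        res = use_value(_matrix([[2], [1], [0]]), "s0")
        assert res.uv == 1.0 and res.total_citations == 3 and res.n == 3

    def test_never_cited_species_scores_zero(self):
        assert use_value(_matrix([[0], [0]]), "s0").uv == 0.0

    def test_matches_brute_force_column_sums(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 6, size=(20, 5))
        mat = _matrix(counts)
        for j, sp in enumerate(mat.species):
            expected = sum(int(counts[i, j]) for i in range(20)) / 20  # brute force
            assert use_value(mat, sp).uv == pytest.approx(expected, abs=1e-12)
        table = use_value_table(mat).set_index("species")["uv"]
        for j, sp in enumerate(mat.species):
            assert table[sp] == pytest.approx(counts[:, j].sum() / 20, abs=1e-12)

    @given(st.lists(st.lists(st.integers(0, 20), min_size=3, max_size=3),
                    min_size=1, max_size=12))
    def test_linearity_and_dilution(self, rows):
        mat = _matrix(rows)
        doubled = _matrix(np.asarray(rows) * 2)
        padded = _matrix(np.vstack([rows, np.zeros((1, 3), dtype=int)]))
        for sp in mat.species:
            uv = use_value(mat, sp).uv
            assert use_value(doubled, sp).uv == pytest.approx(2 * uv)
            assert use_value(padded, sp).uv == pytest.approx(
                uv * mat.n / (mat.n + 1)
            )

    def test_unknown_species_and_empty_panel_rejected(self):
        mat = _matrix([[1]])
        with pytest.raises(SpeciesNotFoundError):
            use_value(mat, "nope")
        empty = CitationMatrix((), ("s0",), np.zeros((0, 1), dtype=int))
        with pytest.raises(ValueError):
            use_value(empty, "s0")


class TestRelativeImportance:
    def test_single_species_inventory_self_normalizes_to_two(self):
        inv = Inventory(records=(make_record("Aus bus L", parts=("leaf",)),))
        res = relative_importance(inv, "Aus bus L")
        assert res.nuc == res.nt == 1 and res.ri == 2

    def test_hand_computed_example(self):
        # maxima: 5 categories (rec a), 8 types (rec b: 2 cats x 4 parts);
        # target has 2 categories and 2 types -> RI = 2/5 + 2/8 = 0.65
        inv = Inventory(
            records=(
                make_record("Aus bus L", cats=("edible", "trade", "medicine",
                                               "forage", "ornamental"),
                            parts=("leaf",)),
                make_record("Cus dus L", cats=("edible", "trade"),
                            parts=("leaf", "root", "stem", "fruit")),
                make_record("Eus fus L", cats=("edible", "forage"),
                            parts=("seed",)),
            )
        )
        res = relative_importance(inv, "Eus fus L")
        assert res.nuc == pytest.approx(2 / 5)
        assert res.nt == pytest.approx(1 / 4)
        assert res.ri == pytest.approx(0.65)

    def test_table_matches_per_species_calls_and_is_bounded(self):
        inv = Inventory(
            records=tuple(
                make_record(f"Gus s{i} L", cats=cats, parts=parts)
                for i, (cats, parts) in enumerate(
                    [
                        (("edible",), ("leaf",)),
                        (("edible", "trade"), ("leaf", "fruit")),
                        (("medicine", "forage", "ornamental"), ("root",)),
                    ]
                )
            )
        )
        table = relative_importance_table(inv).set_index("species")
        for rec in inv:
            res = relative_importance(inv, rec.scientific_name)
            assert table.loc[rec.scientific_name, "ri"] == pytest.approx(res.ri)
            assert 0 < res.ri <= 2
        # someone attains each component maximum
        assert table["nuc"].max() == 1 and table["nt"].max() == 1

    def test_invariant_under_species_relabeling(self):
        base = [
            (("edible", "trade"), ("leaf",)),
            (("medicine",), ("root", "stem")),
        ]
        inv1 = Inventory(records=tuple(
            make_record(f"Aus s{i} L", cats=c, parts=p) for i, (c, p) in enumerate(base)
        ))
        inv2 = Inventory(records=tuple(
            make_record(f"Zus z{i} L", cats=c, parts=p) for i, (c, p) in enumerate(base)
        ))
        for i in range(len(base)):
            r1 = relative_importance(inv1, f"Aus s{i} L")
            r2 = relative_importance(inv2, f"Zus z{i} L")
            assert (r1.nuc, r1.nt) == (r2.nuc, r2.nt)

    def test_unknown_species_rejected(self):
        inv = Inventory(records=(make_record("Aus bus L"),))
        with pytest.raises(SpeciesNotFoundError):
            relative_importance(inv, "Missing plant")


species_sets = st.sets(st.integers(0, 30), min_size=1, max_size=15)


class TestJaccard:
    def test_identical_sets_score_100(self):
        assert jaccard_index({"a", "b"}, {"a", "b"}).ji == 100.0

    def test_disjoint_sets_score_0(self):
        assert jaccard_index({"a"}, {"b"}).ji == 0.0

    def test_hand_computed_example(self):
        res = jaccard_index({"a", "b", "c"}, {"b", "c", "d", "e"})
        assert (res.a, res.b, res.c) == (3, 4, 2)
        assert res.ji == pytest.approx(40.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            jaccard_index(set(), {"a"})

    @given(species_sets, species_sets)
    def test_symmetry_and_bounds(self, sa, sb):
        ab, ba = jaccard_index(sa, sb), jaccard_index(sb, sa)
        assert ab.ji == pytest.approx(ba.ji)
        assert 0 <= ab.ji <= 100
        assert 0 <= ab.c <= min(ab.a, ab.b)

    @given(species_sets, species_sets, st.integers(100, 200))
    def test_monotonicity_under_set_growth(self, sa, sb, new):
        base = jaccard_index(sa, sb).ji
        shared = jaccard_index(sa | {new}, sb | {new}).ji
        unique = jaccard_index(sa | {new}, sb - {new} or sb).ji
        assert shared >= base - 1e-12
        if new not in sa and new not in sb:
            assert unique <= base + 1e-12

    def test_matrix_is_symmetric_with_unit_diagonal(self):
        inv = Inventory(records=tuple(
            make_record(f"Hus s{i} L", towns=towns)
            for i, towns in enumerate(
                [("HK", "LL", "LES")] * 2 + [("HK",), ("LL", "LES"), ("LES",)]
            )
        ))
        matrix, pairs = jaccard_matrix(inv)
        assert (matrix.values == matrix.values.T).all()
        assert (np.diag(matrix.values) == 100.0).all()
        sets = inv.township_species_sets()
        for p in pairs:  # oracle: direct set arithmetic per pair
            assert p.ji == pytest.approx(
                jaccard_index(sets[p.group_a], sets[p.group_b]).ji
            )

    def test_full_overlap_inventory_gives_all_100(self):
        inv = Inventory(records=tuple(
            make_record(f"Ius s{i} L", towns=("HK", "LL", "LES")) for i in range(4)
        ))
        matrix, _ = jaccard_matrix(inv)
        assert (matrix.values == 100.0).all()


class TestShannonWiener:
    def test_single_species_has_zero_diversity(self):
        assert shannon_wiener([7]).shannon_h == 0.0

    def test_uniform_closed_form(self):
        assert shannon_wiener([5, 5, 5, 5]).shannon_h == pytest.approx(math.log(4))

    def test_matches_term_by_term_summation(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 50, size=10)
        counts[0] = 3  # at least one positive
        p = counts / counts.sum()
        expected = -sum(pi * math.log(pi) for pi in p if pi > 0)  # brute force
        assert shannon_wiener(counts).shannon_h == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.integers(0, 40), min_size=2, max_size=10).filter(
        lambda xs: sum(xs) > 0))
    def test_permutation_invariant_and_maximal_at_uniform(self, counts):
        h = shannon_wiener(counts).shannon_h
        assert shannon_wiener(counts[::-1]).shannon_h == pytest.approx(h)
        richness = sum(1 for c in counts if c > 0)
        assert h <= math.log(richness) + 1e-12 if richness else h == 0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_wiener([0, 0, 0])


class TestLandUseDegree:
    @pytest.mark.parametrize("grade, expected", [(1, 100.0), (4, 400.0)])
    def test_exact_bounds(self, grade, expected):
        table = LandUseTable("R", (("only", grade, 1.0),))
        assert land_use_degree(table).la == expected

    def test_hand_computed_example(self):
        table = LandUseTable("R", (("a", 2, 0.5), ("b", 3, 0.5)))
        assert land_use_degree(table).la == pytest.approx(250.0)

    @given(st.floats(0.0, 1.0), st.integers(1, 4), st.integers(1, 4))
    def test_affine_mixture_of_two_tables(self, w, g1, g2):
        la1 = land_use_degree(LandUseTable("A", (("c", g1, 1.0),))).la
        la2 = land_use_degree(LandUseTable("B", (("c", g2, 1.0),))).la
        mixture = LandUseTable(
            "M",
            tuple(
                cls
                for cls in (("c1", g1, w), ("c2", g2, 1.0 - w))
                if cls[2] > 0
            ),
        )
        assert land_use_degree(mixture).la == pytest.approx(w * la1 + (1 - w) * la2)

    def test_invalid_proportions_rejected_at_construction(self):
        with pytest.raises(ValueError, match="sum"):
            LandUseTable("R", (("a", 2, 0.5), ("b", 3, 0.4)))

    def test_grade_map_builder(self):
        from ethnogarden import landuse_from_proportions

        table = landuse_from_proportions(
            "R", {"forest": 0.8, "cropland": 0.15, "built": 0.05}
        )
        assert land_use_degree(table).la == pytest.approx(
            100 * (2 * 0.8 + 3 * 0.15 + 4 * 0.05)
        )
        with pytest.raises(KeyError, match="lava"):
            landuse_from_proportions("R", {"lava": 1.0})
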