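"""Trait-matrix assembly: aggregation, imputation, filtering, standardisation."""

import numpy as np
import pandas as pd
import pytest

from floradiv.traits import (MISSING, TraitDefinition, TraitMatrix, TraitRecord,
                             TraitValidationError, aggregate_records,
                             drop_invariant_traits, impute_genus_means, is_missing,
                             read_trait_table, standardize_and_transform,
                             summarize_missingness, write_trait_table)

from .conftest import MASTER_SEED, make_matrix, small_dictionary


def meta(n, genera=None):
    return pd.DataFrame({
        "genus": genera or ["G"] * n,
        "clade": ["angiosperm"] * n,
        "continent": ["EU"] * n,
    }, index=[f"sp{i + 1}" for i in range(n)])


class TestAggregateRecords:
    def test_single_observation_is_its_own_aggregate(self):
        m = aggregate_records(
            [TraitRecord("sp1", "seed.mass", 5.0)], small_dictionary(), meta(2))
        assert m.cells.at["sp1", "seed.mass"] == 5.0
        assert m.provenance.at["sp1", "seed.mass"] == "aggregated"
        other = m.cells.drop(columns="seed.mass").map(is_missing)
        assert other.all().all() and is_missing(m.cells.at["sp2", "seed.mass"])

    @pytest.mark.parametrize("trait,values,expected", [
        ("height", [2.0, 3.0, 100.0], 3.0),           # continuous -> median
        ("growth.rate", [1, 3], 2.0),                 # ordinal -> mean score
        ("form", ["tree", "tree", "shrub"], "tree"),  # nominal -> mode
        ("n.fix", [1, 1, 0], 1),                      # binary -> mode
        ("form", ["shrub", "tree"], "tree"),          # tie -> earliest declared level
    ])
    def test_per_type_aggregation_rules(self, trait, values, expected):
        recs = [TraitRecord("sp1", trait, v) for v in values]
        m = aggregate_records(recs, small_dictionary(), meta(1))
        assert m.cells.at["sp1", trait] == expected

    def test_matches_per_cell_oracle_on_random_records(self):
        rng = np.random.default_rng(MASTER_SEED)
        traits = small_dictionary()
        species_meta = meta(5)
        records = []
        for sp in species_meta.index:
            for t in traits:
                for _ in range(rng.integers(0, 4)):
                    if t.data_type == "continuous":
                        v = float(rng.uniform(1, 100))
                    elif t.data_type == "ordinal":
                        v = int(rng.choice(t.levels))
                    elif t.data_type == "binary":
                        v = int(rng.integers(2))
                    elif t.data_type == "nominal":
                        v = str(rng.choice(t.levels))
                    else:
                        k = rng.integers(1, len(t.levels) + 1)
                        v = frozenset(rng.choice(t.levels, size=k, replace=False))
                    records.append(TraitRecord(sp, t.name, v))
        m = aggregate_records(records, traits, species_meta)
        # independent per-cell recomputation
        for sp in species_meta.index:
            for t in traits:
                obs = [r.value for r in records if r.species == sp and r.trait == t.name]
                got = m.cells.at[sp, t.name]
                if not obs:
                    assert is_missing(got)
                elif t.data_type == "continuous":
                    assert got == pytest.approx(float(np.median(obs)))
                elif t.data_type == "ordinal":
                    assert got == pytest.approx(float(np.mean(obs)))
                else:
                    counts = pd.Series(list(obs) if t.data_type != "multichoice"
                                       else [frozenset(o) for o in obs]).value_counts()
                    assert counts[got] == counts.max()

    def test_record_order_permutation_invariant(self):
        rng = np.random.default_rng(1)
        recs = [TraitRecord("sp1", "height", v) for v in [4.0, 9.0, 1.0, 2.0]]
        recs += [TraitRecord("sp1", "form", v) for v in ["tree", "shrub", "shrub"]]
        a = aggregate_records(recs, small_dictionary(), meta(1))
        shuffled = list(recs)
        rng.shuffle(shuffled)
        b = aggregate_records(shuffled, small_dictionary(), meta(1))
        assert a.cells.equals(b.cells)

    def test_invalid_value_names_species_and_trait(self):
        with pytest.raises(TraitValidationError, match=r"sp1.*growth\.rate"):
            aggregate_records([TraitRecord("sp1", "growth.rate", 9)],
                              small_dictionary(), meta(1))


class TestImputeGenusMeans:
    def test_complete_matrix_is_a_noop(self):
        m = make_matrix([{"height": 1.0, "n.fix": 0}, {"height": 2.0, "n.fix": 1}])
        out = impute_genus_means(m)
        assert out.cells.equals(m.cells)

    def test_fills_with_genus_mean(self):
        m = make_matrix(
            [{"height": 20.0}, {}, {"height": 30.0}, {"height": 99.0}],
            genera=["Quercus", "Quercus", "Quercus", "Pinus"])
        out = impute_genus_means(m)
        assert out.cells.at["sp2", "height"] == pytest.approx(25.0)
        assert out.provenance.at["sp2", "height"] == "imputed"
        # no donor in other traits / other genera: untouched
        assert is_missing(out.cells.at["sp2", "seed.mass"])

    def test_categorical_traits_and_input_untouched(self):
        m = make_matrix([{"form": "tree"}, {}], genera=["G", "G"])
        before = m.cells.copy()
        out = impute_genus_means(m)
        assert is_missing(out.cells.at["sp2", "form"])  # nominal never imputed
        assert m.cells.equals(before)                   # input unmodified

    def test_never_increases_missingness_nor_alters_observed(self):
        from floradiv.synthdata import SyntheticFlora, SyntheticFloraConfig
        m = SyntheticFlora(SyntheticFloraConfig(
            seed=MASTER_SEED, n_na_angiosperms=20, n_eu_angiosperms=10,
            n_na_gymnosperms=5, n_eu_gymnosperms=5)).trait_matrix()
        out = impute_genus_means(m)
        was = m.missing_mask()
        now = out.missing_mask()
        assert (now <= was).all().all()
        obs = ~was
        assert m.cells[obs].equals(out.cells[obs])


class TestDropInvariantTraits:
    def test_constant_column_dropped(self):
        m = make_matrix([{"height": 1.0, "n.fix": 0}, {"height": 2.0, "n.fix": 0}],
                        traits=[TraitDefinition("height", "continuous", unit="m"),
                                TraitDefinition("n.fix", "binary")])
        out, dropped = drop_invariant_traits(m)
        assert dropped == ["n.fix"] and "n.fix" not in out.trait_names

    def test_varying_matrix_unchanged(self, toy_matrix):
        out, dropped = drop_invariant_traits(toy_matrix)
        assert dropped == [] and out.trait_names == toy_matrix.trait_names

    def test_idempotent(self, toy_matrix):
        once, _ = drop_invariant_traits(toy_matrix)
        twice, again = drop_invariant_traits(once)
        assert again == [] and twice.cells.equals(once.cells)

    def test_all_invariant_is_degenerate(self):
        traits = [TraitDefinition("b", "binary")]
        m = make_matrix([{"b": 1}, {"b": 1}], traits=traits)
        with pytest.raises(ValueError, match="invariant"):
            drop_invariant_traits(m)


class TestStandardize:
    HEIGHT = [TraitDefinition("height", "continuous", unit="m")]
    SEED_LOG = [TraitDefinition("seed.mass", "continuous", unit="mg", transform="log")]

    def test_z_scores_closed_form(self):
        m = make_matrix([{"height": 1.0}, {"height": 2.0}, {"height": 3.0}],
                        traits=self.HEIGHT)
        out = standardize_and_transform(m)
        got = [out.cells.at[s, "height"] for s in m.species]
        assert got == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent_for_untransformed(self):
        m = make_matrix([{"height": -1.0}, {"height": 0.0}, {"height": 1.0}],
                        traits=self.HEIGHT)
        once = standardize_and_transform(m)
        twice = standardize_and_transform(once)
        for s in m.species:
            assert twice.cells.at[s, "height"] == pytest.approx(
                once.cells.at[s, "height"], abs=1e-12)

    def test_log_transform_linearises_decades(self):
        m = make_matrix([{"seed.mass": 10.0}, {"seed.mass": 100.0}, {"seed.mass": 1000.0}],
                        traits=self.SEED_LOG)
        out = standardize_and_transform(m)
        got = [out.cells.at[s, "seed.mass"] for s in m.species]
        assert got == pytest.approx([-1.0, 0.0, 1.0])  # z of {1,2,3} decades

    def test_columns_have_mean0_sd1(self, toy_matrix):
        out = standardize_and_transform(toy_matrix)
        for t in out.traits:
            if not t.quantitative:
                continue
            vals = pd.to_numeric(out.cells[t.name], errors="coerce").dropna()
            assert vals.mean() == pytest.approx(0.0, abs=1e-10)
            assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_errors(self):
        m = make_matrix([{"height": 2.0}, {"height": 2.0}], traits=self.HEIGHT)
        with pytest.raises(ValueError, match="zero variance"):
            standardize_and_transform(m)


class TestMissingness:
    def test_small_fractions(self):
        complete = make_matrix([{"height": 1.0, "n.fix": 0}],
                               traits=small_dictionary()[:1])
        assert summarize_missingness(complete)["fraction_missing"] == 0.0
        m = make_matrix([{"height": 1.0, "n.fix": 0}, {"height": 2.0}],
                        traits=[TraitDefinition("height", "continuous", unit="m"),
                                TraitDefinition("n.fix", "binary")])
        assert summarize_missingness(m)["fraction_missing"] == pytest.approx(0.25)

    def test_generated_rate_within_binomial_bound(self):
        from scipy import stats
        from floradiv.synthdata import SyntheticFlora, SyntheticFloraConfig
        m = SyntheticFlora(SyntheticFloraConfig(seed=MASTER_SEED)).trait_matrix()
        frac = summarize_missingness(m)["fraction_missing"]
        n = m.shape[0] * m.shape[1]
        lo, hi = stats.binom.interval(0.99, n, 0.14)
        assert lo / n <= frac <= hi / n


def test_csv_yaml_roundtrip(tmp_path, toy_matrix):
    table, dic = tmp_path / "t.csv", tmp_path / "d.yaml"
    write_trait_table(toy_matrix, table, dic)
    back = read_trait_table(table, dic)
    assert back.trait_names == toy_matrix.trait_names
    for sp in toy_matrix.species:
        for t in toy_matrix.traits:
            a, b = toy_matrix.cells.at[sp, t.name], back.cells.at[sp, t.name]
            if is_missing(a):
                assert is_missing(b)
            elif t.data_type == "continuous":
                assert b == pytest.approx(a)
            else:
                assert b == a
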