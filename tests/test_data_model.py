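import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import indicar as ic
from indicar.data_model import build_design


def make_table(y, region_index, M, X=None):
    y = np.asarray(y)
    X = np.ones((len(y), 1)) if X is None else X
    return ic.IndividualTable(y=y, X=X, region_index=region_index,
                              n_regions=M)


class TestAggregation:
    def test_simple_example(self):
        t = make_table([1, 0, 2], [0, 0, 1], 2)
        np.testing.assert_array_equal(ic.aggregate_counts(t), [1, 2])

    def test_all_zero_counts(self):
        t = make_table([0, 0, 0], [0, 1, 1], 2)
        np.testing.assert_array_equal(ic.aggregate_counts(t), [0, 0])

    @given(st.lists(st.tuples(st.integers(0, 9), st.integers(0, 4)),
                    min_size=1, max_size=60))
    def test_matches_per_region_loop_and_conserves_total(self, rows):
        y = [r[0] for r in rows]
        g = [r[1] for r in rows]
        t = make_table(y, g, 5)
        agg = ic.aggregate_counts(t)
        brute = [sum(yy for yy, gg in rows if gg == j) for j in range(5)]
        np.testing.assert_array_equal(agg, brute)
        assert agg.sum() == sum(y)


class TestOffsets:
    def test_zero_beta_gives_log_region_sizes(self):
        t = make_table([0, 1, 2, 0], [0, 0, 0, 1], 2)
        np.testing.assert_allclose(
            ic.individual_offset_to_group(t, np.zeros(1)),
            [np.log(3), np.log(1)])

    def test_single_subject_per_region_gives_linear_predictor(self):
        X = np.array([[1.0, 2.0], [1.0, -1.0]])
        t = make_table([1, 1], [0, 1], 2, X=X)
        beta = np.array([0.5, 0.25])
        np.testing.assert_allclose(ic.individual_offset_to_group(t, beta),
                                   X @ beta)

    def test_matches_brute_force_log_sum(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(40), rng.standard_normal(40)])
        g = rng.integers(0, 4, 40)
        g[:4] = [0, 1, 2, 3]
        t = make_table(rng.integers(0, 3, 40), g, 4, X=X)
        beta = np.array([-0.3, 0.8])
        o1 = ic.individual_offset_to_group(t, beta)
        brute = [np.log(np.exp(X[g == j] @ beta).sum()) for j in range(4)]
        np.testing.assert_allclose(o1, brute, atol=1e-12)

    def test_empty_region_rejected(self):
        t = make_table([1, 2], [0, 0], 2)
        with pytest.raises(ic.DataError, match="no subjects"):
            ic.individual_offset_to_group(t, np.zeros(1))

    def test_group_offset_replication(self):
        t = make_table([0, 0, 0], [0, 1, 1], 2)
        np.testing.assert_array_equal(
            ic.group_offset_to_individual(t, np.array([0.5, -0.2])),
            [0.5, -0.2, -0.2])
        np.testing.assert_array_equal(
            ic.group_offset_to_individual(t, np.zeros(2)), np.zeros(3))

    def test_offsets_conserve_expected_counts(self):
        # exp(O1)_j must equal the summed individual means of region j
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(30), rng.uniform(size=30)])
        g = np.repeat(np.arange(3), 10)
        t = make_table(rng.integers(0, 2, 30), g, 3, X=X)
        beta = np.array([0.1, -0.5])
        expected = np.bincount(g, weights=np.exp(X @ beta))
        np.testing.assert_allclose(
            np.exp(ic.individual_offset_to_group(t, beta)), expected)


class TestDesignBuilding:
    def test_categorical_six_levels_five_dummies(self):
        df = pd.DataFrame({"age": [1, 2, 3, 4, 5, 6, 1]})
        schema = {"region_column": "r", "outcome_column": "y",
                  "covariates": [{"name": "age", "type": "categorical",
                                  "levels": [1, 2, 3, 4, 5, 6]}]}
        X, names = build_design(df, schema)
        assert X.shape == (7, 6)  # intercept + 5 dummies
        assert names[0] == "intercept"
        # reference level rows are all-zero in the dummy block
        np.testing.assert_array_equal(X[0, 1:], 0)
        np.testing.assert_array_equal(X[1, 1:], [1, 0, 0, 0, 0])

    def test_unknown_level_names_row(self):
        df = pd.DataFrame({"age": [1, 9]})
        schema = {"region_column": "r", "outcome_column": "y",
                  "covariates": [{"name": "age", "type": "categorical",
                                  "levels": [1, 2]}]}
        with pytest.raises(ic.DataError, match="row 3"):
            build_design(df, schema)


@pytest.fixture
def toy_csv(tmp_path):
    schema = {"region_column": "region", "outcome_column": "y",
              "covariates": [{"name": "treated", "type": "numeric"}]}
    path = tmp_path / "ind.csv"
    pd.DataFrame({"region": ["A", "A", "B"], "y": [1, 0, 2],
                  "treated": [0, 1, 1]}).to_csv(path, index=False)
    return path, schema


class TestCsvReading:
    def test_toy_csv_design(self, toy_csv):
        path, schema = toy_csv
        t = ic.read_individual_csv(path, schema)
        assert t.X.shape == (3, 2)  # intercept + binary covariate
        assert t.x_names == ["intercept", "treated"]
        np.testing.assert_array_equal(t.y, [1, 0, 2])
        np.testing.assert_array_equal(t.region_index, [0, 0, 1])

    def test_round_trip(self, toy_csv, tmp_path):
        path, schema = toy_csv
        t = ic.read_individual_csv(path, schema)
        out = tmp_path / "copy.csv"
        df = pd.DataFrame({"region": [t.region_labels[j]
                                      for j in t.region_index],
                           "y": t.y, "treated": t.frame["treated"]})
        df.to_csv(out, index=False)
        t2 = ic.read_individual_csv(out, schema)
        np.testing.assert_array_equal(t.X, t2.X)
        np.testing.assert_array_equal(t.y, t2.y)

    def test_unknown_region_id(self, toy_csv):
        path, schema = toy_csv
        with pytest.raises(ic.DataError, match="unknown region id"):
            ic.read_individual_csv(path, schema, region_labels=["A", "C"])

    def test_region_with_no_rows_rejected(self, toy_csv):
        path, schema = toy_csv
        with pytest.raises(ic.DataError, match="no subjects"):
            ic.read_individual_csv(path, schema,
                                   region_labels=["A", "B", "C"])

    def test_negative_count_rejected(self, tmp_path, toy_csv):
        _, schema = toy_csv
        path = tmp_path / "bad.csv"
        pd.DataFrame({"region": ["A"], "y": [-1],
                      "treated": [0]}).to_csv(path, index=False)
        with pytest.raises(ic.DataError, match="row 2"):
            ic.read_individual_csv(path, schema)

    def test_missing_cell_rejected(self, tmp_path, toy_csv):
        _, schema = toy_csv
        path = tmp_path / "bad.csv"
        path.write_text("region,y,treated\nA,1,\n")
        with pytest.raises(ic.DataError, match="missing cell"):
            ic.read_individual_csv(path, schema)

    def test_region_csv_reordered_to_canonical(self, tmp_path):
        path = tmp_path / "reg.csv"
        pd.DataFrame({"region": ["B", "A"], "u": [2.0, 1.0]}).to_csv(
            path, index=False)
        reg = ic.read_region_csv(path, region_labels=["A", "B"])
        np.testing.assert_array_equal(reg.U[:, 0], [1.0, 2.0])
        with pytest.raises(ic.DataError, match="missing from table"):
            ic.read_region_csv(path, region_labels=["A", "C"])
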