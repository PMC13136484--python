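"""Mark derivations, z-scores, quantile groups and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nichemark.cell_tables import CellTable
from nichemark.marks import (
    classify_quantile_groups,
    compare_variances,
    concentration_from_sum,
    correlate_marks,
    neighbor_mark_stats,
    population_dot_density,
    zscore_marks,
)


@pytest.mark.parametrize(
    "total,volume,expected",
    [(100, 50, 2.0), (0, 7, 0.0), (6e5, 300, 2000.0)],
)
def test_concentration_from_sum(total, volume, expected):
    assert concentration_from_sum(total, volume) == expected


def test_concentration_rejects_nonpositive_volume():
    with pytest.raises(ValueError):
        concentration_from_sum(10, 0)


class TestZscore:
    def test_two_values(self):
        df = pd.DataFrame(
            {
                "cell_id": ["a", "b"],
                "sample_id": "s1",
                "x_um": [0.0, 1.0],
                "y_um": [0.0, 1.0],
                "volume_um3": 100.0,
                "m": [0.0, 10.0],
            }
        )
        t = zscore_marks(CellTable(df, mark_channels=("m",)), "m")
        np.testing.assert_allclose(t.data["m"], [-1.0, 1.0])

    def test_constant_channel_errors(self):
        df = pd.DataFrame(
            {
                "cell_id": ["a", "b"],
                "sample_id": "s1",
                "x_um": [0.0, 1.0],
                "y_um": [0.0, 1.0],
                "volume_um3": 100.0,
                "m": [3.0, 3.0],
            }
        )
        with pytest.raises(ValueError):
            zscore_marks(CellTable(df, mark_channels=("m",)), "m")

    def test_per_sample_moments(self, li_study):
        table, _, _ = li_study
        z = zscore_marks(table, "n3icd_conc", scope="per_sample")
        for sid in z.samples:
            v = z.marks(sid, "n3icd_conc")
            assert abs(v.mean()) < 1e-12
            assert v.std() == pytest.approx(1.0)


class TestQuantileGroups:
    def _table(self, values, sample="s1"):
        n = len(values)
        return CellTable(
            pd.DataFrame(
                {
                    "cell_id": [f"{sample}_{i}" for i in range(n)],
                    "sample_id": sample,
                    "x_um": np.arange(n, dtype=float),
                    "y_um": np.zeros(n),
                    "volume_um3": 100.0,
                    "m": np.asarray(values, dtype=float),
                }
            ),
            mark_channels=("m",),
        )

    def test_marks_1_to_10(self):
        g = classify_quantile_groups(self._table(range(1, 11)), "m")
        labels = g.labels.to_numpy()
        assert list(labels[:2]) == ["low", "low"]
        assert list(labels[-2:]) == ["high", "high"]
        assert (labels[2:8] == "intermediate").all()

    def test_floor_rule_n5(self):
        g = classify_quantile_groups(self._table([5, 1, 4, 2, 3]), "m")
        assert (g.labels == "low").sum() == 1
        assert (g.labels == "high").sum() == 1

    def test_groups_local_to_each_sample(self):
        # disjoint ranges: pooled thresholds would put every "low" in one sample
        a = self._table(np.arange(10.0), sample="a").data
        b = self._table(np.arange(1000.0, 1010.0), sample="b").data
        t = CellTable(pd.concat([a, b], ignore_index=True), mark_channels=("m",))
        g = classify_quantile_groups(t, "m")
        per = pd.DataFrame({"sample": t.data["sample_id"], "g": g.labels})
        counts = per.groupby("sample")["g"].value_counts()
        assert counts[("a", "low")] == 2 and counts[("b", "low")] == 2

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.integers(min_value=-10000, max_value=10000),
            min_size=6,
            max_size=40,
            unique=True,
        )
    )
    def test_invariant_under_monotone_transform(self, values):
        values = [float(v) for v in values]
        t1 = self._table(values)
        t2 = self._table(np.exp(np.asarray(values) / 2e4))
        g1 = classify_quantile_groups(t1, "m")
        g2 = classify_quantile_groups(t2, "m")
        assert (g1.labels == g2.labels).all()

    def test_zscore_then_classify_matches_raw(self, li_study):
        table, _, _ = li_study
        g_raw = classify_quantile_groups(table, "n3icd_conc")
        g_z = classify_quantile_groups(
            zscore_marks(table, "n3icd_conc"), "n3icd_conc"
        )
        assert (g_raw.labels == g_z.labels).all()


class TestCompareVariances:
    def test_identical_groups_ratio_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        out = compare_variances(x, x)
        assert out["ratio"] == pytest.approx(1.0)
        assert out["p"] == pytest.approx(1.0)

    def test_halved_deviations_quadruple_ratio(self):
        rng = np.random.default_rng(0)
        a = rng.normal(10, 2, 50)
        b = a.mean() + 0.5 * (a - a.mean())
        out = compare_variances(a, b)
        assert out["ratio"] == pytest.approx(4.0)

    def test_levene_available(self):
        rng = np.random.default_rng(1)
        out = compare_variances(
            rng.normal(0, 1, 40), rng.normal(0, 3, 40), method="levene"
        )
        assert out["p"] < 0.01

    def test_insufficient_n(self):
        with pytest.raises(ValueError):
            compare_variances([1.0], [1.0, 2.0])


class TestCorrelateMarks:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert correlate_marks(x, x**3) == pytest.approx(1.0)
        assert correlate_marks(x, -x) == pytest.approx(-1.0)

    def test_ties_match_exhaustive_rank_computation(self):
        a = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 7.0])
        b = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 5.0, 9.0, 8.0])

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2  # average of 1-based ranks
                i = j
            return ranks

        ra, rb = avg_ranks(a), avg_ranks(b)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert correlate_marks(a, b) == pytest.approx(expected)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlate_marks([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestNeighborMarkStats:
    def _table_with_flags(self, n, flags, sample="s1"):
        return CellTable(
            pd.DataFrame(
                {
                    "cell_id": [f"c{i}" for i in range(n)],
                    "sample_id": sample,
                    "x_um": np.arange(n, dtype=float),
                    "y_um": np.zeros(n),
                    "volume_um3": 100.0,
                    "pos": np.asarray(flags, dtype=int),
                }
            ),
            flag_channels=("pos",),
        )

    def test_triangle_one_flagged(self):
        t = self._table_with_flags(3, [1, 0, 0])
        adj = pd.DataFrame(
            {
                "sample_id": "s1",
                "cell_id_a": ["c0", "c1", "c2"],
                "cell_id_b": ["c1", "c2", "c0"],
            }
        )
        out = neighbor_mark_stats(t, adj, "pos")
        assert out["n_neighbors"].tolist() == [2, 2, 2]
        assert out["n_flagged_neighbors"].tolist() == [0, 1, 1]

    def test_empty_adjacency(self):
        t = self._table_with_flags(4, [1, 1, 0, 0])
        adj = pd.DataFrame(columns=["sample_id", "cell_id_a", "cell_id_b"])
        out = neighbor_mark_stats(t, adj, "pos")
        assert (out[["n_neighbors", "n_flagged_neighbors"]] == 0).all().all()

    def test_random_graph_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        n = 30
        flags = rng.integers(0, 2, n)
        t = self._table_with_flags(n, flags)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.15]
        adj = pd.DataFrame(
            {
                "sample_id": "s1",
                "cell_id_a": [f"c{i}" for i, _ in pairs],
                "cell_id_b": [f"c{j}" for _, j in pairs],
            }
        )
        out = neighbor_mark_stats(t, adj, "pos")
        for i in range(n):
            nb = [j for a, j in pairs if a == i] + [a for a, j in pairs if j == i]
            assert out.loc[i, "n_neighbors"] == len(nb)
            assert out.loc[i, "n_flagged_neighbors"] == sum(flags[j] for j in nb)
        # totals identity: sum of flagged-neighbor counts = sum of degrees of flagged cells
        assert (
            out["n_flagged_neighbors"].sum()
            == out.loc[flags.astype(bool), "n_neighbors"].sum()
        )

    def test_dangling_edge_rejected(self):
        t = self._table_with_flags(2, [0, 1])
        adj = pd.DataFrame(
            {"sample_id": ["s1"], "cell_id_a": ["c0"], "cell_id_b": ["ghost"]}
        )
        with pytest.raises(ValueError, match="ghost"):
            neighbor_mark_stats(t, adj, "pos")


@pytest.mark.parametrize(
    "dots,cells,expected", [(0, 50, 0.0), (200, 100, 2.0), (7, 3, 7 / 3)]
)
def test_population_dot_density(dots, cells, expected):
    assert population_dot_density(dots, cells) == pytest.approx(expected)


def test_population_dot_density_zero_denominator():
    with pytest.raises(ValueError):
        population_dot_density(5, 0)
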