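"""Synthetic-niche generator: packing, mark regimes, counts, adjacency."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import cdist, pdist

from nichemark.marks import classify_quantile_groups, correlate_marks
from nichemark.synthetic import (
    GeneratorConfig,
    assign_iid_marks,
    assign_lateral_inhibition_marks,
    attenuate_mark_variance,
    build_adjacency,
    generate_ligand_counts,
    generate_sample,
    generate_study,
    sample_hardcore_positions,
)


class TestHardcorePositions:
    def test_min_distance_respected(self):
        cfg = GeneratorConfig(n_cells=150, seed=0)
        pos = sample_hardcore_positions(cfg)
        assert pdist(pos).min() >= cfg.d_min

    def test_cell_count_range_when_unspecified(self):
        for seed in range(5):
            pos = sample_hardcore_positions(GeneratorConfig(seed=seed))
            assert 100 <= len(pos) <= 200

    def test_seed_determinism(self):
        cfg = GeneratorConfig(n_cells=120, seed=8)
        np.testing.assert_array_equal(
            sample_hardcore_positions(cfg), sample_hardcore_positions(cfg)
        )

    def test_infeasible_packing_rejected(self):
        with pytest.raises((ValueError, RuntimeError)):
            sample_hardcore_positions(
                GeneratorConfig(n_cells=200, width=20, height=20, seed=0)
            )


class TestIidMarks:
    def test_mark_position_independence(self):
        # correlation between mark and x-coordinate ~ 0 over replicates
        cors = []
        for seed in range(30):
            cfg = GeneratorConfig(n_cells=120, seed=seed)
            rng = np.random.default_rng(seed)
            pos = sample_hardcore_positions(cfg, rng)
            marks = assign_iid_marks(pos, cfg, rng)
            cors.append(np.corrcoef(pos[:, 0], marks)[0, 1])
        assert abs(np.mean(cors)) < 0.05

    def test_lognormal_family_positive(self):
        cfg = GeneratorConfig(n_cells=100, mark_family="lognormal", seed=1)
        rng = np.random.default_rng(1)
        pos = sample_hardcore_positions(cfg, rng)
        marks = assign_iid_marks(pos, cfg, rng)
        assert np.all(marks > 0)

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(mark_sd=-1.0)


class TestLateralInhibitionMarks:
    def test_sender_count_and_suppression(self):
        cfg = GeneratorConfig(n_cells=150, mark_model="lateral_inhibition", seed=2)
        rng = np.random.default_rng(2)
        pos = sample_hardcore_positions(cfg, rng)
        marks, senders = assign_lateral_inhibition_marks(pos, cfg, rng)
        assert senders.sum() == int(np.floor(cfg.sender_fraction * len(pos)))
        assert marks[senders].mean() < marks[~senders].mean()

    def test_degenerate_parameters_match_iid(self):
        cfg = GeneratorConfig(
            n_cells=150,
            boost_amplitude=0.0,
            suppression_depth=1.0,
            seed=3,
        )
        rng1 = np.random.default_rng(3)
        pos = sample_hardcore_positions(cfg, rng1)
        marks_li, _ = assign_lateral_inhibition_marks(pos, cfg, np.random.default_rng(4))
        marks_iid = assign_iid_marks(pos, cfg, np.random.default_rng(4))
        # same base draws, zero boost, unit suppression: identical values
        np.testing.assert_allclose(np.sort(marks_li), np.sort(marks_iid))

    def test_senders_recovered_as_low_group(self):
        overlaps = []
        for seed in range(10):
            samp = generate_sample(
                GeneratorConfig(mark_model="lateral_inhibition", n_cells=150, seed=seed)
            )
            g = classify_quantile_groups(samp.table, "n3icd_conc")
            low = g.mask("low")
            senders = samp.sender_flags
            overlaps.append(low[senders].mean())  # sender recall in low group
        assert np.mean(overlaps) > 0.8

    def test_power_monotone_in_amplitude(self):
        from nichemark.inference import deviation_test

        median_ps = []
        for amp in (0.0, 1500.0, 3500.0):
            ps = []
            for seed in range(8):
                cfg = GeneratorConfig(
                    mark_model="lateral_inhibition", boost_amplitude=amp, seed=seed
                )
                table, windows, _ = generate_study(cfg, n_samples=1, seed=seed)
                res = deviation_test(
                    table,
                    "n3icd_conc",
                    windows=windows,
                    s=49,
                    n_ref=50,
                    seed=seed,
                    keep_curves=False,
                )
                ps.append(res.p_hat)
            median_ps.append(np.median(ps))
        assert median_ps[0] > median_ps[2]
        assert sorted(median_ps, reverse=True) == median_ps


class TestAttenuation:
    def test_identity_at_scale_one(self):
        m = np.array([1.0, 5.0, 2.0, 8.0])
        np.testing.assert_allclose(attenuate_mark_variance(m, 1.0), m)

    def test_variance_halved_exactly_mean_preserved(self):
        rng = np.random.default_rng(5)
        m = rng.lognormal(7, 0.4, 300)
        out = attenuate_mark_variance(m, 0.5)
        assert out.mean() == pytest.approx(m.mean())
        assert np.var(out) == pytest.approx(0.5 * np.var(m))

    def test_commutes_with_quantile_classification(self, li_study):
        table, _, _ = li_study
        g_before = classify_quantile_groups(table, "n3icd_conc")
        df = table.data.copy()
        for sid in table.samples:
            idx = df["sample_id"] == sid
            df.loc[idx, "n3icd_conc"] = attenuate_mark_variance(
                df.loc[idx, "n3icd_conc"].to_numpy(), 0.5
            )
        g_after = classify_quantile_groups(table.copy_with(df), "n3icd_conc")
        assert (g_before.labels == g_after.labels).all()


class TestLigandCounts:
    def _draw(self, n=2000, seed=0):
        cfg = GeneratorConfig(n_cells=None, seed=seed)
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 100, size=(n, 2))
        return generate_ligand_counts(pos, cfg, rng)

    def test_counts_nonnegative_integers(self):
        dla, jag = self._draw()
        for c in (dla, jag):
            assert np.issubdtype(c.dtype, np.integer)
            assert c.min() >= 0

    def test_dla_exponential_like_shape(self):
        dla, _ = self._draw(n=10000)
        # mode at zero, heavy right tail
        assert np.bincount(dla).argmax() == 0
        assert stats.skew(dla) > 1.0

    def test_channels_uncorrelated(self):
        rhos = []
        for seed in range(10):
            dla, jag = self._draw(n=500, seed=seed)
            rhos.append(correlate_marks(dla + 0.0, jag + 0.0))
        assert abs(np.mean(rhos)) < 0.05


class TestAdjacency:
    def test_triangle_delaunay(self):
        pos = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 8.0]])
        edges = build_adjacency(pos, rule="delaunay")
        assert len(edges) == 3

    def test_radius_below_hardcore_gives_no_edges(self):
        cfg = GeneratorConfig(n_cells=80, seed=6)
        pos = sample_hardcore_positions(cfg)
        edges = build_adjacency(pos, rule="radius", r_adj=cfg.d_min * 0.9)
        assert len(edges) == 0

    def test_radius_rule_matches_brute_force(self):
        rng = np.random.default_rng(7)
        pos = rng.uniform(0, 40, size=(30, 2))
        r_adj = 8.0
        edges = build_adjacency(pos, rule="radius", r_adj=r_adj)
        got = {frozenset((a, b)) for a, b in zip(edges.cell_id_a, edges.cell_id_b)}
        d = cdist(pos, pos)
        expected = {
            frozenset((f"c{i}", f"c{j}"))
            for i in range(30)
            for j in range(i + 1, 30)
            if d[i, j] <= r_adj
        }
        assert got == expected

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            build_adjacency(np.array([[0.0, 0.0], [1.0, 1.0]]), rule="delaunay")


class TestGenerateSample:
    def test_pure_function_of_config_and_seed(self):
        cfg = GeneratorConfig(mark_model="lateral_inhibition", seed=9)
        a = generate_sample(cfg)
        b = generate_sample(cfg)
        np.testing.assert_array_equal(
            a.table.data["n3icd_conc"], b.table.data["n3icd_conc"]
        )
        np.testing.assert_array_equal(a.sender_flags, b.sender_flags)

    def test_all_cells_inside_window(self):
        samp = generate_sample(GeneratorConfig(seed=10))
        w = samp.window
        pos = samp.table.positions("s1")
        assert w.contains(pos[:, 0], pos[:, 1]).all()

    def test_sum_equals_conc_times_volume(self):
        samp = generate_sample(GeneratorConfig(seed=11))
        df = samp.table.data
        np.testing.assert_allclose(
            df["n3icd_sum"], df["n3icd_conc"] * df["volume_um3"]
        )

    def test_study_has_independent_samples(self):
        table, windows, truth = generate_study(GeneratorConfig(seed=12), n_samples=3)
        assert table.samples == ["s1", "s2", "s3"]
        assert set(windows) == {"s1", "s2", "s3"}
        assert len(truth) == len(table)
        # distinct fields: positions differ between samples
        assert not np.array_equal(
            table.positions("s1")[:5], table.positions("s2")[:5]
        )
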