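"""Generators: planted structure, determinism, and file round-trips."""

import numpy as np
import pandas as pd
import pytest

import pharmgbc as pg
from pharmgbc import io
from pharmgbc.errors import DegenerateGeometryError, InvalidArgumentError
from pharmgbc.synthetic import GroundTruth


class TestMakeAtlas:
    def test_study_scale_layout(self):
        atlas = pg.make_atlas(718, 12, seed=1)
        assert atlas.n_parcels == 718
        assert len(set(atlas.networks)) == 12
        assert {"L", "R"} == set(atlas.hemispheres)
        assert {"association", "sensory"} == set(atlas.klass)

    def test_minimal_layout_balanced(self):
        atlas = pg.make_atlas(4, 2, seed=7)
        counts = pd.Series(atlas.networks).value_counts()
        assert sorted(counts) == [2, 2]
        klass_per_network = (
            atlas.table.groupby("network")["klass"].agg(lambda s: s.iloc[0]).tolist()
        )
        assert sorted(klass_per_network) == ["association", "sensory"]

    def test_deterministic(self):
        a1 = pg.make_atlas(100, 6, seed=3)
        a2 = pg.make_atlas(100, 6, seed=3)
        pd.testing.assert_frame_equal(a1.table, a2.table)

    def test_too_few_parcels_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pg.make_atlas(10, 6, seed=0)

    def test_centroids_on_unit_sphere_nondegenerate(self, atlas_small):
        norms = np.linalg.norm(atlas_small.centroids, axis=1)
        assert np.allclose(norms, 1.0)
        d = atlas_small.distances()
        off = d[~np.eye(len(d), dtype=bool)]
        assert off.min() > 1e-3


class TestSimulateDeltaGbc:
    def test_noiseless_rank_one(self, atlas_small):
        maps, _ = pg.simulate_delta_gbc(atlas_small, 10, 1, [4.0], 0.0, seed=2)
        x = maps - maps.mean(axis=0)
        sv = np.linalg.svd(x, compute_uv=False)
        assert sv[1] < 1e-10 * sv[0]

    def test_planted_components_orthonormal(self, atlas_small):
        _, truth = pg.simulate_delta_gbc(atlas_small, 10, 3, [4, 2, 1], 0.5, seed=2)
        gram = truth.component_maps @ truth.component_maps.T
        assert np.allclose(gram, np.eye(3), atol=1e-8)

    def test_first_component_contrasts_network_classes(self, atlas_small):
        _, truth = pg.simulate_delta_gbc(atlas_small, 10, 1, [4.0], 0.0, seed=2)
        u1 = truth.component_maps[0]
        assert u1[atlas_small.is_association].mean() > 0
        assert u1[~atlas_small.is_association].mean() < 0

    def test_equal_spectrum_participation_ratio(self, atlas_small):
        # exactly planted spectrum: noiseless sample PR equals the planted
        # dimensionality (iid scores would shrink it by Wishart spreading)
        s = 12
        maps, _ = pg.simulate_delta_gbc(
            atlas_small, s, s - 1, [3.0] * (s - 1), 0.0, seed=5, orthonormal_scores=True
        )
        pr = pg.participation_ratio(maps)
        assert pr == pytest.approx(s - 1, rel=0.1)

    def test_invalid_spectrum_rejected(self, atlas_small):
        with pytest.raises(InvalidArgumentError):
            pg.simulate_delta_gbc(atlas_small, 10, 2, [1.0, -1.0], 0.0, seed=0)
        with pytest.raises(InvalidArgumentError):
            pg.simulate_delta_gbc(atlas_small, 10, 2, [1.0, 2.0], 0.0, seed=0)

    def test_deterministic(self, atlas_small):
        m1, _ = pg.simulate_delta_gbc(atlas_small, 8, 2, [4, 2], 1.0, seed=9)
        m2, _ = pg.simulate_delta_gbc(atlas_small, 8, 2, [4, 2], 1.0, seed=9)
        np.testing.assert_array_equal(m1, m2)


class TestGroundTruth:
    def test_rejects_non_orthonormal_components(self):
        bad = np.array([[1.0, 0.0], [1.0, 0.0]]) / np.sqrt(1.0)
        with pytest.raises(InvalidArgumentError):
            GroundTruth(
                component_maps=bad,
                subject_scores=np.zeros((3, 2)),
                eigenspectrum=np.array([2.0, 1.0]),
            )

    def test_rejects_increasing_spectrum(self):
        u = np.eye(2)
        with pytest.raises(InvalidArgumentError):
            GroundTruth(
                component_maps=u,
                subject_scores=np.zeros((3, 2)),
                eigenspectrum=np.array([1.0, 2.0]),
            )


class TestSimulateSession:
    def test_one_factor_correlation_matches_formula(self, atlas_small):
        """Mean sample FC over sessions approaches w_p w_q / sqrt((w_p²+1)(w_q²+1))."""
        w = np.where(np.arange(40) < 20, 0.2, 1.0)
        expected = np.outer(w, w) / np.sqrt(np.outer(w**2 + 1, w**2 + 1))
        acc = np.zeros((40, 40))
        n_rep = 30
        for s in range(n_rep):
            ts = pg.simulate_session(atlas_small, 400, w, seed=100 + s)
            acc += np.corrcoef(ts.data, rowvar=False)
        mean_fc = acc / n_rep
        mask = ~np.eye(40, dtype=bool)
        assert np.abs(mean_fc[mask] - expected[mask]).max() < 0.05

    def test_two_block_weights_separate_perfectly(self, atlas_small):
        # tied two-block weights cap the midrank Spearman at 0.866 even for
        # perfect recovery, so assert full block separation instead
        w = np.where(np.arange(40) < 20, 0.2, 1.0)
        ts = pg.simulate_session(atlas_small, 400, w, seed=11)
        g = pg.gbc(pg.fc_matrix(ts))
        assert g.values[w == 1.0].min() > g.values[w == 0.2].max()

    def test_graded_weights_rank_recovered(self, atlas_small):
        from scipy.stats import spearmanr

        w = np.linspace(0.2, 1.0, 40)
        ts = pg.simulate_session(atlas_small, 400, w, seed=11)
        g = pg.gbc(pg.fc_matrix(ts))
        assert spearmanr(w, g.values).statistic >= 0.9

    def test_gbc_spread_shrinks_with_frames(self, atlas_small):
        w = np.full(40, 0.6)
        spreads = []
        for n_frames in (100, 1600):
            vals = [
                pg.gbc(pg.fc_matrix(pg.simulate_session(atlas_small, n_frames, w, seed=s)))
                .values.std()
                for s in range(8)
            ]
            spreads.append(np.mean(vals))
        assert spreads[1] < spreads[0]

    def test_motion_spike_in_trace_only(self, atlas_small):
        w = np.full(40, 0.5)
        ts = pg.simulate_session(atlas_small, 100, w, motion_spikes=[10], seed=3)
        assert ts.fd[10] > 0.5
        assert (np.delete(ts.fd, 10) <= 0.5).all()
        clean = pg.simulate_session(atlas_small, 100, w, seed=3)
        np.testing.assert_array_equal(ts.data, clean.data)

    def test_short_scan_rejected(self, atlas_small):
        with pytest.raises(InvalidArgumentError):
            pg.simulate_session(atlas_small, 20, np.full(40, 0.5), seed=0)


class TestSimulateGeneMap:
    def test_planted_strong_correlation(self, atlas_200):
        target = pg.simulate_gene_map(atlas_200, 0.5, np.zeros(200), 0.0, seed=1)
        gene = pg.simulate_gene_map(atlas_200, 0.5, target, 0.99, seed=2)
        assert np.corrcoef(target, gene)[0, 1] > 0.9

    def test_zero_target_correlation_unbiased(self, atlas_200):
        target = pg.simulate_gene_map(atlas_200, 0.5, np.zeros(200), 0.0, seed=1)
        rs = [
            np.corrcoef(target, pg.simulate_gene_map(atlas_200, 0.5, target, 0.0, seed=s))[0, 1]
            for s in range(30)
        ]
        assert abs(np.mean(rs)) < 0.08

    def test_planted_moderate_correlation_calibrated(self, atlas_200):
        target = pg.simulate_gene_map(atlas_200, 0.5, np.zeros(200), 0.0, seed=1)
        rs = [
            np.corrcoef(target, pg.simulate_gene_map(atlas_200, 0.5, target, 0.5, seed=s))[0, 1]
            for s in range(30)
        ]
        assert np.mean(rs) == pytest.approx(0.5, abs=0.1)

    def test_output_standardized(self, atlas_200):
        g = pg.simulate_gene_map(atlas_200, 0.5, np.zeros(200), 0.0, seed=4)
        assert abs(g.mean()) < 1e-12
        assert g.std() == pytest.approx(1.0)

    def test_large_scale_approaches_constant_field(self, atlas_200):
        d = atlas_200.distances()
        rough = pg.simulate_gene_map(atlas_200, 0.1, np.zeros(200), 0.0, seed=7)
        smooth = pg.simulate_gene_map(atlas_200, 50.0, np.zeros(200), 0.0, seed=7)
        _, g_rough = pg.empirical_variogram(rough, d, n_bins=10)
        _, g_smooth = pg.empirical_variogram(smooth, d, n_bins=10)
        # both outputs are standardized (sill ~1): judge smoothness by the
        # short-range semivariance relative to the sill
        assert g_smooth[0] / g_smooth.mean() < 0.4
        assert g_rough[0] / g_rough.mean() > 0.7

    def test_duplicate_centroids_rejected(self, atlas_small):
        table = atlas_small.table.copy()
        table.loc[1, ["x", "y", "z"]] = table.loc[0, ["x", "y", "z"]].to_numpy()
        degenerate = pg.ParcelAtlas(table)
        with pytest.raises(DegenerateGeometryError):
            pg.simulate_gene_map(degenerate, 0.5, np.zeros(40), 0.0, seed=0)


class TestSimulateBehavior:
    def test_noiseless_rank_equals_planted(self, rng):
        scores = rng.standard_normal((10, 1))
        coupling = rng.standard_normal((1, 8))
        b = pg.simulate_behavior(10, 8, scores, coupling, noise_sd=0.0, seed=0)
        assert np.linalg.matrix_rank(b) == 1

    def test_missing_cells_injected(self, rng):
        scores = rng.standard_normal((6, 2))
        coupling = rng.standard_normal((2, 5))
        b = pg.simulate_behavior(6, 5, scores, coupling, 1.0, seed=0, missing_cells=[(2, 3)])
        assert np.isnan(b[2, 3])
        assert np.isfinite(np.delete(b.ravel(), 2 * 5 + 3)).all()

    def test_shape_contract(self, rng):
        with pytest.raises(InvalidArgumentError):
            pg.simulate_behavior(6, 5, rng.standard_normal((6, 2)),
                                 rng.standard_normal((3, 5)), 1.0)


class TestRoundTrips:
    def test_atlas_tsv(self, tmp_path, atlas_small):
        path = tmp_path / "atlas.tsv"
        atlas_small.to_tsv(path)
        back = pg.ParcelAtlas.from_tsv(path)
        pd.testing.assert_frame_equal(atlas_small.table, back.table)

    def test_timeseries_and_motion_tsv(self, tmp_path, atlas_small):
        ts = pg.simulate_session(atlas_small, 60, np.full(40, 0.5), seed=1)
        io.write_timeseries(ts, tmp_path / "bold.tsv", tmp_path / "motion.tsv")
        back = io.read_timeseries(tmp_path / "bold.tsv", tmp_path / "motion.tsv", tr=ts.tr)
        np.testing.assert_array_equal(ts.data, back.data)
        np.testing.assert_array_equal(ts.fd, back.fd)
        np.testing.assert_array_equal(ts.rms, back.rms)

    def test_maps_tsv(self, tmp_path, atlas_small, rng):
        maps = rng.standard_normal((5, 40))
        io.write_maps(maps, tmp_path / "maps.tsv", atlas_small)
        np.testing.assert_array_equal(maps, io.read_maps(tmp_path / "maps.tsv"))

    def test_gene_map_tsv(self, tmp_path, rng):
        gm = pg.GeneExpressionMap("SST", rng.standard_normal(40), 0.45)
        io.write_gene_map(gm, tmp_path / "sst.tsv")
        back = io.read_gene_map(tmp_path / "sst.tsv", gene="SST")
        np.testing.assert_array_equal(gm.values, back.values)
        assert back.differential_stability == 0.45
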