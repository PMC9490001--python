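"""Reaction coordinates, Boltzmann-inverted surfaces, basin analysis, RMSF."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nmrdyn.constants import KB_KJ_MOL
from nmrdyn.fes import (
    FESGrid,
    basin_analysis,
    compute_fes,
    radius_of_gyration,
    rmsf,
    sidechain_distance,
)
from nmrdyn.refine import make_hinged_chain
from nmrdyn.types import Conformation, ValidationError

from conftest import build_conformation


def _rigid_copy(conf, seed=0):
    rng = np.random.RandomState(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(size=3) * 20
    return conf.with_coords(conf.coords @ R.T + t)


class TestRadiusOfGyration:
    def test_symmetric_pair(self):
        conf = Conformation(
            res_index=[1, 2], res_aa=["G", "G"], atom_names=["CA", "CA"],
            elements=["C", "C"], coords=[[0, 0, 0], [2, 0, 0]],
        )
        assert radius_of_gyration(conf, weighting="uniform") == pytest.approx(1.0)
        # equal masses: mass weighting gives the same value
        assert radius_of_gyration(conf, weighting="mass") == pytest.approx(1.0)

    def test_rigid_body_invariance(self, random_conf):
        rg0 = radius_of_gyration(random_conf)
        assert radius_of_gyration(_rigid_copy(random_conf)) == pytest.approx(
            rg0, abs=1e-10
        )

    def test_matches_direct_sum_oracle(self):
        conf = build_conformation(n_res=250, seed=8)
        from nmrdyn.fes import _masses
        m = _masses(conf)
        com = (m[:, None] * conf.coords).sum(axis=0) / m.sum()
        brute = np.sqrt(
            sum(mi * np.sum((r - com) ** 2) for mi, r in zip(m, conf.coords)) / m.sum()
        )
        assert radius_of_gyration(conf) == pytest.approx(brute, rel=1e-12)

    def test_single_atom_warns_zero(self):
        conf = Conformation([1], ["G"], ["CA"], ["C"], [[1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning):
            assert radius_of_gyration(conf) == 0.0


class TestSidechainDistance:
    def _two_sidechains(self, d=5.0):
        return Conformation(
            res_index=[1, 1, 2, 2], res_aa=["C", "C", "C", "C"],
            atom_names=["CA", "SG", "CA", "SG"], elements=["C", "S", "C", "S"],
            coords=[[0, 0, 0], [1, 0, 0], [d, 5, 0], [1 + d, 0, 0]],
        )

    def test_single_atom_sidechains_agree_across_modes(self):
        conf = self._two_sidechains(d=5.0)
        for mode in ("centroid", "min", ("SG", "SG")):
            assert sidechain_distance(conf, 1, 2, mode=mode) == pytest.approx(5.0)

    def test_min_leq_centroid(self):
        conf = Conformation(
            res_index=[1, 1, 1, 2, 2, 2], res_aa=["R"] * 3 + ["N"] * 3,
            atom_names=["CA", "CB", "CG", "CA", "CB", "CG"],
            elements=["C"] * 6,
            coords=[[0, 0, 0], [1, 0, 0], [2, 1, 0],
                    [8, 0, 0], [6, 0, 0], [7, 2, 0]],
        )
        d_min = sidechain_distance(conf, 1, 2, mode="min")
        d_cen = sidechain_distance(conf, 1, 2, mode="centroid")
        assert d_min <= d_cen

    def test_centroid_matches_hand_computed(self):
        """Arg/Asn-like pair: centroid distance equals the hand arithmetic."""
        arg_side = np.array([[1.0, 0, 0], [2.0, 0.5, 0], [3.0, 0.2, 0.4]])
        asn_side = np.array([[7.0, 1.0, 0], [8.0, 0.0, 0.5]])
        conf = Conformation(
            res_index=[1] * 4 + [2] * 3,
            res_aa=["R"] * 4 + ["N"] * 3,
            atom_names=["CA", "CB", "CG", "CD", "CA", "CB", "CG"],
            elements=["C"] * 7,
            coords=np.vstack([[0, 0, 0], arg_side, [6, 1, 0], asn_side]),
        )
        expected = np.linalg.norm(arg_side.mean(axis=0) - asn_side.mean(axis=0))
        assert sidechain_distance(conf, 1, 2) == pytest.approx(expected, rel=1e-12)

    def test_glycine_suggests_ca_mode(self):
        conf = Conformation(
            res_index=[1, 2], res_aa=["G", "G"], atom_names=["CA", "CA"],
            elements=["C", "C"], coords=[[0, 0, 0], [4, 0, 0]],
        )
        with pytest.raises(ValidationError, match="ca"):
            sidechain_distance(conf, 1, 2)
        assert sidechain_distance(conf, 1, 2, mode="ca") == pytest.approx(4.0)


class TestComputeFES:
    def test_uniform_two_bins_flat(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, 2, 100_000), rng.uniform(0, 1, 100_000)])
        grid = compute_fes(pts, bins=(2, 1), temperature_K=310.0,
                           ranges=((0, 2), (0, 1)))
        finite = grid.G[np.isfinite(grid.G)]
        assert finite.max() - finite.min() <= 0.1

    def test_two_gaussian_closed_form(self):
        """70:30 population split at 310 K: basin depth difference matches
        -kB T ln(30/70) within 0.2 kJ/mol at n = 1e5."""
        rng = np.random.default_rng(1)
        n = 100_000
        labels = rng.choice(2, size=n, p=[0.7, 0.3])
        means = np.array([[10.0, 5.0], [11.5, 9.0]])
        pts = means[labels] + rng.standard_normal((n, 2)) * 0.3
        grid = compute_fes(pts, bins=40, temperature_K=310.0)
        report = basin_analysis(grid, {"B1": tuple(means[0]), "D1": tuple(means[1])})
        expected = -KB_KJ_MOL * 310.0 * np.log(0.3 / 0.7)
        assert report.delta_G[("B1", "D1")] == pytest.approx(expected, abs=0.2)

    def test_linear_in_temperature(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((5000, 2))
        g1 = compute_fes(pts, bins=10, temperature_K=310.0)
        g2 = compute_fes(pts, bins=10, temperature_K=620.0)
        occ = np.isfinite(g1.G)
        np.testing.assert_allclose(g2.G[occ], 2.0 * g1.G[occ], rtol=1e-12)

    def test_boltzmann_reinversion_round_trip(self):
        """populations() recovers the bin occupancies exactly."""
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((20_000, 2))
        grid = compute_fes(pts, bins=15, temperature_K=353.0)
        p = grid.populations()
        np.testing.assert_allclose(p, grid.counts / grid.counts.sum(), rtol=1e-10)

    def test_degenerate_single_bin_warns(self):
        pts = np.full((500, 2), 3.0)
        with pytest.warns(UserWarning, match="single bin"):
            compute_fes(pts, bins=5)

    def test_few_samples_warn(self):
        with pytest.warns(UserWarning, match="noisy"):
            compute_fes(np.random.default_rng(0).standard_normal((50, 2)), bins=5)


class TestBasinAnalysis:
    def _grid_from_G(self, G, T=310.0):
        G = np.asarray(G, dtype=float)
        kT = KB_KJ_MOL * T
        counts = np.where(np.isfinite(G), np.exp(-G / kT) * 1e4, 0).astype(int)
        nx, ny = G.shape
        return FESGrid(np.arange(nx + 1.0), np.arange(ny + 1.0), counts, G, T)

    def test_single_basin(self):
        G = np.array([[0.0, 1.0, 2.0], [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
        report = basin_analysis(self._grid_from_G(G))
        assert len(report.minima) == 1
        assert report.depth == pytest.approx(4.0)

    def test_hand_built_delta_g(self):
        G = np.full((3, 3), np.inf)
        G[0, 0] = 0.0
        G[2, 2] = 2.2
        report = basin_analysis(
            self._grid_from_G(G), {"B1": (0.5, 0.5), "D1": (2.5, 2.5)}
        )
        assert report.delta_G[("B1", "D1")] == pytest.approx(2.2)

    def test_named_point_in_empty_bin_rejected(self):
        G = np.full((3, 3), np.inf)
        G[0, 0] = 0.0
        G[2, 2] = 2.2
        with pytest.raises(ValidationError, match="empty bin"):
            basin_analysis(self._grid_from_G(G), {"X": (1.5, 1.5)})

    def test_two_gaussian_minima_near_generating_means(self):
        rng = np.random.default_rng(4)
        n = 50_000
        labels = rng.choice(2, size=n, p=[0.6, 0.4])
        means = np.array([[0.0, 0.0], [4.0, 4.0]])
        pts = means[labels] + rng.standard_normal((n, 2)) * 0.4
        grid = compute_fes(pts, bins=30)
        report = basin_analysis(grid, smooth_sigma=1.0)
        bw = (grid.x_edges[1] - grid.x_edges[0], grid.y_edges[1] - grid.y_edges[0])
        for mean in means:
            best = min(
                report.minima,
                key=lambda m: np.hypot(m[0][0] - mean[0], m[0][1] - mean[1]),
            )
            assert abs(best[0][0] - mean[0]) <= bw[0]
            assert abs(best[0][1] - mean[1]) <= bw[1]


class TestRMSF:
    def test_identical_models_zero(self):
        conf, _, _ = make_hinged_chain()
        vals = rmsf([conf.with_coords(conf.coords, model_id=m) for m in range(1, 5)])
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in vals.values())

    def test_rigid_copies_zero_after_superposition(self):
        conf, _, _ = make_hinged_chain()
        models = [_rigid_copy(conf, seed=s) for s in range(6)]
        vals = rmsf(models, superpose=True)
        assert all(v == pytest.approx(0.0, abs=1e-7) for v in vals.values())

    def test_two_point_displacement_closed_form(self):
        """One residue displaced +-d in half the models: its RMSF equals d
        (no superposition), others 0."""
        conf, _, _ = make_hinged_chain()
        d = 0.8
        ia = conf.atom_index(6, "CA")
        models = []
        for m in range(8):
            x = conf.coords.copy()
            x[ia, 2] += d if m % 2 == 0 else -d
            models.append(conf.with_coords(x, model_id=m + 1))
        vals = rmsf(models, superpose=False)
        assert vals[6] == pytest.approx(d, rel=1e-12)
        for r, v in vals.items():
            if r != 6:
                assert v == pytest.approx(0.0, abs=1e-12)
        # with superposition the fit redistributes a small part of the
        # displacement but the picture is unchanged
        vals_s = rmsf(models, superpose=True)
        assert vals_s[6] == pytest.approx(d, rel=0.05)
        assert max(v for r, v in vals_s.items() if r != 6) < 0.1 * d

    def test_topology_mismatch_rejected(self):
        conf, _, _ = make_hinged_chain()
        other = build_conformation(n_res=10)
        with pytest.raises(ValidationError, match="topology"):
            rmsf([conf, other])

    def test_rigid_transform_of_whole_ensemble_invariant(self):
        conf, _, _ = make_hinged_chain()
        rng = np.random.default_rng(5)
        models = [conf.with_coords(conf.coords + rng.normal(size=conf.coords.shape) * 0.3,
                                   model_id=m) for m in range(1, 6)]
        base = rmsf(models)
        R = Rotation.from_euler("xyz", [30, -60, 110], degrees=True).as_matrix()
        moved = [c.with_coords(c.coords @ R.T + np.array([5.0, -3.0, 9.0]))
                 for c in models]
        after = rmsf(moved)
        for r in base:
            assert after[r] == pytest.approx(base[r], abs=1e-8)
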