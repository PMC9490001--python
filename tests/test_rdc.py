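"""RDC back-calculation, tensor fitting, Q factors, restraint energy."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from nmrdyn.constants import dipolar_coupling_constant
from nmrdyn.rdc import (
    AlignmentTensor,
    ConditioningError,
    RDCRecord,
    RDCRestraint,
    ReplicaEnsemble,
    back_calculate_rdc,
    bond_vectors,
    ensemble_average_rdc,
    q_factor,
    rdc_restraint_energy,
    steric_tensor,
    svd_fit_tensor,
)
from nmrdyn.types import Conformation, ResidueID, ValidationError

from conftest import build_conformation

TENSOR = AlignmentTensor.from_components([3e-4, -1e-4, 2e-4, -2.5e-4, 1e-4])


def _records(conf, pairs=("N-H",), d=0.0):
    recs = []
    for rid in conf.residues():
        for pair in pairs:
            if pair == "C-N" and rid.index == 1:
                continue
            recs.append(RDCRecord(rid, pair, d))
    return recs


class TestBondVectors:
    def test_unit_vector_along_x(self):
        conf = Conformation(
            res_index=[1, 1], res_aa=["A", "A"], atom_names=["N", "H"],
            elements=["N", "H"], coords=[[0, 0, 0], [1.02, 0, 0]],
        )
        vecs = bond_vectors(conf, "N-H")
        assert len(vecs) == 1
        np.testing.assert_allclose(vecs[0][1], [1, 0, 0], atol=1e-12)

    def test_proline_has_no_amide_vector(self):
        conf = Conformation(
            res_index=[1, 1, 2, 2], res_aa=["A", "A", "P", "P"],
            atom_names=["N", "H", "N", "CA"], elements=["N", "H", "N", "C"],
            coords=[[0, 0, 0], [1, 0, 0], [5, 0, 0], [6, 0, 0]],
        )
        vecs = bond_vectors(conf, "N-H")
        assert [rid.index for rid, _ in vecs] == [1]

    def test_ideal_helix_vectors_near_axis(self):
        """N-H vectors of an ideal helix stay within 25 degrees of its axis."""
        res_index, res_aa, names, elems, coords = [], [], [], [], []
        axis = np.array([0.0, 0.0, 1.0])
        for i in range(12):
            ang = np.deg2rad(100.0 * i)
            n = np.array([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * i])
            tilt = np.deg2rad(15.0)
            h_dir = np.cos(tilt) * (-axis) + np.sin(tilt) * np.array(
                [np.cos(ang), np.sin(ang), 0.0]
            )
            for nm, el, pos in (("N", "N", n), ("H", "H", n + 1.02 * h_dir)):
                res_index.append(i + 1)
                res_aa.append("A")
                names.append(nm)
                elems.append(el)
                coords.append(pos)
        conf = Conformation(res_index, res_aa, names, elems, np.array(coords))
        for _, v in bond_vectors(conf, "N-H"):
            angle = np.degrees(np.arccos(abs(v @ axis)))
            assert angle < 25.0

    def test_zero_length_vector_rejected(self):
        conf = Conformation(
            res_index=[1, 1], res_aa=["A", "A"], atom_names=["N", "H"],
            elements=["N", "H"], coords=[[0, 0, 0], [0, 0, 0]],
        )
        with pytest.raises(ValidationError, match="zero-length"):
            bond_vectors(conf, "N-H")


class TestBackCalculation:
    def test_zero_tensor_gives_zero(self, random_conf):
        zero = AlignmentTensor(np.zeros((3, 3)))
        recs = _records(random_conf)
        np.testing.assert_array_equal(
            back_calculate_rdc(random_conf, zero, recs), np.zeros(len(recs))
        )

    def test_principal_axis_identity(self):
        """v along the unique axis of an axial tensor gives D_max * S_zz."""
        szz = 6e-4
        tensor = AlignmentTensor(np.diag([-szz / 2, -szz / 2, szz]))
        conf = Conformation(
            res_index=[1, 1], res_aa=["A", "A"], atom_names=["N", "H"],
            elements=["N", "H"], coords=[[0, 0, 0], [0, 0, 1.02]],
        )
        d = back_calculate_rdc(conf, tensor, _records(conf))
        assert d[0] == pytest.approx(dipolar_coupling_constant("N-H") * szz, rel=1e-12)

    def test_matches_brute_force_contraction(self, random_conf):
        recs = _records(random_conf, pairs=("N-H", "C-N"))
        d = back_calculate_rdc(random_conf, TENSOR, recs)
        for rec, dc in zip(recs, d):
            if rec.pair == "N-H":
                a = random_conf.atom_coord(rec.residue.index, "N")
                b = random_conf.atom_coord(rec.residue.index, "H")
            else:
                a = random_conf.atom_coord(rec.residue.index - 1, "C")
                b = random_conf.atom_coord(rec.residue.index, "N")
            v = (b - a) / np.linalg.norm(b - a)
            brute = dipolar_coupling_constant(rec.pair) * v @ TENSOR.saupe @ v
            assert dc == pytest.approx(brute, abs=1e-9)

    def test_rotational_covariance(self, random_conf):
        """Rotating structure and tensor together leaves all couplings fixed."""
        recs = _records(random_conf, pairs=("N-H", "C-N"))
        d0 = back_calculate_rdc(random_conf, TENSOR, recs)
        R = Rotation.from_euler("zyz", [40, 65, -20], degrees=True).as_matrix()
        rot = random_conf.with_coords(random_conf.coords @ R.T)
        d1 = back_calculate_rdc(rot, TENSOR.rotated(R), recs)
        np.testing.assert_allclose(d1, d0, atol=1e-10)


class TestSVDFit:
    def test_noiseless_exact_recovery(self, random_conf):
        recs = _records(random_conf, pairs=("N-H", "C-N"))
        d = back_calculate_rdc(random_conf, TENSOR, recs)
        data = [RDCRecord(r.residue, r.pair, float(v)) for r, v in zip(recs, d)]
        tensor, q = svd_fit_tensor(random_conf, data)
        np.testing.assert_allclose(tensor.saupe, TENSOR.saupe, atol=1e-9)
        assert q < 1e-9

    def test_noisy_q_scales_with_noise(self):
        """5% Gaussian noise on 100 couplings gives Q near 0.05."""
        conf = build_conformation(n_res=50, seed=3)
        recs = _records(conf, pairs=("N-H", "C-N"))
        d = back_calculate_rdc(conf, TENSOR, recs)
        rms = np.sqrt(np.mean(d**2))
        qs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            noisy = d + 0.05 * rms * rng.standard_normal(len(d))
            data = [RDCRecord(r.residue, r.pair, float(v)) for r, v in zip(recs, noisy)]
            _, q = svd_fit_tensor(conf, data)
            qs.append(q)
        assert np.mean(qs) == pytest.approx(0.05, abs=0.02)

    def test_underdetermined_rejected(self, random_conf):
        recs = _records(random_conf)[:4]
        with pytest.raises(ValidationError, match=">= 5"):
            svd_fit_tensor(random_conf, recs)

    def test_collinear_vectors_raise_conditioning_error(self):
        n = 8
        coords = []
        for i in range(n):
            coords += [[3.0 * i, 0, 0], [3.0 * i + 1.02, 0, 0]]  # all N-H along x
        conf = Conformation(
            res_index=np.repeat(np.arange(1, n + 1), 2),
            res_aa=["A"] * 2 * n,
            atom_names=["N", "H"] * n,
            elements=["N", "H"] * n,
            coords=np.array(coords, dtype=float),
        )
        recs = [RDCRecord(ResidueID(i, "A"), "N-H", 1.0) for i in range(1, n + 1)]
        with pytest.raises(ConditioningError, match="condition number"):
            svd_fit_tensor(conf, recs)

    def test_fit_is_a_minimum(self, random_conf):
        """Random perturbations of the fitted tensor increase the residual."""
        recs = _records(random_conf, pairs=("N-H", "C-N"))
        d = back_calculate_rdc(random_conf, TENSOR, recs)
        rng = np.random.default_rng(1)
        noisy = d + 0.3 * rng.standard_normal(len(d))
        data = [RDCRecord(r.residue, r.pair, float(v)) for r, v in zip(recs, noisy)]
        tensor, _ = svd_fit_tensor(random_conf, data)

        def sse(t):
            calc = back_calculate_rdc(random_conf, t, data)
            return np.sum((calc - noisy) ** 2)

        base = sse(tensor)
        for _ in range(20):
            pert = tensor.components + rng.standard_normal(5) * 1e-5
            assert sse(AlignmentTensor.from_components(pert)) >= base


class TestQFactor:
    def test_identity_and_extremes(self):
        d = np.array([3.0, -2.0, 5.0])
        assert q_factor(d, d) == 0.0
        assert q_factor(np.zeros(3), d) == 1.0
        assert q_factor(1.1 * d, d) == pytest.approx(0.1, rel=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError, match="rms"):
            q_factor([1.0], [0.0])

    @given(st.floats(min_value=0.0, max_value=2.0))
    def test_scaling_identity(self, c):
        d = np.array([4.0, -1.5, 2.0, 6.0])
        assert q_factor(c * d, d) == pytest.approx(abs(c - 1.0), abs=1e-12)


class TestEnsembleAveraging:
    def test_identical_replicas_equal_single_structure(self, random_conf):
        recs = _records(random_conf, pairs=("N-H", "C-N"))
        d = back_calculate_rdc(random_conf, TENSOR, recs)
        data = [RDCRecord(r.residue, r.pair, float(v)) for r, v in zip(recs, d)]
        ens = ReplicaEnsemble([random_conf.with_coords(random_conf.coords, model_id=m)
                               for m in range(1, 5)])
        avg = ensemble_average_rdc(ens, data, mode="per-replica-svd")
        single, _ = svd_fit_tensor(random_conf, data)
        np.testing.assert_allclose(
            avg, back_calculate_rdc(random_conf, single, data), atol=1e-10
        )

    def test_plus_minus_theta_closed_form(self):
        """Two replicas at +-theta from the unique axis average to the
        closed-form single value (P2(cos theta) is even in theta)."""
        szz = 5e-4
        tensor_comp = AlignmentTensor(np.diag([-szz / 2, -szz / 2, szz])).components
        theta = np.deg2rad(35.0)
        confs = []
        for sign in (+1, -1):
            v = np.array([np.sin(sign * theta), 0.0, np.cos(sign * theta)])
            confs.append(Conformation(
                res_index=[1, 1], res_aa=["A", "A"], atom_names=["N", "H"],
                elements=["N", "H"], coords=[[0, 0, 0], 1.02 * v],
            ))
        recs = [RDCRecord(ResidueID(1, "A"), "N-H", 0.0)]
        restraint = RDCRestraint(confs[0], recs, alpha=0.0, mode="shared-svd")
        coords = np.stack([c.coords for c in confs])
        d = restraint.d_calc(coords, {"medium1": tensor_comp})
        dmax = dipolar_coupling_constant("N-H")
        p2 = 0.5 * (3 * np.cos(theta) ** 2 - 1)
        assert d[0] == pytest.approx(dmax * szz * p2, rel=1e-10)

    def test_heterogeneous_ensemble_matches_loop_oracle(self):
        base = build_conformation(n_res=12, seed=5)
        rng = np.random.default_rng(9)
        reps = [base.with_coords(base.coords + rng.normal(size=base.coords.shape) * 0.4,
                                 model_id=m) for m in range(1, 17)]
        recs = _records(base, pairs=("N-H", "C-N"), d=1.0)
        ens = ReplicaEnsemble(reps)
        avg = ensemble_average_rdc(ens, recs, mode="per-replica-svd")
        # independent loop: per-replica SVD fit then plain mean
        acc = np.zeros(len(recs))
        for rep in reps:
            t, _ = svd_fit_tensor(rep, recs)
            acc += back_calculate_rdc(rep, t, recs)
        np.testing.assert_allclose(avg, acc / len(reps), atol=1e-10)


class TestStericTensor:
    def test_rod_is_axial_along_rod(self):
        direction = np.array([1.0, 2.0, -1.0])
        direction /= np.linalg.norm(direction)
        coords = np.outer(np.linspace(-10, 10, 21), direction)
        coords += np.random.default_rng(0).normal(size=coords.shape) * 1e-3
        conf = Conformation(
            res_index=np.arange(1, 22), res_aa=["A"] * 21,
            atom_names=[f"C{i}" for i in range(21)][:21], elements=["C"] * 21,
            coords=coords,
        )
        # single residue constraint: use one atom name per residue instead
        tensor = steric_tensor(conf)
        assert abs(tensor.rhombicity) < 0.01
        _, vecs = tensor.principal()
        assert abs(vecs[:, 2] @ direction) > 0.999

    def test_isotropic_point_set_warns(self):
        # vertices of a regular tetrahedron: zero gyration anisotropy
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
        conf = Conformation(
            res_index=[1, 1, 1, 1], res_aa=["A"] * 4,
            atom_names=["C1", "C2", "C3", "C4"], elements=["C"] * 4, coords=verts,
        )
        with pytest.warns(UserWarning, match="isotropic"):
            tensor = steric_tensor(conf)
        assert np.abs(tensor.saupe).max() < 1e-12

    def test_prolate_cloud_low_rhombicity(self):
        rng = np.random.default_rng(4)
        coords = rng.standard_normal((2000, 3)) * np.array([8.0, 4.0, 4.0])
        conf = Conformation(
            res_index=np.arange(1, 2001), res_aa=["A"] * 2000,
            atom_names=["CA"] * 2000, elements=["C"] * 2000, coords=coords,
        )
        # duplicate atom names across residues are fine; within-residue is what counts
        tensor = steric_tensor(conf)
        assert abs(tensor.rhombicity) < 0.05


class TestRestraintEnergy:
    def _setup(self, seed=0, M=3):
        base = build_conformation(n_res=10, seed=seed)
        rng = np.random.default_rng(seed + 100)
        reps = [base.with_coords(base.coords + rng.normal(size=base.coords.shape) * 0.2,
                                 model_id=m) for m in range(1, M + 1)]
        recs = _records(base, pairs=("N-H", "C-N"))
        d = back_calculate_rdc(base, TENSOR, recs)
        data = [RDCRecord(r.residue, r.pair, float(v) + rng.normal() * 1.5, 0.5)
                for r, v in zip(recs, d)]
        return base, ReplicaEnsemble(reps), data

    def test_zero_when_exact(self, random_conf):
        recs = _records(random_conf, pairs=("N-H", "C-N"))
        d = back_calculate_rdc(random_conf, TENSOR, recs)
        data = [RDCRecord(r.residue, r.pair, float(v)) for r, v in zip(recs, d)]
        ens = ReplicaEnsemble([random_conf])
        tensors = {"medium1": TENSOR.components}
        e, g = rdc_restraint_energy(ens, data, alpha=2.0, tensors=tensors)
        assert e == pytest.approx(0.0, abs=1e-16)
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_unit_case(self):
        conf = Conformation(
            res_index=[1, 1], res_aa=["A", "A"], atom_names=["N", "H"],
            elements=["N", "H"], coords=[[0, 0, 0], [0, 0, 1.02]],
        )
        d_true = back_calculate_rdc(conf, TENSOR, _records(conf))[0]
        data = [RDCRecord(ResidueID(1, "A"), "N-H", float(d_true) + 1.0)]
        e, _ = rdc_restraint_energy(
            ens=ReplicaEnsemble([conf]), rdcs=data, alpha=1.0,
            tensors={"medium1": TENSOR.components},
        )
        assert e == pytest.approx(1.0, rel=1e-12)

    def test_gradient_matches_finite_differences(self):
        base, ens, data = self._setup()
        restraint = RDCRestraint(base, data, alpha=0.7, mode="shared-svd")
        coords = ens.coords
        tensors = restraint.fit_tensors(coords)
        e, g = restraint.energy_and_grad(coords, tensors)
        rng = np.random.default_rng(2)
        h = 1e-6
        for _ in range(12):
            m = rng.integers(coords.shape[0])
            a = rng.integers(coords.shape[1])
            k = rng.integers(3)
            cp = coords.copy()
            cp[m, a, k] += h
            cm = coords.copy()
            cm[m, a, k] -= h
            fd = (restraint.energy_and_grad(cp, tensors)[0]
                  - restraint.energy_and_grad(cm, tensors)[0]) / (2 * h)
            assert g[m, a, k] == pytest.approx(fd, rel=1e-5, abs=1e-10)

    def test_nonnegative_and_replica_permutation_symmetry(self):
        base, ens, data = self._setup(seed=3, M=4)
        restraint = RDCRestraint(base, data, alpha=1.3, mode="shared-svd")
        coords = ens.coords
        tensors = restraint.fit_tensors(coords)
        e, g = restraint.energy_and_grad(coords, tensors)
        assert e >= 0
        perm = [2, 0, 3, 1]
        e_p, g_p = restraint.energy_and_grad(coords[perm], tensors)
        assert e_p == pytest.approx(e, rel=1e-12)
        np.testing.assert_allclose(g_p, g[perm], atol=1e-12)

    def test_disjoint_residues_rejected(self):
        base = build_conformation(n_res=5, seed=0)
        data = [RDCRecord(ResidueID(50, "A"), "N-H", 1.0)]
        with pytest.raises(ValidationError, match="overlap"):
            rdc_restraint_energy(ReplicaEnsemble([base]), data, alpha=1.0)
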