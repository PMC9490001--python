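"""Residual dipolar couplings: back-calculation, alignment tensors, restraints.

An RDC for internuclear unit vector v under Saupe order matrix S is

    D_calc = D_max * v^T S v   (Hz),

with D_max the pair-specific static dipolar interaction constant.  The Saupe
matrix is symmetric and traceless (5 independent components), so given a
structure and >= 5 measured couplings the tensor follows from linear least
squares (the "SVD fit").  Agreement is scored by the Q factor

    Q = rms(D_calc - D_exp) / rms(D_exp).

For a replica ensemble the calculated coupling is the average over the M
replicas, and the restraint pseudo-energy

    E_RDC = alpha * sum_i w_i (D_calc,i - D_exp,i)^2

carries analytic gradients with respect to every replica's coordinates
(tensors held fixed during an evaluation, refit at a configurable stride).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import dipolar_coupling_constant
from .types import Conformation, ResidueID, ValidationError

__all__ = [
    "RDCRecord",
    "AlignmentTensor",
    "ReplicaEnsemble",
    "ConditioningError",
    "bond_vectors",
    "back_calculate_rdc",
    "svd_fit_tensor",
    "q_factor",
    "ensemble_average_rdc",
    "steric_tensor",
    "rdc_restraint_energy",
    "RDCRestraint",
]

PAIR_TYPES = ("N-H", "C-N")


class ConditioningError(ValidationError):
    """The tensor-fit design matrix is (near-)rank-deficient."""


@dataclass
class RDCRecord:
    residue: ResidueID
    pair: str  # "N-H" or "C-N"
    D_exp: float  # Hz
    error: float = 0.0  # Hz
    medium: str = "medium1"

    def __post_init__(self) -> None:
        if self.pair not in PAIR_TYPES:
            raise ValidationError(f"unknown coupling type {self.pair!r}")
        if self.error < 0:
            raise ValidationError("RDC error must be >= 0")
        if not np.isfinite(self.D_exp):
            raise ValidationError("D_exp must be finite")


@dataclass
class AlignmentTensor:
    """Traceless symmetric Saupe order matrix (dimensionless)."""

    saupe: np.ndarray  # (3, 3)

    def __post_init__(self) -> None:
        self.saupe = np.asarray(self.saupe, dtype=float)
        if self.saupe.shape != (3, 3):
            raise ValidationError("Saupe matrix must be 3x3")
        if not np.allclose(self.saupe, self.saupe.T, atol=1e-12):
            raise ValidationError("Saupe matrix must be symmetric")
        if abs(np.trace(self.saupe)) > 1e-12 * max(1.0, np.abs(self.saupe).max()):
            raise ValidationError("Saupe matrix must be traceless")

    @classmethod
    def from_components(cls, s: Sequence[float]) -> "AlignmentTensor":
        """Build from the 5-vector (Sxx, Syy, Sxy, Sxz, Syz); Szz = -Sxx-Syy."""
        sxx, syy, sxy, sxz, syz = map(float, s)
        szz = -sxx - syy
        return cls(np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]]))

    @property
    def components(self) -> np.ndarray:
        S = self.saupe
        return np.array([S[0, 0], S[1, 1], S[0, 1], S[0, 2], S[1, 2]])

    def principal(self) -> tuple[np.ndarray, np.ndarray]:
        """(eigenvalues, eigenvectors) ordered by |eigenvalue| ascending.

        The last eigenvalue S_zz' is the axial component; columns of the
        returned matrix are the principal axes.
        """
        vals, vecs = np.linalg.eigh(self.saupe)
        order = np.argsort(np.abs(vals))
        return vals[order], vecs[:, order]

    @property
    def rhombicity(self) -> float:
        """R = (2/3)(Sxx' - Syy') / Szz'; 0 for an axially symmetric tensor."""
        vals, _ = self.principal()
        sxx, syy, szz = vals
        if szz == 0:
            return 0.0
        return float((2.0 / 3.0) * (sxx - syy) / szz)

    def d_a(self, pair: str) -> float:
        """Axial magnitude D_a = D_max * Szz' / 2 (Hz) for a coupling type."""
        vals, _ = self.principal()
        return float(dipolar_coupling_constant(pair) * vals[2] / 2.0)

    def euler_angles(self) -> tuple[float, float, float]:
        """zyz Euler angles (degrees) of the principal frame."""
        _, vecs = self.principal()
        R = vecs
        if np.linalg.det(R) < 0:
            R = R.copy()
            R[:, 0] *= -1
        return tuple(Rotation.from_matrix(R).as_euler("zyz", degrees=True))

    def rotated(self, R: np.ndarray) -> "AlignmentTensor":
        return AlignmentTensor(R @ self.saupe @ R.T)


@dataclass
class ReplicaEnsemble:
    """M simultaneously simulated conformations sharing one topology."""

    replicas: list[Conformation]

    def __post_init__(self) -> None:
        if len(self.replicas) < 1:
            raise ValidationError("ensemble needs at least one replica")
        first = self.replicas[0]
        for i, c in enumerate(self.replicas[1:], start=2):
            if not c.same_topology(first):
                raise ValidationError(f"replica {i} differs in atom topology")

    @property
    def M(self) -> int:
        return len(self.replicas)

    @property
    def coords(self) -> np.ndarray:
        """(M, n_atoms, 3) coordinate stack."""
        return np.stack([c.coords for c in self.replicas])


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _pair_atom_indices(
    conf: Conformation, pair: str, quiet: bool = False
) -> list[tuple[ResidueID, int, int]]:
    """(residue, from-atom index, to-atom index) for each available coupling.

    N-H: N(i) -> H(i) (amide proton; prolines have none and are skipped).
    C-N: C'(i-1) -> N(i).
    """
    if pair not in PAIR_TYPES:
        raise ValidationError(f"unknown coupling type {pair!r}")
    out = []
    for rid in conf.residues():
        if pair == "N-H":
            if rid.aa == "P":
                continue
            i_from = conf.atom_index(rid.index, "N")
            i_to = conf.atom_index(rid.index, "H")
            if i_to is None:
                i_to = conf.atom_index(rid.index, "HN")
        else:
            i_from = conf.atom_index(rid.index - 1, "C")
            i_to = conf.atom_index(rid.index, "N")
        if i_from is None or i_to is None:
            if not quiet and pair == "N-H" and conf.atom_index(rid.index, "N") is not None:
                warnings.warn(
                    f"residue {rid.index}: missing atoms for {pair} vector; skipped",
                    stacklevel=2,
                )
            continue
        out.append((rid, i_from, i_to))
    return out


def bond_vectors(
    conf: Conformation, pair: str
) -> list[tuple[ResidueID, np.ndarray]]:
    """Unit internuclear vectors in the molecular frame for one coupling type."""
    out = []
    for rid, i_from, i_to in _pair_atom_indices(conf, pair):
        v = conf.coords[i_to] - conf.coords[i_from]
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise ValidationError(
                f"residue {rid.index}: zero-length {pair} vector"
            )
        out.append((rid, v / norm))
    return out


def _record_geometry(
    conf: Conformation, rdcs: Sequence[RDCRecord], strict: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-record (i_from, i_to, D_max, available) arrays for a topology."""
    cache: dict[str, dict[int, tuple[int, int]]] = {}
    for pair in PAIR_TYPES:
        cache[pair] = {
            rid.index: (i_f, i_t) for rid, i_f, i_t in _pair_atom_indices(conf, pair, quiet=True)
        }
    i_from = np.full(len(rdcs), -1, dtype=int)
    i_to = np.full(len(rdcs), -1, dtype=int)
    dmax = np.zeros(len(rdcs))
    avail = np.zeros(len(rdcs), dtype=bool)
    for k, rec in enumerate(rdcs):
        hit = cache[rec.pair].get(rec.residue.index)
        dmax[k] = dipolar_coupling_constant(rec.pair)
        if hit is None:
            if strict:
                raise ValidationError(
                    f"no {rec.pair} vector available for residue "
                    f"{rec.residue.index} in the structure"
                )
            continue
        i_from[k], i_to[k] = hit
        avail[k] = True
    return i_from, i_to, dmax, avail


def _unit_vectors(coords: np.ndarray, i_from: np.ndarray, i_to: np.ndarray):
    r = coords[i_to] - coords[i_from]
    norms = np.linalg.norm(r, axis=1)
    if np.any(norms < 1e-9):
        raise ValidationError("zero-length bond vector")
    return r / norms[:, None], norms


def _design_matrix(v: np.ndarray, dmax: np.ndarray) -> np.ndarray:
    """Rows map the Saupe 5-vector (Sxx, Syy, Sxy, Sxz, Syz) to D_calc."""
    x, y, z = v[:, 0], v[:, 1], v[:, 2]
    A = np.column_stack([x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z])
    return A * dmax[:, None]


# ---------------------------------------------------------------------------
# Back-calculation and fitting
# ---------------------------------------------------------------------------

def back_calculate_rdc(
    conf: Conformation,
    tensor: AlignmentTensor,
    rdcs: Sequence[RDCRecord],
    strict: bool = True,
) -> np.ndarray:
    """D_calc (Hz) for each record; NaN for unavailable geometry if not strict."""
    i_from, i_to, dmax, avail = _record_geometry(conf, rdcs, strict=strict)
    out = np.full(len(rdcs), np.nan)
    if not avail.any():
        return out
    v, _ = _unit_vectors(conf.coords, i_from[avail], i_to[avail])
    out[avail] = _design_matrix(v, dmax[avail]) @ tensor.components
    return out


def q_factor(d_calc: Sequence[float], d_exp: Sequence[float]) -> float:
    """Cornilescu Q = rms(D_calc - D_exp) / rms(D_exp)."""
    d_calc = np.asarray(d_calc, dtype=float)
    d_exp = np.asarray(d_exp, dtype=float)
    if d_calc.shape != d_exp.shape or d_calc.size < 1:
        raise ValidationError("D_calc and D_exp must have equal nonzero length")
    denom = np.sqrt(np.mean(d_exp**2))
    if denom == 0:
        raise ValidationError("Q factor undefined: rms(D_exp) = 0")
    return float(np.sqrt(np.mean((d_calc - d_exp) ** 2)) / denom)


def _weights(rdcs: Sequence[RDCRecord]) -> np.ndarray:
    errs = np.array([r.error for r in rdcs])
    if np.all(errs > 0):
        return 1.0 / errs**2
    return np.ones(len(rdcs))


def svd_fit_tensor(
    conf: Conformation,
    rdcs: Sequence[RDCRecord],
    cond_max: float = 1e8,
) -> tuple[AlignmentTensor, float]:
    """Least-squares Saupe tensor for one structure; returns (tensor, Q).

    Requires >= 5 records with available bond vectors.  Error-weighted when
    all records carry errors.  A design-matrix condition number above
    ``cond_max`` (collinear vectors) raises ConditioningError.
    """
    i_from, i_to, dmax, avail = _record_geometry(conf, rdcs, strict=False)
    if avail.sum() < 5:
        raise ValidationError(
            f"tensor fit needs >= 5 couplings with geometry, have {int(avail.sum())}"
        )
    v, _ = _unit_vectors(conf.coords, i_from[avail], i_to[avail])
    A = _design_matrix(v, dmax[avail])
    d_exp = np.array([r.D_exp for r in rdcs])[avail]
    w = np.sqrt(_weights(rdcs)[avail])
    cond = np.linalg.cond(A * w[:, None])
    if cond > cond_max:
        raise ConditioningError(
            f"design matrix condition number {cond:.3g} exceeds {cond_max:.3g}; "
            "bond vectors are (near-)collinear"
        )
    s, *_ = np.linalg.lstsq(A * w[:, None], d_exp * w, rcond=None)
    tensor = AlignmentTensor.from_components(s)
    return tensor, q_factor(A @ s, d_exp)


def steric_tensor(
    conf: Conformation, magnitude: float = 1e-3
) -> AlignmentTensor:
    """Shape-based alignment surrogate from the heavy-atom gyration tensor.

    The principal frame is that of the gyration tensor and the Saupe
    magnitudes are proportional to its (traceless) eigenvalue anisotropies,
    scaled so the largest principal component equals ``magnitude``.  This is
    an approximate steric model: it captures the orientation and rhombicity
    of shape-induced alignment, not its absolute strength; charge effects are
    not modelled.
    """
    heavy = conf.elements != "H"
    xyz = conf.coords[heavy]
    if len(xyz) < 3:
        raise ValidationError("steric tensor needs >= 3 heavy atoms")
    centered = xyz - xyz.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValidationError("steric tensor undefined for collinear atoms")
    G = centered.T @ centered / len(xyz)
    aniso = G - np.trace(G) / 3.0 * np.eye(3)
    scale = np.abs(np.linalg.eigvalsh(aniso)).max()
    if scale < 1e-9 * max(np.trace(G), 1.0):
        warnings.warn(
            "molecular shape is nearly isotropic; steric tensor is ~zero",
            stacklevel=2,
        )
        return AlignmentTensor(np.zeros((3, 3)))
    return AlignmentTensor(aniso * (magnitude / scale))


# ---------------------------------------------------------------------------
# Ensemble averaging and restraint energy
# ---------------------------------------------------------------------------

MODES = ("per-replica-svd", "shared-svd", "per-replica-steric")


def _medium_groups(rdcs: Sequence[RDCRecord]) -> dict[str, np.ndarray]:
    media: dict[str, list[int]] = {}
    for k, rec in enumerate(rdcs):
        media.setdefault(rec.medium, []).append(k)
    return {m: np.array(ix) for m, ix in media.items()}


class RDCRestraint:
    """Cached replica-averaged RDC machinery for one topology + RDC table.

    Groups records by alignment medium; maintains one tensor per medium
    (shared-svd) or per medium and replica (per-replica modes).  Tensors are
    held fixed within an energy evaluation and refit on demand, so gradients
    ignore tensor derivatives.
    """

    def __init__(
        self,
        topology: Conformation,
        rdcs: Sequence[RDCRecord],
        alpha: float = 1.0,
        mode: str = "shared-svd",
        steric_magnitude: float = 1e-3,
    ):
        if alpha < 0:
            raise ValidationError("force constant alpha must be >= 0")
        if mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
        self.rdcs = list(rdcs)
        self.alpha = float(alpha)
        self.mode = mode
        self.steric_magnitude = steric_magnitude
        self.i_from, self.i_to, self.dmax, avail = _record_geometry(
            topology, self.rdcs, strict=False
        )
        if not avail.any():
            raise ValidationError(
                "no overlapping residues between the ensemble topology and the "
                "RDC table"
            )
        if not avail.all():
            missing = [self.rdcs[k].residue.index for k in np.flatnonzero(~avail)]
            warnings.warn(
                f"{len(missing)} RDC record(s) without geometry dropped: "
                f"residues {sorted(set(missing))}",
                stacklevel=2,
            )
            keep = np.flatnonzero(avail)
            self.rdcs = [self.rdcs[k] for k in keep]
            self.i_from, self.i_to, self.dmax = (
                self.i_from[keep], self.i_to[keep], self.dmax[keep],
            )
        self.d_exp = np.array([r.D_exp for r in self.rdcs])
        self.w = _weights(self.rdcs)
        self.groups = _medium_groups(self.rdcs)
        self._topology = topology

    # -- tensors -----------------------------------------------------------

    def fit_tensors(self, coords: np.ndarray) -> dict[str, np.ndarray]:
        """Refit tensors for a coordinate stack (M, n_atoms, 3).

        Returns {medium: components array}; shape (5,) for shared-svd, else
        (M, 5).
        """
        M = coords.shape[0]
        tensors: dict[str, np.ndarray] = {}
        for medium, ix in self.groups.items():
            if self.mode == "shared-svd":
                A_bar = np.zeros((len(ix), 5))
                for m in range(M):
                    v, _ = _unit_vectors(coords[m], self.i_from[ix], self.i_to[ix])
                    A_bar += _design_matrix(v, self.dmax[ix])
                A_bar /= M
                wr = np.sqrt(self.w[ix])
                s, *_ = np.linalg.lstsq(A_bar * wr[:, None], self.d_exp[ix] * wr, rcond=None)
                tensors[medium] = s
            elif self.mode == "per-replica-svd":
                comps = np.zeros((M, 5))
                wr = np.sqrt(self.w[ix])
                for m in range(M):
                    v, _ = _unit_vectors(coords[m], self.i_from[ix], self.i_to[ix])
                    A = _design_matrix(v, self.dmax[ix])
                    comps[m], *_ = np.linalg.lstsq(
                        A * wr[:, None], self.d_exp[ix] * wr, rcond=None
                    )
                tensors[medium] = comps
            else:  # per-replica-steric
                comps = np.zeros((M, 5))
                for m in range(M):
                    conf_m = self._topology.with_coords(coords[m])
                    comps[m] = steric_tensor(conf_m, self.steric_magnitude).components
                tensors[medium] = comps
        return tensors

    def _tensor_matrix(self, comps: np.ndarray) -> np.ndarray:
        return AlignmentTensor.from_components(comps).saupe

    def d_calc(self, coords: np.ndarray, tensors: dict[str, np.ndarray]) -> np.ndarray:
        """Replica-averaged D_calc aligned with the record list."""
        M = coords.shape[0]
        out = np.zeros(len(self.rdcs))
        for medium, ix in self.groups.items():
            comp = tensors[medium]
            acc = np.zeros(len(ix))
            for m in range(M):
                v, _ = _unit_vectors(coords[m], self.i_from[ix], self.i_to[ix])
                A = _design_matrix(v, self.dmax[ix])
                s = comp if comp.ndim == 1 else comp[m]
                acc += A @ s
            out[ix] = acc / M
        return out

    def q(self, coords: np.ndarray, tensors: Optional[dict] = None) -> float:
        if tensors is None:
            tensors = self.fit_tensors(coords)
        return q_factor(self.d_calc(coords, tensors), self.d_exp)

    # -- incremental evaluation (Monte-Carlo hot path) ---------------------

    def replica_contrib(
        self, coords_m: np.ndarray, m: int, tensors: dict[str, np.ndarray]
    ) -> dict[str, np.ndarray]:
        """Per-medium back-calculated couplings of one replica (tensors fixed)."""
        out = {}
        for medium, ix in self.groups.items():
            comp = tensors[medium]
            s = comp if comp.ndim == 1 else comp[m]
            v, _ = _unit_vectors(coords_m, self.i_from[ix], self.i_to[ix])
            out[medium] = _design_matrix(v, self.dmax[ix]) @ s
        return out

    def all_contribs(
        self, coords: np.ndarray, tensors: dict[str, np.ndarray]
    ) -> dict[str, np.ndarray]:
        """{medium: (M, n_records_in_medium)} contribution matrices."""
        M = coords.shape[0]
        out = {
            medium: np.zeros((M, len(ix))) for medium, ix in self.groups.items()
        }
        for m in range(M):
            rows = self.replica_contrib(coords[m], m, tensors)
            for medium in out:
                out[medium][m] = rows[medium]
        return out

    def energy_from_contribs(self, contribs: dict[str, np.ndarray]) -> float:
        e = 0.0
        for medium, ix in self.groups.items():
            diff = contribs[medium].mean(axis=0) - self.d_exp[ix]
            e += self.alpha * np.sum(self.w[ix] * diff**2)
        return float(e)

    def q_from_contribs(self, contribs: dict[str, np.ndarray]) -> float:
        d_calc = np.zeros(len(self.rdcs))
        for medium, ix in self.groups.items():
            d_calc[ix] = contribs[medium].mean(axis=0)
        return q_factor(d_calc, self.d_exp)

    def energy_and_grad(
        self, coords: np.ndarray, tensors: dict[str, np.ndarray]
    ) -> tuple[float, np.ndarray]:
        """E_RDC and dE/dx for every replica atom; tensors held fixed."""
        M, n_atoms, _ = coords.shape
        grad = np.zeros_like(coords)
        energy = 0.0
        for medium, ix in self.groups.items():
            comp = tensors[medium]
            nk = len(ix)
            dcalc = np.zeros(nk)
            # cache per-replica unit vectors for the gradient pass
            vs, norms, Ss = [], [], []
            for m in range(M):
                v, nrm = _unit_vectors(coords[m], self.i_from[ix], self.i_to[ix])
                s = comp if comp.ndim == 1 else comp[m]
                S = self._tensor_matrix(s)
                dcalc += _design_matrix(v, self.dmax[ix]) @ s
                vs.append(v)
                norms.append(nrm)
                Ss.append(S)
            dcalc /= M
            diff = dcalc - self.d_exp[ix]
            energy += self.alpha * np.sum(self.w[ix] * diff**2)
            pref = 2.0 * self.alpha * self.w[ix] * diff * self.dmax[ix] / M
            for m in range(M):
                v, nrm, S = vs[m], norms[m], Ss[m]
                Sv = v @ S  # (nk, 3)
                vSv = np.einsum("ki,ki->k", v, Sv)
                dvec = (pref / nrm)[:, None] * 2.0 * (Sv - vSv[:, None] * v)
                np.add.at(grad[m], self.i_to[ix], dvec)
                np.add.at(grad[m], self.i_from[ix], -dvec)
        return float(energy), grad


def ensemble_average_rdc(
    ens: ReplicaEnsemble,
    rdcs: Sequence[RDCRecord],
    mode: str = "per-replica-svd",
    steric_magnitude: float = 1e-3,
) -> np.ndarray:
    """Replica-averaged D_calc for an ensemble: (1/M) sum over replicas.

    ``mode`` selects how each replica's tensor is obtained: refit per replica
    by SVD, one shared SVD tensor fit against the ensemble-averaged geometry,
    or predicted per replica from molecular shape.
    """
    restraint = RDCRestraint(ens.replicas[0], rdcs, alpha=0.0, mode=mode,
                             steric_magnitude=steric_magnitude)
    coords = ens.coords
    tensors = restraint.fit_tensors(coords)
    full = np.full(len(rdcs), np.nan)
    kept = {id(r): i for i, r in enumerate(restraint.rdcs)}
    vals = restraint.d_calc(coords, tensors)
    for i, rec in enumerate(rdcs):
        j = kept.get(id(rec))
        if j is not None:
            full[i] = vals[j]
    return full


def rdc_restraint_energy(
    ens: ReplicaEnsemble,
    rdcs: Sequence[RDCRecord],
    alpha: float,
    mode: str = "shared-svd",
    tensors: Optional[dict] = None,
) -> tuple[float, np.ndarray]:
    """E_RDC = alpha * sum_i w_i (D_calc,i - D_exp,i)^2 and its gradients.

    D_calc is the replica average; gradients are with respect to every
    replica's coordinates with tensors held fixed (refit here unless given).
    Returns (energy, gradient stack of shape (M, n_atoms, 3)).
    """
    restraint = RDCRestraint(ens.replicas[0], rdcs, alpha=alpha, mode=mode)
    coords = ens.coords
    if tensors is None:
        tensors = restraint.fit_tensors(coords)
    return restraint.energy_and_grad(coords, tensors)
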