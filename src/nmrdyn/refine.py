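"""Replica-averaged, RDC-restrained simulated-annealing refinement.

The production protocol this module implements is: equilibrate while gently
raising the restraint force constant alpha, then run cycles of simulated
annealing between a low and a high temperature, imposing the RDC pseudo-energy
as an average over M simultaneously simulated replicas,

    E_total = E_FF + E_RDC,

and extract conformations from the low-temperature end of each post-burn-in
cycle.  Replica averaging is what lets a heterogeneous set of couplings be
satisfied: the M replicas can populate different conformational basins whose
average matches the data, which no single structure can do.

Sampling is Metropolis Monte Carlo in Cartesian/torsion moves over a small
toy force field (harmonic bonds/angles, cosine torsions, soft excluded
volume, optional position restraints).  The toy potential stands in for a
molecular-mechanics force field at desk scale; it preserves the protocol's
logic (total energy, annealing ladder, replica-averaged restraint), not
production-scale energetics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import KB_KJ_MOL
from .rdc import RDCRecord, RDCRestraint
from .types import Conformation, ValidationError

logger = logging.getLogger("nmrdyn.refine")

__all__ = [
    "AnnealingSchedule",
    "RestraintRamp",
    "ToyPotential",
    "MoveSet",
    "TorsionMove",
    "RefinementTrajectory",
    "build_schedule",
    "run_refinement",
    "extract_ensemble",
    "make_harmonic_dimer",
    "make_hinged_chain",
    "make_beta_hairpin",
]


# ---------------------------------------------------------------------------
# Protocol configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnealingSchedule:
    """Simulated-annealing ladder.

    Within each cycle the temperature ramps T_low -> T_high -> T_low
    (triangular profile over ``steps_per_cycle`` MC steps).  Conformations
    are extracted from the final ``extraction_window`` fraction of each
    post-burn-in cycle, where the system sits at the low temperature.
    Defaults mirror the production protocol: 50 cycles, the first 20 excluded
    for convergence, extraction from the last eighth of each cycle.
    """

    T_low: float = 310.0
    T_high: float = 500.0
    n_cycles: int = 50
    burn_in_cycles: int = 20
    steps_per_cycle: int = 10_000
    extraction_window: float = 0.125
    frames_per_window: int = 1

    def __post_init__(self) -> None:
        if not (self.T_high > self.T_low > 0):
            raise ValidationError(
                f"need T_high > T_low > 0, got {self.T_high}, {self.T_low}"
            )
        if not (0 <= self.burn_in_cycles < self.n_cycles):
            raise ValidationError(
                f"burn-in ({self.burn_in_cycles}) must be < n_cycles "
                f"({self.n_cycles})"
            )
        if not (0 < self.extraction_window <= 1):
            raise ValidationError("extraction window must be in (0, 1]")
        if self.steps_per_cycle < 1 or self.frames_per_window < 1:
            raise ValidationError("steps_per_cycle and frames_per_window must be >= 1")

    @property
    def contributing_cycles(self) -> int:
        return self.n_cycles - self.burn_in_cycles

    def temperature(self, step: int) -> float:
        """Instantaneous temperature at an MC step within one cycle."""
        S = self.steps_per_cycle
        frac = 0.0 if S == 1 else step / (S - 1)
        tri = 1.0 - abs(2.0 * frac - 1.0)
        return self.T_low + (self.T_high - self.T_low) * tri

    def extraction_steps(self) -> np.ndarray:
        """Step indices (within a cycle) of the extracted frames."""
        S = self.steps_per_cycle
        start = int(np.floor(S * (1.0 - self.extraction_window)))
        candidates = np.arange(start, S)
        if len(candidates) == 0:
            raise ValidationError("extraction window contains no steps")
        picks = np.linspace(0, len(candidates) - 1, self.frames_per_window)
        return np.unique(candidates[np.round(picks).astype(int)])


def build_schedule(cfg: Optional[dict] = None) -> AnnealingSchedule:
    """AnnealingSchedule from a config mapping; unknown keys are rejected."""
    cfg = dict(cfg or {})
    known = {f for f in AnnealingSchedule.__dataclass_fields__}
    unknown = set(cfg) - known
    if unknown:
        raise ValidationError(f"unknown schedule keys: {sorted(unknown)}")
    return AnnealingSchedule(**cfg)


@dataclass(frozen=True)
class RestraintRamp:
    """Force-constant ramp for the equilibration phase.

    ``profile`` multipliers are applied stage by stage before the annealing
    cycles start; they must be non-decreasing and end at 1 so the cycles run
    at the full alpha_target.  Default: linear 10-stage ramp.
    """

    alpha_target: float = 1.0
    profile: tuple = tuple(np.linspace(0.1, 1.0, 10))
    steps_per_stage: int = 500

    def __post_init__(self) -> None:
        if self.alpha_target < 0:
            raise ValidationError("alpha_target must be >= 0")
        prof = np.asarray(self.profile, dtype=float)
        if len(prof) and (np.any(np.diff(prof) < 0) or abs(prof[-1] - 1.0) > 1e-12):
            raise ValidationError("ramp multipliers must be non-decreasing, ending at 1")


# ---------------------------------------------------------------------------
# Toy force field
# ---------------------------------------------------------------------------

class ToyPotential:
    """Small molecular-mechanics surrogate with analytic gradients.

    Terms (all energies kJ/mol, lengths Å, angles rad):

    * harmonic bonds        k (r - r0)^2
    * harmonic angles       k (theta - theta0)^2
    * cosine torsions       k (1 - cos(m (phi - phi_min)))
    * soft excluded volume  eps (1 - d/sigma)^2 for non-excluded pairs, d < sigma
    * position restraints   k |r - r_ref|^2
    """

    def __init__(
        self,
        n_atoms: int,
        bonds: Sequence[tuple[int, int, float, float]] = (),
        angles: Sequence[tuple[int, int, int, float, float]] = (),
        torsions: Sequence[tuple[int, int, int, int, float, float, int]] = (),
        repulsion_eps: float = 0.0,
        repulsion_sigma: float = 2.5,
        position_restraints: Sequence[tuple[int, np.ndarray, float]] = (),
        parameter_set: str = "custom",
    ):
        self.n_atoms = n_atoms
        self.bonds = [(int(i), int(j), float(r0), float(k)) for i, j, r0, k in bonds]
        self.angles = [
            (int(i), int(j), int(k), float(t0), float(kk))
            for i, j, k, t0, kk in angles
        ]
        self.torsions = [
            (int(i), int(j), int(k), int(l), float(kk), float(pmin), int(m))
            for i, j, k, l, kk, pmin, m in torsions
        ]
        self.repulsion_eps = float(repulsion_eps)
        self.repulsion_sigma = float(repulsion_sigma)
        self.position_restraints = [
            (int(i), np.asarray(r, dtype=float), float(k))
            for i, r, k in position_restraints
        ]
        self.parameter_set = parameter_set
        # pairs excluded from repulsion: bonded and angle-linked atoms
        excl = {(min(i, j), max(i, j)) for i, j, *_ in self.bonds}
        for i, j, k, *_ in self.angles:
            excl.add((min(i, k), max(i, k)))
        self._excluded = excl
        if self.repulsion_eps > 0:
            ii, jj = np.triu_indices(n_atoms, k=1)
            keep = np.array(
                [(a, b) not in excl for a, b in zip(ii, jj)], dtype=bool
            )
            self._pairs = (ii[keep], jj[keep])
        else:
            self._pairs = (np.array([], dtype=int), np.array([], dtype=int))
        # vectorized views for the fast energy path
        ba = np.array([(i, j) for i, j, _, _ in self.bonds], dtype=int).reshape(-1, 2)
        self._b_ij = ba
        self._b_r0 = np.array([r0 for _, _, r0, _ in self.bonds])
        self._b_k = np.array([k for *_, k in self.bonds])
        aa = np.array([(i, j, k) for i, j, k, _, _ in self.angles], dtype=int).reshape(-1, 3)
        self._a_ijk = aa
        self._a_t0 = np.array([t0 for *_, t0, _ in self.angles])
        self._a_k = np.array([k for *_, k in self.angles])
        ta = np.array([(i, j, k, l) for i, j, k, l, _, _, _ in self.torsions], dtype=int).reshape(-1, 4)
        self._t_ijkl = ta
        self._t_k = np.array([k for *_, k, _, _ in self.torsions])
        self._t_pmin = np.array([p for *_, p, _ in self.torsions])
        self._t_m = np.array([m for *_, m in self.torsions])
        pr = self.position_restraints
        self._p_i = np.array([i for i, _, _ in pr], dtype=int)
        self._p_ref = (
            np.stack([r for _, r, _ in pr]) if pr else np.zeros((0, 3))
        )
        self._p_k = np.array([k for _, _, k in pr])

    # -- energy ------------------------------------------------------------

    def energy(self, coords: np.ndarray) -> float:
        """Vectorized energy (no gradients); the Monte-Carlo hot path."""
        x = np.asarray(coords, dtype=float)
        e = 0.0
        if len(self._b_ij):
            d = x[self._b_ij[:, 0]] - x[self._b_ij[:, 1]]
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            e += np.sum(self._b_k * (r - self._b_r0) ** 2)
        if len(self._a_ijk):
            u = x[self._a_ijk[:, 0]] - x[self._a_ijk[:, 1]]
            v = x[self._a_ijk[:, 2]] - x[self._a_ijk[:, 1]]
            cos_t = np.einsum("ij,ij->i", u, v) / (
                np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
            )
            theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
            e += np.sum(self._a_k * (theta - self._a_t0) ** 2)
        if len(self._t_ijkl):
            b1 = x[self._t_ijkl[:, 1]] - x[self._t_ijkl[:, 0]]
            b2 = x[self._t_ijkl[:, 2]] - x[self._t_ijkl[:, 1]]
            b3 = x[self._t_ijkl[:, 3]] - x[self._t_ijkl[:, 2]]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            phi = np.arctan2(
                np.einsum("ij,ij->i", np.cross(n1, n2), b2) / nb2,
                np.einsum("ij,ij->i", n1, n2),
            )
            e += np.sum(self._t_k * (1.0 - np.cos(self._t_m * (phi - self._t_pmin))))
        if self.repulsion_eps > 0 and len(self._pairs[0]):
            d = x[self._pairs[0]] - x[self._pairs[1]]
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            t = 1.0 - r / self.repulsion_sigma
            e += self.repulsion_eps * np.sum(np.where(t > 0, t, 0.0) ** 2)
        if len(self._p_i):
            d = x[self._p_i] - self._p_ref
            e += np.sum(self._p_k * np.einsum("ij,ij->i", d, d))
        if not np.isfinite(e):
            raise ValidationError("toy potential energy is not finite")
        return float(e)

    def energy_and_grad(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        return self._eval(coords, want_grad=True)

    def _eval(self, coords: np.ndarray, want_grad: bool) -> tuple[float, np.ndarray]:
        x = np.asarray(coords, dtype=float)
        g = np.zeros_like(x) if want_grad else None
        e = 0.0
        for i, j, r0, k in self.bonds:
            d = x[i] - x[j]
            r = np.linalg.norm(d)
            e += k * (r - r0) ** 2
            if want_grad and r > 1e-12:
                f = 2 * k * (r - r0) * d / r
                g[i] += f
                g[j] -= f
        for i, j, k_at, t0, k in self.angles:
            u = x[i] - x[j]
            v = x[k_at] - x[j]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            cu, cv = u / nu, v / nv
            cos_t = np.clip(cu @ cv, -1.0, 1.0)
            theta = np.arccos(cos_t)
            e += k * (theta - t0) ** 2
            if want_grad:
                sin_t = max(np.sqrt(1 - cos_t**2), 1e-8)
                dt_di = -(cv - cos_t * cu) / (nu * sin_t)
                dt_dk = -(cu - cos_t * cv) / (nv * sin_t)
                pref = 2 * k * (theta - t0)
                g[i] += pref * dt_di
                g[k_at] += pref * dt_dk
                g[j] -= pref * (dt_di + dt_dk)
        for i, j, k_at, l, k, pmin, m in self.torsions:
            b1 = x[j] - x[i]
            b2 = x[k_at] - x[j]
            b3 = x[l] - x[k_at]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2)
            phi = np.arctan2(np.cross(n1, n2) @ b2 / nb2, n1 @ n2)
            e += k * (1.0 - np.cos(m * (phi - pmin)))
            if want_grad:
                de_dphi = k * m * np.sin(m * (phi - pmin))
                dphi_di = -nb2 / max(n1 @ n1, 1e-12) * n1
                dphi_dl = nb2 / max(n2 @ n2, 1e-12) * n2
                s12 = (b1 @ b2) / (nb2**2)
                s32 = (b3 @ b2) / (nb2**2)
                dphi_dj = -(1.0 + s12) * dphi_di + s32 * dphi_dl
                dphi_dk = -dphi_di - dphi_dj - dphi_dl
                g[i] += de_dphi * dphi_di
                g[j] += de_dphi * dphi_dj
                g[k_at] += de_dphi * dphi_dk
                g[l] += de_dphi * dphi_dl
        if self.repulsion_eps > 0 and len(self._pairs[0]):
            ii, jj = self._pairs
            d = x[ii] - x[jj]
            r = np.linalg.norm(d, axis=1)
            close = r < self.repulsion_sigma
            if close.any():
                rr = r[close]
                t = 1.0 - rr / self.repulsion_sigma
                e += self.repulsion_eps * np.sum(t**2)
                if want_grad:
                    f = (
                        -2 * self.repulsion_eps * t / self.repulsion_sigma
                    )[:, None] * (d[close] / rr[:, None])
                    np.add.at(g, ii[close], f)
                    np.add.at(g, jj[close], -f)
        for i, ref, k in self.position_restraints:
            d = x[i] - ref
            e += k * (d @ d)
            if want_grad:
                g[i] += 2 * k * d
        if not np.isfinite(e):
            raise ValidationError("toy potential energy is not finite")
        return float(e), g


# ---------------------------------------------------------------------------
# Moves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TorsionMove:
    """Rigid rotation of ``moved`` atoms about the axis atom_a -> atom_b."""

    atom_a: int
    atom_b: int
    moved: tuple
    sigma: float = 1.0  # rad


@dataclass(frozen=True)
class MoveSet:
    cartesian_sigma: float = 0.03  # Å, applied to every atom of one replica
    p_torsion: float = 0.5
    torsions: tuple = ()

    def __post_init__(self) -> None:
        if not self.torsions and self.p_torsion > 0:
            object.__setattr__(self, "p_torsion", 0.0)


def _apply_torsion(coords: np.ndarray, mv: TorsionMove, angle: float) -> np.ndarray:
    axis_origin = coords[mv.atom_a]
    axis = coords[mv.atom_b] - axis_origin
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + s * K + (1 - c) * (K @ K)
    out = coords.copy()
    idx = np.array(mv.moved)
    out[idx] = (coords[idx] - axis_origin) @ R.T + axis_origin
    return out


# ---------------------------------------------------------------------------
# Refinement driver
# ---------------------------------------------------------------------------

@dataclass
class RefinementTrajectory:
    topology: Conformation
    M: int
    schedule: AnnealingSchedule
    frames: list  # (cycle index, step index, coords stack (M, n, 3))
    log: pd.DataFrame  # per-log-point energies, temperature, acceptance, Q
    final_coords: np.ndarray
    final_q: float


def run_refinement(
    start: Conformation,
    rdcs: Sequence[RDCRecord],
    M: int,
    schedule: AnnealingSchedule,
    ramp: RestraintRamp,
    potential: ToyPotential,
    seed: int,
    moves: MoveSet,
    mode: str = "shared-svd",
    tensor_stride: int = 100,
    log_interval: int = 200,
    energy_abort: float = 1e8,
) -> RefinementTrajectory:
    """Replica-averaged restrained simulated annealing; reproducible by seed.

    Metropolis acceptance uses E_total = E_FF + E_RDC at the instantaneous
    cycle temperature.  Restraint tensors are refit every ``tensor_stride``
    accepted moves (and at every cycle boundary); between refits they are
    frozen, so the restraint behaves as a fixed quadratic bias.
    """
    if M < 1:
        raise ValidationError("M must be >= 1")
    rng = np.random.default_rng(seed)
    n_atoms = start.n_atoms
    coords = np.repeat(start.coords[None], M, axis=0).astype(float)

    use_rdc = ramp.alpha_target > 0 and len(rdcs) > 0
    restraint = (
        RDCRestraint(start, rdcs, alpha=ramp.alpha_target, mode=mode)
        if len(rdcs) > 0
        else None
    )

    e_ff = np.array([potential.energy(coords[m]) for m in range(M)])

    tensors = restraint.fit_tensors(coords) if restraint is not None else None
    contribs = (
        restraint.all_contribs(coords, tensors) if restraint is not None else None
    )

    frames = []
    log_rows = []
    n_acc = n_tot = 0
    acc_since_refit = 0

    def refit():
        nonlocal tensors, contribs
        tensors = restraint.fit_tensors(coords)
        contribs = restraint.all_contribs(coords, tensors)

    def mc_sweep(n_steps, temperature_of, alpha_mult, cycle_idx, record_steps=()):
        nonlocal coords, e_ff, n_acc, n_tot, acc_since_refit, contribs
        use = restraint is not None and alpha_mult > 0
        e_rdc = restraint.energy_from_contribs(contribs) * alpha_mult if use else 0.0
        record = set(int(s) for s in record_steps)
        for s in range(n_steps):
            T = temperature_of(s)
            kT = KB_KJ_MOL * T
            m = int(rng.integers(M))
            do_torsion = (
                len(moves.torsions) > 0 and rng.random() < moves.p_torsion
            )
            if do_torsion:
                mv = moves.torsions[int(rng.integers(len(moves.torsions)))]
                angle = rng.normal() * mv.sigma
                new_m = _apply_torsion(coords[m], mv, angle)
            else:
                new_m = coords[m] + rng.normal(size=(n_atoms, 3)) * moves.cartesian_sigma
            e_ff_new = potential.energy(new_m)
            if e_ff_new > energy_abort:
                raise RuntimeError(
                    f"diverging toy-potential energy {e_ff_new:.3g} kJ/mol at "
                    f"cycle {cycle_idx}, step {s} (overlap catastrophe)"
                )
            if use:
                new_rows = restraint.replica_contrib(new_m, m, tensors)
                old_rows = {med: contribs[med][m].copy() for med in contribs}
                for med in contribs:
                    contribs[med][m] = new_rows[med]
                e_rdc_new = restraint.energy_from_contribs(contribs) * alpha_mult
            else:
                e_rdc_new = 0.0
            dE = (e_ff_new - e_ff[m]) + (e_rdc_new - e_rdc)
            n_tot += 1
            if dE <= 0 or rng.random() < np.exp(-dE / kT):
                coords[m] = new_m
                e_ff[m] = e_ff_new
                e_rdc = e_rdc_new
                n_acc += 1
                acc_since_refit += 1
                if use and acc_since_refit >= tensor_stride:
                    refit()
                    e_rdc = restraint.energy_from_contribs(contribs) * alpha_mult
                    acc_since_refit = 0
            elif use:
                for med in contribs:
                    contribs[med][m] = old_rows[med]
            if s in record:
                frames.append((cycle_idx, s, coords.copy()))
            if log_interval and (s % log_interval == 0 or s == n_steps - 1):
                if restraint is None:
                    q = np.nan
                elif use:
                    q = restraint.q_from_contribs(contribs)
                else:
                    q = restraint.q(coords)
                log_rows.append(
                    {
                        "cycle": cycle_idx,
                        "step": s,
                        "T": T,
                        "E_ff": float(e_ff.sum()),
                        "E_rdc": float(e_rdc),
                        "acceptance": n_acc / max(n_tot, 1),
                        "Q": q,
                    }
                )

    # equilibration: gently raise alpha
    if use_rdc:
        for stage, mult in enumerate(ramp.profile):
            mc_sweep(
                ramp.steps_per_stage,
                lambda s: schedule.T_low,
                float(mult),
                cycle_idx=-(len(ramp.profile) - stage),
            )
            refit()

    extraction = schedule.extraction_steps()
    alpha_mult = 1.0 if use_rdc else 0.0
    for cycle in range(schedule.n_cycles):
        if restraint is not None:
            refit()
        mc_sweep(
            schedule.steps_per_cycle,
            schedule.temperature,
            alpha_mult,
            cycle_idx=cycle,
            record_steps=extraction,
        )

    if restraint is not None:
        tensors = restraint.fit_tensors(coords)
        final_q = restraint.q(coords, tensors)
    else:
        final_q = float("nan")
    logger.info(
        "refinement done: M=%d, acceptance %.2f, final Q %.3f",
        M, n_acc / max(n_tot, 1), final_q,
    )
    return RefinementTrajectory(
        topology=start,
        M=M,
        schedule=schedule,
        frames=frames,
        log=pd.DataFrame(log_rows),
        final_coords=coords,
        final_q=final_q,
    )


def extract_ensemble(
    traj: RefinementTrajectory, schedule: Optional[AnnealingSchedule] = None
) -> list[Conformation]:
    """Pool replicas from each post-burn-in cycle's extraction window.

    Ensemble size = (n_cycles - burn_in) * M * frames_per_window.
    """
    schedule = schedule or traj.schedule
    post = [
        (c, s, stack)
        for (c, s, stack) in traj.frames
        if c >= schedule.burn_in_cycles
    ]
    max_cycle = max((c for c, _, _ in traj.frames), default=-1)
    if max_cycle < schedule.n_cycles - 1:
        raise ValidationError(
            f"trajectory holds cycles up to {max_cycle}; schedule expects "
            f"{schedule.n_cycles}"
        )
    if not post:
        raise ValidationError("no frames beyond burn-in")
    out = []
    model = 1
    for c, s, stack in post:
        for m in range(stack.shape[0]):
            out.append(traj.topology.with_coords(stack[m], model_id=model))
            model += 1
    return out


# ---------------------------------------------------------------------------
# Toy systems
# ---------------------------------------------------------------------------

def make_harmonic_dimer(
    k: float = 50.0, separation: float = 1.5
) -> tuple[Conformation, ToyPotential, MoveSet]:
    """Two atoms tethered to reference positions by 3D harmonic wells.

    Each Cartesian coordinate is then Boltzmann-distributed with variance
    kB*T / (2k), which makes this the detailed-balance benchmark system.
    """
    coords = np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])
    conf = Conformation(
        res_index=[1, 2],
        res_aa=["G", "G"],
        atom_names=["CA", "CA"],
        elements=["C", "C"],
        coords=coords,
    )
    pot = ToyPotential(
        n_atoms=2,
        position_restraints=[(0, coords[0], k), (1, coords[1], k)],
        parameter_set="harmonic-dimer",
    )
    return conf, pot, MoveSet(cartesian_sigma=0.15, p_torsion=0.0)


def _dihedral(p0, p1, p2, p3) -> float:
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    return float(
        np.arctan2(np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)), n1 @ n2)
    )


def _angle(p0, p1, p2) -> float:
    u, v = p0 - p1, p2 - p1
    return float(
        np.arccos(
            np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
        )
    )


def make_hinged_chain(
    n_res: int = 12,
    hinge_res: int = 6,
    k_bond: float = 500.0,
    k_angle: float = 100.0,
    k_torsion: float = 30.0,
    sequence: Optional[str] = None,
) -> tuple[Conformation, ToyPotential, MoveSet]:
    """A two-state hinged peptide-like chain (N, H, CA, C per residue).

    The chain is rigid (stiff bonds/angles plus cosine torsions restraining
    the built geometry) except for the rotation of everything beyond the
    hinge residue's CA-C bond, which is left free — a one-dimensional
    conformational coordinate connecting two arbitrarily different "open" and
    "closed" states.  Residues 1-2 are position-restrained so the proximal
    arm defines a fixed molecular frame.  Amide H orientations advance around
    the chain axis so the N-H vectors span orientations (a well-conditioned
    alignment-tensor fit needs non-collinear vectors).
    """
    if not (1 < hinge_res < n_res):
        raise ValidationError("hinge residue must be interior to the chain")
    seq = sequence or ("A" * n_res)
    if len(seq) != n_res:
        raise ValidationError("sequence length must equal n_res")
    golden = np.pi * (3.0 - np.sqrt(5.0))
    res_index, res_aa, names, elems, coords = [], [], [], [], []
    for i in range(n_res):
        x0 = 3.4 * i
        zig = 0.4 * (-1) ** i
        n_pos = np.array([x0, zig, 0.0])
        phi = golden * i
        h_dir = np.array([0.25, np.cos(phi), np.sin(phi)])
        h_pos = n_pos + 1.02 * h_dir / np.linalg.norm(h_dir)
        ca_pos = n_pos + np.array([1.3, -zig * 0.8, 0.35 * np.sin(phi / 2)])
        c_pos = ca_pos + np.array([1.2, zig * 0.5, -0.3 * np.cos(phi / 2)])
        for nm, el, pos in (
            ("N", "N", n_pos),
            ("H", "H", h_pos),
            ("CA", "C", ca_pos),
            ("C", "C", c_pos),
        ):
            res_index.append(i + 1)
            res_aa.append(seq[i])
            names.append(nm)
            elems.append(el)
            coords.append(pos)
    coords = np.array(coords)
    conf = Conformation(res_index, res_aa, names, elems, coords)

    def ai(res, name):
        return conf.atom_index(res, name)

    bonds, angles, torsions = [], [], []

    def add_bond(a, b, k=k_bond):
        bonds.append((a, b, float(np.linalg.norm(coords[a] - coords[b])), k))

    def add_angle(a, b, c, k=k_angle):
        angles.append((a, b, c, _angle(coords[a], coords[b], coords[c]), k))

    def add_torsion(a, b, c, d, k=k_torsion):
        torsions.append(
            (a, b, c, d, k, _dihedral(coords[a], coords[b], coords[c], coords[d]), 1)
        )

    hinge_axis = None
    for i in range(1, n_res + 1):
        N, H, CA, C = ai(i, "N"), ai(i, "H"), ai(i, "CA"), ai(i, "C")
        add_bond(N, H)
        add_bond(N, CA)
        add_bond(CA, C)
        add_angle(H, N, CA)
        add_angle(N, CA, C)
        add_torsion(H, N, CA, C)
        if i < n_res:
            Nn, CAn = ai(i + 1, "N"), ai(i + 1, "CA")
            add_bond(C, Nn)
            add_angle(CA, C, Nn)
            add_angle(C, Nn, CAn)
            is_hinge = i == hinge_res
            if is_hinge:
                hinge_axis = (CA, C)
            else:
                add_torsion(N, CA, C, Nn)  # phi-like
            add_torsion(CA, C, Nn, CAn)  # psi/omega-like, keeps peptide planar

    posres = [
        (ai(i, nm), coords[ai(i, nm)], 200.0)
        for i in (1, 2)
        for nm in ("N", "H", "CA", "C")
    ]
    pot = ToyPotential(
        n_atoms=conf.n_atoms,
        bonds=bonds,
        angles=angles,
        torsions=torsions,
        repulsion_eps=2.0,
        repulsion_sigma=2.0,
        position_restraints=posres,
        parameter_set="hinged-chain",
    )
    moved = tuple(
        idx
        for idx in range(conf.n_atoms)
        if conf.res_index[idx] > hinge_res
    )
    mv = TorsionMove(hinge_axis[0], hinge_axis[1], moved, sigma=0.8)
    moves = MoveSet(cartesian_sigma=0.02, p_torsion=0.5, torsions=(mv,))
    return conf, pot, moves


def hinge_rotated(
    conf: Conformation, moves: MoveSet, angle: float
) -> Conformation:
    """The hinged chain rotated by ``angle`` (rad) about its hinge axis."""
    mv = moves.torsions[0]
    return conf.with_coords(_apply_torsion(conf.coords, mv, angle))


def make_beta_hairpin(
    n_per_strand: int = 5,
) -> tuple[Conformation, ToyPotential, MoveSet]:
    """An idealized two-stranded antiparallel hairpin (CA trace + N, H, C).

    Used for geometry-level tests (anisotropic shape, alternating N-H
    orientations); the potential holds the built geometry.
    """
    n_res = 2 * n_per_strand + 2
    res_index, res_aa, names, elems, coords = [], [], [], [], []
    for i in range(n_res):
        if i < n_per_strand:
            base = np.array([3.3 * i, 0.0, 0.0])
        elif i < n_per_strand + 2:
            t = i - n_per_strand
            base = np.array([3.3 * (n_per_strand - 1) + 2.0, 2.4 * (t + 1), 0.5])
        else:
            t = i - n_per_strand - 2
            base = np.array([3.3 * (n_per_strand - 1 - t), 4.8, 0.0])
        flip = 1.0 if i % 2 == 0 else -1.0
        n_pos = base
        h_pos = base + np.array([0.0, 0.0, 1.02 * flip])
        ca_pos = base + np.array([1.2, 0.3 * flip, 0.0])
        c_pos = ca_pos + np.array([1.2, -0.3 * flip, 0.0])
        for nm, el, pos in (
            ("N", "N", n_pos),
            ("H", "H", h_pos),
            ("CA", "C", ca_pos),
            ("C", "C", c_pos),
        ):
            res_index.append(i + 1)
            res_aa.append("A")
            names.append(nm)
            elems.append(el)
            coords.append(pos)
    coords = np.array(coords)
    conf = Conformation(res_index, res_aa, names, elems, coords)
    posres = [(i, coords[i], 100.0) for i in range(conf.n_atoms)]
    pot = ToyPotential(
        n_atoms=conf.n_atoms,
        position_restraints=posres,
        parameter_set="beta-hairpin",
    )
    return conf, pot, MoveSet(cartesian_sigma=0.05, p_torsion=0.0)
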