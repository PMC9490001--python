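"""Seeded synthetic-data generators with stored ground truth.

Experimental NMR dynamics data of the kind this package analyses are rarely
deposited, so every analysis stage is validated by parameter recovery:
each generator here draws data from the exact statistical model the
corresponding analysis stage assumes, keeps the generating truth alongside
the output, and is deterministic given a seed.

Seed splitting: a user-facing seed fans out to independent per-generator
streams via ``numpy.random.default_rng([seed, KIND_ID])`` with a fixed
integer id per generator kind, so adding data of one kind never perturbs
another kind's stream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import FieldParams
from .hx import EX2KineticModel, simulate_kobs
from .refine import (
    MoveSet,
    RestraintRamp,
    ToyPotential,
    build_schedule,
    hinge_rotated,
    make_hinged_chain,
    run_refinement,
)
from .rdc import AlignmentTensor, RDCRecord, back_calculate_rdc
from .relaxation import ModelFreeParams, RelaxationRecord, relaxation_rates
from .types import Conformation, DecayCurve, ResidueID, ValidationError

__all__ = [
    "synth_relaxation",
    "make_modelfree_truth",
    "synth_two_state_ensemble",
    "TwoStateEnsemble",
    "synth_rdc",
    "two_conformer_rdc_target",
    "replica_necessity_run",
    "synth_hx",
    "R1_DELAY_GRID",
    "CLEANEX_GRID",
]

_KIND_IDS = {"relaxation": 1, "ensemble": 2, "rdc": 3, "hx": 4, "refine": 5}

# canonical measurement grids (s)
R1_DELAY_GRID = np.array([0.1, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2])
R2_DELAY_GRID = np.array(
    [0.017, 0.034, 0.051, 0.068, 0.102, 0.153, 0.170, 0.204, 0.238, 0.289]
)
CLEANEX_GRID = np.array([0.0, 0.010, 0.015, 0.020, 0.025])
HX_DECAY_GRID = np.concatenate([[120.0], np.geomspace(300.0, 86400.0, 19)])


def _rng(seed: int, kind: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _KIND_IDS[kind]])


# ---------------------------------------------------------------------------
# Relaxation
# ---------------------------------------------------------------------------

def make_modelfree_truth(
    n_res: int = 50,
    mean_s2: float = 0.84,
    sd_s2: float = 0.05,
    tau_m: float = 5.0,
    tau_e_range: tuple[float, float] = (20.0, 120.0),
    seed: int = 0,
) -> list[ModelFreeParams]:
    """Per-residue model-free ground truth for a synthetic protein.

    S^2 values are drawn around ``mean_s2`` (clipped to [0.5, 1]); internal
    correlation times are uniform in ``tau_e_range`` (ps); the global
    tumbling time is shared.  No exchange contribution by default.
    """
    rng = _rng(seed, "relaxation")
    out = []
    for i in range(1, n_res + 1):
        s2 = float(np.clip(rng.normal(mean_s2, sd_s2), 0.5, 1.0))
        te = float(rng.uniform(*tau_e_range))
        out.append(
            ModelFreeParams(
                residue=ResidueID(i, "A"), S2=s2, tau_m=tau_m, tau_e=te, model_id=2
            )
        )
    return out


def synth_relaxation(
    truth: Sequence[ModelFreeParams],
    field: Optional[FieldParams] = None,
    noise: float = 0.03,
    seed: int = 0,
) -> tuple[list[RelaxationRecord], list[ModelFreeParams]]:
    """(R1, R2, NOE) triples from the Lipari-Szabo forward model plus noise.

    ``noise`` is the relative Gaussian noise on R1/R2 and the absolute noise
    on the NOE ratio (which is itself of order 1).  Returns (records, truth)
    so recovery can be scored.
    """
    field = field or FieldParams()
    rng = _rng(seed, "relaxation")
    records = []
    for p in truth:
        r1, r2, noe = relaxation_rates(p.S2, p.tau_m, p.tau_e, p.R_ex, field)
        if noise > 0:
            r1_obs = r1 * (1 + noise * rng.standard_normal())
            r2_obs = r2 * (1 + noise * rng.standard_normal())
            noe_obs = noe + noise * rng.standard_normal()
        else:
            r1_obs, r2_obs, noe_obs = r1, r2, noe
        # a numerically noiseless dataset still carries a (tiny) declared
        # uncertainty so that downstream weighting/model selection is defined
        rel = max(noise, 1e-9)
        records.append(
            RelaxationRecord(
                residue=p.residue,
                R1=float(r1_obs),
                R2=float(r2_obs),
                hetNOE=float(min(noe_obs, 1.25)),
                R1_err=rel * r1,
                R2_err=rel * r2,
                hetNOE_err=rel,
            )
        )
    return records, list(truth)


# ---------------------------------------------------------------------------
# Two-state ensembles
# ---------------------------------------------------------------------------

@dataclass
class TwoStateEnsemble:
    """Samples and structures drawn from two conformational wells.

    ``samples`` are (Rg, pair distance) draws from the two Gaussian wells in
    coordinate space (cheap, any n); ``conformations`` materialise a bounded
    number of hinged-chain structures whose hinge angle realises the two
    states.  ``truth`` records well means, widths and populations.
    """

    samples: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,) well index
    conformations: list  # list[Conformation]
    truth: dict


def _bend_chain(chain: Conformation, hinge_res: int, angle: float) -> Conformation:
    """Rotate residues beyond ``hinge_res`` about a z-axis through its CA."""
    ca = chain.atom_coord(hinge_res, "CA")
    axis = np.array([0.0, 0.0, 1.0])
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    x = chain.coords.copy()
    idx = np.flatnonzero(chain.res_index > hinge_res)
    x[idx] = (x[idx] - ca) @ R.T + ca
    return chain.with_coords(x)


def synth_two_state_ensemble(
    populations: tuple[float, float] = (0.7, 0.3),
    n_samples: int = 100_000,
    n_structures: int = 200,
    bend_deg: float = 70.0,
    well_sd: tuple[float, float] = (0.15, 0.40),
    seed: int = 0,
) -> TwoStateEnsemble:
    """Draws from a compact (closed) and an expanded (open) conformational well.

    Well 1 is the chain bent by ``bend_deg`` at its hinge — the compact
    ground state with the designated residue pair in close proximity.  Well 2
    is the extended chain: globally less compact with the pair opened up.
    Well means in the (Rg, pair-distance) plane are those of the two
    reference structures; samples are Gaussian around them with widths
    ``well_sd``, and structures are materialised by jittering the bend angle
    within each well.  ``populations`` must sum to 1.
    """
    p = np.asarray(populations, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
        raise ValidationError("populations must be non-negative and sum to 1")
    rng = _rng(seed, "ensemble")
    chain, _, _ = make_hinged_chain()
    hinge_res = 6
    angles = (np.deg2rad(bend_deg), 0.0)  # (compact ground state, open)
    refs = [_bend_chain(chain, hinge_res, a) for a in angles]

    from .fes import radius_of_gyration, sidechain_distance

    pair = (3, 12)
    means = np.array([
        [radius_of_gyration(c), sidechain_distance(c, *pair, mode="ca")]
        for c in refs
    ])
    if np.allclose(means[0], means[1]):
        import warnings

        warnings.warn("two-state wells have identical means", stacklevel=2)
    labels = rng.choice(2, size=n_samples, p=p)
    sds = np.asarray(well_sd)
    samples = means[labels] + rng.standard_normal((n_samples, 2)) * sds

    confs = []
    for k in range(min(n_structures, n_samples)):
        theta = rng.normal(angles[labels[k]], np.deg2rad(6.0))
        c = _bend_chain(chain, hinge_res, theta)
        confs.append(c.with_coords(c.coords, model_id=k + 1))
    truth = {
        "populations": p,
        "well_means": means,
        "well_sds": sds,
        "pair": pair,
        "bend_deg": bend_deg,
    }
    return TwoStateEnsemble(samples, labels, confs, truth)


# ---------------------------------------------------------------------------
# RDCs
# ---------------------------------------------------------------------------

DEFAULT_TENSOR = AlignmentTensor.from_components(
    [4e-4, -1.5e-4, 2.5e-4, -3e-4, 1.5e-4]
)
# a second medium with a deliberately different principal frame
SECOND_TENSOR = AlignmentTensor.from_components(
    [-2e-4, 3.5e-4, -1e-4, 2e-4, 2.5e-4]
)


def _all_records(
    conf: Conformation, pairs: Sequence[str], medium: str, error: float
) -> list[RDCRecord]:
    recs = []
    res = conf.residues()
    for rid in res:
        for pair in pairs:
            if pair == "N-H" and (rid.aa == "P" or conf.atom_index(rid.index, "H") is None):
                continue
            if pair == "C-N" and conf.atom_index(rid.index - 1, "C") is None:
                continue
            recs.append(RDCRecord(rid, pair, 0.0, error, medium))
    return recs


def synth_rdc(
    ensemble: Sequence[Conformation],
    tensors: Optional[dict] = None,
    noise: float = 1.0,
    seed: int = 0,
    pairs: Sequence[str] = ("N-H", "C-N"),
    error: float = 0.5,
) -> tuple[list[RDCRecord], dict]:
    """Ensemble-averaged couplings from known tensors plus Gaussian noise (Hz).

    One tensor per alignment medium is applied to every ensemble member and
    the back-calculated couplings are averaged; truth stores the tensors and
    the generating ensemble.
    """
    if len(ensemble) < 1:
        raise ValidationError("need at least one conformation")
    tensors = tensors or {"medium1": DEFAULT_TENSOR}
    rng = _rng(seed, "rdc")
    records: list[RDCRecord] = []
    for medium, tensor in tensors.items():
        template = _all_records(ensemble[0], pairs, medium, error)
        d = np.zeros(len(template))
        for conf in ensemble:
            d += back_calculate_rdc(conf, tensor, template)
        d /= len(ensemble)
        if noise > 0:
            d = d + rng.standard_normal(len(d)) * noise
        records.extend(
            RDCRecord(r.residue, r.pair, float(v), error, medium)
            for r, v in zip(template, d)
        )
    truth = {"tensors": tensors, "ensemble": list(ensemble)}
    return records, truth


# ---------------------------------------------------------------------------
# The two-conformer refinement study
# ---------------------------------------------------------------------------

# canonical study conditions for the replica-averaging experiments: a
# 12-residue hinged chain whose open state is 120 degrees away, a single
# generic alignment tensor, noiseless couplings, and a desk-scale annealing
# protocol
STUDY_SEPARATION_DEG = 120.0
STUDY_ALPHA = 40.0
STUDY_SCHEDULE = dict(n_cycles=8, burn_in_cycles=3, steps_per_cycle=1000)
STUDY_RAMP_STAGES = 5
STUDY_TENSOR_STRIDE = 25


def two_conformer_rdc_target(
    noise: float = 0.0, seed: int = 0
) -> tuple[Conformation, ToyPotential, MoveSet, list[RDCRecord], dict]:
    """Noiseless-by-default RDC target averaged over two hinge conformers.

    The couplings are the 50:50 average of the closed and open (120 deg)
    states of the hinged chain under one fixed tensor — data that no single
    rigid structure reproduces (best rigid-structure Q ~ 0.3) but a replica
    ensemble can.
    """
    conf, pot, moves = make_hinged_chain(k_torsion=60.0, k_angle=200.0)
    moves = MoveSet(
        cartesian_sigma=0.01, p_torsion=moves.p_torsion, torsions=moves.torsions
    )
    opened = hinge_rotated(conf, moves, np.deg2rad(STUDY_SEPARATION_DEG))
    template = _all_records(conf, ("N-H", "C-N"), "medium1", 0.5)
    d = 0.5 * (
        back_calculate_rdc(conf, DEFAULT_TENSOR, template)
        + back_calculate_rdc(opened, DEFAULT_TENSOR, template)
    )
    if noise > 0:
        d = d + _rng(seed, "rdc").standard_normal(len(d)) * noise
    records = [
        RDCRecord(r.residue, r.pair, float(v), 0.5, r.medium)
        for r, v in zip(template, d)
    ]
    truth = {
        "tensor": DEFAULT_TENSOR,
        "conformers": [conf, opened],
        "populations": (0.5, 0.5),
    }
    return conf, pot, moves, records, truth


def replica_necessity_run(
    M: int,
    seed: int,
    alpha: float = STUDY_ALPHA,
) -> float:
    """One arm of the replica-averaging experiment; returns the final ensemble Q.

    Runs the canonical restrained annealing protocol on the two-conformer
    target with M replicas and the given restraint strength (alpha = 0 is the
    unrestrained control).
    """
    conf, pot, moves, records, _ = two_conformer_rdc_target()
    schedule = build_schedule(STUDY_SCHEDULE)
    if alpha > 0:
        ramp = RestraintRamp(
            alpha_target=alpha,
            profile=tuple(np.linspace(0.2, 1.0, STUDY_RAMP_STAGES)),
            steps_per_stage=300,
        )
    else:
        ramp = RestraintRamp(alpha_target=0.0, profile=(), steps_per_stage=0)
    traj = run_refinement(
        conf,
        records,
        M,
        schedule,
        ramp,
        pot,
        seed=seed,
        moves=moves,
        tensor_stride=STUDY_TENSOR_STRIDE,
        log_interval=0,
    )
    return traj.final_q


# ---------------------------------------------------------------------------
# Hydrogen exchange
# ---------------------------------------------------------------------------

def synth_hx(
    truth: dict[int, EX2KineticModel],
    time_grid: Optional[np.ndarray] = None,
    noise: float = 0.05,
    seed: int = 0,
    fast_threshold: float = 3.0,
) -> tuple[list[DecayCurve], list[tuple[float, np.ndarray]], dict]:
    """HX observables from per-residue EX2 kinetic models.

    Residues with k_obs * t_first < ``fast_threshold`` produce decay curves
    I(t) = exp(-k_obs t) + noise on ``time_grid``; faster exchangers (gone
    before the first spectrum) are emitted as CLEANEX buildup tables
    I/I0 = 1 - exp(-k tau) + noise on the canonical 0-25 ms grid.

    Returns (decay curves, [(residue index, buildup ratios)], truth dict with
    per-residue k_obs).
    """
    grid = np.asarray(time_grid if time_grid is not None else HX_DECAY_GRID)
    if np.any(grid <= 0) or not np.all(np.diff(grid) > 0):
        raise ValidationError("time grid must be positive and increasing")
    rng = _rng(seed, "hx")
    curves: list[DecayCurve] = []
    cleanex: list[tuple[int, np.ndarray]] = []
    k_obs_truth: dict[int, float] = {}
    for res_idx in sorted(truth):
        model = truth[res_idx]
        k = simulate_kobs(model)
        k_obs_truth[res_idx] = k
        if k * grid[0] < fast_threshold:
            I = np.exp(-k * grid)
            if noise > 0:
                I = I + noise * rng.standard_normal(len(grid))
            I = np.clip(I, 1e-9, None)
            curves.append(DecayCurve(ResidueID(res_idx, "A"), grid.copy(), I))
        else:
            ratios = 1.0 - np.exp(-k * CLEANEX_GRID)
            if noise > 0:
                ratios = ratios + noise * rng.standard_normal(len(CLEANEX_GRID)) * np.where(
                    CLEANEX_GRID > 0, 1.0, 0.0
                )
            cleanex.append((res_idx, np.column_stack([CLEANEX_GRID, ratios])))
    return curves, cleanex, {"k_obs": k_obs_truth, "models": dict(truth)}
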