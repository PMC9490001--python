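"""Ensemble analysis: reaction coordinates, free-energy surfaces, RMSF.

A structural ensemble is projected onto a global coordinate (radius of
gyration) and a local one (distance between two side chains, e.g. a pair of
catalytic residues); Boltzmann inversion of the binned sample density,

    G(bin) = -kB T ln( n_bin / n_max ),

gives a free-energy surface whose occupied global minimum is 0 and whose
empty bins carry an infinite sentinel (never interpolated).  Basin analysis
reports local minima, free-energy differences between named basins, and the
overall surface depth.  Per-residue RMSF is computed about the iteratively
superposed ensemble mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .constants import KB_KJ_MOL
from .types import Conformation, ResidueID, ValidationError

__all__ = [
    "FESGrid",
    "BasinReport",
    "radius_of_gyration",
    "sidechain_distance",
    "compute_fes",
    "basin_analysis",
    "rmsf",
]

ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971,
}

BACKBONE_NAMES = {"N", "CA", "C", "O", "H", "HA", "OXT", "HN"}


def _masses(conf: Conformation) -> np.ndarray:
    return np.array([ATOMIC_MASS.get(str(e).upper(), 12.011) for e in conf.elements])


def radius_of_gyration(conf: Conformation, weighting: str = "mass") -> float:
    """Radius of gyration (Å), mass-weighted by default.

    Rg^2 = sum_i m_i |r_i - r_cm|^2 / sum_i m_i; invariant under rigid-body
    transforms.
    """
    if conf.n_atoms < 2:
        warnings.warn("single atom: radius of gyration is 0", stacklevel=2)
        return 0.0
    if weighting == "mass":
        m = _masses(conf)
    elif weighting == "uniform":
        m = np.ones(conf.n_atoms)
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")
    com = np.average(conf.coords, axis=0, weights=m)
    d2 = np.sum((conf.coords - com) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=m)))


def _sidechain_heavy(conf: Conformation, res: int) -> np.ndarray:
    mask = (
        (conf.res_index == res)
        & (conf.elements != "H")
        & ~np.isin(conf.atom_names, list(BACKBONE_NAMES))
    )
    return conf.coords[np.flatnonzero(mask)]


def sidechain_distance(
    conf: Conformation,
    resA: int,
    resB: int,
    mode: Union[str, tuple[str, str]] = "centroid",
) -> float:
    """Distance (Å) between the side chains of two residues.

    Modes: ``centroid`` (default) — distance between heavy-atom side-chain
    centroids; ``min`` — minimum heavy-atom distance; ``ca`` — Cα-Cα; a
    ``(atomA, atomB)`` tuple — that named atom pair.
    """
    if isinstance(mode, tuple):
        a = conf.atom_coord(resA, mode[0])
        b = conf.atom_coord(resB, mode[1])
        if a is None or b is None:
            raise ValidationError(
                f"atoms {mode} not found in residues {resA}/{resB}"
            )
        return float(np.linalg.norm(a - b))
    if mode == "ca":
        a = conf.atom_coord(resA, "CA")
        b = conf.atom_coord(resB, "CA")
        if a is None or b is None:
            raise ValidationError(f"CA missing in residue {resA} or {resB}")
        return float(np.linalg.norm(a - b))
    xa = _sidechain_heavy(conf, resA)
    xb = _sidechain_heavy(conf, resB)
    for res, x in ((resA, xa), (resB, xb)):
        if len(x) == 0:
            raise ValidationError(
                f"residue {res} has no side-chain heavy atoms (glycine?); "
                "use mode='ca'"
            )
    if mode == "centroid":
        return float(np.linalg.norm(xa.mean(axis=0) - xb.mean(axis=0)))
    if mode == "min":
        d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
        return float(d.min())
    raise ValidationError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Free-energy surface
# ---------------------------------------------------------------------------

@dataclass
class FESGrid:
    """Binned 2D free-energy surface.

    ``G`` is in kJ/mol with min(occupied) = 0 and np.inf for empty bins;
    ``counts`` sums to the sample size.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # (nx, ny) ints
    G: np.ndarray  # (nx, ny) kJ/mol, inf sentinel for empty bins
    temperature: float  # K

    def __post_init__(self) -> None:
        occ = self.counts > 0
        if occ.any() and abs(self.G[occ].min()) > 1e-9:
            raise ValidationError("minimum over occupied bins must be 0")

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    def populations(self) -> np.ndarray:
        """Boltzmann reinversion: relative populations from G (occupied bins)."""
        kT = KB_KJ_MOL * self.temperature
        with np.errstate(over="ignore"):
            p = np.where(np.isfinite(self.G), np.exp(-self.G / kT), 0.0)
        return p / p.sum()

    def bin_of(self, x: float, y: float) -> tuple[int, int]:
        ix = int(np.searchsorted(self.x_edges, x, side="right")) - 1
        iy = int(np.searchsorted(self.y_edges, y, side="right")) - 1
        if not (0 <= ix < self.counts.shape[0] and 0 <= iy < self.counts.shape[1]):
            raise ValidationError(f"point ({x}, {y}) lies outside the grid")
        return ix, iy

    def depth(self) -> float:
        """Overall surface depth: max finite G (kJ/mol)."""
        finite = self.G[np.isfinite(self.G)]
        return float(finite.max())


@dataclass
class BasinReport:
    minima: list  # ((x_center, y_center), G) per local minimum
    named_G: dict  # name -> G at the requested point's bin
    delta_G: dict  # (nameA, nameB) -> |G_b - G_a|, names sorted
    depth: float


def compute_fes(
    samples: np.ndarray,
    bins: Union[int, tuple[int, int]] = 40,
    temperature_K: float = 310.0,
    padding: float = 0.05,
    ranges: Optional[tuple] = None,
) -> FESGrid:
    """Boltzmann inversion of a 2D sample density.

    G(bin) = -kB T ln(n_bin / n_max), so the most populated bin sits at 0 and
    every finite G scales linearly with temperature.  Extents default to the
    data range padded by 5% on each side.
    """
    pts = np.asarray(samples, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("samples must be an (n, 2) array of (x, y)")
    n = len(pts)
    if n < 100:
        warnings.warn(
            f"only {n} samples; free-energy estimates will be noisy", stacklevel=2
        )
    if isinstance(bins, int):
        bins = (bins, bins)
    if ranges is None:
        spans = pts.max(axis=0) - pts.min(axis=0)
        pad = np.where(spans > 0, spans * padding, 1e-6)
        ranges = (
            (pts[:, 0].min() - pad[0], pts[:, 0].max() + pad[0]),
            (pts[:, 1].min() - pad[1], pts[:, 1].max() + pad[1]),
        )
    counts, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins, range=ranges)
    if (counts > 0).sum() == 1:
        warnings.warn(
            "all samples fall in a single bin; surface is degenerate-flat",
            stacklevel=2,
        )
    kT = KB_KJ_MOL * temperature_K
    with np.errstate(divide="ignore"):
        G = np.where(counts > 0, -kT * np.log(counts / counts.max()), np.inf)
    return FESGrid(xe, ye, counts.astype(int), G, temperature_K)


def basin_analysis(
    grid: FESGrid,
    named_points: Optional[dict] = None,
    smooth_sigma: float = 0.0,
) -> BasinReport:
    """Local minima, named-basin free-energy differences, and surface depth.

    Optional Gaussian smoothing (``smooth_sigma`` in bins, off by default) is
    applied only for minima detection; named-point free energies are read
    from the unsmoothed surface.  Requested points must fall in occupied
    bins.
    """
    occ = np.isfinite(grid.G)
    if occ.sum() < 2:
        raise ValidationError("need >= 2 occupied bins for basin analysis")
    G = grid.G
    if smooth_sigma > 0:
        filled = np.where(occ, G, G[occ].max())
        G_s = ndimage.gaussian_filter(filled, smooth_sigma)
    else:
        G_s = G
    # local minima: occupied bins not exceeded by any occupied 8-neighbour
    minima = []
    nx, ny = G.shape
    for i in range(nx):
        for j in range(ny):
            if not occ[i, j]:
                continue
            g0 = G_s[i, j]
            is_min = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < nx and 0 <= b < ny and occ[a, b]:
                        if G_s[a, b] < g0:
                            is_min = False
            if is_min:
                minima.append(
                    ((float(grid.x_centers[i]), float(grid.y_centers[j])), float(G[i, j]))
                )
    named_G = {}
    for name, (x, y) in (named_points or {}).items():
        ix, iy = grid.bin_of(x, y)
        if not occ[ix, iy]:
            raise ValidationError(
                f"requested basin {name!r} at ({x}, {y}) falls in an empty bin"
            )
        named_G[name] = float(G[ix, iy])
    delta = {}
    names = sorted(named_G)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            delta[(names[a], names[b])] = abs(named_G[names[b]] - named_G[names[a]])
    return BasinReport(minima, named_G, delta, grid.depth())


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping mobile onto ref."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    H = (mobile - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


def rmsf(
    ensemble: Sequence[Conformation],
    superpose: bool = True,
    fit_atoms: tuple = ("N", "CA", "C"),
    max_iter: int = 10,
    tol: float = 1e-8,
) -> dict[int, float]:
    """Per-residue Cα RMSF (Å) about the superposed ensemble mean.

    Models are iteratively superposed (Kabsch, backbone atoms) onto the
    evolving mean structure until the mean converges, then
    RMSF_r = sqrt(<|r_CA - <r_CA>|^2>).  Rigid-body motion common to all
    models is removed entirely, so rotated/translated copies of one structure
    give RMSF = 0.
    """
    if len(ensemble) < 2:
        raise ValidationError("RMSF needs >= 2 conformations")
    first = ensemble[0]
    for k, c in enumerate(ensemble[1:], start=2):
        if not c.same_topology(first):
            raise ValidationError(f"model {k} differs in topology from model 1")
    fit_idx = np.flatnonzero(np.isin(first.atom_names, list(fit_atoms)))
    if len(fit_idx) < 3:
        raise ValidationError("need >= 3 backbone atoms for superposition")
    coords = np.stack([c.coords for c in ensemble]).astype(float)
    if superpose:
        mean = coords[0].copy()
        for _ in range(max_iter):
            for m in range(len(coords)):
                R, t = _kabsch(coords[m][fit_idx], mean[fit_idx])
                coords[m] = coords[m] @ R.T + t
            new_mean = coords.mean(axis=0)
            if np.abs(new_mean - mean).max() < tol:
                mean = new_mean
                break
            mean = new_mean
    mean = coords.mean(axis=0)
    out: dict[int, float] = {}
    for rid in first.residues():
        ia = first.atom_index(rid.index, "CA")
        if ia is None:
            continue
        dev = coords[:, ia, :] - mean[ia]
        out[rid.index] = float(np.sqrt(np.mean(np.sum(dev**2, axis=1))))
    return out
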