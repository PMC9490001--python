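"""Core domain containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
AA_1TO3["X"] = "UNK"


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(ValidationError):
    """A file could not be parsed as the declared format."""


class FitError(RuntimeError):
    """A numerical fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, residuals: Optional[np.ndarray] = None):
        super().__init__(message)
        self.residuals = residuals


class InsufficientDataError(ValidationError):
    """Too few observations for the requested analysis."""


@dataclass(frozen=True, order=True)
class ResidueID:
    """1-based sequence position plus one-letter amino-acid code."""

    index: int
    aa: str = "X"

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError(f"residue index must be >= 1, got {self.index}")
        if self.aa not in AA_ALPHABET:
            raise ValidationError(f"unknown amino-acid code {self.aa!r}")


@dataclass
class DecayCurve:
    """A per-residue intensity decay series I(t).

    Times in seconds, intensities in arbitrary units; optional per-point
    errors.  At least 3 points, strictly increasing delays.
    """

    residue: ResidueID
    times: np.ndarray
    intensities: np.ndarray
    errors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.times.shape:
                raise ValidationError("errors must match times in length")
        if self.times.shape != self.intensities.shape:
            raise ValidationError("times and intensities must have equal length")
        if len(self.times) < 3:
            raise ValidationError(
                f"decay curve for residue {self.residue.index} has "
                f"{len(self.times)} points; need >= 3"
            )
        if not np.all(np.diff(self.times) > 0):
            raise ValidationError(
                f"delays for residue {self.residue.index} are not strictly increasing"
            )
        if not np.any(self.intensities > 0):
            raise ValidationError(
                f"decay curve for residue {self.residue.index} has no positive intensity"
            )


@dataclass
class Conformation:
    """One structural model: per-atom residue ids, names, elements, coordinates (Å)."""

    res_index: np.ndarray  # (n_atoms,) int, 1-based
    res_aa: np.ndarray  # (n_atoms,) one-letter codes
    atom_names: np.ndarray  # (n_atoms,) str
    elements: np.ndarray  # (n_atoms,) str
    coords: np.ndarray  # (n_atoms, 3) float, Å
    model_id: int = 1

    def __post_init__(self) -> None:
        self.res_index = np.asarray(self.res_index, dtype=int)
        self.res_aa = np.asarray(self.res_aa, dtype="U1")
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.res_index)
        if self.coords.shape != (n, 3):
            raise ValidationError("coords must be (n_atoms, 3)")
        if not (len(self.res_aa) == len(self.atom_names) == len(self.elements) == n):
            raise ValidationError("per-atom arrays must share length")
        if n == 0:
            raise ValidationError("conformation has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        # atom names unique within each residue
        seen = set()
        for ri, an in zip(self.res_index, self.atom_names):
            key = (int(ri), str(an))
            if key in seen:
                raise ValidationError(
                    f"duplicate atom {an!r} in residue {ri}"
                )
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.res_index)

    def residues(self) -> list[ResidueID]:
        """Residues in order of first appearance."""
        out: list[ResidueID] = []
        seen: set[int] = set()
        for ri, aa in zip(self.res_index, self.res_aa):
            if int(ri) not in seen:
                seen.add(int(ri))
                out.append(ResidueID(int(ri), str(aa)))
        return out

    def atom_coord(self, res_index: int, atom_name: str) -> Optional[np.ndarray]:
        mask = (self.res_index == res_index) & (self.atom_names == atom_name)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            return None
        return self.coords[idx[0]]

    def atom_index(self, res_index: int, atom_name: str) -> Optional[int]:
        mask = (self.res_index == res_index) & (self.atom_names == atom_name)
        idx = np.flatnonzero(mask)
        return int(idx[0]) if len(idx) else None

    def with_coords(self, coords: np.ndarray, model_id: Optional[int] = None) -> "Conformation":
        """Copy with replaced coordinates (same topology)."""
        return Conformation(
            res_index=self.res_index,
            res_aa=self.res_aa,
            atom_names=self.atom_names,
            elements=self.elements,
            coords=np.array(coords, dtype=float),
            model_id=self.model_id if model_id is None else model_id,
        )

    def same_topology(self, other: "Conformation") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.res_index, other.res_index)
            and np.array_equal(self.atom_names, other.atom_names)
        )
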