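"""Readers and writers for the pipeline's tabular and structural formats.

Tabular files are tab-separated with a single commented header line::

    # residue	aa	R1	R1_err	...

Numeric values are written with 17 significant digits so that a write/read
round trip is bit-identical for finite floats.  Structural ensembles are
standard multi-model PDB files (MODEL/ENDMDL records), handled via biotite.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .types import (
    AA_1TO3,
    AA_3TO1,
    Conformation,
    DecayCurve,
    FormatError,
    ResidueID,
    ValidationError,
)

logger = logging.getLogger("nmrdyn")

PathLike = Union[str, Path]


def _format_value(v) -> str:
    if isinstance(v, (float, np.floating)):
        return f"{v:.17g}"
    return str(v)


def _read_header(path: Path) -> list[str]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if not line.startswith("#"):
                raise FormatError(
                    f"{path}: expected a commented header line starting with '#', "
                    f"found {line[:40]!r}"
                )
            return line.lstrip("#").strip().split("\t")
    return []


def read_table(path: PathLike) -> pd.DataFrame:
    """Read a TSV table with a ``# col1<TAB>col2...`` header into a DataFrame."""
    path = Path(path)
    columns = _read_header(path)
    if not columns:
        return pd.DataFrame()
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=columns,
                     skip_blank_lines=True, float_precision="round_trip")
    return df


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    """Write a DataFrame in the package's commented-header TSV dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(map(str, df.columns)) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_format_value(v) for v in row) + "\n")


def write_per_residue_table(records: pd.DataFrame, path: PathLike) -> None:
    """Write a per-residue result table, sorted by residue index.

    ``records`` must contain a ``residue`` column of 1-based indices; duplicate
    residue ids are rejected.
    """
    if "residue" not in records.columns:
        raise ValidationError("per-residue table requires a 'residue' column")
    res = records["residue"].to_numpy()
    if len(np.unique(res)) != len(res):
        dupes = sorted({int(r) for r in res if np.sum(res == r) > 1})
        raise ValidationError(f"duplicate residue ids: {dupes}")
    ordered = records.sort_values("residue", kind="stable").reset_index(drop=True)
    write_table(ordered, path)


def read_per_residue_table(path: PathLike) -> pd.DataFrame:
    df = read_table(path)
    if len(df) and "residue" not in df.columns:
        raise FormatError(f"{path}: missing 'residue' column")
    if len(df):
        df["residue"] = df["residue"].astype(int)
    return df


# ---------------------------------------------------------------------------
# Decay tables
# ---------------------------------------------------------------------------

def read_decay_table(path: PathLike) -> list[DecayCurve]:
    """Read per-residue intensity decay series.

    The header is ``# residue<TAB>aa<TAB><t1><TAB><t2>...`` where the delay
    column names are times in seconds.  Missing (NaN) cells are dropped from
    the affected curve with a warning.
    """
    path = Path(path)
    columns = _read_header(path)
    if not columns:
        return []
    if len(columns) < 3 or columns[0] != "residue" or columns[1] != "aa":
        raise FormatError(
            f"{path}: decay-table header must be '# residue aa <delays...>', "
            f"got {columns[:4]}"
        )
    try:
        delays = np.array([float(c) for c in columns[2:]])
    except ValueError as exc:
        raise FormatError(f"{path}: delay columns must be numeric seconds: {exc}")
    if not np.all(np.diff(delays) > 0):
        raise ValidationError(f"{path}: delay columns are not strictly increasing")
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=columns,
                     skip_blank_lines=True, float_precision="round_trip")
    curves: list[DecayCurve] = []
    for _, row in df.iterrows():
        rid = ResidueID(int(row["residue"]), str(row["aa"]))
        vals = row.iloc[2:].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if not ok.all():
            warnings.warn(
                f"residue {rid.index}: dropped {int((~ok).sum())} missing cell(s)",
                stacklevel=2,
            )
        curves.append(DecayCurve(rid, delays[ok], vals[ok]))
    return curves


def write_decay_table(curves: Sequence[DecayCurve], path: PathLike) -> None:
    """Write decay curves sharing one delay grid as a decay TSV."""
    if not curves:
        Path(path).write_text("")
        return
    grid = curves[0].times
    for c in curves:
        if len(c.times) != len(grid) or not np.allclose(c.times, grid, rtol=0, atol=0):
            raise ValidationError("all curves must share one delay grid for writing")
    cols = ["residue", "aa"] + [f"{t:.17g}" for t in grid]
    rows = [[c.residue.index, c.residue.aa] + list(c.intensities) for c in curves]
    write_table(pd.DataFrame(rows, columns=cols), path)


# ---------------------------------------------------------------------------
# Multi-model structures
# ---------------------------------------------------------------------------

def _atom_array_to_conformation(arr: struc.AtomArray, model_id: int) -> Conformation:
    aa = np.array([AA_3TO1.get(str(r).upper(), "X") for r in arr.res_name], dtype="U1")
    elements = np.array(
        [str(e) if str(e) else str(n)[0] for e, n in zip(arr.element, arr.atom_name)],
        dtype="U2",
    )
    return Conformation(
        res_index=np.asarray(arr.res_id, dtype=int),
        res_aa=aa,
        atom_names=np.asarray(arr.atom_name, dtype="U6"),
        elements=elements,
        coords=np.asarray(arr.coord, dtype=float),
        model_id=model_id,
    )


def read_ensemble(path: PathLike) -> list[Conformation]:
    """Read a multi-model PDB file into one Conformation per MODEL.

    All models must share the same atom count; offenders are reported by
    model id.
    """
    path = Path(path)
    pdb_file = pdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    confs: list[Conformation] = []
    counts: dict[int, int] = {}
    for m in range(1, n_models + 1):
        arr = pdb_file.get_structure(model=m)
        counts[m] = arr.array_length()
        confs.append(_atom_array_to_conformation(arr, model_id=m))
    ref = counts[1]
    offenders = [m for m, c in counts.items() if c != ref]
    if offenders:
        raise ValidationError(
            f"{path}: models {offenders} have atom counts differing from model 1 "
            f"({ref} atoms): {[counts[m] for m in offenders]}"
        )
    return confs


def write_ensemble(confs: Sequence[Conformation], path: PathLike) -> None:
    """Write conformations as a multi-model PDB file."""
    if not confs:
        raise ValidationError("cannot write an empty ensemble")
    first = confs[0]
    for c in confs[1:]:
        if not c.same_topology(first):
            raise ValidationError("all models must share atom topology for writing")
    n = first.n_atoms
    arr = struc.AtomArray(n)
    arr.res_id = first.res_index
    arr.res_name = np.array([AA_1TO3.get(a, "UNK") for a in first.res_aa])
    arr.atom_name = first.atom_names
    arr.element = np.char.upper(first.elements)
    arr.chain_id = np.full(n, "A")
    arr.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([arr] * len(confs))
    stack.coord = np.stack([c.coords for c in confs])
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path: Optional[PathLike]) -> dict:
    """Load the structured key-value config file (YAML mapping); {} if absent."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a key-value mapping")
    return cfg


def setup_logging(level: str = "INFO") -> None:
    """Timestamped logging to stderr."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
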