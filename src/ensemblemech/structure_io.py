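"""Structure and ensemble I/O plus atom-selection machinery.

A conformational ensemble is an ordered stack of coordinate frames sharing
one set of atom metadata, tagged with its provenance (``unbound`` or
``bound``).  Selections are defined by inclusive author-numbered residue
ranges plus an atom-class filter (``calpha`` | ``backbone`` | ``heavy`` |
``all``), the convention used throughout protein-ensemble comparison work.

Multi-model PDB is the canonical interchange format (parsed/written through
biotite); a trivial whitespace "XYZ-frames" text format is provided for
synthetic bead ensembles.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "ConformationalEnsemble",
    "AtomSelection",
    "StructureError",
    "SelectionError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_xyz_frames",
    "write_xyz_frames",
    "parse_selection",
    "resolve_selection",
    "ATOM_CLASSES",
]

ATOM_CLASSES = ("calpha", "backbone", "heavy", "all")
_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

#: columns of the per-atom metadata table
_META_COLUMNS = [
    "atom_name",
    "residue_name",
    "residue_number",
    "insertion_code",
    "chain_id",
    "element",
    "hetero",
]


class StructureError(ValueError):
    """Malformed or inconsistent structural input."""


class SelectionError(ValueError):
    """Invalid or empty atom selection."""


@dataclass
class ConformationalEnsemble:
    """Ordered coordinate frames with shared per-atom metadata.

    Parameters
    ----------
    atoms : pandas.DataFrame
        One row per atom with columns ``atom_name, residue_name,
        residue_number, insertion_code, chain_id, element, hetero``.
    coords : numpy.ndarray, shape (n_frames, n_atoms, 3), Å
    provenance : {"unbound", "bound"}
    frame_stride_ps : float, optional
        Time between stored frames, picoseconds.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    provenance: str = "unbound"
    frame_stride_ps: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise StructureError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise StructureError("ensemble must contain at least one frame")
        if len(self.atoms) != self.coords.shape[1]:
            raise StructureError(
                f"metadata rows ({len(self.atoms)}) != atoms per frame "
                f"({self.coords.shape[1]})"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("ensemble coordinates contain non-finite values")
        if self.provenance not in ("unbound", "bound"):
            raise StructureError(f"provenance must be 'unbound' or 'bound', got {self.provenance!r}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def subset(self, indices: np.ndarray) -> "ConformationalEnsemble":
        """New ensemble restricted to the given atom indices (order kept)."""
        idx = np.asarray(indices, dtype=int)
        return ConformationalEnsemble(
            atoms=self.atoms.iloc[idx].reset_index(drop=True),
            coords=self.coords[:, idx, :],
            provenance=self.provenance,
            frame_stride_ps=self.frame_stride_ps,
        )

    def with_provenance(self, provenance: str) -> "ConformationalEnsemble":
        return replace(self, provenance=provenance)


@dataclass
class AtomSelection:
    """Named atom subset: residue intervals plus an atom-class filter.

    ``residue_ranges`` holds ``(chain_id, first, last)`` inclusive intervals;
    ``chain_id`` of ``"*"`` matches every chain.  ``indices`` is filled by
    :func:`resolve_selection` and is ordered by ensemble atom order.
    """

    name: str
    residue_ranges: list[tuple[str, int, int]]
    atom_class: str = "calpha"
    indices: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.atom_class not in ATOM_CLASSES:
            raise SelectionError(
                f"atom_class must be one of {ATOM_CLASSES}, got {self.atom_class!r}"
            )

    @property
    def resolved(self) -> bool:
        return self.indices is not None

    @property
    def n_atoms(self) -> int:
        if self.indices is None:
            raise SelectionError(f"selection {self.name!r} is not resolved")
        return len(self.indices)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _meta_from_atom_array(arr: struc.AtomArray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "atom_name": arr.atom_name.astype(str),
            "residue_name": arr.res_name.astype(str),
            "residue_number": arr.res_id.astype(int),
            "insertion_code": arr.ins_code.astype(str),
            "chain_id": arr.chain_id.astype(str),
            "element": arr.element.astype(str),
            "hetero": arr.hetero.astype(bool),
        }
    )


def read_multimodel_pdb(path, model_limit: int | None = None) -> ConformationalEnsemble:
    """Read a (multi-model) PDB file into a :class:`ConformationalEnsemble`.

    Alternate locations are reduced to the first conformer (blank or 'A');
    every model must contain the same number of atoms.  ``model_limit`` caps
    the number of models read.

    Raises
    ------
    StructureError
        On unparseable records or an atom-count mismatch between models.
    """
    try:
        pdb = PDBFile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc

    n_models = pdb.get_model_count()
    n_read = n_models if model_limit is None else min(model_limit, n_models)
    frames = []
    meta = None
    for m in range(1, n_read + 1):
        try:
            arr = pdb.get_structure(model=m, altloc="first")
        except Exception as exc:
            raise StructureError(f"cannot read model {m} of {path}: {exc}") from exc
        if meta is None:
            meta = _meta_from_atom_array(arr)
            n_atoms = arr.array_length()
        elif arr.array_length() != n_atoms:
            raise StructureError(
                f"model {m} of {path} has {arr.array_length()} atoms, "
                f"expected {n_atoms} (model 1)"
            )
        frames.append(np.asarray(arr.coord, dtype=float))
    if not frames:
        raise StructureError(f"{path} contains no models")
    return ConformationalEnsemble(atoms=meta, coords=np.stack(frames))


def write_multimodel_pdb(ensemble: ConformationalEnsemble, path) -> None:
    """Write an ensemble as a standard multi-model PDB (fixed columns, %8.3f).

    Raises
    ------
    StructureError
        If any coordinate magnitude is ≥ 10000 Å (fixed-column overflow).
    """
    if np.any(np.abs(ensemble.coords) >= 10000.0):
        raise StructureError(
            "coordinate magnitude >= 10000 Å cannot be represented in "
            "fixed-column PDB format"
        )
    n = ensemble.n_atoms
    arr = struc.AtomArrayStack(ensemble.n_frames, n)
    # round to the printed precision first so the float32 pass-through cannot
    # push a value across a 3rd-decimal rounding boundary
    arr.coord = np.round(ensemble.coords, 3).astype(np.float32)
    meta = ensemble.atoms
    arr.atom_name = meta["atom_name"].to_numpy(dtype="U6")
    arr.res_name = meta["residue_name"].to_numpy(dtype="U5")
    arr.res_id = meta["residue_number"].to_numpy(dtype=int)
    arr.ins_code = meta["insertion_code"].to_numpy(dtype="U1")
    arr.chain_id = meta["chain_id"].to_numpy(dtype="U4")
    arr.element = meta["element"].to_numpy(dtype="U2")
    arr.hetero = meta["hetero"].to_numpy(dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
    with open(path, "r+") as fh:
        content = fh.read()
        if not content.rstrip().endswith("END"):
            fh.seek(0, 2)
            if not content.endswith("\n"):
                fh.write("\n")
            fh.write("END\n")


# ---------------------------------------------------------------------------
# XYZ-frames text format:  "n_atoms" header line, then n_atoms*(x y z) lines
# per frame, frames concatenated.
# ---------------------------------------------------------------------------

def write_xyz_frames(ensemble: ConformationalEnsemble, path) -> None:
    """Write coordinates in the plain whitespace XYZ-frames format."""
    with open(path, "w") as fh:
        fh.write(f"{ensemble.n_atoms}\n")
        for frame in ensemble.coords:
            for x, y, z in frame:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_frames(path, atoms: pd.DataFrame | None = None,
                    provenance: str = "unbound") -> ConformationalEnsemble:
    """Read the XYZ-frames format; generic CA-bead metadata if none given."""
    with open(path) as fh:
        header = fh.readline()
        try:
            n_atoms = int(header.strip())
        except ValueError as exc:
            raise StructureError(f"{path}: bad XYZ-frames header {header!r}") from exc
        values = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise StructureError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                values.append([float(p) for p in parts])
            except ValueError as exc:
                raise StructureError(f"{path}:{lineno}: bad coordinate field") from exc
    data = np.asarray(values, dtype=float)
    if data.shape[0] % n_atoms != 0:
        raise StructureError(
            f"{path}: {data.shape[0]} coordinate rows not divisible by n_atoms={n_atoms}"
        )
    coords = data.reshape(-1, n_atoms, 3)
    if atoms is None:
        atoms = bead_metadata(n_atoms)
    return ConformationalEnsemble(atoms=atoms, coords=coords, provenance=provenance)


def bead_metadata(n_atoms: int, chain_id: str = "A") -> pd.DataFrame:
    """Metadata table for Cα pseudo-atom beads, sequential residue numbers."""
    return pd.DataFrame(
        {
            "atom_name": ["CA"] * n_atoms,
            "residue_name": ["GLY"] * n_atoms,
            "residue_number": np.arange(1, n_atoms + 1),
            "insertion_code": [""] * n_atoms,
            "chain_id": [chain_id] * n_atoms,
            "element": ["C"] * n_atoms,
            "hetero": [False] * n_atoms,
        }
    )


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

_INTERVAL_RE = re.compile(r"^(?:(?P<chain>[A-Za-z0-9]+):)?(?P<first>\d+)-(?P<last>\d+)$")


def parse_selection(spec: str, atom_class: str = "calpha",
                    name: str | None = None) -> AtomSelection:
    """Parse a residue-range spec like ``"A:353-363,A:370-391"``.

    Intervals are inclusive on both ends; omitting the chain prefix makes the
    interval match every chain.
    """
    if not spec or not spec.strip():
        raise SelectionError("empty selection spec")
    ranges: list[tuple[str, int, int]] = []
    for token in spec.split(","):
        token = token.strip()
        m = _INTERVAL_RE.match(token)
        if m is None:
            raise SelectionError(f"cannot parse residue interval {token!r}")
        first, last = int(m.group("first")), int(m.group("last"))
        if last < first:
            raise SelectionError(f"reversed interval {token!r} (last < first)")
        ranges.append((m.group("chain") or "*", first, last))
    return AtomSelection(name=name or spec, residue_ranges=ranges, atom_class=atom_class)


def _atom_class_mask(atoms: pd.DataFrame, atom_class: str) -> np.ndarray:
    name = atoms["atom_name"].str.strip().str.upper()
    element = atoms["element"].str.strip().str.upper()
    if atom_class == "calpha":
        return ((name == "CA") & (element == "C")).to_numpy()
    if atom_class == "backbone":
        return name.isin(_BACKBONE_NAMES).to_numpy()
    if atom_class == "heavy":
        return (element != "H").to_numpy()
    return np.ones(len(atoms), dtype=bool)


def resolve_selection(selection: AtomSelection,
                      ensemble: ConformationalEnsemble) -> AtomSelection:
    """Resolve residue ranges + atom class to concrete atom indices.

    HETATM records are excluded from every selection (analyses here are
    protein-atom based).  Resolution is deterministic and idempotent; atom
    order follows the ensemble's atom order.
    """
    atoms = ensemble.atoms
    in_range = np.zeros(len(atoms), dtype=bool)
    res_num = atoms["residue_number"].to_numpy()
    chain = atoms["chain_id"].to_numpy()
    for chain_id, first, last in selection.residue_ranges:
        mask = (res_num >= first) & (res_num <= last)
        if chain_id != "*":
            mask &= chain == chain_id
        in_range |= mask
    mask = in_range & _atom_class_mask(atoms, selection.atom_class)
    mask &= ~atoms["hetero"].to_numpy()
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        raise SelectionError(
            f"selection {selection.name!r} matches no atoms "
            f"(ranges={selection.residue_ranges}, atom_class={selection.atom_class})"
        )
    return replace(selection, indices=indices)


def concatenate(unbound: ConformationalEnsemble,
                bound: ConformationalEnsemble) -> tuple[ConformationalEnsemble, np.ndarray]:
    """Concatenate two ensembles (unbound first).

    Returns the combined ensemble (provenance of the first) and a per-frame
    provenance array of ``"unbound"`` / ``"bound"`` strings.
    """
    if unbound.n_atoms != bound.n_atoms:
        raise StructureError(
            f"ensembles differ in atom count ({unbound.n_atoms} vs {bound.n_atoms})"
        )
    coords = np.concatenate([unbound.coords, bound.coords], axis=0)
    prov = np.array(
        ["unbound"] * unbound.n_frames + ["bound"] * bound.n_frames, dtype=object
    )
    combined = ConformationalEnsemble(
        atoms=unbound.atoms, coords=coords, provenance=unbound.provenance
    )
    return combined, prov
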