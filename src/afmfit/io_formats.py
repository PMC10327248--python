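"""Readers and writers for coarse-grained RNA structures, AFM height grids,
secondary-structure lists and trajectory energy tables.

Coarse-graining scheme
----------------------
Each nucleotide is reduced to three beads: a *phosphate* bead at the P atom,
a *sugar* bead at the C4' atom, and a *base* bead at the centroid of the base
ring atoms.  The 5'-terminal residue may lack a phosphate.  This is the
standard three-bead nucleic-acid mapping and is reproducible from any
full-atom PDB file.

AFM height grids are plain text: a two-line header (``pixel_size_ang``,
``origin_ang``) followed by rows of heights in Angstrom.  Grids are indexed
row-major with the origin at the lower-left pixel center and x running along
columns.  An ``x y z`` triplet dialect on a regular grid is also accepted.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

__all__ = [
    "Bead",
    "CoarseModel",
    "AFMSurface",
    "SecondaryStructure",
    "EnergyRecord",
    "ENERGY_FIELDS",
    "read_coarse_structure",
    "write_coarse_pdb",
    "read_afm_surface",
    "write_afm_surface",
    "read_energy_table",
    "write_energy_table",
    "read_secondary_structure",
    "write_secondary_structure",
]

BEAD_KINDS = ("phosphate", "sugar", "base")

#: base-ring atoms used for the base-bead centroid
_PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
_PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

_RNA_RESNAMES = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "RA": "A", "RC": "C", "RG": "G", "RU": "U",
    "ADE": "A", "CYT": "C", "GUA": "G", "URA": "U", "URI": "U",
}
_PURINES = {"A", "G"}


@dataclass(frozen=True)
class Bead:
    residue_index: int
    kind: str
    position: np.ndarray
    nucleotide: str

    def __post_init__(self):
        if self.kind not in BEAD_KINDS:
            raise ValueError(f"unknown bead kind {self.kind!r}")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("bead position must be a finite 3-vector")


@dataclass
class CoarseModel:
    """Bead-level RNA structure (phosphate / sugar / base beads)."""

    beads: list[Bead]
    chain_id: str = "A"

    def __post_init__(self):
        per_res: dict[int, list[str]] = {}
        for b in self.beads:
            per_res.setdefault(b.residue_index, []).append(b.kind)
        for idx, kinds in per_res.items():
            if kinds.count("sugar") != 1 or kinds.count("base") != 1:
                raise ValueError(
                    f"residue {idx} must have exactly one sugar and one base bead"
                )
            if kinds.count("phosphate") > 1:
                raise ValueError(f"residue {idx} has more than one phosphate bead")

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def n_residues(self) -> int:
        return len({b.residue_index for b in self.beads})

    @property
    def residue_indices(self) -> list[int]:
        return sorted({b.residue_index for b in self.beads})

    @property
    def coords(self) -> np.ndarray:
        """(n_beads, 3) array of positions, in bead order."""
        return np.array([b.position for b in self.beads], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "CoarseModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_beads, 3):
            raise ValueError("coordinate array shape mismatch")
        beads = [
            Bead(b.residue_index, b.kind, c, b.nucleotide)
            for b, c in zip(self.beads, coords)
        ]
        return CoarseModel(beads, chain_id=self.chain_id)

    def bead_selection(self, kind: str) -> np.ndarray:
        """Boolean mask over beads of the given kind."""
        return np.array([b.kind == kind for b in self.beads], dtype=bool)

    def residue_of_bead(self) -> np.ndarray:
        return np.array([b.residue_index for b in self.beads], dtype=int)


@dataclass
class AFMSurface:
    """Rectangular AFM height grid (Angstrom) with fixed pixel size.

    ``heights[i, j]`` is the height at y = origin[1] + i*pixel_size,
    x = origin[0] + j*pixel_size (row-major, lower-left origin).
    """

    heights: np.ndarray
    pixel_size: float = 5.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or min(self.heights.shape) < 2:
            raise ValueError("height grid must be 2-D with both dims >= 2")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("height grid contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    def x_coords(self) -> np.ndarray:
        return self.origin[0] + self.pixel_size * np.arange(self.heights.shape[1])

    def y_coords(self) -> np.ndarray:
        return self.origin[1] + self.pixel_size * np.arange(self.heights.shape[0])


@dataclass
class SecondaryStructure:
    """Base-pair and base-stack lists over residue indices (1-based)."""

    pairs: list[tuple[int, int]] = field(default_factory=list)
    stacks: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.pairs = [(min(i, j), max(i, j)) for i, j in self.pairs]
        self.stacks = [(min(i, j), max(i, j)) for i, j in self.stacks]
        seen: set[int] = set()
        for i, j in self.pairs:
            if i == j:
                raise ValueError("a residue cannot pair with itself")
            if i in seen or j in seen:
                raise ValueError(f"residue in more than one base pair: ({i},{j})")
            seen.update((i, j))

    def validate_indices(self, n_residues: int) -> None:
        for i, j in self.pairs + self.stacks:
            if not (1 <= i <= n_residues and 1 <= j <= n_residues):
                raise ValueError(f"secondary-structure index ({i},{j}) out of range")


ENERGY_FIELDS = (
    "e_total",
    "e_go",
    "e_local",
    "e_stacking",
    "e_pairing",
    "e_repulsive",
    "e_electrostatic",
    "b_stage",
    "v_afm",
    "cc_afm",
)


@dataclass
class EnergyRecord:
    """Per-frame energy components and the AFM cross-correlation score."""

    frame: int
    e_total: float
    e_go: float
    e_local: float
    e_stacking: float
    e_pairing: float
    e_repulsive: float
    e_electrostatic: float
    b_stage: float
    v_afm: float
    cc_afm: float

    def __post_init__(self):
        if not -1.0 <= self.cc_afm <= 1.0:
            raise ValueError(f"cc_afm must lie in [-1, 1], got {self.cc_afm}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in ENERGY_FIELDS], dtype=float)


def records_to_frame(records: Sequence[EnergyRecord]) -> pd.DataFrame:
    rows = [{"frame": r.frame, **{f: getattr(r, f) for f in ENERGY_FIELDS}} for r in records]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PDB coarse-graining
# ---------------------------------------------------------------------------

def read_coarse_structure(path, scheme: str = "p-c4p-basecentroid") -> CoarseModel:
    """Read a PDB file and coarse-grain each RNA residue to three beads.

    Non-RNA residues (including waters and ions) are skipped with a single
    summary warning.  A residue missing its C4' atom is a hard error.
    """
    if scheme != "p-c4p-basecentroid":
        raise ValueError(f"unknown coarse-grain scheme {scheme!r}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("m", str(path))
    model = next(structure.get_models())
    beads: list[Bead] = []
    chain_id = "A"
    n_skipped = 0
    first_residue = True
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip()
            nt = _RNA_RESNAMES.get(resname)
            if nt is None:
                n_skipped += 1
                continue
            chain_id = chain.id if isinstance(chain.id, str) else "A"
            idx = residue.id[1]
            atoms = {a.get_name(): a.get_coord() for a in residue}
            if "P" in atoms:
                beads.append(Bead(idx, "phosphate", atoms["P"], nt))
            elif not first_residue:
                raise ValueError(f"residue {idx} lacks a P atom")
            if "C4'" in atoms:
                sugar = atoms["C4'"]
            elif "C4*" in atoms:
                sugar = atoms["C4*"]
            else:
                raise ValueError(f"residue {idx} lacks a C4' atom")
            beads.append(Bead(idx, "sugar", sugar, nt))
            ring = _PURINE_RING if nt in _PURINES else _PYRIMIDINE_RING
            ring_coords = [atoms[a] for a in ring if a in atoms]
            if not ring_coords:
                raise ValueError(f"residue {idx} has no base ring atoms")
            beads.append(Bead(idx, "base", np.mean(ring_coords, axis=0), nt))
            first_residue = False
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-RNA residue(s)", stacklevel=2)
    if not beads:
        raise ValueError(f"no RNA residues found in {path}")
    return CoarseModel(beads, chain_id=chain_id)


_BEAD_ATOM = {"phosphate": "P", "sugar": "C4'"}


def _base_atom_name(nucleotide: str) -> str:
    return "N9" if nucleotide in _PURINES else "N1"


def write_coarse_pdb(models: CoarseModel | Sequence[CoarseModel], path) -> None:
    """Write one model (or a multi-model trajectory) as PDB.

    Bead atom names are P / C4' / N9-or-N1 so the file round-trips through
    :func:`read_coarse_structure` (a single ring atom makes the base centroid
    the atom itself).
    """
    if isinstance(models, CoarseModel):
        models = [models]
    if not models:
        raise ValueError("no models to write")
    lines: list[str] = []
    multi = len(models) > 1
    for imodel, m in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {imodel:4d}")
        serial = 1
        for b in m.beads:
            name = _BEAD_ATOM.get(b.kind) or _base_atom_name(b.nucleotide)
            x, y, z = b.position
            lines.append(
                f"ATOM  {serial:5d} {name:^4s} {b.nucleotide:>3s} {m.chain_id[:1]}"
                f"{b.residue_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}"
            )
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# AFM grid text
# ---------------------------------------------------------------------------

def read_afm_surface(path) -> AFMSurface:
    """Read an AFM height grid, either header+grid or x/y/z triplet text."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValueError(f"empty AFM surface file: {path}")
    if lines[0].split()[0] == "pixel_size_ang":
        return _read_grid_format(lines, path)
    return _read_triplet_format(lines, path)


def _read_grid_format(lines: list[str], path) -> AFMSurface:
    pixel_size = float(lines[0].split()[1])
    tok = lines[1].split()
    if tok[0] != "origin_ang":
        raise ValueError(f"malformed header in {path}: expected origin_ang line")
    origin = (float(tok[1]), float(tok[2]))
    rows = [[float(v) for v in ln.split()] for ln in lines[2:]]
    heights = np.array(rows, dtype=float)
    if np.any(np.isnan(heights)):
        raise ValueError(f"NaN heights in {path}")
    return AFMSurface(heights, pixel_size=pixel_size, origin=origin)


def _read_triplet_format(lines: list[str], path) -> AFMSurface:
    data = np.array([[float(v) for v in ln.split()] for ln in lines], dtype=float)
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValueError(f"triplet file must have 3 columns: {path}")
    if np.any(np.isnan(data)):
        raise ValueError(f"NaN values in {path}")
    xs = np.unique(data[:, 0])
    ys = np.unique(data[:, 1])
    if len(xs) < 2 or len(ys) < 2 or len(xs) * len(ys) != len(data):
        raise ValueError(f"triplet grid is not a full rectangular grid: {path}")
    dx = np.diff(xs)
    dy = np.diff(ys)
    if np.ptp(dx) > 1e-6 or np.ptp(dy) > 1e-6 or abs(dx[0] - dy[0]) > 1e-6:
        raise ValueError(f"triplet grid spacing is irregular: {path}")
    heights = np.full((len(ys), len(xs)), np.nan)
    ix = np.searchsorted(xs, data[:, 0])
    iy = np.searchsorted(ys, data[:, 1])
    heights[iy, ix] = data[:, 2]
    if np.any(np.isnan(heights)):
        raise ValueError(f"triplet grid has missing pixels: {path}")
    return AFMSurface(heights, pixel_size=float(dx[0]), origin=(float(xs[0]), float(ys[0])))


def write_afm_surface(surface: AFMSurface, path) -> None:
    """Write a surface in the 2-line-header grid dialect (lossless to 1e-9)."""
    if surface.heights.size == 0:
        raise ValueError("cannot write an empty surface")
    buf = io.StringIO()
    buf.write(f"pixel_size_ang {surface.pixel_size!r}\n")
    buf.write(f"origin_ang {surface.origin[0]!r} {surface.origin[1]!r}\n")
    for row in surface.heights:
        buf.write(" ".join(repr(float(v)) for v in row))
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Energy tables
# ---------------------------------------------------------------------------

def read_energy_table(path, column_map: Mapping[str, str] | None = None) -> list[EnergyRecord]:
    """Read a delimited trajectory energy table into EnergyRecords.

    ``column_map`` maps record field names (``e_total`` ... ``cc_afm``,
    ``frame``) to column names in the file; unmapped fields use their own
    name.  Extra columns are ignored.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    column_map = dict(column_map or {})
    records = []
    fields = ("frame",) + ENERGY_FIELDS
    colnames = {}
    for f in fields:
        col = column_map.get(f, f)
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} (for field {f!r}) in {path}")
        colnames[f] = col
    for row_number, (_, row) in enumerate(df.iterrows(), start=1):
        vals = {}
        for f in fields:
            v = row[colnames[f]]
            try:
                vals[f] = float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {v!r} in column {colnames[f]!r}, row {row_number}"
                ) from None
            if not np.isfinite(vals[f]):
                raise ValueError(
                    f"non-numeric value {v!r} in column {colnames[f]!r}, row {row_number}"
                )
        vals["frame"] = int(vals["frame"])
        records.append(EnergyRecord(**vals))
    return records


def write_energy_table(records: Sequence[EnergyRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Secondary structure lists
# ---------------------------------------------------------------------------

def read_secondary_structure(path) -> SecondaryStructure:
    """Read a pair/stack list: lines of ``pair i j`` or ``stack i j``."""
    pairs, stacks = [], []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        kind, i, j = ln.split()
        if kind == "pair":
            pairs.append((int(i), int(j)))
        elif kind == "stack":
            stacks.append((int(i), int(j)))
        else:
            raise ValueError(f"unknown record kind {kind!r}")
    return SecondaryStructure(pairs=pairs, stacks=stacks)


def write_secondary_structure(ss: SecondaryStructure, path) -> None:
    lines = [f"pair {i} {j}" for i, j in ss.pairs]
    lines += [f"stack {i} {j}" for i, j in ss.stacks]
    Path(path).write_text("\n".join(lines) + "\n")
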