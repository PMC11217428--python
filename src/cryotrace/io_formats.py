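"""File formats and grid geometry.

Density maps are read and written through :mod:`gemmi` (MRC/CCP4 mode-2
float).  The in-memory convention is fixed here once and used by every other
module: grids are indexed ``values[ix, iy, iz]`` with 0-based indices, and
the world coordinate of a voxel is its center,

    coordinate = origin + index * voxel_size   (Angstrom).

Sequences are FASTA via Biopython; structural models are C-alpha-only PDB
files via gemmi.
"""

from __future__ import annotations

import logging
import string
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import AA_ALPHABET, AA_ONE, AA_THREE, SUBGRID_SIZE

log = logging.getLogger(__name__)


class MapFormatError(ValueError):
    """Malformed or unsupported density-map file."""


class SequenceFormatError(ValueError):
    """Malformed FASTA input or illegal residue characters."""


class StructureFormatError(ValueError):
    """Malformed structure file or an unwritable model."""


# ---------------------------------------------------------------------------
# density grids
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """3D scalar density field on a regular orthogonal voxel grid.

    Attributes
    ----------
    values : ndarray, shape (nx, ny, nz)
        Density values, indexed (x, y, z).
    voxel_size : ndarray, shape (3,)
        Per-axis voxel edge length in Angstrom (all > 0).
    origin : ndarray, shape (3,)
        World coordinate (Angstrom) of the center of voxel (0, 0, 0).
    axis_order : tuple
        Permutation that mapped the file's (column, row, section) axes to
        (x, y, z) at read time; (1, 2, 3) when no permutation was needed.
    """

    values: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    axis_order: tuple[int, int, int] = (1, 2, 3)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise MapFormatError("density grid must be 3-dimensional")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        if not np.all(self.voxel_size > 0):
            raise MapFormatError("voxel_size: all components must be > 0")
        if not np.allclose(self.voxel_size, self.voxel_size[0]):
            log.warning("anisotropic voxel size %s", self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_to_angstrom(self, index: np.ndarray) -> np.ndarray:
        """World coordinate (Angstrom) of voxel center(s) at ``index``."""
        return self.origin + np.asarray(index, dtype=float) * self.voxel_size

    def angstrom_to_voxel(self, coord: np.ndarray) -> np.ndarray:
        """Nearest voxel index for world coordinate(s) in Angstrom."""
        idx = (np.asarray(coord, dtype=float) - self.origin) / self.voxel_size
        return np.rint(idx).astype(int)


def read_density_map(path) -> DensityGrid:
    """Read an MRC/CCP4 density map into the (x, y, z) convention.

    Axis permutations declared in the header (MAPC/MAPR/MAPS) are undone so
    that ``values[ix, iy, iz]`` always indexes crystallographic x, y, z.
    The origin is taken from the ORIGIN header words, falling back to
    NXSTART-based offsets when ORIGIN is all zero.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot read density map {path}: {exc}") from exc
    axis_order = tuple(m.header_i32(i) for i in (17, 18, 19))
    cell = m.grid.unit_cell
    for name, ang in (("alpha", cell.alpha), ("beta", cell.beta),
                      ("gamma", cell.gamma)):
        if abs(ang - 90.0) > 1e-3:
            raise MapFormatError(
                f"non-orthogonal cell: angle {name} = {ang:.2f} deg "
                "(only orthogonal voxel grids are supported)")
    m.setup(float("nan"))  # reorder axes to x, y, z and fill gaps
    values = np.array(m.grid, copy=True)
    if np.isnan(values).any():
        raise MapFormatError("map does not cover its full unit-cell grid")
    voxel_size = np.array(m.grid.spacing, dtype=float)
    if not np.all(voxel_size > 0):
        raise MapFormatError("voxel_size: header cell/grid size gives "
                             f"non-positive spacing {voxel_size}")
    origin = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=float)
    if np.all(origin == 0.0):
        nstart = np.array([m.header_i32(i) for i in (5, 6, 7)], dtype=float)
        # nstart is stored in file (column,row,section) order; permute to xyz
        perm = np.argsort(np.array(axis_order))
        origin = nstart[perm] * voxel_size
    return DensityGrid(values=values, voxel_size=voxel_size, origin=origin,
                       axis_order=axis_order)  # type: ignore[arg-type]


def write_density_map(grid: DensityGrid, path) -> None:
    """Write a :class:`DensityGrid` as an MRC/CCP4 mode-2 map."""
    vals = np.ascontiguousarray(grid.values, dtype=np.float32)
    g = gemmi.FloatGrid(vals)
    nx, ny, nz = vals.shape
    vx, vy, vz = grid.voxel_size
    g.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90, 90, 90)
    g.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), grid.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


def normalize_density(grid: DensityGrid) -> DensityGrid:
    """Clamp negative density to zero, then min-max scale to [0, 1]."""
    v = np.clip(grid.values.astype(np.float32), 0.0, None)
    span = float(v.max() - v.min())
    if span > 0:
        v = (v - v.min()) / span
    return DensityGrid(values=v, voxel_size=grid.voxel_size,
                       origin=grid.origin, axis_order=grid.axis_order)


# ---------------------------------------------------------------------------
# sub-grid tiling
# ---------------------------------------------------------------------------

@dataclass
class SubGrid:
    """A cubic tile of a parent grid, zero-padded at map boundaries."""

    values: np.ndarray  # (size, size, size)
    offset: tuple[int, int, int]  # voxel index of the tile corner


def tile_into_subgrids(grid: DensityGrid,
                       size: int = SUBGRID_SIZE) -> list[SubGrid]:
    """Cut a grid into non-overlapping ``size``^3 tiles covering every voxel.

    Boundary tiles are zero-padded; offsets allow exact stitching.
    """
    shape = grid.shape
    tiles: list[SubGrid] = []
    for ox in range(0, shape[0], size):
        for oy in range(0, shape[1], size):
            for oz in range(0, shape[2], size):
                block = grid.values[ox:ox + size, oy:oy + size, oz:oz + size]
                if block.shape != (size, size, size):
                    padded = np.zeros((size, size, size),
                                      dtype=grid.values.dtype)
                    padded[:block.shape[0], :block.shape[1],
                           :block.shape[2]] = block
                    block = padded
                tiles.append(SubGrid(values=block, offset=(ox, oy, oz)))
    return tiles


def stitch_subgrids(tiles: list[tuple[tuple[int, int, int], np.ndarray]],
                    shape: tuple[int, int, int]) -> np.ndarray:
    """Reassemble per-tile arrays into a parent-shaped array.

    Each item is ``(offset, array)`` where ``array`` has shape
    ``(..., size, size, size)`` — leading channel axes are preserved.
    Padding that falls outside ``shape`` is discarded.  Raises if the tiles
    do not cover every parent voxel exactly once.
    """
    if not tiles:
        raise ValueError("no tiles to stitch")
    lead = tiles[0][1].shape[:-3]
    out = np.empty(lead + tuple(shape), dtype=tiles[0][1].dtype)
    covered = np.zeros(shape, dtype=bool)
    for offset, arr in tiles:
        ox, oy, oz = offset
        sx = min(arr.shape[-3], shape[0] - ox)
        sy = min(arr.shape[-2], shape[1] - oy)
        sz = min(arr.shape[-1], shape[2] - oz)
        if sx <= 0 or sy <= 0 or sz <= 0:
            raise ValueError(f"tile at offset {offset} lies outside {shape}")
        out[..., ox:ox + sx, oy:oy + sy, oz:oz + sz] = arr[..., :sx, :sy, :sz]
        covered[ox:ox + sx, oy:oy + sy, oz:oz + sz] = True
    if not covered.all():
        raise ValueError("tiles do not cover the full parent grid")
    return out


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass
class ChainSequenceSet:
    """Ordered protein chain sequences over the 20 standard amino acids."""

    chains: list[tuple[str, str]]  # (chain_id, sequence)

    def __post_init__(self) -> None:
        if not self.chains:
            raise SequenceFormatError("no chains provided")
        for cid, seq in self.chains:
            if not seq:
                raise SequenceFormatError(f"chain {cid!r} has empty sequence")
            bad = set(seq) - set(AA_ALPHABET)
            if bad:
                raise SequenceFormatError(
                    f"chain {cid!r} contains non-standard residue "
                    f"character(s) {sorted(bad)}; allowed: {AA_ALPHABET}")

    @property
    def total_residues(self) -> int:
        return sum(len(seq) for _, seq in self.chains)


def read_fasta(path) -> ChainSequenceSet:
    """Read a FASTA file with one record per chain, order preserved."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceFormatError(f"no FASTA records in {path}")
    return ChainSequenceSet(
        chains=[(rec.id, str(rec.seq).upper()) for rec in records])


def write_fasta(chains: ChainSequenceSet, path) -> None:
    records = [SeqRecord(Seq(seq), id=cid, description="")
               for cid, seq in chains.chains]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# structure models
# ---------------------------------------------------------------------------

@dataclass
class Residue:
    """One modeled residue: a C-alpha position plus per-residue metadata."""

    coord: np.ndarray  # (3,) Angstrom
    aa: str  # one-letter code
    ca_confidence: float = 0.0
    aa_confidence: float = 0.0
    ca_prob: float = 0.0  # classifier C-alpha probability of the source atom
    emission_prob: float = 0.0  # HMM emission used at this position

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float).reshape(3)
        if self.aa not in AA_THREE:
            raise StructureFormatError(f"unknown amino-acid code {self.aa!r}")


@dataclass
class StructureModel:
    """Per-chain ordered C-alpha residues, writable as a PDB file."""

    chains: list[tuple[str, list[Residue]]] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return sum(len(res) for _, res in self.chains)

    def all_residues(self) -> list[Residue]:
        return [r for _, res in self.chains for r in res]

    def coordinates(self) -> np.ndarray:
        """(n_residues, 3) array of C-alpha coordinates in chain order."""
        res = self.all_residues()
        if not res:
            return np.zeros((0, 3))
        return np.stack([r.coord for r in res])


_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def write_pdb(model: StructureModel, path) -> None:
    """Write a C-alpha-only PDB file.

    One CA ATOM record per residue; residues numbered 1..n per chain.  The
    B-factor column carries ``aa_confidence`` scaled to [0, 100] and the
    occupancy column carries ``ca_confidence``.
    """
    if len(model.chains) > len(_CHAIN_IDS):
        raise StructureFormatError(
            f"{len(model.chains)} chains exceed the {len(_CHAIN_IDS)} "
            "single-character PDB chain identifiers")
    st = gemmi.Structure()
    st.name = "cryotrace"
    md = gemmi.Model("1")
    for k, (cid, residues) in enumerate(model.chains):
        name = cid if len(cid) == 1 and cid in _CHAIN_IDS else _CHAIN_IDS[k]
        ch = gemmi.Chain(name)
        for i, res in enumerate(residues, start=1):
            r = gemmi.Residue()
            r.name = AA_THREE[res.aa]
            r.seqid = gemmi.SeqId(i, " ")
            r.het_flag = "A"  # always ATOM records, even for lone residues
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*res.coord)
            atom.occ = float(np.clip(res.ca_confidence, 0.0, 1.0))
            atom.b_iso = float(np.clip(res.aa_confidence, 0.0, 1.0) * 100.0)
            r.add_atom(atom)
            ch.add_residue(r)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


def read_reference_pdb(path) -> StructureModel:
    """Read a PDB file keeping C-alpha atoms only.

    Alternate locations are resolved to the highest-occupancy CA; residues
    with non-standard names are skipped with a warning; chain order is
    preserved.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot read {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models in file")
    chains: list[tuple[str, list[Residue]]] = []
    for ch in st[0]:
        residues: list[Residue] = []
        for res in ch:
            cas = [a for a in res if a.name == "CA"]
            if not cas:
                continue
            best = max(cas, key=lambda a: a.occ)
            one = AA_ONE.get(res.name)
            if one is None:
                warnings.warn(f"skipping non-standard residue {res.name} "
                              f"in chain {ch.name}")
                continue
            residues.append(Residue(
                coord=np.array([best.pos.x, best.pos.y, best.pos.z]),
                aa=one,
                ca_confidence=float(best.occ),
                aa_confidence=float(best.b_iso) / 100.0,
            ))
        if residues:
            chains.append((ch.name, residues))
    if not chains:
        raise StructureFormatError(f"{path}: no C-alpha atoms found")
    return StructureModel(chains=chains)
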