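"""Synthetic proteins, density maps, label grids and surrogate predictions.

Every stage of the pipeline is testable without experimental maps or
trained weights.  The generator emulates exactly the statistics the method
assumes: adjacent C-alpha distances drawn from N(3.8047 A, 0.036 A)
truncated to [3.6, 4.0] A, blob-like density at atom positions on a 1-A
voxel grid, one labeled voxel per atom, and probability grids in which the
labeled class receives a configurable share of the mass.

Everything is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .constants import (AA_ALPHABET, AA_NONE_INDEX, CA_CA_MEAN, CA_CA_SIGMA,
                        background_frequencies)
from .io_formats import (ChainSequenceSet, DensityGrid, Residue,
                         StructureModel)
from .voxelnet.predict import PredictionGrids

BOND_RANGE = (3.6, 4.0)
BOND_ANGLE_RANGE = (80.0, 150.0)  # degrees, at the shared atom
EXCLUSION_RADIUS = 3.0  # A, minimum distance between any two C-alpha atoms
ATOM_NONE = 3  # index of the "no atom" class


@dataclass
class SyntheticProtein:
    """Ground-truth chains: sequences and C-alpha traces."""

    chains: list[tuple[str, np.ndarray]]  # (sequence, (n, 3) coords)
    seed: int
    params: dict = field(default_factory=dict)

    def all_coords(self) -> np.ndarray:
        return np.concatenate([c for _, c in self.chains])

    def to_sequences(self) -> ChainSequenceSet:
        ids = [chr(ord("A") + i) for i in range(len(self.chains))]
        return ChainSequenceSet(chains=[(i, seq) for i, (seq, _) in
                                        zip(ids, self.chains)])

    def to_structure(self) -> StructureModel:
        model = StructureModel()
        for cid, (seq, coords) in zip(
                (chr(ord("A") + i) for i in range(len(self.chains))),
                self.chains):
            model.chains.append((cid, [
                Residue(coord=c, aa=a, ca_confidence=1.0, aa_confidence=1.0)
                for c, a in zip(coords, seq)]))
        return model


def _sample_bond_length(rng: np.random.Generator) -> float:
    lo, hi = BOND_RANGE
    a = (lo - CA_CA_MEAN) / CA_CA_SIGMA
    b = (hi - CA_CA_MEAN) / CA_CA_SIGMA
    return float(truncnorm.rvs(a, b, loc=CA_CA_MEAN, scale=CA_CA_SIGMA,
                               random_state=rng))


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotate_about(v: np.ndarray, axis: np.ndarray,
                  angle: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis`` by ``angle`` rad."""
    return (v * np.cos(angle) + np.cross(axis, v) * np.sin(angle)
            + axis * (axis @ v) * (1.0 - np.cos(angle)))


def _next_direction(prev: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """New bond direction with a bond angle in the allowed range.

    The bond angle theta is measured at the shared atom between the two
    bonds, so the new direction deviates from the previous one by
    180 deg - theta, at a uniformly random dihedral.
    """
    theta = np.deg2rad(rng.uniform(*BOND_ANGLE_RANGE))
    deviation = np.pi - theta
    # random axis perpendicular to prev
    r = _random_unit(rng)
    axis = np.cross(prev, r)
    while np.linalg.norm(axis) < 1e-8:
        r = _random_unit(rng)
        axis = np.cross(prev, r)
    axis /= np.linalg.norm(axis)
    return _rotate_about(prev, axis, deviation)


def generate_protein(n_chains: int, residues_per_chain,
                     seed: int = 0,
                     exclusion_radius: float = EXCLUSION_RADIUS,
                     max_restarts: int = 200) -> SyntheticProtein:
    """Self-avoiding random C-alpha walks with realistic bond statistics.

    ``residues_per_chain`` may be an int (same length for every chain) or a
    sequence of per-chain lengths.  Sequences are drawn from the background
    amino-acid frequencies.  Raises after ``max_restarts`` failed chain
    placements (suggesting a larger exclusion radius is infeasible).
    """
    if np.isscalar(residues_per_chain):
        lengths = [int(residues_per_chain)] * n_chains
    else:
        lengths = [int(x) for x in residues_per_chain]
        if len(lengths) != n_chains:
            raise ValueError("residues_per_chain length != n_chains")
    if n_chains < 1 or min(lengths) < 1:
        raise ValueError("need at least one chain of at least one residue")
    rng = np.random.default_rng(seed)
    bg = background_frequencies()
    placed: list[np.ndarray] = []
    chains: list[tuple[str, np.ndarray]] = []
    for length in lengths:
        for attempt in range(max_restarts):
            coords = _grow_chain(length, placed, rng, exclusion_radius)
            if coords is not None:
                break
        else:
            raise RuntimeError(
                f"could not place a {length}-residue chain after "
                f"{max_restarts} restarts; consider fewer/shorter chains")
        seq = "".join(rng.choice(list(AA_ALPHABET), p=bg, size=length))
        chains.append((seq, coords))
        placed.extend(coords)
    return SyntheticProtein(chains=chains, seed=seed,
                            params={"n_chains": n_chains,
                                    "lengths": lengths,
                                    "exclusion_radius": exclusion_radius})


def _grow_chain(length: int, placed: list[np.ndarray],
                rng: np.random.Generator,
                exclusion: float, max_tries: int = 60) -> np.ndarray | None:
    others = np.stack(placed) if placed else np.zeros((0, 3))
    if len(others):
        lo, hi = others.min(axis=0) - 15.0, others.max(axis=0) + 15.0
        start = rng.uniform(lo, hi)
        if len(others) and np.linalg.norm(others - start,
                                          axis=1).min() < exclusion:
            return None
    else:
        start = np.zeros(3)
    coords = [start]
    direction = _random_unit(rng)
    for _ in range(length - 1):
        for _ in range(max_tries):
            cand_dir = (_next_direction(direction, rng)
                        if len(coords) > 1 else _random_unit(rng))
            cand = coords[-1] + cand_dir * _sample_bond_length(rng)
            prior = np.array(coords[:-1])
            ok = True
            if len(prior) and np.linalg.norm(
                    prior - cand, axis=1).min() < exclusion:
                ok = False
            if ok and len(others) and np.linalg.norm(
                    others - cand, axis=1).min() < exclusion:
                ok = False
            if ok:
                coords.append(cand)
                direction = cand_dir
                break
        else:
            return None
    return np.stack(coords)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

@dataclass
class SyntheticMapBundle:
    """A density grid plus per-voxel ground-truth label grids."""

    grid: DensityGrid
    atom_labels: np.ndarray  # int in {0: CA, 1: C, 2: N, 3: none}
    aa_labels: np.ndarray  # int in {0..19 types, 20: none}
    truth: SyntheticProtein


def _add_blob(density: np.ndarray, grid: DensityGrid, center: np.ndarray,
              sigma: float, amplitude: float) -> None:
    r = int(np.ceil(4 * sigma / grid.voxel_size.min()))
    c_idx = grid.angstrom_to_voxel(center)
    lo = np.maximum(c_idx - r, 0)
    hi = np.minimum(c_idx + r + 1, np.array(density.shape))
    ix, iy, iz = [np.arange(lo[d], hi[d]) for d in range(3)]
    pos = np.stack(np.meshgrid(ix, iy, iz, indexing="ij"), axis=-1)
    world = grid.voxel_to_angstrom(pos)
    d2 = ((world - center) ** 2).sum(axis=-1)
    density[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += \
        amplitude * np.exp(-d2 / (2 * sigma * sigma))


def rasterize(protein: SyntheticProtein, voxel_size: float = 1.0,
              blob_sigma: float = 1.0, padding: float = 10.0,
              include_cn: bool = True) -> SyntheticMapBundle:
    """Render a protein as a normalized density map with label grids.

    Density is a sum of isotropic Gaussian blobs at C-alpha positions
    (plus weaker blobs at pseudo C and N positions interpolated along the
    chain when ``include_cn``), min-max normalized to [0, 1].  Exactly one
    voxel — the nearest — is labeled per C-alpha; pseudo C/N labels never
    overwrite a C-alpha label.
    """
    coords = protein.all_coords()
    lo = coords.min(axis=0) - padding
    shape = tuple(np.ceil((coords.max(axis=0) + padding - lo)
                          / voxel_size).astype(int) + 1)
    grid = DensityGrid(values=np.zeros(shape, dtype=np.float32),
                       voxel_size=np.full(3, voxel_size), origin=lo)
    atom_labels = np.full(shape, ATOM_NONE, dtype=np.int8)
    aa_labels = np.full(shape, AA_NONE_INDEX, dtype=np.int8)
    density = grid.values

    pseudo_c, pseudo_n = [], []
    for _, chain_coords in protein.chains:
        for a, b in zip(chain_coords[:-1], chain_coords[1:]):
            pseudo_c.append(a + (b - a) / 3.0)
            pseudo_n.append(a + 2.0 * (b - a) / 3.0)

    for ca in coords:
        _add_blob(density, grid, ca, blob_sigma, 1.0)
    if include_cn:
        for p in pseudo_c + pseudo_n:
            _add_blob(density, grid, p, blob_sigma * 0.8, 0.6)
        for p, cls in [(p, 1) for p in pseudo_c] + \
                      [(p, 2) for p in pseudo_n]:
            idx = tuple(grid.angstrom_to_voxel(p))
            if atom_labels[idx] == ATOM_NONE:
                atom_labels[idx] = cls
    for seq, chain_coords in protein.chains:
        for aa, ca in zip(seq, chain_coords):
            idx = tuple(grid.angstrom_to_voxel(ca))
            atom_labels[idx] = 0  # C-alpha wins any collision
            aa_labels[idx] = AA_ALPHABET.index(aa)
    n_ca_voxels = int((atom_labels == 0).sum())
    if n_ca_voxels != len(coords):
        raise RuntimeError(
            f"{len(coords)} C-alpha atoms map to {n_ca_voxels} voxels; "
            "atoms closer than the voxel size are not representable")
    mx = density.max()
    if mx > 0:
        density /= mx
    return SyntheticMapBundle(grid=grid, atom_labels=atom_labels,
                              aa_labels=aa_labels, truth=protein)


# ---------------------------------------------------------------------------
# surrogate predictions
# ---------------------------------------------------------------------------

def simulate_predictions(bundle: SyntheticMapBundle,
                         correct_prob: float = 0.95,
                         noise_seed: int = 0,
                         fp_rate: float = 0.0) -> PredictionGrids:
    """Probability grids that put ``correct_prob`` mass on the true class.

    The remaining mass is spread uniformly over the other classes.  With
    ``fp_rate`` > 0, that fraction of unlabeled voxels is flipped to a
    random atom class before the mass assignment (false positives).
    """
    if not 0.0 < correct_prob <= 1.0:
        raise ValueError("correct_prob must be in (0, 1]")
    rng = np.random.default_rng(noise_seed)
    atom_labels = bundle.atom_labels.copy()
    if fp_rate > 0:
        none_idx = np.argwhere(atom_labels == ATOM_NONE)
        n_flip = int(len(none_idx) * fp_rate)
        if n_flip:
            pick = rng.choice(len(none_idx), size=n_flip, replace=False)
            for ix, iy, iz in none_idx[pick]:
                atom_labels[ix, iy, iz] = rng.integers(0, 3)
    atom = _labels_to_probs(atom_labels, 4, correct_prob)
    aa = _labels_to_probs(bundle.aa_labels, 21, correct_prob)
    return PredictionGrids(atom_probs=atom, aa_probs=aa)


def _labels_to_probs(labels: np.ndarray, n_classes: int,
                     correct_prob: float) -> np.ndarray:
    rest = (1.0 - correct_prob) / (n_classes - 1)
    probs = np.full((n_classes,) + labels.shape, rest, dtype=np.float32)
    for c in range(n_classes):
        mask = labels == c
        probs[c][mask] = correct_prob
    return probs


def training_dataset(bundle: SyntheticMapBundle, task: str = "atom",
                     size: int = 32) -> list[tuple[np.ndarray, np.ndarray]]:
    """(sub-grid, label-grid) pairs for the toy training loop.

    Label padding at map boundaries uses the "none" class of the task.
    """
    if task == "atom":
        labels, pad = bundle.atom_labels, ATOM_NONE
    elif task == "aa":
        labels, pad = bundle.aa_labels, AA_NONE_INDEX
    else:
        raise ValueError(f"unknown task {task!r}")
    shape = bundle.grid.shape
    pairs = []
    for ox in range(0, shape[0], size):
        for oy in range(0, shape[1], size):
            for oz in range(0, shape[2], size):
                g = np.zeros((size, size, size), dtype=np.float32)
                l = np.full((size, size, size), pad, dtype=np.int64)
                block = bundle.grid.values[ox:ox + size, oy:oy + size,
                                           oz:oz + size]
                lb = labels[ox:ox + size, oy:oy + size, oz:oz + size]
                g[:block.shape[0], :block.shape[1], :block.shape[2]] = block
                l[:lb.shape[0], :lb.shape[1], :lb.shape[2]] = lb
                pairs.append((g, l))
    return pairs


def make_confidence_dataset(n: int, beta0: float, beta1: float,
                            seed: int = 0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Planted logistic data: x ~ U(0,1), y ~ Bernoulli(sigmoid(b0+b1*x))."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=(n, 1))
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x[:, 0])))
    y = (rng.uniform(size=n) < p).astype(int)
    return x, y
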