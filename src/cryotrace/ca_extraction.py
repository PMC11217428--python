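"""From per-voxel predictions to a deduplicated set of C-alpha atoms.

Voxels whose C-alpha class probability exceeds a threshold (strictly) are
selected as candidates; candidates within a linkage radius of each other are
grouped into single-linkage connected components; each cluster is
represented by its medoid voxel carrying the cluster-averaged probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .constants import AA_ALPHABET, AA_NONE_INDEX, CA_PROB_THRESHOLD, \
    CLUSTER_RADIUS
from .io_formats import DensityGrid
from .voxelnet.predict import PredictionGrids

log = logging.getLogger(__name__)


@dataclass
class CaCandidate:
    """A single above-threshold C-alpha voxel."""

    coord: np.ndarray  # (3,) Angstrom
    ca_prob: float
    aa_probs: np.ndarray  # (20,) renormalized over the standard types
    voxel_index: int  # flat index in the parent grid (tie-break key)


@dataclass
class CaAtom:
    """A clustered predicted C-alpha atom."""

    coord: np.ndarray  # medoid voxel center, Angstrom
    ca_prob: float  # cluster mean
    aa_probs: np.ndarray  # cluster mean, renormalized to sum 1
    cluster_size: int = 1


@dataclass
class CaAtomSet:
    atoms: list[CaAtom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.coord for a in self.atoms])

    def ca_probs(self) -> np.ndarray:
        return np.array([a.ca_prob for a in self.atoms])

    def aa_prob_matrix(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 20))
        return np.stack([a.aa_probs for a in self.atoms])


def _renormalize_aa(aa_vec: np.ndarray) -> np.ndarray:
    """Drop the none/unknown class and renormalize over the 20 types."""
    v = np.asarray(aa_vec, dtype=float)[:AA_NONE_INDEX]
    s = v.sum()
    if s <= 0:
        return np.full(20, 1.0 / 20.0)
    return v / s


def select_ca_voxels(preds: PredictionGrids, grid: DensityGrid,
                     threshold: float = CA_PROB_THRESHOLD
                     ) -> list[CaCandidate]:
    """Candidate C-alpha voxels with probability strictly above threshold."""
    if preds.shape != grid.shape:
        raise ValueError(f"prediction shape {preds.shape} != grid shape "
                         f"{grid.shape}")
    ca = preds.atom_probs[0]
    idx = np.argwhere(ca > threshold)
    candidates = []
    for ix, iy, iz in idx:
        flat = int(np.ravel_multi_index((ix, iy, iz), grid.shape))
        candidates.append(CaCandidate(
            coord=grid.voxel_to_angstrom((ix, iy, iz)),
            ca_prob=float(ca[ix, iy, iz]),
            aa_probs=_renormalize_aa(preds.aa_probs[:, ix, iy, iz]),
            voxel_index=flat))
    return candidates


def cluster_ca(candidates: list[CaCandidate],
               radius: float = CLUSTER_RADIUS) -> CaAtomSet:
    """Merge candidates into atoms by single-linkage components at ``radius``.

    The representative of each cluster is the medoid (member minimizing the
    summed distance to the other members), with ties broken by higher
    C-alpha probability and then lower voxel index; the probabilities are
    cluster means (amino-acid means renormalized to sum 1).
    """
    if radius <= 0:
        raise ValueError("cluster radius must be > 0")
    if not candidates:
        return CaAtomSet()
    # deterministic processing order regardless of caller ordering
    order = sorted(range(len(candidates)),
                   key=lambda i: candidates[i].voxel_index)
    cands = [candidates[i] for i in order]
    coords = np.stack([c.coord for c in cands])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    n = len(cands)
    if len(pairs):
        rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    else:
        graph = csr_matrix((n, n))
    n_comp, labels = connected_components(graph, directed=False)
    atoms = []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        sub = coords[members]
        d = np.linalg.norm(sub[:, None] - sub[None, :], axis=-1).sum(axis=1)
        # medoid; ties -> higher ca_prob, then lower voxel index
        keys = [(d[i], -cands[m].ca_prob, cands[m].voxel_index)
                for i, m in enumerate(members)]
        rep = members[min(range(len(members)), key=lambda i: keys[i])]
        aa_mean = np.mean([cands[m].aa_probs for m in members], axis=0)
        aa_mean = aa_mean / aa_mean.sum()
        atoms.append(CaAtom(
            coord=cands[rep].coord.copy(),
            ca_prob=float(np.mean([cands[m].ca_prob for m in members])),
            aa_probs=aa_mean,
            cluster_size=len(members)))
    # stable output order: by representative position, lexicographic
    atoms.sort(key=lambda a: tuple(a.coord))
    return CaAtomSet(atoms=atoms)


def extract_ca_atoms(preds: PredictionGrids, grid: DensityGrid,
                     threshold: float = CA_PROB_THRESHOLD,
                     radius: float = CLUSTER_RADIUS) -> CaAtomSet:
    """Selection followed by clustering (the full extraction step)."""
    return cluster_ca(select_ca_voxels(preds, grid, threshold), radius)


def atoms_to_tsv(atoms: CaAtomSet, path) -> None:
    """Dump extracted atoms for inspection (x, y, z, probability, top type,
    cluster size)."""
    with open(path, "w") as fh:
        fh.write("x\ty\tz\tca_prob\ttop_aa\tcluster_size\n")
        for a in atoms.atoms:
            top = AA_ALPHABET[int(np.argmax(a.aa_probs))]
            fh.write(f"{a.coord[0]:.3f}\t{a.coord[1]:.3f}\t{a.coord[2]:.3f}"
                     f"\t{a.ca_prob:.4f}\t{top}\t{a.cluster_size}\n")
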