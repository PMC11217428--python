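"""Tiled inference: density grid -> per-voxel probability fields.

The prediction source is pluggable: a pair of trained
:class:`~cryotrace.voxelnet.network.VoxelClassifier` heads, or any callable
(surrogate) mapping a 32-cubed sub-grid to (atom, amino-acid) probability
sub-grids — which lets synthetic probability grids stand in for a trained
network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax as _softmax

from ..io_formats import DensityGrid, stitch_subgrids, tile_into_subgrids
from .network import VoxelClassifier

_TOL = 1e-6


@dataclass
class PredictionGrids:
    """Per-voxel class probabilities aligned to a parent density grid.

    ``atom_probs``: (4, nx, ny, nz) over (CA, C, N, none);
    ``aa_probs``: (21, nx, ny, nz) over the 20 standard amino acids plus a
    no/unknown class.  Every per-voxel vector sums to 1.
    """

    atom_probs: np.ndarray
    aa_probs: np.ndarray

    def __post_init__(self) -> None:
        self.atom_probs = np.asarray(self.atom_probs, dtype=np.float32)
        self.aa_probs = np.asarray(self.aa_probs, dtype=np.float32)
        if self.atom_probs.shape[0] != 4 or self.aa_probs.shape[0] != 21:
            raise ValueError("expected 4 atom and 21 amino-acid channels")
        if self.atom_probs.shape[1:] != self.aa_probs.shape[1:]:
            raise ValueError("shape mismatch between atom and amino-acid "
                             "probability grids")
        for name, arr in (("atom", self.atom_probs), ("aa", self.aa_probs)):
            if arr.min() < -_TOL:
                raise ValueError(f"negative {name} probabilities")
            s = arr.sum(axis=0)
            if np.abs(s - 1.0).max() > 1e-4:
                raise ValueError(f"{name} probability vectors do not sum "
                                 "to 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.atom_probs.shape[1:]  # type: ignore[return-value]


class NetworkPredictor:
    """Wraps the two classification heads into one sub-grid predictor."""

    def __init__(self, atom_net: VoxelClassifier, aa_net: VoxelClassifier):
        if atom_net.spec.out_channels != 4 or aa_net.spec.out_channels != 21:
            raise ValueError("atom head must have 4 channels and the "
                             "amino-acid head 21")
        self.atom_net = atom_net
        self.aa_net = aa_net

    def __call__(self, subgrid: np.ndarray):
        x = np.asarray(subgrid, dtype=np.float32)[None, None]
        atom = _softmax(self.atom_net.forward(x).data[0], axis=0)
        aa = _softmax(self.aa_net.forward(x).data[0], axis=0)
        return atom, aa


def predict_grids(predictor, grid: DensityGrid) -> PredictionGrids:
    """Run tiled inference over a whole density grid.

    ``predictor`` is called per 32-cubed tile and must return
    ``(atom, aa)`` arrays of shapes (4, 32, 32, 32) and (21, 32, 32, 32);
    values that are not already normalized per voxel are softmax-normalized
    when they do not sum to 1.  Tiles are stitched back to the parent shape
    with boundary padding discarded.
    """
    tiles = tile_into_subgrids(grid)
    atom_tiles, aa_tiles = [], []
    for tile in tiles:
        atom, aa = predictor(tile.values)
        atom = np.asarray(atom, dtype=np.float32)
        aa = np.asarray(aa, dtype=np.float32)
        if atom.shape[1:] != tile.values.shape or atom.shape[0] != 4:
            raise ValueError(f"atom head returned shape {atom.shape}")
        if aa.shape[1:] != tile.values.shape or aa.shape[0] != 21:
            raise ValueError(f"amino-acid head returned shape {aa.shape}")
        atom = _ensure_normalized(atom)
        aa = _ensure_normalized(aa)
        atom_tiles.append((tile.offset, atom))
        aa_tiles.append((tile.offset, aa))
    shape = grid.shape
    return PredictionGrids(
        atom_probs=stitch_subgrids(atom_tiles, shape),
        aa_probs=stitch_subgrids(aa_tiles, shape))


def _ensure_normalized(probs: np.ndarray) -> np.ndarray:
    s = probs.sum(axis=0)
    if np.abs(s - 1.0).max() <= _TOL and probs.min() >= 0:
        return probs
    return _softmax(probs, axis=0)
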