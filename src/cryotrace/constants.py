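"""Shared constants: amino-acid alphabet, class layouts, model defaults."""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids, one-letter codes, in the fixed symbol order
#: used everywhere in this package (emission matrices, probability vectors,
#: one-hot encodings).
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA_ALPHABET)}

AA_THREE: dict[str, str] = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
AA_ONE: dict[str, str] = {v: k for k, v in AA_THREE.items()}

#: Atom-classification classes, in channel order.
ATOM_CLASSES: tuple[str, ...] = ("CA", "C", "N", "none")
N_ATOM_CLASSES: int = 4

#: Amino-acid classification adds one "no/unknown amino acid" class after
#: the 20 standard types.
N_AA_CLASSES: int = 21
AA_NONE_INDEX: int = 20

#: Mean and standard deviation (Angstrom) of the distance between adjacent
#: C-alpha atoms along a protein chain, as estimated from experimental
#: structures; these parameterize both the HMM transition model and the
#: synthetic backbone generator.
CA_CA_MEAN: float = 3.8047
CA_CA_SIGMA: float = 0.036

#: Dimensionless scaling factor applied to sigma in the transition density,
#: widening it to tolerate discretization error in predicted coordinates.
LAMBDA_SCALE: float = 10.0

#: Default probability threshold for selecting predicted C-alpha voxels
#: (strictly greater than) and the clustering radius in Angstrom.
CA_PROB_THRESHOLD: float = 0.4
CLUSTER_RADIUS: float = 2.0

#: Side length (voxels) of the cubic sub-grids fed to the voxel classifier.
SUBGRID_SIZE: int = 32

# Background amino-acid frequencies (fraction of residues) compiled from the
# UniProtKB/Swiss-Prot database, ordered per AA_ALPHABET.  Used as the prior
# in the HMM emission model; overridable through configuration.
_BG = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.73,
    "S": 6.64, "T": 5.35, "W": 1.09, "Y": 2.92, "V": 6.86,
}


def background_frequencies() -> np.ndarray:
    """Default background amino-acid frequency vector (sums to 1)."""
    b = np.array([_BG[a] for a in AA_ALPHABET], dtype=float)
    return b / b.sum()
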