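"""End-to-end orchestration: map + sequences -> C-alpha backbone model.

Stages: read and normalize the density map, obtain per-voxel predictions
(trained network heads, a surrogate callable, or precomputed probability
grids), select and cluster C-alpha voxels, build the HMM, align every
chain with the no-repeat Viterbi decoder, optionally apply fitted
confidence models, and write the PDB plus a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .ca_extraction import extract_ca_atoms
from .confidence import LogisticModel, apply_confidence
from .constants import (CA_CA_MEAN, CA_CA_SIGMA, CA_PROB_THRESHOLD,
                        CLUSTER_RADIUS, LAMBDA_SCALE,
                        background_frequencies)
from .hmm_alignment import align_all_chains, build_hmm, paths_to_structure
from .io_formats import (DensityGrid, StructureModel, normalize_density,
                         read_density_map, read_fasta, write_pdb)
from .voxelnet.network import NetworkSpec, build_network
from .voxelnet.predict import (NetworkPredictor, PredictionGrids,
                               predict_grids)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable pipeline constants; defaults are the method's values."""

    ca_threshold: float = CA_PROB_THRESHOLD
    cluster_radius: float = CLUSTER_RADIUS
    mu: float = CA_CA_MEAN
    sigma: float = CA_CA_SIGMA
    lambda_scale: float = LAMBDA_SCALE
    background_frequencies: str = "default"  # or path to a 20-value file
    normalization: bool = True
    atom_checkpoint: str = ""  # network weights; empty -> surrogate mode
    aa_checkpoint: str = ""
    ca_confidence_model: str = ""  # fitted LogisticModel JSON, optional
    aa_confidence_model: str = ""
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load a YAML config; unknown keys are rejected."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}; "
                             f"known: {sorted(known)}")
        return cls(**data)

    def background(self) -> np.ndarray:
        if self.background_frequencies == "default":
            return background_frequencies()
        b = np.loadtxt(self.background_frequencies)
        if b.shape != (20,) or np.any(b < 0):
            raise ValueError("background frequency file must hold 20 "
                             "non-negative values")
        return b / b.sum()

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    model: StructureModel
    manifest: dict = field(default_factory=dict)


def _resolve_predictor(config: PipelineConfig, predictor):
    if predictor is not None:
        return predictor
    if not config.atom_checkpoint or not config.aa_checkpoint:
        raise ValueError(
            "no prediction source: pass predictions/predictor or set both "
            "atom_checkpoint and aa_checkpoint in the config")
    atom_net = build_network(NetworkSpec(out_channels=4), seed=config.seed)
    atom_net.load(config.atom_checkpoint)
    aa_net = build_network(NetworkSpec(out_channels=21), seed=config.seed)
    aa_net.load(config.aa_checkpoint)
    return NetworkPredictor(atom_net, aa_net)


def run_pipeline(map_path=None, fasta_path=None,
                 config: PipelineConfig | None = None,
                 predictor=None,
                 predictions: PredictionGrids | None = None,
                 grid: DensityGrid | None = None,
                 chains=None,
                 out_pdb=None,
                 manifest_path=None) -> PipelineResult:
    """Run the full workflow; returns the model and a run manifest.

    Inputs may be given as file paths (``map_path``, ``fasta_path``) or as
    in-memory objects (``grid``, ``chains``).  The prediction source is, in
    order of precedence: precomputed ``predictions``, a ``predictor``
    callable, or network checkpoints from the config.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    timings: dict[str, float] = {}

    def tick(stage: str) -> None:
        nonlocal t0
        now = time.perf_counter()
        timings[stage] = round(now - t0, 4)
        t0 = now

    try:
        if grid is None:
            grid = read_density_map(map_path)
        if chains is None:
            chains = read_fasta(fasta_path)
    except Exception as exc:
        raise type(exc)(f"[stage input] {exc}") from exc
    tick("input")

    if config.normalization:
        grid = normalize_density(grid)
    tick("normalize")

    if predictions is None:
        pred_source = _resolve_predictor(config, predictor)
        try:
            predictions = predict_grids(pred_source, grid)
        except Exception as exc:
            raise type(exc)(f"[stage predict] {exc}") from exc
    elif predictions.shape != grid.shape:
        raise ValueError("[stage predict] precomputed predictions do not "
                         f"match the map shape {grid.shape}")
    tick("predict")

    atoms = extract_ca_atoms(predictions, grid,
                             threshold=config.ca_threshold,
                             radius=config.cluster_radius)
    n_candidates = int((predictions.atom_probs[0] >
                        config.ca_threshold).sum())
    tick("extract")

    try:
        hmm = build_hmm(atoms, mu=config.mu, sigma=config.sigma,
                        lambda_scale=config.lambda_scale,
                        background=config.background())
        results = align_all_chains(hmm, chains)
    except Exception as exc:
        raise type(exc)(f"[stage align] {exc}") from exc
    model = paths_to_structure(results, atoms, chains)
    tick("align")

    if config.ca_confidence_model and config.aa_confidence_model:
        apply_confidence(model,
                         LogisticModel.from_json(config.ca_confidence_model),
                         LogisticModel.from_json(config.aa_confidence_model))
        tick("confidence")

    if out_pdb is not None:
        write_pdb(model, out_pdb)
        tick("write")

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": dataclasses.asdict(config),
        "stage_timings_s": timings,
        "counts": {
            "map_voxels": int(np.prod(grid.shape)),
            "ca_candidates": n_candidates,
            "ca_atoms": len(atoms),
            "hmm_states": hmm.n_states,
            "chains": len(chains.chains),
            "aligned_residues": model.n_residues,
        },
    }
    if model.n_residues != chains.total_residues:
        raise AssertionError("aligned residue count != sequence length")
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
    log.info("pipeline: %d candidates -> %d atoms -> %d aligned residues",
             n_candidates, len(atoms), model.n_residues)
    return PipelineResult(model=model, manifest=manifest)
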