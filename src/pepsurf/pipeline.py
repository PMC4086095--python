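"""End-to-end orchestration: sequence + structure in, propensities out.

Stages: conformer ensemble generation (or external ensemble load),
coarse-graining, blind rigid docking of each centroid conformer,
per-simulation redundancy clustering, global aggregation and ranking, a
final cross-conformer redundancy pass, and the per-residue propensity
map over the 50 best poses.  All outputs are deterministic functions of
the inputs, the configuration and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__, cluster, coarse_grain, confgen, docking, \
    propensity, structio

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_on_models"]


@dataclasses.dataclass
class RunConfig:
    """All pipeline settings; defaults follow the published protocol where
    it states values (10 A start spacing, 260 orientations, 1 A / 50-window
    pose clustering, 50 scoring poses, 5 A contacts, 200 conformers, up to
    20 centroids)."""

    spacing: float = 10.0
    n_orientations: int = 260
    cluster_threshold: float = 1.0
    cluster_window: int = 50
    n_top: int = 50
    contact_cutoff: float = 5.0
    contact_mode: str = "heavy"
    n_conformers: int = 200
    max_centroids: int = 20
    ensemble_rmsd_threshold: float = 2.0
    energy_cutoff: float = 20.0
    gtol: float = 0.05
    maxiter: int = 500
    workers: int = 1
    seed: int = 0
    forcefield: str | None = None

    def dock_settings(self) -> docking.DockSettings:
        return docking.DockSettings(
            spacing=self.spacing, n_orientations=self.n_orientations,
            cutoff=self.energy_cutoff, gtol=self.gtol,
            maxiter=self.maxiter, workers=self.workers)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


@dataclasses.dataclass
class PipelineResult:
    """In-memory results of a pipeline run."""

    receptor: structio.Structure
    receptor_model: coarse_grain.ReducedModel
    ensemble: confgen.ConformerEnsemble
    poses: cluster.ClusterSet
    propensities: propensity.PropensityMap
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _pymol_script(outdir: Path) -> str:
    return "\n".join([
        "# Generated viewer script: load the propensity-coloured receptor",
        "# and the ranked peptide poses for offline inspection.",
        "load propensity.pdb, receptor",
        "load poses.pdb, poses",
        "hide everything",
        "show surface, receptor",
        "spectrum b, blue_white_red, receptor, 0, 100",
        "show sticks, poses",
        "set all_states, off",
        "",
    ])


def run_on_models(receptor_model, ensemble, config: RunConfig):
    """Dock every centroid conformer and score propensities.

    Returns ``(cluster_set, propensity_map)``.  Exposed separately from
    file handling so synthetic fixtures can run the same path.
    """
    settings = config.dock_settings()
    conformers = ensemble.conformers
    per_conformer = []
    for cid in ensemble.centroid_indices:
        poses = docking.dock_conformer(receptor_model, conformers[cid],
                                       settings, conformer_id=cid)
        cs = cluster.greedy_cluster(poses, conformers,
                                    threshold=config.cluster_threshold,
                                    window=config.cluster_window)
        per_conformer.append(cs.representatives)
    merged = docking.merge_and_rank(per_conformer)
    # final cross-conformer redundancy pass on the aggregated ranking
    final = cluster.greedy_cluster(merged, conformers,
                                   threshold=config.cluster_threshold,
                                   window=config.cluster_window)
    pmap = propensity.compute_propensities(
        receptor_model, final, conformers, n_top=config.n_top,
        cutoff=config.contact_cutoff, mode=config.contact_mode)
    return final, pmap


def run_pipeline(protein: str | Path, peptide: str,
                 config: RunConfig | None = None,
                 outdir: str | Path = "pepsurf_out") -> PipelineResult:
    """Run the full blind site-finding pipeline and write the output bundle.

    ``peptide`` is either a sequence (optionally FASTA text or a path to
    a FASTA/plain file) or a path to a multi-model PDB conformer
    ensemble.  Outputs written to ``outdir``: ``propensity.pdb`` (B-factor
    annotated receptor), ``propensities.tsv``, ``poses.pdb`` (ranked
    multi-model peptide poses), ``view_poses.pml`` and ``manifest.json``.
    """
    config = config or RunConfig()
    outdir = Path(outdir)
    protein = Path(protein)
    params = coarse_grain.load_params(config.forcefield)

    receptor = structio.read_pdb(protein, keep_hetero=False)
    receptor_model = coarse_grain.assign_charges(
        coarse_grain.reduce(receptor, params), params)

    pep_path = Path(peptide)
    if pep_path.exists() and _looks_like_pdb(pep_path):
        ensemble = confgen.load_external_ensemble(
            pep_path, params=params, max_conformers=config.max_centroids)
        seq = ensemble.conformers[0].sequence.sequence
    else:
        text = pep_path.read_text() if pep_path.exists() else peptide
        pseq = structio.validate_peptide_sequence(text)
        seq = pseq.sequence
        conformers = confgen.sample_conformers(
            pseq, n=config.n_conformers, seed=config.seed, params=params)
        ensemble = confgen.cluster_ensemble(
            conformers, k_max=config.max_centroids,
            rmsd_threshold=config.ensemble_rmsd_threshold)
    logger.info("ensemble: %d conformers, %d centroids",
                len(ensemble.conformers), len(ensemble.centroid_indices))

    final, pmap = run_on_models(receptor_model, ensemble, config)

    outdir.mkdir(parents=True, exist_ok=True)
    structio.write_propensity_pdb(receptor, pmap.values,
                                  outdir / "propensity.pdb")
    structio.write_propensity_table(receptor, pmap.values,
                                    outdir / "propensities.tsv")
    structio.write_pose_models(final.representatives[:config.n_top],
                               ensemble.conformers, outdir / "poses.pdb")
    (outdir / "view_poses.pml").write_text(_pymol_script(outdir))

    manifest = {
        "package": {"name": "pepsurf", "version": __version__},
        "inputs": {
            "protein": {"path": str(protein), "sha256": _sha256(protein)},
            "peptide": seq,
        },
        "settings": dataclasses.asdict(config),
        "forcefield_sha256": params.checksum,
        "counts": {
            "receptor_residues": len(receptor),
            "conformers": len(ensemble.conformers),
            "centroids": len(ensemble.centroid_indices),
            "poses_after_clustering": len(final.representatives),
            "poses_scored": pmap.n_used,
        },
        "outputs": {
            name: _sha256(outdir / name)
            for name in ("propensity.pdb", "propensities.tsv", "poses.pdb")
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(receptor=receptor, receptor_model=receptor_model,
                          ensemble=ensemble, poses=final,
                          propensities=pmap, manifest=manifest)


def _looks_like_pdb(path: Path) -> bool:
    try:
        head = path.read_text()[:4000]
    except UnicodeDecodeError:
        return False
    return any(line.startswith(("ATOM", "HETATM", "MODEL"))
               for line in head.splitlines())
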