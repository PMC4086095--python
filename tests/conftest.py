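"""Shared fixtures: force-field parameters, synthetic bead models, and the
session-scoped end-to-end recovery experiment on planted-groove complexes."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from pepsurf import coarse_grain, confgen, evaluate, structio
from pepsurf.coarse_grain import ReducedModel
from pepsurf.pipeline import RunConfig, run_on_models
from pepsurf.structio import Atom, Residue


@pytest.fixture(scope="session")
def params():
    return coarse_grain.load_params()


def make_bead_model(positions, params, type_name="APO_S", charges=None,
                    one_residue_per_bead=True):
    """Build a minimal ReducedModel around raw bead coordinates."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    if isinstance(type_name, str):
        type_ids = np.full(n, params.type_index[type_name], dtype=np.intp)
    else:
        type_ids = np.asarray([params.type_index[t] for t in type_name],
                              dtype=np.intp)
    charges = np.zeros(n) if charges is None else np.asarray(charges, float)
    if one_residue_per_bead:
        residue_index = np.arange(n, dtype=np.intp)
        residues = [Residue("X", i + 1, "", "ALA",
                            [Atom("CA", "C", "ALA", i + 1, "", "X",
                                  tuple(positions[i]))])
                    for i in range(n)]
        bead_names = ["CA"] * n
    else:
        residue_index = np.zeros(n, dtype=np.intp)
        residues = [Residue("X", 1, "", "ALA", [])]
        bead_names = [f"B{i}" for i in range(n)]
    return ReducedModel(
        positions=positions, type_ids=type_ids, charges=charges,
        residue_index=residue_index,
        is_backbone=np.ones(n, dtype=bool),
        bead_names=bead_names, residues=residues, params=params)


@pytest.fixture(scope="session")
def bead_model_factory(params):
    def factory(positions, **kw):
        return make_bead_model(positions, params, **kw)
    return factory


@pytest.fixture(scope="session")
def sphere_receptor(params):
    """Dummy receptor: 300 single-bead residues on a sphere of radius 15 A."""
    from pepsurf.geometry import fibonacci_sphere
    return make_bead_model(15.0 * fibonacci_sphere(300), params)


@pytest.fixture(scope="session")
def small_conformers(params):
    seq = structio.validate_peptide_sequence("ATVRTYSC")
    return confgen.sample_conformers(seq, n=8, seed=7, params=params)


# ---------------------------------------------------------------------------
# End-to-end recovery experiment (shared by several acceptance checks).
# Study conditions: planted-groove complexes with a 4-residue peptide and a
# compact receptor, docked at spacing 12 A with 60 orientations.
# ---------------------------------------------------------------------------

E2E_SEEDS = list(range(1, 11))
E2E_PEPTIDE = "ATVS"
E2E_CONFIG = dict(spacing=12.0, n_orientations=60, energy_cutoff=25.0,
                  gtol=0.01, maxiter=300)
E2E_RECEPTOR_RADIUS = 8.0


@dataclasses.dataclass
class E2EResult:
    seed: int
    ref: evaluate.ReferenceComplex
    cluster_set: object
    pmap: object
    top_distance: float
    p_native_mean: float
    p_other_mean: float


def run_e2e_seed(seed: int) -> E2EResult:
    ref = evaluate.make_synthetic_complex(
        seed=seed, peptide_seq=E2E_PEPTIDE,
        outer_radius=E2E_RECEPTOR_RADIUS)
    ens = confgen.ConformerEnsemble(conformers=[ref.peptide_free],
                                    assignments=[0], centroid_indices=[0])
    cfg = RunConfig(**E2E_CONFIG)
    final, pmap = run_on_models(ref.receptor_model, ens, cfg)
    top = final.representatives[0]
    cen = top.pose.apply(ens.conformers[0].reduced.positions).mean(axis=0)
    dist = float(np.linalg.norm(cen - ref.planted_centroid))
    native = ref.native_interface
    p_nat = float(np.mean([pmap.get(k) for k in native]))
    p_oth = float(np.mean([pmap.get(r.key) for r in ref.receptor.residues
                           if r.key not in native]))
    return E2EResult(seed=seed, ref=ref, cluster_set=final, pmap=pmap,
                     top_distance=dist, p_native_mean=p_nat,
                     p_other_mean=p_oth)


@pytest.fixture(scope="session")
def e2e_results():
    return [run_e2e_seed(s) for s in E2E_SEEDS]
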