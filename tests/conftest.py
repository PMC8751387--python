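import numpy as np
import pytest

from cadsite import (
    FixtureSpec,
    GeometryParameterSet,
    PipelineConfig,
    generate_fixture,
    run_design,
)
from cadsite.fixtures import _template_backbone, _with_cb
from cadsite.geometry import MetalPosition, modes_for
from cadsite.rotamers import CoordinationResidue, build_sidechain_atoms


@pytest.fixture(scope="session")
def params():
    return GeometryParameterSet.default()


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Noise-free fixture with the default planted 2xCys + Glu + backbone-O site."""
    out = tmp_path_factory.mktemp("fixture")
    return generate_fixture(FixtureSpec(), out)


def config_for(bundle, **overrides):
    kwargs = dict(
        pdb=str(bundle.scaffold_path),
        chain=bundle.chain,
        rotlib=str(bundle.rotlib_path),
        params=str(bundle.params_path),
        domain_i_ranges=bundle.domain_definition.domain_i_ranges,
        domain_ii_ranges=bundle.domain_definition.domain_ii_ranges,
        mask_ranges=[],
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def run_result(bundle):
    return run_design(config_for(bundle))


@pytest.fixture(scope="session")
def scaffold(run_result):
    return run_result.scaffold


def placed_residue(restype: str, chi=None):
    """A template residue with a rebuilt side chain (or bare backbone for
    a backbone-oxygen candidate) and its coordination modes."""
    atoms = _with_cb(_template_backbone())
    if restype == "BBO":
        return atoms, modes_for("backbone_oxygen", "ALA", atoms)
    defaults = {"CYS": (-65.0,), "HIS": (-60.0, 90.0), "ASP": (-70.0, 20.0),
                "GLU": (-60.0, 180.0, -40.0)}
    chi = chi if chi is not None else defaults[restype]
    atoms.update(build_sidechain_atoms(atoms, restype, chi))
    return atoms, modes_for("sidechain_mutation", restype, atoms)


def make_entry(position, xyzs, restype="CYS", kind="sidechain_mutation"):
    """Bare coordination-library entry for combinatorial tests: metal
    positions given directly, no placed atoms (so never a mutual clash)."""
    mps = [MetalPosition(np.asarray(x, float), None) for x in xyzs]
    return CoordinationResidue(
        position=position, kind=kind, restype_new=restype, rotamer=None,
        rotamer_index=0, backrub_angle=0.0, placed_atoms={}, modes=[],
        metal_positions=mps,
    )
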