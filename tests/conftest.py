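"""Shared fixtures: all structures are generated programmatically."""

import numpy as np
import pytest

import opepdock as od
from opepdock.synthetic import DecoyGenSpec, ToyComplexSpec, generate_rigid_decoys, make_toy_complex


@pytest.fixture(scope="session")
def config():
    return od.load_default()


@pytest.fixture(scope="session")
def soft(config):
    return od.soften_parameters(config.pair_table, config)


@pytest.fixture(scope="session")
def config_nocut(config):
    """Cutoff-free configuration for exact pairwise contracts."""
    import copy

    cfg = copy.copy(config)
    cfg.cutoff = None
    return cfg


@pytest.fixture(scope="session")
def toy_complex():
    """A small two-chain toy complex (PDB text + native CG model)."""
    spec = ToyComplexSpec(receptor_seq="ASAHSASSTASA", ligand_seq="SSAHASAS",
                          fold="extended", interface_pairs=((3, 3),), seed=11)
    return make_toy_complex(spec)


@pytest.fixture(scope="session")
def toy_native(toy_complex):
    return toy_complex[1]


@pytest.fixture(scope="session")
def toy_decoys(toy_native):
    return generate_rigid_decoys(
        toy_native,
        DecoyGenSpec(n_decoys=80, fraction_near_native=0.1, seed=3))


@pytest.fixture(scope="session")
def tiny_pdb():
    """Three-residue single-chain all-atom PDB text."""
    from opepdock.synthetic import _build_chain, _chain_pdb_lines

    rng = np.random.default_rng(0)
    residues = _build_chain("ASG", "extended", rng)
    lines, _ = _chain_pdb_lines(residues, "ASG", "A")
    return "\n".join(lines + ["TER", "END"]) + "\n"
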