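import pytest

from alphaturn import (
    BackboneSpec,
    HBondCriteria,
    SMILES_1A,
    build_backbone,
    derive_role_map,
    load_structure,
    monoisotopic_mass,
)


@pytest.fixture(scope="session")
def graph_1a():
    """The alpha-turn scaffold, validated by formula and exact mass before
    any test trusts it (the structure is reconstructed from a printed name)."""
    g = load_structure(SMILES_1A)
    comp = g.composition()
    assert comp.hill() == "C27H29N5O5"
    assert abs(monoisotopic_mass(comp) - 503.2169) <= 0.0005
    return g


@pytest.fixture(scope="session")
def graph_1a_h(graph_1a):
    return graph_1a.with_all_hydrogens()


@pytest.fixture(scope="session")
def roles_1a(graph_1a_h):
    return derive_role_map(graph_1a_h)


@pytest.fixture(scope="session")
def criteria():
    return HBondCriteria()


@pytest.fixture(scope="session")
def helix():
    """Ideal alpha-helical pentapeptide backbone, (phi, psi) = (-63, -42)."""
    return build_backbone(BackboneSpec([(-63.0, -42.0)] * 5))


@pytest.fixture(scope="session")
def inverse_gamma():
    """Tripeptide with central (phi, psi) = (-75, 65): inverse gamma-turn."""
    return build_backbone(
        BackboneSpec([(180.0, 180.0), (-75.0, 65.0), (180.0, 180.0)])
    )


@pytest.fixture(scope="session")
def extended():
    """Fully extended pentapeptide, all (phi, psi) = (180, 180)."""
    return build_backbone(BackboneSpec([(180.0, 180.0)] * 5))
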