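"""Formula arithmetic, structure loading, H-bond typing, pseudo-ring size."""

import pytest
from hypothesis import given, settings, strategies as st

from alphaturn import (
    ChemError,
    derive_role_map,
    hbond_typing,
    load_structure,
    monoisotopic_mass,
    parse_formula,
    pseudo_ring_size,
)
from alphaturn.chem import ISOTOPE_MASS, Composition, SMILES_1B

# Printed HRMS [M+] calcd values for the six characterised compounds.
HRMS = [
    ("C27H29N5O5", 503.2169),
    ("C22H23N3O4", 393.1689),
    ("C14H19NO4", 265.1314),
    ("C22H23NO6", 397.1525),
    ("C44H44N4O9", 772.3108),
    ("C28H30N4O6", 518.2165),
]


class TestFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C27H29N5O5", {"C": 27, "H": 29, "N": 5, "O": 5}),
            ("H2O", {"H": 2, "O": 1}),
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("ClCH3", {"Cl": 1, "C": 1, "H": 3}),  # Hill order not required
        ],
    )
    def test_parse(self, text, expected):
        assert dict(parse_formula(text)) == expected

    @pytest.mark.parametrize("bad", ["", "  ", "Xx3", "C0H4", "C2(H6)", "c6h6"])
    def test_parse_errors(self, bad):
        with pytest.raises(ChemError):
            parse_formula(bad)

    @given(
        st.dictionaries(
            st.sampled_from(sorted(ISOTOPE_MASS)),
            st.integers(min_value=1, max_value=200),
            min_size=1,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_hill_round_trip(self, counts):
        comp = Composition(counts)
        assert parse_formula(comp.hill()) == comp

    @pytest.mark.parametrize("formula,mass", HRMS)
    def test_hrms_masses(self, formula, mass):
        assert monoisotopic_mass(parse_formula(formula)) == pytest.approx(
            mass, abs=0.0005
        )

    def test_carbon_defines_scale(self):
        assert monoisotopic_mass(parse_formula("C")) == 12.0

    @given(
        st.dictionaries(
            st.sampled_from(sorted(ISOTOPE_MASS)),
            st.integers(min_value=1, max_value=50),
            min_size=1,
        ),
        st.dictionaries(
            st.sampled_from(sorted(ISOTOPE_MASS)),
            st.integers(min_value=1, max_value=50),
            min_size=1,
        ),
    )
    @settings(max_examples=50, deadline=None)
    def test_mass_additivity(self, a, b):
        ca, cb = Composition(a), Composition(b)
        assert monoisotopic_mass(ca + cb) == pytest.approx(
            monoisotopic_mass(ca) + monoisotopic_mass(cb), abs=1e-9
        )


class TestLoadStructure:
    def test_scaffold_validates_by_mass(self, graph_1a):
        # fixture already asserts formula C27H29N5O5 and 503.2169 Da
        assert graph_1a.stereocenters and set(graph_1a.stereocenters.values()) == {"S"}

    def test_epimer_flips_one_center(self, graph_1a):
        gb = load_structure(SMILES_1B)
        labels_a = sorted(graph_1a.stereocenters.values())
        labels_b = sorted(gb.stereocenters.values())
        assert labels_a == ["S", "S", "S"] and labels_b == ["R", "S", "S"]

    def test_ethane_keeps_implicit_h(self):
        g = load_structure("CC")
        assert g.n_atoms == 2
        assert sum(h for _i, _s, _c, h in g.atoms) == 6

    def test_malformed_smiles(self):
        with pytest.raises(ChemError):
            load_structure("C(")

    def test_molblock_round_trip(self, graph_1a):
        block = graph_1a.with_all_hydrogens().to_molblock()
        g2 = load_structure(block)
        assert g2.composition() == graph_1a.composition()
        assert g2.to_smiles() == graph_1a.with_all_hydrogens().to_smiles()
        assert sorted(g2.stereocenters.values()) == ["S", "S", "S"]


class TestHBondTyping:
    def test_scaffold_donors_and_acceptors(self, graph_1a):
        donors, acceptors = hbond_typing(graph_1a)
        mol = graph_1a.mol
        donor_syms = {mol.GetAtomWithIdx(d).GetSymbol() for d, _h in donors}
        # indole N-H, carbamate N-H, methylamide N-H
        assert donor_syms == {"N"} and len(donors) == 3
        # all five oxygens accept; no basic nitrogen in the scaffold
        acc_syms = [mol.GetAtomWithIdx(a).GetSymbol() for a in acceptors]
        assert acc_syms.count("O") == 5 and "N" not in acc_syms

    def test_methane_has_neither(self):
        assert hbond_typing(load_structure("C")) == ([], [])

    def test_formamide(self):
        donors, acceptors = hbond_typing(load_structure("NC=O"))
        assert len(donors) == 2  # two N-H options on one donor nitrogen
        assert len({d for d, _h in donors}) == 1
        assert len(acceptors) == 1

    def test_trimethylamine_nitrogen_accepts(self):
        _d, acceptors = hbond_typing(load_structure("CN(C)C"))
        assert len(acceptors) == 1


class TestPseudoRingSize:
    def test_gamma_and_alpha_rings(self, graph_1a_h, roles_1a):
        assert pseudo_ring_size(graph_1a_h, roles_1a.donor_h, roles_1a.acceptor_o_pos3) == 7
        assert pseudo_ring_size(graph_1a_h, roles_1a.donor_h, roles_1a.acceptor_o_pos1) == 13

    def test_intra_amide_is_four(self):
        g = load_structure("CNC=O")  # N-methylformamide
        donors, _ = hbond_typing(g)
        mol = g.mol
        o = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O")
        _n, h = donors[0]
        assert pseudo_ring_size(g, h, o) == 4

    def test_requires_hydrogen(self, graph_1a_h, roles_1a):
        with pytest.raises(ChemError):
            pseudo_ring_size(graph_1a_h, roles_1a.donor_n, roles_1a.acceptor_o_pos1)

    def test_disconnected_atoms(self):
        g = load_structure("O.O")
        donors, _ = hbond_typing(g)
        (_n0, h0), *_ = [d for d in donors if d[0] == 0]
        other_o = 1
        with pytest.raises(ChemError):
            pseudo_ring_size(g, h0, other_o)


class TestRoleMap:
    def test_derived_roles_are_consistent(self, graph_1a_h, roles_1a):
        mol = graph_1a_h.mol
        assert mol.GetAtomWithIdx(roles_1a.donor_n).GetSymbol() == "N"
        assert mol.GetAtomWithIdx(roles_1a.donor_h).GetAtomicNum() == 1
        assert len(set(roles_1a.calpha_surrogates)) == 5
        # position-1 surrogate is the benzyl (ester) oxygen of the Cbz group
        assert mol.GetAtomWithIdx(roles_1a.calpha_surrogates[0]).GetSymbol() == "O"
        # position-5 surrogate is the methylamide methyl carbon
        cap = mol.GetAtomWithIdx(roles_1a.calpha_surrogates[-1])
        assert cap.GetSymbol() == "C"
        assert cap.GetTotalNumHs(includeNeighbors=True) == 3

    def test_yaml_round_trip(self, roles_1a, tmp_path):
        from alphaturn import RoleMap

        p = tmp_path / "roles.yaml"
        roles_1a.to_yaml(p)
        again = RoleMap.from_yaml(p)
        assert again == roles_1a

    def test_derivation_fails_without_anchor(self):
        with pytest.raises(ChemError):
            derive_role_map(load_structure("CCO"))
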