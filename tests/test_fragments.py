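"""Fragment assembly and combinatorial enumeration of the D-A/D-A-D space."""

import itertools
import math

import pytest
from rdkit import Chem

from photoscreen import fragments as F

PXZ = F.Fragment("PXZ", "donor", "[*:1]N1c2ccccc2Oc2ccccc21")
TH = F.Fragment("TH", "bridge", "[*:1]c1ccc([*:2])s1")
PN = F.Fragment("PN", "acceptor", "[*:1]c1cc(C#N)c(C#N)cc1[*:2]")
DMAC = F.Fragment("DMAC", "donor", "[*:1]N1c2ccccc2C(C)(C)c2ccccc21")

# 4-(5-(phenoxazin-10-yl)thiophen-2-yl)phthalonitrile, transcribed and
# canonicalized independently of the assembler
M1_CANONICAL = Chem.CanonSmiles("N#Cc1ccc(-c2ccc(N3c4ccccc4Oc4ccccc43)s2)cc1C#N")


class TestFragmentInvariants:
    def test_donor_with_two_sites_rejected(self):
        with pytest.raises(F.FragmentError):
            F.Fragment("bad", "donor", "[*:1]c1ccc([*:2])cc1")

    def test_bridge_needs_two_sites(self):
        with pytest.raises(F.FragmentError):
            F.Fragment("bad", "bridge", "[*:1]c1ccccc1")

    def test_unparseable_structure_rejected(self):
        with pytest.raises(F.FragmentError):
            F.Fragment("bad", "donor", "not-a-smiles(((")

    def test_unknown_role_rejected(self):
        with pytest.raises(F.FragmentError):
            F.Fragment("bad", "linker", "[*:1]c1ccccc1")

    def test_sites_inferred_from_markers(self):
        assert TH.sites == (1, 2)
        assert PN.sites == (1, 2)


class TestAssembleDA:
    def test_phenoxazine_thiophene_phthalonitrile_gives_m1(self):
        cand = F.assemble_da(PXZ, TH, PN, 1)
        assert cand.is_valid
        assert cand.topology == "DA"
        assert cand.canonical_structure == M1_CANONICAL

    def test_direct_bond_bridge_gives_biphenyl(self):
        donor = F.Fragment("ph_d", "donor", "[*:1]c1ccccc1")
        bond = F.Fragment("bond", "bridge", "[*:1][*:2]")
        acc = F.Fragment("ph_a", "acceptor", "[*:1]c1ccccc1")
        cand = F.assemble_da(donor, bond, acc, 1)
        assert cand.canonical_structure == Chem.CanonSmiles("c1ccc(-c2ccccc2)cc1")

    def test_role_mismatch_raises(self):
        with pytest.raises(F.FragmentError):
            F.assemble_da(TH, TH, PN, 1)  # bridge in the donor slot

    def test_unknown_acceptor_site_raises(self):
        with pytest.raises(F.FragmentError):
            F.assemble_da(PXZ, TH, PN, 9)

    def test_symmetric_acceptor_sites_give_identical_molecule(self):
        a = F.assemble_da(PXZ, TH, PN, 1)
        b = F.assemble_da(PXZ, TH, PN, 2)
        assert a.canonical_structure == b.canonical_structure


class TestAssembleDAD:
    def test_identical_donors_symmetric(self):
        cand = F.assemble_dad(PXZ, TH, PN, PXZ, (1, 2))
        assert cand.topology == "DAD_symmetric"

    def test_different_donors_asymmetric(self):
        cand = F.assemble_dad(PXZ, TH, PN, DMAC, (1, 2))
        assert cand.topology == "DAD_asymmetric"

    def test_donor_order_irrelevant_on_symmetric_acceptor(self):
        ab = F.assemble_dad(PXZ, TH, PN, DMAC, (1, 2))
        ba = F.assemble_dad(DMAC, TH, PN, PXZ, (1, 2))
        assert ab.canonical_structure == ba.canonical_structure

    def test_single_site_acceptor_rejected(self):
        mono = F.Fragment("mono", "acceptor", "[*:1]c1ccc(C#N)cc1")
        with pytest.raises(F.FragmentError):
            F.assemble_dad(PXZ, TH, mono, PXZ, (1, 2))

    def test_identical_site_indices_rejected(self):
        with pytest.raises(F.FragmentError):
            F.assemble_dad(PXZ, TH, PN, PXZ, (1, 1))


def _brute_force_counts(library):
    """Independent nested-loop oracle for the raw DA/DAD combination counts."""
    da = 0
    for d in library.donors:
        for b in library.bridges:
            for a in library.acceptors:
                for _s in a.sites:
                    da += 1
    dad = 0
    for d1, d2 in itertools.combinations_with_replacement(library.donors, 2):
        for b in library.bridges:
            for a in library.acceptors:
                for _pair in itertools.combinations(a.sites, 2):
                    dad += 1
    return da, dad


def _formula_counts(library):
    D, B, A = library.donors, library.bridges, library.acceptors
    da = len(D) * len(B) * sum(len(a.sites) for a in A)
    dad = (
        len(D) * (len(D) + 1) // 2
        * len(B)
        * sum(math.comb(len(a.sites), 2) for a in A)
    )
    return da, dad


SMALL_LIBRARIES = [
    F.FragmentLibrary([PXZ, TH, PN]),
    F.FragmentLibrary([PXZ, DMAC, TH, PN]),
    F.default_library(),
]


class TestEnumerateSpace:
    def test_two_donor_library_raw_count_is_seven(self):
        lib = F.FragmentLibrary([PXZ, DMAC, TH, PN])
        _, report = F.enumerate_space(lib)
        assert report.raw_da == 4
        assert report.raw_dad == 3
        assert report.raw_total == 7

    @pytest.mark.parametrize("lib", SMALL_LIBRARIES)
    def test_raw_counts_match_formula_and_bruteforce(self, lib):
        _, report = F.enumerate_space(lib)
        assert (report.raw_da, report.raw_dad) == _formula_counts(lib)
        assert (report.raw_da, report.raw_dad) == _brute_force_counts(lib)

    def test_empty_donor_list_warns_and_returns_empty(self):
        lib = F.FragmentLibrary([TH, PN])
        with pytest.warns(UserWarning):
            cands, report = F.enumerate_space(lib)
        assert cands == [] and report.raw_total == 0

    def test_idempotent(self):
        lib = F.FragmentLibrary([PXZ, DMAC, TH, PN])
        first = {c.canonical_structure for c in F.enumerate_space(lib)[0]}
        second = {c.canonical_structure for c in F.enumerate_space(lib)[0]}
        assert first == second

    def test_order_independent(self, rng):
        frags = F.default_library().fragments
        shuffled = list(frags)
        rng.shuffle(shuffled)
        a = {c.canonical_structure for c in F.enumerate_space(F.FragmentLibrary(frags))[0]}
        b = {c.canonical_structure for c in F.enumerate_space(F.FragmentLibrary(shuffled))[0]}
        assert a == b

    def test_all_outputs_reparse(self):
        cands, report = F.enumerate_space(F.default_library())
        assert report.n_unique == len(cands)
        for c in cands:
            mol = Chem.MolFromSmiles(c.canonical_structure)
            assert mol is not None
            assert all(a.GetAtomicNum() > 0 for a in mol.GetAtoms())  # no leftover dummies


class TestLibraryIO:
    def test_tsv_round_trip(self, tmp_path):
        lib = F.default_library()
        path = tmp_path / "frags.tsv"
        lib.to_tsv(path)
        again = F.FragmentLibrary.from_tsv(path)
        assert [(f.id, f.role, f.structure, f.sites) for f in lib.fragments] == [
            (f.id, f.role, f.structure, f.sites) for f in again.fragments
        ]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(F.FragmentError):
            F.FragmentLibrary([PXZ, PXZ])
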