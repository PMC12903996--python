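"""Combinatorial enumeration of donor–bridge–acceptor photosensitizer candidates.

Candidate Type I photosensitizers are assembled from three fragment classes —
electron-rich donors, π-bridges, and electron-deficient acceptors — joined by
single bonds at pre-marked attachment sites.  Two topologies are produced:

* **DA** (donor–bridge–acceptor): one donor arm on one acceptor site.
* **DAD** (donor–bridge–acceptor–bridge–donor): two donor arms, sharing the
  same bridge, on two distinct acceptor sites.  A DAD candidate is *symmetric*
  when both donors are the same fragment.

Attachment sites are encoded as dummy atoms with atom-map numbers in the
fragment SMILES (e.g. ``[*:1]N1c2ccccc2Oc2ccccc21`` is phenoxazine with its
single N-site marked ``1``).  Joining two fragments bonds the neighbours of
the two dummies with a single bond and deletes the dummies, which also makes
a two-dummy "direct bond" bridge (``[*:1][*:2]``) collapse to a plain
single bond between donor and acceptor.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import inchi as _inchi
from rdkit import RDLogger

_RDLOG = RDLogger.logger()

ROLES = ("donor", "bridge", "acceptor")


class FragmentError(ValueError):
    """Raised for malformed fragments or invalid assembly requests."""


@dataclass(frozen=True)
class Fragment:
    """A donor, bridge or acceptor substructure with marked attachment sites.

    Parameters
    ----------
    id : str
        Short unique identifier, e.g. ``"PXZ"``.
    role : str
        One of ``donor``, ``bridge``, ``acceptor``.
    structure : str
        SMILES containing one dummy atom ``[*:n]`` per attachment site.
    sites : tuple of int
        Ordered atom-map numbers of the attachment sites.  Donors declare
        exactly one site, bridges exactly two, acceptors at least one.
    """

    id: str
    role: str
    structure: str
    sites: tuple = ()

    def __post_init__(self):
        if self.role not in ROLES:
            raise FragmentError(f"fragment {self.id!r}: unknown role {self.role!r}")
        mol = Chem.MolFromSmiles(self.structure)
        if mol is None:
            raise FragmentError(f"fragment {self.id!r}: unparseable structure {self.structure!r}")
        found = sorted(
            a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomicNum() == 0 and a.GetAtomMapNum() > 0
        )
        sites = tuple(self.sites) if self.sites else tuple(found)
        object.__setattr__(self, "sites", sites)
        if sorted(sites) != found:
            raise FragmentError(
                f"fragment {self.id!r}: declared sites {sites} do not match markers {found}"
            )
        n = len(sites)
        if self.role == "donor" and n != 1:
            raise FragmentError(f"donor {self.id!r} must declare exactly 1 site, got {n}")
        if self.role == "bridge" and n != 2:
            raise FragmentError(f"bridge {self.id!r} must declare exactly 2 sites, got {n}")
        if self.role == "acceptor" and n < 1:
            raise FragmentError(f"acceptor {self.id!r} must declare at least 1 site")

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.structure)


@dataclass(frozen=True)
class CandidateMolecule:
    """An assembled candidate with canonical structure and provenance."""

    canonical_structure: str
    topology: str  # DA | DAD_symmetric | DAD_asymmetric
    provenance: tuple  # fragment ids and acceptor site(s) used
    is_valid: bool = True

    @property
    def inchi(self) -> str:
        """InChI of the candidate, for strict-mode duplicate comparison."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return _inchi.MolToInchi(Chem.MolFromSmiles(self.canonical_structure))


def _join(smiles_a: str, map_a: int, smiles_b: str, map_b: int) -> str | None:
    """Bond fragment A's site ``map_a`` to fragment B's site ``map_b``.

    Returns the joined SMILES, or None when the product fails sanitization.
    """
    a = Chem.MolFromSmiles(smiles_a)
    b = Chem.MolFromSmiles(smiles_b)
    if a is None or b is None:
        return None
    combo = Chem.RWMol(Chem.CombineMols(a, b))
    n_a = a.GetNumAtoms()

    def _dummy(lo, hi, mapnum):
        for at in combo.GetAtoms():
            if (
                lo <= at.GetIdx() < hi
                and at.GetAtomicNum() == 0
                and at.GetAtomMapNum() == mapnum
            ):
                return at.GetIdx()
        return None

    ia = _dummy(0, n_a, map_a)
    ib = _dummy(n_a, combo.GetNumAtoms(), map_b)
    if ia is None or ib is None:
        raise FragmentError(f"attachment site {map_a if ia is None else map_b} not found")
    nbr_a = combo.GetAtomWithIdx(ia).GetNeighbors()[0].GetIdx()
    nbr_b = combo.GetAtomWithIdx(ib).GetNeighbors()[0].GetIdx()
    combo.AddBond(nbr_a, nbr_b, Chem.BondType.SINGLE)
    for idx in sorted((ia, ib), reverse=True):
        combo.RemoveAtom(idx)
    product = combo.GetMol()
    try:
        _RDLOG.setLevel(RDLogger.CRITICAL)
        Chem.SanitizeMol(product)
    except Exception:
        return None
    finally:
        _RDLOG.setLevel(RDLogger.ERROR)
    return Chem.MolToSmiles(product)


def _finalize(smiles: str) -> str | None:
    """Delete any unused attachment dummies (implicit H caps the valence)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    rw = Chem.RWMol(mol)
    for idx in sorted(
        (a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0), reverse=True
    ):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def _check_roles(donor, bridge, acceptor):
    for frag, want in ((donor, "donor"), (bridge, "bridge"), (acceptor, "acceptor")):
        if frag.role != want:
            raise FragmentError(f"fragment {frag.id!r} has role {frag.role!r}, expected {want!r}")


def assemble_da(
    donor: Fragment, bridge: Fragment, acceptor: Fragment, acceptor_site: int
) -> CandidateMolecule | None:
    """Assemble donor–bridge–acceptor at the given acceptor site.

    The donor's single site bonds to the bridge's first site; the bridge's
    second site bonds to ``acceptor_site``.  Returns None when the product is
    chemically invalid (it is excluded, not raised).
    """
    _check_roles(donor, bridge, acceptor)
    if acceptor_site not in acceptor.sites:
        raise FragmentError(
            f"acceptor {acceptor.id!r} declares sites {acceptor.sites}, not {acceptor_site}"
        )
    arm = _join(donor.structure, donor.sites[0], bridge.structure, bridge.sites[0])
    if arm is None:
        return None
    smi = _join(arm, bridge.sites[1], acceptor.structure, acceptor_site)
    smi = _finalize(smi) if smi is not None else None
    if smi is None:
        return None
    return CandidateMolecule(
        canonical_structure=smi,
        topology="DA",
        provenance=(donor.id, bridge.id, acceptor.id, acceptor_site),
    )


def assemble_dad(
    donor1: Fragment,
    bridge: Fragment,
    acceptor: Fragment,
    donor2: Fragment,
    site_pair: tuple,
) -> CandidateMolecule | None:
    """Assemble donor–bridge–acceptor–bridge–donor on two distinct acceptor sites.

    The same bridge fragment links both donors to the central acceptor.
    Topology is ``DAD_symmetric`` iff the two donor ids are identical.
    """
    _check_roles(donor1, bridge, acceptor)
    if donor2.role != "donor":
        raise FragmentError(f"fragment {donor2.id!r} has role {donor2.role!r}, expected 'donor'")
    s1, s2 = site_pair
    if s1 == s2:
        raise FragmentError("DAD assembly needs two distinct acceptor sites")
    if len(acceptor.sites) < 2:
        raise FragmentError(f"acceptor {acceptor.id!r} has fewer than 2 sites")
    for s in (s1, s2):
        if s not in acceptor.sites:
            raise FragmentError(f"acceptor {acceptor.id!r} does not declare site {s}")
    arm1 = _join(donor1.structure, donor1.sites[0], bridge.structure, bridge.sites[0])
    if arm1 is None:
        return None
    core = _join(arm1, bridge.sites[1], acceptor.structure, s1)
    if core is None:
        return None
    arm2 = _join(donor2.structure, donor2.sites[0], bridge.structure, bridge.sites[0])
    if arm2 is None:
        return None
    smi = _join(arm2, bridge.sites[1], core, s2)
    smi = _finalize(smi) if smi is not None else None
    if smi is None:
        return None
    topology = "DAD_symmetric" if donor1.id == donor2.id else "DAD_asymmetric"
    return CandidateMolecule(
        canonical_structure=smi,
        topology=topology,
        provenance=(donor1.id, bridge.id, acceptor.id, donor2.id, s1, s2),
    )


@dataclass
class EnumerationReport:
    """Raw / valid / unique bookkeeping for one enumeration run."""

    raw_da: int = 0
    raw_dad: int = 0
    n_invalid: int = 0
    n_unique: int = 0

    @property
    def raw_total(self) -> int:
        return self.raw_da + self.raw_dad

    @property
    def n_valid(self) -> int:
        return self.raw_total - self.n_invalid


class FragmentLibrary:
    """An ordered collection of donor / bridge / acceptor fragments."""

    def __init__(self, fragments: Iterable[Fragment]):
        self.fragments = list(fragments)
        ids = [f.id for f in self.fragments]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FragmentError(f"duplicate fragment ids: {dupes}")

    def by_role(self, role: str) -> list:
        return [f for f in self.fragments if f.role == role]

    @property
    def donors(self):
        return self.by_role("donor")

    @property
    def bridges(self):
        return self.by_role("bridge")

    @property
    def acceptors(self):
        return self.by_role("acceptor")

    @classmethod
    def from_tsv(cls, path) -> "FragmentLibrary":
        """Load a tab-separated fragment table: id, role, structure, sites.

        ``sites`` is a comma-separated list of map numbers; it may be left
        blank to take the markers found in the structure, in order.
        """
        frags = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "id" and lineno == 1:
                    continue
                if len(parts) < 3:
                    raise FragmentError(f"line {lineno}: expected id<TAB>role<TAB>structure[<TAB>sites]")
                fid, role, structure = parts[0], parts[1], parts[2]
                sites = ()
                if len(parts) > 3 and parts[3].strip():
                    sites = tuple(int(s) for s in parts[3].split(","))
                frags.append(Fragment(fid, role, structure, sites))
        return cls(frags)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\trole\tstructure\tsites\n")
            for f in self.fragments:
                fh.write(f"{f.id}\t{f.role}\t{f.structure}\t{','.join(map(str, f.sites))}\n")


def default_library() -> FragmentLibrary:
    """A small built-in donor/bridge/acceptor library of common D–A dye motifs.

    Donors: phenoxazine, phenothiazine, 9,9-dimethyl-9,10-dihydroacridine,
    diphenylamine, carbazole.  Bridges: thiophene, 1,4-phenylene, direct
    bond.  Acceptors: phthalonitrile (two sites), benzothiadiazole (two
    sites), benzonitrile.
    """
    return FragmentLibrary(
        [
            Fragment("PXZ", "donor", "[*:1]N1c2ccccc2Oc2ccccc21"),
            Fragment("PTZ", "donor", "[*:1]N1c2ccccc2Sc2ccccc21"),
            Fragment("DMAC", "donor", "[*:1]N1c2ccccc2C(C)(C)c2ccccc21"),
            Fragment("DPA", "donor", "[*:1]N(c1ccccc1)c1ccccc1"),
            Fragment("CZ", "donor", "[*:1]n1c2ccccc2c2ccccc21"),
            Fragment("TH", "bridge", "[*:1]c1ccc([*:2])s1"),
            Fragment("PH", "bridge", "[*:1]c1ccc([*:2])cc1"),
            Fragment("BOND", "bridge", "[*:1][*:2]"),
            Fragment("PN", "acceptor", "[*:1]c1cc(C#N)c(C#N)cc1[*:2]"),
            Fragment("BTD", "acceptor", "[*:1]c1ccc([*:2])c2nsnc12"),
            Fragment("BCN", "acceptor", "[*:1]c1ccc(C#N)cc1"),
        ]
    )


def enumerate_space(
    library: FragmentLibrary,
    da_site_mode: str = "all",
    strict_inchi: bool = False,
) -> tuple[list, EnumerationReport]:
    """Enumerate every DA and DAD combination from the library.

    DA candidates cover every donor × bridge × acceptor × acceptor-site
    (``da_site_mode="first"`` restricts to each acceptor's first declared
    site); DAD candidates cover every unordered donor pair (with repetition)
    × bridge × acceptor × unordered site pair.  Chemically invalid products
    are dropped and canonical duplicates collapsed (by canonical SMILES, or
    by InChI when ``strict_inchi``).

    Returns
    -------
    (candidates, report)
        Unique valid candidates in deterministic (sorted) order, plus the
        raw / valid / unique counts.
    """
    donors = sorted(library.donors, key=lambda f: f.id)
    bridges = sorted(library.bridges, key=lambda f: f.id)
    acceptors = sorted(library.acceptors, key=lambda f: f.id)
    report = EnumerationReport()
    if not donors or not bridges or not acceptors:
        warnings.warn("empty fragment role class: enumeration produces no candidates")
        return [], report

    seen: dict[str, CandidateMolecule] = {}

    def _keep(cand):
        if cand is None:
            report.n_invalid += 1
            return
        key = cand.inchi if strict_inchi else cand.canonical_structure
        if key not in seen:
            seen[key] = cand

    for d, b, a in itertools.product(donors, bridges, acceptors):
        sites = a.sites if da_site_mode == "all" else a.sites[:1]
        for s in sites:
            report.raw_da += 1
            _keep(assemble_da(d, b, a, s))

    for (d1, d2) in itertools.combinations_with_replacement(donors, 2):
        for b, a in itertools.product(bridges, acceptors):
            for s1, s2 in itertools.combinations(a.sites, 2):
                report.raw_dad += 1
                _keep(assemble_dad(d1, b, a, d2, (s1, s2)))

    candidates = sorted(seen.values(), key=lambda c: c.canonical_structure)
    report.n_unique = len(candidates)
    return candidates, report


def write_candidates(candidates: Sequence[CandidateMolecule], smiles_path, provenance_path) -> None:
    """Write one-SMILES-per-line output plus a tabular provenance file."""
    with open(smiles_path, "w") as fh:
        for i, c in enumerate(candidates):
            fh.write(f"{c.canonical_structure}\tcand{i:05d}\n")
    with open(provenance_path, "w") as fh:
        fh.write("id\tsmiles\ttopology\tprovenance\n")
        for i, c in enumerate(candidates):
            prov = ",".join(str(p) for p in c.provenance)
            fh.write(f"cand{i:05d}\t{c.canonical_structure}\t{c.topology}\t{prov}\n")
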