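"""Excited-state energy descriptors for photosensitizer classification.

Each molecule is represented by the energies of its 15 lowest singlet
(S1..S15) and 15 lowest triplet (T1..T15) excited states, in eV relative to
the ground state S0 = 0, plus the aromatic ring count (AR).  The fixed
31-feature order is S1..S15, T1..T15, AR.

Two gap statistics drive the screening rules:

* ``gap_s1_tn`` — the smallest |S1 − Tn| over all 15 triplets, with the
  index n of that closest triplet (lowest n wins on ties).  A small gap
  (< 0.3 eV) favours intersystem crossing.
* ``gap_t1_s0`` — the T1 energy itself, compared to the singlet-oxygen
  formation thresholds 0.98 and 1.63 eV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

N_STATES = 15
SINGLET_COLS = [f"S{i}" for i in range(1, N_STATES + 1)]
TRIPLET_COLS = [f"T{i}" for i in range(1, N_STATES + 1)]
FEATURE_NAMES = SINGLET_COLS + TRIPLET_COLS + ["AR"]
N_FEATURES = len(FEATURE_NAMES)  # 31


class ProfileError(ValueError):
    """Raised for malformed excited-state tables or profiles."""


@dataclass(frozen=True)
class ExcitedStateProfile:
    """Excited-state energies (eV, relative to S0 = 0) plus aromatic ring count."""

    molecule_id: str
    singlet_energies: tuple
    triplet_energies: tuple
    aromatic_ring_count: int

    def __post_init__(self):
        s = tuple(float(x) for x in self.singlet_energies)
        t = tuple(float(x) for x in self.triplet_energies)
        object.__setattr__(self, "singlet_energies", s)
        object.__setattr__(self, "triplet_energies", t)
        for name, manifold in (("singlet", s), ("triplet", t)):
            if len(manifold) != N_STATES:
                raise ProfileError(
                    f"{self.molecule_id}: {name} manifold has {len(manifold)} states, expected {N_STATES}"
                )
            if any(e <= 0 for e in manifold):
                raise ProfileError(f"{self.molecule_id}: non-positive {name} energy")
            if any(b < a for a, b in zip(manifold, manifold[1:])):
                raise ProfileError(f"{self.molecule_id}: {name} manifold not non-decreasing")
        if self.aromatic_ring_count < 0 or int(self.aromatic_ring_count) != self.aromatic_ring_count:
            raise ProfileError(f"{self.molecule_id}: aromatic_ring_count must be a non-negative integer")


def build_descriptor(profile: ExcitedStateProfile) -> np.ndarray:
    """Concatenate S1..S15, T1..T15, AR into the fixed 31-vector."""
    return np.asarray(
        list(profile.singlet_energies) + list(profile.triplet_energies) + [profile.aromatic_ring_count],
        dtype=float,
    )


def gap_s1_tn(profile: ExcitedStateProfile) -> tuple[float, int]:
    """Energy gap between S1 and its closest triplet state.

    Returns (min |S1 − Tn|, n); the lowest triplet index wins on ties.
    """
    s1 = profile.singlet_energies[0]
    gaps = [abs(s1 - t) for t in profile.triplet_energies]
    best = min(range(N_STATES), key=lambda i: (gaps[i], i))
    return gaps[best], best + 1


def gap_t1_s0(profile: ExcitedStateProfile) -> float:
    """T1 energy relative to the ground state (energies are referenced to S0 = 0)."""
    return profile.triplet_energies[0]


def aromatic_ring_count(structure: str) -> int:
    """Number of aromatic rings in the smallest set of smallest rings.

    Fused aromatics count each ring: naphthalene → 2, carbazole → 3.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ProfileError(f"unparseable structure: {structure!r}")
    ri = mol.GetRingInfo()
    count = 0
    for ring in ri.BondRings():
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring):
            count += 1
    return count


def parse_state_table(path_or_buf) -> list[ExcitedStateProfile]:
    """Parse a comma-separated excited-state table into profiles.

    Expected header: ``id,S1..S15,T1..T15,AR``.  Rows violating the profile
    invariants are rejected with a diagnostic naming the offending row;
    missing columns or duplicate ids are hard errors.
    """
    df = pd.read_csv(path_or_buf)
    missing = [c for c in ["id"] + FEATURE_NAMES if c not in df.columns]
    if missing:
        raise ProfileError(f"state table missing columns: {missing}")
    dupes = df["id"][df["id"].duplicated()].unique().tolist()
    if dupes:
        raise ProfileError(f"duplicated molecule ids: {dupes}")
    profiles = []
    errors = []
    for idx, row in df.iterrows():
        try:
            vals = row[FEATURE_NAMES].astype(float)
        except (TypeError, ValueError) as exc:
            raise ProfileError(f"row {idx} ({row['id']}): non-numeric energy: {exc}") from exc
        try:
            profiles.append(
                ExcitedStateProfile(
                    molecule_id=str(row["id"]),
                    singlet_energies=tuple(vals[SINGLET_COLS]),
                    triplet_energies=tuple(vals[TRIPLET_COLS]),
                    aromatic_ring_count=int(vals["AR"]),
                )
            )
        except ProfileError as exc:
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise ProfileError("rejected rows:\n" + "\n".join(errors))
    return profiles


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Tabulate profiles as a DataFrame with columns id, S1..S15, T1..T15, AR."""
    rows = [
        {"id": p.molecule_id, **dict(zip(FEATURE_NAMES, build_descriptor(p)))}
        for p in profiles
    ]
    return pd.DataFrame(rows, columns=["id"] + FEATURE_NAMES)


def write_state_table(profiles, path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False)
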