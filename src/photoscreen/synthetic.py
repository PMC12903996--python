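"""Synthetic fixtures: labeled excited-state profiles and candidate tables.

No public excited-state dataset ships with the pipeline (the energies come
from quantum-chemistry calculations upstream), so this module generates
synthetic data with the statistical structure the pipeline assumes:

* **Training fixture** — profiles labeled by the planted, axis-aligned
  Type I rule: label 1 iff min_n |S1 − Tn| < 0.3 eV *and* T1 > 1.63 eV.
  The default composition matches the curated training set the models
  target: 77 records with 31 (40.3%) Type I.  Type I records are drawn
  with lower S1 and near-degenerate S1/T1; non-Type I records either sit
  at low T1 or keep every triplet well away from S1, giving the
  attribution analyses a decreasing trend in S1 and Type I density at
  intermediate T1.
* **Candidate fixture** — valid structures from the built-in fragment
  library paired with synthetic state tables in which documented fractions
  pass the two energy-gap funnel stages by construction.

Energies are in eV with manifold gaps between successive states drawn from
[0.05, 0.4] eV, plausible for donor–acceptor dyes; all of it is synthetic
and emulates no specific real spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import descriptors as D
from . import fragments as F


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class LabeledRecord:
    """An excited-state profile with its binary Type I label (1 = Type I)."""

    profile: D.ExcitedStateProfile
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise FixtureError(f"label must be 0 or 1, got {self.label}")

    @property
    def descriptor(self) -> np.ndarray:
        return D.build_descriptor(self.profile)


@dataclass
class FixtureSpec:
    """Parameters of the synthetic training fixture.

    The defaults reproduce the target composition (77 records, 31 Type I =
    40.3%) and the planted label rule: Type I iff min_n |S1−Tn| <
    ``gap_threshold`` and T1 > ``t1_floor``.
    """

    n_records: int = 77
    n_type1: int = 31
    seed: int = 0
    s1_range_type1: tuple = (2.0, 2.6)
    s1_range_other: tuple = (2.0, 3.5)
    inter_state_gap: tuple = (0.05, 0.4)
    gap_threshold: float = 0.3
    t1_floor: float = 1.63
    label_noise: float = 0.0  # probability of flipping a label; default off

    def __post_init__(self):
        if not 0 <= self.n_type1 <= self.n_records:
            raise FixtureError("need 0 <= n_type1 <= n_records")
        for lo, hi in (self.s1_range_type1, self.s1_range_other, self.inter_state_gap):
            if hi < lo:
                raise FixtureError("ranges must be ordered (lo <= hi)")


def _ladder(rng, start: float, spec: FixtureSpec, n: int = D.N_STATES) -> list:
    lo, hi = spec.inter_state_gap
    vals = [start]
    for _ in range(n - 1):
        vals.append(vals[-1] + rng.uniform(lo, hi))
    return vals


def _type1_profile(rng, spec: FixtureSpec):
    # near-degenerate S1/T1 with T1 safely above the floor
    s1 = rng.uniform(*spec.s1_range_type1)
    t1 = s1 - rng.uniform(0.02, 0.2)
    while t1 <= spec.t1_floor + 0.1:
        s1 = rng.uniform(max(spec.t1_floor + 0.25, spec.s1_range_type1[0]), spec.s1_range_type1[1])
        t1 = s1 - rng.uniform(0.02, 0.2)
    return _ladder(rng, s1, spec), _ladder(rng, t1, spec)

def _low_t1_profile(rng, spec: FixtureSpec):
    # fails the T1 floor regardless of the gap; S1 sits well above T1 so the
    # S1-T1 separation also exceeds the Type I construction margin
    s1 = rng.uniform(*spec.s1_range_other)
    t1 = rng.uniform(0.8, spec.t1_floor - 0.23)
    return _ladder(rng, s1, spec), _ladder(rng, t1, spec)


def _wide_gap_profile(rng, spec: FixtureSpec):
    # T1 above the floor but every triplet kept >= 0.45 eV away from S1
    margin = spec.gap_threshold + 0.15
    s1 = rng.uniform(2.4, spec.s1_range_other[1])
    t1 = rng.uniform(spec.t1_floor + 0.05, s1 - margin)
    lo, hi = spec.inter_state_gap
    triplets = [t1]
    for _ in range(D.N_STATES - 1):
        nxt = triplets[-1] + rng.uniform(lo, hi)
        if abs(nxt - s1) < margin:
            nxt = s1 + margin + rng.uniform(0.0, hi)
        triplets.append(nxt)
    return _ladder(rng, s1, spec), triplets


def _rule_label(profile: D.ExcitedStateProfile, spec: FixtureSpec) -> int:
    gap, _ = D.gap_s1_tn(profile)
    return int(gap < spec.gap_threshold and D.gap_t1_s0(profile) > spec.t1_floor)


def generate_training_fixture(spec: FixtureSpec | None = None) -> list:
    """Generate the labeled training fixture under the planted Type I rule.

    Every record's planted label is re-derived from the rule after
    construction (construction failing the rule is a bug, not noise);
    optional ``label_noise`` then flips labels independently.  Record order
    is shuffled so class blocks do not leak into unshuffled splits.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_type1):
        s, t = _type1_profile(rng, spec)
        prof = D.ExcitedStateProfile(f"fix{i:03d}", tuple(s), tuple(t), int(rng.integers(2, 9)))
        if _rule_label(prof, spec) != 1:
            raise FixtureError("constructed Type I record violates the planted rule")
        records.append(LabeledRecord(prof, 1))
    for i in range(spec.n_type1, spec.n_records):
        maker = _low_t1_profile if rng.random() < 0.5 else _wide_gap_profile
        s, t = maker(rng, spec)
        prof = D.ExcitedStateProfile(f"fix{i:03d}", tuple(s), tuple(t), int(rng.integers(2, 9)))
        if _rule_label(prof, spec) != 0:
            raise FixtureError("constructed non-Type I record violates the planted rule")
        records.append(LabeledRecord(prof, 0))
    if spec.label_noise > 0:
        records = [
            LabeledRecord(r.profile, 1 - r.label) if rng.random() < spec.label_noise else r
            for r in records
        ]
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def records_to_xy(records) -> tuple[np.ndarray, np.ndarray]:
    """Stack labeled records into a design matrix and label vector."""
    X = np.vstack([r.descriptor for r in records])
    y = np.array([r.label for r in records], dtype=int)
    return X, y


#: Fractions of candidate-fixture records constructed to pass each energy stage.
CANDIDATE_PASS_FRACTIONS = {"gap_s1_tn": 0.6, "gap_t1_s0": 0.7}


def generate_candidate_fixture(n: int, seed: int = 0):
    """n candidate structures from the built-in library plus synthetic states.

    Structures come from the deduplicated enumeration of the default
    fragment library (so they are unique and chemically valid); each is
    paired with a synthetic excited-state profile constructed so that a
    fraction ``CANDIDATE_PASS_FRACTIONS["gap_s1_tn"]`` has
    min|S1−Tn| < 0.3 eV and ``CANDIDATE_PASS_FRACTIONS["gap_t1_s0"]`` has
    T1 > 1.63 eV, independently.

    Returns ``(smiles_list, profiles)`` of equal length n.
    """
    if n < 1:
        raise FixtureError("n must be at least 1")
    candidates, _ = F.enumerate_space(F.default_library())
    if n > len(candidates):
        raise FixtureError(
            f"built-in library yields only {len(candidates)} unique candidates, requested {n}"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(candidates), size=n, replace=False)
    smiles = [candidates[i].canonical_structure for i in pick]
    spec = FixtureSpec()
    profiles = []
    for i in range(n):
        high_t1 = rng.random() < CANDIDATE_PASS_FRACTIONS["gap_t1_s0"]
        small_gap = rng.random() < CANDIDATE_PASS_FRACTIONS["gap_s1_tn"]
        t1 = rng.uniform(1.7, 2.4) if high_t1 else rng.uniform(0.9, 1.55)
        lo, hi = spec.inter_state_gap
        if small_gap:
            triplets = [t1]
            for _ in range(D.N_STATES - 1):
                triplets.append(triplets[-1] + rng.uniform(lo, hi))
            j = int(rng.integers(0, 5))
            s1 = triplets[j] + rng.uniform(0.01, 0.24)
        else:
            # widen one triplet spacing and park S1 mid-gap, >= 0.4 eV away
            j = int(rng.integers(0, 5))
            triplets = [t1]
            for k in range(D.N_STATES - 1):
                step = 0.85 if k == j else rng.uniform(lo, hi)
                triplets.append(triplets[-1] + step)
            s1 = triplets[j] + 0.42
        singlets = [s1]
        for _ in range(D.N_STATES - 1):
            singlets.append(singlets[-1] + rng.uniform(lo, hi))
        ar = D.aromatic_ring_count(smiles[i])
        prof = D.ExcitedStateProfile(f"cand{i:05d}", tuple(singlets), tuple(triplets), ar)
        gap, _idx = D.gap_s1_tn(prof)
        assert (gap < spec.gap_threshold) == small_gap, "planted gap class violated"
        profiles.append(prof)
    return smiles, profiles


def two_family_fixture(n_per_family: int = 30) -> tuple[list, list]:
    """Two structurally disjoint molecule families for embedding tests.

    Family 0: para-linked oligophenylenes of 2–7 rings with a halogen or
    methyl on the terminal ring (homologous, mutually similar aromatics).
    Family 1: linear alkanes C5–C34.  The families share essentially no
    circular substructures, so a faithful 2-D chemical-space embedding
    separates them into two clusters.

    Returns ``(smiles, family_labels)``.
    """

    def oligophenylene(k: int, sub: str = "") -> str:
        head = "".join(f"c{i}ccc(-" for i in range(1, k))
        tail = f"c{k}ccccc{k}" + "".join(f")cc{i}" for i in range(k - 1, 0, -1))
        return sub + head + tail

    fam_a = []
    for sub in ("", "F", "Cl", "Br", "C"):
        for k in range(2, 8):
            fam_a.append(oligophenylene(k, sub))
    fam_a = fam_a[:n_per_family]
    if len(fam_a) < n_per_family:
        raise FixtureError("aromatic family supports at most 30 members")
    fam_b = ["C" * n for n in range(5, 5 + n_per_family)]
    return fam_a + fam_b, [0] * len(fam_a) + [1] * len(fam_b)


def perturb_energies(records, sd: float, seed: int = 0) -> list:
    """Gaussian jitter of all 30 energies, re-sorted to restore ordering.

    Supports minority-class oversampling augmentation; ``sd=0`` is the
    identity.  Labels, ids and ring counts are untouched.
    """
    if sd < 0:
        raise FixtureError("jitter SD must be non-negative")
    if sd == 0:
        return list(records)
    rng = np.random.default_rng(seed)
    out = []
    for r in records:
        s = np.sort(np.asarray(r.profile.singlet_energies) + rng.normal(0, sd, D.N_STATES))
        t = np.sort(np.asarray(r.profile.triplet_energies) + rng.normal(0, sd, D.N_STATES))
        s = np.clip(s, 1e-6, None)
        t = np.clip(t, 1e-6, None)
        prof = D.ExcitedStateProfile(
            r.profile.molecule_id, tuple(np.sort(s)), tuple(np.sort(t)), r.profile.aromatic_ring_count
        )
        out.append(LabeledRecord(prof, r.label))
    return out
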