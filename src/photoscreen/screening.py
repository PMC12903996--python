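"""Staged screening funnel for Type I photosensitizer candidates.

Every candidate is scored on four criteria and must clear each active stage
(the flags are conjunctive, so the survivor set does not depend on stage
order):

1. Type I probability from the trained classifier (default cutoff ≥ 0.5).
2. Structural novelty = 1 − max Tanimoto similarity to the known Type I
   reference set (report-only by default; optional cutoff).
3. Synthetic accessibility: fragment-based Bayesian score, pass iff > 0.
4. Small ΔE(S1−Tn): pass iff strictly < 0.3 eV.
5. Large ΔE(T1−S0): pass iff strictly > 1.63 eV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .embedding import tanimoto

#: Default stage thresholds; novelty None means report-only (no filtering).
DEFAULT_THRESHOLDS = {
    "probability": 0.5,
    "novelty": None,
    "sa": 0.0,
    "gap_s1_tn": 0.3,
    "gap_t1_s0": 1.63,
}

STAGE_ORDER = ("probability", "novelty", "sa", "gap_s1_tn", "gap_t1_s0")


class ScreeningError(ValueError):
    pass


@dataclass
class ScreeningRecord:
    """One candidate's metrics and per-stage pass flags."""

    candidate_id: str
    type1_probability: float
    novelty: float
    sa_score: float
    gap_s1_tn: float
    gap_t1_s0: float
    flags: dict = field(default_factory=dict)

    def metric(self, stage: str) -> float:
        return {
            "probability": self.type1_probability,
            "novelty": self.novelty,
            "sa": self.sa_score,
            "gap_s1_tn": self.gap_s1_tn,
            "gap_t1_s0": self.gap_t1_s0,
        }[stage]


@dataclass
class FunnelSummary:
    """Per-stage input/output counts and the thresholds actually applied."""

    stages: list
    input_counts: list
    output_counts: list
    thresholds: dict

    def as_dict(self) -> dict:
        return {
            "stages": self.stages,
            "input_counts": self.input_counts,
            "output_counts": self.output_counts,
            "thresholds": {k: v for k, v in self.thresholds.items()},
        }


def novelty_score(candidate_fp, reference_fps) -> float:
    """1 − max Tanimoto similarity of the candidate to the reference set.

    0 means the candidate is (by fingerprint) already in the references;
    1 means it shares no set bits with any of them.  Adding references can
    only lower the score.
    """
    refs = list(reference_fps)
    if not refs:
        raise ScreeningError("novelty needs a non-empty reference set")
    return 1.0 - max(tanimoto(candidate_fp, r) for r in refs)


def _count_fragments(smiles: str, radius: int = 2) -> dict:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ScreeningError(f"unparseable candidate: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    return gen.GetSparseCountFingerprint(mol).GetNonzeroElements()


def sa_score(smiles: str, fragment_table: dict | None = None, radius: int = 2) -> float:
    """Fragment-based Bayesian synthetic-accessibility score.

    The candidate's circular-fragment identifiers (Morgan environments up to
    ``radius``) are looked up in a table of per-fragment log-likelihood
    ratios (easy vs. hard to synthesize); the score is the multiplicity-
    weighted sum, positive ⇒ easy.  Identifiers absent from the table
    contribute 0; an empty table gives 0.  A table from the published SYBA
    scorer can be plugged in; the bundled table (:func:`toy_fragment_table`)
    is a small synthetic stand-in trained on a handful of molecules.
    """
    counts = _count_fragments(smiles, radius=radius)
    if not fragment_table:
        return 0.0
    return float(sum(n * fragment_table.get(frag, 0.0) for frag, n in counts.items()))


# Tiny synthetic training lists for the bundled toy score: commodity aromatics
# and simple heterocycles vs. strained / caged / cumulated systems.
_EASY_SMILES = (
    "c1ccccc1", "c1ccsc1", "c1ccncc1", "c1ccc2ccccc2c1", "c1ccc(-c2ccccc2)cc1",
    "N#Cc1ccccc1C#N", "c1ccc(N(c2ccccc2)c2ccccc2)cc1", "Cc1ccccc1", "COc1ccccc1",
    "c1ccc2[nH]ccc2c1", "O=C(O)c1ccccc1", "c1ccc2c(c1)oc1ccccc12",
)
_HARD_SMILES = (
    "C1CC2CC1C1CC2C1", "C1C2CC3CC1CC(C2)C3", "C1=C=C1", "C1CC11CC1",
    "B1C2CC3CC1CC(C2)C3", "C12C3C4C1C5C2C3C45", "C1CC2(C1)CC1(CC2)CC1",
)


def toy_fragment_table(radius: int = 2, pseudocount: float = 1.0) -> dict:
    """Build the bundled toy fragment log-likelihood-ratio table.

    Synthetic stand-in for a published synthetic-accessibility fragment
    table: per-fragment ``log((n_easy + pc) / (n_hard + pc))`` counted over
    the small built-in easy / hard molecule lists.
    """
    easy: dict = {}
    hard: dict = {}
    for smi in _EASY_SMILES:
        for f, n in _count_fragments(smi, radius).items():
            easy[f] = easy.get(f, 0) + n
    for smi in _HARD_SMILES:
        for f, n in _count_fragments(smi, radius).items():
            hard[f] = hard.get(f, 0) + n
    table = {}
    for f in set(easy) | set(hard):
        table[f] = float(
            np.log((easy.get(f, 0) + pseudocount) / (hard.get(f, 0) + pseudocount))
        )
    return table


def _passes(stage: str, value: float, threshold) -> bool:
    if threshold is None:
        return True
    if stage == "probability":
        return value >= threshold
    if stage == "novelty":
        return value >= threshold
    if stage == "sa":
        return value > threshold  # strictly positive ⇒ easy
    if stage == "gap_s1_tn":
        return value < threshold  # strictly below 0.3 eV
    if stage == "gap_t1_s0":
        return value > threshold  # strictly above 1.63 eV
    raise ScreeningError(f"unknown stage {stage!r}")


def apply_funnel(records, thresholds: dict | None = None, stage_order=STAGE_ORDER):
    """Run the conjunctive staged filter over screening records.

    Each record's flags are evaluated against every active stage; survivors
    pass all of them.  The summary reports counts per stage in the given
    order (the survivor set itself is order-independent).
    """
    th = dict(DEFAULT_THRESHOLDS)
    th.update(thresholds or {})
    missing = [s for s in stage_order if s not in th]
    if missing:
        raise ScreeningError(f"no threshold given for stages: {missing}")
    flagged = []
    for r in records:
        flags = {s: _passes(s, r.metric(s), th[s]) for s in stage_order}
        flagged.append(replace(r, flags=flags))
    input_counts, output_counts = [], []
    current = flagged
    for s in stage_order:
        input_counts.append(len(current))
        current = [r for r in current if r.flags[s]]
        output_counts.append(len(current))
    summary = FunnelSummary(
        stages=list(stage_order),
        input_counts=input_counts,
        output_counts=output_counts,
        thresholds=th,
    )
    return current, summary


def select_candidates(survivors, k: int):
    """Top-k survivors by Type I probability, ties broken by higher novelty."""
    if k < 1:
        raise ScreeningError("k must be at least 1")
    ranked = sorted(survivors, key=lambda r: (-r.type1_probability, -r.novelty, r.candidate_id))
    if k > len(ranked):
        import warnings

        warnings.warn(f"requested {k} candidates but only {len(ranked)} survive")
    return ranked[:k]
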