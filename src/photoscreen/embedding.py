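"""Fingerprints, Tanimoto similarity and 2-D chemical-space embedding.

Molecules are hashed to 2048-bit extended-connectivity fingerprints (ECFP,
Morgan radius 2, RDKit dialect) and projected to two dimensions with UMAP
(neighbourhood size 15, minimum distance 0.5) for the Type I / non-Type I
landscape view.
"""

from __future__ import annotations

import warnings

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

N_BITS = 2048
RADIUS = 2

_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=RADIUS, fpSize=N_BITS)


class EmbeddingError(ValueError):
    pass


def fingerprint(structure: str) -> np.ndarray:
    """2048-bit ECFP (radius 2) as a uint8 0/1 vector.

    Deterministic for a given canonical structure; equivalent SMILES
    notations of the same molecule hash identically.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise EmbeddingError(f"unparseable structure: {structure!r}")
    bv = _GEN.GetFingerprint(mol)
    arr = np.zeros(N_BITS, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a ∧ b| / |a ∨ b| on binary vectors; defined as 1 when both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise EmbeddingError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def umap_project(
    fingerprints: np.ndarray,
    n_neighbors: int = 15,
    min_dist: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """UMAP projection of fingerprints to n×2 coordinates.

    Reproducible under a fixed seed (single-threaded exact mode).  When n is
    too small for the requested neighbourhood, ``n_neighbors`` is shrunk to
    n − 1 with a warning.
    """
    import umap  # deferred: heavy import

    X = np.asarray(fingerprints, dtype=float)
    n = X.shape[0]
    if n <= n_neighbors:
        warnings.warn(f"n_neighbors shrunk from {n_neighbors} to {n - 1} for n={n}")
        n_neighbors = max(2, n - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=seed,
            n_jobs=1,
            metric="jaccard",
        )
        coords = reducer.fit_transform(X)
    return np.asarray(coords, dtype=float)
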