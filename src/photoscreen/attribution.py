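"""Shapley additive attributions for descriptor-based classifiers.

Each prediction f(x) is decomposed as ``base_value + Σ_i φ_i`` where φ_i is
the Shapley value of feature i under the interventional value function

    v(S) = E_z~background [ f(x_S, z_{S̄}) ],

i.e. features outside the coalition S are replaced by background-sample
values and the model's outputs averaged.  The Shapley value weights each
coalition S ⊆ N\\{i} by ``|S|! (d − |S| − 1)! / d!`` and sums the marginal
contributions ``v(S ∪ {i}) − v(S)``.

Two modes are provided:

* ``exact`` — enumerates all 2^d coalitions.  Feasible for small d and used
  as the in-package oracle; refused above 15 features.
* ``sampled`` — averages marginal contributions over random feature
  permutations (seed-controlled).  Because each permutation's contributions
  telescope to ``v(N) − v(∅)``, additivity holds exactly at any sample size;
  only the per-feature split is approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class AttributionError(ValueError):
    pass


@dataclass
class AttributionSet:
    """Per-record, per-feature Shapley values with the shared base value."""

    values: np.ndarray  # (n_records, n_features)
    base_value: float
    feature_names: list

    def additivity_residual(self, predictions: np.ndarray) -> np.ndarray:
        """|base + Σφ − f(x)| per record; ~0 when additivity holds."""
        return np.abs(self.base_value + self.values.sum(axis=1) - np.asarray(predictions))


def _value_function(predict, x, background, mask):
    """v(S): mean prediction with masked-out features drawn from the background."""
    synth = np.array(background, dtype=float, copy=True)
    synth[:, mask] = x[mask]
    return float(np.mean(predict(synth)))


def _exact_single(predict, x, background, d):
    # One model call per coalition, vectorised over the background sample.
    values = {}
    for code in range(2 ** d):
        mask = np.array([(code >> j) & 1 for j in range(d)], dtype=bool)
        values[code] = _value_function(predict, x, background, mask)
    phi = np.zeros(d)
    fact = [math.factorial(k) for k in range(d + 1)]
    for i in range(d):
        for code in range(2 ** d):
            if (code >> i) & 1:
                continue
            s = bin(code).count("1")
            w = fact[s] * fact[d - s - 1] / fact[d]
            phi[i] += w * (values[code | (1 << i)] - values[code])
    return phi, values[0]


def _sampled_single(predict, x, background, d, n_permutations, rng):
    # antithetic pairs: every drawn permutation is followed by its reverse,
    # which cancels much of the variance from pairwise interactions
    phi = np.zeros(d)
    base = _value_function(predict, x, background, np.zeros(d, dtype=bool))
    order = None
    for k in range(n_permutations):
        order = rng.permutation(d) if k % 2 == 0 else order[::-1]
        mask = np.zeros(d, dtype=bool)
        prev = base
        for i in order:
            mask[i] = True
            cur = _value_function(predict, x, background, mask)
            phi[i] += cur - prev
            prev = cur
    return phi / n_permutations, base


def shapley_attributions(
    model,
    background: np.ndarray,
    queries: np.ndarray,
    mode: str = "sampled",
    n_permutations: int = 50,
    seed: int = 0,
    predict=None,
    feature_names=None,
) -> AttributionSet:
    """Shapley attributions of ``model`` predictions for each query record.

    Parameters
    ----------
    model : object
        Anything with ``predict_proba`` (column 1 is attributed) or
        ``predict``; alternatively pass a callable via ``predict``.
    background : array (m, d)
        Reference sample defining the interventional expectation; by
        convention the full training set or a seeded subsample of it.
    queries : array (n, d)
        Records to explain.
    mode : {"exact", "sampled"}
        ``exact`` enumerates all coalitions (d ≤ 15 enforced); ``sampled``
        uses ``n_permutations`` random permutations per record, i.e.
        ``n_permutations × d`` coalition evaluations.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if background.size == 0:
        raise AttributionError("background set must be non-empty")
    d = queries.shape[1]
    if predict is None:
        if hasattr(model, "predict_proba"):
            predict = lambda X: model.predict_proba(X)[:, 1]  # noqa: E731
        elif callable(model):
            predict = model
        else:
            predict = model.predict
    if mode == "exact":
        if d > 15:
            raise AttributionError(f"exact mode limited to 15 features, got {d}")
        results = [_exact_single(predict, q, background, d) for q in queries]
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        results = [
            _sampled_single(predict, q, background, d, n_permutations, rng) for q in queries
        ]
    else:
        raise AttributionError(f"unknown mode {mode!r}")
    phis = np.vstack([r[0] for r in results])
    base = results[0][1]
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(d)]
    return AttributionSet(values=phis, base_value=base, feature_names=names)


def rank_features(attributions: AttributionSet) -> list:
    """Feature names in descending mean |φ|; ties keep the input feature order."""
    if attributions.values.size == 0:
        raise AttributionError("empty attribution set")
    mean_abs = np.abs(attributions.values).mean(axis=0)
    order = sorted(range(len(mean_abs)), key=lambda i: (-mean_abs[i], i))
    return [attributions.feature_names[i] for i in order]


def dependence_profile(feature_values, phi_values, bins: int = 10):
    """Binned mean/SD trend of φ against a feature, with a cutoff suggestion.

    The trend is the per-bin mean of φ over equal-width bins of the feature.
    The suggested cutoff is the bin center where the second difference of
    the (3-point moving-average) smoothed trend is largest in magnitude —
    a curvature heuristic for the inflection the trend plots mark by eye.

    Returns ``(table, cutoff)`` where table has columns bin_center, mean_phi,
    sd_phi, count.
    """
    x = np.asarray(feature_values, dtype=float)
    phi = np.asarray(phi_values, dtype=float)
    if x.shape != phi.shape:
        raise AttributionError("feature and attribution arrays differ in length")
    if x.size < bins:
        raise AttributionError(f"need at least {bins} points for {bins} bins")
    edges = np.linspace(x.min(), x.max(), bins + 1)
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, bins - 1)
    centers = (edges[:-1] + edges[1:]) / 2
    mean_phi = np.full(bins, np.nan)
    sd_phi = np.full(bins, np.nan)
    counts = np.zeros(bins, dtype=int)
    for b in range(bins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            mean_phi[b] = phi[sel].mean()
            sd_phi[b] = phi[sel].std()
    # 3-point moving average over occupied bins, then maximal |Δ²| curvature
    occ = ~np.isnan(mean_phi)
    trend = mean_phi[occ]
    ctr = centers[occ]
    smooth = np.convolve(trend, np.ones(3) / 3, mode="same") if trend.size >= 3 else trend
    cutoff = None
    if smooth.size >= 3:
        d2 = np.abs(np.diff(smooth, n=2))
        cutoff = float(ctr[1:-1][int(np.argmax(d2))])
    table = {
        "bin_center": centers,
        "mean_phi": mean_phi,
        "sd_phi": sd_phi,
        "count": counts,
    }
    return table, cutoff
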