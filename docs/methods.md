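# Methods

## Scope and model

`photoscreen` treats Type I photosensitizer discovery as a supervised
screening problem over excited-state energy descriptors. The physical
picture: after photoexcitation to S₁, a photosensitizer must cross to the
triplet manifold (ISC), and its triplet must then react by electron
transfer (Type I, radicals) rather than energy transfer to ³O₂ (Type II,
¹O₂). Three energetic quantities dominate this competition and anchor the
package's rules:

* **ΔE(S₁−Tₙ)** — the gap between S₁ and its *closest* triplet
  (`descriptors.gap_s1_tn`; ties go to the lowest triplet index). ISC is
  taken as efficient for channels with gap < 0.3 eV
  (`photophysics.isc_channels`).
* **ΔE(T₁−S₀)** — the T₁ energy itself (energies are referenced to
  S₀ = 0 eV throughout). Compared to the ¹O₂ excitation thresholds
  0.98 eV (¹Δg) and 1.63 eV (¹Σg⁺); these rules state *energetic*
  accessibility only — a dye can clear both thresholds yet produce no
  ¹O₂ when electron transfer outcompetes energy transfer kinetically.
* **Redox feasibility** — superoxide generation requires the dye's
  ground-state reduction potential below the O₂/O₂⁻• couple, −0.33 V vs.
  NHE (strict), and a negative Rehm–Weller free energy
  ΔG = E_ox − E_red − E₀₀.

The classifier does not see these rules; it learns from the raw
31-feature descriptor (S₁…S₁₅, T₁…T₁₅, aromatic ring count). The rules
re-enter downstream as funnel filters and as post-hoc rationalization.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| ISC gap threshold | 0.3 | eV | conventional window for efficient S₁→Tₙ crossing |
| ¹O₂ thresholds | 0.98 / 1.63 | eV | ¹Δg and ¹Σg⁺ excitation energies of O₂ |
| O₂/O₂⁻• couple | −0.33 | V vs. NHE | one-electron oxygen reduction potential |
| Ag/AgCl→NHE offset | +0.20 | V | reproduces matched experimental potential pairs; textbook 0.197 V selectable |
| probability cutoff | 0.5 | — | symmetric decision threshold on the calibrated score |
| train fraction | 0.8 | — | 77 records → 61 train / 16 test (test count is the ceiling of 0.2·n) |
| CV folds | 5 | — | stratified; 77 records at 40/60 balance make unstratified folds unstable |
| fingerprint | 2048 bits, radius 2 | — | ECFP dialect of RDKit's Morgan generator |
| UMAP | n_neighbors 15, min_dist 0.5, Jaccard metric | — | neighbourhood scale for ~10²–10⁴ molecule landscapes |

Boundary conventions are strict everywhere: a record at exactly 0.3 eV,
exactly 1.63 eV, exactly −0.33 V or synthetic-accessibility score exactly
0 fails its filter. The probability stage is inclusive (≥ 0.5), matching
the classification threshold.

## Fragment assembly

Attachment sites are dummy atoms `[*:n]` in the fragment SMILES; joining
bonds the dummies' neighbours with a single bond and deletes the dummies.
A two-dummy bridge `[*:1][*:2]` therefore collapses to a direct
donor–acceptor bond. After assembly any *unused* acceptor sites are
removed and implicitly hydrogen-capped. Duplicates collapse by canonical
SMILES (InChI comparison available as a strict mode). Acceptors with
more than two sites contribute every single site to DA enumeration and
every unordered site pair to DAD enumeration; restricting DA to each
acceptor's first declared site is available via `da_site_mode="first"`.
The built-in library (5 donors, 3 bridges, 3 acceptors of common D–A dye
motifs) is a small demonstration space — 165 raw combinations, 135 unique
molecules — not a reproduction of any published fragment list.

## Classifier bench

All five families run inside a scikit-learn pipeline whose first step is
`StandardScaler` fit on the training folds only (no leakage; verified by
a mutation test). Grid search is exhaustive with selection by mean fold
accuracy and ties broken by grid order. The SVM uses an RBF kernel with
C ∈ {0.1, 1, 10, 100} and γ ∈ {scale, 0.01, 0.1}; its probability is the
Platt-scaled decision function. Grids are deliberately small defaults,
recorded per run in the `ClassifierReport`; they are a starting point,
not a tuned optimum. Optional minority-class augmentation is implemented
as oversampling with Gaussian energy jitter re-sorted to preserve
manifold ordering (`synthetic.perturb_energies`, default off).

## Shapley attributions

Attributions use the interventional value function
v(S) = E_z∼background[f(x_S, z_{S̄})] with standard Shapley weights
|S|!(d−|S|−1)!/d!. Exact mode enumerates all 2^d coalitions and is
refused above 15 features; it is the package's own oracle. Sampled mode
averages marginal contributions over random feature permutations in
antithetic pairs (each drawn permutation is followed by its reverse),
which cancels most first-order interaction variance; because each
permutation's contributions telescope to v(N) − v(∅) = f(x) − base,
additivity holds exactly at any sample size. The background defaults to
the training set (or a seeded subsample). The dependence-profile cutoff
(location of maximal second difference of the 3-point-smoothed binned
trend) is a heuristic for by-eye inflection marking and is labelled as
such.

## Synthetic accessibility

The score is a multiplicity-weighted sum of per-fragment log-likelihood
ratios over the molecule's circular (Morgan) environments, positive ⇒
easy to synthesize. Any fragment table can be plugged in (including one
exported from a published Bayesian scorer). The bundled table is a
small **synthetic** stand-in built at import time from a dozen commodity
aromatics vs. a handful of strained cage hydrocarbons with Laplace
smoothing; it orders obviously-easy vs. obviously-hard structures
correctly but has no quantitative meaning beyond its sign.

## Synthetic fixtures: what they emulate and what they do not

The training fixture plants the label rule
*Type I ⇔ min|S₁−Tₙ| < 0.3 eV ∧ T₁ > 1.63 eV* and is constructed
margin-separated: Type I records have near-degenerate S₁/T₁
(gap ≤ 0.2 eV, T₁ ≥ 1.73 eV, S₁ ∈ [2.0, 2.6] eV); non-Type I records
either sit at low T₁ (≤ 1.4 eV) or keep every triplet ≥ 0.45 eV from S₁.
Successive states climb with gaps drawn from [0.05, 0.4] eV, plausible
for conjugated D–A dyes. Every record's label is re-derived from the rule
after construction, so a decision tree recovers it with 100 % training
accuracy and the margin-based SVM cross-validates at ≥ 0.95 across seeds.
The candidate fixture pairs unique library molecules with state tables in
which 60 % pass the ISC-gap stage and 70 % the T₁ stage by construction.

Passing on these fixtures demonstrates that the pipeline's bookkeeping,
filters and learners are correct — it does **not** show that real Type I
activity is this separable. Real excited-state data carry correlated
manifolds, label noise from assay heterogeneity, functional/basis-set
bias, and aggregation effects (the energies of a dye's aggregate differ
from its monomer; this package scores monomer tables only).

## Problem sizes and determinism

The shipped analyses use the 77-record fixture, a 120-candidate screening
table, 1,000-record random funnel and gap-statistic oracle checks, ~10⁴
sampled coalitions for the attribution comparison, and a 60-molecule
two-family embedding check. Every stochastic step — fixture generation,
splitting, folding, model initialisation, coalition sampling, UMAP — is
driven by an explicit seed; identical seeds give identical outputs
(single-threaded UMAP in exact mode).

## Known limitations

* No quantum-chemistry log parsing: excited-state energies enter as CSV
  tables; computing them is out of scope.
* Spin–orbit couplings are accepted as inputs only, never computed.
* The funnel is conjunctive in one pass; iterative batch-wise screening
  with expert triage would give the same survivor set for fixed
  thresholds but different intermediate counts.
* The novelty stage is report-only by default (no published novelty
  cutoff exists); the funnel summary records whatever threshold is used.
* UMAP coordinates are reproducible per seed but not comparable across
  library versions or seeds.
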