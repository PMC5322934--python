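# Methods

## Problem setting

Correlated atomic motion in a molecular-dynamics (MD) trajectory is
classically summarized by the dynamic cross-correlation (DCC)

    DCC(i,j) = <Δr_i(t)·Δr_j(t)>_t / sqrt(<‖Δr_i‖²>_t <‖Δr_j‖²>_t),
    Δr_i(t) = r_i(t) − <r_i(t)>_t,

a time-averaged, normalized dot product of deviations from the mean
position.  DCC assumes each atom fluctuates about a *single* basin.  Many
atoms do not: a side chain flipping between rotamers, or a loop residue
that transiently binds and releases a DNA phosphate, samples a multi-modal
spatial distribution.  Deviations from the global mean then mix the
between-basin switch with the within-basin motion, and a genuine coupling
that exists only while a contact is formed can average away to near zero.

## The multi-modal DCC

mdcckit resolves this by modelling each heavy atom's sampled coordinates as
a Gaussian mixture.  Each component ("mode") k has a weight π_k, a center
μ_k and a full 3×3 covariance; the per-frame membership probability
p_k(r_i(t)) is the standard mixture responsibility.  The multi-modal DCC of
mode k of atom i against mode l of atom j is

    mDCC(i,j;k,l) = <w(t) Δr_{i,k}·Δr_{j,l}>_t
                    / sqrt(<w ‖Δr_{i,k}‖²>_t <w ‖Δr_{j,l}‖²>_t),

with Δr_{i,k}(t) = r_i(t) − μ_k and the joint weight
w(t) = p_k(r_i(t)) p_l(r_j(t)).  Both DCC and mDCC lie in [−1, 1]
(Cauchy–Schwarz with non-negative frame weights), and when both atoms are
uni-modal w ≡ 1 and μ is the mean, so mDCC collapses exactly to DCC — the
implementation's headline reduction property, tested to 1e−9.

Residue-level summary: the representative mDCC of a residue pair (a,b) is
the maximum over all atom pairs (i∈a, j∈b) and mode pairs (k,l), after
omitting mode pairs that only rarely coexist.  The rare-pair condition is
applied to the *time-averaged* joint probability, <w>_t ≤ 0.1: a per-frame
condition would exclude either nothing or everything, while the time
average matches the interpretation of mode probabilities as occupancies.
Ties in the maximum are broken toward the larger mean weight, then the
smaller mode-center distance, so provenance favors the better-populated,
contact-relevant pair.  A companion residue DCC (maximum conventional DCC
over the same atom pairs, mirroring the max summary) is kept for the
transient-edge rule below, and the signed minimum mDCC is stored per cell
as a diagnostic.

## Mode fitting

Mixtures are fitted per atom by expectation–maximization (scikit-learn,
full covariances) with 5 seeded restarts; the mode count K is chosen by the
Bayesian information criterion over K = 1..max_modes (default 6; observed
side-chain atoms rarely need more than ~5 modes).  The criterion is a
keyword argument (AIC available) since different Bayesian model-selection
rules are defensible here.  Numerical choices:

- covariance regularization 1e−6 Å² on the diagonal, preventing singular
  fits for frozen atoms; a constant coordinate short-circuits to a single
  mode with floor covariance;
- components with converged weight < 0.01 are pruned and the remainder
  renormalized — physically meaningful minor modes sit above ~1%
  occupancy, numerical splinters below it;
- modes are sorted by non-increasing weight (lexicographic center
  comparison on ties) so mode indices are reproducible;
- per-atom fit seeds are derived from the global seed and the atom index,
  so results do not depend on selection order.

Responsibilities are recomputed from the stored (pruned) mixture rather
than taken from the fitting object, keeping posterior and mixture
consistent.

## Network analysis

Residue pairs with representative mDCC ≥ 0.5 *and* a distance between the
maximizing mode centers < 5 Å are connected by an edge: a strong positive
correlation through an actual atomic contact.  Edges with companion DCC
below the threshold are flagged *transient* — interactions formed during
only part of the trajectory, which conventional DCC misses.  Edge
eligibility uses the provenance (maximizing) mode pair by default; a
stricter/looser alternative, "any mode pair jointly passing both
thresholds", is available behind a flag since the choice is not uniquely
determined by the definition.

Betweenness g(i) = Σ_{s≠i,t≠i,s≠t} σ_st(i)/σ_st is computed over unordered
node pairs with unweighted shortest paths (Brandes' dependency
accumulation).  The ordered reading of the sum would double every value
uniformly and leave rankings unchanged; unordered is the standard
convention.  Pairs in different components contribute nothing (σ_st = 0 is
treated as no term).  Per-molecule top-k tables rank by value with node
order as the deterministic tie-break.

## Trajectory handling and descriptors

Superposition is the closed-form SVD (Kabsch) solution with determinant
correction; reflections are never applied, degenerate selections (< 3 atoms
or collinear) are rejected.  Superposition conventions differ by use case —
RMSF per molecule (each molecule fitted on its own backbone), RMSD usually
global — so the fitting selection is always the caller's choice; the same
applies to the frame of reference used before mode fitting.  PDB topology
and multi-model trajectories are read strictly (malformed records are
errors, not warnings); DCD/XTC pass through mdtraj with nm→Å conversion.
No periodic-boundary handling is attempted: inputs are assumed pre-imaged,
with a bounding-box sanity warning.

Cartesian PCA uses the population (1/n) covariance of the flattened 3N
vector — contribution rates are ratios and unaffected, but the convention
must be fixed for reproducible eigenvalues.  PC-plane clustering evaluates
a Gaussian KDE on a grid, thresholds at a fraction (default 0.1) of the
peak density, and labels connected super-threshold regions; every frame is
assigned its nearest labelled region.  Density contouring of the score
plane is inherently bandwidth-dependent; defaults resolve well-separated
basins (≳ 5 bandwidths apart) and merge overlapping ones.

## Synthetic benchmarks and what they do (not) show

The generators plant the exact structure the analysis is meant to recover:

- **unimodal system** — independent isotropic jitter, the null case
  (planted K = 1, zero correlation);
- **two-state pair** — one shared latent two-state process (a Markov chain
  with mean dwell 100 frames by default, i.i.d. switching available)
  selecting each atom's active center, plus within-mode jitter correlated
  with coefficient ρ along matched axes.  In the *anti-aligned* geometry
  the two inter-center vectors oppose, so the switch's covariance
  contribution cancels the jitter correlation: conventional DCC is driven
  to ≲ 0.3 (typically negative) while the matched-mode mDCC recovers ρ.
  Default box: ρ = 0.9, 6σ center separation, σ = 0.3 Å, occupancy 0.5,
  20 000 frames — well inside the regime where EM reliably resolves the
  two modes and sampling error on mDCC is a few hundredths;
- **allosteric chain** — molecules A, bridge, B whose residues form a
  linear coupling path (consecutive members 4 Å apart, jitter-coupled at
  ρ = 0.9; everything else distant and independent), with the central
  bridge link optionally a two-state transient pair.  The intended edge
  set, transient flags and top-betweenness (middle bridge) residue are
  recorded as ground truth for end-to-end recovery.

All generators are bit-deterministic given their seed and emit coordinates
already superposed (an optional rigid tumble exercises the superposition
stage).  Problem sizes used in the test suite and acceptance script —
2 000-frame/50-atom collapse check, 20 000-frame pair benchmarks,
100 mixture replicates at n = 10 000, 5 chain seeds at 6 000 frames — were
chosen so each planted effect sits several standard errors from its
decision boundary.

These benchmarks are labelled point atoms, not physics: no excluded
volume, no force field, no solvent, no kinetic realism beyond dwell times.
Passing them shows that the estimators recover what they are defined to
measure under their own model assumptions — not that a particular
biological system exhibits any specific correlation.

## Known limitations

- BIC-EM is one defensible reading of "automatic" Gaussian-mixture model
  selection; variational-Bayes alternatives can prefer different K on
  marginal data.  The criterion is pluggable for this reason.
- The residue-level max summary reports the least-negative value for cells
  whose candidates are all negative; the stored per-cell minimum should be
  consulted when anti-correlation matters.
- With Markov switching (dwell ≫ 1 frame) the effective sample size for
  occupancy-like quantities is roughly n_frames/(2·dwell); tolerance
  arithmetic in the tests accounts for this.
- Betweenness is computed on the thresholded, unweighted graph; it ranks
  bottleneck residues but implies no directionality or causality.
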