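# mdcckit

Multi-modal dynamic cross-correlation (mDCC) analysis of molecular-dynamics
trajectories, with the downstream contact-correlation network and
betweenness-centrality ranking used to propose allosteric pathways.

## Who this is for

Structural bioinformaticians analysing MD trajectories of proteins,
nucleic acids and their complexes who need to detect *transient*
correlated motions — couplings that exist only while a contact is formed
(a flipping rotamer, a loop residue intermittently gripping a DNA
phosphate) and that the conventional dynamic cross-correlation map dilutes
or cancels entirely.

## The method

The conventional DCC between atoms *i* and *j*,

```
DCC(i,j) = ⟨Δr_i(t)·Δr_j(t)⟩_t / √(⟨‖Δr_i‖²⟩_t ⟨‖Δr_j‖²⟩_t),   Δr_i(t) = r_i(t) − ⟨r_i⟩_t,
```

measures deviations from a single mean position.  mdcckit instead fits
each heavy atom's coordinate distribution with a Gaussian mixture — each
component a spatial "mode" (weight π_k, center μ_k, 3×3 covariance) — and
correlates *mode pairs*, weighting every frame by the joint membership
probability w(t) = p_k(r_i(t)) p_l(r_j(t)):

```
mDCC(i,j;k,l) = ⟨w Δr_{i,k}·Δr_{j,l}⟩_t / √(⟨w ‖Δr_{i,k}‖²⟩_t ⟨w ‖Δr_{j,l}‖²⟩_t),
Δr_{i,k}(t) = r_i(t) − μ_k.
```

Residue pairs are summarized by the largest mDCC over their atom and mode
pairs (rarely coexisting mode pairs, ⟨w⟩_t ≤ 0.1, are omitted).  Pairs
with mDCC ≥ 0.5 whose mode centers are within 5 Å become network edges;
edges whose conventional DCC is below 0.5 are flagged *transient*.
Residues are ranked by betweenness centrality
g(i) = Σ_{s≠i,t≠i} σ_st(i)/σ_st over unweighted shortest paths.

The package also provides the standard descriptors such an analysis leans
on (rigid-body superposition, RMSD, RMSF, Cartesian PCA with PC-plane
density clustering, interatomic distance series), PDB/DCD/XTC I/O, and a
seeded synthetic-trajectory generator that plants modes, two-state
switching and couplings with full ground truth.

## Worked example

The hard case for conventional DCC: two atoms share a two-state switch
whose inter-center displacements oppose each other (anti-aligned), while
their within-mode jitter is strongly coupled (ρ = 0.9).

```python
from mdcckit import (generate_two_state_pair, dcc, fit_all_modes,
                     mode_posterior, residue_matrix, build_network)

traj, truth = generate_two_state_pair(20_000, rho=0.9, seed=1)
print("DCC :", round(dcc(traj, 0, 1), 3))

modes = fit_all_modes(traj, max_modes=3, seed=1)
post = {i: mode_posterior(m, traj) for i, m in modes.items()}
mat = residue_matrix(traj, modes, post)
print("mDCC:", round(mat.mdcc[0, 1], 3))

net = build_network(mat)
for a, b, d in net.edges():
    print(f"edge {a} -- {b}: mdcc {d['mdcc']:.2f}, transient {d['transient']}")
```

prints

```
DCC : -0.526
mDCC: 0.899
edge A:1:ALA -- B:1:ALA: mdcc 0.90, transient True
```

The conventional DCC (−0.53) is dominated by the anti-aligned basin
switching and completely misses the coupling; the matched-mode mDCC
recovers the planted within-mode correlation (0.90 ≈ ρ) and the network
records the pair as a transient edge — correlated *and* in contact, but
only part of the time.

The same pipeline runs from the shell:

```
mdcckit synth chain --frames 6000 --seed 1 -o bench
mdcckit modes fit bench.pdb --top bench.pdb --max-modes 3 --seed 1 -o modes.json
mdcckit mdcc run bench.pdb --top bench.pdb --modes modes.json -o mat
mdcckit net betweenness --matrix-prefix mat -o top.tsv
```

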