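# Methods

This note records the models, estimators, numerical choices and known
limitations behind luciflux, in the order the analysis chain runs.

## Synthetic data: what it emulates and what it does not

The generators stand in for all-atom MD trajectories of a small helical
protein.  They reproduce the *statistical structure* each downstream
estimator assumes, not the physics that produces it:

- **Discrete jump trajectories** are sampled exactly from a prescribed
  row-stochastic matrix by per-row inverse-CDF draws.  They are Markovian
  by construction at every lag, which is precisely what makes them the
  right oracle for transition-matrix estimation, implied-timescale
  flatness and the Chapman–Kolmogorov test.
- **Continuous well dynamics** use overdamped (first-order) Langevin
  integration, Euler–Maruyama with a fixed step:
  x ← x + βD F(x) dt + √(2D dt) ξ.  A single well of stiffness equal to
  `barrier_height` gives free or harmonic diffusion; two centers give the
  quartic double well U = h((x−m)/a)² − 1)², barrier height h in kT at the
  midpoint.  First-order dynamics is the simplest process with tunable
  metastability; it exercises discretization and MSM estimation without
  inertia, solvent or force-field detail.  The explicit integrator is
  only stable for dt ≲ 1/(4βDh); callers picking very high barriers must
  shrink `dt` accordingly.
- **Gaussian positional ensembles** add zero-mean displacements to a
  reference structure, isotropic per site with SD σ_i per Cartesian
  component and a prescribed site×site correlation shared by x, y, z.
  Displacements are drawn through the symmetric matrix square root of the
  site covariance, so the ground truth is analytic: RMSF_i = σ_i√3 and
  DCCM_ij equals the prescribed correlation.  A non-PSD correlation is
  rejected outright — silently projecting to the nearest PSD matrix would
  change the ground truth under the caller's feet.
- **Energy tables** are independent Gaussians per component.  Real
  MM/PBSA components are autocorrelated and cross-correlated frame to
  frame; the generator deliberately ignores that, because the aggregation
  identities under test are moment identities that hold either way.  The
  default table size is 450 frames with component scales (σ_vdW ≈ 4.3,
  σ_ele ≈ 32, σ_solv ≈ 30 kcal/mol) typical of end-point analyses of a
  ~20 kDa protein–ligand complex.

What passing tests on these inputs shows: the estimators implement their
definitions correctly and recover known ground truth at realistic sample
sizes.  What it does not show: robustness to the non-Markovianity,
anisotropy and slow drift of real MD data.

Defaults follow the emulated study design: 0.1 ns between saved frames,
4500 frames per 450 ns run.  All generators take one explicit integer
seed and never touch global RNG state; identical arguments give
bit-identical output.

## Units and bookkeeping

Å for coordinates, ns for time, kcal/mol for energies, everywhere; no
implicit conversions.  Residue identity is (chain, residue number,
insertion code) verbatim from the input file — selections are quoted in
crystallographic numbering (the luciferase active pocket: α1 residues
12–18, α7 residues 109–119).  Trajectory formats are text only (fixed
column PDB, xmol XYZ, a CSV array container with a JSON header line);
PDB altloc handling keeps the highest-occupancy conformer.

## Observables

- **Superposition** is Kabsch SVD on the selected atoms, proper rotations
  enforced by the determinant correction.  RMSD series allow distinct fit
  and measurement selections (ligand RMSD with the binding site aligned).
- **RMSF** optionally removes rigid-body motion by iterative superposition
  onto the running mean structure (10 iterations or mean-structure change
  below 1e-8 Å).
- **DCCM** uses deviations from the time-mean structure after a single
  superposition pass — the standard convention; iterating changes little
  and costs a pass per iteration.  Sites with zero positional variance
  yield NaN rows rather than 0: absence of motion is not evidence of
  absence of correlation.
- **SASA** is Shrake–Rupley quadrature on a deterministic golden-spiral
  point set (default 960 points/atom, probe 1.4 Å, Bondi radii with a
  per-element override table).  The isolated-sphere error at 960 points
  is well under 0.5%.
- **Helix content** reduces the hydrogen-bond pattern of full secondary
  structure assignment to the α-helix class only: a residue is helical in
  a frame when it participates in an i→i+4 backbone H-bond (donor or
  acceptor) with dipole-model energy
  0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol.  The
  amide H is reconstructed 1 Å from N along the preceding residue's O→C
  axis.  β-classes and turns are out of scope — only helix probabilities
  are reported.

## Markov-state model

- **k-means**: Lloyd iterations from k-means++ with an explicit seed;
  convergence when the largest center shift drops below `tol`.
  Microstate assignment breaks distance ties toward the lowest center
  index.  The featurization is coordinate-space k-means on superposed Cα
  coordinates; pairwise-RMSD medoid clustering would be an alternative
  reading of common practice, and the two disagree only through the
  superposition metric.
- **Counting** uses sliding (overlapping) windows by default, maximizing
  data use; strided counting is available where independence of counts
  matters.
- **Estimation** is restricted to the largest strongly connected
  component of the count graph (largest by contained counts), without
  which no stationary distribution is defined.  Non-reversible mode is
  row normalization; reversible mode is the detailed-balance
  maximum-likelihood fixed point x_ij ← (c_ij+c_ji)/(c_i/x_i + c_j/x_j),
  iterated to 1e-10.  Eigenvalues are sorted by descending real part with
  a deterministic imaginary-part tie-break.
- **Implied timescales** t_i = −τ/ln λ_i are reported only for real
  λ_i ∈ (0,1); complex or non-positive eigenvalues produce a warning and
  a missing value — they carry no relaxation timescale.
- **VAMP-2** scores a discretization as the squared Frobenius norm of
  C00^{-1/2} C01 C11^{-1/2} over indicator features; the stationary
  process contributes a unit singular value, so the score is ≥ 1 and
  approaches 1 + Σλ_i² on well-resolved chains.  For *selecting* k the
  in-sample score is useless — it never decreases under refinement — so
  selection uses a cross-validated score (singular functions fit on the
  first half of the data, covariances evaluated on the second) plus a
  parsimony rule: the smallest k within 1% of the grid maximum.  The lag
  is the smallest grid point where the slowest implied timescale varies
  by less than 10% over the next two grid points; if none converges the
  largest lag is returned with a warning.
- **Chapman–Kolmogorov**: the model at lag τ propagated k steps is
  compared with a model re-estimated at lag kτ, both coarse-grained onto
  PCCA macrostates, on macrostate self-transition probabilities weighted
  by the lag-τ stationary distribution.  "Agreement" is operationalized
  as 1 − mean(|predicted − estimated|/predicted), clamped to [0,1]
  (the conventional adequacy threshold being 95%); it is exactly 1 at
  k = 1 by construction.  States absent from the lag-kτ connected set
  keep identity rows.

## Coarse-graining and flux analysis

- **PCCA+** rotates the top-n right eigenvectors (computed through the
  π-weighted symmetrization for numerical stability; non-reversible
  input is flow-symmetrized with a warning) by the inner-simplex
  construction: n microstates are found as simplex vertices by iterated
  orthogonal projection, memberships are barycentric coordinates clipped
  to [0,1] and row-renormalized, crisp labels by argmax.  Requesting more
  macrostates than there are positive leading eigenvalues is an error
  naming the usable maximum.
- **Committors**: q⁺ solves the dense linear system with boundary
  conditions 0 on the source set A and 1 on the sink set B; a singular
  system (B unreachable) warns and returns q⁺ = 0 outside B.  q⁻ is the
  committor of the time-reversed chain — for reversible models this
  reduces to 1 − q⁺, and tests assert that identity rather than assuming
  it.
- **Flux**: gross f_ij = ρ_i q⁻_i T_ij q⁺_j with zeroed diagonal; net
  f⁺_ij = max(f_ij − f_ji, 0) — the standard nonnegative net flux; total
  flux is the net outflow of A, equal to the net inflow of B by
  conservation.
- **Pathways**: the net-flux graph is decomposed by repeatedly removing
  the strongest-bottleneck simple A→B path and its bottleneck flux.
  Greedy mode finds each path with a widest-path Dijkstra; exhaustive
  mode (≤ 12 states) brute-forces all simple paths per round and serves
  as the reference — run to exhaustion its path probabilities sum to 1.
  Path probability is path flux over total flux.
- **Endpoint naming**: the macrostate-level summary labels the net coarse
  flux source SA and the net sink SB (maximal outflow−inflow balance,
  equivalent to ranking by backward/forward committor density), remaining
  macrostates S1, S2, … in index order.  The labelling rule is a
  documented operational choice; "initial state" is not otherwise
  well-defined from a stationary flux network.

## Energetics

Derived quantities (∆G_gas, ∆G_sol, ∆G_total, ∆G_bind) are computed per
frame and then summarized, so the identities
Average(∆G_gas) = Average(∆E_ele) + Average(∆E_vdW) (+ ∆E_int) and
Average(∆G_total) = Average(∆G_gas) + Average(∆G_sol) hold to machine
precision.  Std. Err. of Mean is sample SD (n−1 denominator) over √n —
the convention consistent with published vdW rows at n = 450; a
single-frame table reports SEM as missing.  The entropy term −T∆S is
optional and absent by default, matching the common practice of
reporting ∆G_total without it.  ∆E_int defaults to absent (it cancels in
single-trajectory end-point analysis); ∆G_solv may be supplied whole or
as ∆G_pb + ∆G_np.  Reported precision is 4 decimals.

`recompute_derived` checks a *published* table the way a reader does:
each derived row from the printed rows above it (∆G_total from the
printed ∆G_gas row when present).  This matters because printed rows are
individually rounded; summing raw components can differ from the printed
derived value by one unit in the last decimal.

## Pipeline

Stages run in declared order over a shared in-memory state and write
plain-text artifacts; every stochastic stage must declare a seed, and the
manifest records each output's SHA-256 digest, so reruns of the same
config are byte-identical.  The demo problem sizes (20 000 Langevin
frames, 2 000 ensemble frames × 24 sites, 450 energy frames) are chosen
so a full run completes in seconds on one CPU while leaving every
estimator in its asymptotic regime; the test suite uses a further
reduced copy.

## Known limitations

- The observables assume a shared topology across frames; no PBC
  unwrapping, mass-weighting defaults to unit masses except where masses
  are passed.
- Helix content needs complete N/CA/C/O backbones; residues missing atoms
  are excluded with a warning rather than imputed.
- The reversible MLE fixed point is first-order; on pathological count
  matrices (many zero rows) convergence can be slow, though the 1e-10
  tolerance is reached in well under the iteration cap on all tested
  inputs.
- Exhaustive path decomposition is exponential and deliberately refuses
  more than 12 states.
- The CK agreement metric is one of several in use; it is configurable by
  passing explicit macrostate sets, and its definition is stated above
  precisely so results are comparable.
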