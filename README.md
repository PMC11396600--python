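# luciflux

Conformational-dynamics analysis for luciferase-style protein systems:
trajectory observables, Markov-state-model (MSM) construction and
validation, transition-path-theory (TPT) flux and pathway analysis, and
MM/PBSA binding-energy aggregation — together with synthetic-trajectory
generators whose statistical structure is known exactly, so every stage of
the chain can be tested against analytic ground truth.

## Who this is for

Computational structural biologists who have (or want to emulate)
molecular-dynamics trajectories of a protein — the motivating system is
*Gaussia* luciferase and its glow-/flash-type mutants bound to
coelenterazine — and want to go from raw frames to a quantitative story:
which conformational basins exist, how probability flows between them, and
how binding-energy components break down.

## What it computes

**Observables** (Å, Å², fractions): best-fit Cα RMSD time series (Kabsch
superposition, with independent fit/measure selections for ligand RMSD),
radius of gyration, per-site RMSF, Shrake–Rupley SASA with Bondi radii,
the dynamical cross-correlation matrix
C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), the α1–α7 active-pocket
centroid distance, and α-helix content from backbone i→i+4 hydrogen bonds
(dipole-model energy < −0.5 kcal/mol).

**MSM**: k-means microstates (k-means++ with explicit seed), sliding-window
transition counts at lag τ, row-normalized or detailed-balance
maximum-likelihood transition matrices restricted to the largest strongly
connected set, VAMP-2 discretization scoring (cross-validated variant for
choosing k), implied timescales t_i = −τ/ln λ_i, and the
Chapman–Kolmogorov test comparing T(τ)^k against a model re-estimated at
lag kτ on PCCA macrostate self-transition probabilities.

**TPT**: PCCA+ metastable coarse-graining, forward/backward committors
q⁺/q⁻, gross flux f_ij = ρ_i q⁻_i T_ij q⁺_j, net flux
f⁺_ij = max(f_ij − f_ji, 0), and pathway decomposition with occurrence
probabilities P_i = f_i / Σ_j f_j (widest-path greedy, with exhaustive
enumeration as the small-system reference).

**Energetics**: per-frame MM/PBSA component tables aggregated as
∆G_gas = ∆E_ele + ∆E_vdW (+ ∆E_int), ∆G_sol = ∆G_pb + ∆G_np,
∆G_total = ∆G_gas + ∆G_sol, optional ∆G_bind = ∆G_total − T∆S, reported
as Average / Std. Dev. / Std. Err. of Mean, plus per-residue contribution
ranking.

**Synthetic data**: discrete jump trajectories from a prescribed stochastic
matrix, overdamped Langevin paths on multi-well potentials, Gaussian
positional ensembles with prescribed per-site SDs and site–site
correlations (making RMSF = σ√3 and DCCM ground truth analytic), and
Gaussian energy-component tables.

## Worked example

The bundled demo config runs the whole chain on a synthetic two-well
system (20 000 Langevin frames discretized into two microstates, a
24-site correlated Gaussian ensemble for the observables, and a 450-frame
energy table):

```sh
luciflux run --out demo_run
luciflux report demo_run
```

prints (abridged):

```
Chapman–Kolmogorov test (k=5): agreement 95.1%

Implied timescales (ns):
lag_steps,t2_ns
1,5.042802181
2,6.530335205
5,9.995601825
10,13.32677831
20,16.20947673

Dominant pathway: SA→SB (100.0% of total flux)
  SA→SB: flux 0.01205 (100.0%)

MM/PBSA-style aggregation (kcal/mol)
Energy Component       Average   Std. Dev.   Std. Err. of Mean
∆E_vdW                -65.0081      4.4482              0.2097
∆E_ele               -106.2303     31.0953              1.4658
∆G_gas               -171.2384     30.9058              1.4569
∆G_solv               123.9100     29.6702              1.3987
∆G_total              -47.3283     40.9092              1.9285
```

Reading it: the CK agreement above 95% says the two-state Markov model at
the chosen lag propagates self-consistently out to five lags.  The t₂
column shows the slowest implied timescale per candidate lag — here it
still climbs with lag because a two-center discretization of a continuous
double well is genuinely lossy at short lags.  The flux section says all
source-to-sink probability current flows through a single direct channel.
The energy block shows the aggregation identities on a synthetic table:
∆G_gas is exactly ∆E_vdW + ∆E_ele, and ∆G_total exactly ∆G_gas + ∆G_solv.

Every run writes a `manifest.json` recording each output file's SHA-256
digest and each stochastic stage's seed; rerunning the same config
produces byte-identical artifacts.

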