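# Methods

## Titration model

A protein is reduced to N two-state titratable sites. Site i carries charge
`q_i = q_deprot,i + x_i` with protonation indicator `x_i ∈ {0,1}`: acids
(Asp, Glu, Cys, Tyr, C-terminus) titrate −1 ↔ 0, bases (His, Lys, Arg,
N-terminus) 0 ↔ +1. Each site has

* a **model pKa** — the unperturbed reference-compound value, used for the
  unfolded state (defaults: Asp 3.8, Glu 4.5, His 6.5, Cys 9.0, Tyr 10.0,
  Lys 10.5, Arg 12.5, N-term 8.0, C-term 3.6; all config-overridable), and
* an **intrinsic pKa** — the folded-state value before site–site coupling.
  By default it equals the model pKa; perturbations enter either through
  the coupling matrix, through an external per-site pKa table (e.g. from a
  Poisson–Boltzmann tool), or directly as planted values in synthetic
  fixtures.

The folded-state microstate free energy, in units of kT, is

    G(x)/kT = ln10 · Σ_i x_i (pH − pKa_int,i) + (1/kT) Σ_{i<j} W_ij q_i q_j

with the screened-Coulomb coupling `W_ij = 332.0636/(ε r_ij) · exp(−κ r_ij)`
kcal/mol between unit charges (r in Å). Defaults: uniform dielectric ε = 20,
ionic strength 0.15 mol/L, T = 298.15 K (kT = 0.5925 kcal/mol). κ is
computed from the ionic strength with the same uniform dielectric; at ε =
78.5 it reduces to the familiar aqueous Debye length (~7.9 Å at 0.15 M).
Distances below a 2.0 Å clash floor are clamped upward so W stays finite on
imperfect geometries; exactly coincident charge centers are an error. This
uniform-dielectric model deliberately omits Born/background desolvation
terms and conformational response; external pKa tables are the intended
route to higher-fidelity folded-state pKas.

The unfolded state is treated as independent sites at model pKas — the
standard assumption that unfolded-state pKas are unperturbed. No unfolded
ensemble is generated.

## Solvers

* **Exact enumeration** (N ≤ 16): Boltzmann average over all 2^N
  microstates, vectorised over the pH grid with a log-sum-exp softmax.
  This is the reference oracle for everything else.
* **Mean field**: self-consistent iteration of
  `θ_i = 1/(1 + 10^(pH − pKa_int,i − Δ_i))`,
  `Δ_i = −(1/(kT ln10)) Σ_j W_ij ⟨q_j⟩`, damped with weight 0.5 on the
  previous iterate (escalated to 0.9 on non-convergence), tolerance 1e−6 on
  max |θ change|, 10 000 iterations max, swept low→high pH with warm
  starts. After convergence one undamped application of the fixed-point map
  is taken, so the decoupled (W = 0) limit reproduces
  Henderson–Hasselbalch to machine precision. Non-converged grid points are
  flagged, returned, and fatal only under `--strict`.
* **Metropolis Monte Carlo**: single-site-flip sampling (numba kernel),
  default 10 000 sweeps per grid point, burn-in 20%, warm-started along the
  pH sweep, bitwise-reproducible per seed. Reported standard errors are the
  maximum of batch-means estimates at two batch lengths (20 and 5 batches)
  and a Laplace-smoothed binomial floor. The composite is deliberately
  conservative: single-flip chains are autocorrelated, and near-frozen
  sites show clumped rare excursions for which any single-scale chain
  estimate is biased low.

Solver-equivalence testing is statistical by nature. The mean-field check
is a hard band (max |θ − oracle| ≤ 0.05 over 50 random ≤12-site fixtures;
observed worst ≈ 0.005). For MC, a literal "every point within 3 SE" bound
is unattainable by construction — across the ~17 000 (site, pH)
comparisons of a 50-fixture battery a perfect sampler would exceed 3 SE at
~0.3% of points — so the criterion is: ≥99% of comparisons within 3 SE,
and every comparison within max(5 SE, 0.01). The 0.01 absolute floor is
~2× the worst-case binomial SE at 8 000 kept sweeps and covers the
near-frozen corners where SE estimates are unreliable.

## Free-energy curve

With Δq(pH) = Q_folded − Q_unfolded, the pH-dependent folding free energy
is `ΔΔG(pH) = ln10·kT·∫ Δq dpH + constant`, evaluated by cumulative
trapezoidal integration on the uniform grid (a left-rectangle rule is
available behind `method="rectangle"` for literal summation fidelity; both
converge to the same limit, trapezoid at second order). The curve is
anchored exactly at the window's start pH: constant 0 for wild type (no
absolute folding free energies are assumed known), and the consensus
predictor ΔΔG for a variant — applied as a uniform offset at the start pH,
the same anchor convention as the wild type. Sign convention: more negative
= more stable; the **pH optimum of stability** is the grid argmin, ties
broken toward the lowest pH, boundary optima flagged (`<=start` / `>=end`).

The Wyman-linkage identity `d(ΔΔG)/dpH = ln10·kT·Δq` is enforced in tests
at interior grid points via central differences. For trapezoid integration
the residual is exactly `ln10·kT·(h²/4)·Δq''`; with the logistic curvature
bound (|θ''| ≤ ln10²·0.0962 ≈ 0.51 per site) the test tolerance is
`ln10·kT·h²·max(1, N/4)` — an O(h²) constant fixed analytically, not
fitted.

**Decomposition.** Per-site Δq_i curves are integrated separately
(constant 0) and summed within residue-class groups: acidic
(Asp/Glu/Cys/Tyr/C-term), His, basic (Lys/Arg/N-term). By linearity the
class curves sum exactly to the total. His is kept separate because its
model pKa makes it the main driver of near-neutral pH dependence, while
acidic groups drive the acidic window.

**Ensemble averaging.** Pseudo-snapshot ensembles are averaged on the
charge curves *before* integration (mean θ across members, SD of Q
reported). Averaging anchored energy curves after integration is also
offered; for a fixed constant the two routes are identical by linearity
(asserted in tests).

## Variants

Substitutions are applied as residue-name edits without side-chain
rebuilding: the mutated site inherits the replaced side chain's charge
center (falling back to the side-chain centroid, then Cβ, then Cα), and the
center is retained on site removal so the reverse variant restores the
original site list exactly. Wild-type mismatches abort, naming expected vs.
found.

Consensus ΔΔG values are the arithmetic mean ± sample SD of external
predictor outputs (the predictors themselves are inputs, not run here);
multi-variant ΔΔG is the sum of the individual averages. Sign convention:
positive = stabilizing (a flag flips files using the opposite convention).
Curve comparisons report ΔpH-optimum with a qualitative label; |ΔpH| ≤ 0.2
(two grid steps at default resolution) counts as "unshifted".

## Synthetic fixtures

Toy proteins are poly-Ala chains whose titratable residues sit at uniform
random positions in a 40 Å box with ≥7 Å separation (seeded 64-bit
generator); side-chain atoms are placed so the extracted charge center
equals the planted coordinate exactly. Planted folded pKas are imposed
directly as intrinsic pKas with coupling off ("planted" mode, exact ground
truth); "coupled" mode keeps the geometric W for oracle and jitter
experiments. Snapshots are isotropic Gaussian coordinate jitters (default
0.5 Å, 20 snapshots).

Two named scenarios encode the perturbation patterns of interest:

* **positive_regulator** — 3 Asp + 3 Glu with folded pKas shifted +1.5
  (plus 2 His, 2 Lys unshifted): Δq > 0 across the window, optimum at the
  acidic boundary, acidic-class dominated.
* **neutral_optimum** — 5 His with mixed shifts (three −1.0, two +2.0,
  plus unshifted Asp/Glu/Lys): Δq changes sign near pH 6.6, giving an
  interior optimum in the 6.5–8 window, His-dominated. The mixed-direction
  shift is deliberate: a single-direction His shift yields only a boundary
  optimum, since an interior optimum requires Δq to cross zero inside the
  window.

What the generator does **not** emulate: real backbone geometry, buried
sites and heterogeneous dielectrics, desolvation-driven pKa shifts,
correlated conformational dynamics, or tautomers. Passing tests therefore
demonstrate the correctness of the titration/linkage machinery and the
internal consistency of the pipeline on known ground truth — not the
accuracy of absolute pKas or optima for real proteins, which inherit the
quality of the upstream pKa source.

## Problem sizes and numerical defaults

Default pH grid 4.0–8.0, step 0.1 (integration-accuracy tests use 0.01);
enumeration cap 16 sites; random oracle fixtures 4–12 sites, 50 per
battery; scenario battery 20 seeds; MC 10 000 sweeps/grid point; consensus
recovery 100 trials of 9 predictors at 0.5 kcal/mol noise. These sizes keep
every battery exact (enumeration-backed) while exercising all code paths.

## Known limitations

* The uniform-dielectric point-charge model is a deliberately simple
  stand-in for continuum electrostatics; absolute folded-state pKas should
  come from an external tool via the pKa-table interface when fidelity
  matters.
* Only one chain is analysed per run; oligomer interfaces are not modelled.
* His tautomers are not distinguished; termini default to excluded.
* The variant machinery edits site lists, not geometry; steric/packing
  effects of substitutions enter only through the consensus ΔΔG constant.
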