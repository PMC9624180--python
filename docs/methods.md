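# Methods

`sadsmar` determines anomalous-scatterer (AS) substructures from
single-wavelength anomalous diffraction (SAD) data with a |ρ|-based
dual-space recycling algorithm of the SMAR family (S for sum function, M
for modulus function, AR for "absolute ρ"), followed by classical
Fourier recycling. This note records the model, the numerical choices
and their rationale, what the synthetic verification data do and do not
emulate, and the known limitations.

## Physical model

A crystal holds N atoms of which N_A scatter anomalously. With the
phase convention F(H) = Σ_j f_j exp(+2πi H·r_j) and isotropic
displacement damping exp(−B s²), s = sinθ/λ, the structure factor
splits into a normal part F_N (all atoms, f0 + f′) and the imaginary
substructure part i·F″_A. For a Bijvoet pair the exact anomalous
difference |D| = ||F(+H)| − |F(−H)|| obeys, when the substructure is
much weaker than the total scattering,

    |D| ≈ 2 |F″_A| |sin ψ| ,

ψ being the phase angle between F_N and the substructure's normal part
F_A. Because ψ is essentially random across reflections (protein and
substructure phases are uncorrelated, so ⟨sin²ψ⟩ = 1/2), |D| carries
|F″_A| information modulated by an unknown |sin ψ| factor — this is the
signal all downstream stages work from. The package computes both the
exact and approximate |D| by direct summation (`sf_oracle`); the
approximation is trusted when |F″_A|/|F|_av ≤ 0.3 (configurable — the
exact validity conditions are magnitude-ratio statements, and this
surrogate reproduces the intended regime).

By default f0 is a constant electron count per element: every quantity
the method consumes (|E|, X, CC_h) is a normalized ratio, so the
resolution dependence of f0 cancels to first order, and a constant f0
keeps the oracle exactly invertible. Four-Gaussian international-tables
form factors are available (`f0_model="it92"` via gemmi) when absolute
amplitudes matter.

## From |D| to the working data set

1. **Shells.** Equal-count resolution shells in s² (default 15, at
   least 50 reflections per shell; tiny data sets fall back to up to 5
   shells). Equal counts stabilize shell averages of the very noisy
   |D|² at small problem sizes.
2. **Normalization.** |E|² = |F|²_av / (ε ⟨|F|²_av/ε⟩_shell) with ε the
   symmetry enhancement factor recomputed from the space group.
3. **Selection** (fixed order; each stage sees the survivors of the
   previous one):
   ECUT — keep |E| ≥ 0.25 (removes ≈ 5–7% of acentrics under Wilson
   statistics, P(|E| < 0.25) = 1 − e^(−0.0625) ≈ 6.1%);
   DFCUT — keep |D| > 0.4·σ(|D|) with σ(|D|) = (σ²_F+ + σ²_F−)^½ (the
   estimator is not prescribed anywhere authoritative; the quadrature
   sum is the standard choice for a difference of independent
   measurements);
   outlier — drop |D|/r.m.s.(|D|) > 4.0, with the r.m.s. computed over
   the DFCUT survivors (plain root mean square).
   The order is observable: computing the r.m.s. before DFCUT changes
   the survivor set, and a unit test pins the specified order.
4. **Wilson scaling.** ⟨|D|²⟩_s ≈ 2 K ε̄ Σ_j σ″²_j exp(−2Bs²), where
   σ″_j are per-site anomalous strengths normalized by the strongest
   site (occupancy included). A least-squares line through
   ln[⟨|D|²⟩_s/(2 ε̄_s Σσ″²)] vs ⟨s²⟩_s gives slope −2B and intercept
   ln K; shells with fewer than 3 usable reflections are dropped.
   Numerical constants of order one (the ⟨sin²ψ⟩ = 1/2, the 2-vs-4
   factors) are deliberately absorbed into K: only the renormalized X
   below is ever consumed, so the literal K scale is immaterial, while
   the amplitude-scaling law (|D| → 2|D| ⇒ K → 4K exactly, B unchanged)
   is preserved and tested.
5. **X values.** X² ∝ |D|²/(K ε Σσ″² exp(−2Bs²)), then rescaled per
   shell so that the shell mean of X² is exactly 1. This per-shell
   renormalization is the operative meaning of ⟨X²⟩ = 1 and makes X
   invariant under any global rescaling of the input amplitudes; it
   also settles the √2 ambiguity between "X estimates |E″||sinψ|" and
   "⟨X²⟩ = 1 although ⟨sin²ψ⟩ = 1/2" in favour of the normalization
   contract.
6. **|X_m|.** The modulus function M is synthesized from (X, current
   phases), its negative regions are set to zero, and the
   back-transform amplitudes at the same reflections are |X_m|. They
   are computed once per trial, from the trial's starting phases, so
   that each refinement cycle keeps exactly four Fourier transforms.

## The SMAR cycle

Refinement runs under **lattice symmetry only**: the unique reflections
are expanded to a P1 Friedel hemisphere (amplitudes copied, phases
free) and the solution may land anywhere in the cell and in either
hand; space-group symmetry re-enters only at evaluation. Each cycle:

(i) synthesize ρ_Φ from |X_m| restricted to Φ_h = {H : X > XCUT}
(XCUT = 1.00) with current phases; store the ternary mask m = +1 where
ρ_Φ > 0, 0 down to −tσ, −1 below (t = 2.65, σ² = var ρ_Φ);
(ii) Fourier-transform |ρ_Φ| and take the updated phases for all
reflections; (iii) synthesize ρ_X from the experimental X with those
phases and form η = m·ρ_X; (iv) apply the peakness-enhancing ipp
modification to η, transform, adopt the new phases and X_calc, and
record CC_h = Pearson(X, X_calc over Φ_h). Eq-16-style weighting is not
specified anywhere legible, so CC_h is the plain correlation.

**ipp (inner-pixel preservation).** The canonical operator is defined
in work not available here; the package implements a faithful
parameterized surrogate honouring the name and stated purpose: within
every connected region of positive density (6-connectivity, periodic),
nodes at or above q × (region maximum) are preserved and the remaining
region nodes are scaled by γ; negative density passes through. Defaults
q = 0.6, γ = 0.15. The choice of γ deserves a note: with γ = 0 the
iterate never settles — CC_h fluctuates by ±0.015 cycle-to-cycle and
solved trials scatter over ≈ 0.05 in CC_h, which defeats any
correlation-based convergence bookkeeping — while a large γ (≳ 0.3)
lets so much experimental amplitude leak through η that CC_h becomes
insensitive to solution correctness (signal-destroyed controls reach
the same level). q = 0.6, γ = 0.15 sits between those failure modes:
solved trials cluster within about 0.01 of the best trial's level and
shuffled-|D| controls stay roughly 0.02–0.03 below it. Both parameters
remain configurable so the canonical operator can be slotted in.

**Initialization.** A trial draws a uniform random shift Δ in the cell
and seeds phases φ_H = −2π H·Δ (the randomly shifted modulus function);
one absolute-value recycling step (synthesize from (X, φ_seed), take
|ρ|, back-transform) turns these into the starting phase set, and the
clipped-negative variant of the same synthesis yields |X_m|.

**Convergence bookkeeping.** A trial stops at a CC_h plateau
(|ΔCC_h| < 10⁻⁴ over 10 cycles) or at max_cycles (default 150). Because
the iterate is a high-dimensional map with stochastic-looking
fluctuations at the 10⁻³ level, the strict plateau rarely triggers and
the attractor level is estimated as the best sustained 10-cycle running
mean of CC_h over the trial history; trials within 0.01 of the best
trial's level are classified converged, and an external reference level
can be supplied instead (negative controls are classified against the
intact-data level).

## Fourier recycling and interpretation

Γ = [K ε Σσ″² exp(−2Bs²)]^½ · X puts X back on an absolute-like scale
so the Γ-weighted map behaves like a substructure density. Each
recycling cycle (the pipeline runs 8, within the customary 5–10)
synthesizes the map, picks the strongest peaks, and recomputes phases
by direct summation over the picked peaks weighted by their heights.
Two model widths are tried per trial: a tight one (1.2 × the whole-cell
expected site count) that condenses a clean solution, and a generous
one (2 ×) that keeps the dominant copy of a partially superposed
solution alive. Final sites are local maxima above 5.0 σ (quadratic
sub-node interpolation, heights reported in ρ_peak/σ so they are
scale-invariant). Occupancies are estimated by normalizing the sum of
peak heights to the known total scatterer content, truncating values
above 1.00. The residual R_CC = 100·(1 − CC(X, X_calc)) over
reflections with X ≥ 0.7 scores each recycled model; only the
"correlation-based over the strong-X subset" structure of this residual
is authoritative, so the formula sits behind one function
(`fourier_refine.r_cc`) for easy substitution.

**Trial selection.** The pipeline recycles *every* trial and keeps the
model with the lowest R_CC, rather than the trial with the highest
CC_h. At the converged plateau CC_h is nearly degenerate across trials,
and on noisy data a ghost superposition (two origin/hand copies of the
substructure) can even out-score the clean solution on CC_h because the
extra density overfits the random |sin ψ| modulation of X; R_CC ranks
the recycled point-atom models by how well a single consistent
substructure explains the data, which is exactly the question at this
stage.

## Evaluation

Found sites are compared with reference sites modulo the full ambiguity
group: permissible origin translations (hard-coded tables for P1, P2₁,
C2, P2₁2₁2₁, P2₁2₁2, C222₁, P4₁2₁2/P4₃2₁2, P6₁22/P6₅22, unit-tested
against the conjugation identity (R−I)t ≡ 0), continuous shifts along
polar directions (candidate shifts seeded from site differences,
refined by Nelder–Mead), enantiomorph inversion (translations negated),
and symmetry images. Assignment is greedy nearest-neighbour within a
1.5 Å capture radius; the r.m.s.d. is over matched pairs. Because
recycling runs in P1, a whole-cell solution is evaluated against the
space-group-expanded reference with a free 3-D origin.

## Synthetic data: what it emulates and what it does not

`synthetic_data` builds protein-like crystals — many carbon-like light
atoms (f0 = 6) plus a few strong, mutually well-separated AS — and
simulates merged Bijvoet pairs with independent Gaussian noise on the
amplitudes (σ = noise_fraction·|F|, recorded truthfully). Presets:

- `se_like_small` — 8 Se-like sites (f″ = 3.9 e⁻) among 400 light atoms
  in a 40×50×60 Å P1 cell, B = 15 Å², d_min = 2.5 Å, 5% noise. The
  workhorse recovery fixture: small enough to phase in minutes, with an
  anomalous signal (Bijvoet ratio ≈ 0.07–0.09) deliberately stronger
  than typical experiments so recovery is decided by the algorithm, not
  by CPU budget.
- `se_like` — the same substructure among 1200 light atoms at 2.5%
  noise: a realistic protein:substructure scattering ratio whose
  Bijvoet ratio (≈ 0.05) and precision indicator ⟨|D|⟩/⟨σ|D|⟩ (≈ 1.6)
  sit where usable experimental Se-SAD data sit (the indicator should
  exceed 1.5). Selection-percentage statements are made here.
- `s_like_weak` (3 S sites, f″ = 1.1, 0.5% noise) and `iodide_like`
  (6 I sites, f″ = 6.9, occupancies graded 0.3–1.0, 2% noise) mirror
  the weak-sulfur and halide-soak regimes.
- `tiny` — 2 sites among 30 atoms, for smoke tests.

Noise fractions of the realistic presets were set from the indicator
thresholds above, not from any recovery outcome. Deviations from real
data that the generator does **not** emulate: intensity-space counting
statistics and merging (noise is Gaussian on amplitudes, because the
selection operates on amplitude-space σ(|D|); an intensity-space option
exists), radiation damage, anisotropic displacement, solvent
contribution, unmerged multiplicity, and crystallographic special
positions (presets are P1; space-group machinery is exercised by unit
tests and the evaluation module). Passing recovery tests therefore
demonstrate the correctness and self-consistency of the algorithmic
chain under controlled conditions, not performance on experimental
data.

All randomness is seeded: a fixture seed fixes the crystal and noise
streams (coordinates at seed+1, noise at seed+2), and each phasing
trial i uses base_seed+i.

## Problem sizes and degenerate inputs

Verification runs use the `se_like_small` fixture (≈ 16 000 unique
acentric reflections, 48×60×72 grid) with 25 trials of up to 150
cycles — a few minutes per run — and the `tiny` fixture for mechanics.
Degenerate inputs are handled explicitly: zero-σ data make
⟨|D|⟩/⟨σ(|D|)⟩ NaN (reported, not raised) and DFCUT reduces to |D| > 0;
constant density grids degrade the mask to sign(ρ) with a warning;
zero-variance CC_h inputs report NaN; empty selections raise with
advice to relax thresholds; grids coarser than d_min/2 are rejected.

## Known limitations

- CC_h on these fixtures levels around 0.67 rather than the ≈ 0.88 seen
  on experimental data sets; the level depends on how much experimental
  amplitude modulation survives the mask/ipp product, so absolute CC_h
  levels are not comparable across data regimes — only relative gaps
  (converged vs failed vs signal-destroyed) are meaningful, and those
  are what the package asserts.
- On the synthetic fixtures essentially every random-shift trial
  converges to a correct solution and the CC_h distribution is a
  unimodal continuum; the converged/non-converged split is then a
  knife-edge on that continuum rather than the bimodal separation seen
  with genuinely hard data.
- At amplitude noise levels that push ⟨|D|⟩/⟨σ(|D|)⟩ below the ≈ 1.5
  usability threshold (e.g. 5% amplitude noise on the small fixture,
  giving ≈ 1.2), most random-shift trials settle into two-copy
  origin/hand superposition states. The clean single-copy state is
  stable — runs seeded at the true phases hold all sites at every ipp
  setting tested — but is rarely reached from random shifts, and the
  best single consistent copy extractable from a superposed map
  typically carries 5–7 of 8 sites (at ≈ 0.1–0.2 Å accuracy). Data
  meeting the usability indicator do not show this failure mode.
- Disulfide-bridged sulfur pairs (overlapping peaks) defeat the
  spherical-peak assumption of ipp; no special handling is attempted.
- The evaluation origin tables cover the space groups listed above;
  other groups raise a clear error rather than guessing.
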