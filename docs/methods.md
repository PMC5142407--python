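# Methods

This note documents the models implemented in `pepgcm`, the choices made
where the published description left the design open, and what the packaged
synthetic generators do and do not emulate.

## The group-contribution model

The target quantity is the Gibbs free-energy change of inserting a peptide
at a dodecane–water interface (kJ/mol; more negative = stronger interface
affinity). The model assumes the molecular value decomposes over residues,

ΔG_molecule = Σ_i Σ_{j∈{C1,C2}} n_(i,j) · ΔG_i / α_(i,j),

with three ingredients:

- **ΔG_i** — per-residue contributions measured by alchemical MD of single
  amino acids in a dodecane–water box (packaged in `data/residues.csv`, with
  their MD uncertainties). They are inputs to this package, not outputs: no
  attempt is made to recompute them, and all twenty are negative.
- **C1/C2 classification** — residue *k* is C1 when residue *k+1* shares
  its binary hydropathy, C2 otherwise; the final residue, having no
  follower, is coupled backwards and classed against its predecessor. The
  penultimate residue keeps its forward comparison; both comparisons use
  the same residue pair, so no conflict can arise. One-residue sequences
  are rejected rather than guessed. Plain additivity over-predicts
  interface affinity by roughly 3–4×, and by different margins for
  same-hydropathy and mixed neighbourhoods (see the pair analysis below);
  conditioning α on the neighbour class is the model's minimal way of
  encoding that coupling.
- **α_(i,j)** — 40 positive scale factors (20 residues × 2 classes),
  packaged in `data/alphas.csv`. C2 values are systematically slightly
  smaller than C1 values, i.e. a residue contributes more strongly when its
  neighbour differs in hydropathy.

Evaluating the sum by grouped counts or per-position is algebraically
identical; both are exposed and property-tested. A second evaluation mode
(`reciprocal`, contribution ΔG_i·α/100) is kept as an alternative reading
of the α convention; `as_printed` (divide by α) is the default and is the
form that reproduces the packaged reference energies — on the 21-peptide
reference set it matches the tabulated model values to a median 0.6%, and
the longest peptide (35 residues) to 0.7%. The two modes coincide under
α′ = 100/α, which the suite asserts on random sequences.

### Hydropathy partition

The binary partition is a loadable column, defaulting to
nonpolar = {A,C,F,G,I,L,M,P,V,W}, polar = {D,E,H,K,N,Q,R,S,T,Y} — the
standard side-chain split, consistent with every classification anchor the
reference decapeptide KLGWSQYHDT fixes (K,S,Q,Y,H,D,T hydrophilic; L,G,W
hydrophobic). Users with a different convention override the column.

### Folding correction

Additivity cannot see self-interactions of a folded chain. As a cheap
folding proxy the package correlates residue position (1..n) against the
per-residue Chou–Fasman β-turn propensity P(turn) (the packaged turn scale;
also overridable). When the Pearson r exceeds 0.40, a correction of
292.8·r − 86.6 kJ/mol (positive on that branch) is subtracted from — or,
configurably, added to — the model energy. Zero-variance propensity vectors
return r = 0 by convention. On the packaged reference set only two of the
21 peptides cross the threshold, so the correction rarely fires; its
default direction (`subtract`) pushes predictions more negative, the
direction that closes the residual gap on the reference set. `off`
disables it.

## Pair ideality analysis

For each Ala–X dipeptide the deviation from ideal additivity is
(ΔG_Ala + ΔG_X) − ΔG_pair(Ala–X); all twenty packaged deviations are
negative, i.e. the measured pairs bind the interface less strongly than the
sum of their parts. The outlier screen uses Tukey boxplot fences
[Q1 − k·IQR, Q3 + k·IQR] with k = 1.5 and **hinge** quartiles (median of
each half, median shared when n is odd) — the convention a boxplot actually
draws; on the packaged table it flags the Arg, Asp and Glu pairs, the three
largest side chains with the strongest electrostatics. Of the seventeen
survivors, the largest absolute deviation (Ala–Trp) represents
same-hydropathy coupling and the smallest (Ala–Lys) mixed coupling;
exact ties break alphabetically (impossible on the packaged data). With an
infinite fence multiplier the screen returns no outliers, including the
degenerate IQR = 0 case.

## α calibration

`fit_alpha` minimises Σ_p (ΔG_ref,p − model_p(α))² by bounded nonlinear
least squares (scipy `trf`, analytic Jacobian, α ≥ 10⁻⁶), started from the
packaged table, optionally with a ridge penalty λ·Σ(α − α_prior)² toward
the prior (default λ = 0). The model is linear in 1/α (as-printed) or α
(reciprocal), so the problem is smooth and fast. A parameter whose (residue,
class) combination never occurs in the reference set is unidentifiable:
with no regularization the fit raises an error listing the entries (or, on
request, holds them at the prior and reports them). Because trf is a
descent method from the prior start point, the fitted objective never
exceeds the prior's — asserted on the packaged 21-peptide set, where 4 of
40 combinations are unobserved. Fits are deterministic given inputs;
permuting the peptides changes only floating-point summation order, so
order equivariance is asserted to solver numerics rather than bit-exactly.

### Synthetic reference generator

`generate_reference_set` draws sequences uniformly over the twenty residues
(composition weights optional), lengths uniform on a range, and energies
from the model under chosen "true" α plus i.i.d. Gaussian noise — an
idealised stand-in for an MD-simulated training set. It reproduces exactly
per seed. What it does *not* emulate: real peptides' biased composition,
correlated MD errors, or any model misspecification — so recovery tests
certify the estimator (identifiability, bias → 0 with noise, 10% recovery
at σ = 5 kJ/mol from 500 peptides of length 8–20, even with truth displaced
35% from the start point), not accuracy on laboratory data.

## Bennett acceptance ratio

A segment between coupling states λ_i → λ_j is estimated from forward
samples w_F = U(λ_j) − U(λ_i) (drawn in state i) and reverse samples
w_R = U(λ_i) − U(λ_j) (drawn in state j) by solving

Σ_F f(w_F + M − ΔG) = Σ_R f(w_R − M + ΔG),  M = kT·ln(N_i/N_j),

with the Fermi function f(x) = 1/(1 + e^{x/kT}). The left side rises and
the right side falls monotonically in ΔG, so the root is unique; it is
found by bisection with an initial bracket ±(max|ΔU|/kT + 10), doubled
until it encloses a sign change, tolerance 10⁻⁸ kT, at most 200 iterations
(non-convergence raises, carrying the final bracket). Both Fermi averages
are evaluated in log space (`log_expit` + `logsumexp`), so samples tens of
thousands of kT from the root cannot underflow. The reported shift constant
C satisfies ΔG = kT·ln(N_j/N_i) + C exactly by construction. Two
presentation details of the published equations are treated as typos, being
dimensionally or mutually inconsistent: the Fermi argument is divided (not
multiplied) by kT, and the sign of the ln(N_j/N_i) term follows from the
partition-function definition of C. A per-segment standard error comes from
first-order propagation through the two Fermi averages; it is used only for
±3 SE stochastic assertions. A multi-state path (default: six equidistant
λ states) sums its segment estimates.

`bar_at` evaluates the general fixed-C form
ΔG = kT·ln(⟨f(w_R + C)⟩_R / ⟨f(w_F − C)⟩_F) + C, unbiased in expectation
for any C; as C falls below the sample support it collapses to the forward
exponential (Zwanzig) average, which the suite asserts within 0.1 kT.
The *self-consistent* root does not have that limit — under one-sided
dominance it tends to the midpoint of the two one-sided estimates — which
is why the Zwanzig comparison is made through the fixed-C form.

The overlap diagnostic is a histogram intersection Σ_b min(p_i, p_j) on a
shared 50-bin grid spanning the pooled range: 1 for identical samples, 0
for disjoint supports. It is a descriptive adequacy check for adjacent λ
states, not a variance estimate.

### Synthetic work generator

`synth_work` draws forward work from N(ΔF + σ²/2, σ²) and reverse work from
N(−ΔF + σ²/2, σ²) (kT units, converted to kJ/mol) — the unique Gaussian
pair satisfying the Crooks fluctuation theorem with free-energy difference
ΔF, giving an analytic truth for estimator tests (recovery of ΔF ∈ {1,2,5}
kT within 3 SE at 5×10⁴ samples per side). It emulates none of the serial
correlation, anharmonicity or soft-core artefacts of real alchemical MD
output; file-based input (plain text or GROMACS xvg dialect, one segment
per file pair) is the route for real data.

## Numerical conventions and sizes

- Energies in kJ/mol throughout; kB = 0.0083144621 kJ/(mol·K); default
  temperature 300 K (the NPT setting of the underlying simulations).
- Report display: energies two decimals, percent errors one decimal,
  summary means to the nearest integer, half-up rounding.
- Relative error is reported as a magnitude, |(ΔG_sim − ΔG_calc)/ΔG_sim|·100.
- Test problem sizes (500-peptide fits, 5×10⁴-sample BAR segments, 10⁵-point
  overlap checks) were chosen so each stochastic criterion has comfortable
  statistical margin while the whole suite runs in well under a minute of
  CPU.

## Known limitations

- The model is calibrated for short peptides at a dodecane–water interface;
  the packaged reference set shows it degrades badly for a folded porin
  (73% error), and the folding proxy is a blunt instrument.
- The hydropathy partition and turn scale are conventions, not fitted
  quantities; both are deliberately user-overridable.
- The α table and the per-residue ΔG values are treated as data; only the
  α values are refittable through this package.
- Appending a residue usually lowers the model energy, but reclassification
  of the former terminal residue can raise it; monotonicity holds only for
  class-preserving extensions.
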