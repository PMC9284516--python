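# Methods

`deeroligo` links two kinds of evidence about Cu(II)-loaded amyloid-beta
oligomers: a pulsed-EPR DEER measurement of the Cu-Cu distance
distribution, and structural ensembles of tetramers built as dimers of
dimers (chains A-D).  This note records the models, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## DEER forward model

The intramolecular dipolar form factor is

    F(t) = ∫ p(r) K(t, r) dr,
    K(t, r) = ∫₀¹ cos( 2π ν₀ r⁻³ (1 − 3x²) t ) dx,   x = cos θ,

with the free-electron point-dipole constant ν₀ = 52.04 MHz·nm³ and
exchange coupling set to zero.  Orientation selection is neglected:
for Cu²⁺ pairs whose coordination-plane normals are spread by ~20° and
more, orientation weighting of the Q-band trace is a second-order
effect, and the model-free analysis with an isotropic kernel is the
standard approximation.  Whether a Cu-specific effective constant
would fit a given spectrometer setup better is not resolvable from the
data the package targets; the free-electron constant is used
throughout.

The orientation average is a fixed 1001-node Gauss-Legendre quadrature
in cos θ, which resolves the kernel to better than 1e-9 over the 1-8 nm
by 0-4 µs window (verified against the Fresnel-integral closed form and
a 10⁶-orientation Monte-Carlo average).  At phases far beyond that
window (very small r with very long t) the fixed order undersamples the
integrand; the acquisition grids in scope stay well inside it.

The measured signal is modeled as

    V(t) = B(τ) (1 − λ + λ F(τ)) + ε,   B(τ) = exp(−k τ),

with τ the dipolar evolution time, λ the modulation depth, and an
exponential background from a homogeneous three-dimensional bulk spin
distribution.  The zero of dipolar evolution is fixed at the first
recorded sample (the initial spectrometer delay, 100 ns on the default
grid, is treated as an instrument offset); no zero-time refinement is
attempted.  The default acquisition grid is the experimental one:
t₀ = 100 ns, Δt = 10 ns, 200 points.  The experiment does not fix λ,
k, or the noise level; the defaults λ = 0.3, k = 5·10⁻⁴ /ns and white
noise of 1% of V(0) are realistic values for Q-band Cu-Cu DEER at these
acquisition times and are used as the study conditions everywhere.

## Inversion

Background and modulation depth are fitted jointly as
(1 − λ)·exp(−k τ) on the tail τ ≥ 0.5·τ_max (the window is a package
default; λ bounded to (0.01, 0.99), k ≥ 0 with a warning when the tail
does not decay).  A fitted λ at its lower bound signals a trace with no
dipolar modulation and raises instead of dividing by ~0.  The corrected
form factor F = (V/B − (1 − λ))/λ is rescaled to F(0) = 1.

The distance distribution solves

    min over p ≥ 0 of ‖K_w p − F‖² + α² ‖L p‖²,

with K_w the kernel matrix carrying trapezoid weights, L the unscaled
second-difference operator, and the non-negativity enforced by
nonnegative least squares on the stacked system [K_w; αL].  The output
is renormalized to unit integral.  The default grid is 1-8 nm with 201
points (0.035 nm spacing), the distance window DEER is sensitive to at
these trace lengths; the grid spacing is the resolution of any reported
mode.  On small instances the solver is verified to 1e-6 against an
exhaustive active-set enumeration (every support set, KKT-checked).

α is chosen at the L-curve corner: the point of maximum Menger
curvature of the (log residual, log penalty) curve over a log-spaced
grid (default 10⁻⁴-10², 25 values).  Two robustness measures matter in
practice: both log axes are normalized to the unit square, and the
curvature at each point uses the nearest neighbours at least 0.1 of
arc-length away.  Without these, noise-scale wiggles in the nearly flat
small-α stretch of an NNLS L-curve (where consecutive points nearly
coincide) masquerade as high-curvature corners and the selection
becomes erratic.  Ties break to smaller α; a fully degenerate curve
falls back to the grid midpoint with a warning.  A trace with F ≡ 1
(no decay) pushes all mass to the upper grid edge — the documented
no-signal behavior.

Modes are global maxima (ties to the smallest r); multimodality is
counted by peak finding with a prominence threshold of 10% of the
maximum, boundary peaks included.

## Synthetic ensembles

The generator emulates the observables the analysis consumes, not
peptide physics.  Intra-dimer Cu-Cu distances (AB, CD) are exact draws
from a truncated normal (lower bound 0.3 nm, hard-sphere contact).
The four cross-dimer distances are built sequentially — AC free, then
BC, AD, BD each drawn from the inter-dimer law restricted to its
geometric feasibility interval (triangle and sphere-circle bounds
given the already-placed Cu) — so every cross distance is a draw from
the law conditioned on realizability.  Naive independent draws of all
six pair distances are non-Euclidean about 65% of the time and
conditioning on rejection biases the accepted means by several
standard errors; the sequential construction keeps pooled means
unbiased to well below the cluster-level sampling error (residual bias
~0.01 nm on the 3.6 nm law; the drawn-law sd is mildly shrunk, ~0.85
for a nominal 0.9).  Because the four cross distances of one
configuration share a rigid placement they are correlated, and the
honest standard error of a pooled mean is the cluster SE over
per-configuration means — the recovery tests use that.

Each dimer draws a base coordination-plane normal uniformly on the
sphere; one site uses it exactly, the partner is tilted about a random
in-plane axis by N(0, plane_angle_sd), so the within-dimer relative
angle has RMS equal to the parameter (default 20°, the observed spread)
while across-dimer normals are uncorrelated.  The reported orientation
statistic is the signed scalar product of unit normals with the His6
ligand first in the cross product, and the angle spread is the RMS of
arccos(s) about perfect alignment.

Chains are clouds of 42 beads (one per residue of the 42-residue
peptide, radius 0.34 nm) uniform in a 1.4 nm sphere anchored halfway
between the chain's Cu site and the tetramer Cu centroid, mimicking
peptide mass filling the space between metal centers; Cu-free chains of
the 1:2 stoichiometry anchor to their dimer partner's Cu.  A
compactness factor c in (0, 1] rescales the dimer-center separation by
1/c after Cu placement: c = 1 (default) leaves the distance laws exact
and produces dimers in contact; small c (0.25 in the separated
fixtures) pulls them ~10 nm apart.  What the blobs do not emulate:
chain connectivity, secondary structure, residue-specific packing, and
any coupling between Cu coordination and backbone conformation —
passing tests therefore validate the measurement chain on geometrically
faithful inputs, not the realism of any particular peptide model.

Stoichiometries follow the three binding models: Cu1 and Cub carry one
Cu per chain (they differ only through the distance/orientation laws
supplied); Cuh carries Cu on chains A and C only, so its intra-dimer
pair class is empty and only AC contributes across dimers.

Ensembles round-trip through multi-model PDB (coordinates in Å,
converted to nm on read).  The naming convention: beads are ALA/CA ATOM
records; each Cu site is three HETATMs on its chain — CU (resseq 901),
ND1 in residue L06 (the His6-role Nδ, resseq 902), NE2 in residue L13
(the His13-role Nε, resseq 903).  Fixed seeds give byte-identical
files.

## SASA, compactness filter, Rg

SASA is Shrake-Rupley with a deterministic golden-section-spiral point
set (960 points, probe 1.4 Å), evaluated on the bead spheres of the
selected chains in isolation; exact duplicate spheres are counted once.
A configuration is an assembled tetramer when
SASA(ABCD)/(SASA(AB) + SASA(CD)) < 0.95 (strict), each term on the
configuration's own coordinates with the complementary chains deleted.
The implementation is cross-checked against an independent
Shrake-Rupley (Biopython's, different point set) to ~1%, against the
single-sphere closed form, and against exact additivity for separated
bodies.  The radius of gyration is mass-unweighted (coarse beads carry
no masses) over bead centers, in nm.

The published accepted-tetramer fractions for the three binding models
depend on trajectories that are not distributed; they are not
reproduction targets.  The filter is instead validated by construction:
contact-built fixtures are accepted and 10 nm-separated ones rejected,
with the ratio decreasing monotonically as dimers approach.

## Statistics

Distance samples are compared with the two-sided Mann-Whitney U test by
default (the analysis precedent names no test; Kolmogorov-Smirnov is
selectable), pooling AB and CD as separate observations, with an
optional subsampling stride against serial correlation.  Significance
is flagged at p < 0.05.  Calibration is simulated: type-I error at the
nominal level within binomial error, p-values uniform under the null,
and essentially full power for the effect sizes the distance laws of
the competing binding models imply.

Representative configurations are those in the maximally populated bin
of a 20×20 histogram of two structural quantities (intra-dimer Cu-Cu
distance and Rg by default), ties to the lowest bin index, optionally
intersected with a distance window around a distribution maximum.

## Pipeline and problem sizes

The end-to-end run generates (or reads) an ensemble, derives its
distance model — the unit-integral intra-dimer histogram (inter-dimer
for Cuh) interpolated onto the inversion grid — simulates a trace from
it, inverts, and reports the mode difference and the overlap
coefficient ∫ min(p₁, p₂) dr.  Both comparison metrics are package
additions; the underlying comparison in the source analysis is
qualitative.  Reports carry the config hash and seed, and rerunning a
config reproduces every number bit for bit.

Default problem sizes — 1000 configurations for parameter recovery,
400 for end-to-end runs, 50 + 50 SASA fixtures, 20-seed inversion
replication, 200 + 100 calibration replicates — were chosen so each
check's sampling error sits well below the tolerance it asserts.  The
SASA filter inside the pipeline caps at `filter_max_configs`
(default 100) because the filter scales linearly in configurations and
the distance statistics do not need it.

## Known limitations

- No orientation-selection DEER treatment; no multispin (>2)
  contributions; no Bruker binary I/O; no model-based (multi-Gaussian)
  fitting or ghost-peak validation.
- The L-curve corner is grid-resolved: α is reported only at grid
  values.
- The bead-cloud SASA ratio threshold was taken from the all-atom
  convention (0.95); its bead-level behavior is validated only on
  clearly compact vs clearly separated geometries, where it is
  unambiguous.
- Distances below the 1 nm grid edge are invisible to the inversion;
  short-distance mass folds into an edge feature, which is exactly how
  the short-peak (non-cross-linked-like) worlds are flagged.
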