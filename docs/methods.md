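# Methods

This note documents the models, conventions and numerical choices behind
`packrate`, and what the synthetic-data tests do and do not establish.

## Two-node residue representation

Each residue of the selected chain with a resolved C-alpha becomes one site
with two pseudo-atoms: the main-chain node `alpha` at the C-alpha
coordinate, and the side-chain node `rho` at the *unweighted* mean of the
side-chain heavy atoms (every atom not in {N, CA, C, O, OXT}; hydrogens
excluded, since most crystal structures lack them). Glycine, and any residue
whose side-chain atoms are all unresolved, carries a single merged node
(`rho = alpha`, flagged `has_distinct_rho = False`); collapsing rather than
dropping such residues keeps the site list in register with per-site rate
profiles. A mass-weighted center would be a defensible alternative
("geometric center" vs "center of mass" are used interchangeably in parts
of the literature); the unweighted mean is the default because it is the
common convention for side-chain centroids and is insensitive to element
assignment errors. Alternate locations resolve to the highest-occupancy
conformer (ties by altloc identifier), only the first model of multi-model
files is read, and common parent-mapped residues (MSE→MET, SEP→SER, ...)
are retained; other non-standard residues are skipped with a warning.

## Packing measures

All four WCN variants are pure inverse-square sums with **no distance
cutoff** — the elastic network they derive from is cutoff-free, and a cutoff
would break the exact stress-model proportionality below. Units are
1/Angstrom^2. Implementation is vectorized over full distance matrices;
coincident nodes belonging to distinct sites raise `degenerate geometry`
naming the offending pair.

A subtlety the underlying theory leaves open: when a *neighbor* site j has a
merged node, the alpharho-superscript measures can either evaluate the
rho_j term at the coincident position (counting that node once per
interaction class, i.e. twice) or drop it. The default, `gly_rho_term =
"duplicate"`, keeps the sums fixed-length across residue types and matches
the spring network, where the merged node carries both interaction classes;
`"once"` is available and tested. This is a documented convention, not an
empirical fact.

RSA is the residue's Shrake–Rupley solvent-accessible surface area (probe
radius 1.4 A, 960 sphere points, heavy atoms of the isolated selected chain
only — the intended inputs are monomeric enzymes) divided by the maximum
accessible area of its amino-acid type. The default normalization table is
the theoretical (tripeptide-derived) Tien et al. set, with the empirical set
as an option. Because those maxima include occlusion by flanking residues,
RSA can exceed 1 for unusually exposed residues (a genuinely isolated
residue measures ~1.5); such values are retained and flagged, with optional
clipping, since truncation would discard information.

## Stress model

The elastic network joins every node pair of distinct sites with a spring of
equilibrium length d and force constant k = 1/d^2 (so k d^2 = 1 exactly, by
construction); there are no intra-site springs. A mutation at site i adds
independent zero-mean increments delta to the equilibrium lengths of the
springs incident to rho_i. With the native conformation held fixed — no
minimization, normal modes or Hessian — the energy penalty is

    dV* = 1/2 sum_{j != i} (k_{rho_i alpha_j} delta^2_{.alpha} + k_{rho_i rho_j} delta^2_{.rho}),

whose expectation over mutations is (sigma^2/2) * WCN_rho_alpharho(i). Only
sigma^2 enters; the distribution family is irrelevant to the expectation,
which the tests verify with Gaussian and variance-matched uniform
increments. The default sigma = 0.3 A is a plausible scale for a
substitution's effect on equilibrium contact distances, but any value
exercises the theory identically because sigma cancels from every
correlation-based output. A merged-node neighbor contributes one physical
spring with two independent perturbation slots (one per interaction class),
which is exactly the duplicate-counting convention of the packing module —
the closed form and `wcn_rho_alpharho` therefore agree to round-off, not
merely to a tolerance.

The weak-selection proportionality constant between rate and -<dV*> is
never estimated: predicted rates are either the least-squares affine map of
-<dV*> onto a supplied empirical profile, or (absent one) the sign-flipped
stress vector shifted to mean 1. R^2 against empirical rates is invariant
to this choice. The fixation weight exp(-beta dV*) is exposed for
completeness; beta is otherwise a free parameter that cancels from all
reported quantities.

## Statistics

Predictive power is the squared *Pearson* correlation (a Spearman option
exists but is not the default). Unique contributions use the semipartial
convention — the control is regressed out of the predictor only — because
that squared quantity equals the R^2 increment from the one-variable to the
two-variable linear model, which is the interpretation attached to it;
partial correlation would not have this property. Collinearity is declared
when the residual variance of x given z falls below 1e-12 of x's variance.

Aggregation bootstraps the *protein* (never the site) with replacement.
Expected values are plain means over the original set; SDs are the standard
deviations of replicate means; p-values are one-sided (fraction of
replicates in which the difference statistic fails to be positive) and are
reported as 1/n_boot, an upper bound, when no replicate qualifies — never
as 0. Win counts are computed on the original set with exact ties counted
separately (ties have measure zero on real data but occur in degenerate
synthetic settings). Default n_boot = 10,000; tests use smaller values where
dispersion is not the quantity under test.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
protein chemistry. Geometries: an ideal alpha-helix trace (rise 1.5 A,
twist 100 degrees, radius 2.3 A, side chains radially outward), a uniform
sphere of C-alpha positions at 3.1 * n^(1/3) A radius (~125 A^3 per
residue, protein-like density) with a 3.5 A excluded volume, or a 3.8 A-step
self-avoiding walk. Side-chain offsets are N(2.0, 0.6^2) A truncated at
0.5 A; a configurable fraction of sites gets a merged node, as glycine
does. Rates follow the decreasing law rate = a - b*x + eps with Gaussian
noise, floored at 1e-6 (substitution rates are non-negative) and
renormalized to mean 1; when a target population R^2 is requested the noise
SD is derived per protein from b^2 Var(x) (1 - R^2)/R^2, and the default
intercept leaves a ~6-sigma positivity margin so the floor essentially
never binds.

Fixture PDBs encode each site as poly-Ala (or Gly for merged nodes) with CB
placed *at* the rho position, so the parser's centroid rule recovers the
generated geometry to PDB coordinate precision (1e-3 A) without involving
multi-atom averaging; separate hand-built multi-atom fixtures test the
averaging rule itself.

What passing the synthetic suite shows: the measures, the stress algebra,
the semipartial identity and the pipeline's statistical calibration are
implemented correctly, and the analysis recovers a planted packing→rate law
(50 proteins × 150 sites at population R^2 = 0.4 recovers the mean R^2
within ±0.05 and assigns every non-generating predictor a mean semipartial
rho^2 below 0.01). What it does not show: anything about real proteins —
real side-chain centroids are correlated with backbone geometry, empirical
rate profiles have heavier tails and site-to-site correlation, and real
predictor intercorrelations are stronger than in these geometries.

## Numerical choices and edge cases

- WCN/stress computations use full double-precision distance matrices; the
  oracle-equivalence tests pin them to a naive double loop at 1e-10
  relative.
- Coordinates in the node-dump TSV are written with `repr` (shortest
  round-trip form), making the dump bit-exact on re-read.
- Rate files: relative rates are always recomputed from the raw column;
  duplicate positions are an error, not a silent overwrite.
- Alignment of rates to sites joins on residue sequence number by default
  (`by_position`); `by_order` requires equal lengths. Only matched sites
  enter any statistic.
- Monte-Carlo stress estimates report the standard error of the mean; the
  100,000-draw acceptance check requires every site within 4 SEs of the
  closed form.
- Problem sizes in tests and the acceptance script (100 geometries up to
  500 sites for oracle checks; 50 proteins × 150 sites with n_boot = 1,000
  for recovery; 200 proteins with n_boot = 10,000 for calibration) were
  chosen as the smallest scales at which the statistical claims are sharp.

## Known limitations

- PDB input only (no mmCIF); single chain, first model; no structure repair.
- RSA depends mildly on the sphere-point count and conformer selection;
  values are not comparable across different normalization tables.
- The stress model treats mutation as spring-length perturbation at fixed
  conformation; models that relax the structure or move nodes are out of
  scope, as is any normal-mode analysis.
- One-sided bootstrap p-values are not corrected for multiple predictor
  pairs.
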