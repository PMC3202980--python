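# Methods

## The physical model

A cross-specific biosensor array is a panel of receptors (here modelled
after engineered GPCRs expressed in yeast reporter strains) with
overlapping specificities for a panel of ligands.  All ligands are assumed
to compete for a single binding site on each receptor, with no kinetics,
cooperativity, or receptor-number effects.  At equilibrium the probability
that receptor *j* is occupied by ligand *i* follows a grand-canonical
partition function:

    p_ij = w_ij / Z_j,   w_ij = exp((mu_i - dG_ij) / kT),   Z_j = 1 + sum_i w_ij

where `dG_ij` is the binding free energy (kcal/mol, favourable < 0) and
`mu_i = kT ln(c_i / 1 M)` the chemical potential of ligand *i*.  The
normalized reporter intensity is background plus efficacy-weighted
occupancy,

    I_j = bg_j + sum_i e_ij p_ij ,

with efficacy `e_ij` in [0, 1]: 1 for a full agonist, 0 for a full
antagonist that occupies the site without signalling and thereby
competitively suppresses agonists.  With a single ligand this reduces to a
logistic binding curve in `mu`; the reduction is exact (bit-level) in the
implementation and is tested as such.

Mixtures are parameterized by relative concentrations `x_i` (ratios to an
arbitrary reference ligand, `x_ref = 1`) and a total chemical potential:
`mu_i = mu_total + kT ln(x_i / sum_k x_k)`.  Absent ligands are encoded by
an exact `-inf` chemical-potential sentinel rather than a tiny epsilon, so
zeros are representable.  A dilution series fixes known increments
`delta_mu` between points; only the reference-point potential `mu0` is
unknown when decoding a real mixture, and `c_i = exp(mu0/kT) x_i / sum x`
converts the inferred parameters to absolute molar concentrations.

**Conventions.** `kT = 0.6 kcal/mol` by default (~302 K, a typical yeast
incubation temperature), configurable through `ModelConstants`.  The 1 M
standard state is a convention: fits depend only on relative potentials,
but the absolute concentration readout inherits it.  No constraint
`bg + sum e <= 1` is imposed; plate normalization makes intensities of
order one but the model does not require it.

## Likelihood and priors

Measurements are modelled as Gaussian around the predicted intensity with a
per-receptor noise scale `sigma_r`; the log-likelihood sums over all series
points and replicates, and over all receptors in the chosen subset.
Location-like parameters (dG, eff, bg, mu0) get uniform priors; scale-like
parameters (sigma, concentration ratios x) get Jeffreys (log-uniform)
priors.  Default bounds, chosen to cover the experimental dynamic range (a
million-fold concentration span) with margin:

| parameter | prior    | bounds              | units |
|-----------|----------|---------------------|-------|
| dG        | uniform  | [-16, -1]           | kcal/mol |
| eff       | uniform  | [0, 1]              | — |
| bg        | uniform  | [0, 0.5]            | normalized intensity |
| sigma     | Jeffreys | [5e-3, 0.5]         | normalized intensity |
| x         | Jeffreys | [1e-4, 1e4]         | — |
| mu0       | uniform  | kT ln [1e-9, 1e-1]  | kcal/mol (molar window) |

The x floor of 1e-4 doubles as the operational "zero": decoding always fits
the full ligand panel, and truly absent ligands collapse toward the floor.
A ligand is reported absent when its posterior mean concentration is below
5% of the total **and** its 95% credible interval reaches within a factor 3
of the floor.  The two-part rule avoids calling a ligand absent when the
data merely bound it below the detection limit but away from zero.

## Nested sampling

Posteriors and evidences are computed by a standard nested sampler
implemented in-package: `n_live` points (default 100) are drawn from the
prior via the unit-cube quantile transform (which makes Jeffreys priors
exact log-uniform draws); the worst live point is repeatedly replaced by a
Metropolis walk under the hard likelihood constraint (20 steps by default,
per-dimension scales adapted towards ~50% acceptance, reflecting
boundaries); the evidence accumulates over the geometrically shrinking
prior mass, terminating when the best remaining contribution would change
log Z by less than 1e-4.  The reported log-evidence error is the usual
sqrt(H / n_live) with H the information.  Runs are deterministic given the
seed.  Summaries (means, stds, quantiles) come from the weighted samples;
an optional single-chain Metropolis refinement (50 000 models by default,
started from the likelihood maximum found by nested sampling) reproduces
posterior histograms.

Routine fits and scans use a reduced preset (50 live points, 15 steps);
spot checks against the full preset showed no change in the conclusions,
only in run time.  The evidence of a flat likelihood is recovered at zero
in log to well within the estimator error for both prior kinds, and the
Gaussian-likelihood toy matches its closed form.

## Calibration

Single-receptor, single-ligand dilution curves (9 log-spaced totals over
1 nM–1 mM, 4 replicates = 36 points by default) determine
(dG, eff, bg, sigma) per receptor-ligand pair.  Calibration mixtures are
prepared by the experimenter, so total concentrations — hence mu0 — are
treated as exactly known; only decoding infers mu0.  Point estimates are
posterior means (stabler under sampling noise than the mode; MAP estimates
are available).  Per-receptor background and noise are averaged over that
receptor's fits, mirroring how a shared assay background is estimated from
all experiments involving the receptor.

A full antagonist yields a flat curve and an unidentifiable dG; it is
calibrated instead from a binary mixture with a known agonist, where its
binding strength is read off the suppression of the agonist signal.  Among
candidate agonist partners the one minimizing the posterior std of the
antagonist's dG is selected.  Plate bias — systematic per-plate gain and
offset shifts — is refit with dG and sigma held fixed; the response is then
linear in (eff, bg) per plate, so the maximum-likelihood adjustment is an
exact weighted least-squares solve rather than a sampling run.

## Fisher (Hessian) engine and D-optimal design

In the low-noise limit the curvature of the log-likelihood at the truth is
the Gauss-Newton matrix

    H_kl = sum_r sigma_r^-2 sum_m  dI_r(mu_m)/dtheta_k dI_r(mu_m)/dtheta_l

over theta = (x_{i != ref}, mu0), with closed-form derivatives of the
competitive-binding response.  `delta_k = sqrt((H^-1)_kk)` forecasts each
parameter's uncertainty; numerically null eigendirections (below 1e-13 of
the largest eigenvalue) yield infinite deltas for the parameters they load
on instead of an exception.  The analytic matrix agrees with
finite-difference oracles (both of the response curves and of the actual
log-likelihood on noise-free data) to better than 1e-4 relative error.
The Hessian is parameterized on the linear x scale so deltas compare
directly with posterior stds of relative concentrations.

Design maximizes det H (D-optimality) over binding energies in [-14, -2]
kcal/mol and, optionally, efficacies in [0, 1], at a stated evaluation
composition (equal proportions at 1 mM total by default, 9-point series,
4 replicates, sigma = 0.02).  The search is nested sampling over the design
box (likelihood := log det H) followed by a tight bounded Powell polish;
multi-start polishing enumerates symmetry-related optima, clustered by
their agonist/antagonist assignment pattern modulo receptor relabelling.
A receptor-ligand bond counts as functionally relevant only if weakening it
to the top of the box lowers det H by more than 1%, which keeps flat
directions of the landscape from leaking into the classification.

**Why capacity is exactly 2 receptors per ligand.**  Along a dilution
series a receptor's mixture response depends on the composition only
through two scalars, `K = sum_i x_i exp(-dG_ri/kT)/sum x` and
`A = sum_i e_ri x_i exp(-dG_ri/kT)/sum x`:

    I_r(mu_tot) = bg_r + C A / (1 + C K),   C = exp(mu_tot / kT).

Each receptor therefore contributes at most rank 2 to H — rank 1 when all
efficacies are pinned to 1 (then A = K).  An array of N_R receptors can
pin down at most 2 N_R (resp. N_R) concentration parameters; since theta
has N_L components, det H is structurally singular for N_L > 2 N_R, and
the observed capacity law is a rank statement rather than a tuned
threshold.  It also explains the agonist-antagonist optimum: splitting a
receptor's two scalars as far apart as possible (one ligand all signal,
one ligand all suppression) maximizes the information per receptor, and an
agonist-agonist pair (A = K) cannot jointly resolve a ratio and a total.

"Successfully discriminated" means every delta_x below 30% of the true
ratio and delta_mu0 below kT ln 2 (a two-fold total-concentration window).
The numbers are configurable; because failures above capacity are rank
failures (deltas diverge), the measured capacities are insensitive to the
exact cutoffs.

## Synthetic data

The generator emulates plate-style reporter assays: the competitive-binding
response along the default ladder plus iid Gaussian noise, with optional
per-plate efficacy scaling and background shifts.  Each (seed, receptor,
plate) triple gets an independent RNG stream, so restricting to a receptor
subset never changes the other receptors' draws, and fixed seeds reproduce
byte-identical tables.  What it does **not** emulate: raw (un-normalized)
fluorescence counts, plate-reader optics, growth effects, intensity-
dependent or correlated noise, and model misspecification generally.
Passing tests therefore demonstrate correctness of the inference machinery
under the stated model, not robustness to the systematics of real assays
(plate bias excepted, which is modelled explicitly).

## Problem sizes and numerical choices

Routine analyses use the defaults above; the validation suite runs 50
calibration replicates for coverage, 15-mixture decode suites at
sigma = 0.01 (a few times below the experimental scale, and safely inside
the sigma prior support) for the Hessian-vs-sampling comparison, 3-run
scans per grid point for the accuracy trends, and 8–14 polish starts for
optimum enumeration.  Degenerate inputs are handled explicitly: empty
datasets, fewer than three distinct concentrations, all-absent
compositions, and singular Hessians all raise or report infinities rather
than returning silently wrong numbers.

## Known limitations

- Nested-sampling error bars on log Z are the information-based estimate,
  not bootstrap; treat them as 1-sigma guidance.
- The constrained-Metropolis replacement step can under-explore widely
  separated posterior modes; decoding posteriors here are effectively
  unimodal, but pathological arrays could violate that.
- det H is parametrization-dependent (linear-x convention); comparisons of
  determinants are only meaningful within a fixed parametrization.
- Capacity scans search a 2·N_R·N_L-dimensional design box; beyond ~3
  receptors the global search budget, not the physics, limits accuracy.
- Efficacies are treated as constants of a receptor-ligand pair; partial
  agonism that varies with occupancy is outside the model.
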