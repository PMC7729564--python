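# Methods

## The measurement model

Each well holds one strain at one time point after the switch to
nitrogen-free medium. The cytometer reports, per particle, forward/side
scatter (FSC-A, FSC-H, SSC-A), an amine-reactive viability-dye intensity
(VIAB) and the area and width of the DNA-stain pulse (DNA-A, DNA-W), all in
arbitrary positive units. The pipeline assumes:

* singlets have FSC-H proportional to FSC-A with a tight ratio, while
  doublets roughly double the area but not the height;
* dead cells stain much brighter on the viability channel than live ones
  (the dye reacts with free intracellular amines exposed in dead cells);
* among live singlets, quiescent G0 cells are mononuclear 1C (DNA-A low,
  DNA-W low), G2 cells mononuclear 2C (DNA-A high, DNA-W low), and G1/M
  particles binuclear 2C (DNA-A high, DNA-W high, because fission yeast
  delays septation so two G1 nuclei can share one particle).

## Gating

Doublet exclusion keeps events with FSC-H/FSC-A inside a band (default
0.7–1.3). Events with FSC-A = 0 cannot form a ratio; they are assigned to
the doublet class and counted in an anomaly tally. Mortality is
dead/(dead+live) **among singlets** — doublets are excluded before the
viability gate, and the denominator choice is recorded here because the
acquisition software leaves it implicit. DNA-content quadrants classify
only live singlets; the DNA-A-low/DNA-W-high quadrant (e.g. S-phase or >2C
oddities) is reported as an unclassified remainder, never forced into a
class. Wells with fewer than `min_singlets` (default 1000) single cells
fail QC; their fractions are still reported but flagged, and the fitter
treats them as missing time points rather than zeros.

**Auto thresholds.** The viability and DNA splits default to `"auto"`: the
exact order-statistics two-class split minimizing within-class variance of
the log-intensities (the continuous analogue of Otsu's histogram rule).
The split quality — between-class variance as a fraction of total — gates
the decision: below 0.8 the distribution is effectively unimodal (a single
Gaussian caps near 0.64), the configured fixed fallback threshold is used
(defaults 31.6 for viability and 141.4 for both DNA splits: geometric
midpoints of the default simulator geometry), and the well is flagged. All
thresholds actually used are recorded in the well summary for audit.

## Mortality kinetics

Seven candidate models (parameters a, d in %, b, c in 1/day or day, e
dimensionless; Φ is the standard normal CDF):

| model | f(t) | arity |
|---|---|---|
| logistic3p | a/(1+exp(−b(t−c))) | 3 |
| mech_growth | a(1−b·exp(−ct)) | 3 |
| gompertz3p | a·exp(−exp(−b(t−c))) | 3 |
| logistic5p | d+(a−d)/(1+exp(−b(t−c)))^e | 5 |
| exp3p | a+b·exp(ct) | 3 |
| exp2p | a·exp(bt) | 2 |
| probit4p | d+(a−d)Φ(b(t−c)) | 4 |

The probit model uses a linear time argument because day 0 is always
observed and a log-time form would be undefined there. Fitting is
trust-region nonlinear least squares with 8 deterministic starts per model
derived from the data range (initial value, maximum, log-slope and
midpoint heuristics), box constraints keeping asymptotes in [0, 105]% and
rate parameters in [−5, 5]/day, and tolerances of 1e−12 so that noise-free
data is recovered to ~1e−6. A model of arity p needs p+1 usable
observations or it is skipped (marked non-converged with a reason).

**Selection.** r² is standardized to a z score across the converged
candidates (a monotone transform of r², recorded per fit). The winner must
also predict a finite day of 99% mortality within the extrapolation
horizon (default 1000 days); if no candidate does, the best-r² fit is kept
and all threshold times are censored at the horizon. Ties in r² occur
structurally — exp2p is nested in exp3p, and mech_growth is exactly exp3p
reparameterized — and are broken by parsimony (fewer parameters), then by
the fixed listing order above. Censored T values enter clustering at the
horizon with a flag (a toggle excludes such strains instead).

**Threshold times.** T_level is the smallest t in [0, horizon] with
f(t) ≥ level, found by a 4097-point grid bracket plus Brent bisection to
1e−6 day; for exp2p the closed form ln(level/a)/b is used. Confidence
intervals come from residual resampling: residuals of the selected fit are
bootstrapped onto the fitted curve, each pseudo-trajectory is refitted
warm-started from the original parameters, and the 2.5–97.5 percentiles of
the uncensored refit threshold times are reported; the interval is flagged
unreliable if fewer than half the refits converge.

## Clustering and the CCC

Features (T₁/₂, T₁/₄, G2% day 0, G0% day 1, G0% day 7) are z-scored with
the sample standard deviation (n−1); zero-variance columns are left at 0
and flagged. Ward's minimum-variance agglomeration runs on Euclidean
distances (the default pairing for Ward). For each candidate k (default
2–15) the dendrogram is cut and

    CCC(k) = ln[(1 − E(R²))/(1 − R²)] · sqrt(n·p*/2) / (0.001 + E(R²))^1.2

with R² = 1 − SSwithin/SStotal and E(R²) from the uniform-hypercube null:
with s_j the singular values of the centered matrix over √(n−1), hypercube
edge scale c = (∏_{j≤p*} s_j / k)^{1/p*} and u_j = s_j/c,

    E(R²) = 1 − [ (Σ_{j≤p*} 1/(n+u_j) + Σ_{j>p*} u_j²/(n+u_j)) / Σ_j u_j² ]
            · (n−k)²/n · (1 + 4/n).

p* is the largest integer below k with u_{p*} ≥ 1 — only dimensions wider
than one cluster diameter count as clusterable. (An alternative p* rule —
counting singular values above their mean — was tried first and rejected:
it understates dimensionality under a spherical null, making CCC grow
monotonically in k on pure noise.) The k maximizing CCC is chosen; a
partition with R² = 1 gets a +∞ marker and wins. Under a single-Gaussian
null the maximum CCC over k = 2–15 sits around −4 to −6, comfortably below
the conventional "structure" threshold of 2; with seven planted archetypes
at 6-sd separation the criterion recovers k = 7 in ≥ 96% of seeded
replicates (see the test suite). Mutant-vs-control comparisons use Welch's
unequal-variance t-test.

## Enrichment

Fold enrichment is the exact ratio (k/n)/(K/N). Both the hypergeometric
point probability P(X=k) and upper tail P(X≥k) are reported: published
per-complex probabilities in screens of this kind are point probabilities,
so that column is the headline statistic, while the tail is the classical
one-sided test. The background N is the set of analyzed
strains (strains surviving QC and fitting), not the full library. BH
adjustment over all reported (cluster, category) pairs is appended as a
supplementary column.

## Synthetic screens

The generator plants, per well: a doublet fraction (default 5%), a dead
fraction among singlets given by the strain's trajectory model (+ Gaussian
noise, clamped to [0, 100]%), and a G0/G2/G1M split of live singlets
following a per-strain schedule (vegetative day 0 ≈ 3% G0; starved days
use the strain's entry phenotype). Intensities are log-normal per
population. Defaults: scatter CV 30%, DNA CV 12% (typical of good PI
staining), viability CV 30%, live:dead viability separation 10× in mean,
G0:G2 DNA-A separation 2× (1C vs 2C), mono:binuclear DNA-W separation 2×.
FSC-H is generated as FSC-A times a tight ratio (CV 5%), so the singlet
band works as in real scatter pulses; doublets double FSC-A and DNA-A but
keep FSC-H at singlet level. Dead cells get arbitrary mid-range DNA values
— they are excluded before DNA analysis, and no downstream quantity may
depend on that choice. A single global seed drives everything; each well
derives an independent substream from CRC32(strain_id) and the day, so any
well is reproducible in isolation and outputs are byte-identical across
runs.

Seven built-in archetypes (control-like, fast death, sigmoid death, strong
and mild G0-entry defect, high vegetative G2, and a low-asymptote class
whose curve never reaches 99% and therefore exercises the censoring path)
assemble demo screens; a separate feature-space generator plants archetype
centroids at a configurable noise-sd separation for clustering studies.

**What the synthetic data does not emulate:** spectral spillover and
compensation, acquisition-time drift, debris and clumps beyond simple
doublets, correlated noise across time points of one strain, and
plate-position effects. Passing the recovery tests therefore shows the
estimators are correct under the stated mixture model, not that the gates
are robust to every instrument artifact.

## Problem sizes and numerical notes

The test suite runs the recovery studies at the scale used throughout:
20,000 events/well for gating recovery (20 seeds), 50 strains for the
half-life recovery study (6 time points, 2% noise), 25 seeded replicates
for the clustering studies, 50 replicates × 200 resamples for bootstrap
coverage, and exhaustive oracle checks for the hypergeometric (N ≤ 30,
exact rational combinatorics) and Ward merges (n ≤ 12, O(n³) reference).
Degenerate inputs are handled explicitly: constant trajectories fit exp2p
with b ≈ 0; single-point hypergeometric supports return probability 1
exactly; identical records merge at height 0; R² on zero-variance data is
defined as 1 for a perfect fit. Merge ties (probability zero for
continuous data) resolve by scipy's deterministic nearest-neighbor-chain
order, so repeated runs are identical.

## Known limitations

* The five-parameter logistic can nearly interpolate any monotone
  six-point trajectory; identifiability of the generating model is only
  guaranteed for noise-free data with the parsimony tie-break.
* CCC is evaluated on Ward cuts only (as in the screen); it is not a
  general-purpose cluster-number estimator here.
* FCS support covers uncompressed list-mode FCS 3.0/3.1 with float,
  double, or uniform 16/32-bit integer data — enough for exported raw
  plate data, not the full standard.
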