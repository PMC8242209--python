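# Methods

## Model

For one solute/solvent pair the observable is the saturation solubility
*s*(*c*) of the aromatic solute at solvent concentration *c* (M). With the
plain-buffer solubility *s*₀ the solubility ratio is *r*(*c*) = *s*(*c*)/*s*₀,
fixed to 1 at *c* = 0 by construction. The solubility-slope index is

PSAS = Δ*r*/Δ*c*  [per M],

the slope of a straight line fitted to (*c*, *r*) over the whole measured
concentration range, without segmentation into low- and high-concentration
regimes. A positive slope means the solvent residue solubilizes the
aromatic solute (a "soluble", droplet-like interaction), a negative slope
that it insolubilizes it (an "insoluble", aggregate-like interaction).

### Estimator

Because the ratio is identically 1 in plain buffer, the default fit
constrains the intercept: the slope of *y* = *r* − 1 on *c* through the
origin has the closed form

b = Σ cᵢ yᵢ / Σ cᵢ²,

with standard error √(RSS/(n−1)/Σcᵢ²) from the through-origin residual
variance and an uncentered R² = 1 − RSS/Σyᵢ². A free-intercept ordinary
least-squares fit (`mode="free"`, via `scipy.stats.linregress`) is offered
as a robustness check; which variant an experimental analysis used is
generally not reported, and the two agree whenever the data are truly
linear through (0, 1). Replicates are averaged per concentration before
fitting (unweighted); weighted fitting would matter only if replicate
counts varied strongly across the grid.

Degenerate inputs are errors, not silent results: fewer than two distinct
concentrations, a missing or non-positive water baseline, a constant
vector passed to a rank correlation.

### Classification

A fitted slope is classified soluble if PSAS > τ, insoluble if
PSAS < −τ, neutral otherwise. τ = 0.05 per M by default: the neutral band
is a pragmatic cutoff for "close to zero" (no published threshold exists)
and is configurable everywhere it appears. A solvent's class is the class
of its column mean over the three solutes.

## Synthetic assay generator

No raw solubility table for this assay is publicly distributable, so the
generator produces records with the same structure and known ground
truth:

s(c) = s₀ · (1 + PSAS·c + γ·c²) + ε,  ε ~ N(0, (σ·s₀)²), truncated at 0,

per replicate, on an evenly spaced grid from 0 to the solvent's maximum
usable concentration. Defaults: 5 concentrations including 0 M, 3
replicates, relative noise σ = 0.05, curvature γ = 0 (γ exists only as a
robustness stressor for the linear estimator; the estimator itself is
deliberately linear). Negative draws are truncated at zero and flagged
rather than resampled, which keeps the noise model simple and the
truncation observable. All randomness flows through a single seed;
identical seeds give byte-identical CSV output.

### Solvent concentration ranges

The maximum usable concentration of each solvent is its aqueous
solubility: the packaged water-solubility column (taken as g per 100 mL)
converted to molarity via the residue molar mass, `cmax = 10·S/MW`. This
reproduces the experimentally important fact that usable ranges vary by
three orders of magnitude — ~3 mM for a Tyr solvent versus ~11 M for Pro —
and is overridable per solvent.

### The `paper_like` preset

Numeric slope values for this assay are not publicly available, so the
preset encodes the qualitative interaction structure reported for free
amino acids in solution and chooses magnitudes once, on physical grounds. Each solvent is assigned a relative solubility
change of the solute at that solvent's cmax:

| solvent group | Δ at cmax | rationale |
| --- | --- | --- |
| Tyr, Trp, Phe | +0.25, +0.30, +0.20 | π–π stacking with the aromatic solute |
| Arg | +0.25 | cation–π |
| His | +0.15 | weaker aromatic/cation character |
| Pro | +1.00 | hydrotropic solubilization at multi-molar levels |
| Gly, Ser, Thr, Lys | 0 | water-like, inert |
| Ala, Val, Leu, Ile, Met, Cys | −0.20 | hydrophobic coprecipitation |
| Gln, Asn | −0.20 | amide-mediated coaggregation |
| Glu, Asp | −0.30 | electrostatic repulsion at pH 7 |

The true slope is Δ·w/cmax, where w is a solute weight (Trp 1.25, Tyr
1.00, Phe 0.80 in solubilizing solvents; Tyr 1.25, Trp 1.00, Phe 0.80 in
insolubilizing ones). Dividing by cmax makes the sparingly soluble
aromatic solvents the strongest solubilizers *per mole* — Tyr and Trp
solvents carry the largest positive slopes and Glu/Asp the most negative —
and the solute weights yield the Trp > Tyr > Phe ordering in soluble
columns and Phe > Trp > Tyr in insoluble ones. These are the qualitative
claims the comparison module tests; the magnitudes themselves are design
choices, asserted nowhere.

### Observation layer

Optionally, solubilities are mapped to UV absorbances through per-solute
standard curves (A = slope·s/dilution + intercept) whose slopes derive
from the molar extinction coefficients of free Trp, Tyr and Phe at their
absorption maxima (5500, 1490 and 195 per M per cm at 280, 275 and
260 nm). The dilution is the smallest factor from a 1–2–5 ladder that
brings the absorbance into the photometric window (0.1–1.0 by default;
the top of the window counts as detector saturation and is excluded).
Calibration inverts the same line, so observe-then-calibrate is exact to
rounding; an absorbance below the blank is a calibration error.

### What the generator does and does not emulate

It emulates the data *structure* (per-pair grids, replicates, baselines,
heavily varying solvent maxima, photometric quantification) and a
homoscedastic relative noise model. It does not emulate saturation
kinetics, temperature protocol, pH shifts at high cosolvent
concentration, solvent-effect artifacts of extremely soluble cosolvents
(the Pro caveat), or correlated inter-day error. Passing tests therefore
demonstrate correctness of the estimation and comparison machinery under
the stated noise model — not that real assays are this well behaved.

## Comparison machinery

By-row: a solute's 20-solvent slope profile is rank-correlated (Spearman
default; Kendall τ-b for tie robustness) with each classical scale.
"Partial consistency" between scales is thereby reported as a
coefficient, not a verdict — with n = 20 and many near-zero cells no
significance testing is attempted. By-column: solutes are ordered by
descending slope within each solvent; ties render as `A=B` with
alphabetical order inside a tie group, and the ordering string is matched
against the orderings the reference scales induce on {Tyr, Trp, Phe}.

Ranking of full scales (`rank_residues`) breaks ties by the packaged-table
row order instead, so both conventions are deterministic.

## Sequence profiles

`seq_profile` applies the classic hydropathy-plot scheme to any scale:
the score at a window center is the mean scale value over the w residues
(w odd; centers reported 1-based; a length-L sequence yields L − w + 1
windows). Windows containing a non-canonical residue are skipped and
their centers recorded — no imputation is defensible for an unknown
residue. This is a convenience for using fitted slope columns as sequence
features; it deliberately stops short of any disorder or phase-separation
predictor, since free-amino-acid behavior and in-chain behavior are known
to diverge.

## Numerical and testing choices

* Noiseless end-to-end recovery is asserted to 1e-9 per cell (the
  pipeline is algebraically exact; the tolerance absorbs float
  accumulation).
* The slope estimator is cross-checked against an independent brute-force
  grid search over the residual sum of squares (tolerance 1e-6), and the
  rank statistics against exhaustive pair-counting/mid-rank oracles
  (tolerance 1e-12) on short, tie-heavy vectors.
* Monte-Carlo suite sizes — 10⁴ curves for estimator bias (band:
  < 0.02 absolute at true slope 0.5), 100 seeded full assays for
  sign-class recovery (band: ≥ 90% of 60 cells at τ = 0.05) — keep the
  whole suite under a minute while leaving comfortable stochastic margin;
  seeds are fixed in the tests and derived from `--seed` in the
  acceptance script.
* CSV round-trips read floats with `float_precision="round_trip"`;
  index tables are parsed as text and converted with Python `float`, with
  the Unicode minus normalized, so written tables reload exactly.

## Known limitations

* Slope magnitudes of the `paper_like` preset are plausible constructions,
  not measurements; only their signs and orderings carry meaning.
* The water-solubility column of the packaged table is stored as printed
  (units not stated in the source compilations; nominally g per 100 mL at
  room temperature), and cmax inherits that assumption.
* The estimator is strictly linear; real ratio curves can bend at low or
  high cosolvent concentration, and the simulator's curvature term exists
  precisely to probe how much that biases a linear slope.
* With a 5-point grid and 5% noise, solvents with mid-range cmax and true
  slopes near τ (e.g. an inert solvent with cmax ≈ 0.8 M) are the main
  source of residual misclassification; increasing replicates or grid
  density narrows it.
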