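# Methods

This note documents the models, conventions and numerical choices behind
`acepep`, and what the synthetic-data generators do and do not emulate.

## Occurrence and release statistics

The occurrence frequency of an activity in a protein is `A = a/N`: `a`
counts matches of the activity's reference fragments as substrings,
where every (fragment, start-position) pair counts once and overlapping
matches all count. Reference databases differ on whether repeated
occurrences of the same fragment should be re-counted, so
`occurrence_frequency(..., unique_fragments=True)` switches to counting
each distinct fragment at most once per protein; the all-occurrences
convention is the default. Activity labels are matched
case-insensitively after trimming because reference tables are
user-supplied. `ΣA` is the exact sum of the per-activity values.

The release frequency after digestion is `A_E = d/N`, where `d` counts
fragments *exactly equal* to a reference fragment, with multiplicity. A
bioactive motif still embedded in a longer fragment is deliberately not
counted: it has not been released. Absolute A/ΣA/A_E values therefore
depend entirely on the reference table used; the bundled
`ace_reference.tsv` is a small curated demonstration set of literature
di/tripeptides, not a database redistribution, and numbers computed
against it are not comparable to numbers computed against any full
database.

## Protease rules

A protease is a data-driven P1/P1′ rule: the bond after residue i is
cleaved iff residue i ∈ P1 and residue i+1 is not excluded. The bundled
seven-enzyme table uses simplified literature specificities (trypsin K/R
not-before-P; chymotrypsin A F/Y/W not-before-P; pepsin at pH 1.3 F/L;
papain's P2-hydrophobic preference collapsed to a broad P1 set; broad
hydrophobic/aromatic P1 sets for stem bromelain, subtilisin and
proteinase K). These defaults are approximations: absolute DHt and A_E
panels are rule-table-dependent, and users with exact cleavage tables
should substitute their own file. DHt uses N−1 bonds per chain; for
multi-protein substrates the panel reports both the per-protein mean and
the pooled (total cleaved bonds / total bonds) aggregation, since either
is defensible.

## Box–Behnken response surface

The 17-run, three-factor Box–Behnken design (12 edge midpoints + 5
center replicates) is validated structurally before fitting. The full
10-term quadratic model in coded units is fitted by OLS (statsmodels).
Per-term sums of squares are partial (type III), `SS_j = β_j²/[(X'X)⁻¹]_jj`,
which a drop-one-column refit reproduces and which equals sequential SS
for the orthogonal main effects and interactions (both identities are
asserted in tests; for main effects `SS = 8β²` on this design). Pure
error comes from the center replicates; lack of fit is tested against
pure-error mean square. PRESS uses the leave-one-out identity
`Σ(e_i/(1−h_ii))²`, predicted R² = 1 − PRESS/SS_total, and adequate
precision is `(max ŷ − min ŷ)/√(p·MS_resid/n)` with p = 10, n = 17.
Degenerate constant responses are defined to have R² = 1 and an
undefined (omitted) F.

The optimum is the analytic stationary point when the Hessian is
negative definite and the point lies in the coded cube [−1,1]³;
otherwise a 41³ grid scan polished by bounded L-BFGS-B restarts searches
the cube and the result is flagged as a boundary/saddle case. The
analytic branch is exact; the fallback agrees with a dense-grid
brute-force oracle to grid resolution except on flat ridges, where the
maximizer is non-unique and agreement is judged on the attained value.

The bundled design's responses are triplicate means; fitting the 17
means (rather than 51 replicate values) is the convention adopted
throughout, and small deviations from the source report's printed ANOVA
(e.g. model F 60.1 here vs 58.08 printed; pure error 1.38 vs 1.52) are
consistent with that report having fitted pre-rounding data. Two printed
diagnostics of that report ("Mean 73.83", "C.V.% 1.26") are inconsistent
with its own design table (response mean 58.85) and are not reproduced.

## Candidate scoring

Channels: abundance (score A), de novo confidence (score B), |binding
energy| (score C); all must be strictly positive, and binding energies
strictly negative. Although composite-screening protocols often say
"min-max scaling", the published worked examples this scheme follows are
reproduced by ratio-to-maximum scaling (`100·v/max v`), not by
min-subtraction, so ratio-to-max is the default and classical min-max is
available via `normalization="min_max"`. Weights default to
(0.40, 0.30, 0.30) and must sum to 1. Ranking ties are broken by
descending abundance, then sequence, for reproducibility. Subscores are
invariant under positive rescaling of a channel, and exactly one
candidate per channel attains 100 unless tied.

## Inhibition kinetics

The endpoint formula `100·[(a1−a2)−(b1−b2)]/(a1−a2)` requires the blank
to have progressed (a1 > a2); negative values (activation) are returned
with a warning. Rate series require ≥3 distinct substrate
concentrations. Two fitting routes are provided and cross-checked:
unweighted OLS of 1/v on 1/[S] (the Lineweaver–Burk line, the field's
presentation standard) and direct nonlinear Michaelis–Menten regression
(scipy). Both recover noiseless data exactly; under multiplicative rate
noise the nonlinear fit has lower parameter RMSE (asserted statistically
in tests), so it is the default for classification while the reciprocal
fit supplies the plot geometry.

Mode classification compares apparent Km and Vmax at the highest
inhibitor concentration against the zero-inhibitor baseline. A
parameter counts as shifted only if its relative change exceeds the
tolerance (default 0.10) *and* its absolute change exceeds ~2 combined
standard errors. The SE gate matters: when apparent Km grows past the
fixed substrate range, Vmax becomes weakly identified and a purely
relative threshold misfires on noisy competitive data. Km↑ with flat
Vmax → competitive; Vmax↓ with flat Km → non-competitive; both → mixed;
a decreasing Km (uncompetitive-like) or no significant trajectory →
"none" with a diagnostic. Ki comes from the secondary plot: the
Lineweaver–Burk slopes `Km_app/Vmax_app` are regressed on [I] and the
X-intercept is −Ki; this is exact for competitive and non-competitive
inhibition and approximate for mixed.

IC50 uses the four-parameter logistic
`y = bottom + (top−bottom)/(1+(IC50/x)^hill)` fitted by least squares,
initialized from the data envelope with the midpoint concentration as
the IC50 start; an IC50 outside the measured span and inhibition values
outside (−20, 120)% are flagged, not rejected. mg/mL→µM conversion uses
the peptide's average molecular mass (biopython).

## Synthetic-data generators

All generators are pure functions of (parameters, seed); streams are
derived from the master seed by labelled sub-seeding (SeedSequence with
a CRC32 label word), so adding a generator never perturbs another.
Defaults mirror a realistic royal-jelly hydrolysate screen: hydrolysate
activities ~50–66% (true surface coefficients at the effect sizes of the
bundled design, center ≈ 65.7%), response noise σ = 0.9 percentage
points, docking energies uniform on (−9.5, −6.8) kcal/mol, abundances
log-normal around 10¹⁰, confidences ~395–425, kinetic assays with Vmax
= 1, Km = 1 mM, Ki = 10 µM (mixed α = 2), a 6-point geometric substrate
series spanning 0.2–5 × Km, inhibitor levels (0, 5, 10, 20) µM,
triplicate rates with multiplicative Gaussian noise (CV 1–5%), and 4PL
dose–response curves with additive noise of 2 percentage points.

What the generators do *not* emulate: real cleavage-site promiscuity and
missed cleavages; correlated MS abundance/confidence structure;
substrate depletion and product inhibition in rate measurements; and
inter-assay batch effects. Passing tests therefore demonstrate
correctness of the computations and robustness at realistic noise, not
performance on any particular wet-lab dataset.

## Problem sizes in the test suite

The randomized suites use sizes chosen to exercise the identities
thoroughly while keeping the default run quick: 1000 random
(sequence, rule) digestion pairs; 100 random proteomes against the
brute-force substring oracle; 100 random ANOVA fits; 50 random
quadratics against a 0.01-step grid oracle; 200 seeds for coefficient
recovery at σ = 0.9; a 3 mode × 3 noise × 100 seed classification grid
(aggregate accuracy ≥ 95%); 60 seeds for Ki recovery; 500 seeds for
IC50 bias.

## Known limitations

- Cleavage rules are context-free P1/P1′ sets; P2/P2′ context, missed
  cleavages and pH/temperature dependence are out of scope.
- The composite score treats confidence as an opaque positive number; no
  attempt is made to harmonize scores across search engines.
- Mixed-mode Ki from the secondary plot inherits the usual bias of
  slope-replots when α is far from 1.
- The Box–Behnken machinery is specific to the three-factor, 17-run
  design; other response-surface designs are not generated or fitted.
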