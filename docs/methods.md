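# Methods

This note documents the quantitative choices behind proteoalloc: the
estimators, the model, the synthetic-data generator and the places where
the design was genuinely open.

## iBAQ mass fractions

A protein's share of proteome mass is φᵢ = iBAQᵢ·MWᵢ / Σⱼ iBAQⱼ·MWⱼ.
iBAQ intensity approximates copy number, so multiplying by molecular
weight converts it to a mass-proportional quantity ("iBAQ mass");
normalizing by the whole-proteome sum closes each sample to Σφᵢ = 1
(enforced to 1e-9). Consequences used throughout:

* **Scale invariance.** A global rescaling of intensities (instrument
  gain, loading) cancels; only relative abundances matter.
* **Order of operations.** Fractions are computed per sample and then
  averaged across biological replicates, never the other way round:
  per-sample closure is what makes fractions comparable across runs
  whose total signal differs.
* **Missing intensities.** MaxQuant writes 0 for "not detected". The
  reader records these as *missing* (for QC counting) and the allocator
  converts them to zero mass, the only defensible default — an
  undetected protein carries no measured mass. The missing count is
  logged per sample.

Identifier policy: the locus tag is the join key between the proteome
and gene sets (regulon and sector lists are locus-tag keyed); gene names
are display-only. Contaminant/decoy rows are removed by the `CON__` /
`REV__` identifier prefixes — the standard MaxQuant convention; the
upstream FDR settings are not re-estimated here. Molecular weight is
converted kDa→Da once, at read time.

## Sector schemes and balance accounting

A scheme distinguishes a disjoint **partition** (translation, NT
biosynthesis, AA biosynthesis, motility, …, closed by an implicit
`other` remainder) from **overlay** sets such as a regulon, which may
intersect partition sectors. Conservation — Σ_S Δφ_S = 0 between any two
conditions (1e-6) — is asserted only on the partition; overlays are
reported alongside and decomposed against partition sectors
(`overlay_decomposition`: regulon-inside vs regulon-outside shares of a
sector, exact by construction since both halves are sums over disjoint
tag sets).

`balance_analysis` reports Δφ per sector, totals over user-named
increase/decrease groups and the residual (increase − |decrease|). The
residual is the scientifically interesting number: when a repressor is
deleted, the mass gained by derepressed sectors should be paid for,
nearly exactly, by translation machinery and its afferent pathways.

The BCAA vs non-BCAA split of the AA sector is just another scheme
(an *ilv/leu* overlay against the AA partition sector); no special code.

## Growth-physiology estimators

* **Growth rate.** OLS of ln OD₆₀₀ vs time restricted to readings in the
  OD window 0.05–0.5 (the usual exponential sampling range; 5–8 points
  in practice), requiring ≥4 in-window points. Natural-log base, units
  h⁻¹; doubling time ln2/λ. A window fit with r² < 0.98 is flagged, not
  rejected. On a noiseless exponential the estimator is exact to machine
  precision, and it is invariant to rescaling all OD values.
* **RNA.** OD₂₆₀·31/OD₆₀₀ in µg/ml/OD₆₀₀. The coefficient 31 is the
  perchloric-acid protocol constant and is treated as opaque (it bundles
  extinction coefficient and path length); exposed as
  `RNA_OD260_COEFFICIENT`.
* **Protein.** OLS standard curve through ≥2 distinct BSA standards
  (typically 0.4–2 mg/ml); readings outside the standards' OD range are
  flagged as extrapolated rather than rejected.
* **Miller units.** 1000·OD₄₂₀/(t[min]·V[ml]·OD₆₀₀), the classical
  convention *without* the OD₅₅₀ debris-correction term, which this
  protocol does not record. Stated here explicitly because both
  conventions circulate.
* **Promoter-activity ratios.** mean_null/mean_wt with first-order error
  propagation (relative variances add). Adequate for CVs ≲ 20%; no
  higher-order correction is attempted.
* **Two-sample test.** Welch's unequal-variance t-test by default
  (`equal_var=True` restores pooled Student); "unpaired t-test" alone
  does not pin the flavor down, and Welch is the safer default for n=3
  biological replicates.

### Downshift lag

The lag after a rich→minimal transfer is defined by back-extrapolation
(the Monod-style geometric construction): fit the steady post-shift
exponential, extend it back to the OD at the shift time t₀, and call the
crossing delay the lag,

lag = (ln OD(t₀) − b)/λ_post − t₀, clipped at 0,

where b is the fitted intercept. The steady window is chosen as the
trailing window (≥4 points) with the *maximum* r² of ln OD vs t — with
measurement noise the longest clean exponential wins this criterion
automatically because its signal-to-noise grows with window span, while
any window reaching back past the growth-resumption kink is penalized by
systematic curvature. An estimate is refused if the best window has
r² < 0.99. On noiseless constructions OD(t) = OD₀·e^{λ·max(0,t−L)} the
estimator returns L exactly. This definition is a documented package
choice; other lag conventions (e.g. threshold-crossing delay) differ by
O(noise) on clean curves but are not implemented.

## The R-line and the Q/R/A(/U) model

The R-line is fitted directly in measured coordinates — RNA/protein
ratio vs λ — without converting to ribosomal protein fraction; a
conversion constant would add nothing and imports an extra assumption.
Whether two strains share one line is decided by a nested-model F-test
(pooled 2-parameter line vs separate 4-parameter lines, α = 0.05): a
burden strain should move *along* the wild-type line, not onto a new
one.

The partition model coarse-grains the proteome into housekeeping Q
(fixed), ribosomal/translation R, amino-acid supply A and useless burden
U, with closure φ_Q+φ_U+φ_R+φ_A = 1. Two linear flux laws,

λ = γ(φ_R − φ_R0)   (translation)
λ = ν·φ_A           (supply),

balanced at steady state give λ = γν(1−φ_Q−φ_U−φ_R0)/(γ+ν). This is the
standard linear growth-law closure of the proteome-partition picture,
kept deliberately minimal: no Michaelis–Menten saturation, no dynamic
reallocation kinetics.
Properties asserted in tests: four-sector closure to 1e-9; λ strictly
decreasing in φ_U and increasing in γ and ν; agreement with a numerical
flux-crossing oracle; and exact reduction, as ν→∞, to the burden law
λ = λ₀(1 − φ_U/φ_max) with φ_max = 1−φ_Q−φ_R0.

φ_R0 (inactive-ribosome offset) defaults to 0; it is exposed because the
R-line's nonzero intercept implies one, but the analyses here do not
require it.

**Downshift readiness** is ordinal only: strains are ranked by
φ_A(pre-shift)/φ_A* where φ_A* is the post-shift steady-state demand; a
higher score predicts a shorter lag. No quantitative lag–φ_A law is
claimed (none is established), so the model is never used to predict lag
durations.

Default parameters for demo runs: φ_Q = 0.45, γ = 10 h⁻¹, ν = 2 h⁻¹ —
chosen so the model's steady states land in the physiological range
(λ ≈ 0.9 h⁻¹ in glucose minimal medium, λ → ~2 h⁻¹ as ν grows large,
φ_R ≈ 0.1–0.25), matching typical *B. subtilis* rates.

## Synthetic-data generator

The generator is the test bed: every estimator is validated against its
manifest of ground truth.

* **Proteome.** Per sector, within-sector relative abundances are
  lognormal (σ = 1 by default — proteome abundance distributions are
  heavy-tailed over orders of magnitude) and renormalized so sector sums
  equal the stated fractions *exactly*; per-replicate iBAQ intensities
  are true mass / MW × scale × multiplicative lognormal noise (median 1)
  with a stated CV — multiplicative because MS intensity error scales
  with signal. Default study conditions: 400 proteins in five sectors
  with wild-type-LB fractions (translation 25%, NT 4%, AA 5%, motility
  0.76%), 3 biological replicates, 5% CV; the built-in contrast
  re-weights to the derepressed condition (AA 11.5%, motility 2.5%,
  translation 18%, NT 2.76%), i.e. 8.24% of proteome mass moved, with
  Σ Δφ = 0 by construction. A regulon-style overlay (all motility plus
  40% of AA members) exercises overlay decomposition.
* **Molecular weights** are drawn on a 125-Da grid between 10 and
  100 kDa. 125 Da = 0.125 kDa is exactly representable in binary, so the
  kDa file column round-trips bit-exactly through write→read — which
  lets the round-trip identity test demand exact equality instead of a
  tolerance.
* **Growth curves.** OD(t) = OD₀e^{λt}×noise sampled at 7 points across
  OD 0.05–0.5; downshift curves OD(t) = OD₀e^{λ·max(0,t−L)}×noise at 24
  points. OD noise is lognormal with *median* 1, making the log-linear
  slope estimator exactly unbiased — the generator tests the estimator,
  not a bias correction.
* **Determinism.** All draws come from one `numpy` Generator seeded from
  the config; identical (config, seed) reproduce byte-identical files.

What the generator does **not** emulate: peptide-level detection and
missing-value mechanisms (beyond whole-cell zeros), ionization biases
correlated with protein properties, batch effects between replicates,
and any protein-level regulation finer than sector re-weighting. Passing
recovery tests therefore show that the *bookkeeping and estimators* are
correct and unbiased under realistic noise — not that real MS data meet
these assumptions.

## Problem sizes and numerical conventions

Test and demo runs use the 400-protein universe, 3 replicates, 100-seed
ensembles for recovery checks, and 1000-draw sweeps for invariants —
sizes at which the estimators' standard errors are far below the effects
being checked, while the whole suite stays fast. Summation of fractions
uses compensated `math.fsum`; closure tolerances are 1e-9 per sample and
1e-6 across condition deltas. Flat series (zero variance in y) are
treated as perfect fits with slope 0 rather than undefined r². The lag
estimator refuses curves with no steady window (best r² < 0.99) and
clips small negative back-extrapolations to 0.

## Known limitations

* No differential-expression statistics (moderated tests, imputation);
  sector membership always comes from user-supplied lists, never
  inferred.
* Shift dynamics are not modeled; the model gives steady states and an
  ordinal lag prediction only.
* The run log is deterministic by design (no timestamps), which trades
  audit convenience for reproducible bytes.
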