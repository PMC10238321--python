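# Methods

## Scope and model

`metalrisk` implements a deterministic dietary risk characterisation for
metal residues in poultry edibles (chest muscle, thigh muscle, liver),
following the standard USEPA ingestion-pathway methodology. The study it
reproduces measured 12 metals (Al, Cd, Pb, Ba, Bi, Co, Ni, Cr, Fe, Cu,
Zn, Se) in six retail brands, 20 birds per brand, and published only
group summaries (mean ± SE per brand × tissue × metal). Four quantities
are computed per group:

* **EDI** (estimated daily intake, µg/kg body weight/day):
  `EDI = C · FIR / BW`, with C the mean residue concentration (µg/g wet
  weight), FIR the ingestion rate (39.53 g/day for muscle, 0.1 g/day for
  liver) and BW = 70 kg.
* **THQ** (target hazard quotient): chronic intake relative to the oral
  reference dose RfD (mg/kg/day). Values at or above 1 flag potential
  non-cancer risk.
* **HI** (hazard index): the sum of a group's twelve THQs.
* **TR** (target cancer risk): intake times the oral carcinogenic
  potency slope CPSo, for the five metals with a defined slope (Cd, Pb,
  Co, Ni, Cr). The 10⁻⁶–10⁻⁴ band is the usual regulatory concern range.

Screening against maximum-residue limits is separate from the dose-based
measures: a group exceeds an authority's limit when its mean is strictly
greater than the limit for its tissue class (chest/thigh → muscle,
liver → offal); a mean exactly at the limit is compliant. Study-level
exceedance percentages are sample-weighted (20 birds per flagged group
over 360 birds) and displayed with half-up integer rounding. This exact
convention — strict inequality, group-mean judgement, half-up display —
is the only one that reproduces every published percentage (94, 67, 44,
33, 33, 17, 11).

## Formula modes

The source publication's stated THQ and TR equations do not reproduce its
own printed tables, so the engine implements both readings explicitly and
labels results with the mode used:

* `published` (default): `THQ = EDI·10⁻³/RfD` — the exposure-duration
  factor ED·EF/AT collapses to 1 — and `TR = EDI_mg · CPSo`
  (= EDI·10⁻⁶·CPSo). This reproduces every audited printed cell.
* `stated`: the equations as written. THQ carries the non-cancer time
  factor ED·EF/(AT·365) = 30/70; TR keeps the written 10⁻³ instead of
  the published 10⁻⁶. Exact identities link the modes:
  `THQ_stated = (30/70)·THQ_published` and
  `TR_published = 10⁻³·TR_stated`; both are asserted in the test suite.

Two further numerical conventions matter. First, the printed THQ/HI
tables carry a "×10⁻³" scale label that is dimensionally inconsistent
with their own intake column (the cadmium THQ column numerically equals
the EDI column); printed numerals are therefore matched as numerals and
the label treated as display metadata. The published safety conclusion
(THQ and HI "far below 1") holds on that table scale and is asserted as
`value·10⁻³ < 1`. Second, all chained quantities are computed from the
raw group means, never from rounded intermediate intakes; several printed
cells (e.g. the chromium cancer risk of chest brand 1) match only under
full-precision propagation.

## Reference values

The registry ships the study constants as packaged defaults: per-metal
RfD (Al 0.0004, Cd 0.001, Pb 0.004, Ba 0.07, Bi 0.00029, Co 0.0003,
Ni 0.02, Cr 0.003, Fe 0.7, Cu 0.005, Zn 0.3, Se 0.005 mg/kg/day), CPSo
(Cd 0.38, Pb 0.0085, Co 0.7, Ni 1.7, Cr 0.5), IARC classes, the limit
rules of FAO/WHO, EU, EOS, FNB and the international proposals (applied
to muscle and offal alike, as the study applies them), the exposure
scenario, and the analytical spike-recovery percentages as metadata. The
source text's running list of reference doses has eleven values for
twelve metals and is internally misaligned; the per-row table column is
used instead because it reproduces the printed hazard quotients. A
registry can also be loaded from TOML/JSON; lookups for undeclared keys
raise distinct errors rather than defaulting to zero.

## Golden fixtures and misprint policy

The published concentration summaries are transcribed as printed (216
groups; two typographic oddities preserved verbatim and flagged). The
four derived tables are stored with the printed numeral kept as a string
plus an audit status. Comparison tolerance is 0.5 % relative, widened to
one unit in the last printed decimal for the few cells truncated to two
significant figures. Fourteen cells across the four tables are
publication-internal misprints (digit scrambles, one decimal-point shift
that the publication's own hazard-index column sum inherits, two
chromium cancer-risk cells inconsistent with any combination of the
stated constants); they are excluded from golden comparisons and
individually documented in `src/metalrisk/data/fixture_notes.md`. The
pipeline itself always computes from the concentration fixture, so the
exclusions affect only what is compared, never what is computed.

## Statistics

Group summaries use the arithmetic mean and SE = sd/√n (sample sd, n−1
denominator). Tissue comparisons per brand × metal use the classic
one-way ANOVA F test (with F defined as 0 when the data are entirely
constant), and pairwise contrasts use Tukey's HSD by default, with
Dunnett's many-to-one test (chest as control) as an option — the source
names both procedures without distinguishing their roles. Letters follow
the published convention: "a" marks a tissue that differs from chest,
"b" one that differs from thigh, at α = 0.05. The published letters
themselves are not a reproduction target: they derive from unpublished
per-bird data, so letter logic is exercised on synthetic data only.

## Synthetic data generator

Because the raw per-bird measurements were never deposited, the generator
draws strictly positive samples whose population mean equals the target
group mean and whose population sd equals SE·√n. The default family is
lognormal — residue concentrations are positive and right-skewed — with
parameters moment-matched in closed form; a zero-truncated normal is
offered for sensitivity analysis, with the pre-truncation location and
scale solved numerically (infeasible when sd ≥ mean, which raises naming
the group). SE = 0 degenerates to a constant. Randomness is keyed per
group on (master seed, brand, tissue, metal) via CRC-32 into a numpy
`SeedSequence` spawn key, so identical seeds give byte-identical tables
and subsetting a design never changes a group's draw.

The generator claims only moment fidelity: the true within-group
distribution, any between-metal correlation, and measurement error are
unknown and not emulated. Tests passing on synthetic data therefore
validate the pipeline's algebra and the study-design plumbing, not
distributional features of real residue data.

## Problem sizes and verification

All desk-scale: the full pipeline over the 216-group fixture runs in
well under a second; the synthetic end-to-end checks use the full
216 × 20 = 4 320-bird design, the type-I-error calibration uses 400
seeded replicates of 3 × 10 observations, and the generator
moment-recovery checks use one 50 000-draw group. Hypothesis-based
property tests are derandomised. The end-to-end tolerance for synthetic
risk outputs is ±4 combined standard errors, with the per-metal
coefficient obtained from the linearity of the hazard quotient in the
group mean and group tolerances combined root-sum-square for the hazard
index.

## Known limitations

* Deterministic point estimates only; no Monte-Carlo uncertainty
  propagation, and no dermal or inhalation routes.
* The liver ingestion rate (0.1 g/day, per the study) is far below the
  muscle rate and is used as given; whether it is per-capita or
  per-consumer is not stated in the source.
* Limit screening judges groups by their mean (the only published
  statistic); individual birds above a limit inside a compliant group
  are invisible at group level, though sample-level screening is
  available when per-bird data exist.
* Units are µg/g wet weight throughout, treated as identical to mg/kg;
  no wider unit-conversion framework is provided.
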