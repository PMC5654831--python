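# Methods

## The measurement model

A shotgun-lipidomics experiment on a QTRAP-style instrument acquires, per
sample, one unit-resolution peak list per class-specific scan.  The
package models each acquisition channel as a list of `(m/z, intensity,
s/n)` sticks:

| channel | polarity | quantifies | extract |
|---|---|---|---|
| precursor 184.1 | + | PC, PC-O | total |
| precursor 184.1 | + | SM | hydrolyzed |
| neutral loss 141 | + | PE, PE-O | total |
| class scans | + | TAG, DAG, CE, PS, CER | total (CER: hydrolyzed) |
| fatty-acyl precursor scans | − | chain evidence for PL isobars | total |

Sphingolipids are read from a separately hydrolyzed extract (the
hydrolysis strips acyl-linked glycerolipids that would otherwise crowd the
spectrum).  Positive-mode precursors are modeled as [M+H]⁺ for
PC/PE/PS/SM/CER and [M+NH₄]⁺ for the neutral classes TAG/DAG/CE;
negative-mode precursors as [M−H]⁻ and acyl fragments as carboxylate
anions.  These adducts are the community-standard choices and are
configurable; the original acquisition details are not restated in the
modeled study.

Elemental compositions are assembled as head-group/backbone residue +
aggregate chains − one condensation water per chain, with an ether chain
substituting (+2 H, −1 O).  Sum-composition and molecular-level species of
equal totals therefore share a composition, which is what makes them
isobaric.  SM and CER carry the d18:1 sphingoid backbone by assumption;
their names record only the N-linked acyl.

### Identification database

The database enumerates sum compositions per class over even chain carbons
12–24 (total double bonds capped at 12) plus SM/CER N-acyls (C12–C26,
0–1 double bonds), and candidate chain pairs for the phospholipid classes
from a curated acyl set (14:0 … 24:1) and alkyl set (O-16:0, O-18:0,
O-18:1).  Odd-chain diacyl readings exist only as the alternative
interpretation in the ether/odd-chain ambiguity rule: a mass matching both
an ether and an odd-chain species within tolerance is assigned to the
ether species, the decision logged.  Matching tolerance defaults to 0.3 Th
(unit-resolution data).

### Isotope correction

Two stages, within one channel, ascending target m/z:

1. **Type-II (contamination removal).**  At unit resolution the M+2
   isotopologue of a species falls on the monoisotopic peak of the
   same-class species one double bond down (Δm/z ≈ 0.009 Th).  The
   correction subtracts `a_k(j) · corrected(j)` from every species whose
   target sits `k·1.00336 ± 0.2` Th above an already-corrected species j
   (k = 1..4, `a_k = e_k/e_0`).  Keying on target-m/z differences rather
   than class membership also removes the unit-resolution collisions
   between diacyl isotopologues and ether-class targets (e.g. PC 34:1's
   M+4 lies 0.039 Th from the PC-O 36:6 target) — the dominant
   one-double-bond overlap is a special case of this rule.  Negative
   results clamp to zero with a warning.
2. **Type-I (distribution normalization).**  Division by the species'
   monoisotopic envelope fraction so corrected intensities represent total
   species abundance.

Envelope fractions come from a carbon-only binomial with ¹³C abundance
0.0107 by default.  For a phospholipid the binomial M0 fraction exceeds the
true multi-element value by ~3% (the O₈P and ~80 hydrogens contribute);
a `composition` mode computes the full aggregated convolution over C, H,
N, O and P when that accuracy matters.  In internal-standard quantification
the bias largely cancels because analyte and standard share a class
scaffold and similar carbon counts.  The spectrum simulator uses the same
configured envelope model, so simulation and correction are exactly
self-consistent — noise-free cohorts are recovered to machine precision.

After stage 1 the s/n inclusion rule is applied a second time: a peak that
passed the raw-peak filter but whose contamination-free residual no longer
clears the threshold was an isotopologue of a neighbour, not a detection,
and is dropped.  Without this, every abundant species seeds a halo of
noise-scale ghost species.

### s/n filtering

Inclusion requires s/n **strictly greater than** 10 (configurable); the
boundary reading of "over" is deliberate.  The simulator reports true s/n
(intensity over its own noise σ), as an instrument does.  For peak lists
lacking the column, s/n is estimated as intensity over the MAD-based noise
scale (1.4826 × median absolute intensity) of the non-peak baseline, where
candidate peaks are local maxima or isolated sticks (no neighbour within
1.5 Th).  The estimate needs a dense baseline; sparse noise-free lists get
infinite s/n by construction.

### Quantification and isobar resolution

`conc_i = (I_i / I_IS) · n_IS / m_tissue`, one internal standard per class
(ether classes reference their diacyl class standard — one physical
standard per channel).  Ether-PE species fragment the 141 head-group loss
~3.45× less efficiently than diacyl PE, so PE-O concentrations are
multiplied by 3.45; the factor is applied at class quantification, before
fractional allocation, which is order-invariant under proportional splits.
Sub-detection concentrations (< 10⁻⁶ of the IS-equivalent) are treated as
zero.

Molecular species of PC/PE/PS (and the ether classes) are resolved by
evidence at the sum species' [M−H]⁻ precursor m/z in each chain's
fatty-acyl channel: `evidence(pair) = Σ` over the pair's distinct acyl
chains (alkyl chains yield no carboxylate), fractions are evidence over
total evidence, and molecular concentrations are fractions × the
head-group-scan concentration — conservation of the sum-species total is
exact by construction.  `min` is available as a conservative combiner.
Sum species without fragment evidence pass through unresolved and flagged;
they still count toward class totals but are excluded (logged) from
chain-level metrics.

## Derived metrics

Class totals in nmol/mg tissue; the phospholipid pool is defined as
PC + PC-O + PE + PE-O + PS.  The PC/PE ratio uses the diacyl classes by
default (ether inclusion is a flag; either choice is defensible and the
default is stated rather than implied).  PUFA means ≥ 2 double bonds.
Omega families come from a lookup keyed by (carbons, double bonds) —
shorthand cannot encode double-bond position — with defaults
{18:2→n-6, 18:3→n-3, 20:3→n-6, 20:4→n-6, 20:5→n-3, 22:4→n-6, 22:5→n-3,
22:6→n-3}; 22:5 is genuinely ambiguous and the table is configurable.  A
species with one n-6 and one n-3 chain counts in both family sums
(exclusive majority assignment is available).  Diet deltas are arithmetic
`mean(HFD) − mean(CHOW)` on raw concentrations; the log transform exists
for testing only.

## Statistics

Concentrations are natural-log transformed (positive, right-skewed data);
zeros are replaced by half the species' minimum positive value, all-zero
species excluded, both logged.  The omnibus screen is a one-way ANOVA
across all 10 strain×diet cells; only species with P < 0.05 receive
per-strain CHOW-vs-HFD t tests using the pooled ANOVA MSE with N − k
degrees of freedom, two-sided, significant at p < 0.01, direction taken
from the raw mean difference.  A per-strain two-group ANOVA mode is
provided as configuration, since a two-group reading of the one-way layout
is also coherent; the 10-cell default is the reading consistent with a
*protected* LSD's pooled error.  The p-value-versus-rank table (with
expected uniform quantiles) is a diagnostic output only — it gates
nothing.  No FDR correction is layered on top: protection is the screen.

The same screened-LSD procedure runs on per-sample class totals, the
machine form of highlighting significant class totals in a summary table.

Calibration (`scripts/acceptance.py`, also a test): under a complete null
(10 cells, n = 4, 1000 lognormal species, CV 0.2) the per-comparison
false-positive rate — significant calls over `species × strains`
comparisons, unscreened contrasts counting as evaluated-not-significant —
is ~0.005, at or below the 0.01 LSD threshold.  Note the *conditional*
rate among screened species is ~0.07: protection controls the procedure,
not the conditional error.

## The synthetic cohort

Defaults: 5 strains × {CHOW, HFD} × 4 replicates, 25 mg tissue, 59-species
panel with baseline means scaled to mouse muscle magnitudes (TAG ≈ 8, PC ≈
11, PE ≈ 3, sphingolipids 0.07–0.3 nmol/mg; CER 18:0 dominates its class).
Replicates are mean-preserving lognormal draws, CV 0.2 (comparable to
published SEM/mean ratios at n = 4); CV 0 reproduces group means exactly.
Diet effects: TAG ×2; DAG/CER/SM/CE ×1; n-6-containing PL ×1.3;
n-3-containing ×0.8; double-PUFA PL ×0.6 except in the protected strain
(×1).  Double-PUFA baselines (PC 18:2/20:4 = 0.13, PC 18:2/22:6 = 0.10,
PE 20:4/22:6 = 0.09 nmol/mg) put the double-PUFA share of the PL pool at
1.0–2.6% in every strain×diet cell, the observed range for muscle.  Strain
baselines vary ×0.9–1.1.  Response is 10⁵ counts/nmol, additive noise
σ = 30 counts over a baseline of 30, and the PE-O response in the 141
channel is divided by 3.45.  Fatty-acyl channels are emitted envelope-off:
isobaric partners share an elemental composition, so the envelope cancels
in the fractional split those channels exist to provide.

What the generator does **not** emulate — and hence what green tests do
not certify about real data: chromatography-free matrix effects (ion
suppression), in-source fragmentation, adduct competition, mass-axis
drift, correlated biological covariance between species (draws are
independent), profile-mode peak shapes, and real between-class response
differences beyond the single ether-PE factor.  Parameter recovery on this
simulator validates the arithmetic of the pipeline, not instrument
physics.

One stochastic caveat: with ~75 null species-level diet contrasts
(CER/DAG) at an effective per-comparison rate of ~0.5%, roughly one cohort
in three shows a single stray species call in a null class.  That is the
procedure's designed behaviour, which is why the no-change claim for
ceramide and DAG is asserted on class totals, where the expected stray
rate is negligible.

## Numerical choices and degenerate inputs

- Peaks closer than 0.05 Th merge (intensity-weighted m/z), mirroring
  unit-resolution reporting of coincident isotopologues.
- Matching ties (equidistant targets) break toward lower m/z and are
  logged; several peaks matching one target sum.
- Zero within-cell variance: ANOVA p is 1 when all cell means agree, 0
  otherwise (logged convention); an LSD with zero SE behaves accordingly.
- Smoothing (odd-window moving average with edge truncation) defaults to
  window 1 — the identity — because the simulator emits centroided
  sticks; the operation exists for profile-like inputs.
- Missing diet groups in a strain skip that strain's contrast with a log
  entry; a missing or zero internal standard raises, flagging the sample
  rather than silently dropping it.
- Seeds fully determine output; writing a cohort twice with one seed is
  byte-identical.

## Known limitations

- Unit-resolution collisions are real and not all recoverable: a PC-O
  species sits 0.037 Th from the PE species two carbons up in negative
  mode, so when both share an acyl chain their fragment evidence merges
  and the ether species cannot be resolved; it is retained, flagged, at
  sum level.  The default panel avoids seeding that collision.
- One internal standard per class — no per-species response calibration
  curves; lyso-phospholipid classes are out of scope.
- sn-position and double-bond-position assignment are out of scope;
  "molecular species" here means chain composition, not full structure.
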