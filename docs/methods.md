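# Methods

## Trial design and mass balance

The package models the classical indirect digestibility design for feeds
that cannot be offered alone.  A reference diet (here barley meal) is fed
by itself to one cohort; each test ingredient is fed to another cohort
blended at a fixed as-fed inclusion (default 20%) into the reference diet.
Animals are housed singly in metabolic cages; for each animal and day the
feed offered, the residue (refusal), the fresh feces mass and its
dry-matter fraction are recorded, and each animal's feces are pooled over
the collection period (default 7 days) for proximate analysis on a
dry-matter basis.  The canonical cohort is 9 animals.

Nutrient intake is net fresh consumption times the diet's nutrient content;
fecal output is daily fecal DM times the pooled fecal composition.
Apparent digestibility is `D = (I − F)/I × 100`, "apparent" because
endogenous fecal losses are not corrected.  No clamping is applied
anywhere: values outside [0, 100] are legitimate outcomes of noisy mass
balance and are propagated with an `out_of_range` flag, because silently
clamping would bias the downstream energy estimates.

## Composition basis

Proximate profiles carry an explicit `basis`.  Ingredient tables are
interpreted on the analyzed (air-dry) fraction — the bundled meal rows
close to 100 without dry matter — while fecal compositions are on a DM
basis.  Conversion between bases is always explicit
(`to_dry_matter_basis`), never guessed.  Component closure to 100 is
checked with a ±2 pp default tolerance but is a logged warning, never an
error: the bundled blood-meal row sums to 76.9 and must load regardless
(the missing mass is unexplained in the source tables; the package
records, warns and proceeds).

## The difference method

Assuming the reference diet's indigestibility is unchanged by mixing, the
test ingredient's digestibility follows from the blend's.  The subtraction
is weighted by *nutrient-intake shares* (the Schneider–Flatt convention),
`s = f_ref·ref% / (f_ref·ref% + (1−f_ref)·ing%)`, because diet-mass
weighting is dimensionally wrong whenever the two feeds differ in nutrient
concentration; the two weightings coincide for DM.  Nutrients the
ingredient does not supply (`s = 1`; crude fiber and NFE for the animal
tissue meals) are reported absent — there is nothing to estimate.

Coefficients are computed per animal and then averaged (mean of ratios),
matching the convention of reporting per-treatment sd across animals;
ratio-of-pooled-totals aggregation is available as an option.  The
reference coefficients entering the subtraction are the reference
treatment's means, so per-animal variation of the test cohort propagates
through the linear inversion as `sd(D_ing) = sd(D_diet)/(1−s)`.  This
1/(1−s) inflation is a real statistical property of the method: an
ingredient supplying a small share of a nutrient (e.g. the blood meal's
ether extract, s ≈ 0.97) has its digestibility estimated with ~30-fold
amplified uncertainty.

## Energy chain

`dX = X% × D_X/100`, `TDN% = dCP + 2.25·dEE + dCF + dNFE` (the 2.25
reflects fat's energy density), `DE = TDN% × 44.09 kcal/kg`,
`ME = 0.82 × DE`.  All constants live in `EnergyConstants` and are
overridable per run; the pipeline logs the exact values used.  Absent
components contribute zero TDN terms.  Computation is in full precision;
comparisons against printed tables use tolerances (±0.02 pp on
percentages, ±2 kcal/kg on energies) because published tables round every
intermediate.  Standard deviations propagate assuming independent
coefficient errors — exactly through scalar stages, in quadrature through
the TDN sum.  Published TDN sds are *not* generally recoverable this way:
they reflect per-animal correlations between components (the study's
per-animal aggregation of products), which mean-level inputs cannot
reproduce; the package supports per-animal energy chains when per-animal
coefficients are available.

## Intake and growth metrics

Test-ingredient intake inside a homogeneous mash cannot be measured, so it
is attributed by the inclusion fraction.  The default attribution applies
the fraction to fresh (as-fed) consumption and converts with the
ingredient's own DM content, since rations are formulated as-fed and
selective refusal is unmeasurable; proportional attribution on diet DM is
available (`attribution="dm"`), and the two coincide when ingredient and
diet DM are equal.  Reference plus test attributed intakes sum exactly to
the diet's DM intake.  Body-size scaling uses the mean of initial and
final weight (the natural choice when only those two are recorded;
configurable) as %LW and per kg metabolic weight `(W/1000)^0.75`.  Daily
gain is total gain over the collection length (default 7 days).

## Group comparison

One-way ANOVA uses the classical sums-of-squares decomposition (the MSE is
needed downstream); identical data degenerate to "no difference" (F = 0,
p = 1) rather than an undefined ratio.  Duncan's multiple range test
computes least significant ranges from studentized-range quantiles at
protection levels `1−(1−α)^(p−1)` — quantiles are computed, not tabulated,
so any error df is supported — with the harmonic mean group size under
unequal n.  The letter display follows the classical sequential procedure:
spans are tested widest first, a span contained in a non-significant span
is itself non-significant, and maximal non-significant spans share a
letter, assigned so the largest mean always carries "a"; ties in means
keep input order.  Duncan is unprotected by default (the common choice in
animal-science software); `protected=True` gates the letters on a
significant ANOVA F.  Both the span test and an exhaustive brute-force
re-derivation are kept in the test suite as mutually independent routes.

## The trial simulator

`simulate_trial` runs the mass balance forwards from known truths: daily
offered feed ~ Normal(mean, CV), refusal fraction ~ truncated Normal,
nutrient intakes from the blended ration, per-nutrient fecal output
`I × (1 − D_animal/100)` where `D_animal` is the share-weighted blend of
the reference and ingredient truths plus a per-animal Normal deviation
(biological variation, in percentage points, drawn once per animal and
nutrient).  Fecal fresh mass is back-computed from fecal DM at a fixed
fecal DM fraction (default 0.35), and the pooled fecal composition from
the summed fluxes.  Measurement noise is applied last and only to measured
quantities: multiplicative (CV) on daily fecal fresh mass, additive (pp,
truncated to [0, 100]) on pooled fecal composition.  Truth records are
stored separately and never perturbed.  Refusals are non-selective (mash
assumption), so refusal composition equals diet composition, consistent
with the intake attribution.

Defaults mirror the bundled study's conditions: 9 animals, 7 days, 20%
inclusion, body weight 822 ± 18 g.  Where the study states no value the
defaults are chosen once at realistic levels for adult guinea pigs on
concentrate: 40 g offered/day (CV 10%), refusal fraction 0.25 (CV 30%),
daily gain 6 ± 1 g.  The reference diet's own measured digestibilities
were never published; the simulator's placeholders (DM 77, CP 75, EE 80,
CF 40, NFE 85) are labelled synthetic, with the DM value pinned so that
fecal organic matter never exceeds fecal DM in any blend.  All recovery
claims are conditional on these simulated truths.

Two deliberate tolerances: (1) a configuration whose truths imply a
negative *nutrient* flux (digestibility above 100) is rejected with a
diagnostic; (2) an implied negative fecal-ash residual (fecal organics
exceeding fecal DM) is only warned about, because published coefficient
sets — including the bundled rumen-content row — need not satisfy an exact
component/DM balance, and the closure tests must be able to simulate
exactly those values.

Seeding is mandatory and flows through a single `numpy` Generator, so
identical configurations are bit-reproducible and distinct seeds give
independent trials.

## What the tests show — and problem sizes

With all noise off, analysis inverts simulation to machine precision
(checked to ≥10 significant digits over 100 random feasible truth
configurations; feasible means every nutrient present in both feeds and
reference shares kept below ~0.99 so the inversion stays
well-conditioned).  Under 5% fecal measurement noise and 1 pp per-animal
deviation, 500 replicated rumen-content trials (each with its own
reference trial) recover every nutrient's truth with |bias| < 0.5 pp, and
the recovered animal-to-animal sd matches the injected deviation within a
factor of 2 at the diet level where it is injected.  Duncan letters match
the exhaustive-span definition on 1000 random 2–6-group instances, and
cohorts drawn at the bundled daily-gain means/sds separate the
rumen-content treatment from the protein meals in the large majority of
200 replicates.  These sizes (100 / 500 / 1000 / 200) were chosen as the
smallest giving Monte-Carlo standard errors comfortably below the asserted
margins.

The generator emulates measurement and biological variation but not
physiology: no digestive interactions between ingredients (the difference
method's core assumption is built in, so the simulator cannot probe its
violation), no cecotrophy, no day-to-day autocorrelation of digestibility,
no selective refusal, and linear growth only.  Passing tests therefore
demonstrate the *estimation machinery* is correct and calibrated, not that
the biological assumption holds in real animals.

## Known limitations

- Marker (indicator) methods, true/ileal digestibility and nitrogen
  balance are out of scope.
- The energy system is TDN-based; calorimetric gross energy and net-energy
  systems are not implemented.
- Published per-treatment sds of derived quantities (TDN and energies)
  are reproducible only when per-animal coefficients are supplied;
  mean-level inputs yield independence-assumption sds instead.
- The intake metrics are reported on the package's own consistent
  definitions; inconsistencies inside published intake tables (ratios of
  %LW to g/kg W^0.75 incompatible across rows) are not reproduced.
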