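# Methods

## Scope and assumptions

`pestiscreen` is a descriptor-level screening tool. It consumes
frontier-orbital energies (E_HOMO, E_LUMO in eV, and E_SOMO for the
sensitizer panel), log *D*_o/w at pH 7.4, and — at the substructural tier —
NBO E(2) stabilization energies and Hirshfeld ring charges. It never
computes any of these from structure: the user supplies them from whatever
level of theory they trust, and all compounds in one screen are assumed to
come from a *consistent* level of theory (the cutoffs and bounds are only
meaningful within one method family). Orbital energies are stored in eV,
reaction energetics in kcal/mol; the conversion constant 23.0605
kcal/mol/eV is applied only inside model operations.

The central physical picture: indirect photodegradation is rate-limited by
single-electron transfer from the pesticide to ³CDOM\*, so the SOMO−HOMO
gap is the thermodynamic driver (higher pesticide HOMO ⇒ smaller gap ⇒
more favorable transfer); classical Marcus theory converts the driving
force into an activation barrier, ΔG‡ = (λ + ΔG⁰)²/4λ, which is convex
with its zero exactly at ΔG⁰ = −λ (the inverted region is therefore
represented, and the rate model is capped at the diffusion limit to keep
activationless predictions physical). Ecotoxicity screening rests on the
empirical observation that aquatic concern is minimized for compounds with
low bioavailability (log *D* < 1.7) and large HOMO–LUMO gaps (ΔE > 6 eV),
with E_LUMO as the electrophilicity-specific axis that decouples safety
from photodegradability.

## Parameters and defaults

| parameter | default | units | notes |
|---|---|---|---|
| tier-2 gap → ΔG⁰ model | slope 23.0605, intercept 0 | kcal/mol per eV | placeholder = pure unit conversion; refit with `fit_linear` against reference kinetics data |
| Marcus λ | 35 | kcal/mol | typical aqueous outer-sphere reorganization scale; configurable, recorded in every report |
| barrier → log k model | slope −0.18, intercept 12.09 | — | calibrated, see below |
| diffusion cap | log k = 9.7 | — | near-diffusion-limited second-order rate in water |
| safer space | log D < 1.7, ΔE > 6 eV | — | strict inequalities |
| Briggs rule | log D < 3 | — | strict |
| E(2) good-photodegradation cutoff | > 24 | kcal/mol | strict |
| E(2) lower group boundary | 12 | kcal/mol | midpoint of the published group CI edges (9.9 and 14.3); configurable |
| ring-charge model | slope 146.62, intercept −38.89 | kcal/mol per e | the published univariate fit |
| performance bounds | 12 inclusive (log D, ΔE) boxes | — | five functional classes + seven MOAs |

The tier-2 coefficients (gap → ΔG⁰ and barrier → log k) belong to an
upstream kinetics calibration that is not part of this package, so they
are shipped as *named config entries with documented placeholder defaults*
rather than pretended ground truth, together with `fit_linear` so users
holding reference data can refit them. The default log k coefficients were
fixed once, by solving numerically for the (slope, intercept) under which
the default synthetic population — mixture-mean ΔG⁰ ~ N(10.68, 10.83²)
through λ = 35 and the 9.7 cap, averaged over the default 23-sensitizer
panel — reproduces the declared mixture-mean log k moments (mean 8.65,
SD 0.95). That closes the generator's parameter set self-consistently: the
declared log k moments are *emergent* pipeline outputs, not direct draws.

`logk_predictor` may be switched from `"barrier"` to `"gap"`: the
functional form of the upstream rate calibration (barrier-based vs.
gap-based) is not uniquely determined, so the chaining is a config choice
rather than a hard-coded one.

## Percentile and scoring conventions

`percentile_rank` uses counting with midrank tie handling,
(#below + ½·#equal)/n × 100, with one refinement: when the query value is
itself a member of the reference list, one exact occurrence is removed
first, so a member of a population is ranked against the *other* members.
This makes the unique best of a population score exactly 100, the median
of an odd population score 50, and two identical compounds tie at 50 —
while coinciding with the plain counting formula for external queries
(`exclude_self=False` gives the plain formula, which the property tests
pin against a brute-force oracle).

The composite photodegradation score is the arithmetic mean of the log k
percentile and the −ΔG⁰ percentile. The combination rule is a declared
design choice (the two axes are given equal weight); because both inputs
are rank-based, the score is invariant under any strictly increasing
transform of either underlying quantity.

Semaphore bins: photodegradation uses score quintiles (five colors,
red → green); a score exactly on a bin edge goes to the higher bin.
E_LUMO coding: purple ≥ 50th percentile, pink from the 1st to below the
50th, black below the 1st (displayed as "<1st"). Bracket intervals are
half-open [lo, hi) with the topmost bracket closed at 100.

Boundary semantics throughout: scalar cutoffs are strict (<, >) as
printed; the per-category performance ranges are inclusive on both ends
(they are printed as plain ranges with no openness stated).

## Synthetic data generator

The generator emulates the *statistical* shape of a registry-scale screen,
not its chemistry. Marginals are Gaussian at the declared population
moments (log D 2.87/2.56; ΔE 5.29/0.99 eV; mixture-mean ΔG⁰ 10.68/10.83
kcal/mol); Gaussianity is a declared assumption — only means and SDs are
specified by the study conditions. ΔE is truncated at zero by redrawing
the joint (ΔG⁰, ΔE) pair (a ≈5σ event at the defaults). `homo_coupling`
(default 0.3) correlates ΔE with the photodegradation axis, reflecting
the observed coupling of reactivity and degradability through the HOMO;
setting it to 0 makes the axes independent (verified by a correlation
test at n = 5000). Each compound's E_HOMO is back-solved from its drawn
mixture-mean ΔG⁰ through the configured tier-2 model, so the generating
coefficients are exact ground truth for recovery tests. Sensitizer SOMOs
are spread evenly over ±0.8 eV around −5.54 eV so that pairwise ΔG⁰
spans favorable (negative) and unfavorable values.

SMILES are drawn from a small library of real core exemplars so the
SMARTS detector and deduplicator are exercised, but descriptor values are
**not** structure-consistent; datasets are labeled SYNTHETIC. Consequently,
passing tests demonstrate the pipeline's statistical and algorithmic
contracts — determinism, conservation, moment convergence, coefficient
recovery — not predictive accuracy on real pesticides. In particular the
synthetic safer-space count (~8% of 700) reflects the near-independence
of log D and ΔE in the generator, and should not be read as a statement
about any real registry, where the correlation structure differs.

Tier-3 generation draws ring charges from N(0.338, 0.0678²) — the mean
maps the published line onto the tier-2 ΔG⁰ population mean, and the SD
is chosen so the declared noise scale (SD 4.50 kcal/mol, the published
residual error) yields r² ≈ 0.83 in expectation, which a 200-seed
Monte-Carlo test confirms. E(2) totals are drawn uniformly within the
published per-group confidence bands, with the group keyed to the
compound's ΔG⁰ tercile (stronger donors photodegrade more easily).

## Numerical choices

- `fit_linear` solves OLS explicitly (slope = S_xy/S_xx); r² is defined
  as 0 for constant y; RMSE uses divisor n by default (the convention
  matching the published fit diagnostics; `"n-2"` gives the residual
  standard error); the slope p-value is the two-sided t test, degenerating
  to 0/1 for exact fits and n = 2.
- Duplicate structures are collapsed on RDKit canonical SMILES (default
  aromaticity perception), first occurrence kept.
- Default SMARTS are minimal single patterns per core class; the aniline
  pattern excludes amide/sulfonamide and nitro nitrogens. Whether a vetted
  pattern table treats anilides differently is absorbed by the loadable
  pattern file.
- The E_LUMO no/low-concern reference distribution is not redistributable;
  the package ships a fixed-seed synthetic normal stand-in (mean −0.5 eV,
  SD 1.0 eV, n = 1000), flagged `elumo_reference_synthetic` in configs and
  reports. Absolute E_LUMO percentiles under the default config are
  therefore illustrative only; supply the real reference list via config
  for interpretable values.
- Reports embed a config hash; `compare_redesign` refuses to compare rows
  screened under different configs, since percentile scores are only
  meaningful within one population and parameterization.

## Problem sizes

The registry-scale checks run at n = 700 compounds × 23 sensitizers
(16,100 pairs) and the substructural subset at n = 43, the natural sizes
of the workflow this package supports; the full test suite and the
acceptance script each complete in well under a minute.

## Known limitations

- No quantum chemistry, no log D estimation, no tautomer/protonation
  handling: garbage descriptors in, garbage verdicts out.
- The cutoffs encode acute aquatic toxicity as the hazard proxy; they are
  not a substitute for target-specific or chronic assessment.
- Tier-1 pathway energetics (explicit reaction modeling, electrochemical
  calibration) are out of scope; the tier-2 defaults are placeholders
  until refit against reference kinetics.
- The composite score is relative to the screened population: adding or
  removing compounds changes everyone's percentiles.
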