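# Methods

`dtims` implements the quantitative core of a drift-tube ion mobility
spectrometry–mass spectrometry (DTIMS-MS) reference-library workflow: how
collision cross sections (CCS) are calibrated from arrival times, how raw
per-run feature observations are curated into high-confidence consensus
entries, and how the resulting library is interrogated (suspect screening,
reproducibility, detection and contingency analytics).  This note records
the models, the parameters that matter, and the design choices made where
the workflow left them open.

## Single-field CCS calibration

In the low-field limit the Mason–Schamp relation gives the drift time of an
ion with collision cross section Ω (Å²), charge z, through a tube of length
L under field E in a buffer gas of number density N = P/(k_B T):

    t_d = 16 L N Ω √(μ k_B T / 2π) / (3 |z| e E),        μ = m_ion m_gas / (m_ion + m_gas).

Because t_d is exactly proportional to γΩ with γ = √μ/|z|, arrival times at
a single field strength obey

    t_A = β γ Ω + t_fix,

where t_fix is the mobility-independent transport time through the rest of
the instrument.  `SingleFieldCalibration.fit()` estimates (β, t_fix) by
ordinary least squares over a calibrant table (tune-mix ions of accepted
reference CCS); `ccs_from_arrival` inverts the relation for unknowns.  The
fit is unweighted by default (a weighted option exists); standard errors are
the usual OLS ones.  The ion mass entering μ is taken as measured m/z × |z|.
An optional pre-correction linear in √(m/z) (mass-dependent TOF transit) is
available and off by default.

Geometry defaults are the standard commercial drift-tube configuration
(L = 78.24 cm, E = 17 V/cm, P = 3.95 torr of nitrogen).  Drift temperature
is not part of single-field inversion; the physics oracle defaults to 300 K,
configurable.  Internal computation is SI with declared conversion
constants; all interfaces use ms, Th, Å², torr, V/cm, cm, Da.

## Curation cascade

Observations flow through four gates, in this order:

1. **CCS computation.**  Arrival times are inverted through the fitted
   calibration (tables may instead supply pre-computed CCS).
2. **Expected-ion gates.**  An observation survives only if its measured
   m/z lies within `ppm_max` (default 10 ppm, strict `<`; the inclusive
   variant is a config switch) of the m/z expected for the candidate ion
   species — [M+H]+, [M+Na]+, [M−H]−, or [M]•+, with electron mass included
   so the gate is unbiased at low m/z — and its observed M+1/M abundance
   ratio matches the ¹³C-dominated prediction from the molecular formula.
   The isotope gate is |observed − predicted| ≤ max(20% · predicted, 0.005),
   inclusive; only M+1 is gated by default (an M+2 check for Cl/Br is
   available but off).  The tolerance values are a design choice — the
   workflow convention ("correct isotopic distribution") does not prescribe
   numbers — and both are configurable.
3. **Replicate consensus.**  Per (chemical, ion type, mode) group, the
   largest subset of replicates whose pairwise percent difference
   (100·|a−b|/mean — the symmetric convention; the denominator is a design
   choice) stays within `replicate_pct_max` (default 1%, inclusive) is
   found; it must contain at least `min_replicates` (default 2) members.
   Consensus CCS and m/z are arithmetic means over that subset; excluded
   replicates are logged with reason `replicate`.
4. **Trendline filter.**  A power law Ω = a·(m/z)^b is fitted in log–log
   space across consensus entries, separately per polarity (positive-mode
   ion types pooled, negative separately; `global` and `per_ion_type`
   scopes are available), with one robust re-fit that drops points more
   than 3 MADs from the median residual so outliers cannot drag the trend.
   Entries deviating more than `trend_pct_max` (default 15%, inclusive)
   from the trend are removed with reason `trendline`.  This is the gate
   that catches multimer streaking: solution multimers drift as the
   multimer but dissociate to monomer m/z afterwards, showing anomalously
   large CCS per m/z.  The power-law form is a design choice (CCS–m/z
   clouds of small molecules are power-law-like; a linear form is
   available), as is applying the filter after replicate consensus (the
   order is configurable).  A polarity with fewer than five consensus
   entries cannot define a trend and passes unfiltered with its deviation
   reported as missing.

Every input observation is accounted for exactly once: it either
contributes to a library entry or appears in the rejection log with one of
six closed reasons (`mass_error`, `isotope`, `replicate`,
`insufficient_replicates`, `trendline`, `missing_formula`).  Conservation
and the monotonicity of all three thresholds (tightening never gains
entries) are asserted by the test suite.

Isotope patterns are computed by convolving per-element isotope
distributions on nominal mass offsets, using a static vendored table of
NIST-style isotope masses and representative abundances (`dtims.isotopes`);
no runtime lookups.  The monoisotopic mass uses the lightest stable isotope
per element.

## Screening and comparison

`screen` gates candidate entries on mode (and optionally ion type), a ppm
window on m/z and a percent window on CCS, both inclusive.  The match score
(1 − |ppm|/tol)(1 − pct/tol) is a heuristic ranking aid of this package —
the raw errors are always reported alongside.  `compare_libraries` pairs
two libraries on (chemical, ion type) — mode excluded by default, since
laboratories source the same ion type differently; multiple entries per key
are averaged before pairing — and bins CCS percent differences at the
community's conventional 2% and 5% cuts (upper bounds inclusive).

## Analytics

Detection is defined as library presence.  `mode_overlap` partitions
detected chemicals into the seven exclusive regions of the three-mode Venn
diagram; `class_detection_rates` tallies per-class totals and fractions.
`fisher_exact_2x2` performs the two-sided Fisher exact test under the
probability-mass criterion (all tables with the observed margins whose
probability does not exceed the observed one); a zero margin returns p = 1
flagged degenerate.  The test itself delegates to scipy and is checked in
the suite against a from-scratch hypergeometric enumeration.  Stability and
ionization-amenability labels are consumed as given; chemicals without a
label are excluded from the corresponding contingency table, mirroring
campaigns where such annotations cover only part of the inventory.

## Synthetic campaign generator

`dtims.synthetic` emulates a duplicate-injection, three-mode
(ESI+/ESI−/APCI+) campaign over an inventory drawn from ~80 bundled real
xenobiotic molecular formulas (100–800 Da; repeated formulas are genuine
isomer pairs, so isotope checks and the isomer-aware run planner stay
meaningful).  Chemicals are assigned to thirteen broad use classes with
inventory fractions typical of a large regulatory screening library.

Ground truth: per (chemical, ion type), true CCS = a·(m/z)^b × log-normal
scatter (defaults a = 9.8, b = 0.5, σ = 5% — a realistic spread of
molecular shape about the main trend, comfortably inside the 15% filter
band).  Detectability is Bernoulli per (class, mode) with base rates
0.30/0.25/0.18 for ESI+/ESI−/APCI+ and class overrides encoding the strong
chemistry effects (PAHs ionize by APCI, PFAS by ESI−, dyes and
pharmaceuticals broadly, food additives poorly).

Measurement model: arrival time = β_scale·t_d(Mason–Schamp) + t_fix
(0.25 ms) + Gaussian noise (σ = 0.05 ms, set so that the share of duplicate
pairs passing the 1% replicate gate sits near the ~95% retention typical of
this workflow class); measured m/z carries 2 ppm Gaussian noise; M and M+1
abundances follow the predicted isotope ratio with 5% relative noise.
Artifacts: multimer-streaking chemicals (5%) emit at monomer m/z with CCS
inflated by a factor drawn uniformly from 1.25–1.60 — far enough above the
15% band to be separable, close enough not to be trivial — and degraded
chemicals (3%) emit nothing.  Stability/amenability flags are drawn
correlated with detection so the contingency analytics have signal.

Randomness uses one `numpy` Generator stream per stage, spawned from the
master seed via `SeedSequence`, so adding a stage never perturbs earlier
streams; identical seeds give identical outputs on any platform.

What the generator does **not** emulate: chromatographic peak shapes, raw
profile spectra, saturation, co-elution/interference, carryover, and real
ionization chemistry beyond Bernoulli detectability.  Passing tests
therefore demonstrate the correctness of the calibration algebra, the QC
bookkeeping and the analytics — not instrument-level performance on real
data.

## Numerical choices and degenerate inputs

- Gate boundaries: the ppm gate is strict `<` (the stated convention is
  "less than"); the replicate, trendline, isotope and screening gates are
  inclusive `≤`.
- The replicate-consensus subset is found exactly: for positive values the
  maximal mutually-agreeing subset is a contiguous window in sorted order;
  ties between equally large windows go to the tightest.
- Trendline fitting refuses fewer than 5 points or a single distinct m/z;
  the robust re-fit threshold is 3 × MAD with a 1e-12 absolute floor so an
  exact fit (MAD = 0) keeps all exact points.
- A calibration needs ≥ 2 matched calibrants with distinct γ·Ω; arrival
  times at or below t_fix raise a non-physical-measurement error.
- Zero-margin contingency tables return p = 1 with a degenerate flag;
  an all-zero table is an error.
- Canonical library CSV: fixed column order, `%.6g` floats, UTF-8, LF —
  write∘read is byte-stable, enabling diff-based regression checks.
- Inventory dedup keeps the first occurrence of a repeated chemical_id and
  reports every duplicate with both row indices.
- Run-order planning is greedy largest-remaining-group-first (optimal for
  cooldown-style scheduling), deterministic in the input order, preserving
  input order exactly when no isomers are present; infeasible isomer loads
  raise an error naming the group.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` verify: calibration recovery on
10 calibrants (noise-free to machine precision; 200 Monte-Carlo seeds at
σ = 0.01 ms for bias); end-to-end recovery on a 1000-chemical campaign
under the default noise/artifact conditions; isotope-pattern equivalence
with exhaustive multinomial enumeration on 500 random formulas up to
C50H100N10O10S2Cl2; Fisher agreement with full enumeration over all 135 750
tables of total ≤ 40; screening equivalence with a linear scan on
1000 queries × 1000 entries; and interlaboratory binning on constructed
deviation mixtures.  These sizes keep the full verification run in the
low minutes on a single CPU while exercising every code path at scale.

## Known limitations

- Only singly charged species and four ion types; no multiply charged ions,
  no further adducts, no structure handling (SMILES/InChI).
- Single-field calibration only; travelling-wave and trapped-IMS
  calibration, stepped-field measurement and high-field corrections are out
  of scope.
- The trendline filter assumes one dominant CCS–m/z trend per polarity;
  libraries with strongly separated conformer families may need the
  per-ion-type scope or a looser band.
- Inter-library comparison pairs one value per (chemical, ion type); if an
  external library reports several values per key they are averaged first,
  which differs from comparisons that keep every published value.
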