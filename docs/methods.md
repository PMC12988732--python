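# Methods

## Scope and model

`eggrisk` implements the standard deterministic and probabilistic risk
calculus for trace metals ingested via eggs. Per sampling area and
population group:

- **EDI** (mg/kg bw/day) = C · (FIR/1000) / BW, with C the area-level
  summary concentration (arithmetic mean by default; median and maximum
  are options) in mg/kg and FIR in g/person/day. The gram→kilogram
  conversion happens exactly once, inside the risk kernels — profile
  objects always store FIR in g/day.
- **THQ** = (EF · ED · (FIR/1000) · C) / (RfD · BW · AT). When
  EF·ED = AT this reduces algebraically to EDI/RfD; the test suite
  asserts that identity to 1e-12 relative.
- **HI** = Σ THQ over the assessed metals. The HI of an empty metal set
  is treated as undefined (an error), not zero.
- **CR** = EDI · SF for the carcinogens Cr, Cd, Pb; **TCR** is their sum
  and requires exactly those three components.

All metrics are homogeneous of degree 1 in the concentration vector,
which the property tests exploit.

Classification conventions: HI ≥ 1 → `potential_adverse`; CR/TCR
< 1e-6 → `negligible`, 1e-6 ≤ CR < 1e-4 → `acceptable`, ≥ 1e-4 →
`potentially_unacceptable`. Boundary values go to the flagged/higher
band: published risk tables bold cells "≥ 1.0×10⁻⁴", so exactly 1e-4 is
a flag, and by the same logic exactly 1.0 is an HI flag while exactly
1e-6 is acceptable.

Only the ingestion route is modelled — no dermal or inhalation exposure,
and no age-stratified lifetime averaging beyond the EF/ED/AT parameters.

## Units and bases

Concentrations are carried in mg/kg on the basis declared in the input
(`basis` metadata, dry by default, reflecting freeze-dried egg digests).
The pipeline never converts between dry and fresh mass — no reliable
moisture factor is assumed — so FIR must be supplied on the same basis
as the concentrations. The shipped example profiles are illustrative
USEPA-style values (male 65 kg / 40 g/day, female 56 kg / 40 g/day,
child 15.9 kg / 20 g/day, EF 365 d/a, ED 70 a, AT 25550 d); the child's
intake per kg body weight is ~2× the adults', in the range reported for
child-to-adult non-carcinogenic risk ratios. RfDs and slope factors
(Cr 0.5, Cd 6.1, Pb 0.0085 (mg/kg/day)⁻¹) follow common IRIS/RAIS usage
and are user-editable examples, not measured or survey-specific inputs.

Below-detection-limit records carry the LOD itself and a flag; the
substitution convention (LOD/2 default; LOD/√2, LOD, 0 as options) is an
explicit, logged step, since surveys rarely state theirs.

## Monte Carlo engine

Uncertain inputs are assigned sampling laws (`DistributionSpec`): point,
0-truncated normal, lognormal (log-scale parameters), uniform,
triangular, or empirical (bootstrap of observed values). Defaults:
concentration → empirical per (area, metal); BW → truncated normal with
CV 7.5%; FIR → triangular at ±30% around the profile value; EF/ED/AT,
RfD and SF → points (toxicity references are treated as constants).
Every assignment is overridable; the defaults are explicit modelling
choices and are not claimed to reproduce the settings of any particular
commercial risk package.

Within one iteration, one concentration draw per (area, metal) and one
BW/FIR draw per (area, group) are shared across all metals, so HI sums
comonotone-by-iteration terms and mean(HI) = Σ mean(THQ) holds to
floating precision (asserted). Percentiles use numpy's linear
interpolation between order statistics ("type 7"). Each (area, group)
cell draws from a child stream derived from the master seed and the
CRC-32 of the cell labels, making results bit-reproducible and invariant
to evaluation order; the draw order within a cell (BW, FIR, then metals
alphabetically) is part of the reproducibility contract.

Degenerate (all-point) simulations reproduce the deterministic
assessment bit-exactly on every percentile. The *mean* of a constant
array under pairwise floating summation can differ from the constant in
the last ulp (fl(n·k)/n ≠ k for some k, n), so the degeneracy tests
assert bit-equality on percentiles and ≤ 4 ulp on means. A convergence
checker reports p95 at n ∈ {1e3, 5e3, 1e4, 5e4} and passes when the last
step changes it by < 1%.

## Synthetic data generator

The generator emulates the *design* of a nine-area Chinese egg survey —
codes GY, WC, DG, XY, GZ, SJZ-C, SJZ-F, DZ, EM; free-range vs commercial
production; mining (WC, DZ, EM) vs non-mining; 10 eggs per area; the ten
metals Cr, Mn, Co, Ni, Cu, Zn, As, Se, Cd, Pb. Per (area, metal) it
draws lognormal values with mean = base_mean × free-range factor ×
mining factor and CV `base_cv` (default 0.25, a typical within-area
egg-to-egg spread for trace elements), clipped to per-metal ranges by
rejection resampling.

Default base means are the midpoints of across-region ranges typical for
these metals in eggs (e.g. Cr 0.053–0.14, Zn 9.99–25.09, Cd
1.5–2.3×10⁻³ mg/kg), and the default clips are those ranges. This is a
calibration, not data. Two consequences are documented deliberately:

- The default elevation factors are small (1.1 each) because clipping to
  the across-region ranges caps how much elevation is realizable — the
  Cd range alone limits the combined factor to ≈ 1.21. Experiments with
  larger factors (e.g. the factor-3 parameter-recovery test) set
  `range_clip=None`.
- Midpoint calibration fixes the truth ranking of metals by construction;
  for the closely spaced As and Pb ranges the midpoint order (As > Pb)
  need not match any particular survey's observed order. Ranking tests
  therefore assert against the generator's own truth table, which
  `truth_table()` exposes (pre-clip generating means) for
  parameter-recovery checks.

What passing tests show: the pipeline recovers designed effects (a
free-range factor of 3 is detected at α = 0.05 in ≥ 95% of 200
replicates at 10 eggs/area) and its null behaviour is calibrated (ANOVA
type-I error within [0.03, 0.07] over 1000 replicates). What they do not
show: real eggs have inter-metal correlations, area-specific skew,
censoring at the LOD and matrix effects that the generator does not
emulate, so passing here does not validate conclusions about any real
dataset.

## Statistical comparisons

Per metal: one-way ANOVA across groups (areas, production systems, or
mining classes) at α = 0.05, Tukey HSD pairwise contrasts when the
omnibus test rejects, Shapiro-Wilk (per group, minimum p reported) and
Levene screens reported but not enforced — no silent switch to
nonparametric tests; Kruskal-Wallis is available behind
`method="kruskal"`. Groups that are identical constants yield no finite
F and are reported as degenerate, never significant. Compliance
screening compares each metal's maximum against every configured maximum
permitted level; a value exactly at the limit passes (limits are
maximum *permitted* levels), and an unconfigured metal is reported as
such rather than passed.

## Numerical and interface choices

- Area summary statistics use numpy reductions so the degenerate Monte
  Carlo path reproduces them bit-exactly.
- CSV floats are written with 12 significant digits; a write/read round
  trip is value-exact for such decimals (property-tested).
- Rank ties are broken alphabetically and flagged explicitly.
- Rendered risk matrices use 2-significant-figure scientific notation
  ("5.9×10⁻⁵") with cells ≥ 1e-4 marked; machine-readable CSV/JSON
  outputs are the source of truth and carry full precision.
- Validation is total: every malformed row or config entry is reported
  with its row number or key path; nothing is silently dropped.

## Problem sizes

Default runs use 10,000 Monte Carlo iterations (the conventional choice
for p95 stability, confirmed by the convergence checker); oracle tests
use 100,000 iterations for a 2% closed-form quantile comparison;
calibration and recovery simulations use 1000 and 200 replicates at the
survey's own cell size of 10 eggs/area.

## Known limitations

- No inter-metal correlation structure in generator or simulation beyond
  the shared-draw comonotonicity; no variance-based global sensitivity
  analysis.
- No dry↔fresh basis conversion; mismatched bases between concentration
  and intake are the user's responsibility to reconcile.
- Compliance verdicts depend entirely on the user-supplied limits table;
  the shipped limits are examples, not a current regulatory compilation.
- The exposure-parameter defaults are population-generic examples;
  site-specific assessments must replace them.
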