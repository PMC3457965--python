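# Methods

## The model

`hseprobe` treats probe–target hybridization as an isolated two-state
equilibrium per allele: P + T ⇌ PT with
K = exp(−ΔG°(T)·1000 / (R·T_K)), R = 1.987 cal mol⁻¹ K⁻¹. ΔH° and ΔS° are
sums of published nearest-neighbor dinucleotide parameters (unified
Watson–Crick table; single-internal-mismatch tables; terminal-mismatch
table) plus per-end initiation terms, all at the 1 M NaCl reference
condition. The packaged CSV (`data/nn_params_santalucia.csv`) carries the
source label of each transcribed table and can be replaced by the user.

Only two mismatch geometries are parameterized — the probe 3′ terminus and
the penultimate (−1) position — because those are the only geometries an
allele-discriminating extension probe uses. A 3′-terminal mismatch replaces
its single flanking stack with a terminal-mismatch stack; a penultimate
mismatch replaces its two flanking stacks with internal-mismatch stacks.
Any other mismatch placement, multiple mismatches, ambiguity codes, or
probes < 2 bp raise errors rather than being silently mis-parameterized.
Initiation terms are assigned per duplex end from the probe-strand terminal
base (A/T vs G/C) even when that end is mismatched; this is the same
convention used by other nearest-neighbor implementations and keeps
cross-checks well defined.

The specificity predictor is the match-minus-mismatch duplex concentration

Δcon_M−MM(L) = con_M(L) − con_MM(L)

across the 5′-truncation series of a design. Both con terms rise with
length; their difference is largest in the window where the matched duplex
is near saturation but the mismatched one is not — a difference of two
sigmoids in length, hence the characteristic unimodal ("parabola-like")
curve whose argmax is the predicted best probe length. Single Δcon values
carry no meaning across sets; only the relative comparison within one
series does.

## Numerical choices

- **Equilibrium solver.** The physical root of
  K·x² − (1 + K(P₀+T₀))·x + K·P₀·T₀ = 0 is evaluated in the citardauq form
  x = 2KP₀T₀ / (b + √(b² − 4K²P₀T₀)), b = 1 + K(P₀+T₀), which is stable for
  K·P₀ from ≪1 to ≫1; ln K beyond ±700 short-circuits to the exact limits 0
  and min(P₀, T₀). The discriminant is clamped at 0 against rounding when
  the roots coincide. The test suite checks the closed form against an
  independent iterative mass-action root finder to 10 significant digits.
- **Salt correction.** ΔS°′ = ΔS° + 0.368·N·ln[Na⁺eq], with N = L − 1
  phosphates per strand and [Na⁺eq] = [monovalent] + 3.795·√[Mg²⁺] (the
  120·√(mM Mg) sodium-equivalent). Identity at the 1 M Na⁺ reference.
- **Tm.** Hetero-duplex, CT/4 convention:
  Tm = 1000·ΔH° / (ΔS°′ + R·ln(CT/4)) − 273.15 with CT = P₀ + T₀. A
  non-negative denominator is reported as "no two-state Tm" (None), not NaN.
- **Rounding.** G/C% and Tm are exact internally and rounded only in
  display/TSV layers.
- **Ties and floors.** The plateau is every length with Δcon within 10% of
  the maximum (experimental optima are frequently near-ties across two
  adjacent lengths); the argmax tie-break is toward the shorter probe
  (cheaper, and non-specificity grows with length). A curve whose maximum
  Δcon is below 1% of the per-allele target concentration is flagged
  no-discrimination — the regime where the mismatch is (nearly) as stable
  as the match and no confident optimum exists.

## Default assay conditions

All configurable via `DuplexParams` / `RunConfig`:

| parameter | default | rationale |
|---|---|---|
| temperature | 64 °C | hybridization temperature of the modelled extraction protocol |
| probe concentration | 5 × 10⁻⁶ M | oligonucleotide probe in vast excess |
| per-allele target | 3 × 10⁻¹⁵ M | few hundred ng genomic DNA in 30 µl, two contributors |
| monovalent salt | 0.05 M | typical extension-buffer ionic strength |
| Mg²⁺ | 1.5 × 10⁻³ M | typical extension buffer |

The probe/target ratio (~10⁹) means con_M and con_MM are target-limited;
reported concentrations use the 10⁻¹⁷ M unit in TSVs.

## What the engine does and does not reproduce

The packaged experimental tables include per-length Tm/ΔG°/con values that
were originally produced by a proprietary multi-state simulation engine
under unpublished buffer conditions. Those values are treated as
calibration references only: the package's own engine reproduces their
*structure* — monotone Tm/|ΔG| growth along a trim series, the unimodal
Δcon curve with decline beyond ~21 nt for the worked forward design, the
shift of the optimum to shorter lengths as G/C rises — not their printed
magnitudes. Two structural caveats found while validating:

- Strict monotonicity of Tm and |ΔG(T_assay)| in length is not a theorem:
  a near-neutral added stack (e.g. TA/TA at 64 °C under low salt) can be
  net destabilizing, and the published per-length tables themselves wobble
  by 1 °C in one series. The monotonicity tests therefore target the
  worked forward designs, where every added stack is stabilizing.
- Pointwise dominance of the match melting curve over the mismatch curve
  holds throughout the assay-relevant range but can invert far above the
  melting transition (enthalpy–entropy compensation), where both
  concentrations are ~10⁻⁸ of target; the dominance test runs 0–80 °C.

The multi-state effects the proprietary engine adds (hairpins, probe
dimers, competing genomic sites in one coupled equilibrium) are out of
scope; probe self-structure is covered only by the warning-level poly-G
heuristic in the screen module.

## The G/C-vs-length model

Optimal length falls roughly linearly with G/C content. `GcLengthModel`
fits ordinary least squares of optimal length on G/C% (statsmodels OLS;
residuals and R² retained) and predicts integer lengths. Fitted on the 11
catalogued best-probe points the slope is ≈ −0.23 nt per G/C percentage
point and every experimental optimum is recovered within 2 nt. The
coefficients are this package's own fit to the packaged points; no claim is
made to reproduce any previously published regression line.

## Mismatch-position summary

For the 15 design pairs with both a 3′-terminal and a penultimate (−1)
variant, the summary tabulates the change in best enrichment. With the
strict > 10 percentage-point rule, exactly three pairs improve at −1
(P30FA +12, P244FA +22, rs13304202RC +11; P240FT sits exactly at +10 and is
excluded by strictness) and two degrade beyond −10 (P30RC −22, P38FC −23).
The prose accompanying the original tables lists P240FT rather than P244FA
among the improvers; this package follows the printed per-set values.

## Specificity screen

Count-based sliding comparison of the probe against both strands of the
flanking sequence (default ±50 kb — the maximum locus-to-marker distance at
which successful extraction has been scored). A hit has ≤ 2 mismatches
(configurable); it is "extendable" if its 3′-terminal 3 bases are perfectly
paired. The thresholds are explicit configuration: the original alignment
tool's internal criteria are unpublished, so hit lists are qualitative
diagnostics, not numeric targets. No thermodynamic scoring of off-target
sites is attempted.

## Synthetic loci

`generate_locus` emulates only what the screen and design layers need from
real flanking sequence: i.i.d. background with a target G/C composition, a
central biallelic SNP, and optional planted near-copies of the probe
footprint with a recorded number of internal mismatches and an intact or
broken 3′ end (intact copies spare the whole 3′ anchor region so the
ground-truth label matches the screen's rule). It does not emulate repeat
structure, segmental duplications, or homopolymer tracts, so passing screen
tests demonstrate correctness of the counting rules, not real-genome
off-target rates. Generation is byte-identical for a fixed seed; all
randomness flows from one seeded generator.

## Problem sizes

The packaged analyses are small by construction: 41 probe sets, series of
≤ 21 lengths, screens over a few tens of kb, and 1,000-instance randomized
solver checks; the full test suite and the acceptance script each run in
seconds on one CPU.
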