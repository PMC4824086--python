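# Methods

## Thermodynamic model

`foldlock` scores exactly two structures per design: the locked hairpin
(anchor:sensing stem closed around the cytosine loop) and the unlocked
sensing:miRNA duplex.  Both are treated with the additive two-state
nearest-neighbor (NN) model — an initiation term plus one stacking term per
dinucleotide step — with no dangling ends, terminal mismatches, internal
loops or partition function over alternative structures.  This is a
deliberate restriction: the probe architecture confines the secondary
structure to a single designed hairpin, and scoring anything beyond it
would suggest a precision the two-state model does not have.

Parameter provenance (shipped as versioned CSVs under `foldlock/data/`):

- **DNA/DNA stacks** — Sugimoto et al. 1996 (NAR 24:4501): 10 unique steps
  with reverse-complement-symmetric lookup, initiation ΔH = +0.6 kcal/mol,
  ΔS = −9.0 cal/(mol·K).  Its strongest stacks are CG/GC/GG at −2.8/−2.3/
  −2.1 kcal/mol.  Some secondary sources print these magnitudes labelled
  kJ/mol; the values are kcal/mol, consistent with their ΔH/ΔS sources, and
  the table records `units = "kcal/mol"` explicitly.
- **RNA/DNA hybrid stacks** — Sugimoto et al. 1995 (Biochemistry 34:11211):
  16 asymmetric steps keyed on the RNA strand 5'→3', initiation
  ΔH = +1.9 kcal/mol, ΔS = −3.9 cal/(mol·K).  Used for the sensing:miRNA
  duplex; this is the physical reason unlocking can be favorable at all —
  the RNA target must outcompete a DNA anchor of essentially its own
  sequence.
- **Hairpin loop penalties** — SantaLucia & Hicks 2004 (Table 4), DNA loops
  of 3–10 nt; larger loops use the Jacobson–Stockmayer extrapolation
  ΔG(n) = ΔG(10) + 1.75·R·T·ln(n/10).  Loops below 3 nt cannot close a stem
  and are rejected.  Both tables are cross-checked in the test suite
  against the identical ΔH/ΔS values carried by biopython's
  `MeltingTemp` module, which also serves as an independent oracle for the
  melting-temperature arithmetic.

Every tabulated ΔG°37 satisfies ΔG = ΔH − (310.15 K)·ΔS within
0.1 kcal/mol (the tables' own rounding), enforced by a test.

### Conditions

- **Temperature** — free energies are reported at 37 °C (ΔG°37) throughout.
- **Salt** — single monovalent correction ΔS += 0.368·N·ln[Na⁺] with N =
  number of stacks.  Default [Na⁺] = 45 mM: the assay buffer (20 mM
  Tris-acetate + 25 mM NaNO₃) treated as a monovalent-sodium equivalent.
  The equivalence is a documented package convention, not a measured
  activity; no divalent correction is attempted.
- **Strand concentration** — bimolecular Tm uses the C_T/4 molarity term
  for non-self-complementary association with C_T = 1.5 µM by default, the
  probe/target concentration of the reference assays.  Hairpin melting is
  unimolecular (no concentration term); the loop penalty enters as a pure
  entropy at 37 °C (ΔS_loop = −ΔG_loop/T), i.e. the loop is modelled as
  temperature-independent conformational cost.

### Unlock score

ΔΔG_unlock = ΔG°37(sensing:miRNA duplex, including bimolecular initiation)
− (ΔG_stem + ΔG_loop).  Negative values mean the open probe:target state is
thermodynamically preferred.  Because every NN stack is stabilizing,
ΔΔG_unlock is strictly monotone in anchor length for a fixed target, which
reproduces the qualitative sensitivity ordering of the published anchor
series (22 bp ≪ 11 bp < 10 bp ≈ 9 bp).  With the anchor spanning the full
sensing sequence and a single shared parameter table, all stacks cancel and
the score algebraically reduces to ΔG_init − ΔG_loop — the frozen value the
corresponding test asserts.

## Design engine and calibration

`design_probe` enumerates anchors (default 4 bp up to the sensing length —
4 bp is the shortest published anchor), scores each candidate, and flags:

- **over-locked** — ΔG_hairpin below the *ceiling*: stem too stable to be
  opened, bright but insensitive;
- **under-locked** — ΔG_hairpin above the *floor*: stem too weak to
  template an emissive cluster, sensitive but dim.

Selection is `tm_match` (minimize |Tm_stem − Tm_stem(reference)| among
unflagged candidates, ties to the shorter anchor, since shorter stems were
more sensitive in every published comparison) or `dg_window` (shortest
anchor inside a ΔG_hairpin window).  `dg_window` exists because Tm matching
cannot rationalize the published 4-bp miR-27b anchor (see Limitations).

Three conventions of the published design are shown only graphically and
are fixed by `calibrate()`, a deterministic exhaustive search against the
packaged registry:

1. **Pairing end** — whether the anchor covers the 5' or the 3' terminus of
   the sensing sequence (equivalently, whether the probe reads
   anchor–loop–sensing or sensing–loop–anchor; both close the stem at the
   loop).
2. **Tm objective** — the full unimolecular hairpin estimate (loop entropy
   + salt) or the bare stack-limited ΔH/ΔS two-state estimate.  The latter
   is a *matching objective*, not a physical melting prediction (it ignores
   the loop's entropic clamp and can exceed 100 °C); only relative
   distances between stems matter to the selection.
3. **Floor and ceiling** — free parameters of the flagging rule, never
   hard-coded.  The published screening series constrains both intervals:
   the 6-bp stem must fall above the floor while the 9–11-bp stems fall
   below it, and the 22-bp stem must fall below the ceiling while the
   9–11-bp stems stay above it.  The floor is set to the midpoint of its
   admissible interval; the ceiling is scanned on a 200-point grid inside
   its admissible interval.

A convention succeeds when `tm_match` with the factory reference
(6C-miR-21-10bp) reproduces *every* published anchor choice — 11 bp for
miR-18a and 10 bp for miR-21 itself.  With the packaged canonical miRNA
sequences exactly one convention does: anchor on the sensing 3' terminus,
stack-limited Tm objective, ceiling ≈ −12.5 kcal/mol (admissible interval
roughly −13.7 to −11.3).  The ceiling is load-bearing: without it the
13-bp miR-18a stem matches the reference marginally better (|ΔTm| 0.13 °C
vs 0.27 °C) but is excluded as over-locked.  `calibrate()` records
per-convention diagnostics (selected lengths, distance tables, admissible
intervals) whether it succeeds or not, raises with those diagnostics if no
convention reproduces the registry, and is idempotent.  The calibrated
tolerance (`tm_tolerance_c`, grid 0.5–5 °C) is the smallest grid value
covering twice the worst reproduction distance; it gates selection for new
targets so a wildly mismatched "best" candidate is reported as an empty
selection rather than silently returned.

## Assay pipeline

- **Peak readout** — maximum intensity inside a wavelength window (default),
  tolerant to small peak shifts; per-probe windows come from the registry
  (580 nm readout for the miR-21 probe).  A fixed-wavelength readout is
  available.
- **Quench ratio** — I₀/I per concentration; I₀/I ≡ 1 at c = 0.  Ratios
  below 1 (emission increase on non-target addition, as seen with
  non-target total RNA) are preserved and yield negative log₂ values.
- **Stern–Volmer fit** — least squares of I₀/I = 1 + K_SV·c with the
  intercept fixed at 1 by default (the model forces I₀/I(0) = 1; the
  closed-form slope is Σc(y−1)/Σc²).  A free-intercept variant is provided
  since the original fitting convention is not stated.  Requires ≥ 3
  non-zero concentrations.
- **LOD** — k·CV(blank)/K_SV with k = 3 by default, from ≥ 3 blank
  replicates; reported in concentration and, given a sample volume, in
  moles (20 nM in 500 µl ⇒ 10 pmol).  The rule is configurable because the
  reference experiments state only an achieved bound ("at least 20 nM"),
  not a decision rule.
- **Specificity** — detection call I₀/I ≥ 2 by default, a threshold that
  cleanly separates the published non-target ratios (≈ 1) from target
  ratios (≥ 7); configurable.

## Synthetic data generator

Emulates what the assay assumes and nothing more: a Gaussian emission peak
(center/width per probe color), amplitude divided by (1 + K_SV·c) for
cognate additions (static quenching — the linear plots cannot distinguish
static from dynamic, and the distinction is out of scope), amplitude
multiplied by a drift factor for non-cognate additions (drift > 1 mimics
the emission increase seen with non-target total RNA), and multiplicative
Gaussian noise at a fixed CV (fluorimeter counts scale with signal).
Defaults are the study conditions of the reference assays: 580 nm peak
under 480 nm excitation, I₀ ≈ 3×10⁶ counts, K_SV = 5.33×10⁶ M⁻¹ (I₀/I = 9
at the 1.5 µM panel concentration), titrations spanning 0–1.0 µM, 5% noise
CV, and baseline 0 (baseline-corrected instrument output).  A seed is
mandatory for any stochastic call and identical config+seed gives
bit-identical output.

Passing the closed-loop suites therefore shows that the pipeline recovers
the parameters of data obeying its own model — it says nothing about
spectral shape changes, nanocluster species conversion, inner-filter
effects or matrix effects beyond a scalar drift, none of which the
generator emulates.

## Numerical and interface choices

- Probe/candidate rankings are fully deterministic; ties in `tm_match`
  break to the shorter anchor, in `dg_window` to the shortest in-window
  anchor.
- Loop lengths other than 6 are allowed but warn: in the published loop
  screen 4C loops never fluoresced and 8C loops were irregular, so the
  hexacytosine loop is the fixed design constant.
- Sequences are validated strictly (no IUPAC ambiguity codes — ambiguous
  bases have no defined NN thermodynamics); internal coordinates are
  0-based half-open, user-facing positions 1-based.
- JSON reports carry schema and tool versions, sorted keys and
  6-significant-digit floats, so re-runs are byte-identical and diffable.
  Logs go to stderr; exit codes distinguish unreadable input (2) from
  invalid configuration or empty selection (3).
- The packaged panel uses canonical mature miRNA sequences (miR-21,
  miR-18a, miR-27b, miR-200c, miR-125b, miR-221, miR-451).  The miR-18a
  probe's excitation wavelength is recorded with all three published
  variants (510/520/560 nm); emission readouts known only by color are
  stored as nominal values and flagged as such.

## Test problem sizes

The suite exercises the duplex engine against an independent loop-over-
stacks oracle on 1 000 random 8–22-mers (both duplex classes), recovers
K_SV from 200 seeded 8-point titrations at 5% noise (median within 10%),
and runs the calibration search (2 × 2 conventions × 200-point ceiling
grid) in about one second.  These sizes keep the full suite around ten
seconds while leaving every statistical margin wide.

## Known limitations

- The NN model is two-state: no Mg²⁺, mismatches, bulges, co-axial stacks
  or AgNC–DNA binding energetics; absolute fluorescence intensity and
  emission color are not predicted.
- The calibration fixes conventions by fitting the published registry; it
  is honest about that dependence (diagnostics are always emitted) but a
  different registry or parameter table may calibrate to different
  conventions.
- Tm matching cannot explain the published 4-bp miR-27b anchor — its stem
  (ΔG_hairpin ≈ −0.4 kcal/mol) lies far above any floor the screening
  series admits.  Whether that anchor came from a GC-content criterion or
  empirical screening is unknown; `dg_window` mode is the provided
  alternative, and the registry entry is kept for reference and spectral
  metadata rather than reproduced by the engine.
- Cross-hybridization against a transcriptome background is out of scope;
  specificity is assessed only through measured or simulated panels.
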