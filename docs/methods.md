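# Methods

This note documents the modelling and numerical choices behind `xmlbspm`:
what the format's semantics are taken to be where its description is
ambiguous, how the synthetic data are produced and what they can and cannot
stand in for, and the conventions the maps and renderer use.

## The document model

An XML-BSPM file is one `bspm` root with a metadata `header` and a `leads`
section. The `type` attribute takes exactly four values —
`AVERAGED-BEATS-BSPM`, `AVERAGED-BEATS-BSPM-TRANSFORM`, `CONTINUOUS-BSPM`,
`CONTINUOUS-BSPM-TRANSFORM` — and only the two `*-TRANSFORM` kinds may
contain calculated (`data="calc"`) leads. The legacy spellings
`CONTINUOUS-BEATS-BSPM[-TRANSFORM]` that appear in circulation are accepted
on read with a warning and normalised to the canonical values.

Resolved ambiguities, all surfaced in API documentation:

* **patient / annotations presence.** The format's element tables mark both
  required while its prose treats both as optional (a database may already
  hold the demographics). `validate_document` warns by default and errors
  under `strict=True`.
* **Limb-lead names.** The nine accepted names are aVF, aVR, aVL, I, II,
  III, VF, VR, VL (the legacy unipolar VF/VR/VL are retained by
  Kornreich-style datasets).
* **Beat markers are 0-based sample indices**; no base is stated anywhere,
  so this is declared prominently. A lead-specific `leadAnn` entry takes
  precedence over the `"*"` wildcard when both could apply.
* **Coordinates** are in the embedded SVG's user-unit space, origin
  top-left, y downward (the SVG convention); the format only ever shows
  pixel offsets against the diagram.
* **`mVSteps`** is mentioned once in circulation as a record attribute but
  defined nowhere; only `sampleMultiplier` is implemented.
* **comment `fullName`/`email`** are strings (their printed "Float" type is
  an obvious typo).

Defaults applied on read and elided on write: `sampleMultiplier` 1,
`waveScale` 0.04, `data` `raw`.

## Serialisation dialect

The format prints no complete example document, so the writer fixes a
dialect: no XML namespace, header children in table order (patient, record,
annotations, comments, limbLeads, transformations, diagram), numbers in
their shortest exact decimal form (so `read(write(doc)) == doc` bit-for-bit
on every field; a `numeric_precision` option can round instead),
`recordingTime` in the canonical `HH:MM:SS:SSS` (the dotted form is accepted
leniently). The embedded SVG travels in a CDATA section and is therefore
never entity-escaped; an SVG containing the sequence `]]>` (legal only
inside an attribute value) cannot be stored and is rejected with a clear
error rather than silently corrupted.

## The equation language

Grammar: `[Lead` + decimal integer + `]` and `[limbLead` + name + `]`
references, decimal literals, `+ − * /`, parentheses; `*`/`/` bind tighter
than `+`/`−`, operators are left-associative, whitespace is insignificant,
and keywords are matched case-sensitively as printed. Unary minus is
accepted (needed for VCG polarity flips) and represented as `0 − x`, with
negated literals folded so printing and re-parsing is an exact identity.

Evaluation is element-wise over aligned sample vectors with literals
broadcasting. Three deliberate choices:

* **Calculated leads see physical units.** Raw stored values are multiplied
  by `sampleMultiplier` *before* any equation is evaluated, because
  transformations express physiology, not storage encoding.
* **Calc may reference calc**, resolved in topological order with cycle
  detection (a cycle is reported with the offending lead ids). This is
  neither required nor forbidden by the format; allowing it maximises
  expressiveness and cycles are unambiguous errors.
* **Division by zero is an error naming the sample position**, not a silent
  NaN, so corrupt files fail loudly.

The evaluator is cross-checked in the tests against an independently
written per-sample recursive interpreter, exactly, on 1,000 random
expression trees.

## Built-in Lux-192 transformations

The Lux-192 constants are: RA = lead 25, LA = lead 85, LF = lead 96
(Mason–Likar torso sites, yielding the exercise variant of the 12-lead
ECG); V1 = mean of leads 52 and 53; Frank sites I=16, A=100, H=145, F=156,
E=64, M=148. The Einthoven/Goldberger formulas themselves are standard
electrocardiography supplied by this package, not part of any stored
dataset; they are correct as plain differences because the WCT reference
cancels. V2–V6 have no published interpolation for this layout and are an
extension point (`precordial=` argument or an external transformation
file), not a guess. VCG polarity follows the common Frank convention
(X = A−I leftward, Y = F−H inferior, Z = M−E posterior) with a
`flip_polarity` option.

## Maps

* Time→index uses round-half-up; sub-sample behaviour is otherwise
  unspecified, and no interpolation between samples is attempted.
* Isointegral uses the rectangle rule (value = Σ samples × 1000/f, units
  µV·ms). Rectangle sums make window additivity exact in exact arithmetic;
  in float64 it is bit-exact whenever sample values are integers — which
  stored-unit BSPM data always are — and holds to rounding error (~1e−12
  relative) on arbitrary physical-unit signals.
* ST40 evaluates the isopotential field at `qrsOffset` + 40 ms, per lead
  when per-lead markers exist.
* Grid interpolation is piecewise-linear over a Delaunay triangulation of
  the electrode positions (NaN outside the hull); `wrap_horizontal`
  duplicates electrodes shifted by ± the diagram width to close the
  unrolled thorax seam. Linear interpolation preserves constants and obeys
  the maximum principle, both of which are tested.
* Rendered traces are scaled by `waveScale` in both time and amplitude and
  centred on the electrode; positive potential is drawn upward, i.e.
  toward decreasing SVG y (SVG's axis points down).

## Synthetic data

The generator reproduces the two study conditions the format was exercised
with:

* **Lux-192**: a 12 × 16 grid, rows equally spaced over the central 70% of
  the diagram height, columns equidistant over the full width; 600 samples
  per lead at 1000 Hz (115,200 stored values).
* **Kornreich-117**: 9 × 13 = 117 electrodes with unequal,
  seed-deterministic column spacing; 300 samples per lead at 500 Hz
  (35,100 values) plus VR/VL/VF limb leads (900 values).

Lead numbering is column-major, top-to-bottom then left-to-right. This is a
declared stand-in: the historical Lux numbering is not recoverable from the
format description, and the built-in transformation constants are applied
to this numbering as given, so derived "12-lead" waveforms are shape-
plausible but not anatomically calibrated.

Signals come from a single dipole on the axis of a cylinder whose
circumference equals the diagram width. The moment is a sum of Gaussian
wave components (P at 120±12 ms, a biphasic QRS at 210±6/225±7 ms, T at
400±30 ms) and each electrode at surface point *p* sees
φ = k·(p̂·d(t))/|p|², with k = 3×10⁷ chosen so potentials peak near 2 mV.
Samples are stored as integers with `sampleMultiplier` set so the peak
stored magnitude is ≈2000, deliberately exercising the multiplier path.
Wildcard beat markers are placed at µ±3σ of each wave (a fixture
convention); with the defaults, qrsOffset lands at sample 246 so the ST40
instant is 286 ms. Limb leads are sampled at three fixed remote points of
the same field. Everything is deterministic in the seed; equal seeds give
byte-identical files.

What the model does give: spatially smooth fields, antipodal sign
inversion for horizontal moment components, realistic document sizes
(~320 KB raw, ~16% after gzip) and plausible beat morphology. What it does
not: torso inhomogeneity (it is a far-field kernel, not a boundary-element
model), pathology, noise, beat-to-beat variability, or a anatomically
faithful electrode numbering. Tests passing on these fixtures demonstrate
format, evaluator and map correctness — not clinical validity of any
derived waveform.

`random_document` additionally fuzzes the serialiser with small randomized
but always-valid documents (optional metadata present/absent, calc leads,
unusual multipliers) for the round-trip property.

## Problem sizes and tolerances

The test suite and the acceptance script run the full study conditions
(192×600 and 117×300) — generation, serialisation and analysis all complete
in seconds, so nothing is scaled down. Identity checks (Einthoven,
Goldberger) are asserted at 1e−12 relative to the signal scale;
exact-equality assertions are restricted to computations that are exact in
float64 (integer-valued sums, index arithmetic, round trips).

## Known limitations

* Continuous multi-beat recordings are storable (`CONTINUOUS-*` types) but
  the generator only emits averaged beats, and no streaming parser is
  provided for multi-gigabyte files.
* No XSD/Schematron artifact is generated; `validate_document` is the
  reference validator.
* Contour-line vectorisation and interactive viewing are out of scope; the
  raster output is intended for downstream contouring tools.
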