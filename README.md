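# xmlbspm

A Python library and command-line tool for **XML-BSPM**, an XML interchange
format for Body Surface Potential Map (BSPM) recordings.

A BSPM records the heart's electrical activity with a large array of
unipolar torso electrodes — published layouts range from 32 to 219 leads —
instead of the ten standardised electrodes of the 12-lead ECG. Because no
two BSPM systems agree on electrode count or placement, a storage format
must carry not just the waveforms but also the electrode geometry: XML-BSPM
embeds an unrolled 2D torso diagram as SVG and anchors each lead's electrode
to it with `(x, y)` coordinates. Derived leads (the 12-lead ECG, the Frank
vectorcardiogram, other BSPM layouts) are stored as arithmetic equations
over the map's own leads, e.g. a pseudo-V1 interpolated between two chest
electrodes:

```
V1 = ([Lead52] + [Lead53])/2
```

Since every BSPM lead is unipolar against the Wilson central terminal (WCT),
the WCT cancels in differences and the limb leads follow from the
Mason–Likar torso sites that coincide with map electrodes (Lux-192: RA=25,
LA=85, LF=96):

```
I = LA − RA      II = LF − RA      III = LF − LA
aVR = RA − (LA+LF)/2   aVL = LA − (RA+LF)/2   aVF = LF − (RA+LA)/2
```

## What the package does

* **model / xmlio** — typed in-memory documents, structural validation
  (lenient and strict modes), lossless read/write with CDATA-wrapped SVG,
  default handling (`sampleMultiplier` → 1, `waveScale` → 0.04), diagram
  resolution with external-URL fallback, compression statistics.
* **equations** — parser, pretty-printer and element-wise evaluator for the
  derived-lead equation language (`[LeadN]`, `[limbLeadX]`, `+ − * /`,
  parentheses), plus full signal resolution (multiplier applied, calculated
  leads materialised in dependency order).
* **transforms** — built-in Lux-192 → 12-lead ECG and Lux-192 → Frank VCG
  transformation sets, generic application of any transformation, and
  reading/writing shareable external transformation XML files.
* **maps** — isopotential and isointegral maps, the ST40 ischaemia map
  driven by beat-marker annotations, linear interpolation onto a raster for
  contouring, and SVG rendering of all leads as scalar traces over the
  torso diagram.
* **synthetic** — deterministic generators for the Lux-192 (12×16 grid)
  and Kornreich-117 (unequal column spacing, VR/VL/VF limb leads) study
  conditions, a compact torso SVG, and a single-dipole beat simulator so
  the whole stack is testable offline.

## Worked example

Generate a synthetic Lux-192 recording and inspect it:

```
$ python -c "
from xmlbspm.synthetic import lux192_preset
from xmlbspm.xmlio import write_bspm
open('lux.xml','wb').write(write_bspm(lux192_preset(seed=1, include_transformations=True)))"
$ xmlbspm info lux.xml
type:             AVERAGED-BEATS-BSPM
id:               lux-192-synthetic-1
layout:           Lux-192
leads:            192
samples/lead:     600
frequency:        1000 Hz
sampleMultiplier: 1.05967
annotations:      present
limb leads:       0
transformations:  12-lead ECG, VCG
size:             332296 bytes raw, 51918 gzip
```

192 leads × 600 samples at 1000 Hz is one averaged beat per electrode
(115,200 stored values); samples are stored as compact integers and scaled
back to microvolts by the `sampleMultiplier` (here 1.05967). The gzip size —
about 16% of the raw XML — is why the format's verbosity is acceptable for
telemonitoring.

Derive the vectorcardiogram and an ST40 map:

```
$ xmlbspm derive lux.xml --transform vcg --out vcg.csv   # columns X,Y,Z
$ xmlbspm map lux.xml --kind st40 --out st40.csv         # leadId,x,y,value
$ xmlbspm render lux.xml --out traces.svg                # 192 scalar traces
```

The same operations are one-liners in Python:

```python
from xmlbspm import read_bspm, resolve_signals, apply_transformation
from xmlbspm import lux192_to_12lead_transformation, isointegral

doc = read_bspm("lux.xml")
twelve = apply_transformation(doc, lux192_to_12lead_transformation())
# Einthoven's identity holds to machine precision:
# max |I + III - II| ~ 5.7e-14 microvolts
qrst_area = isointegral(resolve_signals(doc), 0.0, 600.0)
```

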