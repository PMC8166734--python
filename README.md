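# hipcal

Deterministic modelling of how radiographic **calibration errors**
propagate into **implant-size selection** during digital templating for
total hip arthroplasty (THA).

Preoperative templating overlays CAD outlines of prosthetic components
on a calibrated digital radiograph. The calibration (magnification)
factor is usually derived from a radio-opaque marker; a malpositioned
marker miscalibrates the image by several percent. `hipcal` answers the
question surgeons and planners actually face: *given a calibration error
of e percent, how many component sizes off will the templated acetabular
cup be?*

## The model

A cup of true diameter `s` (mm) templated under a calibration error `e`
(percent) appears with projected diameter

```
s_proj = s * (100 + e) / 100
```

The pre-snap deviation `s * e / 100` is linear in both arguments, so a
given error costs more on large cups. The planner then selects the
catalog size nearest `s_proj` (cup catalogs come in 2 mm increments),
which quantizes the deviation into whole component sizes. The inverse
lookup divides the error back out: a cup templated at 56 mm under a
suspected +8% error should really be `snap(56/1.08) = 52` mm. The
relationship is inverse — a marker placed too close to the X-ray source
inflates the assumed magnification and yields undersized templates.

Two preset scenarios are swept exhaustively, in 1% error steps:

| scenario | cup sizes (mm) | errors | rationale |
|----------|----------------|--------|-----------|
| `group1` | 44–66, 2 mm steps (12 sizes) | ±12% | common cups, common errors |
| `group2` | 38–72, 2 mm steps (18 sizes) | ±24% | all plausible cups incl. revision, extreme errors |

## Worked example

```
$ hipcal lookup 56 --error 8
templated 56 mm at +8% error -> optimal 52 mm (-4 mm, -2 sizes)

$ hipcal lookup 52 --error 8 --direction templated_from_optimal
optimal 52 mm at +8% error -> templated 56 mm (+4 mm, +2 sizes)
```

An 8% calibration error makes a 52 mm cup project to 56.16 mm; the
nearest catalog size is 56 mm, i.e. the plan is two component sizes
(4 mm) too large — and correcting the templated 56 mm cup recovers the
52 mm optimum.

```
$ hipcal matrix --preset group1 --out t1.csv --html t1.html --plot f1.png
matrix: 12 sizes x 13 errors (44-66 mm, +/-12% in 1% steps)
max deviation: 7.9 mm pre-snap, 8 mm snapped = 4 component sizes
wrote t1.csv
wrote t1.html
wrote f1.png
```

Over the common scenario the worst continuous deviation is 7.9 mm
(66 mm cup at ±12%), equivalent to 4 component sizes after snapping.
The CSV holds the size × error deviation matrix in mm (one decimal); a
`*_bins.csv` sidecar holds the severity bins (deviations above eight
sizes are combined into one `>8` bin); the HTML table color-codes each
cell by its bin; the plot shows one straight projection line per cup
size. By symmetry the matrix reports the positive error side by default
(`--report-side both` for the full axis). Batch lookups read a
two-column CSV (`hipcal batch cases.csv`).

The same API is available in Python:

```python
from hipcal import build_matrix, scenario, summarize
s = summarize(build_matrix(scenario("group2")))
s.max_abs_snapped_mm, s.max_abs_steps   # (18.0, 9)
```

## Layout

- `hipcal.catalog` — discrete implant catalogs, nearest-size snapping,
  mm ↔ component-size conversion
- `hipcal.error_model` — the projection formula, full per-case
  evaluation, and the inverse (templated → optimal) correction
- `hipcal.matrix` — error-grid sweeps, severity binning, summaries,
  figure series
- `hipcal.render` — CSV / color-coded HTML / PNG-SVG plot writers
- `hipcal.cli` — `hipcal matrix | lookup | batch`
- `hipcal.fixtures` — seeded random catalogs and case lists for
  property-based tests

See `docs/methods.md` for modelling assumptions and design choices.
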