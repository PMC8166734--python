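# Methods

## Model

Digital templating scales a CAD template by the radiograph's
magnification factor, so a relative calibration error `e` (percent)
multiplies every templated dimension by `(100 + e)/100`. For a cup of
true diameter `s` mm the projected diameter is

    s_proj = s * (100 + e) / 100,

a deterministic, linear model: the pre-snap deviation `s·e/100` is odd
in `e`, strictly increasing in `s` for fixed `e ≠ 0`, and zero at
`e = 0`. There is no stochastic component anywhere in the model; the
only randomness in the repository lives in the test fixtures and the
oracle cross-checks.

The planner cannot use the continuous projection: acetabular cups come
in discrete catalogs, essentially universally in 2 mm increments. The
selection rule is nearest-neighbour snapping of the projection onto the
catalog lattice. Snapping quantizes the linear deviation into whole
component sizes, the clinical unit in which templating errors are
reported (1 size = 1 increment = 2 mm here).

The inverse lookup answers the practical question "what should have
been chosen": dividing the error back out, `snap(templated·100/(100+e))`.
The error enters multiplicatively, so forward and inverse are exact
inverses before snapping; after double snapping the round trip can
drift by at most one increment, a bound the test suite verifies
exhaustively on both scenario grids.

## Scenarios

Two preset sweeps define the study conditions; both use 2 mm catalogs
and 1% error steps:

- `group1`: sizes 44–66 mm (12 sizes), errors ±12% — the clinically
  common range of cups and of observed calibration errors;
- `group2`: sizes 38–72 mm (18 sizes), errors ±24% — all plausible
  sizes including revision cups, and the extreme errors reported in the
  calibration literature.

These values are fixed presets, not tuning knobs; custom catalogs and
grids are first-class through `make_catalog` / `make_error_grid`.

## Numerical and design choices

**Lattice extension (unclamped snapping).** At +24% a 72 mm cup
projects to 89.28 mm, far beyond any real catalog. Clamping to the
catalog span would silently cap the reported deviation at the span, so
by default the increment lattice extends beyond both catalog ends and
the deviation matrix reports the full selection error (up to 18 mm = 9
sizes in `group2`). A `clamped` flag models a realistic bounded
catalog, where out-of-range projections return the nearer endpoint.
The extension never produces non-physical sizes: candidates are
restricted to positive diameters. Catalogs given as explicit irregular
size lists have no increment lattice; they are always clamped and the
mm→sizes conversion is undefined for them.

**Tie rule at exact midpoints.** A projection exactly halfway between
two lattice sizes (e.g. 51.0 between 50 and 52) has no unique nearest
neighbour. The default `toward_true` picks the candidate nearer the
true size, i.e. minimizes the final deviation — the conservative
reading of "choose the size closest to the true one"; deterministic
`down`/`up` alternatives are selectable. On the preset grids midpoints
are rare (integer sizes × integer percents hitting an odd mm value)
and the choice never affects the reported maxima.

**Floating point.** Lattice membership and midpoint detection use an
absolute tolerance of 1e-9 mm; all deviations are kept at full
precision internally.

**Display rounding.** Table cells print the mm deviation to one
decimal with ties rounded away from zero (7.92 → 7.9, 0.25 → 0.3);
bankers rounding would distort half-way cells. The headline "7.9 mm"
for `group1` is the pre-snap maximum 66 × 12% = 7.92 rounded this way;
the snapped maximum is 8 mm = 4 sizes.

**Severity binning.** Deviations are binned by |sizes|: 0…8 each get
their own bin, anything larger is combined into a single `>8` bin
(signed variants `-3`, `<-8` in two-sided reports). The HTML writer
colors cells by bin with a white→dark-red sequential ramp; the palette
is configurable since no canonical one exists.

**Reporting side.** The snapped deviation is symmetric in the error
sign except possibly at midpoint ties, so matrices default to the
positive error half-axis; `report_side="both"` gives the full axis.
Figure series always cover both signs.

**Known inconsistency in the large sample.** The worst case sometimes
quoted for the extreme scenario, ±21.1 mm ≈ ±10 sizes, is not
derivable from the projection formula on the stated grids: the maximum
continuous deviation is 72 × 24% = 17.28 mm, and snapping (89.28 →
90 mm) gives 18 mm = 9 component sizes. The package reports the
formula-derived values; tests assert 18 mm / 9 sizes.

## Fixture generator

`hipcal.fixtures` draws uniform catalogs (min size, size count,
increment from a small set) and (size, error) case lists from a single
integer seed, for property-based tests: snapping vs a brute-force
nearest-size enumeration, round-trip bounds, serialization stability.
It emulates catalog *structure* only — it does not model radiographic
geometry, marker placement, or the distribution of real calibration
errors, so passing tests establish the correctness of the deterministic
propagation and snapping logic, not claims about error prevalence in
clinical practice.

## Problem sizes

Everything is desk-scale: the largest sweep is 18 sizes × 49 errors,
and the oracle cross-checks use 10^4 random projections. The full test
suite and the acceptance script each run in seconds.

## Limitations

- Only acetabular cups are modelled; femoral stem templating involves
  additional geometry and is out of scope.
- The model takes the calibration error as given; estimating it from
  marker geometry (intercept-theorem projection, spherical-marker
  distortion, dual-marker schemes) is out of scope.
- Real planning involves human judgment and intraoperative findings;
  the matrix isolates the calibration contribution only.
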