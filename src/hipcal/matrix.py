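"""Deviation matrices: sweep an error grid over a catalog.

The central artifact is a size x error grid of expected templating
deviations — how far the selected component ends up from the optimal one,
in mm and in whole component sizes — together with the per-size linear
error curves that the matrix quantizes.

Two preset scenarios match the study conditions:

``group1``
    common cup sizes 44-66 mm, calibration errors up to +/-12% in 1% steps
    (the clinically common range);
``group2``
    all plausible sizes 38-72 mm, errors up to +/-24% in 1% steps
    (the extremes reported in the calibration literature).

Because the deviation is odd in the error (up to snapping ties), reports
conventionally show only the positive half of the error axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal

import numpy as np
import pandas as pd

from .catalog import ImplantCatalog, TieRule, preset

__all__ = [
    "ErrorGrid",
    "make_error_grid",
    "ScenarioConfig",
    "scenario",
    "SCENARIO_PRESETS",
    "DeviationMatrix",
    "build_matrix",
    "bin_label",
    "MatrixSummary",
    "summarize",
    "figure_series",
    "round_half_away",
]

ReportSide = Literal["positive_only", "both"]

#: Deviations beyond this many component sizes share one bin.
BIN_CAP = 8


@dataclass(frozen=True)
class ErrorGrid:
    """Symmetric sweep of signed calibration errors in percent."""

    max_abs_pct: float
    step_pct: float
    values: tuple[float, ...]

    def positive(self) -> tuple[float, ...]:
        return tuple(v for v in self.values if v >= 0)


def make_error_grid(max_abs_pct: float, step_pct: float = 1.0) -> ErrorGrid:
    """Build the grid ``-max, ..., -step, 0, +step, ..., +max``."""
    if max_abs_pct < 0:
        raise ValueError(f"max error must be non-negative, got {max_abs_pct}")
    if step_pct <= 0:
        raise ValueError(f"step must be positive, got {step_pct}")
    n = max_abs_pct / step_pct
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"step {step_pct}% does not divide the range +/-{max_abs_pct}%"
        )
    n = int(round(n))
    values = tuple(i * step_pct for i in range(-n, n + 1))
    return ErrorGrid(max_abs_pct=max_abs_pct, step_pct=step_pct, values=values)


@dataclass(frozen=True)
class ScenarioConfig:
    """A catalog + error grid + reporting conventions, ready to sweep."""

    catalog: ImplantCatalog
    grid: ErrorGrid
    tie_rule: TieRule = "toward_true"
    report_side: ReportSide = "positive_only"


SCENARIO_PRESETS = {
    "group1": ("group1", 12.0),
    "group2": ("group2", 24.0),
}


def scenario(
    name: str,
    tie_rule: TieRule = "toward_true",
    report_side: ReportSide = "positive_only",
) -> ScenarioConfig:
    """Preset scenario: ``group1`` (44-66 mm, +/-12%) or ``group2``
    (38-72 mm, +/-24%), both in 2 mm / 1% steps."""
    try:
        cat_name, max_err = SCENARIO_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIO_PRESETS)}"
        ) from None
    return ScenarioConfig(
        catalog=preset(cat_name),
        grid=make_error_grid(max_err, 1.0),
        tie_rule=tie_rule,
        report_side=report_side,
    )


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (7.92 -> 7.9, 0.25 -> 0.3, -0.25 -> -0.3).

    Table cells are printed to one decimal with this convention; numpy's
    bankers rounding would print 0.25 as 0.2.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def bin_label(steps: int, signed: bool = False) -> str:
    """Severity bin for a deviation of ``steps`` component sizes.

    Magnitudes 0..8 get their own bin; anything larger is combined into
    one ``">8"`` group. With ``signed=True`` the sign is preserved
    (``"-3"``, ``"<-8"``) for two-sided reports.
    """
    mag = abs(int(steps))
    if mag <= BIN_CAP:
        return str(int(steps)) if signed else str(mag)
    if signed and steps < 0:
        return f"<-{BIN_CAP}"
    return f">{BIN_CAP}"


@dataclass(frozen=True)
class DeviationMatrix:
    """Size x error grid of templating deviations.

    Rows are true component sizes (mm), columns calibration errors (%).
    ``deviation_mm`` holds full-precision mm deviations of the selected
    size from the optimal size; ``deviation_steps`` the same in whole
    component sizes; ``bins`` the severity labels used for color coding.
    ``presnap_mm`` is the continuous deviation before catalog snapping
    (``size * error / 100``).
    """

    config: ScenarioConfig
    deviation_mm: pd.DataFrame
    deviation_steps: pd.DataFrame
    bins: pd.DataFrame
    presnap_mm: pd.DataFrame

    @property
    def sizes(self) -> tuple[float, ...]:
        return tuple(self.deviation_mm.index)

    @property
    def errors(self) -> tuple[float, ...]:
        return tuple(self.deviation_mm.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.deviation_mm.shape


def build_matrix(config: ScenarioConfig) -> DeviationMatrix:
    """Evaluate every (size, error) cell of the scenario.

    Each cell composes projection, catalog snapping and mm-to-steps
    conversion for one true size under one calibration error. With
    ``report_side="positive_only"`` only errors >= 0 are kept (the
    negative half is its mirror image up to snapping ties)."""
    from .error_model import evaluate  # local import avoids cycle at import time

    errors = (
        config.grid.positive()
        if config.report_side == "positive_only"
        else config.grid.values
    )
    sizes = config.catalog.sizes
    signed = config.report_side == "both"

    mm = np.empty((len(sizes), len(errors)))
    steps = np.empty((len(sizes), len(errors)), dtype=int)
    labels = np.empty((len(sizes), len(errors)), dtype=object)
    presnap = np.empty((len(sizes), len(errors)))
    for i, s in enumerate(sizes):
        for j, e in enumerate(errors):
            r = evaluate(s, e, config.catalog, tie_rule=config.tie_rule)
            mm[i, j] = r.deviation_mm
            steps[i, j] = r.deviation_steps
            labels[i, j] = bin_label(r.deviation_steps, signed=signed)
            presnap[i, j] = r.projected_size - s

    idx = pd.Index(sizes, name="size_mm")
    cols = pd.Index(errors, name="error_pct")
    return DeviationMatrix(
        config=config,
        deviation_mm=pd.DataFrame(mm, index=idx, columns=cols),
        deviation_steps=pd.DataFrame(steps, index=idx, columns=cols),
        bins=pd.DataFrame(labels, index=idx, columns=cols),
        presnap_mm=pd.DataFrame(presnap, index=idx, columns=cols),
    )


@dataclass(frozen=True)
class MatrixSummary:
    """Worst-case deviations over a whole matrix.

    ``max_abs_presnap_mm`` is the largest continuous deviation before
    snapping, reported to one decimal as in the tables;
    ``max_abs_snapped_mm`` and ``max_abs_steps`` are the largest
    deviations of the actually selected size.
    """

    max_abs_presnap_mm: float
    max_abs_snapped_mm: float
    max_abs_steps: int


def summarize(matrix: DeviationMatrix) -> MatrixSummary:
    """Maxima of |deviation| over all cells, pre- and post-snapping."""
    if matrix.deviation_mm.empty:
        raise ValueError("cannot summarize an empty matrix")
    return MatrixSummary(
        max_abs_presnap_mm=round_half_away(
            float(matrix.presnap_mm.abs().to_numpy().max()), 1
        ),
        max_abs_snapped_mm=float(matrix.deviation_mm.abs().to_numpy().max()),
        max_abs_steps=int(matrix.deviation_steps.abs().to_numpy().max()),
    )


def figure_series(config: ScenarioConfig) -> dict[float, list[tuple[float, float]]]:
    """Per-size straight lines of projected size vs calibration error.

    One series per catalog size, evaluated before snapping on the full
    symmetric error grid (figures show both signs regardless of the
    matrix reporting side). Returns ``{size: [(error_pct, projected_mm),
    ...]}``.
    """
    from .error_model import project_size

    return {
        s: [(e, project_size(s, e)) for e in config.grid.values]
        for s in config.catalog.sizes
    }
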