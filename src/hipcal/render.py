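"""Serialize deviation matrices: CSV, color-coded HTML, line plots.

Output mirrors the conventional presentation: a table whose cells print
the mm deviation to one decimal and are colored by the deviation in
whole component sizes (one color per bin 0..8 plus a combined ">8"
bin), and per-size straight lines of projected diameter against
calibration error.

All writers are deterministic: identical inputs produce byte-identical
CSV/HTML.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

from .matrix import BIN_CAP, DeviationMatrix, round_half_away

__all__ = ["ColorScheme", "DEFAULT_SCHEME", "to_csv", "to_html", "to_plot"]

PathLike = Union[str, Path]

# white -> dark red sequential ramp, one entry per severity bin
_RAMP = (
    "#ffffff", "#fee5d9", "#fcbba1", "#fc9272", "#fb6a4a",
    "#ef3b2c", "#cb181d", "#a50f15", "#67000d", "#40000a",
)


@dataclass(frozen=True)
class ColorScheme:
    """Mapping from severity bin label to a CSS color.

    Must cover every unsigned bin (``"0"`` .. ``"8"`` and ``">8"``);
    signed labels from two-sided reports are colored by magnitude.
    """

    colors: Mapping[str, str]

    def __post_init__(self) -> None:
        required = [str(i) for i in range(BIN_CAP + 1)] + [f">{BIN_CAP}"]
        missing = [b for b in required if b not in self.colors]
        if missing:
            raise ValueError(f"color scheme is missing bins: {missing}")

    def color(self, label: str) -> str:
        """Color for a possibly signed bin label (by magnitude)."""
        if label in self.colors:
            return self.colors[label]
        if label.startswith("<-") or label.startswith(">"):
            return self.colors[f">{BIN_CAP}"]
        return self.colors[str(abs(int(label)))]


DEFAULT_SCHEME = ColorScheme(
    colors={**{str(i): _RAMP[i] for i in range(BIN_CAP + 1)}, f">{BIN_CAP}": _RAMP[9]}
)


def _fmt_num(x: float) -> str:
    """Axis label: integer when integral, else minimal decimal."""
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def _csv_lines(matrix: DeviationMatrix) -> list[str]:
    header = "size_mm," + ",".join(_fmt_num(e) for e in matrix.errors)
    lines = [header]
    for s in matrix.sizes:
        cells = (
            f"{round_half_away(matrix.deviation_mm.at[s, e], 1):.1f}"
            for e in matrix.errors
        )
        lines.append(_fmt_num(s) + "," + ",".join(cells))
    return lines


def _bins_lines(matrix: DeviationMatrix) -> list[str]:
    header = "size_mm," + ",".join(_fmt_num(e) for e in matrix.errors)
    lines = [header]
    for s in matrix.sizes:
        lines.append(
            _fmt_num(s) + "," + ",".join(matrix.bins.at[s, e] for e in matrix.errors)
        )
    return lines


def to_csv(matrix: DeviationMatrix, path: PathLike) -> Path:
    """Write the matrix as CSV; a sibling ``*_bins.csv`` holds bin labels.

    Header row: calibration errors in percent; first column: true sizes
    in mm; cells: deviation of the selected from the optimal size in mm,
    exactly one decimal, ties rounded away from zero. Returns the main
    CSV path.
    """
    path = Path(path)
    try:
        path.write_text("\n".join(_csv_lines(matrix)) + "\n", encoding="utf-8")
        bins_path = path.with_name(path.stem + "_bins" + path.suffix)
        bins_path.write_text("\n".join(_bins_lines(matrix)) + "\n", encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write matrix CSV to {path}: {exc}") from exc
    return path


def to_html(
    matrix: DeviationMatrix,
    scheme: ColorScheme = DEFAULT_SCHEME,
    path: PathLike = "matrix.html",
) -> Path:
    """Write a standalone color-coded HTML table of the matrix.

    One ``<td>`` per cell, background color taken from the severity bin,
    value printed to one decimal. Output is deterministic.
    """
    path = Path(path)
    rows = []
    head = "".join(f"<th>{_fmt_num(e)}%</th>" for e in matrix.errors)
    rows.append(f"<tr><th>size (mm)</th>{head}</tr>")
    for s in matrix.sizes:
        cells = []
        for e in matrix.errors:
            label = matrix.bins.at[s, e]
            val = f"{round_half_away(matrix.deviation_mm.at[s, e], 1):.1f}"
            color = scheme.color(label)
            cells.append(
                f'<td style="background-color:{color}" '
                f'data-bin="{_html.escape(label)}">{val}</td>'
            )
        rows.append(f"<tr><th>{_fmt_num(s)}</th>{''.join(cells)}</tr>")
    doc = (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\">"
        "<title>Templating deviation matrix</title>"
        "<style>table{border-collapse:collapse}"
        "td,th{border:1px solid #999;padding:2px 6px;text-align:right}"
        "</style></head>\n<body>\n"
        "<p>Deviation of the selected from the optimal component size (mm); "
        "cell color encodes the deviation in component sizes.</p>\n"
        "<table>\n" + "\n".join(rows) + "\n</table>\n</body></html>\n"
    )
    try:
        path.write_text(doc, encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write HTML table to {path}: {exc}") from exc
    return path


def to_plot(
    series: dict[float, list[tuple[float, float]]],
    path: PathLike,
) -> Path:
    """Plot the per-size error curves (one straight line per size).

    x axis: calibration error in percent; y axis: projected component
    size in mm. The file format follows the extension (``.png`` or
    ``.svg``).
    """
    if not series:
        raise ValueError("no series to plot")
    path = Path(path)
    if path.suffix.lower() not in (".png", ".svg"):
        raise ValueError(
            f"unsupported plot format {path.suffix!r}; use .png or .svg"
        )
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    cmap = matplotlib.colormaps["viridis"]
    n = max(len(series) - 1, 1)
    for k, (size, pts) in enumerate(sorted(series.items())):
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        ax.plot(xs, ys, color=cmap(k / n), label=f"{_fmt_num(size)} mm")
    ax.set_xlabel("calibration error (%)")
    ax.set_ylabel("projected component size (mm)")
    ax.legend(fontsize=7, ncols=2, title="true size")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
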