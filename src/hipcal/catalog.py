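"""Discrete implant catalogs and nearest-size selection.

Acetabular cup systems offer a finite set of shell diameters, almost
universally spaced in 2 mm increments. Digital templating produces a
*continuous* projected diameter; the planner then picks the catalog size
closest to it. This module models that catalog and the snapping rule.

Two presets mirror the two study conditions used throughout the package:

``group1``
    Common cup sizes, 44-66 mm in 2 mm steps (12 sizes).
``group2``
    All plausible sizes including revision cups, 38-72 mm in 2 mm steps
    (18 sizes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

__all__ = [
    "ImplantCatalog",
    "make_catalog",
    "catalog_from_sizes",
    "preset",
    "PRESETS",
    "snap",
    "steps_between",
    "TieRule",
]

#: Absolute tolerance (mm) for lattice membership / midpoint comparisons.
LATTICE_TOL = 1e-9

TieRule = Literal["toward_true", "down", "up"]
_TIE_RULES = ("toward_true", "down", "up")


@dataclass(frozen=True)
class ImplantCatalog:
    """An ordered set of selectable component diameters.

    Parameters
    ----------
    sizes
        Strictly increasing, positive diameters in mm.
    increment
        Nominal spacing in mm when the catalog is a uniform arithmetic
        progression; ``None`` for irregular catalogs.
    clamped
        If True, snapping never leaves ``[min, max]``. If False (default
        for uniform catalogs), the increment lattice is extended beyond
        both ends, so a projection larger than the largest catalog size
        still maps onto the nearest lattice point. Irregular catalogs are
        always clamped.
    """

    sizes: tuple[float, ...]
    increment: Optional[float] = None
    clamped: bool = False

    def __post_init__(self) -> None:
        if len(self.sizes) < 1:
            raise ValueError("catalog needs at least one size")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("catalog sizes must be positive")
        if any(b - a <= 0 for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("catalog sizes must be strictly increasing")
        if self.increment is not None:
            if self.increment <= 0:
                raise ValueError("increment must be positive")
            for a, b in zip(self.sizes, self.sizes[1:]):
                if abs((b - a) - self.increment) > LATTICE_TOL:
                    raise ValueError(
                        "sizes are not uniformly spaced by the stated increment"
                    )
        elif not self.clamped:
            raise ValueError(
                "a catalog without a uniform increment cannot be unclamped"
            )

    @property
    def min(self) -> float:
        return self.sizes[0]

    @property
    def max(self) -> float:
        return self.sizes[-1]

    def __len__(self) -> int:
        return len(self.sizes)

    def contains(self, size_mm: float) -> bool:
        """Whether ``size_mm`` is a catalog member (within tolerance)."""
        return any(abs(s - size_mm) <= LATTICE_TOL for s in self.sizes)

    def nearest_members(self, size_mm: float) -> tuple[float, float]:
        """The two catalog sizes bracketing ``size_mm`` (for messages)."""
        below = max((s for s in self.sizes if s <= size_mm), default=self.min)
        above = min((s for s in self.sizes if s >= size_mm), default=self.max)
        return below, above


def make_catalog(
    min_mm: float,
    max_mm: float,
    increment_mm: float,
    clamped: bool = False,
) -> ImplantCatalog:
    """Build a uniform catalog ``min, min+increment, ..., max``.

    Raises
    ------
    ValueError
        If the bounds are not positive and ordered, the increment is not
        positive, or ``max_mm - min_mm`` is not an exact multiple of the
        increment.
    """
    if not (0 < min_mm < max_mm):
        raise ValueError(f"need 0 < min ({min_mm}) < max ({max_mm})")
    if increment_mm <= 0:
        raise ValueError(f"increment must be positive, got {increment_mm}")
    n_steps = (max_mm - min_mm) / increment_mm
    if abs(n_steps - round(n_steps)) > LATTICE_TOL:
        raise ValueError(
            f"range {min_mm}..{max_mm} mm is not divisible by the "
            f"increment {increment_mm} mm"
        )
    n = int(round(n_steps)) + 1
    sizes = tuple(min_mm + i * increment_mm for i in range(n))
    return ImplantCatalog(sizes=sizes, increment=increment_mm, clamped=clamped)


def catalog_from_sizes(sizes: Sequence[float]) -> ImplantCatalog:
    """Build a catalog from an explicit size list.

    A uniform increment is inferred when the spacing is constant; otherwise
    the catalog is irregular and snapping is clamped to its span.
    """
    sizes = tuple(float(s) for s in sizes)
    if len(sizes) >= 2:
        diffs = [b - a for a, b in zip(sizes, sizes[1:])]
        if all(abs(d - diffs[0]) <= LATTICE_TOL for d in diffs):
            return ImplantCatalog(sizes=sizes, increment=diffs[0], clamped=False)
    return ImplantCatalog(sizes=sizes, increment=None, clamped=True)


PRESETS = {
    "group1": (44.0, 66.0, 2.0),
    "group2": (38.0, 72.0, 2.0),
}


def preset(name: str, clamped: bool = False) -> ImplantCatalog:
    """Return a named preset catalog (``group1`` or ``group2``)."""
    try:
        lo, hi, inc = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return make_catalog(lo, hi, inc, clamped=clamped)


def _pick(
    lo: float,
    hi: float,
    projected_mm: float,
    tie_rule: TieRule,
    true_mm: Optional[float],
) -> float:
    """Choose between the two lattice neighbours of a projection."""
    d_lo = abs(projected_mm - lo)
    d_hi = abs(hi - projected_mm)
    if d_lo < d_hi - LATTICE_TOL:
        return lo
    if d_hi < d_lo - LATTICE_TOL:
        return hi
    # exact midpoint
    if tie_rule == "down":
        return lo
    if tie_rule == "up":
        return hi
    if tie_rule == "toward_true":
        if true_mm is None:
            raise ValueError("tie_rule 'toward_true' requires true_mm")
        # candidate nearer the true size minimizes the final deviation;
        # a doubly-symmetric tie falls back to the lower size.
        return hi if abs(hi - true_mm) < abs(lo - true_mm) else lo
    raise ValueError(f"unknown tie_rule {tie_rule!r}; choose from {_TIE_RULES}")


def snap(
    projected_mm: float,
    catalog: ImplantCatalog,
    tie_rule: TieRule = "toward_true",
    true_mm: Optional[float] = None,
) -> float:
    """Map a continuous projected diameter to a selectable size.

    Returns the lattice diameter minimizing ``|size - projected_mm|``. On
    an unclamped uniform catalog the lattice extends beyond the catalog
    span in both directions (a 74 mm projection snaps to 74, not 72). On a
    clamped catalog, out-of-range projections return the nearer endpoint.
    Exact midpoints between two lattice points are resolved by
    ``tie_rule``; the default ``toward_true`` picks the candidate closer
    to the known true size.
    """
    if projected_mm <= 0:
        raise ValueError(f"projected size must be positive, got {projected_mm}")
    if tie_rule not in _TIE_RULES:
        raise ValueError(f"unknown tie_rule {tie_rule!r}; choose from {_TIE_RULES}")

    if not catalog.clamped:
        inc = catalog.increment
        assert inc is not None  # enforced by ImplantCatalog.__post_init__
        k = (projected_mm - catalog.min) / inc
        lo_k = math.floor(k + LATTICE_TOL)
        lo = catalog.min + lo_k * inc
        hi = lo + inc
        if lo <= LATTICE_TOL:
            # the extended lattice stays physical: diameters must be > 0
            return hi
        if abs(projected_mm - lo) <= LATTICE_TOL:
            return lo
        return _pick(lo, hi, projected_mm, tie_rule, true_mm)

    # clamped: restrict to actual members
    if projected_mm <= catalog.min:
        return catalog.min
    if projected_mm >= catalog.max:
        return catalog.max
    below, above = catalog.nearest_members(projected_mm)
    if abs(below - above) <= LATTICE_TOL:
        return below
    return _pick(below, above, projected_mm, tie_rule, true_mm)


def steps_between(a_mm: float, b_mm: float, catalog: ImplantCatalog) -> int:
    """Signed number of catalog increments from ``a_mm`` to ``b_mm``.

    Converts a deviation in mm into the clinical unit "component sizes".
    Both endpoints must lie on the catalog lattice and the catalog must
    have a uniform increment.
    """
    if catalog.increment is None:
        raise ValueError("steps are undefined for an irregular catalog")
    for x in (a_mm, b_mm):
        k = (x - catalog.min) / catalog.increment
        if abs(k - round(k)) > 1e-6:
            below, above = catalog.nearest_members(x)
            raise ValueError(
                f"{x} mm is not on the catalog lattice "
                f"(nearest members: {below} and {above} mm)"
            )
    return int(round((b_mm - a_mm) / catalog.increment))
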