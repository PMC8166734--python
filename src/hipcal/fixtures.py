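"""Randomized catalogs and case lists for property-based testing.

Everything is generated from a single integer seed; no external data is
needed anywhere. The generated objects always satisfy the catalog
invariants (strictly increasing positive sizes, exact increment
divisibility), so they can feed any operation in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import ImplantCatalog, make_catalog

__all__ = ["FixtureSpec", "random_catalog", "random_cases"]


@dataclass(frozen=True)
class FixtureSpec:
    """Bounds for the fixture generator.

    min_size_range: bounds (mm) for the smallest catalog size;
    count_range: bounds on the number of sizes; increment_choices:
    allowed spacings (mm); error_bound: cases draw errors uniformly in
    +/- this many percent.
    """

    seed: int = 0
    n_catalogs: int = 10
    min_size_range: tuple[float, float] = (30.0, 60.0)
    count_range: tuple[int, int] = (2, 25)
    increment_choices: tuple[float, ...] = (1.0, 2.0, 4.0)
    error_bound: float = 30.0

    def __post_init__(self) -> None:
        if self.min_size_range[0] <= 0 or self.min_size_range[0] > self.min_size_range[1]:
            raise ValueError(f"degenerate min_size_range {self.min_size_range}")
        if self.count_range[0] < 2 or self.count_range[0] > self.count_range[1]:
            raise ValueError(f"degenerate count_range {self.count_range}")
        if not self.increment_choices or any(i <= 0 for i in self.increment_choices):
            raise ValueError("increment choices must be positive")
        if self.error_bound < 0 or self.error_bound >= 100:
            raise ValueError("error bound must lie in [0, 100)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def random_catalog(
    spec: FixtureSpec, rng: np.random.Generator | None = None
) -> ImplantCatalog:
    """Draw a uniform catalog with (min, count, increment) within bounds.

    Pass the same generator across calls for a reproducible stream, or
    omit it to draw the first catalog of the seed's stream.
    """
    rng = spec.rng() if rng is None else rng
    min_mm = float(rng.uniform(*spec.min_size_range))
    count = int(rng.integers(spec.count_range[0], spec.count_range[1] + 1))
    inc = float(rng.choice(spec.increment_choices))
    return make_catalog(min_mm, min_mm + (count - 1) * inc, inc)


def random_cases(
    spec: FixtureSpec,
    catalog: ImplantCatalog,
    n: int,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float]]:
    """Draw ``n`` (size, error) pairs.

    Sizes come from the catalog, errors uniformly from
    ``+/- spec.error_bound`` percent; reproducible under the seed.
    """
    rng = spec.rng() if rng is None else rng
    sizes = rng.choice(np.asarray(catalog.sizes), size=n)
    errors = rng.uniform(-spec.error_bound, spec.error_bound, size=n)
    return [(float(s), float(e)) for s, e in zip(sizes, errors)]
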