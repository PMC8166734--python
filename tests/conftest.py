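import pytest

from hipcal.catalog import ImplantCatalog, preset
from hipcal.matrix import scenario


@pytest.fixture(scope="session")
def group1() -> ImplantCatalog:
    return preset("group1")


@pytest.fixture(scope="session")
def group2() -> ImplantCatalog:
    return preset("group2")


@pytest.fixture(scope="session")
def group1_scenario():
    return scenario("group1")


@pytest.fixture(scope="session")
def group2_scenario():
    return scenario("group2")


def brute_force_snap(projected_mm, catalog, tie_rule="toward_true", true_mm=None):
    """Independent nearest-size oracle: explicit enumeration + argmin.

    Enumerates the (possibly extended) lattice far beyond any projection
    used in tests, then scans all candidates.
    """
    if catalog.clamped or catalog.increment is None:
        candidates = list(catalog.sizes)
    else:
        inc = catalog.increment
        lo = catalog.min
        # wide enough for any projection in tests
        candidates = [lo + k * inc for k in range(-200, 400)]
        candidates = [c for c in candidates if c > 0]
    best = None
    best_d = None
    for c in candidates:
        d = abs(c - projected_mm)
        if best is None or d < best_d - 1e-9:
            best, best_d = c, d
        elif abs(d - best_d) <= 1e-9:
            # tie between best (lower) and c (higher)
            if tie_rule == "up":
                best, best_d = c, d
            elif tie_rule == "toward_true" and true_mm is not None:
                if abs(c - true_mm) < abs(best - true_mm):
                    best, best_d = c, d
    return best
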