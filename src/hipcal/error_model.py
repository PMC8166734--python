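"""Linear propagation of calibration errors into templated component size.

Digital templating scales a CAD template of the implant by the
radiograph's magnification factor. If that factor is calibrated with a
relative error of *e* percent, a component of true diameter *s* mm appears
on the plan with a projected diameter of

    s_projected = s * (100 + e) / 100

The projection is linear in both the size and the error, and its
deviation from the true size, ``s * e / 100``, grows with the component
size: the same calibration error costs more sizes on a large cup than on
a small one. The planner then selects the catalog size nearest the
projection, which quantizes the deviation into whole component sizes.

The inverse view answers the clinically useful question: given the size
that *was* templated under a suspected calibration error, which size
should have been chosen? Because the error enters multiplicatively, the
correction divides it out: an overestimated magnification (marker too
close to the X-ray source) leads to undersized templates and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass

from .catalog import ImplantCatalog, TieRule, snap, steps_between

__all__ = [
    "ProjectionResult",
    "project_size",
    "evaluate",
    "optimal_from_templated",
]


@dataclass(frozen=True)
class ProjectionResult:
    """One (true size, calibration error) evaluation.

    Attributes
    ----------
    true_size : float
        The optimal component diameter in mm (a catalog member).
    error_pct : float
        Signed calibration error in percent.
    projected_size : float
        Continuous projected diameter, ``true_size * (100+error)/100``.
    snapped_size : float
        The catalog size the planner would select for the projection.
    deviation_mm : float
        ``snapped_size - true_size``.
    deviation_steps : int
        The same deviation in whole component sizes (catalog increments).
    """

    true_size: float
    error_pct: float
    projected_size: float
    snapped_size: float
    deviation_mm: float
    deviation_steps: int


def project_size(true_mm: float, error_pct: float) -> float:
    """Projected component diameter under a calibration error.

    ``true_mm * (100 + error_pct) / 100``; strictly increasing in both
    arguments. An error of -100% or below would collapse the projection
    to zero or negative size and is rejected.
    """
    if true_mm <= 0:
        raise ValueError(f"true size must be positive, got {true_mm}")
    if error_pct <= -100:
        raise ValueError(
            f"calibration error must exceed -100%, got {error_pct}%"
        )
    return true_mm * (100.0 + error_pct) / 100.0


def evaluate(
    true_mm: float,
    error_pct: float,
    catalog: ImplantCatalog,
    tie_rule: TieRule = "toward_true",
) -> ProjectionResult:
    """Project a true size under an error and snap it to the catalog.

    Composes :func:`project_size`, :func:`hipcal.catalog.snap` and
    :func:`hipcal.catalog.steps_between`. ``true_mm`` must be a catalog
    lattice member so the deviation in component sizes is well defined.
    """
    projected = project_size(true_mm, error_pct)
    snapped = snap(projected, catalog, tie_rule=tie_rule, true_mm=true_mm)
    dev_mm = snapped - true_mm
    dev_steps = steps_between(true_mm, snapped, catalog)
    return ProjectionResult(
        true_size=true_mm,
        error_pct=error_pct,
        projected_size=projected,
        snapped_size=snapped,
        deviation_mm=dev_mm,
        deviation_steps=dev_steps,
    )


def optimal_from_templated(
    templated_mm: float,
    error_pct: float,
    catalog: ImplantCatalog,
    tie_rule: TieRule = "toward_true",
) -> float:
    """The size that should have been chosen, given what was templated.

    Divides the calibration error back out of the templated size and
    snaps the result: ``snap(templated * 100 / (100 + error))``. With an
    8% error a templated 56 mm cup corrects to 52 mm.
    """
    if error_pct <= -100:
        raise ValueError(
            f"calibration error must exceed -100%, got {error_pct}%"
        )
    corrected = templated_mm * 100.0 / (100.0 + error_pct)
    return snap(corrected, catalog, tie_rule=tie_rule, true_mm=templated_mm)
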