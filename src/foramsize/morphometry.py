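"""Biovolume morphometry for foraminiferal tests.

Linear measurements of a test (shell) are converted into a volume in
cubic micrometers through an idealized geometric solid chosen per
specimen: sphere, hemispheroid, cone, oval cone, cylinder, oval
cylinder, discoid, oval discoid, or ellipsoid.  Volumes are analyzed on
the log10 scale and aggregated to the genus level (arithmetic mean of
per-specimen log10 volumes, i.e. the geometric-mean volume), alongside
species-richness tabulation and a large/small size classification at a
configurable log10-volume threshold.

All linear inputs are full external diameters/heights in micrometers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Genus-mean log10 volume (um^3) at or above which a genus counts as "large".
SIZE_THRESHOLD_LOG10_UM3 = 7.4

#: Species labels treated as indeterminate (excluded from richness counts).
INDETERMINATE_SPECIES = {"", "sp.", "spp.", "sp", "spp", "indet.", "indet"}

EVENTS = ("F-F", "G-L", "P-T", "T-J", "K-Pg", "modern")


class ShapeClass(str, Enum):
    """Geometric approximations used for test volume."""

    SPHERE = "sphere"
    HEMISPHEROID = "hemispheroid"
    CONE = "cone"
    OVAL_CONE = "oval_cone"
    CYLINDER = "cylinder"
    OVAL_CYLINDER = "oval_cylinder"
    DISCOID = "discoid"
    OVAL_DISCOID = "oval_discoid"
    ELLIPSOID = "ellipsoid"


class ArityError(ValueError):
    """An axis required by the specimen's shape class is missing."""


class AxisDomainError(ValueError):
    """A supplied axis is non-positive or non-finite."""


class UnresolvedMeasurementError(ValueError):
    """A missing axis cannot be imputed from the aspect-ratio table."""


# Required and optional axes per shape class.  d2 on a hemispheroid is
# optional: a second equatorial diameter defaulting to the first.
_SHAPE_AXES: dict[ShapeClass, tuple[tuple[str, ...], tuple[str, ...]]] = {
    ShapeClass.SPHERE: (("d1",), ()),
    ShapeClass.HEMISPHEROID: (("d1", "h"), ("d2",)),
    ShapeClass.CONE: (("d1", "h"), ()),
    ShapeClass.OVAL_CONE: (("d1", "d2", "h"), ()),
    ShapeClass.CYLINDER: (("d1", "h"), ()),
    ShapeClass.OVAL_CYLINDER: (("d1", "d2", "h"), ()),
    ShapeClass.DISCOID: (("d1", "h"), ()),
    ShapeClass.OVAL_DISCOID: (("d1", "d2", "h"), ()),
    ShapeClass.ELLIPSOID: (("d1", "d2", "d3"), ()),
}


def required_axes(shape: ShapeClass) -> tuple[str, ...]:
    """Axis names a specimen of this shape must carry."""
    return _SHAPE_AXES[ShapeClass(shape)][0]


# The circular shapes evaluate through their oval generalizations with
# d2 = d1, so the degenerate identities (ellipsoid(d,d,d) == sphere(d),
# oval_cylinder(d,d,h) == cylinder(d,h)) hold bit-for-bit.

def _vol_ellipsoid(a: Mapping[str, float]) -> float:
    return math.pi / 6.0 * a["d1"] * a["d2"] * a["d3"]


def _vol_sphere(a: Mapping[str, float]) -> float:
    return _vol_ellipsoid({"d1": a["d1"], "d2": a["d1"], "d3": a["d1"]})


def _vol_oval_cylinder(a: Mapping[str, float]) -> float:
    return math.pi * (a["d1"] / 2.0) * (a["d2"] / 2.0) * a["h"]


def _vol_cylinder(a: Mapping[str, float]) -> float:
    return _vol_oval_cylinder({"d1": a["d1"], "d2": a["d1"], "h": a["h"]})


def _vol_oval_cone(a: Mapping[str, float]) -> float:
    return math.pi / 3.0 * (a["d1"] / 2.0) * (a["d2"] / 2.0) * a["h"]


def _vol_cone(a: Mapping[str, float]) -> float:
    return _vol_oval_cone({"d1": a["d1"], "d2": a["d1"], "h": a["h"]})


def _vol_hemispheroid(a: Mapping[str, float]) -> float:
    # Half an ellipsoid whose polar semi-axis is the measured height;
    # the second equatorial diameter defaults to the first.
    d2 = a.get("d2", a["d1"])
    return 2.0 * math.pi / 3.0 * (a["d1"] / 2.0) * (d2 / 2.0) * a["h"]


#: Shape -> volume formula registry.  Discoids reuse the cylinder
#: formulas (a discoid is treated as a low-aspect cylinder); override an
#: entry to swap in an alternate convention.
VOLUME_FORMULAS: dict[ShapeClass, Callable[[Mapping[str, float]], float]] = {
    ShapeClass.SPHERE: _vol_sphere,
    ShapeClass.ELLIPSOID: _vol_ellipsoid,
    ShapeClass.CYLINDER: _vol_cylinder,
    ShapeClass.OVAL_CYLINDER: _vol_oval_cylinder,
    ShapeClass.DISCOID: _vol_cylinder,
    ShapeClass.OVAL_DISCOID: _vol_oval_cylinder,
    ShapeClass.CONE: _vol_cone,
    ShapeClass.OVAL_CONE: _vol_oval_cone,
    ShapeClass.HEMISPHEROID: _vol_hemispheroid,
}


@dataclass
class SpecimenMeasurement:
    """One measured specimen: taxonomy, event, shape, axes (um), occurrence."""

    specimen_id: str
    genus: str
    species: str
    event: str
    shape: ShapeClass
    d1: float | None = None
    d2: float | None = None
    d3: float | None = None
    h: float | None = None
    lon: float | None = None
    lat: float | None = None
    status: str | None = None  # "victim" | "survivor" (genus-level label)

    def axes(self) -> dict[str, float]:
        return {
            k: v
            for k, v in (("d1", self.d1), ("d2", self.d2), ("d3", self.d3), ("h", self.h))
            if v is not None
        }


@dataclass
class GenusRecord:
    """Genus x event analysis row."""

    genus: str
    event: str
    mean_log10_volume: float
    sd_log10_volume: float
    n_specimens: int
    species_richness: int = 0
    range_cells: int = 0
    status: int | None = None  # victim=1, survivor=0
    size_class: str = field(default="")

    def __post_init__(self) -> None:
        if not self.size_class:
            self.size_class = classify_size(self.mean_log10_volume)


def _validate_axes(shape: ShapeClass, axes: Mapping[str, float]) -> None:
    shape = ShapeClass(shape)
    for name, value in axes.items():
        if not (np.isfinite(value) and value > 0):
            raise AxisDomainError(f"axis {name}={value!r} must be positive and finite")
    missing = [n for n in required_axes(shape) if n not in axes]
    if missing:
        raise ArityError(f"shape {shape.value} requires axes {missing}, got {sorted(axes)}")


def compute_volume(shape: ShapeClass | str, axes: Mapping[str, float]) -> float:
    """Test volume in um^3 from linear axes (um) under the shape's formula.

    Parameters
    ----------
    shape
        Geometric approximation of the test.
    axes
        Mapping with keys among {'d1','d2','d3','h'}; full diameters, um.

    Returns
    -------
    float
        Volume in cubic micrometers, strictly positive.
    """
    shape = ShapeClass(shape)
    _validate_axes(shape, axes)
    return VOLUME_FORMULAS[shape](axes)


def impute_missing_axis(
    shape: ShapeClass | str,
    axes: Mapping[str, float],
    genus: str,
    aspect_ratios: Mapping[str, Mapping[str, float]] | None,
) -> dict[str, float]:
    """Fill axes missing for the shape's arity from type-species aspect ratios.

    ``aspect_ratios`` maps genus -> {ratio_name: value} with ratio names
    ``h_over_d1``, ``d2_over_d1``, ``d3_over_d1`` (missing axis = d1 x ratio).

    Raises
    ------
    UnresolvedMeasurementError
        If a required axis is missing and no applicable ratio exists.
    """
    shape = ShapeClass(shape)
    completed = dict(axes)
    ratio_for = {"h": "h_over_d1", "d2": "d2_over_d1", "d3": "d3_over_d1"}
    genus_ratios = (aspect_ratios or {}).get(genus, {})
    for name in required_axes(shape):
        if name in completed:
            continue
        rname = ratio_for.get(name)
        if rname is None or rname not in genus_ratios or "d1" not in completed:
            raise UnresolvedMeasurementError(
                f"cannot impute axis {name!r} for genus {genus!r} (shape {shape.value})"
            )
        completed[name] = completed["d1"] * genus_ratios[rname]
    _validate_axes(shape, completed)
    return completed


def log10_volume(volume_um3: float) -> float:
    """log10 of a volume in um^3; volume must be strictly positive."""
    if not (np.isfinite(volume_um3) and volume_um3 > 0):
        raise AxisDomainError(f"volume must be positive and finite, got {volume_um3!r}")
    return math.log10(volume_um3)


def specimen_log10_volume(
    specimen: SpecimenMeasurement,
    aspect_ratios: Mapping[str, Mapping[str, float]] | None = None,
) -> float:
    """Impute missing axes if needed, then return the specimen's log10 volume."""
    axes = specimen.axes()
    try:
        _validate_axes(specimen.shape, axes)
    except ArityError:
        axes = impute_missing_axis(specimen.shape, axes, specimen.genus, aspect_ratios)
    return log10_volume(compute_volume(specimen.shape, axes))


def classify_size(
    mean_log10_volume: float, threshold: float = SIZE_THRESHOLD_LOG10_UM3
) -> str:
    """'large' iff mean log10 volume >= threshold (closed at the threshold)."""
    if not np.isfinite(mean_log10_volume):
        raise AxisDomainError("mean_log10_volume must be finite")
    return "large" if mean_log10_volume >= threshold else "small"


def tabulate_species_richness(specimens: Iterable[SpecimenMeasurement]) -> int:
    """Number of distinct named species; 'sp.'/'spp.'/unnamed are excluded."""
    named = {
        s.species.strip().lower()
        for s in specimens
        if s.species is not None and s.species.strip().lower() not in INDETERMINATE_SPECIES
    }
    return len(named)


def aggregate_genus(
    specimens: Sequence[SpecimenMeasurement],
    aspect_ratios: Mapping[str, Mapping[str, float]] | None = None,
    threshold: float = SIZE_THRESHOLD_LOG10_UM3,
) -> GenusRecord:
    """Collapse one genus x event's specimens to a :class:`GenusRecord`.

    The genus size is the arithmetic mean of per-specimen log10 volumes.
    Specimens whose axes cannot be completed are dropped with a warning;
    an empty or mixed-genus input is an error.  A single specimen has
    sd = 0 by convention.
    """
    specimens = list(specimens)
    if not specimens:
        raise ValueError("aggregate_genus requires at least one specimen")
    genera = {s.genus for s in specimens}
    events = {s.event for s in specimens}
    if len(genera) != 1 or len(events) != 1:
        raise ValueError(f"specimens span multiple genera/events: {genera} x {events}")

    logvols = []
    kept = []
    for s in specimens:
        try:
            logvols.append(specimen_log10_volume(s, aspect_ratios))
            kept.append(s)
        except UnresolvedMeasurementError as exc:
            logger.warning("dropping specimen %s: %s", s.specimen_id, exc)
    if not logvols:
        raise ValueError(f"no measurable specimens for genus {genera.pop()!r}")

    arr = np.sort(np.asarray(logvols))  # order-independent summation
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    status_labels = {s.status for s in kept if s.status is not None}
    status = None
    if status_labels:
        if len(status_labels) > 1:
            raise ValueError(f"conflicting status labels within genus: {status_labels}")
        status = 1 if status_labels.pop() == "victim" else 0
    return GenusRecord(
        genus=genera.pop(),
        event=events.pop(),
        mean_log10_volume=mean,
        sd_log10_volume=sd,
        n_specimens=len(kept),
        species_richness=tabulate_species_richness(kept),
        status=status,
        size_class=classify_size(mean, threshold),
    )
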