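"""Visual-angle geometry of the VR stimulus display.

The stimulus is laid out in scene units (one unit = one meter) on a sphere
viewed from its center at a fixed distance.  All printed angular extents in
the experimental design follow the chord convention

    angle = 2 * atan(extent / (2 * distance))

i.e. the full angle subtended by a frontal chord of the given extent.  The
gaze-fixation rejection radius is the angular half-extent (radius) of the
central white disc of the stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["StimulusGeometry", "visual_angle", "gaze_radius_deg", "DEFAULT_GEOMETRY"]


@dataclass(frozen=True)
class StimulusGeometry:
    """Physical layout of the glare/halo stimulus in scene units (meters).

    ``peripheral_tilt`` is the displacement of the four eccentric stimulus
    positions from the central position.  It is stored as an independent
    constant together with its nominal angular tilt: the printed ~65 degree
    value does not follow the chord convention used by every other extent
    (the chord formula would give ~42 degrees), so no conversion is applied.
    """

    viewing_distance: float = 100.0
    overall_diameter: float = 40.0
    white_center_diameter: float = 17.62
    gradation_circle_diameter: float = 11.19
    gradation_center_offset: float = 14.41
    fixation_cross_diameter: float = 2.93
    peripheral_tilt: float = 76.64
    peripheral_tilt_deg: float = 65.0

    def __post_init__(self) -> None:
        for name in (
            "viewing_distance",
            "overall_diameter",
            "white_center_diameter",
            "gradation_circle_diameter",
            "gradation_center_offset",
            "fixation_cross_diameter",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"StimulusGeometry.{name} must be positive")
        if self.white_center_diameter >= self.overall_diameter:
            raise ValueError(
                "white_center_diameter must be smaller than overall_diameter"
            )


DEFAULT_GEOMETRY = StimulusGeometry()


def visual_angle(extent: float, distance: float) -> float:
    """Full visual angle (degrees) subtended by ``extent`` at ``distance``.

    Chord convention: ``2 * atan(extent / (2 * distance))``.  Exact for a
    frontal chord centered on the line of sight; the same convention is used
    for eccentric offsets, which is how the display's printed values were
    produced.

    Parameters
    ----------
    extent : float
        Linear size in scene units.  Must be >= 0.
    distance : float
        Viewing distance in the same units.  Must be > 0.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if extent < 0:
        raise ValueError("extent must be non-negative")
    return math.degrees(2.0 * math.atan2(extent, 2.0 * distance))


def invert_visual_angle(angle_deg: float, distance: float) -> float:
    """Extent in scene units subtending ``angle_deg`` at ``distance`` (chord)."""
    if distance <= 0:
        raise ValueError("distance must be positive")
    return 2.0 * distance * math.tan(math.radians(angle_deg) / 2.0)


def gaze_radius_deg(geometry: StimulusGeometry = DEFAULT_GEOMETRY) -> float:
    """Angular radius (degrees) of the central white area of the stimulus.

    Half of the full chord angle of ``white_center_diameter``; this is the
    fixation tolerance used by the gaze rejection rule (5.035 degrees for the
    default geometry).
    """
    return 0.5 * visual_angle(geometry.white_center_diameter, geometry.viewing_distance)
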