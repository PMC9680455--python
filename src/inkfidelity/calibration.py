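"""Pixel-to-physical-length calibration."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError

DEFAULT_PIXELS_PER_MM = 45.0


@dataclass(frozen=True)
class PixelCalibration:
    """Imaging-scale calibration, pixels per millimetre."""

    pixels_per_mm: float = DEFAULT_PIXELS_PER_MM

    def __post_init__(self) -> None:
        if not self.pixels_per_mm > 0:
            raise InvalidParameterError(
                f"pixels_per_mm must be > 0, got {self.pixels_per_mm!r}"
            )


def px_to_length(pixels: float, cal: PixelCalibration, unit: str = "mm") -> float:
    """Convert a pixel count to a physical length in ``mm`` or ``um``.

    Full precision is retained; rounding (e.g. to whole micrometres) is a
    report-formatting concern, not done here.
    """
    if pixels < 0:
        raise InvalidParameterError(f"pixel count must be >= 0, got {pixels!r}")
    mm = pixels / cal.pixels_per_mm
    if unit == "mm":
        return mm
    if unit in ("um", "μm"):
        return mm * 1000.0
    raise InvalidParameterError(f"unsupported unit {unit!r} (use 'mm' or 'um')")
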