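"""End-to-end recovery pipelines tying the image analyzers to the model."""

from __future__ import annotations

import numpy as np

from . import beam, filament
from .fixtures import FilamentFrame

__all__ = ["recover_modulus_from_frame"]


def recover_modulus_from_frame(
    frame: FilamentFrame,
    P: float,
    rho: float,
    calibration: float,
    bracket: tuple[float, float] = beam.DEFAULT_BRACKET,
) -> beam.ModulusEstimate:
    """Measure support angles on a rendered frame and invert for E.

    The measured angles are converted to the straight-chord observable
    and inverted against the model's prediction of the *same* windowed
    line-fit observable, which keeps the inverse self-consistent with the
    measurement operator.  The radius is taken from the measured mid-span
    diameter.
    """
    fm = filament.segment_filament(frame.image, calibration, supports=frame.supports)
    (lo1, hi1), _ = filament.angle_fit_windows(fm)
    theta1, theta2 = filament.measure_deflection_angles(fm)
    r_m = measured_radius_m(fm)
    L_m = frame.gap_mm * 1e-3
    w_obs = beam.angles_to_midpoint_deflection(theta1, theta2, L_m)
    params = beam.BeamParameters(E=1.0, P=P, r=r_m, rho=rho, L=L_m)
    return beam.estimate_modulus(
        w_obs, params, bracket=bracket, observable="chord",
        angle_window=(lo1, hi1), t=frame.t_s,
    )


def measured_radius_m(fm: filament.FilamentMask) -> float:
    """Mid-span radius in metres from the measured diameter."""
    return filament.measure_diameter(fm, at=0.5) / 2.0 * 1e-3
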