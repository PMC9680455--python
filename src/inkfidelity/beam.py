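"""Tensioned simply-supported beam model of a hanging filament.

A freshly printed filament bridging two supports is modelled as a uniform
cylindrical beam under its own weight ``q`` and an axial tension ``P``
(load transferred by adjacent material).  The quasi-static deflection
``w(x)`` (positive downward, sag-positive convention) solves

    w'''' - (P / EI) w'' = q / EI,      w(0) = w(L) = 0,
                                        w''(0) = w''(L) = 0.

The general solution is

    w(x) = c1 + c2 x + c3 e^{kx} + c4 e^{-kx} - q x^2 / (2 P),
    k = sqrt(P / (E I)),

whose coefficients follow from the four simply-supported boundary
conditions.  Internally everything is evaluated in a cosh/sinh basis
centred at L/2, which is overflow-safe for large ``k L``; the raw
``c1..c4`` are recovered by back-transformation for reporting.

For ``P -> 0`` the particular solution degenerates, so below a small
``k L`` threshold the model switches to the classic untensioned limit
``w_max = 5 q L^4 / (384 EI)``.

The inverse problem — find the Young's modulus whose predicted sag
matches an observed one — is solved by bisection on ``log10 E``;
``w_max(E)`` is strictly decreasing, so the root is unique.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .errors import (
    BracketError,
    DomainError,
    InvalidParameterError,
    NumericalFailureError,
    TensionLimitError,
)

__all__ = [
    "KL_SWITCH",
    "BeamParameters",
    "BeamSolution",
    "ModulusEstimate",
    "ModulusRadiusFit",
    "derive_section_properties",
    "solve_coefficients",
    "classic_solution",
    "solve",
    "deflection_profile",
    "deflection_slope",
    "midpoint_deflection",
    "support_angles_deg",
    "windowed_support_angles_deg",
    "chord_deflection",
    "classic_limit_deflection",
    "solve_deflection_numeric",
    "estimate_modulus",
    "fit_modulus_vs_radius",
    "angles_to_midpoint_deflection",
]

#: below this value of k*L the tensioned closed form is numerically
#: degenerate and the classic (untensioned) limit is used instead
KL_SWITCH = 1e-2


@dataclass(frozen=True)
class BeamParameters:
    """Geometry and material state of one suspended filament segment.

    Parameters are SI: Pa, N, m, kg/m^3.  ``P`` is the axial tension
    transferred by adjacent material; it is a configured parameter, not
    something the model can identify from a single filament.
    """

    E: float  # Young's modulus, Pa
    P: float  # axial tension ("transfer loading"), N
    r: float  # filament radius, m
    rho: float  # bioink density, kg/m^3
    L: float  # gap length between supports, m
    g: float = 9.81  # gravitational acceleration, m/s^2

    def __post_init__(self) -> None:
        for name in ("E", "r", "rho", "L", "g"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.P < 0:
            raise InvalidParameterError(f"P must be >= 0, got {self.P!r}")
        if not self.r < self.L:
            raise InvalidParameterError(
                f"slender-filament assumption requires r < L (r={self.r}, L={self.L})"
            )

    @property
    def I(self) -> float:  # noqa: E743 - conventional symbol
        """Second moment of area of the circular cross-section, m^4."""
        return math.pi * self.r**4 / 4.0

    @property
    def A(self) -> float:
        """Cross-section area, m^2."""
        return math.pi * self.r**2

    @property
    def q(self) -> float:
        """Self-weight per unit length (positive in the sag direction), N/m."""
        return self.rho * self.g * self.A

    @property
    def EI(self) -> float:
        return self.E * self.I

    @property
    def k(self) -> float:
        """Tension decay parameter sqrt(P / EI), 1/m."""
        return math.sqrt(self.P / self.EI)

    def with_modulus(self, E: float) -> "BeamParameters":
        return BeamParameters(E=E, P=self.P, r=self.r, rho=self.rho, L=self.L, g=self.g)


def derive_section_properties(params: BeamParameters) -> tuple[float, float, float]:
    """Return ``(I, A, q)`` for a cylindrical filament.

    ``I = pi r^4 / 4``, ``A = pi r^2``, ``q = rho g A``.
    """
    return params.I, params.A, params.q


@dataclass(frozen=True)
class BeamSolution:
    """Deflection solution with explicit coefficients of the closed form."""

    c1: float
    c2: float
    c3: float
    c4: float
    k: float
    q: float
    P: float
    EI: float
    L: float
    mode: str = "closed_form_tensioned"  # or "classic_limit"


def _cosh_ratio(k: float, xi: np.ndarray, half: float) -> np.ndarray:
    """cosh(k*xi) / cosh(k*half) for |xi| <= half, overflow-safe."""
    a = k * np.abs(xi)
    b = k * half
    return np.exp(a - b) * (1.0 + np.exp(-2.0 * a)) / (1.0 + np.exp(-2.0 * b))


def _sinh_ratio(k: float, xi: np.ndarray, half: float) -> np.ndarray:
    """sinh(k*xi) / cosh(k*half), overflow-safe."""
    a = k * np.abs(xi)
    b = k * half
    return np.sign(xi) * np.exp(a - b) * (1.0 - np.exp(-2.0 * a)) / (1.0 + np.exp(-2.0 * b))


def solve_coefficients(params: BeamParameters) -> BeamSolution:
    """Solve the four boundary conditions of the tensioned closed form.

    Raises
    ------
    TensionLimitError
        If ``P == 0`` or ``k L < KL_SWITCH``; the caller should fall back
        to :func:`classic_solution` / :func:`classic_limit_deflection`.
    """
    if params.P == 0:
        raise TensionLimitError("P = 0: use the classic untensioned limit")
    k, L, q, P = params.k, params.L, params.q, params.P
    if k * L < KL_SWITCH:
        raise TensionLimitError(
            f"k*L = {k * L:.3g} below switch threshold {KL_SWITCH}: use the classic limit"
        )
    # centred basis: w = a + b x + A_c cosh(k(x - L/2)) - q x^2 / (2P);
    # the sinh term vanishes by symmetry of the uniform load.
    half = L / 2.0
    # A_c = q / (P k^2 cosh(k L/2)); written via exp to stay finite for large kL
    A_c = (q / (P * k * k)) * 2.0 * math.exp(-k * half) / (1.0 + math.exp(-2.0 * k * half))
    a = -q / (P * k * k)
    b = q * L / (2.0 * P)
    # back-transform A_c cosh(k(x - L/2)) = c3 e^{kx} + c4 e^{-kx}
    c3 = A_c * math.exp(-k * half) / 2.0
    c4 = A_c * math.exp(k * half) / 2.0
    return BeamSolution(
        c1=a, c2=b, c3=c3, c4=c4, k=k, q=q, P=P, EI=params.EI, L=L,
        mode="closed_form_tensioned",
    )


def classic_solution(params: BeamParameters) -> BeamSolution:
    """Untensioned simply-supported solution as a :class:`BeamSolution`."""
    return BeamSolution(
        c1=0.0, c2=0.0, c3=0.0, c4=0.0, k=0.0, q=params.q, P=0.0,
        EI=params.EI, L=params.L, mode="classic_limit",
    )


def solve(params: BeamParameters) -> BeamSolution:
    """Solve with automatic fallback to the classic limit at small k*L."""
    try:
        return solve_coefficients(params)
    except TensionLimitError:
        return classic_solution(params)


def _check_domain(x: np.ndarray, L: float) -> None:
    if np.any(x < -1e-12 * L) or np.any(x > L * (1 + 1e-12)):
        raise DomainError(f"x must lie in [0, L] = [0, {L}]")


def deflection_profile(sol: BeamSolution, x):
    """Evaluate ``w(x)`` (sag-positive, metres) for scalar or array ``x``."""
    x_arr = np.asarray(x, dtype=float)
    _check_domain(x_arr, sol.L)
    L = sol.L
    if sol.mode == "classic_limit":
        w = sol.q * x_arr * (L**3 - 2.0 * L * x_arr**2 + x_arr**3) / (24.0 * sol.EI)
    else:
        k, q, P = sol.k, sol.q, sol.P
        xi = x_arr - L / 2.0
        b = k * L / 2.0
        u = k * np.abs(xi)
        if b <= 30.0:
            # bracket/k^2 with the cancellation between the polynomial and
            # cosh terms removed via cosh(b) - cosh(u) = 2 sinh(s) sinh(d)
            s, d = (b + u) / 2.0, (b - u) / 2.0
            num = 2.0 * (s * d * math.cosh(b) - np.sinh(s) * np.sinh(d))
            g = num / math.cosh(b)
        else:
            g = (b * b - u * u) / 2.0 - 1.0 + _cosh_ratio(k, xi, L / 2.0)
        w = (q / (P * k * k)) * g
    return w if w.ndim else float(w)


def deflection_slope(sol: BeamSolution, x):
    """Evaluate ``w'(x)`` (dimensionless slope) for scalar or array ``x``."""
    x_arr = np.asarray(x, dtype=float)
    _check_domain(x_arr, sol.L)
    L = sol.L
    if sol.mode == "classic_limit":
        s = sol.q * (L**3 - 6.0 * L * x_arr**2 + 4.0 * x_arr**3) / (24.0 * sol.EI)
    else:
        k, q, P = sol.k, sol.q, sol.P
        xi = x_arr - L / 2.0
        s = (q / P) * ((L - 2.0 * x_arr) / 2.0 + _sinh_ratio(k, xi, L / 2.0) / k)
    return s if s.ndim else float(s)


def midpoint_deflection(params: BeamParameters) -> float:
    """Maximum (mid-span) deflection ``w(L/2)`` in metres."""
    return deflection_profile(solve(params), params.L / 2.0)


def support_angles_deg(params: BeamParameters) -> tuple[float, float]:
    """Tangent angles of the deflection curve at the two supports, degrees.

    Equal by symmetry of the uniform load; returned as a pair to mirror
    the two measured angles of the filament test.
    """
    sol = solve(params)
    theta = math.degrees(math.atan(abs(deflection_slope(sol, 0.0))))
    return theta, theta


def windowed_support_angles_deg(
    params: BeamParameters, window: tuple[float, float]
) -> tuple[float, float]:
    """Support angles as a line fit of the analytic profile over a window.

    ``window = (lo, hi)`` are span fractions measured from the support.
    This forward-models how an image-based angle measurement fits a
    straight line over a finite window of the curved profile, so the
    inverse solve can use the exact observable the analyzer produces.
    Both angles are equal by symmetry.
    """
    lo, hi = window
    if not (0 <= lo < hi <= 1):
        raise InvalidParameterError(f"window fractions must satisfy 0 <= lo < hi <= 1, got {window}")
    sol = solve(params)
    xs = np.linspace(lo * params.L, hi * params.L, 100)
    slope = np.polyfit(xs, deflection_profile(sol, xs), 1)[0]
    theta = math.degrees(math.atan(abs(float(slope))))
    return theta, theta


def chord_deflection(params: BeamParameters) -> float:
    """Mid-span depth of the straight-chord construction, metres.

    This is the model-side counterpart of
    :func:`angles_to_midpoint_deflection`: two straight segments leaving
    the supports at the tangent angles meet at mid-span at depth
    ``(L/2) tan(theta)``.  Inverting this observable against chord-derived
    observations is self-consistent, whereas mixing the chord observable
    with the true ``w(L/2)`` is not (the chord overestimates the sag of
    the curved profile by a factor of ~1.6-2).
    """
    theta1, theta2 = support_angles_deg(params)
    return angles_to_midpoint_deflection(theta1, theta2, params.L)


def classic_limit_deflection(params: BeamParameters) -> float:
    """Untensioned limit ``5 q L^4 / (384 EI)`` in metres."""
    return 5.0 * params.q * params.L**4 / (384.0 * params.EI)


def solve_deflection_numeric(params: BeamParameters, n_nodes: int = 1024) -> np.ndarray:
    """Finite-difference solution of the beam BVP on ``n_nodes`` points.

    Splits the fourth-order problem into two tridiagonal second-order
    solves via the bending moment ``m = w''``:

        m'' - (P/EI) m = q/EI,  m(0) = m(L) = 0
        w'' = m,                w(0) = w(L) = 0

    Central differences give second-order accuracy.  Serves as the
    numerical oracle standing in for the original finite-element check.
    """
    if n_nodes < 16:
        raise InvalidParameterError(f"n_nodes must be >= 16, got {n_nodes}")
    L, EI, P, q = params.L, params.EI, params.P, params.q
    n = n_nodes
    h = L / (n - 1)
    n_int = n - 2

    def _tridiag_solve(diag: float, rhs: np.ndarray) -> np.ndarray:
        ab = np.zeros((3, n_int))
        ab[0, 1:] = 1.0 / h**2
        ab[1, :] = diag
        ab[2, :-1] = 1.0 / h**2
        out = solve_banded((1, 1), ab, rhs)
        if not np.all(np.isfinite(out)):
            raise NumericalFailureError("tridiagonal solve produced non-finite values")
        return out

    # moment equation: (m[i-1] - 2 m[i] + m[i+1]) / h^2 - (P/EI) m[i] = q/EI
    m_int = _tridiag_solve(-2.0 / h**2 - P / EI, np.full(n_int, q / EI))
    # deflection: (w[i-1] - 2 w[i] + w[i+1]) / h^2 = m[i]
    w_int = _tridiag_solve(-2.0 / h**2, m_int)
    w = np.zeros(n)
    w[1:-1] = w_int
    return w


@dataclass(frozen=True)
class ModulusEstimate:
    """One inverse-solve result: observed sag and the modulus explaining it."""

    t: float  # time of the observation, s
    E_hat: float  # estimated Young's modulus, Pa
    r: float  # radius used in the solve, m
    w_obs: float  # observed mid-span deflection, m
    observable: str = "midpoint"


DEFAULT_BRACKET = (10.0, 1e7)  # Pa; spans soft hydrogels with margin


def _forward_observable(
    params: BeamParameters, observable: str, angle_window: tuple[float, float] | None
) -> float:
    if observable == "midpoint":
        return midpoint_deflection(params)
    if observable == "chord":
        if angle_window is not None:
            th1, th2 = windowed_support_angles_deg(params, angle_window)
        else:
            th1, th2 = support_angles_deg(params)
        return angles_to_midpoint_deflection(th1, th2, params.L)
    raise InvalidParameterError(f"unknown observable {observable!r}")


def estimate_modulus(
    w_obs: float,
    params_without_E: BeamParameters,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    observable: str = "midpoint",
    angle_window: tuple[float, float] | None = None,
    t: float = 0.0,
    rel_tol: float = 1e-6,
) -> ModulusEstimate:
    """Invert ``w(E) = w_obs`` for the Young's modulus.

    ``params_without_E`` supplies geometry/load; its ``E`` field is
    ignored.  The predicted sag is strictly decreasing in ``E``, so
    bisection on ``log10 E`` converges to the unique root.

    ``observable`` selects what ``w_obs`` is: the true mid-span
    deflection (``"midpoint"``) or the straight-chord depth derived from
    the measured support angles (``"chord"``).  Use ``"chord"`` whenever
    the observation came through :func:`angles_to_midpoint_deflection`,
    and pass the analyzer's ``angle_window`` (span fractions) so the
    model predicts the same windowed-line-fit angle that was measured.
    """
    if not w_obs > 0:
        raise InvalidParameterError(f"w_obs must be > 0, got {w_obs!r}")
    E_lo, E_hi = bracket
    if not (0 < E_lo < E_hi):
        raise InvalidParameterError(f"invalid bracket {bracket!r}")

    def predict(E: float) -> float:
        return _forward_observable(params_without_E.with_modulus(E), observable, angle_window)

    w_at_lo, w_at_hi = predict(E_lo), predict(E_hi)
    if not (w_at_hi <= w_obs <= w_at_lo):
        raise BracketError(
            f"w_obs={w_obs:.4g} m outside achievable range "
            f"[{w_at_hi:.4g}, {w_at_lo:.4g}] m for E in [{E_lo:.4g}, {E_hi:.4g}] Pa",
            achievable=(w_at_hi, w_at_lo),
        )
    lo, hi = math.log10(E_lo), math.log10(E_hi)
    # stop when the bracket width guarantees relative tolerance on E
    width_tol = math.log10(1.0 + rel_tol)
    while hi - lo > width_tol:
        mid = 0.5 * (lo + hi)
        if predict(10.0**mid) > w_obs:
            lo = mid  # sag too large -> modulus too small
        else:
            hi = mid
    E_hat = 10.0 ** (0.5 * (lo + hi))
    return ModulusEstimate(
        t=t, E_hat=E_hat, r=params_without_E.r, w_obs=w_obs, observable=observable
    )


@dataclass(frozen=True)
class ModulusRadiusFit:
    """Ordinary least-squares fit of modulus against filament radius."""

    slope: float  # Pa per metre of radius
    intercept: float  # Pa
    r_squared: float
    n_points: int
    residuals: np.ndarray = field(repr=False, default=None)


def fit_modulus_vs_radius(points) -> ModulusRadiusFit:
    """OLS fit ``E = slope * r + intercept`` over ``(r, E_hat)`` pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise InvalidParameterError("need at least two (r, E) points")
    r, E = pts[:, 0], pts[:, 1]
    if np.ptp(r) == 0:
        raise InvalidParameterError("all radii identical: degenerate fit")
    slope, intercept = np.polyfit(r, E, 1)
    pred = slope * r + intercept
    ss_res = float(np.sum((E - pred) ** 2))
    ss_tot = float(np.sum((E - E.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return ModulusRadiusFit(
        slope=float(slope), intercept=float(intercept), r_squared=r2,
        n_points=len(r), residuals=E - pred,
    )


def angles_to_midpoint_deflection(theta1: float, theta2: float, L: float) -> float:
    """Straight-chord mid-span depth from the two support angles.

    ``w = (L/2) tan((theta1 + theta2) / 2)`` with angles in degrees
    measured from the horizontal.  This is the documented conversion from
    the two measured deflection angles to a single sag observable; pair
    it with ``observable="chord"`` in :func:`estimate_modulus`.
    """
    for th in (theta1, theta2):
        if not (0 <= th < 90):
            raise DomainError(f"angles must lie in [0, 90) degrees, got {th!r}")
    if not L > 0:
        raise InvalidParameterError(f"L must be > 0, got {L!r}")
    return (L / 2.0) * math.tan(math.radians((theta1 + theta2) / 2.0))
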