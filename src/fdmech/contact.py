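"""Hertzian contact mechanics with depth segmentation and bottom-effect
correction.

For a sphere of radius R indenting an elastic half-space to depth delta,

    F = (4/3) * E/(1 - nu^2) * sqrt(R) * delta^{3/2},

so F^{2/3} is linear in delta and the Young's modulus follows from the
slope. Cells are not half-spaces: a soft, thin plasma-membrane-dominated
layer sits on a stiffer actin cortex, so the modulus is extracted separately
in a shallow window (0, 50] nm and a deeper window (50, 200] nm. For thin
layers on a rigid support the measured force is inflated; the polynomial
bottom-effect correction for an incompressible layer of thickness h is

    F = (16 E / 9) sqrt(R) delta^{3/2}
        [1 + 0.884 a + 0.781 a^2 + 0.386 a^3 + 0.0048 a^4],  a = sqrt(R delta)/h,

which reduces to the Hertz sphere with nu = 1/2 as a -> 0.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DomainError, InsufficientDataError
from .model import IndentationCurve, MechanicsFit
from .units import modulus_internal_to_kpa, modulus_kpa_to_internal

BOTTOM_EFFECT_COEFFS = (0.884, 0.781, 0.386, 0.0048)
DEFAULT_PM_WINDOW = (0.0, 50.0)
DEFAULT_CORTEX_WINDOW = (50.0, 200.0)
DEFAULT_LAYER_THICKNESS_NM = 50.0
MIN_WINDOW_SAMPLES = 8


@dataclass(frozen=True)
class BottomEffectParams:
    """Thin-layer correction inputs: layer thickness h (nm) and the fixed
    polynomial coefficients."""

    layer_thickness: float
    coefficients: tuple = BOTTOM_EFFECT_COEFFS

    def __post_init__(self) -> None:
        if self.layer_thickness <= 0:
            raise DomainError("layer thickness h must be > 0")

    def alpha(self, tip_radius: float, delta: np.ndarray) -> np.ndarray:
        return np.sqrt(tip_radius * np.asarray(delta, dtype=float)) \
            / self.layer_thickness

    def factor(self, tip_radius: float, delta: np.ndarray) -> np.ndarray:
        """Multiplicative force correction 1 + 0.884a + ... + 0.0048a^4."""
        a = self.alpha(tip_radius, delta)
        c1, c2, c3, c4 = self.coefficients
        return 1.0 + a * (c1 + a * (c2 + a * (c3 + a * c4)))


def _prefactor(e_kpa: float, tip_radius: float, poisson_ratio: float) -> float:
    """C such that F = C * delta^{3/2}, in pN/nm^{3/2}."""
    e_int = modulus_kpa_to_internal(e_kpa)
    return (4.0 / 3.0) * e_int / (1.0 - poisson_ratio ** 2) * np.sqrt(tip_radius)


def _modulus_from_prefactor(c: float, tip_radius: float,
                            poisson_ratio: float) -> float:
    return modulus_internal_to_kpa(
        0.75 * c * (1.0 - poisson_ratio ** 2) / np.sqrt(tip_radius))


def hertz_force(e_kpa: float, tip_radius: float, delta, poisson_ratio: float = 0.5):
    """Hertz sphere force (pN) at indentation delta (nm); E in kPa, R in nm."""
    delta = np.asarray(delta, dtype=float)
    if e_kpa <= 0 or tip_radius <= 0:
        raise DomainError("E and R must be > 0")
    if not 0.0 <= poisson_ratio <= 0.5:
        raise DomainError("poisson_ratio must be in [0, 0.5]")
    if (delta < 0).any():
        raise DomainError("indentation must be >= 0")
    out = _prefactor(e_kpa, tip_radius, poisson_ratio) * delta ** 1.5
    return float(out) if out.ndim == 0 else out


def bottom_effect_force(e_kpa: float, tip_radius: float, delta,
                        layer_thickness: float):
    """Thin-layer force (pN): Hertz (nu=1/2) times the polynomial factor."""
    delta = np.asarray(delta, dtype=float)
    if e_kpa <= 0 or tip_radius <= 0:
        raise DomainError("E and R must be > 0")
    if (delta < 0).any():
        raise DomainError("indentation must be >= 0")
    be = BottomEffectParams(layer_thickness)
    e_int = modulus_kpa_to_internal(e_kpa)
    out = (16.0 * e_int / 9.0) * np.sqrt(tip_radius) * delta ** 1.5 \
        * be.factor(tip_radius, delta)
    return float(out) if out.ndim == 0 else out


def _window_mask(delta: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (delta > lo) & (delta <= hi)


def hertz_slope_fit(curve: IndentationCurve, window: tuple[float, float],
                    tip_radius: float, poisson_ratio: float = 0.5
                    ) -> tuple[Optional[float], float]:
    """Modulus (kPa) from the slope of F^{2/3} vs delta over a window.

    Ordinary least squares through the origin on (delta, F^{2/3}); the
    signed 2/3-power keeps negative noisy samples informative. Returns
    (modulus, rms); modulus is None when the slope is nonpositive
    (fit-failed flag).
    """
    m = _window_mask(curve.delta, window)
    if int(m.sum()) < MIN_WINDOW_SAMPLES:
        raise InsufficientDataError(
            f"window {window} has {int(m.sum())} samples, "
            f"needs >= {MIN_WINDOW_SAMPLES}")
    x = curve.delta[m]
    f = curve.force[m]
    y = np.sign(f) * np.abs(f) ** (2.0 / 3.0)
    s = float((x * y).sum() / (x * x).sum())
    if s <= 0:
        return None, float("nan")
    c = s ** 1.5
    rms = float(np.sqrt(np.mean((f - c * x ** 1.5) ** 2)))
    return _modulus_from_prefactor(c, tip_radius, poisson_ratio), rms


def _force_space_window_fit(curve: IndentationCurve,
                            window: tuple[float, float],
                            tip_radius: float, poisson_ratio: float,
                            anchor_halfwidth: float = 6.0
                            ) -> tuple[Optional[float], float]:
    """Modulus from LS of force on depth^{3/2} over a window (through origin).

    For a window starting at lo > 0 the fit is incremental: the response of
    the deeper layer is F(delta) - F(lo) = C*(delta^{3/2} - lo^{3/2}), with
    F(lo) anchored on the measured mean force within ``anchor_halfwidth`` nm
    of the window entry. Identical to the plain fit when lo == 0; unbiased
    under additive force noise.
    """
    lo, hi = window
    m = _window_mask(curve.delta, window)
    if int(m.sum()) < MIN_WINDOW_SAMPLES:
        raise InsufficientDataError(
            f"window {window} has {int(m.sum())} samples, "
            f"needs >= {MIN_WINDOW_SAMPLES}")
    d = curve.delta[m]
    f = curve.force[m]
    if lo > 0:
        near = np.abs(curve.delta - lo) <= anchor_halfwidth
        if int(near.sum()) < 3:
            return None, float("nan")
        f_lo = float(curve.force[near].mean())
    else:
        f_lo = 0.0
    x = d ** 1.5 - lo ** 1.5
    g = f - f_lo
    c = float((x * g).sum() / (x * x).sum())
    if c <= 0:
        return None, float("nan")
    rms = float(np.sqrt(np.mean((g - c * x) ** 2)))
    return _modulus_from_prefactor(c, tip_radius, poisson_ratio), rms


def bottom_effect_fit(curve: IndentationCurve, window: tuple[float, float],
                      tip_radius: float, layer_thickness: float
                      ) -> tuple[Optional[float], float]:
    """Modulus (kPa) by LS against the thin-layer model over a window.

    The model force is linear in E, so the estimate is closed-form.
    Returns (modulus, rms); None flags a nonpositive solution.
    """
    m = _window_mask(curve.delta, window)
    if int(m.sum()) < MIN_WINDOW_SAMPLES:
        raise InsufficientDataError(
            f"window {window} has {int(m.sum())} samples, "
            f"needs >= {MIN_WINDOW_SAMPLES}")
    d = curve.delta[m]
    f = curve.force[m]
    basis = bottom_effect_force(1.0, tip_radius, d, layer_thickness)
    e = float((basis * f).sum() / (basis * basis).sum())
    if e <= 0:
        return None, float("nan")
    rms = float(np.sqrt(np.mean((f - e * basis) ** 2)))
    return e, rms


def segmented_moduli(curve: IndentationCurve, tip_radius: float,
                     poisson_ratio: float = 0.5,
                     pm_window: tuple[float, float] = DEFAULT_PM_WINDOW,
                     cortex_window: tuple[float, float] = DEFAULT_CORTEX_WINDOW,
                     method: str = "force",
                     bottom_effect: bool = False,
                     layer_thickness: float = DEFAULT_LAYER_THICKNESS_NM
                     ) -> MechanicsFit:
    """Membrane and cortex moduli from the two indentation windows.

    method="force" (default): least squares in force space, exact noise-free
    and unbiased under additive noise. method="f23": slope of F^{2/3} vs
    delta (only meaningful at high signal-to-noise). With
    ``bottom_effect=True`` the shallow window uses the thin-layer model with
    the given layer thickness instead.
    """
    fitter = {"force": _force_space_window_fit,
              "f23": hertz_slope_fit}[method]
    e_pm = rms_pm = None
    try:
        if bottom_effect:
            e_pm, rms_pm = bottom_effect_fit(curve, pm_window, tip_radius,
                                             layer_thickness)
        else:
            e_pm, rms_pm = fitter(curve, pm_window, tip_radius, poisson_ratio)
    except InsufficientDataError:
        pass
    e_cortex = rms_cortex = None
    if curve.delta.size and curve.delta.max() > cortex_window[0]:
        try:
            e_cortex, rms_cortex = fitter(curve, cortex_window, tip_radius,
                                          poisson_ratio)
        except InsufficientDataError:
            pass
    return MechanicsFit(
        e_pm=e_pm, e_cortex=e_cortex,
        pm_window=pm_window, cortex_window=cortex_window,
        rms_pm=rms_pm, rms_cortex=rms_cortex,
        bottom_effect_used=bottom_effect,
        layer_thickness=layer_thickness if bottom_effect else None)
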