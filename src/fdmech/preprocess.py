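"""Raw-curve conditioning: baseline, noise, contact point, indentation.

The off-contact region of a segment is the configurable fraction of samples
farthest from the surface (smallest piezo extension z); baseline drift is a
2nd-degree polynomial fit there and subtracted from the whole segment, and
the noise level is the standard deviation of residuals about a straight-line
fit of the same region of the retract.

The contact point is found with a deterministic ratio-of-variances scan: for
each candidate split the curve is modelled as flat (zero force) before contact
and a two-layer segmented Hertz response after it, both layer stiffnesses
solved in closed form, and the candidate minimising the total residual sum
of squares wins. The scan runs on tip position w = z - F/k so that cantilever
deflection does not skew deep-indentation candidates.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InsufficientDataError, ParameterError
from .model import ForceCurve, IndentationCurve
from .units import spring_constant_internal

MIN_BASELINE_SAMPLES = 16
MIN_NOISE_SAMPLES = 32
DEFAULT_OFF_CONTACT_FRACTION = 0.30
DEFAULT_CONTACT_MIN_SNR = 5.0
DEFAULT_LAYER_BOUNDARY_NM = 50.0


@dataclass(frozen=True)
class BaselineFit:
    """2nd-degree polynomial drift model over the off-contact z range."""

    coefficients: tuple[float, float, float]     # c0, c1, c2 (pN, pN/nm, pN/nm^2)
    off_contact_fraction: float
    n_samples: int

    def __post_init__(self) -> None:
        if not 0.0 < self.off_contact_fraction <= 0.9:
            raise ParameterError("off_contact_fraction must be in (0, 0.9]")

    def __call__(self, z: np.ndarray) -> np.ndarray:
        c0, c1, c2 = self.coefficients
        return c0 + c1 * z + c2 * z * z


@dataclass(frozen=True)
class NoiseEstimate:
    """Force noise sigma (pN) from the off-contact retract residuals."""

    sigma: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ParameterError("sigma must be >= 0")


def _off_contact_mask(z: np.ndarray, fraction: float) -> np.ndarray:
    """Samples farthest from the surface: the lowest-z fraction."""
    n_off = int(round(len(z) * fraction))
    cut = np.partition(z, n_off - 1)[n_off - 1] if n_off >= 1 else -np.inf
    return z <= cut


def fit_baseline(z: np.ndarray, f: np.ndarray,
                 off_contact_fraction: float = DEFAULT_OFF_CONTACT_FRACTION,
                 mask: Optional[np.ndarray] = None) -> BaselineFit:
    """Fit the 2nd-degree drift polynomial on the off-contact region.

    ``mask`` overrides the fractional off-contact definition (used by the
    pipeline once the contact point is known).
    """
    if mask is None:
        mask = _off_contact_mask(z, off_contact_fraction)
    n = int(mask.sum())
    if n < MIN_BASELINE_SAMPLES:
        raise InsufficientDataError(
            f"baseline needs >= {MIN_BASELINE_SAMPLES} off-contact samples, got {n}")
    a0, a1, a2, mu = _quadfit(z[mask], f[mask])
    # back-transform from the centered variable
    c0 = a0 - a1 * mu + a2 * mu * mu
    c1 = a1 - 2.0 * a2 * mu
    return BaselineFit((float(c0), float(c1), float(a2)),
                       off_contact_fraction, n)


def _quadfit(z: np.ndarray, f: np.ndarray):
    """LS quadratic in the centered variable (well-conditioned, fast)."""
    mu = z.mean()
    zc = z - mu
    z2 = zc * zc
    s1 = zc.sum()
    s2 = z2.sum()
    s3 = (z2 * zc).sum()
    s4 = (z2 * z2).sum()
    a = np.array([[len(zc), s1, s2], [s1, s2, s3], [s2, s3, s4]])
    b = np.array([f.sum(), zc @ f, z2 @ f])
    a0, a1, a2 = np.linalg.solve(a, b)
    return a0, a1, a2, mu


def linefit_sigma(z: np.ndarray, f: np.ndarray, ddof: int = 2) -> float:
    """Residual sd about a straight-line LS fit."""
    mu = z.mean()
    zc = z - mu
    denom = float(zc @ zc)
    slope = float(zc @ f) / denom if denom > 0 else 0.0
    resid = f - f.mean() - slope * zc
    return float(np.sqrt((resid @ resid) / max(len(f) - ddof, 1)))


def correct_baseline(curve: ForceCurve,
                     off_contact_fraction: float = DEFAULT_OFF_CONTACT_FRACTION,
                     segment: str = "retract") -> ForceCurve:
    """Subtract the fitted drift polynomial from a segment's force.

    Returns a new curve; the in-contact shape is preserved up to the
    subtracted polynomial.
    """
    z, f = curve.segment(segment)
    bl = fit_baseline(z, f, off_contact_fraction)
    corrected = f - bl(z)
    if segment == "retract":
        return curve.with_retract_force(corrected)
    return curve.with_approach_force(corrected)


def estimate_noise(curve: ForceCurve,
                   off_contact_fraction: float = DEFAULT_OFF_CONTACT_FRACTION,
                   mask: Optional[np.ndarray] = None) -> NoiseEstimate:
    """Noise sigma = sd of residuals about a line on the off-contact retract."""
    z, f = curve.retract_z, curve.retract_f
    if mask is None:
        mask = _off_contact_mask(z, off_contact_fraction)
    n = int(mask.sum())
    if n < MIN_NOISE_SAMPLES:
        raise InsufficientDataError(
            f"noise estimate needs >= {MIN_NOISE_SAMPLES} samples, got {n}")
    return NoiseEstimate(linefit_sigma(z[mask], f[mask]), n)


def _scan_rss(w: np.ndarray, f: np.ndarray, cand: np.ndarray,
              boundary: float,
              sample_weight: Optional[np.ndarray] = None
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total RSS of the flat + two-layer Hertz model per candidate contact.

    Model: F = 0 for w <= w0; F = C1*d^{3/2} for 0 < d <= b and
    F = C1*b^{3/2} + C2*(d^{3/2} - b^{3/2}) beyond, d = w - w0. C1, C2 from
    the 2x2 normal equations (clipped fallback to the single-layer fit when
    the joint solution leaves the positive quadrant).
    """
    if sample_weight is not None:
        f = f * sample_weight
    big_b = boundary ** 1.5
    d = w[None, :] - cand[:, None]
    np.clip(d, 0.0, None, out=d)
    d *= np.sqrt(d)                      # d^{3/2}, zero off-contact
    b1 = np.minimum(d, big_b)            # shallow-layer basis
    d -= b1                              # deep-layer basis (in place)
    b2 = d
    if sample_weight is not None:
        b1 *= sample_weight
        b2 *= sample_weight
    a11 = np.einsum("ij,ij->i", b1, b1)
    a12 = np.einsum("ij,ij->i", b1, b2)
    a22 = np.einsum("ij,ij->i", b2, b2)
    r1 = b1 @ f
    r2 = b2 @ f
    det = a11 * a22 - a12 * a12
    safe = np.where(det > 0, det, 1.0)
    c1 = np.where(det > 0, (a22 * r1 - a12 * r2) / safe, 0.0)
    c2 = np.where(det > 0, (a11 * r2 - a12 * r1) / safe, 0.0)
    c1_single = np.where(a11 > 0, r1 / np.maximum(a11, 1e-300), 0.0)
    bad = (c1 < 0) | (c2 < 0) | (det <= 0)
    c1 = np.where(bad, np.clip(c1_single, 0.0, None), c1)
    c2 = np.where(bad, 0.0, c2)
    f2 = float(f @ f)
    rss = f2 - 2 * (c1 * r1 + c2 * r2) + c1 ** 2 * a11 \
        + 2 * c1 * c2 * a12 + c2 ** 2 * a22
    return rss, c1, c2


def locate_contact_array(z: np.ndarray, f: np.ndarray, sigma: float,
                         k_pn_per_nm: float,
                         min_snr: float = DEFAULT_CONTACT_MIN_SNR,
                         boundary: float = DEFAULT_LAYER_BOUNDARY_NM,
                         back_range: float = 150.0,
                         forward_range: float = 30.0,
                         coarse_step: float = 2.0,
                         fine_step: float = 0.25,
                         window: Optional[tuple[float, float]] = None
                         ) -> Optional[float]:
    """Contact point z0 (nm) on baseline-corrected samples, or None.

    Deterministic coarse-to-fine scan over candidate contact positions
    within [crossing - back_range, crossing + forward_range] nm of the first
    threshold crossing; None flags a no-contact pixel (maximum force below
    ``min_snr`` times the noise level). Samples may pool several segments.
    """
    w = z - f / k_pn_per_nm
    order = np.argsort(w, kind="stable")
    w = w[order]
    f = f[order]
    thr = max(min_snr * sigma, 1e-9)
    above = f > thr
    if not above.any():
        return None
    # adhesion dips are outside the flat+Hertz model family: mask out the
    # whole tether region (below-threshold samples dilated by 8 neighbours
    # in w-order) so the pull's shallow ramp cannot skew the split
    weight = None
    bad = f < -3.0 * sigma
    if bad.any():
        bad = np.convolve(bad.astype(float), np.ones(17), mode="same") > 0
        weight = (~bad).astype(float)
    w_cross = float(w[int(np.argmax(above))])
    lo = max(float(w[4]) if len(w) > 4 else w[0], w_cross - back_range)
    # the contact always lies below where the 8-sample-smoothed force first
    # clears 1.5 sigma; trim the candidate range accordingly (the 90 nm
    # margin covers the shallowest response in the 3-40 kPa working range)
    if len(f) > 16:
        smooth = np.convolve(f, np.full(8, 0.125), mode="same")
        low_above = smooth > 1.5 * sigma
        if low_above.any():
            lo = max(lo, float(w[int(np.argmax(low_above))]) - 90.0)
    hi = min(float(w[-16]) if len(w) > 16 else w[-1], w_cross + forward_range)
    if window is not None:
        lo = max(lo, window[0])
        hi = min(hi, window[1])
    if hi <= lo:
        return None
    # samples below every candidate contribute a candidate-independent
    # residual, and samples far beyond the crossing constrain only the deep
    # stiffness: drop both from the scan
    keep = (w >= lo) & (w <= w_cross + 160.0)
    w, f = w[keep], f[keep]
    if weight is not None:
        weight = weight[keep]
    cand = np.arange(lo, hi, coarse_step)
    if cand.size < 2:
        return None
    rss, _, _ = _scan_rss(w, f, cand, boundary, sample_weight=weight)
    w_best = float(cand[int(np.argmin(rss))])
    fine = w_best + np.arange(-1.5 * coarse_step, 1.5 * coarse_step, fine_step)
    rss2, _, _ = _scan_rss(w, f, fine, boundary, sample_weight=weight)
    return float(fine[int(np.argmin(rss2))])


def locate_contact_point(curve: ForceCurve,
                         noise: Optional[NoiseEstimate] = None,
                         segment: str = "retract",
                         min_snr: float = DEFAULT_CONTACT_MIN_SNR,
                         boundary: float = DEFAULT_LAYER_BOUNDARY_NM
                         ) -> Optional[float]:
    """Contact point on a baseline-corrected curve; None = no contact."""
    if noise is None:
        noise = estimate_noise(curve)
    z, f = curve.segment(segment)
    k = spring_constant_internal(curve.acquisition.spring_constant)
    return locate_contact_array(z, f, noise.sigma, k,
                                min_snr=min_snr, boundary=boundary)


def to_indentation(curve: ForceCurve, z0: float, k: float,
                   segment: str = "retract") -> IndentationCurve:
    """Transform in-contact samples to (indentation, force).

    delta_i = (z_i - z0) - F_i/k with k in N/m; depths clipped to >= 0 and
    returned shallow-to-deep.
    """
    if k <= 0:
        raise ParameterError(f"spring constant must be > 0 N/m, got {k}")
    k_int = spring_constant_internal(k)
    z, f = curve.segment(segment)
    delta = (z - z0) - f / k_int
    keep = z > z0
    delta, f = delta[keep], f[keep]
    order = np.argsort(delta, kind="stable")
    return IndentationCurve(contact_point=z0,
                            delta=np.clip(delta[order], 0.0, None),
                            force=f[order], segment=segment)
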