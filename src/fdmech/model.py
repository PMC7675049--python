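"""Domain types for force-volume AFM data and derived results.

A force-volume dataset is a grid of force-distance (FD) records, one per
pixel. Each record holds an approach and a retract segment of
(piezo displacement z, cantilever force F) samples, in nm and pN. Larger z
means the piezo has extended further toward the sample; segments are stored
in acquisition (time) order, so the approach has increasing z and the
retract decreasing z. Derived per-pixel quantities (contact height,
depth-segmented Young's moduli, adhesion force, specificity) live in 2-D
channels aligned with the pixel grid, 0-based (row, col), row-major.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ParameterError
from .units import DEFAULT_TEMPERATURE_K

MIN_SEGMENT_SAMPLES = 32


@dataclass(frozen=True)
class AcquisitionParams:
    """Instrument settings needed to interpret raw curves.

    spring_constant   cantilever spring constant k, N/m (0 < k <= 10)
    tip_radius        tip apex radius R, nm
    poisson_ratio     sample Poisson ratio, 0..0.5 (0.5 = incompressible)
    setpoint_force    imaging force trigger, pN
    pixel_size        lateral pixel pitch, nm
    temperature       K, sets k_B*T for tether models
    """

    spring_constant: float = 0.1
    tip_radius: float = 65.0
    poisson_ratio: float = 0.5
    setpoint_force: float = 750.0
    pixel_size: float = 100.0
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if not 0.0 < self.spring_constant <= 10.0:
            raise ParameterError(
                f"spring_constant must be in (0, 10] N/m, got {self.spring_constant}")
        if self.tip_radius <= 0:
            raise ParameterError(f"tip_radius must be > 0, got {self.tip_radius}")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ParameterError(
                f"poisson_ratio must be in [0, 0.5], got {self.poisson_ratio}")
        if self.pixel_size <= 0:
            raise ParameterError(f"pixel_size must be > 0, got {self.pixel_size}")


def _check_segment(z: np.ndarray, f: np.ndarray, name: str) -> None:
    if z.ndim != 1 or f.ndim != 1 or z.size != f.size:
        raise ParameterError(f"{name}: z and force must be 1-D of equal length")
    if z.size < MIN_SEGMENT_SAMPLES:
        raise ParameterError(
            f"{name}: needs >= {MIN_SEGMENT_SAMPLES} samples, got {z.size}")
    dz = np.diff(z)
    if not ((dz > 0).all() or (dz < 0).all()):
        raise ParameterError(f"{name}: z must be strictly monotone")
    if not np.isfinite(f).all():
        raise ParameterError(f"{name}: force contains non-finite values")


@dataclass
class ForceCurve:
    """One pixel's FD record: approach + retract segments and position."""

    approach_z: np.ndarray
    approach_f: np.ndarray
    retract_z: np.ndarray
    retract_f: np.ndarray
    row: int = 0
    col: int = 0
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)

    def validate(self) -> "ForceCurve":
        _check_segment(self.approach_z, self.approach_f, "approach")
        _check_segment(self.retract_z, self.retract_f, "retract")
        return self

    def segment(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        if which == "approach":
            return self.approach_z, self.approach_f
        if which == "retract":
            return self.retract_z, self.retract_f
        raise ParameterError(f"unknown segment {which!r}")

    def with_retract_force(self, f: np.ndarray) -> "ForceCurve":
        return replace(self, retract_f=np.asarray(f, dtype=float))

    def with_approach_force(self, f: np.ndarray) -> "ForceCurve":
        return replace(self, approach_f=np.asarray(f, dtype=float))


@dataclass
class IndentationCurve:
    """In-contact samples transformed to (indentation depth, force).

    delta_i = (z_i - z0) - F_i/k, clipped to >= 0; depths are nondecreasing
    when taken from the approach and stored shallow-to-deep regardless of
    source segment.
    """

    contact_point: float                 # z0, nm
    delta: np.ndarray                    # nm, >= 0, nondecreasing
    force: np.ndarray                    # pN
    segment: str = "retract"

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if (self.delta < -1e-9).any():
            raise ParameterError("indentation depths must be >= 0")
        if (np.diff(self.delta) < -1e-9).any():
            raise ParameterError("indentation depths must be nondecreasing")


@dataclass
class MechanicsFit:
    """Depth-segmented elasticity result for one pixel.

    Moduli are in kPa; the membrane value comes from the shallow window
    (0, 50] nm, the cortex value from (50, 200] nm by default. A modulus is
    None when the fit did not converge or the window had no support --
    never zero, so map statistics stay unbiased.
    """

    e_pm: Optional[float] = None
    e_cortex: Optional[float] = None
    pm_window: tuple[float, float] = (0.0, 50.0)
    cortex_window: tuple[float, float] = (50.0, 200.0)
    rms_pm: Optional[float] = None       # pN
    rms_cortex: Optional[float] = None   # pN
    bottom_effect_used: bool = False
    layer_thickness: Optional[float] = None  # nm

    def __post_init__(self) -> None:
        if self.e_pm is not None and self.e_pm <= 0:
            raise ParameterError("converged e_pm must be > 0")
        if self.e_cortex is not None and self.e_cortex <= 0:
            raise ParameterError("converged e_cortex must be > 0")


@dataclass(frozen=True)
class WLCParams:
    """Worm-like-chain tether parameters (PEG linker + protein)."""

    persistence_length: float          # Lp, nm
    contour_length: float              # Lc, nm
    thermal_energy: float = 4.28       # k_B*T, pN*nm
    rms: float = 0.0                   # fit residual RMS, pN

    def __post_init__(self) -> None:
        if not 0 < self.persistence_length < self.contour_length:
            raise ParameterError(
                f"need 0 < Lp < Lc, got Lp={self.persistence_length}, "
                f"Lc={self.contour_length}")
        if self.thermal_energy <= 0:
            raise ParameterError("thermal_energy must be > 0")


@dataclass
class AdhesionEvent:
    """A rupture on the retract segment.

    rupture_force     magnitude of the most negative force in the event, pN
    rupture_distance  tip-sample separation at rupture, nm
    wlc               accepted tether fit, or None
    specific          passes the specificity rules (force > 80 pN,
                      distance > 5 nm, WLC validated)
    """

    rupture_force: float
    rupture_distance: float
    wlc: Optional[WLCParams] = None
    specific: bool = False
    row: int = 0
    col: int = 0

    def __post_init__(self) -> None:
        if self.rupture_force < 0 or self.rupture_distance < 0:
            raise ParameterError("rupture force/distance must be >= 0")
        if self.specific:
            if self.wlc is None:
                raise ParameterError("a specific event requires a WLC fit")
            if not (self.rupture_force > 80.0 and self.rupture_distance > 5.0):
                raise ParameterError(
                    "a specific event requires force > 80 pN and distance > 5 nm")


# Pixel strata for the cholesterol-domain comparison.
STRATUM_CHOLESTEROL = 1
STRATUM_NON_ADHESIVE = 0
STRATUM_INDETERMINATE = 2
STRATUM_UNASSIGNED = -1

#: canonical channel names, all float64 grids with NaN for absent pixels
CHANNEL_NAMES = ("height", "e_pm", "e_cortex", "adhesion_force")


@dataclass
class SyntheticScene:
    """Ground truth behind a simulated force-volume map.

    Fields share the grid shape. ``events`` maps (row, col) to the injected
    tether truth (rupture force pN, rupture separation nm, Lc nm, Lp nm),
    present only where a binding event was drawn.
    """

    e_pm_true: np.ndarray            # kPa
    e_cortex_true: np.ndarray        # kPa
    domain_mask: np.ndarray          # bool
    p_bind: float                    # per-domain-pixel binding efficiency
    rupture_mean: float              # pN
    rupture_sd: float                # pN
    noise_sd: float                  # pN
    drift_coeffs: tuple[float, float, float]   # c0 pN, c1 pN/nm, c2 pN/nm^2
    seed: int
    events: dict = field(default_factory=dict)
    height_true: Optional[np.ndarray] = None   # true contact z0 per pixel, nm

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_bind <= 1.0:
            raise ParameterError("p_bind must be in [0, 1]")
        shapes = {self.e_pm_true.shape, self.e_cortex_true.shape,
                  self.domain_mask.shape}
        if len(shapes) != 1:
            raise ParameterError("scene fields must share the grid shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.domain_mask.shape

    @property
    def coverage(self) -> float:
        return float(self.domain_mask.mean())


@dataclass
class ForceVolumeMap:
    """Grid of FD curves plus derived channels.

    Curves are stored as dense (rows, cols, n) arrays so that pixel access,
    container I/O and batch processing stay cheap; :meth:`curve` materialises
    a single-pixel view as a :class:`ForceCurve`.
    """

    acquisition: AcquisitionParams
    approach_z: np.ndarray
    approach_f: np.ndarray
    retract_z: np.ndarray
    retract_f: np.ndarray
    channels: dict = field(default_factory=dict)
    specific_mask: Optional[np.ndarray] = None
    stratum: Optional[np.ndarray] = None
    events: list = field(default_factory=list)     # list[AdhesionEvent]
    scene: Optional[SyntheticScene] = None

    def __post_init__(self) -> None:
        if self.approach_z.ndim != 3:
            raise ParameterError("curve arrays must be (rows, cols, n)")
        for name, arr in (("approach_f", self.approach_f),
                          ("retract_z", self.retract_z),
                          ("retract_f", self.retract_f)):
            if arr.shape[:2] != self.approach_z.shape[:2]:
                raise ParameterError(f"{name} grid shape mismatch")
        for name, ch in self.channels.items():
            if ch.shape != self.shape:
                raise ParameterError(f"channel {name!r} shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.approach_z.shape[:2]

    @property
    def rows(self) -> int:
        return self.shape[0]

    @property
    def cols(self) -> int:
        return self.shape[1]

    def curve(self, row: int, col: int) -> ForceCurve:
        return ForceCurve(
            approach_z=self.approach_z[row, col],
            approach_f=self.approach_f[row, col],
            retract_z=self.retract_z[row, col],
            retract_f=self.retract_f[row, col],
            row=row, col=col, acquisition=self.acquisition)

    def iter_pixels(self):
        for r in range(self.rows):
            for c in range(self.cols):
                yield r, c

    def channel(self, name: str) -> np.ndarray:
        from .errors import ChannelError
        if name == "specific":
            if self.specific_mask is None:
                raise ChannelError("channel 'specific' not computed")
            return self.specific_mask
        if name not in self.channels:
            raise ChannelError(f"channel {name!r} not computed")
        return self.channels[name]
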