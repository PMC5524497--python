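"""Camera linearization, white-point balancing, and receptor mapping.

Cameras apply a nonlinear (roughly power-law) encoding to scene radiance,
and their channels have unequal gains under any given illuminant.  Before
colours can be compared across images — let alone mapped into a non-human
receptor space — pixel values must be linearized and white-balanced against
a colour standard of known reflectances placed in the scene.

The model fitted here is a per-channel power law.  The exponent is
estimated from the achromatic (grey) series of the standard using values
relative to the brightest grey patch, so that a global gain imbalance in a
channel is absorbed by the white-point factor rather than the curve shape.
Mapping to a receptor space (e.g. avian cone catches) is exposed as a
user-supplied linear matrix applied after balancing; it defaults to the
identity, leaving values in balanced linear camera space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalibrationError",
    "ColourStandardMeasurement",
    "CameraModel",
    "measure_chart",
    "fit_camera_model",
    "apply_calibration",
]

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised when the colour standard cannot support a valid fit."""


@dataclass(frozen=True)
class ColourStandardMeasurement:
    """Nominal linear reflectances and measured pixel means of chart patches.

    Only the achromatic series drives the fit; both arrays are
    (n_patches, n_channels) with the achromatic patches first, in strictly
    increasing order of nominal reflectance.
    """

    nominal: np.ndarray
    measured: np.ndarray
    n_achromatic: int

    def __post_init__(self) -> None:
        nom = np.asarray(self.nominal, float)
        mea = np.asarray(self.measured, float)
        if nom.shape != mea.shape or nom.ndim != 2:
            raise ValueError("nominal and measured must be matching 2-D arrays")
        if self.n_achromatic < 4:
            raise ValueError("need at least 4 achromatic patches")
        ach = nom[: self.n_achromatic]
        if not np.all(np.diff(ach, axis=0) > 0):
            raise ValueError("achromatic nominal series must be strictly increasing")
        if mea.min() < 0 or mea.max() > 1:
            raise ValueError("measured values must lie in [0, 1]")
        object.__setattr__(self, "nominal", nom)
        object.__setattr__(self, "measured", mea)


@dataclass(frozen=True)
class CameraModel:
    """Per-channel power-law response plus white point and receptor map.

    ``linear = white_scale * measured ** exponent`` per channel, then the
    rows of ``receptor_matrix`` map balanced camera channels to receptor
    channels.
    """

    exponents: np.ndarray
    white_scale: np.ndarray
    receptor_matrix: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        exp = np.asarray(self.exponents, float)
        ws = np.asarray(self.white_scale, float)
        if np.any(exp <= 0) or np.any(ws <= 0):
            raise ValueError("exponents and white-point factors must be > 0")
        rm = self.receptor_matrix
        rm = np.eye(exp.size) if rm is None else np.asarray(rm, float)
        if not np.all(np.isfinite(rm)) or rm.shape[1] != exp.size:
            raise ValueError("receptor_matrix must be finite with one column per channel")
        object.__setattr__(self, "exponents", exp)
        object.__setattr__(self, "white_scale", ws)
        object.__setattr__(self, "receptor_matrix", rm)

    @property
    def n_camera_channels(self) -> int:
        return self.exponents.size

    def linearize(self, values: np.ndarray) -> np.ndarray:
        """Linearize and white-balance camera values (no receptor mapping)."""
        return np.clip(values, 0.0, None) ** self.exponents * self.white_scale


def measure_chart(image: np.ndarray, layout) -> ColourStandardMeasurement:
    """Extract patch means from a chart image given its layout table.

    ``layout`` is a DataFrame with columns nominal_r/g/b, kind, and the
    half-open pixel boxes row0/row1/col0/col1 (as written by
    :func:`camotype.synth.render_colour_standard`).
    """
    order = np.argsort(layout["kind"].ne("achromatic").to_numpy(), kind="stable")
    layout = layout.iloc[order].reset_index(drop=True)
    nominal = layout[["nominal_r", "nominal_g", "nominal_b"]].to_numpy(float)
    measured = np.array([
        image[int(r.row0):int(r.row1), int(r.col0):int(r.col1)].reshape(-1, 3).mean(axis=0)
        for r in layout.itertuples()
    ])
    return ColourStandardMeasurement(
        nominal=nominal,
        measured=measured,
        n_achromatic=int((layout["kind"] == "achromatic").sum()),
    )


def fit_camera_model(
    standard: ColourStandardMeasurement,
    receptor_matrix: np.ndarray | None = None,
) -> CameraModel:
    """Fit the per-channel response curve and white-point factors.

    The exponent of each channel is the log-log regression slope of nominal
    on measured over the achromatic series, both expressed relative to the
    brightest grey patch; the white-point factor then equates the brightest
    grey patch to its nominal reflectance in every channel.
    """
    ach_nom = standard.nominal[: standard.n_achromatic]
    ach_mea = standard.measured[: standard.n_achromatic]
    if not np.all(np.diff(ach_mea, axis=0) > 0):
        raise CalibrationError(
            "measured achromatic series is not strictly increasing; "
            "chart is saturated, clipped or corrupt"
        )
    n_ch = ach_nom.shape[1]
    exponents = np.empty(n_ch)
    white_scale = np.empty(n_ch)
    for c in range(n_ch):
        m_rel = np.log(ach_mea[:, c] / ach_mea[-1, c])
        n_rel = np.log(ach_nom[:, c] / ach_nom[-1, c])
        # slope through the origin: brightest patch is the anchor
        exponents[c] = n_rel[:-1] @ m_rel[:-1] / (m_rel[:-1] @ m_rel[:-1])
        white_scale[c] = ach_nom[-1, c] / ach_mea[-1, c] ** exponents[c]
    return CameraModel(exponents=exponents, white_scale=white_scale,
                       receptor_matrix=receptor_matrix)


def apply_calibration(image: np.ndarray, model: CameraModel) -> np.ndarray:
    """Map a nonlinear camera image to linear receptor space.

    Applies, per pixel: response curve, white-point scaling, then the
    receptor matrix.  Output is clipped at 0 below; values brighter than the
    top chart patch extrapolate along the fitted curve (logged, not clipped).
    """
    image = np.asarray(image, float)
    if image.ndim != 3 or image.shape[2] != model.n_camera_channels:
        raise ValueError(
            f"image has {image.shape[2] if image.ndim == 3 else 'no'} channels; "
            f"model expects {model.n_camera_channels}"
        )
    linear = model.linearize(image)
    if np.any(linear > 1.0):
        log.info("calibrated values above the chart maximum were extrapolated, not clipped")
    out = linear @ model.receptor_matrix.T
    return np.clip(out, 0.0, None)
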