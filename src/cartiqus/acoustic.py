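"""The four acoustic cartilage parameters.

Given per-line echo measurements over the m scan lines of a region of
interest, the cartilage is characterized by

* URI  = sqrt( (1/m) * sum_i (d_i - dbar)^2 )      [µm]
  ultrasound roughness index: the population standard deviation of the
  transducer-to-surface distances, a measure of surface roughness;
* RC1  = (1/m) * sum_i (A_i / A_ref) * 100%        [%]
  mean surface-echo amplitude relative to a perfect reflector;
* RC2  = (1/m) * sum_j (A_j / A_ref) * 100%        [%]
  the same for the cartilage-subchondral bone interface echo.  By
  definition RC2 carries no correction for transmission through the
  surface or for attenuation in the cartilage, so it understates the
  physical interface reflectivity;
* h    = (1/m) * sum_i c_cartilage * TOF_i / 2     [mm]
  mean cartilage thickness from the surface-to-interface time-of-flight
  and an assumed average sound speed in cartilage (default 1675 m/s).

m in each formula is the number of lines with a valid measurement of
that echo; lines where detection failed are excluded and the average is
renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cartiqus.rf_processing import EchoFeatures

DEFAULT_C_CARTILAGE = 1675.0  # m/s, average sound speed in cartilage


@dataclass
class AcousticParams:
    """Scalar acoustic parameters for one scanned site."""

    uri_um: float
    rc1_pct: float
    rc2_pct: float
    h_mm: float
    m_valid_surface: int
    m_valid_interface: int
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "URI_um": self.uri_um,
            "RC1_pct": self.rc1_pct,
            "RC2_pct": self.rc2_pct,
            "h_mm": self.h_mm,
            "m_valid_surface": self.m_valid_surface,
            "m_valid_interface": self.m_valid_interface,
        }


def _valid(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float).ravel()
    return values[np.isfinite(values)]


def compute_uri(d_um) -> float:
    """Ultrasound roughness index (µm): population SD of the d_i."""
    d = _valid(d_um)
    if d.size < 2:
        raise ValueError("URI needs at least 2 valid distances")
    return float(np.sqrt(np.mean((d - d.mean()) ** 2)))


def compute_rc1(amps, a_ref: float) -> float:
    """Surface reflection coefficient (%): mean A_i/A_ref * 100."""
    if not a_ref > 0:
        raise ValueError("reference amplitude must be positive")
    a = _valid(amps)
    if a.size == 0:
        raise ValueError("no valid surface amplitudes")
    return float(np.mean(a / a_ref) * 100.0)


def compute_rc2(amps, a_ref: float) -> float:
    """Interface reflection coefficient (%): mean A_j/A_ref * 100,
    uncorrected for transmission loss or cartilage attenuation."""
    return compute_rc1(amps, a_ref)


def compute_thickness(tof_s, c_cartilage: float = DEFAULT_C_CARTILAGE) -> float:
    """Mean cartilage thickness (mm) from surface-to-interface TOF."""
    if not c_cartilage > 0:
        raise ValueError("sound speed must be positive")
    tof = _valid(tof_s)
    if tof.size == 0:
        raise ValueError("no valid times-of-flight")
    if np.any(tof <= 0):
        raise ValueError("nonpositive time-of-flight among valid lines")
    return float(np.mean(c_cartilage * tof / 2.0) * 1e3)


def compute_acoustic_params(
    features: EchoFeatures, c_cartilage: float | None = None
) -> AcousticParams:
    """All four parameters from one scan's echo features.

    ``c_cartilage`` defaults to the value carried in the features'
    metadata if present, else 1675 m/s.
    """
    if c_cartilage is None:
        c_cartilage = float(features.metadata.get("c_cartilage", DEFAULT_C_CARTILAGE))
    surf = features.valid_surface
    intf = features.valid_interface
    uri = compute_uri(features.d_um[surf])
    rc1 = compute_rc1(features.amp_surface[surf], features.a_ref)
    rc2 = compute_rc2(features.amp_interface[intf], features.a_ref)
    h = compute_thickness(features.tof_s[intf], c_cartilage)
    return AcousticParams(
        uri_um=uri,
        rc1_pct=rc1,
        rc2_pct=rc2,
        h_mm=h,
        m_valid_surface=int(surf.sum()),
        m_valid_interface=int(intf.sum()),
        metadata={"c_cartilage": c_cartilage},
    )
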