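"""Tissue optical properties and light attenuation through phantom plates.

Brain-mimicking optical phantoms attenuate a collimated 630 nm source
roughly exponentially with plate thickness.  This module holds the
reference optical coefficients for the white- and gray-matter substitute
materials, fits a two-parameter log-linear attenuation model

    E(d) = E0_fit * exp(-mu_eff_fit * d)

to measured transmission data by ordinary least squares on ln(E), and
compares the fitted decay constant with the diffusion-approximation
prediction mu_eff = sqrt(3 * mu_a * (mu_a + mu_s')).

Units are fixed throughout: thickness in mm, irradiance in mW/cm2,
attenuation coefficients in 1/mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TISSUES = ("white", "gray")

#: Nominal source irradiance of the irradiation chamber, mW/cm2.
SOURCE_IRRADIANCE_MW_CM2 = 42.25

#: Relative tolerance for the mu_s' = mu_s * (1 - g) consistency check.
_MUS_CONSISTENCY_RTOL = 1e-9


class InsufficientDataError(ValueError):
    """Raised when a fit is requested with too few measurements."""


def reduced_scattering(mu_s: float, g: float) -> float:
    """Reduced scattering coefficient mu_s' = mu_s * (1 - g).

    Parameters
    ----------
    mu_s : float
        Scattering coefficient, 1/mm, >= 0.
    g : float
        Anisotropy factor (mean cosine of the single-scattering angle),
        in [0, 1).

    Returns
    -------
    float
        Reduced scattering coefficient, 1/mm.
    """
    if mu_s < 0:
        raise ValueError(f"mu_s must be non-negative, got {mu_s}")
    if not (0 <= g < 1):
        raise ValueError(f"anisotropy factor g must be in [0, 1), got {g}")
    return mu_s * (1.0 - g)


@dataclass(frozen=True)
class TissueOpticalProperties:
    """Absorption and reduced scattering of one tissue class at one wavelength.

    ``mu_s`` and ``g`` are optional; when both are given they must be
    consistent with ``mu_s_prime`` via mu_s' = mu_s * (1 - g).
    """

    tissue: str
    wavelength_nm: float
    mu_a: float  # 1/mm
    mu_s_prime: float  # 1/mm
    mu_s: float | None = None  # 1/mm
    g: float | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.mu_a <= 0:
            raise ValueError(f"mu_a must be positive, got {self.mu_a}")
        if self.mu_s_prime <= 0:
            raise ValueError(f"mu_s_prime must be positive, got {self.mu_s_prime}")
        if self.g is not None and not (0 <= self.g < 1):
            raise ValueError(f"anisotropy factor g must be in [0, 1), got {self.g}")
        if self.mu_s is not None and self.g is not None:
            expected = self.mu_s * (1.0 - self.g)
            if abs(self.mu_s_prime - expected) > _MUS_CONSISTENCY_RTOL * self.mu_s:
                raise ValueError(
                    f"inconsistent scattering: mu_s*(1-g)={expected} "
                    f"but mu_s_prime={self.mu_s_prime}"
                )


def diffusion_mu_eff(props: TissueOpticalProperties) -> float:
    """Effective attenuation coefficient under the diffusion approximation.

    mu_eff = sqrt(3 * mu_a * (mu_a + mu_s')), the asymptotic exponential
    decay constant of diffuse fluence in a turbid medium, 1/mm.
    """
    return math.sqrt(3.0 * props.mu_a * (props.mu_a + props.mu_s_prime))


@dataclass(frozen=True)
class TransmissionMeasurement:
    """Irradiance measured behind a single phantom plate."""

    tissue: str
    thickness_mm: float
    irradiance: float  # mW/cm2

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.thickness_mm <= 0:
            raise ValueError(f"thickness must be positive, got {self.thickness_mm}")
        if self.irradiance < 0:
            raise ValueError(f"irradiance must be non-negative, got {self.irradiance}")


@dataclass(frozen=True)
class TransmissionTable:
    """Transmission measurements for one tissue, with the source irradiance.

    Thicknesses must be unique and sorted ascending; duplicates are
    rejected rather than averaged.
    """

    measurements: tuple[TransmissionMeasurement, ...]
    source_irradiance: float = SOURCE_IRRADIANCE_MW_CM2
    wavelength_nm: float = 630.0

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValueError("transmission table must contain measurements")
        tissues = {m.tissue for m in self.measurements}
        if len(tissues) != 1:
            raise ValueError(f"table must hold a single tissue, got {sorted(tissues)}")
        d = [m.thickness_mm for m in self.measurements]
        if len(set(d)) != len(d):
            raise ValueError("duplicate thicknesses are not allowed")
        if d != sorted(d):
            raise ValueError("measurements must be sorted by ascending thickness")
        for m in self.measurements:
            if m.irradiance >= self.source_irradiance:
                raise ValueError(
                    f"measured irradiance {m.irradiance} at {m.thickness_mm} mm "
                    f"is not below the source irradiance {self.source_irradiance}"
                )

    @property
    def tissue(self) -> str:
        return self.measurements[0].tissue

    @property
    def thicknesses(self) -> np.ndarray:
        return np.array([m.thickness_mm for m in self.measurements])

    @property
    def irradiances(self) -> np.ndarray:
        return np.array([m.irradiance for m in self.measurements])

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        source_irradiance: float = SOURCE_IRRADIANCE_MW_CM2,
        wavelength_nm: float = 630.0,
    ) -> "TransmissionTable":
        frame = frame.sort_values("thickness_mm")
        ms = tuple(
            TransmissionMeasurement(
                tissue=row.tissue,
                thickness_mm=float(row.thickness_mm),
                irradiance=float(row.irradiance_mw_cm2),
            )
            for row in frame.itertuples()
        )
        return cls(measurements=ms, source_irradiance=source_irradiance,
                   wavelength_nm=wavelength_nm)


@dataclass(frozen=True)
class AttenuationModel:
    """Fitted log-linear attenuation E(d) = E0 * exp(-mu_eff * d).

    ``surface_irradiance_fit`` is the extrapolated irradiance at zero
    thickness; it sits well below the nominal source irradiance because
    it absorbs the near-surface coupling/interface loss visible in the
    measured data.
    """

    tissue: str
    surface_irradiance_fit: float  # mW/cm2
    mu_eff_fit: float  # 1/mm
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.surface_irradiance_fit <= 0:
            raise ValueError("surface_irradiance_fit must be positive")


def fit_attenuation(table: TransmissionTable) -> AttenuationModel:
    """Fit the exponential attenuation model to a transmission table.

    Ordinary least squares of ln(irradiance) on thickness:
    ``mu_eff_fit`` is minus the slope, ``surface_irradiance_fit`` the
    exponentiated intercept, ``r_squared`` the log-domain coefficient of
    determination.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 measurements.
    ValueError
        Any non-positive irradiance (log undefined).
    """
    if len(table.measurements) < 3:
        raise InsufficientDataError(
            f"need at least 3 measurements to fit, got {len(table.measurements)}"
        )
    E = table.irradiances
    if np.any(E <= 0):
        raise ValueError("all irradiances must be strictly positive to fit in log domain")
    d = table.thicknesses
    res = stats.linregress(d, np.log(E))
    e0 = float(np.exp(res.intercept))
    if e0 > table.source_irradiance:
        raise ValueError(
            f"fitted surface irradiance {e0:.3f} exceeds source "
            f"irradiance {table.source_irradiance}"
        )
    return AttenuationModel(
        tissue=table.tissue,
        surface_irradiance_fit=e0,
        mu_eff_fit=float(-res.slope),
        r_squared=float(res.rvalue**2),
        n_points=len(table.measurements),
    )


def predict_irradiance(model: AttenuationModel, thickness_mm: float) -> float:
    """Irradiance predicted at a given depth, mW/cm2.

    Strictly decreasing in thickness whenever ``mu_eff_fit > 0``.
    """
    if thickness_mm < 0:
        raise ValueError(f"thickness must be non-negative, got {thickness_mm}")
    return model.surface_irradiance_fit * math.exp(-model.mu_eff_fit * thickness_mm)


# ---------------------------------------------------------------------------
# Packaged reference data (phantom characterization at 630 nm)
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("pdtdepth.data").joinpath(name)


def reference_optical_properties() -> tuple[TissueOpticalProperties, ...]:
    """The four packaged coefficient records: {white, gray} x {405, 630} nm."""
    with resources.as_file(_data_path("optical_properties.csv")) as p:
        df = pd.read_csv(p)
    return tuple(
        TissueOpticalProperties(
            tissue=row.tissue,
            wavelength_nm=float(row.wavelength_nm),
            mu_a=float(row.mu_a_mm),
            mu_s_prime=float(row.mu_s_prime_mm),
        )
        for row in df.itertuples()
    )


def get_optical_properties(tissue: str, wavelength_nm: float) -> TissueOpticalProperties:
    """Look up one packaged coefficient record."""
    for props in reference_optical_properties():
        if props.tissue == tissue and props.wavelength_nm == wavelength_nm:
            return props
    raise KeyError(f"no packaged optical properties for {tissue!r} at {wavelength_nm} nm")


def load_transmission_csv(
    path, source_irradiance: float = SOURCE_IRRADIANCE_MW_CM2
) -> TransmissionTable:
    """Read a transmission CSV (``tissue,thickness_mm,irradiance_mw_cm2``)."""
    df = pd.read_csv(path)
    required = {"tissue", "thickness_mm", "irradiance_mw_cm2"}
    if not required.issubset(df.columns):
        raise ValueError(f"transmission CSV must have columns {sorted(required)}")
    return TransmissionTable.from_frame(df, source_irradiance=source_irradiance)


def reference_transmission_table(tissue: str) -> TransmissionTable:
    """The packaged 630 nm transmission table for ``white`` or ``gray``."""
    if tissue not in TISSUES:
        raise KeyError(f"tissue must be one of {TISSUES}, got {tissue!r}")
    name = {"white": "white_matter_630.csv", "gray": "gray_matter_630.csv"}[tissue]
    with resources.as_file(_data_path(name)) as p:
        return load_transmission_csv(p)
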