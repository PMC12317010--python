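"""Single-field CCS calibration for drift-tube IMS.

In a drift tube, an ion of collision cross section (CCS) Omega drifts a
length L under a weak uniform field E through buffer gas at number density
N.  The Mason-Schamp low-field relation gives its drift time

    t_d = 16 L N Omega sqrt(mu k_B T / (2 pi)) / (3 |z| e E),

with mu the ion-gas reduced mass.  Because t_d is exactly proportional to
gamma * Omega with gamma = sqrt(mu) / |z|, arrival times measured at a
single field strength calibrate linearly against calibrant ions of known
CCS:

    t_A = beta * gamma * Omega + t_fix,

where t_fix absorbs the fixed (mobility-independent) transport time through
the instrument.  Fitting (beta, t_fix) on a tune-mix calibrant set, the CCS
of any measured ion follows by inversion:  Omega = (t_A - t_fix) / (beta * gamma).

Units at the interface: ms, Th, A^2 (angstrom squared), torr, V/cm, cm, Da.
Internally SI with the conversion constants below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KB",
    "E_CHARGE",
    "DA_KG",
    "TORR_PA",
    "InstrumentGeometry",
    "BufferGas",
    "NITROGEN",
    "CalibrationError",
    "read_calibrant_table",
    "reduced_mass",
    "buffer_number_density",
    "mason_schamp_drift_time",
    "SingleFieldCalibration",
    "SingleFieldFit",
    "fit_single_field",
    "ccs_from_arrival",
]

KB = 1.380649e-23        # Boltzmann constant, J/K
E_CHARGE = 1.602176634e-19  # elementary charge, C
DA_KG = 1.66053906660e-27   # unified atomic mass unit, kg
TORR_PA = 133.322368        # Pa per torr
A2_M2 = 1e-20               # m^2 per A^2
CM_M = 1e-2                 # m per cm


class CalibrationError(ValueError):
    """Raised for invalid calibrant sets or non-physical measurements."""


@dataclass(frozen=True)
class InstrumentGeometry:
    """Drift-cell geometry and conditions.

    Defaults are a standard commercial drift-tube configuration: a 78.24 cm
    tube at ~3.95 torr of nitrogen and a weak 17 V/cm field.  Temperature
    defaults to 300 K and enters only the first-principles drift-time
    computation, not single-field inversion.
    """

    drift_length_cm: float = 78.24
    field_v_per_cm: float = 17.0
    pressure_torr: float = 3.95
    temperature_k: float = 300.0

    def __post_init__(self) -> None:
        for name in ("drift_length_cm", "field_v_per_cm", "pressure_torr", "temperature_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class BufferGas:
    name: str = "N2"
    molar_mass_da: float = 28.0134

    def __post_init__(self) -> None:
        if self.molar_mass_da <= 0:
            raise ValueError("buffer gas molar mass must be positive")


NITROGEN = BufferGas()


def reduced_mass(m_ion_da: float, gas: BufferGas = NITROGEN) -> float:
    """Two-body reduced mass mu = m_ion * m_gas / (m_ion + m_gas), in Da."""
    if m_ion_da <= 0:
        raise ValueError("ion mass must be positive")
    return m_ion_da * gas.molar_mass_da / (m_ion_da + gas.molar_mass_da)


def buffer_number_density(geom: InstrumentGeometry) -> float:
    """Buffer-gas number density N = P / (k_B T), in m^-3."""
    return geom.pressure_torr * TORR_PA / (KB * geom.temperature_k)


def mason_schamp_drift_time(
    ccs_a2: float,
    m_ion_da: float,
    z: int,
    geom: InstrumentGeometry | None = None,
    gas: BufferGas = NITROGEN,
) -> float:
    """First-principles drift time (ms) for an ion of given CCS.

    Low-field Mason-Schamp relation; serves both as the physics behind the
    synthetic-data generator and as an independent check on single-field
    inversion.
    """
    geom = geom or InstrumentGeometry()
    if ccs_a2 <= 0 or m_ion_da <= 0 or z == 0:
        raise ValueError("ccs, ion mass must be positive and z nonzero")
    mu_kg = reduced_mass(m_ion_da, gas) * DA_KG
    n = buffer_number_density(geom)
    length_m = geom.drift_length_cm * CM_M
    e_v_per_m = geom.field_v_per_cm / CM_M
    t_s = (
        16.0
        * length_m
        * n
        * (ccs_a2 * A2_M2)
        * np.sqrt(mu_kg * KB * geom.temperature_k / (2.0 * np.pi))
        / (3.0 * abs(z) * E_CHARGE * e_v_per_m)
    )
    return float(t_s * 1e3)


def read_calibrant_table(path) -> pd.DataFrame:
    """Read a calibrant CSV with columns calibrant_id, mz, z, ccs_ref."""
    table = pd.read_csv(path, comment="#")
    required = {"calibrant_id", "mz", "z", "ccs_ref"}
    missing = required - set(table.columns)
    if missing:
        raise CalibrationError(f"calibrant table missing columns: {sorted(missing)}")
    _validate_calibrant_table(table)
    return table


def _validate_calibrant_table(table: pd.DataFrame) -> None:
    if table["calibrant_id"].duplicated().any():
        dups = table.loc[table["calibrant_id"].duplicated(), "calibrant_id"].tolist()
        raise CalibrationError(f"duplicate calibrant ids: {dups}")
    if (table["mz"] <= 0).any() or (table["ccs_ref"] <= 0).any():
        raise CalibrationError("calibrant mz and ccs_ref must be positive")
    if (table["z"] == 0).any():
        raise CalibrationError("calibrant charge must be nonzero")


def _gamma(m_ion_da: np.ndarray | float, z: np.ndarray | int, gas: BufferGas) -> np.ndarray | float:
    return np.sqrt(reduced_mass_vec(m_ion_da, gas)) / np.abs(z)


def reduced_mass_vec(m_ion_da, gas: BufferGas = NITROGEN):
    m = np.asarray(m_ion_da, dtype=float)
    if np.any(m <= 0):
        raise ValueError("ion mass must be positive")
    out = m * gas.molar_mass_da / (m + gas.molar_mass_da)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SingleFieldFit:
    """Fitted single-field calibration: t_A = beta * gamma * Omega + t_fix.

    ``beta`` is in ms / (A^2 sqrt(Da)); ``t_fix`` in ms.  Standard errors are
    the usual OLS ones (NaN when only two calibrants leave no residual
    degrees of freedom).
    """

    beta: float
    t_fix: float
    beta_se: float
    t_fix_se: float
    residual_rms: float
    n_calibrants: int
    gas: BufferGas = field(default=NITROGEN)

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise CalibrationError(f"fitted slope beta must be positive, got {self.beta}")
        if self.n_calibrants < 2:
            raise CalibrationError("a single-field fit needs at least 2 calibrants")

    def ccs(self, t_arrival_ms: float, m_ion_da: float, z: int) -> float:
        """Invert an arrival time to a CCS in A^2."""
        return ccs_from_arrival(t_arrival_ms, m_ion_da, z, self, self.gas)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "t_fix": self.t_fix,
            "beta_se": self.beta_se,
            "t_fix_se": self.t_fix_se,
            "residual_rms": self.residual_rms,
            "n_calibrants": self.n_calibrants,
            "gas": {"name": self.gas.name, "molar_mass_da": self.gas.molar_mass_da},
        }

    def summary(self) -> str:
        lines = [
            "Single-field CCS calibration (t_A = beta * gamma * Omega + t_fix)",
            "-" * 64,
            f"{'n calibrants':<20}{self.n_calibrants:>12d}",
            f"{'beta [ms/(A^2 sqrt(Da))]':<28}{self.beta:>14.6g}  (se {self.beta_se:.3g})",
            f"{'t_fix [ms]':<28}{self.t_fix:>14.6g}  (se {self.t_fix_se:.3g})",
            f"{'residual RMS [ms]':<28}{self.residual_rms:>14.6g}",
            f"{'buffer gas':<28}{self.gas.name:>14}",
        ]
        return "\n".join(lines)


class SingleFieldCalibration:
    """Model object pairing measured calibrant arrival times with reference CCS.

    Parameters
    ----------
    arrivals
        Sequence of ``(calibrant_id, arrival_time_ms)`` pairs or a DataFrame
        with columns ``calibrant_id`` and ``arrival_time_ms``.
    calibrants
        Reference table (DataFrame) with columns calibrant_id, mz, z, ccs_ref.
    gas
        Buffer gas; nitrogen by default.
    tof_sqrt_mz_slope
        Optional mass-dependent transit pre-correction: if set, the quantity
        ``slope * sqrt(m/z)`` (ms) is subtracted from each arrival time
        before fitting.  Off (None) by default.
    """

    def __init__(
        self,
        arrivals,
        calibrants: pd.DataFrame,
        gas: BufferGas = NITROGEN,
        tof_sqrt_mz_slope: float | None = None,
    ) -> None:
        if not isinstance(arrivals, pd.DataFrame):
            arrivals = pd.DataFrame(arrivals, columns=["calibrant_id", "arrival_time_ms"])
        _validate_calibrant_table(calibrants)
        unmatched = sorted(
            set(arrivals["calibrant_id"]) - set(calibrants["calibrant_id"])
        )
        if unmatched:
            raise CalibrationError(f"arrival times for unknown calibrant ids: {unmatched}")
        self.data = arrivals.merge(calibrants, on="calibrant_id", how="inner")
        if len(self.data) < 2:
            raise CalibrationError("need at least 2 matched calibrants to fit")
        self.gas = gas
        self.tof_sqrt_mz_slope = tof_sqrt_mz_slope

    @classmethod
    def from_csv(cls, arrivals_path, calibrants_path, **kwargs) -> "SingleFieldCalibration":
        arrivals = pd.read_csv(arrivals_path, comment="#")
        if "arrival_time_ms" not in arrivals.columns:
            raise CalibrationError("arrivals file must have an arrival_time_ms column")
        return cls(arrivals[["calibrant_id", "arrival_time_ms"]],
                   read_calibrant_table(calibrants_path), **kwargs)

    def fit(self, weights: np.ndarray | None = None) -> SingleFieldFit:
        """Least-squares fit of arrival time against gamma * Omega_ref.

        Unweighted by default; pass per-calibrant ``weights`` for WLS.
        """
        d = self.data
        m_ion = d["mz"].to_numpy(float) * np.abs(d["z"].to_numpy(int))
        x = _gamma(m_ion, d["z"].to_numpy(int), self.gas) * d["ccs_ref"].to_numpy(float)
        y = d["arrival_time_ms"].to_numpy(float)
        if self.tof_sqrt_mz_slope is not None:
            y = y - self.tof_sqrt_mz_slope * np.sqrt(d["mz"].to_numpy(float))
        if np.ptp(x) <= 0:
            raise CalibrationError("rank-deficient design: calibrants have identical gamma*CCS")
        w = np.ones_like(y) if weights is None else np.asarray(weights, float)
        design = np.column_stack([x, np.ones_like(x)])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
        beta, t_fix = float(coef[0]), float(coef[1])
        resid = y - (beta * x + t_fix)
        n = len(y)
        rms = float(np.sqrt(np.mean(resid**2)))
        if n > 2:
            s2 = float(np.sum(w * resid**2) / (n - 2))
            xtx_inv = np.linalg.inv((design * w[:, None]).T @ design)
            beta_se = float(np.sqrt(s2 * xtx_inv[0, 0]))
            t_fix_se = float(np.sqrt(s2 * xtx_inv[1, 1]))
        else:
            beta_se = t_fix_se = float("nan")
        return SingleFieldFit(
            beta=beta, t_fix=t_fix, beta_se=beta_se, t_fix_se=t_fix_se,
            residual_rms=rms, n_calibrants=n, gas=self.gas,
        )


def fit_single_field(
    arrivals, calibrants: pd.DataFrame, gas: BufferGas = NITROGEN, **kwargs
) -> SingleFieldFit:
    """Functional wrapper: build a :class:`SingleFieldCalibration` and fit it."""
    return SingleFieldCalibration(arrivals, calibrants, gas=gas, **kwargs).fit()


def ccs_from_arrival(
    t_arrival_ms: float,
    m_ion_da: float,
    z: int,
    fit: SingleFieldFit,
    gas: BufferGas = NITROGEN,
) -> float:
    """Invert the single-field relation: Omega = (t_A - t_fix) / (beta * gamma)."""
    if t_arrival_ms <= fit.t_fix:
        raise CalibrationError(
            f"arrival time {t_arrival_ms} ms does not exceed the fixed offset "
            f"{fit.t_fix} ms: non-physical measurement"
        )
    gamma = _gamma(m_ion_da, z, gas)
    return float((t_arrival_ms - fit.t_fix) / (fit.beta * gamma))
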