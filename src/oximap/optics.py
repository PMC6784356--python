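"""Tissue optics: chromophore absorption, reduced scattering, and the
two-layer diffuse reflectance model.

The skin is modeled as a melanin-bearing epidermis of finite thickness
``d_e`` on top of a semi-infinite, blood-perfused dermis.  Per-layer
absorption is a linear mixture of melanosome, oxy- and deoxy-hemoglobin
absorption; reduced scattering follows a Rayleigh + Mie power law anchored
at 500 nm.  Diffuse reflectance is obtained from the one-dimensional
diffusion approximation with an exponentially attenuated collimated source
and a partial-current surface boundary condition, solved in closed form as
a small linear system per wavelength.

Length unit is cm throughout; the epidermis thickness crosses the module
boundary in µm and is converted here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import (
    ChromophoreRangeError,
    DegenerateAbsorptionError,
    ModelEvaluationError,
)

logger = logging.getLogger(__name__)

#: absorption of whole blood (150 g hemoglobin / L) from molar extinction:
#: mu_a [1/cm] = ln(10) * eps [1/cm/M] * (150 g/L) / (64500 g/mol)
WHOLE_BLOOD_FACTOR = np.log(10.0) * 150.0 / 64500.0

# Landmark molar extinction coefficients [1/cm/M] for oxy- and
# deoxy-hemoglobin.  SYNTHETIC approximation of the standard published
# compilation: values are anchored at the well-known landmarks (isosbestic
# points near 500/529/545/570/585 nm, HbO2 double peak at 540/576 nm, Hb
# single peak at 555 nm, the steep HbO2 cliff beyond 585 nm) and smoothly
# interpolated between them.  Adequate for model studies; not metrology.
_LANDMARK_NM = np.array([
    450, 460, 470, 480, 490, 500, 510, 520, 529, 535, 540, 545, 550, 555,
    560, 565, 570, 576, 580, 585, 590, 595, 600, 610, 620, 630, 640, 650,
], dtype=float)
_EPS_OXY = np.array([
    62816, 44480, 33209, 26629, 23684, 20932, 20035, 24202, 39500, 46000,
    53236, 50500, 43016, 37000, 32613, 35000, 45000, 54424, 50104, 33000,
    14000, 6500, 3200, 1506, 942, 610, 442, 368,
], dtype=float)
_EPS_DEOXY = np.array([
    103292, 72872, 55540, 44496, 23388, 20862, 25773, 31256, 39500, 44000,
    46592, 49000, 50000, 53412, 52428, 50000, 45000, 41500, 37020, 33500,
    26600, 20500, 14677, 9443, 7553, 5149, 4345, 3750,
], dtype=float)


def melanosome_absorption(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Absorption coefficient of the melanosome interior [1/cm].

    Standard power law mu_a = 1.70e12 * lambda^-3.48 (lambda in nm),
    roughly 690 1/cm at 500 nm.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    return 1.70e12 * lam ** -3.48


@dataclass
class ChromophoreTable:
    """Tabulated absorption of the three skin chromophores.

    mu_oxy / mu_deoxy are for whole blood at B = 1 (150 g hemoglobin/L);
    mu_mel is the melanosome-interior absorption.  All in 1/cm on a strictly
    increasing nm grid.  Lookups interpolate linearly and refuse to
    extrapolate.
    """

    wavelengths_nm: np.ndarray
    mu_oxy: np.ndarray
    mu_deoxy: np.ndarray
    mu_mel: np.ndarray

    def __post_init__(self):
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.mu_oxy = np.asarray(self.mu_oxy, dtype=float)
        self.mu_deoxy = np.asarray(self.mu_deoxy, dtype=float)
        self.mu_mel = np.asarray(self.mu_mel, dtype=float)

    def validate(self) -> None:
        wl = self.wavelengths_nm
        if wl.ndim != 1 or len(wl) < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        for name in ("mu_oxy", "mu_deoxy", "mu_mel"):
            arr = getattr(self, name)
            if arr.shape != wl.shape or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite and match the grid")
        sel = (wl >= 500) & (wl <= 630)
        if not (np.all(self.mu_oxy[sel] > 0) and np.all(self.mu_deoxy[sel] > 0)
                and np.all(self.mu_mel[sel] > 0)):
            raise ValueError("chromophore absorption must be > 0 on 500-630 nm")
        # oxy and deoxy spectra must cross somewhere in the isosbestic region
        iso = (wl >= 560) & (wl <= 590)
        diff = self.mu_oxy[iso] - self.mu_deoxy[iso]
        if not (np.any(diff <= 0) and np.any(diff >= 0)):
            raise ValueError("no oxy/deoxy crossing found in 560-590 nm")

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def _interp(self, values: np.ndarray, lam) -> np.ndarray:
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        lo, hi = self.support
        if np.any(lam < lo) or np.any(lam > hi):
            raise ChromophoreRangeError(
                f"wavelength outside tabulated support [{lo}, {hi}] nm"
            )
        return np.interp(lam, self.wavelengths_nm, values)

    def oxy(self, lam) -> np.ndarray:
        return self._interp(self.mu_oxy, lam)

    def deoxy(self, lam) -> np.ndarray:
        return self._interp(self.mu_deoxy, lam)

    def mel(self, lam) -> np.ndarray:
        return self._interp(self.mu_mel, lam)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "wavelength_nm": self.wavelengths_nm,
            "mu_oxy": self.mu_oxy,
            "mu_deoxy": self.mu_deoxy,
            "mu_mel": self.mu_mel,
        }).to_csv(path, index=False)


def synthetic_chromophore_table(wl_min: float = 450.0, wl_max: float = 650.0,
                                step: float = 1.0) -> ChromophoreTable:
    """Build the bundled synthetic chromophore table.

    Monotone-cubic interpolation through landmark hemoglobin extinction
    values (see module notes) scaled to whole blood at 150 g/L, plus the
    melanosome power law, on a regular nm grid.
    """
    wl = np.arange(wl_min, wl_max + step / 2, step)
    oxy = PchipInterpolator(_LANDMARK_NM, _EPS_OXY)(wl) * WHOLE_BLOOD_FACTOR
    deoxy = PchipInterpolator(_LANDMARK_NM, _EPS_DEOXY)(wl) * WHOLE_BLOOD_FACTOR
    table = ChromophoreTable(wl, oxy, deoxy, melanosome_absorption(wl))
    table.validate()
    return table


def read_chromophore_table(path) -> ChromophoreTable:
    """Read a delimited chromophore table (wavelength_nm, mu_oxy, mu_deoxy, mu_mel)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = ["wavelength_nm", "mu_oxy", "mu_deoxy", "mu_mel"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"chromophore table missing columns: {missing}")
    table = ChromophoreTable(
        df["wavelength_nm"].to_numpy(), df["mu_oxy"].to_numpy(),
        df["mu_deoxy"].to_numpy(), df["mu_mel"].to_numpy(),
    )
    table.validate()
    return table


def default_chromophore_table() -> ChromophoreTable:
    """The table the pipeline uses when no user table is supplied."""
    return synthetic_chromophore_table()


# ---------------------------------------------------------------------------
# Skin parameter vector
# ---------------------------------------------------------------------------

#: clamp applied to the melanosome fraction (a volume fraction cannot
#: meaningfully exceed ~0.5 and must stay positive for a finite epidermal
#: penetration depth)
M_BOUNDS = (1e-3, 0.5)
B_BOUNDS = (1e-8, 1e-2)
DE_BOUNDS_UM = (60.0, 120.0)


@dataclass
class SkinParams:
    """Two-layer skin parameter vector.

    B       blood volume fraction in the dermis (whole blood, 150 g Hb/L)
    SO2     hemoglobin oxygen saturation, fraction in [0, 1]
    M       melanosome volume fraction in the epidermis
    d_e_um  epidermis thickness in µm
    mus500  reduced scattering at 500 nm [1/cm], both layers
    f_ray   Rayleigh fraction of scattering at 500 nm
    b_mie   Mie scattering power (< 1)
    A_bnd   boundary parameter of the diffusion model
    """

    B: float
    SO2: float
    M: float
    d_e_um: float = 90.0
    mus500: float = 48.0
    f_ray: float = 0.4
    b_mie: float = 0.7
    A_bnd: float = 0.2

    def validate(self, atol: float = 1e-9) -> None:
        if not (-atol <= self.SO2 <= 1 + atol):
            raise ValueError(f"SO2 out of [0, 1]: {self.SO2}")
        if not (B_BOUNDS[0] * (1 - 1e-6) <= self.B <= B_BOUNDS[1] * (1 + 1e-6)):
            raise ValueError(f"B out of {B_BOUNDS}: {self.B}")
        if not (DE_BOUNDS_UM[0] - atol <= self.d_e_um <= DE_BOUNDS_UM[1] + atol):
            raise ValueError(f"d_e out of {DE_BOUNDS_UM} um: {self.d_e_um}")
        for name in ("mus500", "A_bnd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.f_ray <= 1):
            raise ValueError(f"f_ray out of [0, 1]: {self.f_ray}")
        if not (self.b_mie < 1):
            raise ValueError(f"b_mie must be < 1: {self.b_mie}")

    def clamped(self) -> "SkinParams":
        """Return a copy with M clamped into its physical range, logging if so."""
        m = float(np.clip(self.M, *M_BOUNDS))
        if m != self.M:
            logger.warning("melanosome fraction M=%g clamped to %g", self.M, m)
            return replace(self, M=m)
        return self


# ---------------------------------------------------------------------------
# Layer optics
# ---------------------------------------------------------------------------

def absorption_coefficient(lam, layer_kind: str, params: SkinParams,
                           table: ChromophoreTable) -> np.ndarray:
    """Absorption coefficient mu_a(lambda) [1/cm] of one skin layer.

    mu_a = M*mu_mel + B*SO2*mu_oxy + B*(1-SO2)*mu_deoxy, with the layer
    structure imposing B = 0 in the epidermis and M = 0 in the dermis;
    ``layer_kind="generic"`` keeps all terms.
    """
    if layer_kind not in ("epidermis", "dermis", "generic"):
        raise ValueError(f"unknown layer kind: {layer_kind!r}")
    B = 0.0 if layer_kind == "epidermis" else params.B
    M = 0.0 if layer_kind == "dermis" else params.M
    blood = B * (params.SO2 * table.oxy(lam)
                 + (1.0 - params.SO2) * table.deoxy(lam))
    return M * table.mel(lam) + blood


def reduced_scattering(lam, mus500: float, f_ray: float, b_mie: float) -> np.ndarray:
    """Reduced scattering [1/cm]: Rayleigh + Mie power laws anchored at 500 nm."""
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    x = lam / 500.0
    return mus500 * (f_ray * x ** -4.0 + (1.0 - f_ray) * x ** -b_mie)


def diffusion_auxiliaries(mu_a, mus_prime):
    """Diffusion constants per unit length for one layer.

    Returns (sigma, delta) in cm where sigma = 1/(3*(mus' + mu_a)) is the
    diffusion constant (one third of the transport mean free path) and
    delta = 1/sqrt(3*mu_a*(mus' + mu_a)) is the diffusion penetration depth.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mus_prime = np.asarray(mus_prime, dtype=float)
    if np.any(mu_a < 0) or np.any(mus_prime <= 0):
        raise ValueError("require mu_a >= 0 and mus_prime > 0")
    if np.any(mu_a == 0):
        raise DegenerateAbsorptionError(
            "mu_a = 0: diffusion penetration depth is undefined"
        )
    mutr = mus_prime + mu_a
    sigma = 1.0 / (3.0 * mutr)
    delta = 1.0 / np.sqrt(3.0 * mu_a * mutr)
    return sigma, delta


def _particular_denominator(mu_a, mutr, floor_rel: float = 1e-8):
    """1/delta^2 - 1/ell^2 = mutr*(3*mu_a - mutr), kept away from its
    removable zero at mus' = 2*mu_a by a relative floor."""
    x = 3.0 * mu_a - mutr
    lim = floor_rel * mutr
    small = np.abs(x) < lim
    if np.any(small):
        sign = np.where(x >= 0, 1.0, -1.0)
        x = np.where(small, sign * lim, x)
    return mutr * x


def forward_reflectance(params: SkinParams, bands_nm, table: ChromophoreTable,
                        ) -> np.ndarray:
    """Diffuse reflectance of the two-layer skin model at the given bands.

    One-dimensional diffusion approximation: the collimated beam (unit
    irradiance) decays with the transport coefficient 1/(3*sigma) and feeds
    an isotropic source mus' * exp(-z/(3*sigma)); the diffuse fluence phi
    obeys  sigma * phi'' = mu_a * phi - source  in each layer, with

    * surface boundary condition  A_bnd * phi(0) = sigma_e * phi'(0)
      (partial-current condition; A_bnd = (1-R_eff)/(2*(1+R_eff))),
    * continuity of phi and of the diffuse flux at the layer interface,
    * a bounded solution in the semi-infinite dermis.

    The escaping diffuse flux then equals A_bnd * phi(0), which is the
    returned reflectance.  The three remaining solution coefficients are
    obtained from a well-conditioned 3x3 linear solve per wavelength.
    """
    params = params.clamped()
    params.validate()
    bands = np.atleast_1d(np.asarray(bands_nm, dtype=float))
    A = params.A_bnd

    mus = reduced_scattering(bands, params.mus500, params.f_ray, params.b_mie)
    mua_e = absorption_coefficient(bands, "epidermis", params, table)
    mua_d = absorption_coefficient(bands, "dermis", params, table)
    mua_d = np.maximum(mua_d, 1e-12)  # keep delta finite at B -> 0

    sig_e, del_e = diffusion_auxiliaries(mua_e, mus)
    sig_d, del_d = diffusion_auxiliaries(mua_d, mus)
    mutr_e = mua_e + mus
    mutr_d = mua_d + mus
    ell_e = 1.0 / mutr_e
    ell_d = 1.0 / mutr_d
    d_cm = params.d_e_um * 1e-4

    # particular solutions phi_p = C * exp(-z/ell) in each layer
    Ce = mus / (sig_e * _particular_denominator(mua_e, mutr_e))
    F = np.exp(-d_cm / ell_e)  # collimated attenuation through the epidermis
    Cd = mus * F / (sig_d * _particular_denominator(mua_d, mutr_d))
    Em = np.exp(-d_cm / del_e)

    n = len(bands)
    mat = np.zeros((n, 3, 3))
    rhs = np.zeros((n, 3))
    # unknowns: alpha (decaying epidermis mode), beta~ (growing mode scaled
    # by exp(-d/delta_e) for conditioning), gamma (dermis mode)
    mat[:, 0, 0] = -(sig_e / del_e) - A
    mat[:, 0, 1] = (sig_e / del_e - A) * Em
    rhs[:, 0] = Ce * (sig_e / ell_e + A)
    mat[:, 1, 0] = Em
    mat[:, 1, 1] = 1.0
    mat[:, 1, 2] = -1.0
    rhs[:, 1] = Cd - Ce * F
    mat[:, 2, 0] = -(sig_e / del_e) * Em
    mat[:, 2, 1] = sig_e / del_e
    mat[:, 2, 2] = sig_d / del_d
    rhs[:, 2] = sig_e * Ce * F / ell_e - sig_d * Cd / ell_d

    try:
        sol = np.linalg.solve(mat, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise ModelEvaluationError(
            f"singular two-layer system at bands {bands} with params {params}"
        ) from exc
    R = A * (sol[:, 0] + sol[:, 1] * Em + Ce)
    if not np.all(np.isfinite(R)):
        bad = bands[~np.isfinite(R)]
        raise ModelEvaluationError(
            f"non-finite reflectance at {bad} nm with params {params}"
        )
    return R
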