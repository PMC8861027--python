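"""Biophysical inversions: canopy conductance, ci, Vcmax, iWUE.

The canopy is treated as a single big leaf. Surface conductance Gc is obtained
by inverting the Penman-Monteith evaporation equation

    lambda*E = [Delta*(Rn - G) + rho*cp*VPD/ra] / [Delta + gamma*(1 + ra*Gc... )]

written with the canopy resistance rc = 1/Gc, so that

    Gc = (num/lambda*E - Delta - gamma) ** -1 ... (solved in closed form below).

Aerodynamic resistance follows the log-profile form with roughness length
z0 = 0.1 h and displacement height zd = 0.67 h; canopy height h itself is
estimated from the wind-speed / friction-velocity ratio under near-neutral
turbulence. Vcmax follows the Rubisco-limited biochemical model with
Michaelis-Menten and compensation-point kinetics scaled by Arrhenius
activation energies (Bernacchi values, pinned in :class:`BiophysConstants`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

R_GAS = 8.314  # J mol-1 K-1
T_REF_K = 298.15  # 25 degC


@dataclass(frozen=True)
class BiophysConstants:
    """Physical and kinetic constants used by the inversions.

    Kinetic 25 degC values and activation energies (J mol-1) are the Bernacchi
    in-vivo set; they are centralized here so a unit audit touches one place.
    """

    k_vk: float = 0.4            # von Karman constant
    cp: float = 1005.0           # J kg-1 K-1, dry air
    r_gas: float = R_GAS
    vpd0: float = 1.0            # kPa, VPD-decay onset of the light-response plateau
    o2: float = 210.0            # mmol mol-1
    kc25: float = 404.9          # umol mol-1
    ko25: float = 278.4          # mmol mol-1
    gammastar25: float = 42.75   # umol mol-1
    ha_kc: float = 79430.0
    ha_ko: float = 36380.0
    ha_gammastar: float = 37830.0
    ha_vcmax: float = 65330.0
    pressure: float = 101.325    # kPa, default when no pressure column exists
    ca: float = 400.0            # umol mol-1 ambient CO2


CONST = BiophysConstants()


# ----------------------------------------------------------------- moist air

def esat(ta):
    """Saturation vapor pressure (kPa) at air temperature ``ta`` (degC)."""
    ta = np.asarray(ta, dtype=float)
    return 0.6108 * np.exp(17.27 * ta / (ta + 237.3))


def svp_slope(ta):
    """Slope of the saturation vapor pressure curve (kPa K-1)."""
    ta = np.asarray(ta, dtype=float)
    return 4098.0 * esat(ta) / (ta + 237.3) ** 2


def latent_heat(ta):
    """Latent heat of vaporization (J kg-1), weakly temperature dependent."""
    return (2.501 - 0.002361 * np.asarray(ta, dtype=float)) * 1e6


def psychrometric_constant(ta, pressure=CONST.pressure):
    """Psychrometric constant gamma (kPa K-1) from pressure and temperature."""
    return CONST.cp * pressure / (0.622 * latent_heat(ta))


def air_density(ta, pressure=CONST.pressure):
    """Dry-air density (kg m-3) from the ideal gas law."""
    return pressure * 1000.0 / (287.04 * (np.asarray(ta, dtype=float) + 273.15))


def molar_density(ta, pressure=CONST.pressure):
    """Molar density of air (mol m-3): P/(R T)."""
    return pressure * 1000.0 / (R_GAS * (np.asarray(ta, dtype=float) + 273.15))


def gc_ms_to_mol(gc_ms, ta, pressure=CONST.pressure):
    """Convert conductance from m s-1 to mol m-2 s-1 via molar density."""
    return np.asarray(gc_ms, dtype=float) * molar_density(ta, pressure)


def resistance_to_molar(r_sm, ta, pressure=CONST.pressure):
    """Convert a resistance from s m-1 to molar units (m2 s mol-1)."""
    return np.asarray(r_sm, dtype=float) / molar_density(ta, pressure)


# ------------------------------------------------------- turbulent transfer

def aerodynamic_resistance(ws, zm, h_canopy):
    """Aerodynamic resistance ra (s m-1) from the neutral log profile.

    ra = ln((zm - 0.67 h)/(0.1 h))^2 / (ws k^2), with z0 = 0.1 h and
    zd = 0.67 h. Scalars raise :class:`GeometryError` on unphysical input;
    array entries degrade to NaN.
    """
    ws_a = np.asarray(ws, dtype=float)
    h_a = np.asarray(h_canopy, dtype=float)
    zm_a = np.asarray(zm, dtype=float)
    scalar = ws_a.ndim == 0 and h_a.ndim == 0 and zm_a.ndim == 0
    zd = 0.67 * h_a
    z0 = 0.1 * h_a
    bad = (ws_a <= 0) | (zm_a <= zd + z0) | (h_a <= 0)
    if scalar and bad:
        raise GeometryError(
            f"aerodynamic_resistance: need ws>0 and zm > 0.77*h (ws={ws}, zm={zm}, h={h_canopy})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ra = np.log((zm_a - zd) / z0) ** 2 / (ws_a * CONST.k_vk**2)
        ra = np.where(bad, np.nan, ra)
    return float(ra) if scalar else ra


def canopy_height(ws, ustar, zm):
    """Canopy height (m) from wind speed and friction velocity.

    h = zm / (0.6 + 0.1 * exp(k * ws/ustar)); valid under near-neutral
    turbulence. Exponents above 50 are overflow-guarded to NaN.
    """
    ws_a = np.asarray(ws, dtype=float)
    us_a = np.asarray(ustar, dtype=float)
    scalar = ws_a.ndim == 0 and us_a.ndim == 0
    if scalar and us_a <= 0:
        raise GeometryError("canopy_height: ustar must be > 0")
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        expo = CONST.k_vk * ws_a / us_a
        h = np.asarray(zm, dtype=float) / (0.6 + 0.1 * np.exp(expo))
        h = np.where((us_a <= 0) | (expo > 50), np.nan, h)
    return float(h) if scalar else h


def site_canopy_height(series, ustar_min=0.2, rg_min=50.0):
    """Median per-timestep canopy height over near-neutral records.

    Near-neutral is approximated by well-developed turbulence (ustar above
    ``ustar_min``) during insolated hours (rg above ``rg_min``), when the
    surface layer is closest to neutral stratification on average.
    """
    d = series.data
    ok = (d["ustar"] > ustar_min) & (d["rg"] > rg_min) & d["ws"].notna()
    h = canopy_height(d.loc[ok, "ws"].to_numpy(), d.loc[ok, "ustar"].to_numpy(), series.zm)
    return float(np.nanmedian(h))


# -------------------------------------------------------- Penman-Monteith

def penman_monteith_forward(gc_ms, ra, avail_energy, ta, vpd, pressure=CONST.pressure):
    """Forward big-leaf Penman-Monteith latent heat flux (W m-2).

    lambda*E = [Delta*(Rn-G) + rho*cp*VPD/ra] / [Delta + gamma*(1 + rc/ra)]
    with the canopy resistance rc = 1/Gc, so evaporation rises monotonically
    with conductance and saturates at the Penman rate as Gc -> infinity.
    """
    gc = np.asarray(gc_ms, dtype=float)
    ra_a = np.asarray(ra, dtype=float)
    delta = svp_slope(ta)
    gamma = psychrometric_constant(ta, pressure)
    rho = air_density(ta, pressure)
    num = delta * np.asarray(avail_energy, dtype=float) + rho * CONST.cp * np.asarray(vpd, dtype=float) / ra_a
    with np.errstate(divide="ignore", invalid="ignore"):
        den = delta + gamma * (1.0 + 1.0 / (gc * ra_a))
    return num / den


def invert_penman_monteith(le, rn, g_soil, ta, vpd, ra, pressure=CONST.pressure):
    """Surface conductance Gc (m s-1) that reproduces the observed le.

    Returns NaN where the inversion is degenerate (le <= 0, or an implied
    conductance that is negative or infinite -- e.g. le at the Penman limit
    with vanishing vapor-pressure deficit).
    """
    le_a = np.asarray(le, dtype=float)
    delta = svp_slope(ta)
    gamma = psychrometric_constant(ta, pressure)
    rho = air_density(ta, pressure)
    ra_a = np.asarray(ra, dtype=float)
    avail = np.asarray(rn, dtype=float) - np.asarray(g_soil, dtype=float)
    num = delta * avail + rho * CONST.cp * np.asarray(vpd, dtype=float) / ra_a
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = num / le_a - delta - gamma
        gc = gamma / (ra_a * resid)
        # resid at or below rounding noise: implied conductance infinite
        # (le at/above the Penman limit) or negative
        tiny = 1e-10 * (delta + gamma)
        gc = np.where((le_a <= 0) | (resid <= tiny) | (ra_a <= 0), np.nan, gc)
    if np.ndim(le) == 0:
        return float(gc)
    return gc


# ------------------------------------------------------------- Farquhar

def arrhenius(k25, ha, ta):
    """Arrhenius temperature scaling of a rate/constant from its 25 degC value."""
    tk = np.asarray(ta, dtype=float) + 273.15
    return k25 * np.exp(ha * (tk - T_REF_K) / (T_REF_K * R_GAS * tk))


def gammastar(ta, c: BiophysConstants = CONST):
    """CO2 compensation point without mitochondrial respiration (umol mol-1)."""
    return arrhenius(c.gammastar25, c.ha_gammastar, ta)


def michaelis_k(ta, c: BiophysConstants = CONST):
    """Effective Michaelis-Menten coefficient K = Kc (1 + O2/Ko), umol mol-1."""
    kc = arrhenius(c.kc25, c.ha_kc, ta)
    ko = arrhenius(c.ko25, c.ha_ko, ta)
    return kc * (1.0 + c.o2 / ko)


def leaf_internal_co2(gpp, gc_mol, ra_mol=0.0, ca=CONST.ca):
    """Leaf-internal CO2 mole fraction (umol mol-1) via Fick's law.

    ci = ca - GPP * (1.6/Gc + ra_mol); the 1.6 factor converts the water
    vapor conductance to a CO2 conductance. gc_mol <= 0 yields NaN.
    """
    gc = np.asarray(gc_mol, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = ca - np.asarray(gpp, dtype=float) * (1.6 / gc + np.asarray(ra_mol, dtype=float))
        ci = np.where(gc <= 0, np.nan, ci)
    if np.ndim(gpp) == 0 and np.ndim(gc_mol) == 0:
        return float(ci)
    return ci


def forward_amax(vcmax, ci, ta, c: BiophysConstants = CONST):
    """Rubisco-limited assimilation capacity from Vcmax (the inverse of
    :func:`invert_vcmax`, used as the closure oracle)."""
    return np.asarray(vcmax, dtype=float) * (np.asarray(ci, dtype=float) - gammastar(ta, c)) / (
        np.asarray(ci, dtype=float) + michaelis_k(ta, c)
    )


def invert_vcmax(amax, ci, ta, c: BiophysConstants = CONST):
    """Vcmax and its 25 degC standardization from Amax, ci and temperature.

    vcmax = amax * (ci + K)/(ci - Gamma*); NaN where ci <= Gamma* (negative
    carboxylation regime). vcmax25 divides out the Arrhenius factor.
    """
    ci_a = np.asarray(ci, dtype=float)
    gs = gammastar(ta, c)
    k = michaelis_k(ta, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        vcmax = np.asarray(amax, dtype=float) * (ci_a + k) / (ci_a - gs)
        vcmax = np.where(ci_a <= gs, np.nan, vcmax)
    tk = np.asarray(ta, dtype=float) + 273.15
    scal = np.exp(c.ha_vcmax * (tk - T_REF_K) / (T_REF_K * R_GAS * tk))
    vcmax25 = vcmax / scal
    if np.ndim(amax) == 0 and np.ndim(ci) == 0 and np.ndim(ta) == 0:
        return float(vcmax), float(vcmax25)
    return vcmax, vcmax25


def iwue(gpp, gc_mol):
    """Intrinsic water-use efficiency GPP/Gc (umol CO2 per mol H2O)."""
    gc = np.asarray(gc_mol, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(gc > 0, np.asarray(gpp, dtype=float) / gc, np.nan)
    if np.ndim(gpp) == 0 and np.ndim(gc_mol) == 0:
        return float(out)
    return out
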