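"""Climate-to-parameter derivation and dimensional cell respiration.

Maps a grid cell's climatic and soil state (temperature, saturation
degree, texture class, altitude, DOC) to the parameters of the patch
respiration model, then upscales single-patch fluxes to heterotrophic
respiration per unit land area of the 0-10 cm topsoil layer:

1. atmospheric O2 partial pressure from altitude (barometric law);
2. dissolved O2 at equilibrium, C0, via Henry's law with van 't Hoff
   temperature dependence (C0 decreases with T);
3. O2 aqueous diffusivity Dm(T) by Stokes-Einstein scaling with the
   temperature-dependent viscosity of water (Dm increases with T);
4. grain size lambda_c and porosity from a texture lookup table;
5. maximum areal respiration rate Vm(T) = Vm_ref * Q10^((T-Tref)/10),
   zero below 0 degC (frozen water);
6. patch statistics (Nc, Sc) from the percolation closed form (d = 3);
7. the equivalent spherical patch radius r0 from the water volume per
   patch in the representative volume, the dimensionless (alpha, beta),
   and the solved patch oxygen flux u'(1);
8. HR = (Nc / L^2) * 4 pi r0 Dm C0 u'(1) * 12.011 gC/mol * 3.156e7 s/yr.

All constants live in data/constants.csv and are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .patch_dre import DREParams, ReactionEnvironment, nondimensionalize, solve_patch
from .patch_theory import PatchTheoryParams, predict_patches

_T0K = 273.15


def load_constants(path=None) -> dict:
    """Read the constants table (name, value, units, source) as a dict."""
    if path is None:
        with resources.files("porehr.data").joinpath("constants.csv").open() as f:
            df = pd.read_csv(f)
    else:
        df = pd.read_csv(path)
    return dict(zip(df["name"], df["value"].astype(float)))


def load_textures(path=None) -> pd.DataFrame:
    if path is None:
        with resources.files("porehr.data").joinpath("textures.csv").open() as f:
            return pd.read_csv(f).set_index("texture")
    return pd.read_csv(path).set_index("texture")


_CONSTANTS = load_constants()
_TEXTURES = load_textures()


def water_viscosity(t_celsius: float) -> float:
    """Dynamic viscosity of water [Pa s], Vogel correlation."""
    tk = t_celsius + _T0K
    return 2.414e-5 * 10.0 ** (247.8 / (tk - 140.0))


def o2_diffusivity(t_celsius: float, constants: dict | None = None) -> float:
    """O2 aqueous diffusivity [m^2/s], Stokes-Einstein T/mu scaling."""
    c = constants or _CONSTANTS
    tk = t_celsius + _T0K
    return c["d_o2_water_ref"] * (tk / 298.15) * (water_viscosity(25.0) / water_viscosity(t_celsius))


def o2_partial_pressure(altitude_m: float, t_celsius: float, constants: dict | None = None) -> float:
    """Atmospheric O2 partial pressure [Pa] at altitude (barometric law)."""
    c = constants or _CONSTANTS
    tk = t_celsius + _T0K
    p = c["p0_sea_level"] * np.exp(-c["barometric_scale"] * altitude_m / tk)
    return c["o2_mole_fraction"] * p


def dissolved_o2(altitude_m: float, t_celsius: float, constants: dict | None = None) -> float:
    """Henry-equilibrium dissolved O2 [mol m^-3]; decreases with T."""
    c = constants or _CONSTANTS
    tk = t_celsius + _T0K
    h_cp = c["henry_o2_cp_ref"] * np.exp(c["henry_o2_vant_hoff"] * (1.0 / tk - 1.0 / 298.15))
    return o2_partial_pressure(altitude_m, t_celsius, c) * h_cp


def vm_temperature(t_celsius: float, constants: dict | None = None) -> float:
    """Q10 temperature response of the maximum areal rate; 0 below 0 degC."""
    c = constants or _CONSTANTS
    if t_celsius <= 0.0:
        return 0.0
    return c["vm_ref"] * c["q10"] ** ((t_celsius - c["t_ref"]) / 10.0)


@dataclass
class CellEnvironment:
    """Derived physical state of one grid cell."""

    temperature: float  # [degC]
    saturation: float  # theta/theta_s in [0, 1]
    lambda_c: float  # [m]
    porosity: float
    altitude: float  # [m]
    doc: float  # Cs [mol m^-3]
    c0: float  # dissolved O2 [mol m^-3]
    dm: float  # O2 aqueous diffusivity [m^2/s]
    vm: float  # max areal rate [mol m^-2 s^-1]
    km_s: float
    km_o2: float
    ssa: float  # 3 phi / lambda_c [m^-1]
    depth: float  # topsoil depth [m]


@dataclass
class HRValue:
    """Heterotrophic respiration of one cell with its audit decomposition."""

    hr: float  # [gC m^-2 yr^-1] over the topsoil layer
    nc: float  # patches per REV
    nc_per_area: float  # [m^-2]
    per_patch_mol_s: float  # [mol s^-1]
    alpha: float
    beta: float
    r0: float  # [m]
    flux: float  # u'(1)
    sc: float


def derive_environment(
    temperature: float,
    saturation: float,
    texture: str = "loam",
    altitude: float = 0.0,
    doc: float | None = None,
    constants: dict | None = None,
    textures: pd.DataFrame | None = None,
) -> CellEnvironment:
    """Derive all patch-model parameters for one cell."""
    c = constants or _CONSTANTS
    tx = textures if textures is not None else _TEXTURES
    if not 0.0 <= saturation <= 1.0:
        raise ValueError("saturation must lie in [0, 1]")
    if texture not in tx.index:
        raise ValueError(
            f"unknown texture class {texture!r}; valid classes: {sorted(tx.index)}"
        )
    lam = float(tx.loc[texture, "lambda_c_m"])
    phi = float(tx.loc[texture, "porosity"])
    if doc is None:
        doc = c["doc_default"]
    return CellEnvironment(
        temperature=temperature,
        saturation=saturation,
        lambda_c=lam,
        porosity=phi,
        altitude=altitude,
        doc=float(doc),
        c0=float(dissolved_o2(altitude, temperature, c)),
        dm=float(o2_diffusivity(temperature, c)),
        vm=float(vm_temperature(temperature, c)),
        km_s=c["km_s"],
        km_o2=c["km_o2"],
        ssa=3.0 * phi / lam,
        depth=c["topsoil_depth"],
    )


def cell_respiration(
    env: CellEnvironment,
    theory: PatchTheoryParams | None = None,
    constants: dict | None = None,
    n_nodes: int = 200,
) -> HRValue:
    """Upscale the single-patch model to HR per unit land area.

    Returns 0 for zero saturation, frozen cells (Vm = 0) or zero DOC.
    """
    c = constants or _CONSTANTS
    if env.saturation <= 0.0 or env.vm <= 0.0 or env.doc <= 0.0:
        return HRValue(0.0, 0.0, 0.0, 0.0, np.nan, 0.0, 0.0, 0.0, 0.0)
    L = c["rev_length"]
    depth = env.depth
    if theory is None:
        theory = PatchTheoryParams(
            tau=c["tau_3d"], gamma=c["gamma"], L=L, lambda_c=env.lambda_c, d=3
        )
    pred = predict_patches(env.saturation, theory)
    v_rev = L * L * depth
    theta_s = env.porosity  # moisture capacity = porosity
    water_per_patch = pred.sc * theta_s * v_rev  # [m^3]
    r0 = (3.0 * water_per_patch / (4.0 * np.pi)) ** (1.0 / 3.0)
    renv = ReactionEnvironment(
        Dm=env.dm,
        Vm=env.vm,
        phi=env.porosity,
        lambda_c=env.lambda_c,
        Cs=env.doc,
        Km_s=env.km_s,
        Km_O2=env.km_o2,
        C0=env.c0,
    )
    params = nondimensionalize(renv, r0)
    sol = solve_patch(params, n_nodes=n_nodes)
    per_patch = 4.0 * np.pi * r0 * env.dm * env.c0 * sol.flux  # [mol/s]
    nc_per_area = pred.nc / (L * L)
    hr = nc_per_area * per_patch * c["carbon_molar_mass"] * c["seconds_per_year"]
    return HRValue(
        hr=float(hr),
        nc=pred.nc,
        nc_per_area=float(nc_per_area),
        per_patch_mol_s=float(per_patch),
        alpha=params.alpha,
        beta=params.beta,
        r0=float(r0),
        flux=sol.flux,
        sc=pred.sc,
    )


def hr_from_state(
    temperature: float,
    saturation: float,
    texture: str = "loam",
    altitude: float = 0.0,
    doc: float | None = None,
    constants: dict | None = None,
    n_nodes: int = 200,
) -> HRValue:
    """Convenience: derive_environment + cell_respiration in one call."""
    env = derive_environment(temperature, saturation, texture, altitude, doc, constants)
    return cell_respiration(env, constants=constants, n_nodes=n_nodes)
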