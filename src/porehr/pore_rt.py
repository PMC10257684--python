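"""Steady two-phase reactive transport on pore-scale phase rasters.

Dissolved O2, DOC and CO2 diffuse through the water and air phases of an
invaded medium (no advection). Each species is represented by a single
aqueous-equivalent potential that is continuous across air-water
interfaces: in air the species concentration is Henry-partitioned,
C_gas = H * C_aq, so diffusion in air acts on the potential with an
effective diffusivity D_air * H. Heterotrophic respiration is a
Michaelis-Menten surface sink on water pixels adjacent to solid grains:

    R_surf = Vm * Cs/(Cs + Km_s) * C_O2/(C_O2 + Km_O2),

with a fixed atmospheric O2 value on the top boundary, zero-gradient on
the other boundaries, and a Dirichlet DOC value on the grain perimeter
(organic-matter dissolution). Because the DOC Dirichlet sites coincide
with the reaction sites, the DOC Michaelis factor is a constant there
and only O2 requires Picard iteration.

The domain-total dimensionless respiration is the interface line
integral R_h = sum (R_surf / Vm) * dl over the solid-liquid perimeter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .percolation import AIR, SOLID, WATER, PhaseConfig, patch_stats

_HENRY_DIMLESS_O2 = 32.0  # gas/aqueous partition at 25 C
_HENRY_DIMLESS_CO2 = 1.2


@dataclass
class RTConfig:
    """Species transport and kinetic parameters (SI units).

    Diffusivities are per phase; Henry constants are dimensionless
    gas/aqueous concentration ratios. ``c0_o2`` is the aqueous-equivalent
    atmospheric O2 concentration imposed at the top boundary; ``c0_doc``
    the DOC value held at the grain perimeter.
    """

    d_o2_water: float = 2.1e-9
    d_o2_air: float = 1.8e-5
    d_doc_water: float = 7e-10
    d_doc_air: float = 0.0  # DOC is non-volatile
    d_co2_water: float = 1.9e-9
    d_co2_air: float = 1.5e-5
    henry_o2: float = _HENRY_DIMLESS_O2
    henry_co2: float = _HENRY_DIMLESS_CO2
    vm: float = 1e-6  # max areal respiration rate [mol m^-2 s^-1]
    km_s: float = 0.1  # DOC Michaelis constant [mol m^-3]
    km_o2: float = 0.03  # O2 Michaelis constant [mol m^-3]
    c0_o2: float = 0.276  # aqueous-equilibrium O2 [mol m^-3]
    c0_doc: float = 10.0  # grain-surface DOC [mol m^-3]

    def __post_init__(self) -> None:
        if self.d_o2_air <= self.d_o2_water:
            raise ValueError("O2 diffusivity in air must exceed that in water")
        for name in ("vm", "km_s", "km_o2", "c0_o2", "c0_doc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class RTFields:
    """Steady-state fields and interface reaction diagnostics."""

    o2: np.ndarray  # aqueous-equivalent O2 potential [mol m^-3]
    doc: np.ndarray
    co2: np.ndarray
    r_surf: np.ndarray  # per-pixel surface rate [mol m^-2 s^-1], 0 off-interface
    r_h: float  # interface integral of R_surf / Vm [m]
    interface_length: float  # total solid-liquid perimeter [m]
    o2_influx: float  # top-boundary O2 flux [mol s^-1 per m depth]
    o2_consumed: float  # total reactive consumption [mol s^-1 per m depth]
    co2_produced: float
    picard_iterations: int = 0
    picard_history: list = field(default_factory=list)
    disconnected_water: bool = False


def _reactive_sites(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Water pixels with >= 1 solid 4-neighbour, and the neighbour count."""
    solid = labels == SOLID
    water = labels == WATER
    count = np.zeros(labels.shape, dtype=int)
    count[1:, :] += solid[:-1, :]
    count[:-1, :] += solid[1:, :]
    count[:, 1:] += solid[:, :-1]
    count[:, :-1] += solid[:, 1:]
    sites = water & (count > 0)
    return sites, np.where(sites, count, 0)


class _DiffusionOperator:
    """Five-point finite-volume Laplacian with harmonic-mean face coefficients.

    Discretizes  -div(D grad c) + k c = b  per unit depth on the active
    cells (D > 0, not Dirichlet-pinned). Fluxes are D * dc per unit
    depth; cell sinks enter as k * h^2. The top boundary can expose a
    ghost Dirichlet value; Dirichlet-pinned interior cells (e.g. the DOC
    grain perimeter) are folded into the right-hand side. All other
    exterior faces are no-flux. The diffusion stencil is assembled once;
    only the sink diagonal changes between Picard iterations.
    """

    def __init__(
        self,
        diff: np.ndarray,
        h: float,
        dirichlet_mask: np.ndarray | None = None,
        dirichlet_value: float = 0.0,
        top_open: bool = False,
        top_value: float = 0.0,
    ):
        ny, nx = diff.shape
        self.shape = (ny, nx)
        self.h = h
        if dirichlet_mask is None:
            dirichlet_mask = np.zeros((ny, nx), dtype=bool)
        self.dirichlet_mask = dirichlet_mask
        self.dirichlet_value = dirichlet_value
        active = (diff > 0) & ~dirichlet_mask
        self.active = active
        idx = -np.ones((ny, nx), dtype=np.int64)
        idx[active] = np.arange(active.sum())
        self.idx = idx
        n = int(active.sum())
        self.n = n

        rows_list, cols_list, vals_list = [], [], []
        diag = np.zeros(n)
        rhs0 = np.zeros(n)

        def add_faces(sl_a, sl_b):
            da, db = diff[sl_a], diff[sl_b]
            both = (da > 0) & (db > 0)
            t = np.zeros_like(da)
            t[both] = 2.0 * da[both] * db[both] / (da[both] + db[both])
            ia, ib = idx[sl_a], idx[sl_b]
            act_a, act_b = active[sl_a], active[sl_b]
            dir_a, dir_b = dirichlet_mask[sl_a], dirichlet_mask[sl_b]
            # active-active couplings
            m = both & act_a & act_b
            rows_list.append(ia[m]); cols_list.append(ib[m]); vals_list.append(-t[m])
            rows_list.append(ib[m]); cols_list.append(ia[m]); vals_list.append(-t[m])
            np.add.at(diag, ia[m], t[m])
            np.add.at(diag, ib[m], t[m])
            # active-Dirichlet couplings -> rhs
            m = both & act_a & dir_b
            np.add.at(diag, ia[m], t[m])
            np.add.at(rhs0, ia[m], t[m] * dirichlet_value)
            m = both & dir_a & act_b
            np.add.at(diag, ib[m], t[m])
            np.add.at(rhs0, ib[m], t[m] * dirichlet_value)

        add_faces(np.s_[:-1, :], np.s_[1:, :])
        add_faces(np.s_[:, :-1], np.s_[:, 1:])

        if top_open:
            top = active[0, :] & (diff[0, :] > 0)
            t_top = 2.0 * diff[0, :][top]
            k_top = idx[0, :][top]
            np.add.at(diag, k_top, t_top)
            np.add.at(rhs0, k_top, t_top * top_value)

        rows = np.concatenate(rows_list) if rows_list else np.array([], dtype=int)
        cols = np.concatenate(cols_list) if cols_list else np.array([], dtype=int)
        vals = np.concatenate(vals_list) if vals_list else np.array([])
        self._offdiag = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
        self._diag = diag
        self.rhs0 = rhs0

    def solve(self, sink_coeff: np.ndarray | None = None, source: np.ndarray | None = None) -> np.ndarray:
        """Solve with volumetric sink k [1/s] and source [mol m^-3 s^-1] rasters."""
        diag = self._diag.copy()
        rhs = self.rhs0.copy()
        h2 = self.h * self.h
        if sink_coeff is not None:
            diag += sink_coeff[self.active] * h2
        if source is not None:
            rhs += source[self.active] * h2
        mat = self._offdiag + sparse.diags(np.maximum(diag, 1e-300))
        sol = spsolve(mat.tocsr(), rhs)
        out = np.zeros(self.shape)
        out[self.active] = sol
        out[self.dirichlet_mask] = self.dirichlet_value
        return out


def solve_rt(
    config: PhaseConfig,
    rt: RTConfig | None = None,
    picard_tol: float = 1e-8,
    max_picard: int = 200,
) -> RTFields:
    """Solve steady two-phase diffusion-reaction for O2, DOC and CO2.

    Returns the aqueous-equivalent concentration fields, the surface
    reaction map and the interface-integrated dimensionless respiration.
    """
    rt = rt or RTConfig()
    labels = config.labels
    h = config.medium.pixel_size
    ny, nx = labels.shape
    water = labels == WATER
    air = labels == AIR
    if not water.any():
        raise ValueError("phase configuration has no water")

    sites, n_solid = _reactive_sites(labels)
    doc_factor = rt.c0_doc / (rt.c0_doc + rt.km_s) if rt.c0_doc > 0 else 0.0

    # --- O2: Picard iteration on the Michaelis-Menten sink ------------
    diff_o2 = np.where(water, rt.d_o2_water, np.where(air, rt.d_o2_air * rt.henry_o2, 0.0))
    op_o2 = _DiffusionOperator(diff_o2, h, top_open=True, top_value=rt.c0_o2)

    o2 = np.where(labels != SOLID, rt.c0_o2, 0.0)
    it = 0
    history: list[float] = []
    if rt.vm > 0:
        for it in range(1, max_picard + 1):
            k_lin = np.where(
                sites,
                rt.vm * doc_factor / np.maximum(o2 + rt.km_o2, 1e-300) * n_solid / h,
                0.0,
            )  # linearized volumetric sink [1/s]
            o2_new = np.clip(op_o2.solve(sink_coeff=k_lin), 0.0, None)
            denom = max(float(np.abs(o2).max()), 1e-300)
            change = float(np.abs(o2_new - o2).max()) / denom
            history.append(change)
            o2 = o2_new
            if change < picard_tol:
                break
        else:
            raise RuntimeError(
                f"Picard iteration did not converge in {max_picard} steps; "
                f"history tail {history[-5:]}"
            )
    else:
        o2 = op_o2.solve()

    r_surf = np.where(
        sites, rt.vm * doc_factor * o2 / np.maximum(o2 + rt.km_o2, 1e-300), 0.0
    )
    r_h = float(np.sum(r_surf / rt.vm * n_solid * h)) if rt.vm > 0 else 0.0
    interface_length = float(n_solid.sum() * h)

    # O2 balance: top-boundary influx vs consumption (per unit depth)
    top_active = diff_o2[0, :] > 0
    influx = float(np.sum(2.0 * diff_o2[0, top_active] * (rt.c0_o2 - o2[0, top_active])))
    consumed = float(np.sum(r_surf * n_solid * h))

    # --- DOC: linear, Dirichlet at grain perimeter --------------------
    diff_doc = np.where(water, rt.d_doc_water, np.where(air, rt.d_doc_air, 0.0))
    if diff_doc.max() > 0:
        op_doc = _DiffusionOperator(
            diff_doc, h, dirichlet_mask=sites, dirichlet_value=rt.c0_doc
        )
        doc = op_doc.solve() if op_doc.n > 0 else np.where(sites, rt.c0_doc, 0.0)
    else:
        doc = np.where(sites, rt.c0_doc, 0.0)

    # --- CO2: produced 1:1 with O2 consumption, escapes the top -------
    diff_co2 = np.where(
        water, rt.d_co2_water, np.where(air, rt.d_co2_air * rt.henry_co2, 0.0)
    )
    src = np.where(sites, r_surf * n_solid / h, 0.0)  # volumetric source
    op_co2 = _DiffusionOperator(diff_co2, h, top_open=True, top_value=0.0)
    co2 = op_co2.solve(source=src)

    # water disconnected from any O2 source (all-air top and enclosing air)?
    disconnected = bool(water.any() and o2[water].max() < 1e-12 * rt.c0_o2)

    return RTFields(
        o2=o2,
        doc=doc,
        co2=co2,
        r_surf=r_surf,
        r_h=r_h,
        interface_length=interface_length,
        o2_influx=float(influx),
        o2_consumed=consumed,
        co2_produced=consumed,
        picard_iterations=it,
        picard_history=history,
        disconnected_water=disconnected,
    )


def scaling_experiment(
    lambda_c: float = 1e-3,
    saturations: tuple[float, ...] = (0.9, 0.7, 0.5, 0.35, 0.2),
    n_realizations: int = 5,
    seed: int = 0,
    rt: RTConfig | None = None,
    porosity: float = 0.5,
    width: float = 0.03,
    height: float = 0.0225,
    pixels_per_lambda_c: int = 20,
    n_bootstrap: int = 200,
) -> dict:
    """Fit the log-log slope of per-patch respiration vs patch size.

    For each realization, generates a medium, drains it to the requested
    saturations, solves the reactive-transport problem on each phase
    configuration, and collects (Nc, Sc, R_h). Returns the least-squares
    slope of log(R_h / Nc) against log(Sc) with a bootstrap CI.
    """
    from .media import generate_medium

    if len(saturations) < 4:
        raise ValueError("need >= 4 saturation levels")
    rt = rt or RTConfig()
    rows = []
    rng = np.random.default_rng(seed)
    for r in range(n_realizations):
        med = generate_medium(
            lambda_c, porosity, width, height, pixels_per_lambda_c,
            seed=int(rng.integers(2**31 - 1)),
        )
        from .percolation import invade

        configs = invade(med, sorted(saturations, reverse=True))
        seen_sats: set[float] = set()
        for cfg in configs:
            # unreachable targets duplicate the residual trapped state
            key = round(cfg.saturation, 6)
            if key in seen_sats:
                continue
            seen_sats.add(key)
            ps = patch_stats(cfg)
            if ps.n_patches == 0:
                continue
            fields = solve_rt(cfg, rt)
            rows.append(
                {
                    "realization": r,
                    "saturation": cfg.saturation,
                    "nc": ps.nc_emp,
                    "sc": ps.sc_emp,
                    "r_h": fields.r_h,
                }
            )
    return fit_scaling(rows, n_bootstrap=n_bootstrap, seed=seed)


def fit_scaling(rows: list[dict], n_bootstrap: int = 200, seed: int = 0) -> dict:
    """Least-squares slope of log(R_h/Nc) vs log(Sc) with bootstrap CI."""
    import pandas as pd

    df = pd.DataFrame(rows)
    df = df[(df["r_h"] > 0) & (df["sc"] > 0) & (df["nc"] > 0)]
    if len(df) < 4:
        raise ValueError("fewer than 4 valid (Nc, Sc, R_h) points")
    x = np.log(df["sc"].to_numpy())
    y = np.log(df["r_h"].to_numpy() / df["nc"].to_numpy())
    slope, intercept = np.polyfit(x, y, 1)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        pick = rng.integers(0, len(x), len(x))
        if np.ptp(x[pick]) < 1e-12:
            continue
        boots.append(np.polyfit(x[pick], y[pick], 1)[0])
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_points": int(len(df)),
        "table": df,
    }
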