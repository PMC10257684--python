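import numpy as np
import pytest

from porehr.environment import (
    cell_respiration,
    derive_environment,
    dissolved_o2,
    hr_from_state,
    load_constants,
    load_textures,
    o2_diffusivity,
    o2_partial_pressure,
    vm_temperature,
)


class TestDeriveEnvironment:
    def test_sea_level_reference_oxygen(self):
        """At sea level and 25 degC, C0 equals the constants-table value:
        x_O2 * p0 * H_cp(298 K)."""
        c = load_constants()
        ref = c["o2_mole_fraction"] * c["p0_sea_level"] * c["henry_o2_cp_ref"]
        assert dissolved_o2(0.0, 25.0) == pytest.approx(ref, rel=1e-12)

    def test_temperature_monotonicities(self):
        assert o2_diffusivity(25.0) > o2_diffusivity(10.0) > o2_diffusivity(1.0)
        assert dissolved_o2(0, 25.0) < dissolved_o2(0, 10.0) < dissolved_o2(0, 1.0)

    def test_altitude_lowers_oxygen(self):
        assert o2_partial_pressure(3000.0, 10.0) < o2_partial_pressure(0.0, 10.0)

    def test_specific_surface_area(self):
        """phi = 0.5 and lambda_c = 1 mm give SSA = 3 phi / lambda_c = 1500."""
        tx = load_textures().copy()
        tx.loc["sandcheck"] = [1e-3, 0.5]
        env = derive_environment(20.0, 0.5, "sandcheck", textures=tx)
        assert env.ssa == pytest.approx(1500.0)

    def test_frozen_soil_has_no_reaction(self):
        assert vm_temperature(0.0) == 0.0
        assert vm_temperature(-12.0) == 0.0
        assert vm_temperature(10.0) > 0.0

    def test_unknown_texture_lists_classes(self):
        with pytest.raises(ValueError, match="clay"):
            derive_environment(20.0, 0.5, "peat")

    def test_invalid_saturation(self):
        with pytest.raises(ValueError):
            derive_environment(20.0, 1.5, "loam")


class TestCellRespiration:
    def test_zero_moisture_zero_respiration(self):
        assert hr_from_state(25.0, 0.0, "loam").hr == 0.0

    def test_frozen_cell_zero_respiration(self):
        assert hr_from_state(-10.0, 0.5, "loam").hr == 0.0

    def test_bell_shape_single_interior_maximum(self):
        """HR(saturation) rises then falls: one interior maximum."""
        thetas = np.round(np.arange(0.05, 0.96, 0.05), 2)
        hr = np.array([hr_from_state(25.0, float(t), "loam").hr for t in thetas])
        k = int(np.argmax(hr))
        assert 0 < k < len(hr) - 1
        assert np.all(np.diff(hr[: k + 1]) > 0)
        assert np.all(np.diff(hr[k:]) < 0)

    def test_increasing_in_temperature_suboptimal_branch(self):
        hr = [hr_from_state(T, 0.4, "loam").hr for T in (5.0, 10.0, 15.0, 20.0, 25.0)]
        assert all(a < b for a, b in zip(hr, hr[1:]))

    def test_increasing_with_finer_grains(self):
        """Finer texture (smaller lambda_c) exposes more reactive surface."""
        order = ["sand", "loamy_sand", "sandy_loam", "loam"]
        hr = [hr_from_state(20.0, 0.5, tx).hr for tx in order]
        assert all(a < b for a, b in zip(hr, hr[1:]))

    def test_magnitude_envelope_over_parameter_box(self):
        """HR stays within the order-of-magnitude envelope of global maps
        (1 to 1e4 gC m-2 yr-1) over the documented parameter box."""
        box_t = [5.0, 15.0, 30.0]
        box_th = [0.2, 0.5, 0.9]
        box_tx = ["sand", "sandy_loam", "loam", "silt"]
        box_doc = [2.0, 8.0]
        vals = [
            hr_from_state(T, th, tx, doc=doc).hr
            for T in box_t
            for th in box_th
            for tx in box_tx
            for doc in box_doc
        ]
        vals = np.array(vals)
        assert np.all(vals >= 1.0)
        assert np.all(vals <= 1e4)

    def test_audit_decomposition_reconstructs_hr(self):
        """HR recomputed from the logged (Nc, r0, flux) audit fields matches."""
        c = load_constants()
        env = derive_environment(18.0, 0.55, "loam")
        v = cell_respiration(env, constants=c)
        rebuilt = (
            v.nc_per_area
            * 4.0 * np.pi * v.r0 * env.dm * env.c0 * v.flux
            * c["carbon_molar_mass"] * c["seconds_per_year"]
        )
        assert rebuilt == pytest.approx(v.hr, rel=1e-10)

    def test_constants_override(self):
        c = load_constants()
        c["vm_ref"] *= 2.0
        base = hr_from_state(15.0, 0.4, "loam").hr
        doubled = hr_from_state(15.0, 0.4, "loam", constants=c).hr
        assert doubled > base
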