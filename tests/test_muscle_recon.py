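"""Caudofemoral loop reconstruction and extensor-coefficient arithmetic."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dinomorph.muscle_recon import (CaudalSeries, CaudalVertebra, CflLoop,
                                    ExtensorCoefficients, cfl_fraction,
                                    cfl_loops, cfl_mass, cfl_max,
                                    density_corrected_mass, extensor_masses,
                                    overestimate_pct, reconstruct_cfl)
from dinomorph.synthetic_data import crocodile_tail_series, load_fixture


def circle_vertebra(station, radius, center_y=0.0, center_z=0.0):
    """Landmarks placed on a circle (ordered monotonically around it)."""
    angles = {"transverse_process_tip": 30.0, "chevron_tip": 200.0,
              "chevron_lateral": 250.0, "centrum_ventral": 290.0,
              "centrum_lateral": 330.0}
    outer = [90.0, 150.0]

    def pt(deg):
        psi = np.deg2rad(deg)
        return np.array([station, center_y + radius * np.cos(psi),
                         center_z + radius * np.sin(psi)])

    return CaudalVertebra(station,
                          {k: pt(v) for k, v in angles.items()},
                          [pt(d) for d in outer])


def circle_series(n=6, radius=0.5, spacing=0.4):
    verts = [circle_vertebra(k * spacing, radius) for k in range(n)]
    return CaudalSeries(verts, transition_index=n)


class TestCflLoops:
    def test_loops_pass_through_landmarks(self):
        series = circle_series()
        loops = cfl_loops(series, n_points=256)
        v0 = series.vertebrae[0]
        for name in ("transverse_process_tip", "chevron_tip"):
            target = v0.landmarks[name]
            dist = np.linalg.norm(loops[0].points - target, axis=1).min()
            assert dist < 0.02 * 0.5  # within 2% of the loop radius

    def test_transition_index_limits_loop_count(self):
        series = circle_series(n=6)
        series.transition_index = 2
        assert len(cfl_loops(series)) == 2

    def test_missing_chevron_named_in_error(self):
        series = circle_series(n=3)
        del series.vertebrae[1].landmarks["chevron_tip"]
        with pytest.raises(ValueError, match="vertebra 1.*chevron_tip"):
            cfl_loops(series)

    def test_too_few_vertebrae_rejected(self):
        series = circle_series(n=3)
        series.transition_index = 1
        with pytest.raises(ValueError, match=">= 2 vertebrae"):
            cfl_loops(series)

    def test_loop_area_matches_voxelized_territory(self):
        """Loop area vs 2-D pixel counting of the enclosed territory."""
        series = circle_series(radius=0.5)
        loop = cfl_loops(series, n_points=128)[0]
        from shapely.geometry import Polygon

        poly = Polygon(loop.points[:, 1:])
        h = 0.01
        ys = np.arange(-0.7, 0.7, h)
        zs = np.arange(-0.7, 0.7, h)
        grid = np.stack(np.meshgrid(ys, zs), -1).reshape(-1, 2)
        from shapely import points as shp_points, contains

        inside = contains(poly, shp_points(grid)).sum()
        assert loop.area() == pytest.approx(inside * h * h, rel=0.02)


class TestCflMass:
    def test_two_circular_loops_give_cylinder_mass(self):
        n = 64
        ang = 2 * np.pi * np.arange(n) / n
        r, spacing = 0.3, 0.5

        def ring(x):
            return np.column_stack([np.full(n, x), r * np.cos(ang), r * np.sin(ang)])

        loops = [CflLoop(0.0, ring(0.0)), CflLoop(spacing, ring(spacing))]
        result = cfl_mass(loops, density=1000.0)
        polygon_area = 0.5 * n * r ** 2 * np.sin(2 * np.pi / n)
        assert result.mass == pytest.approx(1000.0 * polygon_area * spacing,
                                            rel=1e-9)
        assert result.mass == pytest.approx(1000.0 * np.pi * r * r * spacing,
                                            rel=2e-3)

    def test_mass_linear_in_density(self):
        series = circle_series()
        m1000 = cfl_mass(cfl_loops(series), density=1000.0).mass
        m1060 = cfl_mass(cfl_loops(series), density=1060.0).mass
        assert m1060 == pytest.approx(1.06 * m1000, rel=1e-12)

    def test_density_correction_reproduces_published_validation(self):
        """Crocodile validation arithmetic: a 0.311 kg estimate at the model
        density of 1000 corresponds to 0.330 kg at muscle density 1060,
        a ~4.4% overestimate of the 0.316 kg dissected mass."""
        corrected = density_corrected_mass(0.311, 1000.0, 1060.0)
        assert corrected == pytest.approx(0.330, abs=0.0005)
        assert overestimate_pct(round(corrected, 3), 0.316) == \
            pytest.approx(4.4, abs=0.15)

    def test_rigid_motion_invariance(self):
        """Translating and rolling the landmark set about the tail axis
        leaves the reconstructed mass unchanged."""
        series = circle_series()
        base = cfl_mass(cfl_loops(series)).mass
        rot = Rotation.from_euler("x", 37, degrees=True).as_matrix()
        shift = np.array([0.0, 0.4, -0.2])
        moved = CaudalSeries(
            [CaudalVertebra(v.station,
                            {k: rot @ p + shift for k, p in v.landmarks.items()},
                            [rot @ p + shift for p in v.outer])
             for v in series.vertebrae],
            series.transition_index)
        assert cfl_mass(cfl_loops(moved)).mass == pytest.approx(base, rel=1e-9)

    def test_crocodile_validation_within_five_percent(self):
        """Blind-validation harness: reconstruction vs the analytic muscle
        territory of the crocodile-like tail."""
        series, truth = crocodile_tail_series()
        result = reconstruct_cfl(series)
        assert abs(result.volume - truth) / truth <= 0.05

    def test_tendon_contribution_small_and_separate(self):
        series, _ = crocodile_tail_series()
        result = reconstruct_cfl(series)
        assert 0 < result.tendon_volume < 0.01 * result.volume
        assert result.total_mass == pytest.approx(result.mass + result.tendon_mass)

    def test_json_roundtrip(self, tmp_path):
        series = circle_series()
        path = tmp_path / "landmarks.json"
        series.to_json(path)
        back = CaudalSeries.from_json(path)
        assert cfl_mass(cfl_loops(back)).mass == pytest.approx(
            cfl_mass(cfl_loops(series)).mass, rel=1e-12)


class TestCflScaling:
    def test_published_max_scaling(self):
        t4 = load_fixture(4).data
        t8 = load_fixture(8).data.set_index("specimen")

        def tail(spec, model):
            rows = t4[(t4.specimen == spec) & (t4.segment == "tail")]
            return float(rows[rows.model == model].mass_kg.iloc[0])

        sue = cfl_max(t8.loc["Sue", "cfl_min_kg"], tail("Sue", "max"),
                      tail("Sue", "min"))
        assert round(sue) == 561
        carnegie = cfl_max(t8.loc["Carnegie", "cfl_min_kg"],
                           tail("Carnegie", "max"), tail("Carnegie", "min"))
        assert carnegie == pytest.approx(520, abs=1)

    def test_unit_ratio_and_errors(self):
        assert cfl_max(100.0, 50.0, 50.0) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            cfl_max(100.0, 0.0, 50.0)

    def test_published_fractions(self):
        t6 = load_fixture(6).data.set_index("specimen")
        t8 = load_fixture(8).data.set_index("specimen")
        jane = cfl_fraction(t8.loc["Jane", "cfl_min_kg"],
                            t6.loc["Jane", "min_mass_kg"])
        stan = cfl_fraction(t8.loc["Stan", "cfl_min_kg"],
                            t6.loc["Stan", "min_mass_kg"])
        assert jane == pytest.approx(5.32, abs=0.005)
        assert stan == pytest.approx(3.24, abs=0.005)
        assert cfl_fraction(0.0, 5000.0) == 0.0

    def test_stan_printed_max_is_flagged_erratum(self):
        fixture = load_fixture(8)
        assert fixture.errata
        assert float(fixture.data.set_index("specimen")
                     .loc["Stan", "cfl_max_kg"]) == 22  # packaged bit-for-bit


class TestExtensorMasses:
    @staticmethod
    def _inputs(specimen, which="min"):
        t2 = load_fixture(2).data
        t5 = load_fixture(5).data
        t6 = load_fixture(6).data.set_index("specimen")
        t8 = load_fixture(8).data.set_index("specimen")

        def seg(segment):
            rows = t5[(t5.specimen == specimen) & (t5.segment == segment)]
            return float(rows[rows.model == which].mass_kg.iloc[0])

        def bone(segment):
            return float(t2[(t2.specimen == specimen)
                            & (t2.segment == segment)].volume_m3.iloc[0])

        return dict(
            thigh_mass=seg("thigh"), shank_mass=seg("shank"),
            femur_volume=bone("femur"), tibiotarsus_volume=bone("tibiotarsus"),
            cfl_mass_kg=float(t8.loc[specimen, f"cfl_{which}_kg"]),
            body_mass=float(t6.loc[specimen, f"{which}_mass_kg"]))

    def test_stan_minimal_column(self):
        result = extensor_masses(**self._inputs("Stan"))
        assert result.hip_pct == pytest.approx(12.3, abs=0.05)
        assert result.knee_pct == pytest.approx(5.68, abs=0.05)
        assert result.ankle_pct == pytest.approx(2.52, abs=0.05)
        assert result.total_pct == pytest.approx(20.5, abs=0.05)

    def test_carnegie_minimal_column(self):
        result = extensor_masses(**self._inputs("Carnegie"))
        assert 9.04 <= result.hip_pct <= 9.06
        assert result.knee_pct == pytest.approx(4.10, abs=0.01)
        assert result.ankle_pct == pytest.approx(2.33, abs=0.01)

    def test_total_is_exact_sum(self):
        result = extensor_masses(**self._inputs("Sue"))
        assert result.total_kg == pytest.approx(
            result.hip_kg + result.knee_kg + result.ankle_kg, abs=1e-12)

    def test_zero_cfl_only_lowers_hip(self):
        inputs = self._inputs("Stan")
        with_cfl = extensor_masses(**inputs)
        inputs_zero = dict(inputs, cfl_mass_kg=0.0)
        without = extensor_masses(**inputs_zero)
        drop = inputs["cfl_mass_kg"] / inputs["body_mass"] * 100
        assert with_cfl.hip_pct - without.hip_pct == pytest.approx(drop, abs=1e-9)
        assert with_cfl.knee_pct == without.knee_pct
        assert with_cfl.ankle_pct == without.ankle_pct

    def test_bone_exceeding_segment_rejected(self):
        with pytest.raises(ValueError, match="bone mass"):
            extensor_masses(thigh_mass=30.0, shank_mass=300.0,
                            femur_volume=0.034, tibiotarsus_volume=0.02,
                            cfl_mass_kg=100.0, body_mass=5000.0)

    def test_coefficients_validated(self):
        with pytest.raises(ValueError):
            ExtensorCoefficients(hip=1.2)
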