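"""Strain-rate oracles: analytic flows, log-stretch, projections, accumulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placode import kinematics as kin
from placode.radial import RadialFrame
from placode.synthetic import SyntheticConfig, generate_placode
from placode.tissue_io import GeometryError

from conftest import grid_tissue


def _two_frame_linear_flow(grad: np.ndarray, dt: float = 1.0, n: int = 4):
    """Tissue whose centroids move by the exact linear displacement field
    ``u = (grad*dt) x`` between two frames."""
    G = np.asarray(grad, dtype=float)

    def displace(tid, f):
        if f == 0:
            return (0.0, 0.0)
        i, j = divmod(tid, n)
        x = np.array([j * 2.0, i * 2.0])
        u = (G * dt) @ x
        return (u[0], u[1])

    return grid_tissue(n=n, n_frames=2, dt_min=dt, displace=displace)


def _domain_all(tissue):
    ids = sorted(tissue.frames[0].cells)
    return kin.DomainSpec(focal_id=ids[0], member_ids=ids, f_start=0, f_end=1)


@pytest.mark.parametrize(
    "grad,expected",
    [
        (np.zeros((2, 2)), np.zeros((2, 2))),  # uniform translation
        (-0.01 * np.eye(2), -0.01 * np.eye(2)),  # isotropic contraction
        (np.array([[0.0, 0.01], [0.01, 0.0]]), np.array([[0.0, 0.01], [0.01, 0.0]])),
    ],
)
def test_total_strain_matches_analytic_gradient(grad, expected):
    tissue = _two_frame_linear_flow(grad)
    T, rot = kin.fit_total_strain(_domain_all(tissue), tissue)
    np.testing.assert_allclose(T, expected, atol=1e-9)
    assert rot == pytest.approx(0.0, abs=1e-9)


def test_total_strain_pure_shear_traceless():
    tissue = _two_frame_linear_flow(np.array([[0.0, 0.02], [0.02, 0.0]]))
    T, _ = kin.fit_total_strain(_domain_all(tissue), tissue)
    assert np.trace(T) == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(np.linalg.eigvalsh(T), [-0.02, 0.02], atol=1e-9)


def test_total_strain_collinear_centroids_rejected():
    tissue = grid_tissue(n=4, n_frames=2)
    dom = kin.DomainSpec(focal_id=0, member_ids=[0, 1, 2, 3], f_start=0, f_end=1)
    with pytest.raises(GeometryError, match="collinear"):
        kin.fit_total_strain(dom, tissue)


def test_rotation_diagnostic_nonzero_for_rotating_flow():
    omega = 0.05
    tissue = _two_frame_linear_flow(np.array([[0.0, -omega], [omega, 0.0]]))
    T, rot = kin.fit_total_strain(_domain_all(tissue), tissue)
    np.testing.assert_allclose(T, 0.0, atol=1e-9)
    assert rot == pytest.approx(omega, abs=1e-9)


class TestCellShapeStrain:
    def test_unchanged_ellipses_give_zero(self):
        tissue = grid_tissue(n=3, n_frames=2)
        dom = kin.DomainSpec(0, [0, 1, 3, 4], 0, 1)
        C = kin.fit_cellshape_strain(dom, tissue)
        np.testing.assert_allclose(C, 0.0, atol=1e-12)

    def test_isotropic_scaling_log_ratio(self):
        # closed form: all axes scaled by exp(-k dt) -> principal rates -k
        k = 0.02
        e0 = (3.0, 2.0, 0.7)
        e1 = (3.0 * np.exp(-k), 2.0 * np.exp(-k), 0.7)
        C = kin._cell_log_stretch(e0, e1)
        np.testing.assert_allclose(np.linalg.eigvalsh(C), [-k, -k], atol=1e-12)

    def test_rigid_rotation_carries_no_strain(self):
        e0 = (3.0, 1.5, 0.2)
        e1 = (3.0, 1.5, 0.2 + 0.4)
        C = kin._cell_log_stretch(e0, e1)
        np.testing.assert_allclose(C, 0.0, atol=1e-12)

    def test_anisotropic_stretch_in_mid_frame(self):
        e0 = (2.0, 2.0, 0.0)  # circle
        e1 = (2.0 * np.e, 2.0, np.pi / 3)  # stretched along pi/3
        C = kin._cell_log_stretch(e0, e1)
        evals, evecs = np.linalg.eigh(C)
        assert evals[1] == pytest.approx(1.0, abs=1e-12)
        ang = np.arctan2(evecs[1, 1], evecs[0, 1]) % np.pi
        assert ang == pytest.approx(np.pi / 3, abs=1e-9)


class TestDecomposition:
    def test_t_equals_c_gives_zero_intercalation(self):
        T = np.array([[0.01, 0.002], [0.002, -0.03]])
        rec = kin.decompose_strain(T, T)
        np.testing.assert_allclose(rec.I, 0.0, atol=1e-15)

    def test_pure_constriction_attributed_to_cell_shape(self):
        # no rearrangement: |I| < 10% of |T| on the uniform-contraction flow
        cfg = SyntheticConfig(
            scenario="uniform", n_cells=60, t_start_min=0, t_end_min=6, seed=1
        )
        tissue, _ = generate_placode(cfg)
        doms, _ = kin.build_domains(tissue, 1)
        mags_T, mags_I, mags_C = [], [], []
        for d in doms:
            T, _ = kin.fit_total_strain(d, tissue)
            C = kin.fit_cellshape_strain(d, tissue)
            rec = kin.decompose_strain(T, C)
            mags_T.append(np.abs(np.linalg.eigvalsh(T)).max())
            mags_C.append(np.abs(np.linalg.eigvalsh(C)).max())
            mags_I.append(np.abs(np.linalg.eigvalsh(rec.I)).max())
        assert np.mean(mags_I) < 0.1 * np.mean(mags_T)
        assert np.mean(mags_C) == pytest.approx(np.mean(mags_T), rel=0.05)

    def test_pure_intercalation_attributed_to_residual(self):
        # rigid cell shapes sliding past each other: C ~ 0, I ~ T
        cfg = SyntheticConfig(
            scenario="shear_rigid", n_cells=60, t_start_min=0, t_end_min=6, seed=1
        )
        tissue, _ = generate_placode(cfg)
        doms, _ = kin.build_domains(tissue, 1)
        mags_T, mags_I, mags_C = [], [], []
        for d in doms:
            T, _ = kin.fit_total_strain(d, tissue)
            C = kin.fit_cellshape_strain(d, tissue)
            rec = kin.decompose_strain(T, C)
            mags_T.append(np.abs(np.linalg.eigvalsh(T)).max())
            mags_C.append(np.abs(np.linalg.eigvalsh(C)).max())
            mags_I.append(np.abs(np.linalg.eigvalsh(rec.I)).max())
        assert np.mean(mags_C) < 0.1 * np.mean(mags_T)
        assert np.mean(mags_I) == pytest.approx(np.mean(mags_T), rel=0.05)


class TestProjection:
    def _rframe(self, centroid):
        r = float(np.linalg.norm(centroid))
        return RadialFrame(
            origin=np.zeros(2), r={0: r}, theta={0: 0.0}, D={0: 2 * r}
        )

    def _project(self, M, centroid):
        tissue = grid_tissue(n=1, n_frames=1)
        tissue.frames[0].cells[0].centroid = np.asarray(centroid, dtype=float)
        rec = kin.decompose_strain(np.asarray(M), np.zeros((2, 2)))
        rec.focal_id = 0
        kin.project_strain(rec, self._rframe(centroid), tissue, 0)
        return rec.proj["T_radial"], rec.proj["T_circ"]

    def test_isotropic_tensor(self):
        rad, circ = self._project(0.03 * np.eye(2), [5.0, 3.0])
        assert rad == pytest.approx(0.03, abs=1e-12)
        assert circ == pytest.approx(0.03, abs=1e-12)

    def test_principal_axis_along_radial(self):
        rad, circ = self._project(np.diag([-0.02, 0.0]), [7.0, 0.0])
        assert rad == pytest.approx(-0.02, abs=1e-12)
        assert circ == pytest.approx(0.0, abs=1e-12)

    def test_principal_axis_at_45_degrees(self):
        # rotation oracle: R(45deg) diag(e, 0) R^T projected on x/y axes -> e/2
        e = 0.04
        th = np.pi / 4
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        M = R @ np.diag([e, 0.0]) @ R.T
        rad, circ = self._project(M, [7.0, 0.0])
        assert rad == pytest.approx(e / 2, abs=1e-12)
        assert circ == pytest.approx(e / 2, abs=1e-12)

    def test_frame_invariance_under_corotation(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(2, 2)) * 0.02
        M = 0.5 * (A + A.T)
        centroid = np.array([6.0, 2.0])
        base = self._project(M, centroid)
        for ang in (0.3, 1.2, 2.9):
            R = np.array(
                [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
            )
            got = self._project(R @ M @ R.T, R @ centroid)
            np.testing.assert_allclose(got, base, atol=1e-9)


class TestAccumulation:
    def test_constant_rate_closed_form(self):
        times = np.arange(0.0, 11.0)
        cum, flags = kin.accumulate_strain(np.full(10, 0.01), times)
        assert cum[0] == 0.0
        assert cum[-1] == pytest.approx(np.exp(0.1) - 1.0, abs=1e-12)
        assert not flags.any()

    def test_zero_rates(self):
        cum, _ = kin.accumulate_strain(np.zeros(5), np.arange(6.0))
        np.testing.assert_array_equal(cum, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-0.05, 0.05), min_size=1, max_size=20),
    )
    def test_piecewise_rates_product_oracle(self, rates):
        # brute-force oracle: cumulative = product of per-step ratios - 1
        rates = np.asarray(rates)
        times = np.arange(len(rates) + 1, dtype=float)
        cum, _ = kin.accumulate_strain(rates, times)
        product = 1.0
        for i, r in enumerate(rates):
            product *= np.exp(r * 1.0)
            assert cum[i + 1] == pytest.approx(product - 1.0, abs=1e-12)

    def test_gap_splits_accumulation(self):
        rates = np.array([0.01, np.nan, 0.01])
        cum, flags = kin.accumulate_strain(rates, np.arange(4.0))
        assert flags[2] and flags[3]
        assert not flags[1]


class TestAreaRate:
    def test_constant_area(self):
        r = kin.area_change_rate(np.arange(5.0), np.full(5, 30.0))
        np.testing.assert_allclose(r, 0.0, atol=1e-15)

    def test_exponential_decay(self):
        t = np.arange(0.0, 20.0)
        r = kin.area_change_rate(t, 40.0 * np.exp(-0.01 * t))
        np.testing.assert_allclose(r, -0.01, atol=1e-12)

    def test_halving_mean_rate(self):
        t = np.array([0.0, 10.0])
        r = kin.area_change_rate(t, np.array([30.0, 15.0]))
        assert r[0] == pytest.approx(np.log(0.5) / 10.0, abs=1e-12)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(Exception, match="positive"):
            kin.area_change_rate(np.arange(3.0), np.array([2.0, 0.0, 1.0]))


class TestAspectRatio:
    def test_circle_is_one(self):
        assert kin.aspect_ratio_radial((2.0, 2.0, 0.3), [5.0, 0.0], [0.0, 0.0]) == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_major_axis_circumferential(self):
        # 2:1 ellipse with major axis along u_c (y) for a cell on the +x ray
        ratio = kin.aspect_ratio_radial((4.0, 2.0, np.pi / 2), [5.0, 0.0], [0.0, 0.0])
        assert ratio == pytest.approx(0.5, abs=1e-12)

    def test_45_degree_symmetric(self):
        ratio = kin.aspect_ratio_radial((4.0, 2.0, np.pi / 4), [5.0, 0.0], [0.0, 0.0])
        assert ratio == pytest.approx(1.0, abs=1e-12)


def test_behavior_switch_near_constricts_far_delayed(short_eccentric_run):
    """Near cells constrict from t=0; far cells only after entering the near
    region — the generator's programmed switch recovered from areas."""
    tissue, gt = short_eccentric_run
    t0 = tissue.t0_index
    near = [t for t, reg in gt.region_t0.items() if reg == "near"]
    far = [t for t, reg in gt.region_t0.items() if reg == "far"]
    # near cohort: negative area rate right after t0
    rates = []
    for tid in near:
        t, a = tissue.area_series(tid)
        sel = (t >= 0) & (t < 5)
        if sel.sum() >= 2:
            rates.append(np.mean(np.diff(np.log(a[sel])) / np.diff(t[sel])))
    assert np.mean(rates) < -0.01
    # far cells: area flat before their recorded onset
    flat = []
    for tid in far:
        onset = gt.onset_frame.get(tid)
        t, a = tissue.area_series(tid)
        idx = tissue.presence(tid)
        pre = [ai for i, ai in zip(idx, a) if onset is None or i < onset]
        if len(pre) >= 3:
            flat.append(np.mean(np.abs(np.diff(np.log(pre)))))
    assert np.mean(flat) < 1e-9
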