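"""Time integration: speed curve, heading updates, elongation, avascular
expansion, relaxation, baseline modes and reproducibility."""

import numpy as np
import pytest
from scipy import ndimage, stats
from scipy.spatial import ConvexHull

import vasrem as vr
from vasrem.dynamics import SpeedCurve, make_synthetic_timelapse, relax, simulate
from vasrem.model import AVASCULAR, VASCULAR, Population, seed_agents


def uniform_fields(shape, vx, vy, tau):
    vel = np.zeros(shape + (2,))
    vel[..., 0], vel[..., 1] = vx, vy
    interior = np.full(shape, float(tau))
    return vr.FieldSet(vel, np.full(shape, np.nan), interior)


def two_agents(p0, p1, phase=VASCULAR):
    pos = np.array([p0, p1], dtype=float)
    return Population(pos, np.zeros(2), np.zeros(2), [3.5, 3.5], [3.5, 3.5],
                      [phase] * 2, [-1, -1] if phase == VASCULAR else [1, 1])


class TestSpeedCurve:
    def test_peak_at_tau_max(self):
        assert SpeedCurve(12.0, 0.033)(0.033) == pytest.approx(12.0)

    def test_zero_shear_zero_speed(self):
        assert SpeedCurve(12.0, 0.033)(0.0) == 0.0

    def test_double_tau_max_value(self):
        # V_max * 2 * exp(-1)
        assert SpeedCurve(12.0, 0.033)(0.066) == pytest.approx(24.0 / np.e)

    def test_negative_shear_rejected(self):
        with pytest.raises(ValueError):
            SpeedCurve()(-0.01)

    def test_unimodal_and_bounded(self):
        c = SpeedCurve(12.0, 0.033)
        tau = np.linspace(0, 1.0, 4000)
        v = c(tau)
        assert np.all((v >= 0) & (v <= 12.0 + 1e-12))
        k = int(np.argmax(v))
        assert np.all(np.diff(v[:k]) > 0)
        assert np.all(np.diff(v[k:]) < 0)


class TestHeadingUpdate:
    def test_isolated_agent_migrates_against_flow(self):
        # uniform flow east, alignment only, no noise -> heading = pi
        mask = vr.VesselMask(np.ones((60, 60), dtype=bool))
        fields = uniform_fields((60, 60), 100.0, 0.0, 0.033)
        params = vr.ModelParams(nu=0.0, beta=0, zeta=0, omega=0, kappa=0)
        pop = Population(np.array([[30.0, 30.0]]), [0.0], [0.0], [3.5], [3.5],
                         [VASCULAR], [-1])
        res = simulate(mask, fields, params, params.dt, seed=0, population=pop)
        assert res.final.theta[0] == pytest.approx(np.pi, abs=1e-12)

    def test_vicsek_limit_all_headings_equal_after_one_step(self, channel_mask,
                                                            channel_fields):
        params = vr.ModelParams(nu=0.0, beta=0, zeta=0, omega=0, kappa=0)
        res = simulate(channel_mask, channel_fields, params, params.dt, seed=0)
        th = res.final.theta[res.final.vascular]
        assert np.allclose(np.abs(th), np.pi)

    def test_two_preferred_directions_average(self):
        # agent 1 prefers 0 (flow pointing west), agent 2 prefers pi/2
        # (flow pointing south in image coordinates): both end at pi/4
        grid = np.ones((40, 40), dtype=bool)
        mask = vr.VesselMask(grid)
        vel = np.zeros((40, 40, 2))
        vel[:, :20] = (-50.0, 0.0)
        vel[:, 20:] = (0.0, -50.0)
        fields = vr.FieldSet(vel, np.full((40, 40), np.nan),
                             np.full((40, 40), 0.033))
        params = vr.ModelParams(nu=0.0, beta=0, zeta=0, omega=0, kappa=0)
        pop = Population(np.array([[16.0, 20.0], [24.0, 20.0]]),
                         [0.0, 0.0], [0.0, 0.0], [3.5] * 2, [3.5] * 2,
                         [VASCULAR] * 2, [-1] * 2)
        res = simulate(mask, fields, params, params.dt, seed=0, population=pop)
        assert np.allclose(res.final.theta, np.pi / 4, atol=1e-12)

    def test_pure_noise_heading_increments_are_uniform(self):
        # all deterministic weights zero, nu = 1: the per-step heading
        # change is the raw white-noise draw on [-pi, pi]
        mask = vr.VesselMask(np.ones((200, 200), dtype=bool))
        fields = uniform_fields((200, 200), 0.0, 0.0, 0.0)
        params = vr.ModelParams(alpha=0, beta=0, zeta=0, omega=0, kappa=0, nu=1.0,
                                delta=0.0, delta_av=0.0)
        pop = seed_agents(mask)
        res = simulate(mask, fields, params, 15 * params.dt, seed=3,
                       record_every=1, population=pop)
        diffs = []
        for (_, a), (_, b) in zip(res.snapshots[:-1], res.snapshots[1:]):
            diffs.append(b.theta - a.theta)
        diffs = np.concatenate(diffs)
        assert len(diffs) >= 10_000
        p = stats.kstest(diffs, stats.uniform(loc=-np.pi, scale=2 * np.pi).cdf).pvalue
        assert p > 0.01


class TestAdvance:
    def test_displacement_is_speed_times_dt(self):
        mask = vr.VesselMask(np.ones((60, 60), dtype=bool))
        fields = uniform_fields((60, 60), -100.0, 0.0, 0.033)  # flow west
        params = vr.ModelParams(nu=0.0, beta=0, zeta=0, omega=0, kappa=0,
                                delta=0.0)
        pop = Population(np.array([[30.0, 30.0]]), [0.0], [0.0], [3.5], [3.5],
                         [VASCULAR], [-1])
        res = simulate(mask, fields, params, params.dt, seed=0, population=pop)
        # V(tau_max) = 12 um/h against the flow (east) for 1/12 h -> (+1, 0)
        assert np.allclose(res.final.pos[0] - [30.0, 30.0], [1.0, 0.0])

    def test_zero_speed_leaves_position_unchanged(self):
        mask = vr.VesselMask(np.ones((60, 60), dtype=bool))
        fields = uniform_fields((60, 60), -100.0, 0.0, 0.0)  # zero shear
        params = vr.ModelParams(nu=0.0, beta=0, zeta=0, omega=0, kappa=0)
        pop = Population(np.array([[30.0, 30.0]]), [0.0], [0.0], [3.5], [3.5],
                         [VASCULAR], [-1])
        res = simulate(mask, fields, params, 1.0, seed=0, population=pop)
        assert np.allclose(res.final.pos[0], [30.0, 30.0])

    def test_duration_must_be_step_multiple(self, channel_mask, channel_fields, params):
        with pytest.raises(ValueError):
            simulate(channel_mask, channel_fields, params, 0.1)

    def test_four_hours_is_48_steps(self, channel_mask, channel_fields):
        params = vr.ModelParams(delta_av=0.0)
        res = simulate(channel_mask, channel_fields, params, 4.0, seed=0,
                       record_every=1)
        assert len(res.snapshots) == 49  # t=0 plus 48 steps
        assert res.snapshots[-1][0] == pytest.approx(4.0)

    def test_agent_counts_conserved(self, honeycomb_mask, honeycomb_fields, params):
        pop = seed_agents(honeycomb_mask)
        res = simulate(honeycomb_mask, honeycomb_fields, params, 0.5, seed=2,
                       population=pop)
        assert len(res.final) == len(pop)
        assert res.final.vascular.sum() == pop.vascular.sum()

    def test_trajectories_reproducible_bitwise(self, honeycomb_mask,
                                               honeycomb_fields, params, tmp_path):
        from vasrem import io

        for k in (1, 2):
            res = simulate(honeycomb_mask, honeycomb_fields, params, 0.5, seed=9)
            io.write_population(res.final, tmp_path / f"run{k}.csv")
        assert (tmp_path / "run1.csv").read_bytes() == (tmp_path / "run2.csv").read_bytes()

    def test_channel_migration_is_anti_parallel_to_flow(self, channel_mask,
                                                        channel_fields):
        # flow points east; over 10 seeds the mean vascular displacement is
        # westward with small lateral drift
        params = vr.ModelParams(delta_av=0.0)
        axial, lateral = [], []
        for seed in range(10):
            res = simulate(channel_mask, channel_fields, params, 1.0, seed=seed)
            disp = res.final.pos[res.final.vascular] - res.initial.pos[res.initial.vascular]
            mean = disp.mean(axis=0)
            axial.append(mean[0])
            lateral.append(mean[1])
        axial, lateral = np.mean(axial), np.mean(lateral)
        assert axial < 0
        assert abs(lateral) < 0.1 * abs(axial)


class TestElongation:
    def test_semi_major_axis_linear_in_steps(self, channel_mask, channel_fields):
        params = vr.ModelParams(delta_av=0.0)
        res = simulate(channel_mask, channel_fields, params, 1.0, seed=0,
                       record_every=1)
        for k, (_, pop) in enumerate(res.snapshots):
            expected = (1.0 + params.delta * k) * 3.5
            assert np.allclose(pop.a[pop.vascular], expected)
            assert np.allclose(pop.b[pop.vascular], 3.5)

    def test_eight_hours_reach_aspect_1_3(self, channel_mask, channel_fields):
        params = vr.ModelParams(delta_av=0.0)
        res = simulate(channel_mask, channel_fields, params, 8.0, seed=0)
        a = res.final.a[res.final.vascular]
        assert np.allclose(a, 4.55)  # 1.3 x 3.5 after 96 steps
        assert np.allclose(a / res.final.b[res.final.vascular], 1.3)

    def test_avascular_agents_stay_circular(self, honeycomb_mask, honeycomb_fields,
                                            params):
        res = simulate(honeycomb_mask, honeycomb_fields, params, 1.0, seed=0)
        av = res.final.avascular
        assert np.array_equal(res.final.a[av], res.final.b[av])

    def test_orientation_follows_flow_axis(self, channel_mask, channel_fields):
        params = vr.ModelParams(delta_av=0.0)
        res = simulate(channel_mask, channel_fields, params, 1.0, seed=0)
        interior = res.final.vascular & (np.abs(res.final.pos[:, 1] - 50.0) < 15)
        assert np.allclose(np.abs(np.sin(res.final.orient[interior])), 0.0, atol=0.2)


def isolated_disk_cluster(radius=45.0):
    import warnings

    grid = np.zeros((140, 140), dtype=bool)
    grid[0, 0] = True  # keep one lumen pixel so the raster has both phases
    mask = vr.VesselMask(grid)
    fields = uniform_fields((140, 140), 0.0, 0.0, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        pop = seed_agents(mask)
    keep = pop.avascular & (np.linalg.norm(pop.pos - 70.0, axis=1) <= radius)
    pop = Population(pop.pos[keep], pop.theta[keep], pop.orient[keep],
                     pop.a[keep], pop.b[keep], pop.phase[keep], pop.cluster[keep])
    return mask, fields, pop


class TestAvascularExpansion:
    def test_one_hour_radial_factor(self):
        mask, fields, pop = isolated_disk_cluster()
        params = vr.ModelParams(beta_av=0, kappa_av=0, omega_av=0, nu=0.0)
        res = simulate(mask, fields, params, 1.0, seed=0, population=pop)
        assert np.allclose(res.final.a[res.final.avascular], 1.042 * 3.5)

    def test_disk_cluster_area_growth_over_8h(self):
        mask, fields, pop = isolated_disk_cluster()
        params = vr.ModelParams(beta_av=0, kappa_av=0, omega_av=0, nu=0.0)
        res = simulate(mask, fields, params, 8.0, seed=0, population=pop)
        ratio = ConvexHull(res.final.pos).volume / ConvexHull(pop.pos).volume
        assert ratio == pytest.approx((1.0 + 8 * 0.042) ** 2, rel=1e-9)

    def test_zero_rate_is_static(self):
        mask, fields, pop = isolated_disk_cluster()
        params = vr.ModelParams(beta_av=0, kappa_av=0, omega_av=0, nu=0.0,
                                delta_av=0.0)
        res = simulate(mask, fields, params, 2.0, seed=0, population=pop)
        assert np.array_equal(res.final.pos, pop.pos)
        assert np.array_equal(res.final.a, pop.a)


class TestRelax:
    def test_two_agents_settle_at_equilibrium_distance(self, params):
        pop = two_agents([50.0, 50.0], [60.0, 50.0])
        p = params.with_(alpha=0, zeta=0, omega=0, kappa=0, nu=0.0)
        out, steps = relax(pop, p, speed=p.v_max)
        sep = np.linalg.norm(out.pos[1] - out.pos[0])
        assert sep == pytest.approx(7.0, abs=0.01)

    def test_lattice_cluster_is_a_fixed_point(self, params):
        # agents seeded at the equilibrium pitch feel no net force
        mask = vr.VesselMask(np.ones((40, 40), dtype=bool))
        pop = seed_agents(mask)
        p = params.with_(alpha=0, zeta=0, omega=0, kappa=0, nu=0.0)
        out, steps = relax(pop, p, speed=p.v_max, max_steps=500)
        assert steps < 500
        assert np.allclose(out.pos, pop.pos, atol=0.5)


class TestModesAndTimelapse:
    def test_random_mode_reproducible(self, honeycomb_mask, honeycomb_fields, params):
        a = simulate(honeycomb_mask, honeycomb_fields, params, 0.5, mode="random",
                     seed=5)
        b = simulate(honeycomb_mask, honeycomb_fields, params, 0.5, mode="random",
                     seed=5)
        assert np.array_equal(a.final.pos, b.final.pos)

    def test_gregoire_mode_keeps_avascular_static_and_circular(
            self, honeycomb_mask, honeycomb_fields, params):
        pop = seed_agents(honeycomb_mask)
        res = simulate(honeycomb_mask, honeycomb_fields, params, 0.5,
                       mode="gregoire", seed=0, population=pop)
        av = pop.avascular
        assert np.array_equal(res.final.pos[av], pop.pos[av])
        assert np.all(res.final.a == 3.5)  # no elongation in this mode

    def test_timelapse_duration_zero_is_identity(self, honeycomb_mask,
                                                 honeycomb_fields, params):
        tl = make_synthetic_timelapse(honeycomb_mask, honeycomb_fields, params,
                                      duration=0.0, seed=0)
        assert np.array_equal(tl.initial_mask.grid, tl.final_mask.grid)

    def test_timelapse_deterministic(self, honeycomb_mask, honeycomb_fields, params):
        a = make_synthetic_timelapse(honeycomb_mask, honeycomb_fields, params,
                                     duration=0.5, seed=4)
        b = make_synthetic_timelapse(honeycomb_mask, honeycomb_fields, params,
                                     duration=0.5, seed=4)
        assert np.array_equal(a.final_mask.grid, b.final_mask.grid)

    def test_high_shear_channel_widens(self, honeycomb_spec, honeycomb_truth):
        # the channel carrying the largest flux gains width over 4 h,
        # measured by the lumen distance transform along its centreline
        net = vr.build_flow_network(honeycomb_spec)
        k = int(np.argmax(np.abs(net.flux)))
        u, v = net.edges[k]
        p0, p1 = net.nodes[u], net.nodes[v]
        ts = np.linspace(0.2, 0.8, 25)
        pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
        widths = []
        for mask in (honeycomb_truth.initial_mask, honeycomb_truth.final_mask):
            edt = ndimage.distance_transform_edt(mask.grid)
            rows = np.clip(pts[:, 1].astype(int), 0, mask.shape[0] - 1)
            cols = np.clip(pts[:, 0].astype(int), 0, mask.shape[1] - 1)
            widths.append(edt[rows, cols].mean())
        assert widths[1] > widths[0]
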