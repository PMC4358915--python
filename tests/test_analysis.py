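"""Analysis tests: depletion curves, stretched-exponential fits, PMFs,
diffusion estimates and burial histograms."""

import numpy as np
import pytest

import corralsim as cs
from corralsim.analysis import concentration_percent
from corralsim.constants import BOLTZMANN_KCAL


def traj_from_positions(times, positions, replica=0):
    return cs.Trajectory(times=np.asarray(times, float),
                         positions=np.asarray(positions, float),
                         metadata={"replica": replica})


class TestDepletionSeries:
    def geometry(self):
        return cs.SystemGeometry(box_x_lo=-475.0, box_x_hi=925.0,
                                 box_y_lo=-500.0, box_y_hi=500.0)

    def test_full_corral_reads_six_percent(self, rng):
        geo = self.geometry()
        pos = np.zeros((1, 438, 3))
        pos[0, :, 0] = rng.uniform(-475, -1, 438)
        series = cs.depletion_series([traj_from_positions([0.0], pos)], geo)
        assert series.mean[0] == pytest.approx(6.0, abs=0.01)

    def test_uniform_spread_reads_two_percent(self, rng):
        geo = self.geometry()
        pos = np.zeros((1, 438, 3))
        pos[0, :, 0] = np.linspace(-474.9, 924.9, 438)
        series = cs.depletion_series([traj_from_positions([0.0], pos)], geo)
        expect = concentration_percent(438 * 475 / 1400, geo.corral_area)
        assert series.mean[0] == pytest.approx(expect, abs=0.05)
        assert series.mean[0] == pytest.approx(2.0, abs=0.1)

    def test_empty_pool_reads_zero(self):
        geo = self.geometry()
        pos = np.full((2, 10, 3), 500.0)
        series = cs.depletion_series(
            [traj_from_positions([0.0, 1.0], pos)], geo
        )
        assert np.all(series.mean == 0.0)

    def test_pool_plus_exterior_counts_conserve_particles(self, rng):
        geo = self.geometry()
        pos = rng.uniform([-475, -500, 0], [925, 500, 0], size=(5, 60, 3))
        traj = traj_from_positions(np.arange(5.0), pos)
        inside = (pos[:, :, 0] < 0).sum(axis=1)
        outside = (pos[:, :, 0] >= 0).sum(axis=1)
        assert np.all(inside + outside == 60)


class TestStretchedExponentialFit:
    def test_pure_exponential_recovered(self):
        series = cs.make_decay_curve(6, 2.0, 1e3, 1.0, 0.0, 200, 8e3, seed=0)
        fit = cs.fit_stretched_exponential(series)
        assert fit.converged
        assert fit.tau == pytest.approx(1e3, rel=1e-3)
        assert fit.beta == pytest.approx(1.0, rel=1e-3)
        assert fit.c_inf == pytest.approx(2.0, rel=1e-3)

    def test_stretched_curve_recovered(self):
        series = cs.make_decay_curve(6, 2.0, 5e3, 0.6, 0.0, 400, 6e4, seed=0)
        fit = cs.fit_stretched_exponential(series)
        assert fit.tau == pytest.approx(5e3, rel=5e-3)
        assert fit.beta == pytest.approx(0.6, rel=5e-3)
        assert fit.c_inf == pytest.approx(2.0, rel=5e-3)

    def test_noisy_replicas_recovered_within_bootstrap_interval(self):
        true = dict(c_inf=2.0, tau=5e3, beta=0.6)
        series = cs.make_decay_curve(
            6, true["c_inf"], true["tau"], true["beta"], noise_sd=0.06,
            n_points=300, t_max=6e4, seed=7, n_replicas=20,
        )
        fit = cs.fit_stretched_exponential(series)
        # bootstrap over replicas
        rng = np.random.default_rng(11)
        boots = []
        for _ in range(60):
            pick = rng.integers(0, series.n_replicas, series.n_replicas)
            bs = cs.DepletionSeries(times=series.times,
                                    per_replica=series.per_replica[pick])
            bfit = cs.fit_stretched_exponential(bs)
            boots.append((bfit.tau, bfit.beta, bfit.c_inf))
        boots = np.array(boots)
        for i, key in enumerate(("tau", "beta", "c_inf")):
            sd = boots[:, i].std()
            assert abs([fit.tau, fit.beta, fit.c_inf][i] - true[key]) < 3 * sd + 1e-9

    def test_too_few_points_rejected(self):
        series = cs.make_decay_curve(6, 2, 1e3, 1.0, 0.0, 5, 1e3, seed=0)
        with pytest.raises(ValueError):
            cs.fit_stretched_exponential(series)


class TestMeanRelaxationTime:
    @pytest.mark.parametrize(
        "beta,factor",
        [(1.0, 1.0), (0.5, 2.0), (2.0, np.sqrt(np.pi) / 2)],
    )
    def test_gamma_function_identities(self, beta, factor):
        tau = 1234.5
        assert cs.mean_relaxation_time(tau, beta) == pytest.approx(tau * factor, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            cs.mean_relaxation_time(100.0, 0.0)
        with pytest.raises(ValueError):
            cs.mean_relaxation_time(-1.0, 1.0)


class TestRelaxationRatio:
    def fit(self, tau, beta=1.0, span=1e4, converged=True):
        return cs.StretchedExpFit(c0=6, c_inf=2, tau=tau, beta=beta,
                                  residual_norm=0.0, converged=converged,
                                  t_span=span)

    def test_no_fence_gives_unity(self):
        free = self.fit(1e3)
        xi, blocked = cs.relaxation_ratio(free, free)
        assert xi == 1.0 and not blocked

    def test_sixfold_retardation(self):
        free = self.fit(1e3)
        slow = self.fit(6e3)
        xi, _ = cs.relaxation_ratio(slow, free)
        assert xi == pytest.approx(1 / 6)

    def test_blockade_reports_zero(self):
        free = self.fit(1e3)
        blocked_fit = self.fit(1e7, span=1e4)  # mean tau > 100x span
        xi, blocked = cs.relaxation_ratio(blocked_fit, free)
        assert xi == 0.0 and blocked
        failed = self.fit(1e3, converged=False)
        xi, blocked = cs.relaxation_ratio(failed, free)
        assert xi == 0.0 and blocked


class TestPMF:
    def test_uniform_equilibrium_gives_flat_pmf(self):
        geo = cs.SystemGeometry(box_x_lo=-100.0, box_x_hi=100.0,
                                box_y_lo=-50.0, box_y_hi=50.0)
        # uniform 2%: count per 5 A bin = 0.02 * (5*100)/65
        n_frames, per_bin = 4000, 0.02 * 500 / 65
        n = int(round(per_bin * 40))
        rng = np.random.default_rng(0)
        pos = np.zeros((n_frames, n, 3))
        pos[:, :, 0] = rng.uniform(-100, 100, size=(n_frames, n))
        prof = cs.pmf_1d([traj_from_positions(np.arange(n_frames), pos)], geo)
        assert np.nanmax(np.abs(prof.w[~prof.capped])) < 0.1
        assert abs(prof.w[~prof.capped].mean()) < 0.02

    def test_depleted_bin_carries_positive_barrier(self):
        """Concentration 2%/e in one bin -> W = +k_B T there."""
        conc = np.array([2.0, 2.0 / np.e, 2.0])
        kT = BOLTZMANN_KCAL * 300
        w = -kT * np.log(conc / 2.0)
        assert w[1] == pytest.approx(kT, rel=1e-12)
        assert w[1] == pytest.approx(0.596, abs=5e-3)

    def test_boltzmann_inversion_recovers_imposed_potential(self, pip2):
        """LD tracers in an imposed Gaussian barrier: PMF matches it."""
        geo = cs.SystemGeometry(box_x_lo=-100.0, box_x_hi=100.0,
                                box_y_lo=-30.0, box_y_hi=30.0)
        params = cs.IntegratorParams(friction=0.1, temperature=300.0, timestep=0.01)
        rng = np.random.default_rng(2)
        n = 150
        amp, x0, sigma = 1.0, 0.0, 12.0
        kT = BOLTZMANN_KCAL * 300.0
        # start from the imposed Boltzmann density (rejection sampling) so
        # the run only needs to maintain equilibrium, not reach it
        xs = []
        while len(xs) < n:
            x = rng.uniform(-98, 98)
            u = amp * np.exp(-0.5 * ((x - x0) / sigma) ** 2)
            if rng.uniform() < np.exp(-u / kT):
                xs.append(x)
        pos = np.zeros((n, 3))
        pos[:, 0] = xs
        pos[:, 1] = rng.uniform(-25, 25, n)
        traj = cs.run_replica(
            pos, pip2, geo, params, n_steps=1_500_000, snapshot_every=400,
            seed=8, pair_interactions=False,
            external_gaussian=(amp, x0, sigma),
        )
        prof = cs.pmf_1d([traj], geo, bin_width=10.0, equilibration_fraction=0.1)
        imposed = amp * np.exp(-0.5 * ((prof.x - x0) / sigma) ** 2)
        # reference both to their flat far regions
        far = np.abs(prof.x) > 60
        w = prof.w - prof.w[far].mean()
        assert np.max(np.abs(w - imposed)) < 0.1

    def test_all_empty_profile_rejected(self):
        geo = cs.SystemGeometry(box_x_lo=-100.0, box_x_hi=100.0,
                                box_y_lo=-50.0, box_y_hi=50.0)
        pos = np.zeros((0, 5, 3))
        with pytest.raises(ValueError):
            cs.pmf_1d([traj_from_positions(np.zeros(0), pos)], geo)


class TestMsdDiffusion:
    def test_static_particles_have_zero_diffusion(self):
        pos = np.zeros((50, 8, 3))
        traj = traj_from_positions(np.arange(50.0), pos)
        assert cs.msd_diffusion(traj) == 0.0

    def test_short_window_rejected(self):
        pos = np.zeros((50, 8, 3))
        traj = traj_from_positions(np.arange(50.0), pos)
        with pytest.raises(ValueError):
            cs.msd_diffusion(traj, fit_window=(0.0, 5.0), friction=0.1)

    def test_halving_friction_doubles_diffusion(self):
        d1 = cs.diffusion_constant_cm2_per_s(300, 1043, 1.0)
        d2 = cs.diffusion_constant_cm2_per_s(300, 1043, 0.5)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)


class TestBurialHistogram:
    def atoms(self, zs, residues):
        n = len(zs)
        from corralsim.fences import RESIDUE_FORMAL_CHARGE

        charges = np.array([RESIDUE_FORMAL_CHARGE.get(r, 0.0) for r in residues])
        return cs.FenceAtoms(
            coords=np.column_stack([np.zeros(n), np.arange(n, dtype=float), zs]),
            charges=charges, radii=np.full(n, 2.0), residues=list(residues),
        )

    def test_no_charged_residues_gives_empty_histogram(self):
        atoms = self.atoms(np.array([-8.0, -9.0]), ["LEU", "PHE"])
        _, counts = cs.burial_histogram(atoms, hydrophobic_boundary=-5.0)
        assert counts.sum() == 0

    def test_single_buried_lysine_lands_in_third_bin(self):
        atoms = self.atoms(np.array([-7.5]), ["LYS"])  # 2.5 A below the -5 boundary
        edges, counts = cs.burial_histogram(atoms, hydrophobic_boundary=-5.0)
        assert counts.sum() == 1
        assert counts[2] == 1  # depth bin [2, 3): the third 1-A slab

    def test_raising_filament_never_increases_burial(self):
        rng = np.random.default_rng(5)
        zs = rng.uniform(-20, 5, 30)
        residues = [("LYS", "ASP", "LEU")[i % 3] for i in range(30)]
        atoms = self.atoms(zs, residues)
        totals = []
        for zmin in (-15.0, -10.0, -5.0, 0.0):
            buried = cs.bury_filament(atoms, zmin)
            _, counts = cs.burial_histogram(buried, hydrophobic_boundary=-5.0)
            totals.append(counts.sum())
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_missing_labels_rejected(self):
        atoms = cs.FenceAtoms(coords=np.zeros((2, 3)), charges=np.zeros(2),
                              radii=np.ones(2))
        atoms.residues = []
        with pytest.raises(ValueError):
            cs.burial_histogram(atoms)
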