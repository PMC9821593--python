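"""Binding classification, residence statistics, RDFs and pair energies
against scripted ground truth and brute-force oracles."""

import numpy as np
import pytest
from scipy import constants as const

from dendrikit import (
    BindingScript,
    BindingSeries,
    EllipsoidSpec,
    Frame,
    Trajectory,
    bound_count_series,
    classify_binding,
    com_rdf,
    make_binding_trajectory,
    make_ellipsoid_cloud,
    mean_pair_energy,
    pair_interaction_energy,
    residence_summary,
)
from dendrikit.binding import F_COULOMB

from conftest import static_trajectory, two_group_topology


def _one_pair_traj(distance_nm, **top_kw):
    """Single dendrimer atom at the origin, single-atom ligand on x."""
    top = two_group_topology(1, [1], **top_kw)
    coords = np.array([[0.0, 0, 0], [distance_nm, 0, 0]])
    return static_trajectory([coords], top)


class TestClassify:
    def test_strict_cutoff(self):
        # 3.4 A is bound, exactly 3.5 A is not ("less than", strict)
        assert classify_binding(_one_pair_traj(0.34)).bound[0, 0]
        assert not classify_binding(_one_pair_traj(0.35)).bound[0, 0]

    def test_any_atom_rule(self):
        # a two-atom ligand binds through its closest atom
        top = two_group_topology(1, [2])
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.3, 0, 0]])
        bs = classify_binding(static_trajectory([coords], top))
        assert bs.bound[0, 0]

    def test_minimum_image_distances(self):
        # across a 4 nm box, atoms at x = 0.1 and 3.9 are 0.2 nm apart
        top = two_group_topology(1, [1], box=np.array([4.0, 4.0, 4.0]))
        coords = np.array([[0.1, 1, 1], [3.9, 1, 1]])
        bs = classify_binding(static_trajectory([coords], top))
        assert bs.bound[0, 0]

    def test_monotone_in_cutoff(self, rng):
        top = two_group_topology(20, [1] * 15)
        coords = rng.uniform(0, 2.0, (35, 3))
        traj = static_trajectory([coords], top)
        prev = None
        for cutoff in (2.0, 3.5, 6.0, 10.0):
            cur = classify_binding(traj, cutoff=cutoff).bound
            if prev is not None:
                assert np.all(cur[prev])  # bound set grows with the cutoff
            prev = cur

    def test_no_ligands_rejected(self):
        top = two_group_topology(3, [])
        traj = static_trajectory([np.zeros((3, 3))], top)
        with pytest.raises(ValueError, match="no ligand"):
            classify_binding(traj)


class TestGeneratorOracle:
    """The scripted generator's truth is the classifier's oracle."""

    @staticmethod
    def _random_script(rng, n_ligands=8, t_end=10.0):
        intervals = []
        for _ in range(n_ligands):
            ivals, t = [], 0.0
            while t < t_end and rng.random() < 0.7:
                t_on = t + rng.uniform(0, 3)
                t_off = t_on + rng.uniform(0.3, 4)
                if t_on >= t_end:
                    break
                ivals.append((t_on, min(t_off, t_end + 0.1)))
                t = t_off + 0.2
            intervals.append(ivals)
        return BindingScript(n_ligands=n_ligands, intervals=intervals,
                             seed=int(rng.integers(2**31)))

    def test_classifier_recovers_script_exactly(self):
        dend, _, _ = make_ellipsoid_cloud(EllipsoidSpec((1.5,) * 3, n_beads=40, seed=5))
        master = np.random.default_rng(99)
        for _ in range(100):
            script = self._random_script(master)
            traj, truth = make_binding_trajectory(script, dt=0.2, t_end=10.0,
                                                  dendrimer=dend)
            bs = classify_binding(traj)
            np.testing.assert_array_equal(bs.bound, truth.bound)

    def test_empty_script_never_bound(self):
        dend, _, _ = make_ellipsoid_cloud(EllipsoidSpec((1.5,) * 3, n_beads=30, seed=3))
        script = BindingScript(n_ligands=4, intervals=[[] for _ in range(4)])
        traj, truth = make_binding_trajectory(script, dt=0.5, t_end=5.0, dendrimer=dend)
        bs = classify_binding(traj)
        assert not bs.bound.any() and not truth.bound.any()


class TestBoundCounts:
    def test_all_unbound_gives_zeros(self):
        bs = BindingSeries(cutoff=3.5, times=np.arange(5.0),
                           bound=np.zeros((3, 5), dtype=bool))
        counts, mean = bound_count_series(bs)
        assert np.all(counts == 0) and mean == 0.0

    def test_alternating_ligands(self):
        # three ligands bound in disjoint alternating frames
        bound = np.array([[1, 0, 1, 0], [0, 1, 0, 1], [0, 1, 0, 0]], dtype=bool)
        bs = BindingSeries(cutoff=3.5, times=np.arange(4.0), bound=bound)
        counts, _ = bound_count_series(bs)
        np.testing.assert_array_equal(counts, [1, 2, 1, 1])

    def test_window_mean_matches_scripted_occupancy(self):
        # two ligands each bound in half the window -> mean 1.0
        bound = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=bool)
        bs = BindingSeries(cutoff=3.5, times=np.arange(4.0), bound=bound)
        _, mean = bound_count_series(bs, window=(0.0, 3.0))
        assert mean == 1.0


class TestResidence:
    @staticmethod
    def _series(bound, dt=1.0):
        bound = np.asarray(bound, dtype=bool)
        return BindingSeries(cutoff=3.5, times=np.arange(bound.shape[1]) * dt,
                             bound=bound)

    def test_full_span_ligand_is_persistent(self):
        bs = self._series(np.ones((1, 101), dtype=bool))  # bound 0..100 ns
        rs = residence_summary(bs, window=(90.0, 100.0), tau=10.0)
        assert rs.n_long == 1 and rs.n_short == 0

    def test_two_short_runs_are_transient(self):
        # two 3 ns runs inside a 10 ns window, tau = 10 -> transient
        flags = np.zeros((1, 101), dtype=bool)
        flags[0, 90:94] = True   # 90..93 ns (3 ns run)
        flags[0, 96:100] = True  # 96..99 ns (3 ns run)
        rs = residence_summary(self._series(flags), window=(90.0, 100.0))
        assert rs.n_long == 0 and rs.n_short == 1

    def test_run_entering_window_from_before_counts_long(self):
        flags = np.zeros((1, 101), dtype=bool)
        flags[0, 60:92] = True  # 31 ns run ending just inside the window
        rs = residence_summary(self._series(flags), window=(90.0, 100.0))
        assert rs.n_long == 1

    def test_run_of_exactly_tau_is_transient(self):
        flags = np.zeros((1, 101), dtype=bool)
        flags[0, 90:101] = True  # spans exactly 10 ns, not more
        rs = residence_summary(self._series(flags), window=(90.0, 100.0))
        assert rs.n_long == 0 and rs.n_short == 1

    def test_partition_property_random_series(self, rng):
        # N_long + N_short equals distinct binders in the window, always
        for _ in range(1000):
            n_lig, n_fr = rng.integers(1, 6), rng.integers(5, 30)
            bound = rng.random((n_lig, n_fr)) < 0.4
            bs = self._series(bound, dt=0.7)
            lo = int(rng.integers(0, n_fr - 1))
            hi = int(rng.integers(lo + 1, n_fr))
            window = (lo * 0.7, hi * 0.7)
            tau = float(rng.uniform(0.5, 5))
            rs = residence_summary(bs, window=window, tau=tau)
            distinct = int(bound[:, lo:hi + 1].any(axis=1).sum())
            assert rs.n_long + rs.n_short == distinct

    def test_nonpositive_tau_rejected(self):
        bs = self._series(np.ones((1, 5), dtype=bool))
        with pytest.raises(ValueError, match="tau"):
            residence_summary(bs, tau=0.0)


class TestRDF:
    @staticmethod
    def _traj_with_ligand_radii(radii_nm, n_frames=1, jitter=0.0, seed=0):
        """Single heavy dendrimer atom at the origin plus one-bead ligands
        at the given COM radii."""
        rng = np.random.default_rng(seed)
        n_lig = len(radii_nm)
        top = two_group_topology(1, [1] * n_lig)
        frames = []
        for _ in range(n_frames):
            v = rng.normal(size=(n_lig, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            r = np.asarray(radii_nm) + rng.uniform(-jitter, jitter, n_lig)
            frames.append(np.vstack([np.zeros(3), v * r[:, None]]))
        return static_trajectory(frames, top)

    def test_uniform_cloud_is_flat(self, rng):
        # ligand COMs uniform in the analysis sphere -> g ~ 1
        n_lig, n_frames, r_max_nm = 200, 60, 4.0
        top = two_group_topology(1, [1] * n_lig)
        frames = []
        for _ in range(n_frames):
            v = rng.normal(size=(n_lig, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            r = r_max_nm * rng.random(n_lig) ** (1 / 3)
            frames.append(np.vstack([np.zeros(3), v * r[:, None]]))
        rdf = com_rdf(static_trajectory(frames, top), bin_width=2.0, r_max=40.0)
        outer = rdf.bin_centers > 15.0  # bins with enough expected counts
        assert np.all(np.abs(rdf.g[outer] - 1.0) < 0.25)
        assert np.all(rdf.g >= 0)

    def test_scripted_shell_peaks(self):
        # populations at 5 A and 13 A -> two sharp peaks at those bins
        traj = self._traj_with_ligand_radii([0.5] * 10 + [1.3] * 10,
                                            n_frames=4, jitter=0.02)
        rdf = com_rdf(traj, bin_width=1.0, r_max=30.0)
        occupied = set(np.nonzero(rdf.counts > 0)[0])
        assert occupied <= {4, 5, 12, 13}  # 5 A and 13 A bins (+-bin_width)
        assert rdf.counts[[4, 5]].sum() > 0 and rdf.counts[[12, 13]].sum() > 0

    def test_rebinning_conserves_counts(self):
        traj = self._traj_with_ligand_radii([0.5, 0.9, 1.3, 2.2, 3.1], n_frames=3)
        fine = com_rdf(traj, bin_width=1.0, r_max=40.0)
        coarse = com_rdf(traj, bin_width=2.0, r_max=40.0)
        assert fine.counts.sum() == coarse.counts.sum()

    def test_zero_frame_window_rejected(self):
        traj = self._traj_with_ligand_radii([1.0])
        with pytest.raises(ValueError, match="no frames"):
            com_rdf(traj, window=(99.0, 100.0))


def _coulomb_factor_from_constants():
    """Independent derivation: e^2 N_A / (4 pi eps0), in kJ mol^-1 nm e^-2."""
    f_joule_metre = const.e ** 2 * const.Avogadro / (4 * np.pi * const.epsilon_0)
    return f_joule_metre * 1e9 / 1e3


class TestPairEnergy:
    def test_coulomb_factor_matches_independent_derivation(self):
        assert F_COULOMB == pytest.approx(_coulomb_factor_from_constants(), rel=1e-7)

    def test_lj_zero_crossing_and_minimum(self):
        sigma = np.array([0.3, 0.3])
        eps = np.array([0.5, 0.5])
        q = np.zeros(2)
        top = two_group_topology(1, [1])
        at_sigma = Frame(np.array([[0.0, 0, 0], [0.3, 0, 0]]))
        pe = pair_interaction_energy(at_sigma, top, sigma, eps, q)
        assert pe.lj == pytest.approx(0.0, abs=1e-12)
        at_min = Frame(np.array([[0.0, 0, 0], [2 ** (1 / 6) * 0.3, 0, 0]]))
        pe = pair_interaction_energy(at_min, top, sigma, eps, q)
        assert pe.lj == pytest.approx(-0.5, rel=1e-12)
        assert pe.total == pytest.approx(pe.lj + pe.coul, abs=1e-9)

    def test_unit_charges_at_one_nm(self):
        top = two_group_topology(1, [1])
        fr = Frame(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        pe = pair_interaction_energy(fr, top, np.zeros(2), np.zeros(2),
                                     np.array([1.0, -1.0]))
        assert pe.coul == pytest.approx(-_coulomb_factor_from_constants(), rel=1e-7)
        assert pe.lj == 0.0

    def test_missing_charges_refused(self):
        traj = _one_pair_traj(0.5)
        with pytest.raises(ValueError, match="topology config"):
            pair_interaction_energy(traj.frames[0], traj.topology,
                                    np.ones(2) * 0.3, np.ones(2) * 0.1)

    @staticmethod
    def _brute_force(coords, dend, lig_atoms, sigma, eps, q, cutoff):
        e_lj = e_coul = 0.0
        for i in dend:
            for j in lig_atoms:
                r = float(np.linalg.norm(coords[i] - coords[j]))
                if r >= cutoff:
                    continue
                s = 0.5 * (sigma[i] + sigma[j])
                e = np.sqrt(eps[i] * eps[j])
                sr6 = (s / r) ** 6
                e_lj += 4 * e * (sr6 ** 2 - sr6)
                e_coul += F_COULOMB * q[i] * q[j] / r
        return e_lj, e_coul

    def test_matches_all_pairs_brute_force(self, rng):
        n_d, lig_sizes = 60, [3] * 20
        top = two_group_topology(n_d, lig_sizes)
        n = top.atom_count
        coords = rng.uniform(0, 2.5, (n, 3))
        sigma = rng.uniform(0.25, 0.4, n)
        eps = rng.uniform(0.1, 1.0, n)
        q = rng.uniform(-0.8, 0.8, n)
        pe = pair_interaction_energy(Frame(coords), top, sigma, eps, q, cutoff=1.2)
        lig_atoms = np.concatenate(top.ligand_molecules)
        lj_ref, coul_ref = self._brute_force(coords, top.dendrimer_atoms,
                                             lig_atoms, sigma, eps, q, 1.2)
        assert pe.lj == pytest.approx(lj_ref, rel=1e-9)
        assert pe.coul == pytest.approx(coul_ref, rel=1e-9)
        assert pe.per_ligand_mean == pytest.approx(pe.total / 20, rel=1e-12)

    def test_symmetric_under_group_exchange(self, rng):
        coords = rng.uniform(0, 1.5, (12, 3))
        sigma = rng.uniform(0.25, 0.4, 12)
        eps = rng.uniform(0.1, 1.0, 12)
        q = rng.uniform(-0.5, 0.5, 12)
        top_a = two_group_topology(6, [6])
        from dendrikit import Topology
        top_b = Topology(atom_count=12, masses=np.ones(12),
                         dendrimer_atoms=np.arange(6, 12),
                         ligand_molecules=[np.arange(6)])
        pa = pair_interaction_energy(Frame(coords), top_a, sigma, eps, q)
        pb = pair_interaction_energy(Frame(coords), top_b, sigma, eps, q)
        assert pa.lj == pytest.approx(pb.lj, rel=1e-12)
        assert pa.coul == pytest.approx(pb.coul, rel=1e-12)

    def test_mean_energy_bound_only_averaging(self):
        # one bound attractive ligand, one far ligand outside the cutoff:
        # "bound" averaging divides by 1, "all" by 2
        top = two_group_topology(1, [1, 1])
        coords = np.array([[0.0, 0, 0], [0.3, 0, 0], [5.0, 0, 0]])
        traj = static_trajectory([coords], top)
        sigma = np.full(3, 0.25)
        eps = np.full(3, 0.4)
        q = np.zeros(3)
        pe_b = mean_pair_energy(traj, lj_sigma=sigma, lj_epsilon=eps, charges=q,
                                averaging="bound")
        pe_a = mean_pair_energy(traj, lj_sigma=sigma, lj_epsilon=eps, charges=q,
                                averaging="all")
        assert pe_b.total == pytest.approx(pe_a.total, rel=1e-12)
        assert pe_b.per_ligand_mean == pytest.approx(2 * pe_a.per_ligand_mean, rel=1e-12)
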