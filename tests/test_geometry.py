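"""Macro-trajectory assembly, SASA, distance series and persistence."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from e2dyn.core import Structure, TrajectoryEnsemble
from e2dyn.errors import ConfigurationError, InvalidArgumentError, SelectionError
from e2dyn.geometry import (
    VDW_RADII,
    contact_persistence,
    distance_series,
    preprocess_macro_trajectory,
    sasa_shrake_rupley,
    sasa_series,
)
from e2dyn.synthetic import (
    SpectrumSpec,
    internal_mode_basis,
    make_ca_chain,
    make_contact_series,
    sample_gaussian_ensemble,
)


def _atoms(elements, coords, names=None):
    n = len(elements)
    return Structure(
        serial=np.arange(1, n + 1),
        name=np.array(names if names else ["X"] * n),
        element=np.array(elements),
        res_name=np.array(["UNK"] * n),
        res_id=np.arange(1, n + 1),
        chain_id=np.array(["A"] * n),
        coords=np.asarray(coords, dtype=float),
    )


def _replicate(chain, n_frames, seed):
    spec = SpectrumSpec(eigenvalues=np.array([0.004, 0.002]), n_atoms=chain.n_atoms)
    basis = internal_mode_basis(chain, 2, seed=seed)
    return sample_gaussian_ensemble(chain, spec, basis, n_frames, seed=seed)


class TestMacroTrajectory:
    def test_trim_and_concatenate(self):
        chain = make_ca_chain(10, seed=0)
        reps = [_replicate(chain, 100, 1), _replicate(chain, 100, 2)]
        macro = preprocess_macro_trajectory(reps, trim=10)
        assert macro.n_frames == 180

    def test_zero_trim_concatenates_only(self):
        chain = make_ca_chain(10, seed=0)
        reps = [_replicate(chain, 30, 1), _replicate(chain, 50, 2)]
        macro = preprocess_macro_trajectory(reps, trim=0)
        assert macro.n_frames == 80
        assert np.array_equal(macro.coords[:30], reps[0].coords)
        assert np.array_equal(macro.coords[30:], reps[1].coords)

    def test_replicate_provenance(self):
        chain = make_ca_chain(10, seed=0)
        reps = [_replicate(chain, 100, 1), _replicate(chain, 100, 2)]
        macro = preprocess_macro_trajectory(reps, trim=10)
        assert np.all(macro.replicate_ids[:90] == 1)
        assert np.all(macro.replicate_ids[90:] == 2)

    def test_fractional_trim(self):
        chain = make_ca_chain(10, seed=0)
        reps = [_replicate(chain, 50, 1)]
        macro = preprocess_macro_trajectory(reps, trim=0.1)
        assert macro.n_frames == 45

    def test_trim_longer_than_replicate_names_it(self):
        chain = make_ca_chain(10, seed=0)
        reps = [_replicate(chain, 100, 1), _replicate(chain, 20, 2)]
        with pytest.raises(InvalidArgumentError, match="replicate 2"):
            preprocess_macro_trajectory(reps, trim=50)


class TestSasa:
    def test_isolated_atom_matches_analytic_sphere(self):
        st = _atoms(["C"], [[0.0, 0.0, 0.0]])
        expected = 4 * np.pi * (VDW_RADII["C"] + 0.14) ** 2
        assert sasa_shrake_rupley(st, [0], n_points=960) == pytest.approx(expected,
                                                                          rel=0.02)
        assert sasa_shrake_rupley(st, [0], n_points=3840) == pytest.approx(expected,
                                                                           rel=0.01)

    def test_coincident_atoms_fully_buried(self):
        st = _atoms(["C", "C"], [[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        assert sasa_shrake_rupley(st, [0]) == pytest.approx(0.0, abs=1e-12)

    def test_separated_atoms_have_two_full_spheres(self):
        r_exp = VDW_RADII["C"] + 0.14
        st = _atoms(["C", "C"], [[0.0, 0.0, 0.0], [2.5 * r_exp, 0.0, 0.0]])
        expected = 2 * 4 * np.pi * r_exp**2
        assert sasa_shrake_rupley(st, [0, 1]) == pytest.approx(expected, rel=0.02)

    def test_monotone_burial_on_approach(self):
        r_exp = VDW_RADII["C"] + 0.14
        separations = np.linspace(2 * r_exp, 0.0, 9)
        areas = []
        for d in separations:
            st = _atoms(["C", "C"], [[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
            areas.append(sasa_shrake_rupley(st, [0]))
        full = 4 * np.pi * r_exp**2
        # monotone decrease within point-sampling noise (2% of the full sphere)
        assert all(a2 <= a1 + 0.02 * full for a1, a2 in zip(areas, areas[1:]))
        assert areas[-1] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_element_is_configuration_error(self):
        st = _atoms(["C", "ZZ"], [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        with pytest.raises(ConfigurationError, match="ZZ"):
            sasa_shrake_rupley(st, [0])

    def test_empty_selection_rejected(self):
        st = _atoms(["C"], [[0.0, 0.0, 0.0]])
        with pytest.raises(SelectionError):
            sasa_shrake_rupley(st, np.array([], dtype=int))

    def test_agrees_with_biotite_on_partial_occlusion(self):
        # independent oracle: biotite's implementation with identical radii on
        # a two-atom case away from degenerate geometry
        import biotite.structure as struc

        d = 0.35
        st = _atoms(["C", "N"], [[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        ours = sasa_shrake_rupley(st, [0], n_points=3840)
        arr = struc.AtomArray(2)
        arr.coord = (st.coords * 10).astype(np.float32)
        arr.element = st.element
        arr.res_id = st.res_id
        arr.res_name = st.res_name
        arr.atom_name = st.name
        arr.chain_id = st.chain_id
        radii_angstrom = np.array([VDW_RADII["C"] * 10, VDW_RADII["N"] * 10])
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=3840,
                            vdw_radii=radii_angstrom,
                            atom_filter=np.array([True, False]))[0] / 100.0
        assert ours == pytest.approx(theirs, rel=0.02)

    def test_per_replicate_summary(self):
        ens = make_contact_series([True] * 4 + [False] * 4, 0.3, 0.8)
        ens.replicate_ids = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        series = sasa_series(ens, [0], n_points=240)
        assert set(series.per_replicate_mean) == {1, 2}
        assert series.values.shape == (8,)
        assert np.all(series.values > 0)


class TestDistanceSeries:
    def test_constant_pair(self):
        ens = make_contact_series([True] * 10, 0.35, 0.8)
        series = distance_series(ens, [0], [1], mode="named-pair")
        assert np.allclose(series.distances, 0.35, atol=1e-12)

    def test_min_heavy_matches_brute_force(self):
        rng = np.random.default_rng(21)
        st = _atoms(["C", "N", "O", "S", "C", "H"], rng.uniform(0, 2, (6, 3)))
        coords = rng.uniform(0, 2, (7, 6, 3))
        ens = TrajectoryEnsemble(topology=st, coords=coords)
        series = distance_series(ens, [0, 1, 2], [3, 4, 5], mode="min-heavy")
        for f in range(7):
            brute = min(
                np.linalg.norm(coords[f, i] - coords[f, j])
                for i in (0, 1, 2) for j in (3, 4)      # hydrogen excluded
            )
            assert series.distances[f] == pytest.approx(brute, abs=1e-12)

    def test_overlapping_groups_rejected(self):
        ens = make_contact_series([True] * 3, 0.3, 0.8)
        with pytest.raises(SelectionError):
            distance_series(ens, [0, 1], [1])

    def test_named_pair_requires_single_atoms(self):
        st = _atoms(["C"] * 4, np.arange(12).reshape(4, 3))
        ens4 = TrajectoryEnsemble(topology=st,
                                  coords=np.arange(12, dtype=float).reshape(1, 4, 3))
        with pytest.raises(SelectionError):
            distance_series(ens4, [0, 1], [2], mode="named-pair")

    def test_distances_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(22)
        st = _atoms(["C", "N", "O"], rng.uniform(0, 1, (3, 3)))
        coords = rng.uniform(0, 1, (5, 3, 3))
        ens = TrajectoryEnsemble(topology=st, coords=coords)
        base = distance_series(ens, [0], [1, 2]).distances
        moved = np.array([
            Rotation.random(random_state=rng).apply(f) + rng.uniform(-3, 3, 3)
            for f in coords
        ])
        ens2 = TrajectoryEnsemble(topology=st, coords=moved)
        assert np.abs(distance_series(ens2, [0], [1, 2]).distances - base).max() < 1e-10


class TestPersistence:
    def test_all_frames_below_cutoff(self):
        # a tight ion pair present in every frame of the simulation
        ens = make_contact_series([True] * 20, 0.38, 0.8)
        series = distance_series(ens, [0], [1], mode="named-pair")
        assert contact_persistence(series, 0.48).persistence == 1.0

    def test_all_frames_beyond_cutoff(self):
        ens = make_contact_series([False] * 20, 0.38, 0.70)
        series = distance_series(ens, [0], [1], mode="named-pair")
        assert contact_persistence(series, 0.48).persistence == 0.0

    def test_frame_permutation_invariance(self):
        rng = np.random.default_rng(23)
        pattern = list(rng.random(40) < 0.4)
        ens = make_contact_series(pattern, 0.3, 0.8)
        series = distance_series(ens, [0], [1], mode="named-pair")
        base = contact_persistence(series, 0.48).persistence
        perm = rng.permutation(40)
        from e2dyn.geometry import ContactSeries

        shuffled = ContactSeries(distances=series.distances[perm])
        assert contact_persistence(shuffled, 0.48).persistence == base

    def test_positive_cutoff_required(self):
        ens = make_contact_series([True] * 3, 0.3, 0.8)
        series = distance_series(ens, [0], [1], mode="named-pair")
        with pytest.raises(InvalidArgumentError):
            contact_persistence(series, 0.0)

    def test_hbond_angle_criterion(self):
        # donor-H...acceptor: linear geometry passes, right-angle geometry fails
        st = _atoms(["N", "H", "O"],
                    [[0.0, 0.0, 0.0], [0.1, 0.0, 0.0], [0.29, 0.0, 0.0]],
                    names=["N", "H1", "O"])
        linear = np.tile(st.coords, (4, 1, 1))
        bent = linear.copy()
        bent[2:, 2] = [[0.1, 0.19, 0.0]] * 2      # acceptor at 90 deg from donor
        ens = TrajectoryEnsemble(topology=st, coords=np.concatenate([linear[:2],
                                                                     bent[2:]]))
        series = distance_series(ens, [0], [2], mode="named-pair")
        result = contact_persistence(series, cutoff=0.48, hbond=(0, 1, 2),
                                     ensemble=ens)
        assert np.array_equal(result.contacts, [True, True, False, False])
        assert result.persistence == 0.5

    def test_hbond_requires_hydrogen(self):
        st = _atoms(["N", "C", "O"],
                    [[0.0, 0.0, 0.0], [0.1, 0.0, 0.0], [0.3, 0.0, 0.0]])
        ens = TrajectoryEnsemble(topology=st, coords=st.coords[None])
        series = distance_series(ens, [0], [2], mode="named-pair")
        with pytest.raises(ConfigurationError):
            contact_persistence(series, hbond=(0, 1, 2), ensemble=ens)
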