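"""Generator ground truth: structures, Gaussian ensembles, families, fixtures."""
import numpy as np
import pytest
from scipy.spatial.distance import pdist

from e2dyn.compare import rmsip
from e2dyn.errors import InvalidArgumentError
from e2dyn.synthetic import (
    IndelSpec,
    PerturbationSpec,
    SpectrumSpec,
    internal_mode_basis,
    make_ca_chain,
    make_contact_series,
    make_cosine_trajectory,
    make_homolog_set,
    make_toy_structure,
    make_variant_family,
    sample_gaussian_ensemble,
)


class TestToyStructure:
    def test_atom_and_residue_counts(self):
        st = make_toy_structure(5, 1)
        assert st.n_atoms == 10
        assert st.n_residues == 5

    def test_deterministic(self):
        a = make_toy_structure(5, 1)
        b = make_toy_structure(5, 1)
        assert np.array_equal(a.coords, b.coords)

    @pytest.mark.parametrize("n,seed", [(2, 7), (5, 1), (30, 3), (64, 12)])
    def test_self_avoiding(self, n, seed):
        # brute-force pairwise check: all inter-atom distances exceed 0.2 nm
        st = make_toy_structure(n, seed)
        assert pdist(st.coords).min() > 0.2

    def test_too_few_residues(self):
        with pytest.raises(InvalidArgumentError):
            make_toy_structure(1, 0)

    def test_sequence_names_residues(self):
        st = make_toy_structure(3, 0, sequence="SPA")
        assert list(st.res_name[::2]) == ["SER", "PRO", "ALA"]


class TestGaussianEnsemble:
    def test_zero_spectrum_reproduces_mean(self, chain40):
        spec = SpectrumSpec(eigenvalues=np.zeros(5), n_atoms=40)
        basis = internal_mode_basis(chain40, 5, seed=1)
        ens = sample_gaussian_ensemble(chain40, spec, basis, 10, seed=2)
        assert np.allclose(ens.coords, chain40.coords[None], atol=0)

    def test_unit_variance_along_first_mode(self, chain40):
        spec = SpectrumSpec(eigenvalues=np.array([1.0, 0.0]), n_atoms=40)
        basis = internal_mode_basis(chain40, 2, seed=1)
        ens = sample_gaussian_ensemble(chain40, spec, basis, 10000, seed=3)
        proj = (ens.coords.reshape(10000, -1) - chain40.coords.ravel()) @ basis[:, 0]
        assert abs(proj.var() - 1.0) < 0.05

    def test_seeds_differ_but_mean_agrees(self, chain40):
        spec = SpectrumSpec(eigenvalues=np.array([0.01]), n_atoms=40)
        basis = internal_mode_basis(chain40, 1, seed=1)
        a = sample_gaussian_ensemble(chain40, spec, basis, 4000, seed=10)
        b = sample_gaussian_ensemble(chain40, spec, basis, 4000, seed=11)
        assert not np.array_equal(a.coords, b.coords)
        # projections have sd 0.1 nm; their means agree within 3 standard errors
        pa = (a.coords.reshape(4000, -1) - chain40.coords.ravel()) @ basis[:, 0]
        pb = (b.coords.reshape(4000, -1) - chain40.coords.ravel()) @ basis[:, 0]
        se = np.sqrt(pa.var() / 4000 + pb.var() / 4000)
        assert abs(pa.mean() - pb.mean()) < 3 * se

    def test_deterministic_given_seed(self, chain40):
        spec = SpectrumSpec(eigenvalues=np.array([0.01, 0.005]), n_atoms=40)
        basis = internal_mode_basis(chain40, 2, seed=1)
        a = sample_gaussian_ensemble(chain40, spec, basis, 50, seed=5)
        b = sample_gaussian_ensemble(chain40, spec, basis, 50, seed=5)
        assert np.array_equal(a.coords, b.coords)

    def test_rejects_non_orthonormal_basis(self, chain40):
        spec = SpectrumSpec(eigenvalues=np.array([0.01]), n_atoms=40)
        basis = 1.1 * internal_mode_basis(chain40, 1, seed=1)
        with pytest.raises(InvalidArgumentError):
            sample_gaussian_ensemble(chain40, spec, basis, 10, seed=0)


class TestVariantFamily:
    def test_identity_perturbation_ground_truth(self, separated_spectrum):
        fam = make_variant_family(separated_spectrum, [PerturbationSpec(angle=0.0)],
                                  n_frames=10, n_replicates=1, seed=1)
        assert fam[1].expected_rmsip == pytest.approx(1.0, abs=1e-12)

    def test_full_rotation_ground_truth_zero(self, separated_spectrum):
        fam = make_variant_family(separated_spectrum,
                                  [PerturbationSpec(angle=np.pi / 2)],
                                  n_frames=10, n_replicates=1, seed=1)
        assert fam[1].expected_rmsip == pytest.approx(0.0, abs=1e-12)

    def test_swap_preserves_span_and_moves_pc1(self, swap_family):
        ref, swapped = swap_family
        assert swapped.expected_rmsip == pytest.approx(1.0, abs=1e-12)
        # on the constructed bases, reference mode 1 is variant mode 4 exactly
        overlaps = (ref.modes[:, 0] @ swapped.modes) ** 2
        assert int(np.argmax(overlaps)) + 1 == 4

    def test_ground_truth_matches_rmsip_operation(self, angle_family):
        ref = angle_family[0]
        for member in angle_family:
            assert member.expected_rmsip == pytest.approx(
                rmsip(ref.modes, member.modes, ref.modes.shape[1]), abs=1e-12
            )

    def test_rotation_angle_sets_expected_rmsip(self, separated_spectrum):
        # pure rotation of every mode by angle a gives subspace overlap |cos a|
        for angle in (0.3, 0.8, 1.2):
            fam = make_variant_family(separated_spectrum,
                                      [PerturbationSpec(angle=angle)],
                                      n_frames=10, n_replicates=1, seed=2)
            assert fam[1].expected_rmsip == pytest.approx(np.cos(angle), abs=1e-12)

    def test_swap_index_beyond_spectrum(self, separated_spectrum):
        with pytest.raises(InvalidArgumentError):
            make_variant_family(separated_spectrum,
                                [PerturbationSpec(swap_map=((1, 11),))],
                                n_frames=10, n_replicates=1, seed=1)

    def test_replicates_and_labels(self, angle_family):
        assert [m.label for m in angle_family] == ["reference", "mild", "moderate",
                                                   "strong"]
        for member in angle_family:
            assert len(member.replicates) == 2
            assert {int(r.replicate_ids[0]) for r in member.replicates} == {1, 2}


class TestCosineTrajectory:
    def test_pc1_aligns_with_mode(self, mode20):
        from e2dyn.essential import essential_subspace

        chain, mode = mode20
        ens = make_cosine_trajectory(mode, 0.1, 500, mean=chain)
        sub = essential_subspace(ens)
        assert abs(sub.eigenvectors[:, 0] @ mode) > 0.999

    def test_projection_is_half_cosine(self, mode20):
        chain, mode = mode20
        ens = make_cosine_trajectory(mode, 0.1, 1000, mean=chain)
        proj = (ens.coords.reshape(1000, -1) - chain.coords.ravel()) @ mode
        t = np.arange(1000)
        assert np.allclose(proj, 0.1 * np.cos(np.pi * t / 999), atol=1e-12)

    def test_amplitude_doubling_quadruples_eigenvalue(self, mode20):
        from e2dyn.essential import essential_subspace

        chain, mode = mode20
        e1 = essential_subspace(make_cosine_trajectory(mode, 0.1, 400, mean=chain))
        e2 = essential_subspace(make_cosine_trajectory(mode, 0.2, 400, mean=chain))
        assert e2.eigenvalues[0] / e1.eigenvalues[0] == pytest.approx(4.0, rel=1e-6)

    def test_zero_mode_rejected(self):
        with pytest.raises(InvalidArgumentError):
            make_cosine_trajectory(np.zeros(60), 0.1, 100)

    def test_too_few_frames(self, mode20):
        chain, mode = mode20
        with pytest.raises(InvalidArgumentError):
            make_cosine_trajectory(mode, 0.1, 3, mean=chain)


class TestContactSeries:
    @pytest.mark.parametrize("pattern,expected", [
        ([True] * 3 + [False] * 7, 0.3),
        ([True] * 10, 1.0),
        ([False] * 10, 0.0),
    ])
    def test_designed_occupancy(self, pattern, expected):
        from e2dyn.geometry import contact_persistence, distance_series

        ens = make_contact_series(pattern, 0.30, 0.80)
        series = distance_series(ens, [0], [1], mode="named-pair")
        result = contact_persistence(series, cutoff=0.48)
        assert result.persistence == pytest.approx(expected, abs=1e-12)

    def test_empty_pattern_rejected(self):
        with pytest.raises(InvalidArgumentError):
            make_contact_series([], 0.3, 0.8)

    def test_bound_must_be_below_unbound(self):
        with pytest.raises(InvalidArgumentError):
            make_contact_series([True], 0.8, 0.3)


class TestHomologSet:
    def test_no_indels_all_columns_shared(self):
        hs = make_homolog_set(2, None, seed=1, core_length=10)
        assert hs.ground_truth.n_columns == 10
        assert hs.msa.n_columns == 10

    def test_deletion_excludes_column(self):
        hs = make_homolog_set(2, {1: IndelSpec(deletions=(5,))}, seed=1, core_length=10)
        assert len(hs.shared_core_columns) == 9
        assert 5 not in hs.shared_core_columns

    def test_insertion_gaps_other_systems_core_unchanged(self):
        hs = make_homolog_set(3, {0: IndelSpec(insertions=((4, 2),))}, seed=2,
                              core_length=10)
        assert hs.ground_truth.n_columns == 10          # common core unchanged
        assert hs.msa.n_columns == 12                    # 2 insertion columns added
        # the inserted columns are gaps in the systems that lack the insertion
        ins_cols = [c for c in range(12) if c not in hs.ground_truth.columns]
        for col in ins_cols:
            assert hs.msa.sequences[1][col] == "-"
            assert hs.msa.sequences[2][col] == "-"
            assert hs.msa.sequences[0][col] != "-"

    def test_all_columns_deleted_rejected(self):
        with pytest.raises(InvalidArgumentError):
            make_homolog_set(2, {0: IndelSpec(deletions=tuple(range(9)))},
                             seed=1, core_length=10)

    def test_structures_match_ungapped_sequences(self):
        hs = make_homolog_set(2, {1: IndelSpec(deletions=(0, 3))}, seed=3,
                              core_length=8)
        for sid, st in hs.structures.items():
            n_res = sum(1 for ch in hs.msa.sequence(sid) if ch != "-")
            assert st.n_residues == n_res


def test_ca_chain_minimum_size():
    with pytest.raises(InvalidArgumentError):
        make_ca_chain(2)


def test_spectrum_spec_validation():
    with pytest.raises(InvalidArgumentError):
        SpectrumSpec(eigenvalues=np.array([1.0, 2.0]), n_atoms=10)   # ascending
    with pytest.raises(InvalidArgumentError):
        SpectrumSpec(eigenvalues=np.array([-0.1]), n_atoms=10)       # negative
    with pytest.raises(InvalidArgumentError):
        SpectrumSpec(eigenvalues=np.ones(31), n_atoms=10)            # > 3N modes


def test_perturbation_spec_validation():
    with pytest.raises(InvalidArgumentError):
        PerturbationSpec(angle=2.0)                                   # > pi/2
    with pytest.raises(InvalidArgumentError):
        PerturbationSpec(swap_map=((1, 2), (2, 3)))                   # not disjoint
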