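"""Cross-subject ICA alignment: decomposition, NMI, matching, centrality."""
import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import skew

from netfalff.align import (
    build_similarity_matrix,
    centrality_and_permutation,
    consistency_filter,
    decompose_subject,
    group_map,
    match_components,
    nmi,
)
from netfalff.errors import DegenerateInputError
from netfalff.synthetic import generate_templates, synthesize_network_series
from netfalff.types import AlignedComponent, ComponentSet, SimilarityMatrix, VertexTimeSeries


def _mixture_scan(templates, rng, n_timepoints=128, noise_sd=0.05, subject_id="s"):
    k = templates.n_networks
    series = np.column_stack(
        [synthesize_network_series(n_timepoints, 2.0, 0.5, seed=rng) for _ in range(k)]
    )
    data = series @ templates.maps.T + noise_sd * rng.standard_normal(
        (n_timepoints, templates.n_vertices)
    )
    return VertexTimeSeries(data, tr=2.0, subject_id=subject_id), series


class TestDecompose:
    def test_recovers_disjoint_planted_maps(self, rng):
        templates = generate_templates(600, 3, seed=2)
        ts, _ = _mixture_scan(templates, rng)
        comp = decompose_subject(ts, 3, seed=0)
        corr = np.abs(np.corrcoef(comp.maps.T, templates.maps.T)[:3, 3:])
        ri, ci = linear_sum_assignment(-corr)
        assert (corr[ri, ci] >= 0.95).all()

    def test_maps_are_z_scored_and_sign_aligned(self, rng):
        templates = generate_templates(600, 3, seed=2)
        ts, _ = _mixture_scan(templates, rng)
        comp = decompose_subject(ts, 3, seed=0)
        np.testing.assert_allclose(comp.maps.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(comp.maps.std(axis=0), 1.0, atol=1e-6)
        assert (skew(comp.maps, axis=0) >= 0).all()

    def test_deterministic_given_seed(self, rng):
        templates = generate_templates(600, 3, seed=2)
        ts, _ = _mixture_scan(templates, rng)
        a = decompose_subject(ts, 3, seed=5)
        b = decompose_subject(ts, 3, seed=5)
        np.testing.assert_array_equal(a.maps, b.maps)

    def test_single_component_on_rank_one_signal(self, rng):
        templates = generate_templates(400, 1, seed=1)
        s = synthesize_network_series(128, 2.0, 0.5, seed=4)
        data = s[:, None] @ templates.maps.T + 1e-4 * rng.standard_normal((128, 400))
        comp = decompose_subject(VertexTimeSeries(data, tr=2.0), 1, seed=0)
        assert abs(np.corrcoef(comp.maps[:, 0], templates.maps[:, 0])[0, 1]) >= 0.999


class TestNMI:
    def test_self_similarity_is_one(self, rng):
        x = rng.standard_normal(5000)
        assert abs(nmi(x, x) - 1.0) < 1e-12

    def test_negation_invariance(self, rng):
        x = rng.standard_normal(5000)
        assert abs(nmi(x, -x) - nmi(x, x)) < 1e-12

    def test_shuffled_map_is_near_zero(self, rng):
        x = rng.standard_normal(20000)
        vals = []
        for _ in range(20):
            y = rng.permutation(x)
            vals.append(nmi(x, y))
        assert max(vals) < 0.1

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            nmi(np.zeros(1000), rng.standard_normal(1000))


def _toy_components(rng, n_subjects=2, n_ics=2, v=500):
    return [
        ComponentSet(
            subject_id=f"s{j}",
            maps=rng.standard_normal((v, n_ics)),
            courses=rng.standard_normal((10, n_ics)),
        )
        for j in range(n_subjects)
    ]


class TestSimilarityMatrix:
    def test_shape_symmetry_and_diagonal(self, rng):
        sim = build_similarity_matrix(_toy_components(rng))
        assert sim.values.shape == (4, 4)
        np.testing.assert_array_equal(sim.values, sim.values.T)
        np.testing.assert_allclose(np.diag(sim.values), 1.0)

    def test_identical_subjects_match_perfectly(self, rng):
        maps = rng.standard_normal((500, 2))
        comps = [
            ComponentSet(subject_id=f"s{j}", maps=maps, courses=np.zeros((10, 2)) + 1.0)
            for j in range(2)
        ]
        sim = build_similarity_matrix(comps)
        assert sim.values[0, 2] == pytest.approx(1.0)
        assert sim.values[1, 3] == pytest.approx(1.0)


def _sim_from_cross(cross: np.ndarray) -> SimilarityMatrix:
    """2-subject similarity matrix from a 2x2 cross-subject block."""
    v = np.eye(4)
    v[0:2, 2:4] = cross
    v[2:4, 0:2] = cross.T
    return SimilarityMatrix(
        values=v,
        subject_ids=("A", "B"),
        subject_index=np.array([0, 0, 1, 1]),
        component_index=np.array([0, 1, 0, 1]),
    )


class TestMatching:
    def test_two_subject_example_matches_exhaustive_optimum(self):
        sim = _sim_from_cross(np.array([[0.9, 0.2], [0.3, 0.8]]))
        acs = match_components(sim)
        members = [set(ac.members) for ac in acs]
        assert {("A", 0), ("B", 0)} in members
        assert {("A", 1), ("B", 1)} in members

    def test_identical_component_sets_group_copies(self, rng):
        maps = rng.standard_normal((500, 3))
        comps = [
            ComponentSet(subject_id=f"s{j}", maps=maps, courses=np.ones((10, 3)))
            for j in range(4)
        ]
        sim = build_similarity_matrix(comps)
        acs = match_components(sim)
        assert len(acs) == 3
        for ac in acs:
            assert len({c for _, c in ac.members}) == 1  # same component index everywhere

    def test_invariant_to_subject_input_order(self, rng):
        for trial in range(5):
            comps = _toy_components(rng, n_subjects=4, n_ics=3)
            sim_fwd = build_similarity_matrix(comps)
            sim_rev = build_similarity_matrix(comps[::-1])
            fwd = {frozenset(ac.members) for ac in match_components(sim_fwd)}
            rev = {frozenset(ac.members) for ac in match_components(sim_rev)}
            assert fwd == rev


class TestCentrality:
    def test_identical_maps_give_full_centrality(self, rng):
        maps = rng.standard_normal((500, 2))
        comps = [
            ComponentSet(subject_id=f"s{j}", maps=maps, courses=np.ones((10, 2)))
            for j in range(5)
        ]
        sim = build_similarity_matrix(comps)
        ac = AlignedComponent(members=tuple((f"s{j}", 0) for j in range(5)))
        out = centrality_and_permutation(ac, sim, n_perm=99, seed=1)
        np.testing.assert_allclose(out.centrality, 4.0, atol=1e-9)

    def test_centrality_matches_similarity_row_sums(self, rng):
        comps = _toy_components(rng, n_subjects=4, n_ics=3)
        sim = build_similarity_matrix(comps)
        ac = match_components(sim)[0]
        out = centrality_and_permutation(ac, sim, n_perm=49, seed=0)
        manual = out.inter_subject_similarity.sum(axis=1) - 1.0
        np.testing.assert_allclose(out.centrality, manual, atol=1e-9)

    def test_planted_shared_component_reaches_minimal_p(self, rng):
        shared = rng.standard_normal(2000)
        comps = []
        for j in range(6):
            noise = rng.standard_normal((2000, 5))
            maps = np.column_stack([shared + 0.05 * rng.standard_normal(2000), noise])
            comps.append(
                ComponentSet(subject_id=f"s{j}", maps=maps, courses=np.ones((10, 6)))
            )
        sim = build_similarity_matrix(comps)
        ac = AlignedComponent(members=tuple((f"s{j}", 0) for j in range(6)))
        out = centrality_and_permutation(ac, sim, n_perm=199, seed=3)
        assert (np.abs(out.centrality_p - 1.0 / 200) < 1e-12).sum() >= 5

    def test_p_values_respect_bounds(self, rng):
        comps = _toy_components(rng, n_subjects=4, n_ics=3)
        sim = build_similarity_matrix(comps)
        ac = centrality_and_permutation(match_components(sim)[0], sim, n_perm=99, seed=2)
        assert (ac.centrality_p >= 1.0 / 100).all()
        assert (ac.centrality_p <= 1.0).all()


class TestGroupMapAndFilter:
    def test_identical_member_maps_reproduce_the_map(self, rng):
        maps = rng.standard_normal((500, 1))
        comps = [
            ComponentSet(subject_id=f"s{j}", maps=maps, courses=np.ones((10, 1)))
            for j in range(3)
        ]
        ac = AlignedComponent(
            members=tuple((f"s{j}", 0) for j in range(3)),
            centrality=np.array([1.0, 2.0, 3.0]),
            centrality_p=np.array([0.01, 0.01, 0.01]),
        )
        out = group_map(ac, comps)
        assert np.corrcoef(out.group_map, maps[:, 0])[0, 1] == pytest.approx(1.0)

    def test_weighted_average_hand_computed(self, rng):
        m1, m2 = rng.standard_normal((2, 500))
        comps = [
            ComponentSet(subject_id="a", maps=m1[:, None], courses=np.ones((10, 1))),
            ComponentSet(subject_id="b", maps=m2[:, None], courses=np.ones((10, 1))),
        ]
        ac = AlignedComponent(
            members=(("a", 0), ("b", 0)),
            centrality=np.array([3.0, 1.0]),
            centrality_p=np.array([0.01, 0.01]),
        )
        out = group_map(ac, comps)
        expected = 0.75 * m1 + 0.25 * m2
        expected = (expected - expected.mean()) / expected.std()
        np.testing.assert_allclose(out.group_map, expected, atol=1e-12)

    def test_consistency_boundary_is_strict(self):
        def make(frac):
            n = 10
            p = np.array([0.01] * int(frac * n) + [0.5] * (n - int(frac * n)))
            return AlignedComponent(
                members=tuple((f"s{j}", 0) for j in range(n)),
                centrality=np.ones(n),
                centrality_p=p,
                group_map=np.random.default_rng(0).standard_normal(100),
                consistency=float((p < 0.05).mean()),
            )

        exactly_60 = make(0.6)
        above = make(0.7)
        out = consistency_filter([exactly_60, above], min_fraction=0.6)
        assert out.n_networks == 1
        with pytest.warns(RuntimeWarning):
            assert consistency_filter([exactly_60], min_fraction=0.6) is None
        assert consistency_filter([exactly_60, above], min_fraction=0.0).n_networks == 2
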