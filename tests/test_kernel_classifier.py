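"""The kernel classifier: scoring rules, reductions, and invariants."""

import math
from collections import Counter
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import demetax as dx
from demetax import AssignmentTable, DistanceMatrix, KernelParams


def random_instance(seed, n_max=200, n_taxa=4, undet_fraction=0.15):
    """A random symmetric distance matrix with random labels."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, n_max + 1))
    v = rng.uniform(0.01, 1.0, (n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    ids = [f"s{i}" for i in range(n)]
    labels = {}
    for i in ids:
        if rng.random() < undet_fraction:
            labels[i] = "undetermined"
        else:
            labels[i] = f"T{int(rng.integers(n_taxa))}"
    return DistanceMatrix(ids, v), AssignmentTable(labels)


def reference_knn(m, a, k, r):
    """Independent plain k-NN majority vote (focal excluded), for oracles."""
    out = {}
    for i, focal in enumerate(m.ids):
        cands = [
            (m.values[i, j], other)
            for j, other in enumerate(m.ids)
            if j != i and a.is_determined(other)
        ]
        cands.sort()
        if len(cands) > k:
            cutoff = cands[k - 1][0]
            cands = [c for c in cands if c[0] <= cutoff]
        votes = Counter(a.get(other) for _, other in cands)
        if not votes:
            out[focal] = a.undetermined
            continue
        top = max(votes.values())
        winners = [t for t, c in votes.items() if c == top]
        if len(winners) == 1 and top / len(cands) >= r:
            out[focal] = winners[0]
        else:
            out[focal] = a.undetermined
    return AssignmentTable(out)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(lambda_decay=-1),
            dict(d=0),
            dict(r=0),
            dict(r=1.2),
            dict(k=0),
            dict(k=2.5),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            KernelParams(**kwargs)


class TestNeighborSet:
    def test_all_determined_within_radius_are_neighbours(self, tiny_bench):
        b = tiny_bench
        p = KernelParams(lambda_decay=0, d=math.inf, r=0.66)
        nb = dx.neighbor_set("FOCAL", b.matrix, b.labels, p)
        assert len(nb) == 10  # everyone but the (undetermined) focal itself

    def test_radius_excludes_beyond_d_and_self(self, tiny_bench):
        b = tiny_bench
        p = KernelParams(lambda_decay=0, d=0.2, r=0.66)
        nb = dx.neighbor_set("A1", b.matrix, b.labels, p)
        # everyone else sits at 0.25 from A1 except the focal's 0.05 to FOCAL
        # (undetermined, hence ignored): nothing qualifies
        assert nb == []
        nb_f = dx.neighbor_set("FOCAL", b.matrix, b.labels, p)
        assert all(d_ <= 0.2 for _, d_ in nb_f)
        assert all(i != "FOCAL" for i, _ in nb_f)

    def test_rank_k_ties_keep_all_tied_neighbours(self):
        ids = ["f", "n1", "n2", "n3", "n4"]
        v = np.full((5, 5), 0.5)
        v[0, 1:] = v[1:, 0] = [0.1, 0.2, 0.2, 0.3]
        np.fill_diagonal(v, 0)
        m = DistanceMatrix(ids, v)
        a = AssignmentTable({i: "T" for i in ids})
        p = KernelParams(lambda_decay=0, d=math.inf, r=0.6, k=2)
        kept = {i for i, _ in dx.neighbor_set("f", m, a, p)}
        # brute force: admissible sets are the 2-subsets containing n1 plus one
        # of the tied rank-2 neighbours; the stable superset is their union
        assert kept == {"n1", "n2", "n3"}

    def test_missing_focal_raises(self, tiny_bench):
        with pytest.raises(KeyError):
            dx.neighbor_set("ghost", tiny_bench.matrix, tiny_bench.labels,
                            KernelParams())


class TestScoreCandidates:
    def test_normalisation_multipliers_are_exact(self, tiny_bench):
        """Ten neighbours, 4 of taxon A and 6 of taxon B: A is scaled by
        10/4 and B by 10/6, exactly."""
        b = tiny_bench
        p = KernelParams(lambda_decay=0, d=0.2, r=0.66, normalize=True)
        nb = dx.neighbor_set("FOCAL", b.matrix, b.labels, p)
        res = dx.score_candidates("FOCAL", nb, b.labels, p)
        assert res.raw_scores["taxon_A"] == pytest.approx(4.0)
        assert res.raw_scores["taxon_B"] == pytest.approx(6.0)
        assert res.normalized_scores["taxon_A"] == pytest.approx(4.0 * 10 / 4)
        assert res.normalized_scores["taxon_B"] == pytest.approx(6.0 * 10 / 6)

    def test_flat_kernel_with_normalisation_ties_to_undetermined(self, tiny_bench):
        b = tiny_bench
        p = KernelParams(lambda_decay=0, d=0.2, r=0.66, normalize=True)
        res = dx.classify_accession("FOCAL", b.matrix, b.labels, p)
        assert res.suggestion == b.labels.undetermined
        assert res.winning_proportion == pytest.approx(0.5)

    def test_unanimous_neighbourhood_gives_proportion_one(self):
        ids = ["f", "x", "y", "z"]
        v = np.full((4, 4), 0.1)
        np.fill_diagonal(v, 0)
        m = DistanceMatrix(ids, v)
        a = AssignmentTable({"f": "undetermined", "x": "T", "y": "T", "z": "T"})
        for r in (0.3, 0.66, 1.0):
            res = dx.classify_accession("f", m, a, KernelParams(lambda_decay=5, d=1, r=r))
            assert res.winning_proportion == pytest.approx(1.0)
            assert res.suggestion == "T"

    def test_empty_neighbourhood_is_undetermined_not_an_error(self, tiny_bench):
        b = tiny_bench
        res = dx.score_candidates("FOCAL", [], b.labels, KernelParams())
        assert res.neighbor_count == 0
        assert res.suggestion == b.labels.undetermined

    def test_undetermined_neighbour_rejected(self, tiny_bench):
        b = tiny_bench
        with pytest.raises(ValueError):
            dx.score_candidates("A1", [("FOCAL", 0.05)], b.labels, KernelParams())

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(
        st.integers(1, 12),
        st.integers(1, 12),
        st.integers(0, 10_000),
    )
    def test_two_taxon_neighbourhood_always_ties_with_flat_kernel(self, na, nb, seed):
        """With lambda = 0 and normalisation on, per-neighbour weights are all
        equal, so each taxon's normalised score equals the neighbour total —
        a tie whatever the counts."""
        rng = np.random.default_rng(seed)
        ids = ["f"] + [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
        n = len(ids)
        v = rng.uniform(0.01, 0.3, (n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        m = DistanceMatrix(ids, v)
        labels = {"f": "undetermined"}
        labels.update({f"a{i}": "A" for i in range(na)})
        labels.update({f"b{i}": "B" for i in range(nb)})
        a = AssignmentTable(labels)
        res = dx.classify_accession(
            "f", m, a, KernelParams(lambda_decay=0, d=math.inf, r=0.66, normalize=True)
        )
        assert res.suggestion == a.undetermined
        assert res.normalized_scores["A"] == pytest.approx(res.normalized_scores["B"])


class TestClassifyAll:
    def test_matches_per_accession_path(self):
        m, a = random_instance(5, n_max=60)
        p = KernelParams(lambda_decay=3.0, d=0.7, r=0.5, k=7)
        table, results = dx.classify_all(m, a, p)
        for res in results[::5]:
            solo = dx.classify_accession(res.focal, m, a, p)
            assert solo.suggestion == res.suggestion
            assert solo.neighbor_count == res.neighbor_count
            assert solo.winning_proportion == pytest.approx(res.winning_proportion)

    def test_well_separated_clean_demes_are_a_fixed_point(self, toy_bench):
        b = toy_bench
        clean = b.true_labels
        sugg, _ = dx.classify_all(b.matrix, clean, b.kernel_params)
        assert all(sugg.get(i) == clean.get(i) for i in b.matrix.ids)

    def test_single_mislabel_is_flipped_back_to_deme_majority(self, toy_bench):
        b = toy_bench
        flipped = dict(b.true_labels.entries)
        victim = b.matrix.ids[0]
        assert flipped[victim] == "deme_A"
        flipped[victim] = "deme_B"
        sugg, _ = dx.classify_all(b.matrix, AssignmentTable(flipped), b.kernel_params)
        assert sugg.get(victim) == "deme_A"

    def test_degenerate_parameters_reduce_to_knn_majority_vote(self):
        p = KernelParams(lambda_decay=0, d=math.inf, r=4 / 6, k=6, normalize=False)
        for seed in range(25):
            m, a = random_instance(seed, n_max=80)
            kernel_out, _ = dx.classify_all(m, a, p)
            knn_out = reference_knn(m, a, k=6, r=4 / 6)
            assert all(kernel_out.get(i) == knn_out.get(i) for i in m.ids)

    def test_permutation_invariance(self):
        m, a = random_instance(11, n_max=50)
        p = KernelParams(lambda_decay=2.0, d=0.8, r=0.5, k=5)
        out1, _ = dx.classify_all(m, a, p)
        rng = np.random.default_rng(1)
        perm = rng.permutation(m.n)
        m2 = DistanceMatrix([m.ids[i] for i in perm], m.values[np.ix_(perm, perm)])
        out2, _ = dx.classify_all(m2, a, p)
        assert all(out1.get(i) == out2.get(i) for i in m.ids)

    def test_scale_consistency(self):
        m, a = random_instance(13, n_max=50)
        c = 3.7
        p1 = KernelParams(lambda_decay=2.0, d=0.8, r=0.5, k=5)
        p2 = KernelParams(lambda_decay=2.0 / c, d=0.8 * c, r=0.5, k=5)
        m_scaled = DistanceMatrix(list(m.ids), m.values * c)
        out1, _ = dx.classify_all(m, a, p1)
        out2, _ = dx.classify_all(m_scaled, a, p2)
        assert all(out1.get(i) == out2.get(i) for i in m.ids)

    def test_raising_r_never_decreases_undetermined_calls(self):
        m, a = random_instance(17, n_max=80)
        base = KernelParams(lambda_decay=2.0, d=0.8, k=8)
        counts = []
        for r in (0.3, 0.5, 0.7, 0.9):
            out, _ = dx.classify_all(m, a, replace(base, r=r))
            counts.append(sum(1 for i in m.ids if not out.is_determined(i)))
        assert counts == sorted(counts)

    def test_masked_matrix_is_rejected(self):
        v = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]])
        m = DistanceMatrix(["a", "b", "c"], v)
        a = AssignmentTable({"a": "T", "b": "T", "c": "T"})
        with pytest.raises(ValueError, match="missing"):
            dx.classify_all(m, a, KernelParams())

    def test_relaxed_mode_abstains_only_on_empty_neighbourhood(self):
        m, a = random_instance(23, n_max=60)
        p = KernelParams(lambda_decay=2.0, d=0.3, r=0.95, relaxed_undetermined=True)
        out, results = dx.classify_all(m, a, p)
        for res in results:
            if res.neighbor_count > 0:
                assert out.is_determined(res.focal)
            else:
                assert not out.is_determined(res.focal)


class TestIterateClassification:
    def test_fixed_point_converges_in_one_round(self, toy_bench):
        b = toy_bench
        out, rounds, converged = dx.iterate_classification(
            b.matrix, b.true_labels, b.kernel_params
        )
        assert converged and rounds == 1
        assert all(out.get(i) == b.true_labels.get(i) for i in b.matrix.ids)

    def test_single_mislabel_converges_in_two_rounds(self, toy_bench):
        b = toy_bench
        flipped = dict(b.true_labels.entries)
        flipped[b.matrix.ids[0]] = "deme_B"
        out, rounds, converged = dx.iterate_classification(
            b.matrix, AssignmentTable(flipped), b.kernel_params
        )
        assert converged and rounds == 2
        assert out.get(b.matrix.ids[0]) == "deme_A"

    def test_oscillation_terminates_unconverged(self):
        # two accessions with each other as the only neighbour swap labels
        m = DistanceMatrix(["p", "q"], np.array([[0.0, 0.1], [0.1, 0.0]]))
        a = AssignmentTable({"p": "A", "q": "B"})
        p = KernelParams(lambda_decay=0, d=1.0, r=0.5, normalize=False)
        out, rounds, converged = dx.iterate_classification(m, a, p, max_rounds=5)
        assert rounds == 5 and not converged


def test_results_frame_has_contracted_columns(toy_bench):
    b = toy_bench
    _, results = dx.classify_all(b.matrix, b.labels, b.kernel_params)
    df = dx.results_to_frame(results, b.labels)
    assert list(df.columns) == [
        "accession_id",
        "original_assignment",
        "suggested_assignment",
        "winning_proportion",
        "neighbor_count",
    ]
    assert len(df) == b.matrix.n
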