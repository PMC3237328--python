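"""Pseudo-centroid geometry, observed contacts, SSE axes and ROA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from comap.constraints import ContactSet
from comap.geometry import (
    AxisSegment,
    CaTrace,
    combined_score,
    evaluate_prediction,
    observed_contacts,
    pseudo_centroids,
    read_ca_trace,
    roa,
    screen,
    segment_cosine,
    sse_axes,
    write_ca_trace,
)
from comap.simulate import gen_toy_trace
from comap.sse import SSEWindow


def test_centroid_right_angle_example():
    trace = CaTrace(np.array([[0, 0, 0], [3.8, 0, 0], [3.8, 3.8, 0.0]]))
    pc = pseudo_centroids(trace)
    expected = np.array([3.8, 0, 0]) + 2.0 * np.array([1 / np.sqrt(2), -1 / np.sqrt(2), 0])
    assert np.allclose(pc.positions[1], expected, atol=1e-12)


def test_centroid_distance_is_offset_for_interior_residues():
    trace = gen_toy_trace("ideal_helix", n=20)
    pc = pseudo_centroids(trace)
    d = np.linalg.norm(pc.positions - trace.coords, axis=1)
    assert np.allclose(d[1:-1], 2.0, atol=1e-10)
    assert d[0] == 0.0 and d[-1] == 0.0  # terminals fall back to CA


def test_centroid_rigid_motion_equivariance(rng):
    trace = gen_toy_trace("ideal_helix", n=15)
    pc = pseudo_centroids(trace).positions
    for _ in range(100):
        R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
        t = rng.normal(size=3) * 10
        moved = CaTrace(trace.coords @ R.T + t)
        pc_moved = pseudo_centroids(moved).positions
        assert np.allclose(pc_moved, pc @ R.T + t, atol=1e-8)


def test_centroid_collinear_fallback(caplog):
    trace = CaTrace(np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0.0]]))
    with caplog.at_level("WARNING"):
        pc = pseudo_centroids(trace)
    assert np.allclose(pc.positions[1], trace.coords[1])
    assert "collinear" in caplog.text


def test_centroid_needs_three_residues():
    with pytest.raises(ValueError):
        pseudo_centroids(CaTrace(np.array([[0, 0, 0], [3.8, 0, 0.0]])))


def test_observed_contacts_threshold():
    L = 8
    coords = np.zeros((L, 3))
    coords[:, 0] = np.arange(L) * 3.8
    pc_pos = coords.copy()
    pc_pos[7] = pc_pos[0] + [7.9, 0, 0]
    from comap.geometry import PseudoCentroidSet

    contacts = observed_contacts(PseudoCentroidSet(pc_pos), min_sep=3)
    assert (0, 7) in contacts.as_set()
    pc_pos[7] = pc_pos[0] + [8.1, 0, 0]
    contacts = observed_contacts(PseudoCentroidSet(pc_pos), min_sep=3)
    assert (0, 7) not in contacts.as_set()


def test_observed_contacts_match_brute_force():
    trace = gen_toy_trace("ideal_helix", n=25)
    pc = pseudo_centroids(trace)
    contacts = observed_contacts(pc, min_sep=3)
    expected = set()
    P = pc.positions
    for i in range(25):
        for j in range(i + 3, 25):
            if np.linalg.norm(P[i] - P[j]) < 8.0:
                expected.add((i, j))
    assert contacts.as_set() == expected


def test_helix_trace_geometry():
    trace = gen_toy_trace("ideal_helix", n=18)
    d = np.linalg.norm(np.diff(trace.coords, axis=0), axis=1)
    assert np.allclose(d, d[0])
    assert 3.6 < d[0] < 4.1  # near the virtual CA-CA bond length
    assert trace.virtual_bonds_plausible()


def test_sse_axis_on_exact_line():
    coords = np.column_stack([np.arange(10) * 3.5, np.zeros(10), np.zeros(10)])
    trace = CaTrace(coords)
    w = SSEWindow("E", 2, 7)
    (axis,) = sse_axes(trace, [w])
    assert np.allclose(axis.start, coords[2], atol=1e-10)
    assert np.allclose(axis.end, coords[7], atol=1e-10)
    assert np.allclose(axis.direction, [1, 0, 0], atol=1e-12)


def test_sse_axis_of_ideal_helix_close_to_true_axis():
    trace = gen_toy_trace("ideal_helix", n=12)
    w = SSEWindow("H", 0, 11)
    (axis,) = sse_axes(trace, [w])
    # true axis is z; fitted axis within 0.5 A laterally over its length
    assert abs(axis.direction[2]) > 0.99
    assert np.linalg.norm(axis.start[:2]) < 0.5
    assert np.linalg.norm(axis.end[:2]) < 0.5


def test_sse_axis_flips_with_residue_order():
    coords = np.column_stack([np.arange(8) * 3.5, np.zeros(8), np.zeros(8)])
    w = SSEWindow("E", 0, 7)
    (fwd,) = sse_axes(CaTrace(coords), [w])
    (rev,) = sse_axes(CaTrace(coords[::-1].copy()), [w])
    assert np.allclose(fwd.direction, -rev.direction, atol=1e-10)


def test_sse_axis_short_core_skipped(caplog):
    coords = np.column_stack([np.arange(5) * 3.5, np.zeros(5), np.zeros(5)])
    w = SSEWindow("E", 1, 2)
    with caplog.at_level("WARNING"):
        out = sse_axes(CaTrace(coords), [w])
    assert out == [None]


def _parallel_segments(length=10.0, separation=1.0):
    a = AxisSegment(np.array([0.0, 0, 0]), np.array([length, 0, 0]))
    b = AxisSegment(np.array([0.0, separation, 0]), np.array([length, separation, 0]))
    return a, b


def test_roa_parallel_matches_dense_sampling():
    a, b = _parallel_segments()
    coarse = roa(a, b, step=1.0)
    dense = roa(a, b, step=0.01)
    assert coarse == pytest.approx(dense, rel=0.02)
    # parallel unit-separated overlap of length 10: score is 10/1
    assert coarse == pytest.approx(10.0, rel=0.02)


def test_roa_halves_when_distance_doubles():
    a, b = _parallel_segments(separation=1.0)
    a2, b2 = _parallel_segments(separation=2.0)
    assert roa(a2, b2) == pytest.approx(0.5 * roa(a, b), rel=1e-9)


def test_roa_zero_when_projections_miss():
    a = AxisSegment(np.array([0.0, 0, 0]), np.array([10.0, 0, 0]))
    b = AxisSegment(np.array([20.0, 5, 0]), np.array([20.0, 15, 0]))
    assert roa(a, b) == 0.0


def test_roa_symmetric_and_nonnegative(rng):
    for _ in range(10):
        a = AxisSegment(rng.normal(size=3) * 5, rng.normal(size=3) * 5)
        b = AxisSegment(rng.normal(size=3) * 5 + 3, rng.normal(size=3) * 5 + 3)
        va, vb = roa(a, b), roa(b, a)
        assert va >= 0
        assert va == pytest.approx(vb, rel=1e-9, abs=1e-12)


def test_roa_monotone_in_separation():
    vals = [roa(*_parallel_segments(separation=s)) for s in (1.0, 2.0, 4.0, 8.0)]
    assert all(x > y for x, y in zip(vals, vals[1:]))


def test_segment_cosine_signs():
    a = AxisSegment(np.zeros(3), np.array([10.0, 0, 0]))
    b = AxisSegment(np.array([0.0, 4, 0]), np.array([10.0, 4, 0]))
    c = AxisSegment(np.array([10.0, 4, 0]), np.array([0.0, 4, 0]))
    assert segment_cosine(a, b) == pytest.approx(1.0)
    assert segment_cosine(a, c) == pytest.approx(-1.0)


def test_screen_rules():
    assert screen(5.0, opposite_sides=True) == 0.0
    assert screen(5.0, n_adj=1) == 5.0
    assert screen(5.0, n_adj=3) == pytest.approx(5.0 / 16)
    with pytest.raises(ValueError):
        screen(5.0, n_adj=0)


def test_combined_score_orientation_agreement():
    assert combined_score(A=2.0, c=1.0, T=3.0, P_pol=1.0) == pytest.approx(8.0)
    # disagreement: oriented term negative
    assert combined_score(A=2.0, c=-1.0, T=3.0, P_pol=1.0) == pytest.approx(4.0)
    assert combined_score(A=0.0, c=1.0, T=100.0, P_pol=1.0) == 0.0


def test_strand_pair_traces_give_expected_contact_pattern():
    for kind, expect_parallel in (
        ("strand_pair_parallel", True),
        ("strand_pair_antiparallel", False),
    ):
        trace = gen_toy_trace(kind, n_per_strand=6)
        pc = pseudo_centroids(trace)
        contacts = observed_contacts(pc, min_sep=3)
        # cross-strand contacts: strand1 residues 0-5, strand2 is the last 6
        L = trace.L
        cross = [(i, j) for i, j in contacts.pairs if i < 6 and j >= L - 6]
        assert cross, f"no cross-strand contacts for {kind}"
        # parallel packing: contact band runs along the diagonal (positive
        # register correlation); antiparallel: against it
        ii = np.array([i for i, _ in cross], dtype=float)
        jj = np.array([j for _, j in cross], dtype=float)
        r = np.corrcoef(ii, jj)[0, 1]
        assert (r > 0.8) if expect_parallel else (r < -0.8)


def test_evaluate_prediction_identity_and_disjoint():
    obs = ContactSet(pairs=[(0, 5), (1, 6), (2, 8)], L=10)
    m = evaluate_prediction(obs, obs)
    assert m.precision == 1.0 and m.recall == 1.0
    other = ContactSet(pairs=[(0, 4), (3, 9)], L=10)
    m = evaluate_prediction(other, obs)
    assert m.precision == 0.0 and m.recall == 0.0


def test_evaluate_prediction_matches_set_oracle(rng):
    L = 30
    all_pairs = [(i, j) for i in range(L) for j in range(i + 1, L)]
    pred_idx = rng.choice(len(all_pairs), 40, replace=False)
    obs_idx = rng.choice(len(all_pairs), 50, replace=False)
    pred = ContactSet(pairs=[all_pairs[k] for k in sorted(pred_idx)], L=L,
                      scores={all_pairs[k]: float(rng.random()) for k in pred_idx})
    obs = ContactSet(pairs=[all_pairs[k] for k in sorted(obs_idx)], L=L)
    k = 20
    m = evaluate_prediction(pred, obs, top_k=k)
    top = sorted(pred.pairs, key=lambda p: (-pred.scores[p], p))[:k]
    inter = set(top) & obs.as_set()
    assert m.n_correct == len(inter)
    assert m.precision == pytest.approx(len(inter) / k)
    assert m.recall == pytest.approx(len(inter) / 50)


def test_evaluate_prediction_length_mismatch():
    with pytest.raises(ValueError):
        evaluate_prediction(ContactSet([], 10), ContactSet([], 12))


def test_pdb_roundtrip(tmp_path):
    trace = gen_toy_trace("ideal_helix", n=10)
    path = tmp_path / "helix.pdb"
    write_ca_trace(trace, path)
    back = read_ca_trace(path)
    assert back.L == 10
    assert np.allclose(back.coords, trace.coords, atol=1e-2)  # PDB precision
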