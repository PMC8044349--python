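"""FACT tracking stopping rules and streamline-to-connectome construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strucnet.tracto import (
    Connectome,
    DirectionVolume,
    Parcellation,
    ScalarVolume,
    StreamlineSet,
    TrackingParams,
    build_connectome,
    count_streamline_edges,
    fact_track,
)


def uniform_field(shape=(20, 20, 20), fa=0.8, direction=(1.0, 0.0, 0.0)):
    fa_vol = ScalarVolume(np.full(shape, fa))
    dirs = np.zeros((*shape, 3))
    dirs[...] = np.asarray(direction)
    return fa_vol, DirectionVolume(dirs)


def test_uniform_field_yields_straight_streamline_spanning_grid():
    fa, dirs = uniform_field()
    s = fact_track(fa, dirs, seeds=[(10.0, 10.0, 10.0)])
    assert len(s.streamlines) == 1
    poly = s.streamlines[0]
    assert s.reasons[0] == ("left_volume", "left_volume")
    # straight in x: y and z constant
    assert np.allclose(poly[:, 1], 10.0) and np.allclose(poly[:, 2], 10.0)
    assert poly[:, 0].min() <= 0.0 and poly[:, 0].max() >= 19.0
    steps = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    assert np.allclose(steps, 0.5, atol=1e-9)


def test_low_fa_wall_stops_tracking():
    fa, dirs = uniform_field()
    wall = fa.data.copy()
    wall[15, :, :] = 0.19  # just below the 0.2 threshold
    fa = ScalarVolume(wall)
    s = fact_track(fa, dirs, seeds=[(5.0, 10.0, 10.0)])
    poly = s.streamlines[0]
    assert s.reasons[0][1] == "fa"
    # never enters the wall voxel (x=14.5 still rounds to voxel 14)
    assert poly[:, 0].max() <= 14.5


def test_sharp_turn_terminates_with_angle_reason():
    shape = (20, 20, 20)
    fa = ScalarVolume(np.full(shape, 0.8))
    dirs = np.zeros((*shape, 3))
    dirs[:10] = (1.0, 0.0, 0.0)
    theta = np.radians(50.0)  # 50 degrees > 45-degree threshold
    dirs[10:] = (np.cos(theta), np.sin(theta), 0.0)
    s = fact_track(fa, DirectionVolume(dirs), seeds=[(5.0, 10.0, 10.0)])
    assert s.reasons[0][1] == "angle"


def test_gentle_turn_continues():
    shape = (20, 20, 20)
    fa = ScalarVolume(np.full(shape, 0.8))
    dirs = np.zeros((*shape, 3))
    dirs[:10] = (1.0, 0.0, 0.0)
    theta = np.radians(30.0)  # below threshold: keeps going
    dirs[10:] = (np.cos(theta), np.sin(theta), 0.0)
    s = fact_track(fa, DirectionVolume(dirs), seeds=[(5.0, 10.0, 10.0)])
    assert s.reasons[0][1] == "left_volume"


def test_subthreshold_seed_skipped_with_warning():
    fa, dirs = uniform_field(fa=0.1)
    with pytest.warns(UserWarning, match="sub-threshold"):
        s = fact_track(fa, dirs, seeds=[(10.0, 10.0, 10.0)])
    assert len(s.streamlines) == 0


def test_seed_outside_grid_raises():
    fa, dirs = uniform_field()
    with pytest.raises(ValueError, match="outside grid"):
        fact_track(fa, dirs, seeds=[(30.0, 10.0, 10.0)])


def _parcellation_two_slabs(shape=(20, 20, 20)):
    labels = np.zeros(shape, dtype=np.int32)
    labels[:5] = 1
    labels[15:] = 2
    return Parcellation(labels, region_names=("left", "right"))


def test_endpoint_counting_direct_tally():
    parc = _parcellation_two_slabs()
    s = StreamlineSet(step_size=0.5)
    for _ in range(5):
        s.streamlines.append(np.array([[2.0, 10.0, 10.0], [17.0, 10.0, 10.0]]))
        s.reasons.append(("left_volume", "left_volume"))
    counts = count_streamline_edges(s, parc)
    assert counts[0, 1] == 5 and counts[1, 0] == 5
    assert counts[0, 0] == 0 and counts[1, 1] == 0


def test_background_or_same_region_endpoints_do_not_count():
    parc = _parcellation_two_slabs()
    s = StreamlineSet(step_size=0.5)
    s.streamlines.append(np.array([[2.0, 10.0, 10.0], [10.0, 10.0, 10.0]]))  # bg end
    s.streamlines.append(np.array([[1.0, 10.0, 10.0], [3.0, 10.0, 10.0]]))  # same
    s.reasons += [("fa", "fa"), ("fa", "fa")]
    assert count_streamline_edges(s, parc).sum() == 0


def test_endpoint_tally_matches_bruteforce_on_random_streamlines(rng):
    shape = (12, 12, 12)
    labels = rng.integers(0, 4, size=shape).astype(np.int32)  # 0 = background
    parc = Parcellation(labels)
    s = StreamlineSet(step_size=0.5)
    for _ in range(200):
        a = rng.uniform(0, 11, 3)
        b = rng.uniform(0, 11, 3)
        s.streamlines.append(np.array([a, (a + b) / 2, b]))
        s.reasons.append(("max_steps", "max_steps"))
    counts = count_streamline_edges(s, parc)
    expected = np.zeros((3, 3), dtype=int)
    for poly in s.streamlines:
        la = labels[tuple(np.rint(poly[0]).astype(int))]
        lb = labels[tuple(np.rint(poly[-1]).astype(int))]
        if la > 0 and lb > 0 and la != lb:
            expected[la - 1, lb - 1] += 1
            expected[lb - 1, la - 1] += 1
    assert np.array_equal(counts, expected)


def test_edge_rule_is_strictly_more_than_threshold():
    counts = np.zeros((4, 4), dtype=int)
    counts[0, 1] = counts[1, 0] = 3  # not an edge: 3 is not "more than 3"
    counts[1, 2] = counts[2, 1] = 4  # minimum count that forms an edge
    conn = build_connectome(counts)
    assert conn.adjacency[0, 1] == 0
    assert conn.adjacency[1, 2] == 1
    assert build_connectome(np.zeros((4, 4), dtype=int)).adjacency.sum() == 0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_edge_rule_property_on_random_matrices(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 12))
    c = rng.integers(0, 8, size=(n, n))
    c = np.triu(c, k=1)
    c = c + c.T
    conn = build_connectome(c)
    assert np.array_equal(conn.adjacency, (c > 3).astype(np.int8))


def test_connectome_relabeling_equivariance(rng):
    n = 8
    c = rng.integers(0, 10, size=(n, n))
    c = np.triu(c, k=1)
    c = c + c.T
    perm = rng.permutation(n)
    conn = build_connectome(c)
    conn_p = build_connectome(c[np.ix_(perm, perm)])
    assert np.array_equal(conn_p.adjacency, conn.adjacency[np.ix_(perm, perm)])


def test_build_connectome_rejects_invalid_input():
    bad = np.array([[0, 1], [2, 0]])
    with pytest.raises(ValueError, match="symmetric"):
        build_connectome(bad)
    with pytest.raises(ValueError, match="nonnegative"):
        build_connectome(np.array([[0, -1], [-1, 0]]))
    with pytest.raises(ValueError):
        Connectome(
            counts=np.zeros((2, 2), dtype=int),
            adjacency=np.ones((2, 2), dtype=np.int8),
            labels=("a", "b"),
        )
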