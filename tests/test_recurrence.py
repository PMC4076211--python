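import math

import numpy as np
import pytest

from operand import (
    RecurrenceConfig,
    RecurrenceGraph,
    delay_embed,
    recurrence_matrix,
    transitivity,
    transitivity_dimension,
    window_transitivity_dimension,
)
from operand.errors import (
    DegenerateSeriesError,
    TransitivityDomainError,
    UndefinedTransitivityError,
)
from operand.recurrence import write_edge_list, write_recurrence_csv

from oracles import transitivity_oracle


def _graph(adj):
    return RecurrenceGraph(matrix=np.asarray(adj), epsilon_used=1.0)


def test_transitivity_k5():
    a = np.ones((5, 5), int) - np.eye(5, dtype=int)
    assert transitivity(_graph(a)) == 1.0


def test_transitivity_path_p3():
    a = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
    assert transitivity(_graph(a)) == 0.0


def test_transitivity_triangle_plus_pendant():
    # triangle 0-1-2 with pendant node 3 attached to 2
    a = [[0, 1, 1, 0], [1, 0, 1, 0], [1, 1, 0, 0], [0, 0, 1, 0]]
    # symmetric: fix the 2-3 edge both ways
    a[2][3] = 1
    assert transitivity(_graph(a)) == pytest.approx(0.6, abs=1e-15)
    assert transitivity(_graph(a)) == pytest.approx(transitivity_oracle(a), abs=1e-15)


def test_transitivity_matches_oracle_random_graphs():
    rng = np.random.default_rng(123)
    for _ in range(25):
        n = int(rng.integers(3, 31))
        p = float(rng.uniform(0.1, 0.7))
        a = (rng.random((n, n)) < p).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        graph = _graph(a)
        try:
            got = transitivity(graph)
        except UndefinedTransitivityError:
            with pytest.raises(ValueError):
                transitivity_oracle(a.tolist())
            continue
        assert got == pytest.approx(transitivity_oracle(a.tolist()), abs=1e-12)


def test_transitivity_matches_networkx():
    nx = pytest.importorskip("networkx")
    rng = np.random.default_rng(7)
    for _ in range(10):
        n = int(rng.integers(4, 31))
        a = (rng.random((n, n)) < 0.3).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        g = nx.from_numpy_array(a)
        want = nx.transitivity(g)
        try:
            got = transitivity(_graph(a))
        except UndefinedTransitivityError:
            assert want == 0  # networkx returns 0 when no triads exist
            continue
        assert got == pytest.approx(want, abs=1e-12)


def test_transitivity_undefined_cases():
    with pytest.raises(UndefinedTransitivityError):
        transitivity(_graph(np.zeros((5, 5), int)))
    with pytest.raises(UndefinedTransitivityError):
        transitivity(_graph(np.zeros((2, 2), int)))


def test_dimension_identity():
    for m in range(1, 11):
        assert abs(transitivity_dimension((3.0 / 4.0) ** m) - m) <= 1e-12


def test_dimension_domain():
    with pytest.raises(TransitivityDomainError):
        transitivity_dimension(0.0)
    with pytest.raises(TransitivityDomainError):
        transitivity_dimension(1.5)
    assert transitivity_dimension(1.0) == 0.0


def test_recurrence_rate_mode_hits_target():
    rng = np.random.default_rng(5)
    traj = delay_embed(rng.normal(size=400), m=2, tau=1)
    for rate in (0.05, 0.10, 0.20):
        g = recurrence_matrix(traj, RecurrenceConfig(epsilon=rate))
        n = g.n
        admissible = n * n - n  # theiler=1 removes the diagonal only
        achieved = (int(g.matrix.sum())) / admissible
        assert abs(achieved - rate) <= 2.0 / admissible + 1e-12


def test_absolute_mode_thresholds_distances():
    traj = delay_embed([0.0, 1.0, 3.0, 6.0], m=1, tau=1)
    g = recurrence_matrix(traj, RecurrenceConfig(epsilon_mode="absolute", epsilon=2.0))
    want = np.array(
        [[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 0], [0, 0, 0, 0]], dtype=np.uint8
    )
    # |x_i - x_j| <= 2 off the diagonal: (0,1), (1,2) and the 3-6 pair is 3 > 2
    assert np.array_equal(g.matrix, want)
    assert g.epsilon_used == 2.0


def test_matrix_symmetric_zero_diagonal():
    rng = np.random.default_rng(11)
    traj = delay_embed(rng.normal(size=100), m=3, tau=2)
    g = recurrence_matrix(traj, RecurrenceConfig())
    assert np.array_equal(g.matrix, g.matrix.T)
    assert np.trace(g.matrix) == 0


def test_theiler_band_excluded():
    rng = np.random.default_rng(13)
    traj = delay_embed(rng.normal(size=80), m=2, tau=1)
    g = recurrence_matrix(traj, RecurrenceConfig(theiler=5, epsilon=0.3))
    i, j = np.nonzero(g.matrix)
    assert np.all(np.abs(i - j) >= 5)


def test_identical_points_degenerate():
    traj = delay_embed(np.ones(10) * 2.5, m=2, tau=1)
    with pytest.raises(DegenerateSeriesError):
        recurrence_matrix(traj, RecurrenceConfig())


def test_window_transitivity_dimension_composes():
    rng = np.random.default_rng(3)
    x = rng.normal(size=300)
    cfg = RecurrenceConfig(epsilon=0.1)
    d = window_transitivity_dimension(x, m=2, tau=1, cfg=cfg)
    traj = delay_embed(x, m=2, tau=1)
    want = transitivity_dimension(transitivity(recurrence_matrix(traj, cfg)))
    assert d == want


def test_exports_roundtrip(tmp_path):
    rng = np.random.default_rng(17)
    traj = delay_embed(rng.normal(size=50), m=2, tau=1)
    g = recurrence_matrix(traj, RecurrenceConfig(epsilon=0.2))
    csv_path = tmp_path / "rp.csv"
    write_recurrence_csv(g, csv_path)
    back = np.loadtxt(csv_path, delimiter=",", dtype=int)
    assert np.array_equal(back, g.matrix)
    edge_path = tmp_path / "edges.tsv"
    write_edge_list(g, edge_path)
    pairs = [tuple(map(int, line.split())) for line in edge_path.read_text().splitlines()]
    iu, ju = np.nonzero(np.triu(g.matrix))
    assert pairs == list(zip(iu.tolist(), ju.tolist()))


def test_config_validation():
    with pytest.raises(ValueError):
        RecurrenceConfig(epsilon_mode="fraction")
    with pytest.raises(ValueError):
        RecurrenceConfig(epsilon=0.0)
    with pytest.raises(ValueError):
        RecurrenceConfig(epsilon_mode="absolute", epsilon=-1.0)
    with pytest.raises(ValueError):
        RecurrenceConfig(theiler=-1)
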