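import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytomon import (
    Gate,
    GateSet,
    apply_gate,
    count_populations,
    default_gateset,
    load_gateset,
    save_gateset,
    transform_events,
)
from cytomon.gating import HNA_LNA_FL1_BOUNDARY, GateError, UNGATED

from conftest import make_table


def ray_cast(vertices, x, y):
    """Brute-force even-odd point-in-polygon (open boundary)."""
    inside = False
    n = len(vertices)
    for i in range(n):
        (x1, y1), (x2, y2) = vertices[i], vertices[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


# ---------------------------------------------------------------------------
# log transform
# ---------------------------------------------------------------------------

def test_transform_log10_arithmetic():
    table = make_table([[1.0, 10.0, 1.5e4, 100.0, 1e3]])
    out = transform_events(table)
    assert out.channel("FL1-A")[0] == pytest.approx(np.log10(1.5e4), abs=1e-6)
    assert out.channel("FL3-A")[0] == pytest.approx(2.0)
    assert out.log_transformed


def test_transform_clips_at_one():
    table = make_table([[0.0, 0.5, 1.0, 2.0, 3.0]])
    out = transform_events(table)
    assert out.channel("FSC-A")[0] == 0.0  # log10(max(0, 1)) = 0
    assert out.channel("SSC-A")[0] == 0.0


def test_double_transform_rejected(rng):
    table = make_table(rng.uniform(1, 1e5, (10, 5)))
    once = transform_events(table)
    with pytest.raises(ValueError, match="already"):
        transform_events(once)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_transform_is_monotone_per_channel(seed):
    rng = np.random.default_rng(seed)
    table = make_table(rng.uniform(0, 1e6, (1000, 5)))
    out = transform_events(table)
    for j in range(5):
        order_in = np.argsort(table.events[:, j], kind="stable")
        order_out = np.argsort(out.events[:, j], kind="stable")
        # ties after clipping may permute, so compare sorted transforms
        np.testing.assert_array_equal(
            out.events[order_in, j], np.sort(out.events[:, j])
        )
        assert np.all(np.diff(out.events[order_out, j]) >= 0)


# ---------------------------------------------------------------------------
# gate geometry and defaults
# ---------------------------------------------------------------------------

def test_default_gateset_boundary_and_threshold(gates):
    boundary = np.log10(HNA_LNA_FL1_BOUNDARY)
    hna_x = [v[0] for v in gates["HNA_p"].vertices]
    lna_x = [v[0] for v in gates["LNA_p"].vertices]
    assert min(hna_x) == pytest.approx(boundary)
    assert max(lna_x) == pytest.approx(boundary)
    assert gates.acquisition_threshold == 800.0
    assert gates.threshold_channel == "FL1-H"
    assert gates.priority == ["microalgal", "HFL3_p", "HNA_p", "LNA_p"]


def test_default_gates_pairwise_disjoint(gates):
    # interiors disjoint per the shapely polygon-intersection oracle
    assert gates.pairwise_overlap_area() == pytest.approx(0.0, abs=1e-12)


def test_gate_validation_errors():
    with pytest.raises(GateError, match="vertices"):
        Gate("bad", [(0, 0), (1, 1)])
    with pytest.raises(GateError, match="simple"):
        Gate("bowtie", [(0, 0), (1, 1), (1, 0), (0, 1)])
    with pytest.raises(GateError, match="range"):
        Gate("out", [(0, 0), (9, 0), (9, 9), (0, 9)])
    with pytest.raises(GateError, match="priority"):
        GateSet(gates=[Gate("a", [(0, 0), (1, 0), (1, 1)])], priority=["a", "b"])


def test_gateset_yaml_round_trip(tmp_path, gates):
    path = save_gateset(gates, tmp_path / "gates.yaml")
    back = load_gateset(path)
    assert back.priority == gates.priority
    assert back.acquisition_threshold == gates.acquisition_threshold
    for name in gates.names:
        assert back[name].vertices == gates[name].vertices


# ---------------------------------------------------------------------------
# membership
# ---------------------------------------------------------------------------

def unit_square():
    return Gate("sq", [(0, 0), (1, 0), (1, 1), (0, 1)])


def test_apply_gate_unit_square_and_boundary():
    pts = np.array(
        [
            [0.5, 0.5],  # interior
            [1.0, 1.0],  # vertex -> inside (closed boundary)
            [0.5, 0.0],  # edge -> inside
            [1.5, 0.5],  # outside
        ]
    )
    events = np.zeros((4, 5))
    events[:, 2], events[:, 3] = pts[:, 0], pts[:, 1]
    table = make_table(np.power(10.0, events)).with_events(events, log_transformed=True)
    mask = apply_gate(table, unit_square())
    np.testing.assert_array_equal(mask, [True, True, True, False])


def test_apply_gate_matches_ray_casting_oracle(rng):
    gate = unit_square()
    pts = rng.uniform(0.0, 2.0, size=(10_000, 2))
    events = np.zeros((10_000, 5))
    events[:, 2], events[:, 3] = pts[:, 0], pts[:, 1]
    table = make_table(np.ones_like(events)).with_events(events, log_transformed=True)
    mask = apply_gate(table, gate)
    oracle = np.array([ray_cast(gate.vertices, x, y) for x, y in pts])
    np.testing.assert_array_equal(mask, oracle)
    # expected in-gate fraction 1/4 of the [0,2]^2 box
    assert abs(mask.sum() - 2500) <= 3 * np.sqrt(10_000 * 0.25 * 0.75)


def test_apply_gate_requires_transform_and_channels(rng):
    table = make_table(rng.uniform(1, 1e5, (10, 5)))
    with pytest.raises(ValueError, match="log-transformed"):
        apply_gate(table, unit_square())


# ---------------------------------------------------------------------------
# counting and concentrations
# ---------------------------------------------------------------------------

def in_gate_events(n, gates, name="HNA_p", fl1h=1e4):
    """Linear-scale events placed at the centroid of a named default gate."""
    cx, cy = np.asarray(gates[name].vertices).mean(axis=0)
    events = np.tile([4.0, 4.0, cx, cy, np.log10(fl1h)], (n, 1))
    return np.power(10.0, events)


def test_concentration_arithmetic(gates):
    table = transform_events(
        make_table(in_gate_events(61, gates), acquired_volume_uL=61.0, dilution_factor=100.0)
    )
    result = count_populations(table, gates)
    assert result.counts["HNA_p"] == 61
    assert result.concentrations["HNA_p"] == pytest.approx(100.0)
    assert result.concentrations["LNA_p"] == 0.0  # empty gate -> exactly 0


def test_counts_partition_total(rng, gates):
    table = transform_events(make_table(rng.uniform(1, 3e6, (5000, 5))))
    result = count_populations(table, gates)
    assert sum(result.counts.values()) + result.n_below_threshold == result.total_events
    assert result.counts[UNGATED] >= 0


def test_dilution_linearity_and_volume_scaling(rng, gates):
    raw = rng.uniform(1, 3e6, (2000, 5))
    r1 = count_populations(transform_events(make_table(raw, dilution_factor=100)), gates)
    r2 = count_populations(transform_events(make_table(raw, dilution_factor=200)), gates)
    r3 = count_populations(
        transform_events(make_table(raw, dilution_factor=100, acquired_volume_uL=30.5)), gates
    )
    for name in gates.names:
        assert r2.counts[name] == r1.counts[name]
        assert r2.concentrations[name] == pytest.approx(2 * r1.concentrations[name])
        assert r3.concentrations[name] == pytest.approx(2 * r1.concentrations[name])


def test_acquisition_threshold_discards_low_fl1h(gates):
    events = np.concatenate(
        [in_gate_events(10, gates, fl1h=1e4), in_gate_events(7, gates, fl1h=100.0)]
    )
    table = transform_events(make_table(events))
    result = count_populations(table, gates)
    assert result.n_below_threshold == 7
    assert result.counts["HNA_p"] == 10


def test_monte_carlo_concentration_recovery(gates):
    # constant community at 37.0 cells/µL: mean recovered concentration over
    # 100 seeded replicates within 3 Poisson standard errors
    true_conc, volume, dilution = 37.0, 61.0, 100.0
    lam = true_conc * volume / dilution
    rng = np.random.default_rng(2024)
    recovered = []
    for _ in range(100):
        n = rng.poisson(lam)
        events = in_gate_events(max(n, 0), gates)
        table = transform_events(
            make_table(events, acquired_volume_uL=volume, dilution_factor=dilution)
        )
        recovered.append(count_populations(table, gates).concentrations["HNA_p"])
    se = np.sqrt(lam) * dilution / volume / np.sqrt(100)
    assert abs(np.mean(recovered) - true_conc) <= 3 * se
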