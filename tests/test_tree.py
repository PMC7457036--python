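"""Tree generation, structural invariants, and file IO."""

import numpy as np
import pytest

from corosim.tree import (
    CoronaryTree,
    MorphometrySpec,
    OrderStats,
    TreeParseError,
    TreeValidationError,
    assign_vessel_properties,
    generate_tree,
    read_tree,
    write_tree,
)
from corosim import defaults


def small_spec(seed=7, n_bif=10, n_trif=2):
    return MorphometrySpec(
        n_bif=n_bif, n_trif=n_trif, orders=_orders(), root_order=6, seed=seed
    )


def _orders():
    table = {}
    for o, (d, ln) in enumerate(
        [(0.05, 0.1), (0.08, 0.2), (0.10, 0.3), (0.14, 0.45),
         (0.20, 0.65), (0.27, 0.9), (0.37, 1.2)]
    ):
        table[o] = OrderStats(0.8 * d, d, 1.2 * d, 0.8 * ln, ln, 1.2 * ln)
    return table


# ---- generation -----------------------------------------------------------


def test_generated_counts_match_structural_identity():
    t = generate_tree(small_spec())
    assert t.n_vessels == 1 + 2 * 10 + 3 * 2
    assert t.n_bifurcations == 10
    assert t.n_trifurcations == 2
    assert t.n_leaves == t.n_vessels - t.n_bifurcations - t.n_trifurcations


def test_generation_is_deterministic_per_seed():
    a = generate_tree(small_spec(seed=42))
    b = generate_tree(small_spec(seed=42))
    c = generate_tree(small_spec(seed=43))
    assert np.array_equal(a.parent, b.parent)
    assert np.allclose(a.diameter, b.diameter)
    assert not (np.array_equal(a.parent, c.parent) and np.allclose(a.diameter, c.diameter))


def test_root_carries_highest_order_and_orders_never_increase():
    t = generate_tree(small_spec())
    assert t.order[t.root] == 6
    nonroot = t.parent >= 0
    assert np.all(t.order[nonroot] <= t.order[t.parent[nonroot]])


def test_property_assignment_respects_order_tables():
    spec = small_spec(n_bif=60, n_trif=0)
    t = generate_tree(spec)
    for o in np.unique(t.order):
        st = spec.orders[int(o)]
        d = t.diameter[t.order == o]
        assert np.all((d >= st.d_min - 1e-12) & (d <= st.d_max + 1e-12))
        if len(d) >= 5:  # recentring pins the sample mean inside the range
            assert abs(d.mean() - st.d_mean) < 0.2 * (st.d_max - st.d_min)
    assert np.allclose(t.Ap, spec.ap_frac * t.diameter)
    assert np.allclose(t.Bp, (1 - spec.ap_frac) * t.diameter)


def test_default_specs_build_consistent_trees():
    full = generate_tree(defaults.full_tree_spec(seed=3))
    compact = generate_tree(defaults.compact_tree_spec(seed=3))
    assert full.n_vessels == 1 + 2 * 195 + 3 * 3
    assert compact.n_vessels == 1 + 2 * 24 + 3 * 1
    # individual trees vary a lot with seed; the compact diameter scale is
    # chosen to match the seed-averaged total resistance of the full tree
    mu = 3.5e-3 / 133.322
    seeds = range(1, 6)
    r_full = np.mean(
        [generate_tree(defaults.full_tree_spec(seed=s)).poiseuille_resistance(mu)
         for s in seeds]
    )
    r_compact = np.mean(
        [generate_tree(defaults.compact_tree_spec(seed=s)).poiseuille_resistance(mu)
         for s in seeds]
    )
    assert abs(r_compact - r_full) / r_full < 0.20


# ---- validation -----------------------------------------------------------


def _tree(parent, order=None, **kw):
    n = len(parent)
    args = dict(
        ids=np.arange(n), parent=parent, order=order or [6] * n,
        diameter=np.full(n, 0.1), length=np.full(n, 1.0),
        Ap=np.full(n, 0.08), Bp=np.full(n, 0.02),
        phi_p=np.full(n, 30.0), Cp=np.full(n, 10.0),
    )
    args.update(kw)
    return CoronaryTree(**args)


def test_validate_rejects_multiple_roots():
    with pytest.raises(TreeValidationError, match="root"):
        _tree([-1, -1, 0])


def test_validate_rejects_cycles():
    with pytest.raises(TreeValidationError, match="cycle|root"):
        _tree([2, 0, 1])


def test_validate_rejects_single_child_junction():
    with pytest.raises(TreeValidationError, match="arity"):
        _tree([-1, 0])


def test_validate_rejects_child_order_above_parent():
    with pytest.raises(TreeValidationError, match="order"):
        _tree([-1, 0, 0], order=[5, 6, 4])


def test_validate_rejects_bad_radii_and_lengths():
    with pytest.raises(TreeValidationError, match="Ap > Bp"):
        _tree([-1, 0, 0], Ap=np.full(3, 0.02), Bp=np.full(3, 0.08))
    with pytest.raises(TreeValidationError, match="length"):
        _tree([-1, 0, 0], length=np.array([1.0, -1.0, 1.0]))


def test_spec_rejects_inconsistent_vessel_count():
    with pytest.raises(TreeValidationError, match="n_vessels"):
        MorphometrySpec(n_bif=2, n_trif=0, orders=_orders(), n_vessels=99)


def test_order_stats_reject_degenerate_ranges():
    with pytest.raises(TreeValidationError):
        OrderStats(0.2, 0.1, 0.3, 0.1, 0.2, 0.3)
    with pytest.raises(TreeValidationError):
        OrderStats(0.1, 0.2, 0.3, 0.3, 0.2, 0.1)


def test_missing_order_morphometry_raises():
    spec = small_spec()
    t = generate_tree(spec)
    bad = MorphometrySpec(
        n_bif=10, n_trif=2, orders={6: spec.orders[6]}, seed=1
    )
    with pytest.raises(TreeValidationError, match="order"):
        assign_vessel_properties(t, bad)


# ---- resistance reduction -------------------------------------------------


def test_poiseuille_resistance_series_parallel_oracle():
    # root -> two children: R_total = R0 + (R1 || R2), all full-vessel values
    t = _tree([-1, 0, 0], diameter=np.array([0.2, 0.1, 0.15]),
              length=np.array([2.0, 1.0, 1.5]),
              Ap=np.array([0.16, 0.08, 0.12]), Bp=np.array([0.04, 0.02, 0.03]))
    mu = 0.01
    R = 128 * mu * t.length / (np.pi * t.diameter**4)
    expected = R[0] + 1.0 / (1.0 / R[1] + 1.0 / R[2])
    assert t.poiseuille_resistance(mu) == pytest.approx(expected, rel=1e-12)


# ---- IO -------------------------------------------------------------------


def test_write_read_round_trip_is_exact(tmp_path):
    t = generate_tree(small_spec(seed=11))
    p = tmp_path / "tree.tsv"
    write_tree(t, p)
    t2 = read_tree(p)
    assert np.array_equal(t.parent, t2.parent)
    assert np.array_equal(t.order, t2.order)
    for attr in ("diameter", "length", "Ap", "Bp", "phi_p", "Cp"):
        assert np.array_equal(getattr(t, attr), getattr(t2, attr)), attr


@pytest.mark.parametrize(
    "content,match",
    [
        ("bogus header\n", "header"),
        ("id\tparent_id\torder\tdiameter\tlength\tAp\tBp\tphi_p\tCp\n", "no vessels"),
        (
            "id\tparent_id\torder\tdiameter\tlength\tAp\tBp\tphi_p\tCp\n"
            "0\t\t6\t0.1\t1.0\t0.08\n",
            "fields",
        ),
        (
            "id\tparent_id\torder\tdiameter\tlength\tAp\tBp\tphi_p\tCp\n"
            "0\t\t6\t0.1\t1.0\t0.08\t0.02\t30\t10\n"
            "1\t9\t5\t0.1\t1.0\t0.08\t0.02\t30\t10\n",
            "orphan",
        ),
        (
            "id\tparent_id\torder\tdiameter\tlength\tAp\tBp\tphi_p\tCp\n"
            "0\t\t6\tabc\t1.0\t0.08\t0.02\t30\t10\n",
            "line 2",
        ),
    ],
)
def test_parse_errors_carry_context(tmp_path, content, match):
    p = tmp_path / "bad.tsv"
    p.write_text(content)
    with pytest.raises(TreeParseError, match=match):
        read_tree(p)
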