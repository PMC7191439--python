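"""Lumped bronchial tree: resistances, conservation, flow split."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tracheoflow.network import (
    AirwayTree,
    Branch,
    branch_resistance,
    healthy_infant_tree,
    mirror_symmetric_tree,
    patient_like_tree,
    solve_network,
)

MU, RHO = 1.864e-5, 1.161
Q = 3.0 / 60000.0


def two_branch_tree(d1, d2, k1=0.0, k2=0.0):
    return AirwayTree(
        branches={
            "trachea": Branch("trachea", 0.04, 0.006),
            "A": Branch("A", 0.01, d1, K=k1),
            "B": Branch("B", 0.01, d2, K=k2),
        },
        children={"trachea": ["A", "B"]},
    )


class TestBranchResistance:
    def test_poiseuille_limit(self):
        br = Branch("x", 0.01, 0.003, K=0.0)
        exact = 128 * MU * 0.01 / (np.pi * 0.003**4)
        assert branch_resistance(br, Q) == pytest.approx(exact, rel=1e-12)

    def test_fourth_power_diameter_law(self):
        a = branch_resistance(Branch("a", 0.01, 0.002), Q)
        b = branch_resistance(Branch("b", 0.01, 0.004), Q)
        assert a / b == pytest.approx(16.0, rel=1e-12)

    def test_hand_value_with_minor_loss(self):
        br = Branch("x", 0.012, 0.0026, K=0.6)
        lam = 128 * MU * 0.012 / (np.pi * 0.0026**4)
        A = np.pi * 0.0026**2 / 4
        minor = 0.5 * RHO * (Q / A) ** 2 * 0.6 / Q
        assert branch_resistance(br, Q) == pytest.approx(lam + minor, rel=1e-12)

    def test_invalid_branch(self):
        with pytest.raises(ValueError):
            Branch("x", 0.0, 0.003)
        with pytest.raises(ValueError):
            Branch("x", 0.01, 0.003, K=-1)


class TestSolveNetwork:
    def test_mirror_symmetric_exact_50_50(self):
        sol = solve_network(mirror_symmetric_tree(), Q)
        assert sol.right_share_percent == pytest.approx(50.0, abs=1e-12)
        assert sol.left_share_percent == pytest.approx(50.0, abs=1e-12)

    def test_two_parallel_laminar_branches_closed_form(self):
        tree = two_branch_tree(0.002, 0.003)
        sol = solve_network(tree, Q)
        Ra = branch_resistance(tree.branches["A"], 0.0)
        Rb = branch_resistance(tree.branches["B"], 0.0)
        expect_a = Q * (1 / Ra) / (1 / Ra + 1 / Rb)
        assert sol.flows_m3s["A"] == pytest.approx(expect_a, rel=1e-12)

    def test_junction_conservation_machine_precision(self):
        sol = solve_network(patient_like_tree(), Q)
        f = sol.flows_m3s
        tree = sol.tree
        for parent, kids in tree.children.items():
            assert f[parent] == pytest.approx(sum(f[c] for c in kids), abs=1e-20)
        outlets = tree.outlets()
        assert sum(f[o] for o in outlets) == pytest.approx(Q, rel=1e-14)

    def test_right_dominant_preset(self):
        sol = solve_network(patient_like_tree(), Q)
        assert sol.right_share_percent > sol.left_share_percent
        assert 60 < sol.right_share_percent < 80   # near 7:3

    def test_healthy_preset_milder(self):
        sol = solve_network(healthy_infant_tree(), Q)
        assert 52 < sol.right_share_percent < 62   # near 57:43

    def test_split_invariant_to_root_series_resistance(self):
        a = solve_network(patient_like_tree(root_resistance=0.0), Q)
        b = solve_network(patient_like_tree(root_resistance=1e8), Q)
        assert a.right_share_percent == pytest.approx(
            b.right_share_percent, abs=1e-9
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            solve_network(patient_like_tree(), 0.0)
        with pytest.raises(ValueError):
            AirwayTree(
                branches={"trachea": Branch("trachea", 0.04, 0.006)},
                children={"trachea": ["A"]},
            )


@given(scale=st.floats(0.1, 10.0))
def test_split_invariant_to_uniform_resistance_scaling(scale):
    """Scaling every branch resistance uniformly leaves the split unchanged.

    Laminar resistance scales as L/D^4: multiplying every length by ``scale``
    multiplies every resistance by the same factor.
    """
    base = two_branch_tree(0.002, 0.003)
    scaled = AirwayTree(
        branches={
            b.id: Branch(b.id, b.length * scale, b.diameter, K=0.0)
            for b in base.branches.values()
        },
        children=dict(base.children),
    )
    a = solve_network(base, Q)
    b = solve_network(scaled, Q)
    assert a.flows_m3s["A"] == pytest.approx(b.flows_m3s["A"], rel=1e-10)


def test_solution_frame_shares_sum_to_100():
    sol = solve_network(patient_like_tree(), Q)
    assert sol.right_share_percent + sol.left_share_percent == pytest.approx(100.0)
    df = sol.to_frame()
    assert set(df.columns) == {"branch", "flow_L_min", "share_percent"}
    outlet_rows = df[df.branch.isin(sol.tree.outlets())]
    assert outlet_rows.share_percent.sum() == pytest.approx(100.0)
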