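"""Reduced-order bronchial resistance network for the lung flow split.

The axisymmetric solver resolves the trachea only; the bronchial tree
downstream is represented as a lumped tree of cylindrical branches, each
carrying a Poiseuille resistance plus a quadratic minor-loss term:

    dP(Q) = 128 mu L / (pi D^4) * Q  +  1/2 rho (Q/A)^2 K

All outlets sit at zero gauge pressure (the clinical datum), flows conserve
exactly at junctions, and the right:left split follows from the relative
subtree resistances.  Because the trachea is a common series element, its
surgical state cannot move the split - which is exactly the clinical
observation the network is meant to mirror: correcting tracheal stenoses
leaves the lung flow distribution essentially unchanged.

Default branch dimensions are calibrated (not measured) to give the
right-dominant distribution near 7:3 reported for the reference patient,
whose anomalous left pulmonary artery bows the trachea and favours the
right lung; a healthy-infant preset near 57:43 is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Branch",
    "AirwayTree",
    "NetworkSolution",
    "branch_resistance",
    "solve_network",
    "patient_like_tree",
    "healthy_infant_tree",
    "mirror_symmetric_tree",
]

#: Outlet labels kept verbatim from the clinical description: left main
#: bronchus treated as an outlet alongside the lobar branches.
OUTLET_LABELS = ("LMB", "LSL", "LML", "LIL", "RSL", "RML", "RIL")


@dataclass(frozen=True)
class Branch:
    """One cylindrical airway segment of the lumped tree."""

    id: str
    length: float       # m
    diameter: float     # m
    K: float = 0.0      # minor-loss coefficient (dimensionless, >= 0)

    def __post_init__(self):
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError(f"branch {self.id!r}: length and diameter must be positive")
        if self.K < 0:
            raise ValueError(f"branch {self.id!r}: K must be non-negative")

    @property
    def area(self) -> float:
        return np.pi * self.diameter**2 / 4.0


def branch_resistance(
    branch: Branch, Q: float, mu: float = 1.864e-5, rho: float = 1.161
) -> float:
    """Secant resistance dP/Q at flow Q (Pa s / m^3).

    Laminar Poiseuille term plus the flow-dependent minor-loss term; at
    K = 0 this is exactly the Poiseuille resistance.
    """
    if Q < 0:
        raise ValueError("Q must be non-negative")
    R_lam = 128.0 * mu * branch.length / (np.pi * branch.diameter**4)
    if branch.K > 0.0 and Q > 0.0:
        R_lam += 0.5 * rho * (Q / branch.area) ** 2 * branch.K / Q
    return R_lam


@dataclass
class AirwayTree:
    """Tree of branches rooted at the trachea.

    ``children`` maps a branch id to its child ids; ids without children are
    outlets at zero gauge pressure.  ``root_resistance`` is a fixed series
    resistance for the trachea itself, typically the secant dP/Q taken from
    the axisymmetric CFD solution at the operating flow.
    """

    branches: dict = field(default_factory=dict)   # id -> Branch
    children: dict = field(default_factory=dict)   # id -> list of ids
    root: str = "trachea"
    root_resistance: float = 0.0                   # Pa s / m^3 (from CFD)

    def __post_init__(self):
        seen = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node in seen:
                raise ValueError(f"branch {node!r} appears twice (not a tree)")
            seen.add(node)
            stack.extend(self.children.get(node, []))
        missing = seen - set(self.branches)
        if missing:
            raise ValueError(f"branches without geometry: {sorted(missing)}")

    def outlets(self) -> list:
        return [b for b in self._order() if not self.children.get(b)]

    def _order(self) -> list:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(self.children.get(node, [])))
        return out


@dataclass
class NetworkSolution:
    flows_m3s: dict                 # branch id -> flow
    tree: AirwayTree
    iterations: int
    right_share_percent: float
    left_share_percent: float

    def flows_l_min(self) -> dict:
        return {b: q * 60000.0 for b, q in self.flows_m3s.items()}

    def to_frame(self) -> pd.DataFrame:
        Q_in = self.flows_m3s[self.tree.root]
        rows = [
            {
                "branch": b,
                "flow_L_min": q * 60000.0,
                "share_percent": 100.0 * q / Q_in if Q_in > 0 else 0.0,
            }
            for b, q in self.flows_m3s.items()
        ]
        return pd.DataFrame(rows)


def _effective_resistance(tree, node, flows, mu, rho, memo):
    """Series branch resistance + parallel combination of the children."""
    br = tree.branches[node]
    R = branch_resistance(br, flows.get(node, 0.0), mu, rho)
    if node == tree.root:
        R += tree.root_resistance
    kids = tree.children.get(node, [])
    if kids:
        inv = sum(
            1.0 / _effective_resistance(tree, c, flows, mu, rho, memo) for c in kids
        )
        R += 1.0 / inv
    memo[node] = R
    return R


def _distribute(tree, node, Q, flows, mu, rho, memo):
    flows[node] = Q
    kids = tree.children.get(node, [])
    if not kids:
        return
    inv = [1.0 / memo[c] for c in kids]
    tot = sum(inv)
    for c, iv in zip(kids, inv):
        _distribute(tree, c, Q * iv / tot, flows, mu, rho, memo)


def solve_network(
    tree: AirwayTree,
    Q_in: float,
    mu: float = 1.864e-5,
    rho: float = 1.161,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> NetworkSolution:
    """Fixed-point iteration on the flow-dependent secant resistances.

    Flows conserve at junctions exactly by construction (children split the
    parent flow); the iteration converges the nonlinear minor-loss terms to
    a relative change below ``tol``.
    """
    if Q_in <= 0:
        raise ValueError("Q_in must be positive")
    flows = {b: 0.0 for b in tree.branches}
    flows[tree.root] = Q_in
    prev = None
    for it in range(1, max_iter + 1):
        memo = {}
        _effective_resistance(tree, tree.root, flows, mu, rho, memo)
        flows = {}
        _distribute(tree, tree.root, Q_in, flows, mu, rho, memo)
        vec = np.array([flows[b] for b in sorted(flows)])
        if prev is not None:
            change = np.max(np.abs(vec - prev)) / Q_in
            if change < tol:
                break
        prev = vec
    else:
        raise RuntimeError(
            f"network fixed point did not converge in {max_iter} iterations"
        )
    right = sum(
        q for b, q in flows.items()
        if b.startswith("R") and not tree.children.get(b)
    )
    left = sum(
        q for b, q in flows.items()
        if b.startswith("L") and not tree.children.get(b)
    )
    tot = right + left
    return NetworkSolution(
        flows_m3s=flows,
        tree=tree,
        iterations=it,
        right_share_percent=100.0 * right / tot if tot else 0.0,
        left_share_percent=100.0 * left / tot if tot else 0.0,
    )


# ---------------------------------------------------------------------------
# presets


def _tree(branches, children, root_resistance=0.0):
    return AirwayTree(
        branches={b.id: b for b in branches},
        children=children,
        root_resistance=root_resistance,
    )


def patient_like_tree(root_resistance: float = 0.0) -> AirwayTree:
    """Right-dominant bronchial tree calibrated to a split near 7:3.

    The left main conduit is long and narrow (pulmonary-artery sling bows
    the trachea leftward and compresses the left bronchus); dimensions are
    calibrated, not measured.
    """
    branches = [
        Branch("trachea", 0.045, 0.006),
        Branch("R_main", 0.008, 0.0044, K=0.35),
        Branch("L_main", 0.016, 0.0031, K=0.6),
        Branch("RSL", 0.010, 0.0028, K=0.6),
        Branch("RML", 0.012, 0.0026, K=0.6),
        Branch("RIL", 0.012, 0.0030, K=0.6),
        Branch("LMB", 0.010, 0.0024, K=0.6),
        Branch("LSL", 0.012, 0.0024, K=0.6),
        Branch("LML", 0.013, 0.0022, K=0.6),
        Branch("LIL", 0.012, 0.0026, K=0.6),
    ]
    children = {
        "trachea": ["R_main", "L_main"],
        "R_main": ["RSL", "RML", "RIL"],
        "L_main": ["LMB", "LSL", "LML", "LIL"],
    }
    return _tree(branches, children, root_resistance)


def healthy_infant_tree(root_resistance: float = 0.0) -> AirwayTree:
    """Milder asymmetry giving a split near 57:43 (healthy-infant reference)."""
    branches = [
        Branch("trachea", 0.045, 0.006),
        Branch("R_main", 0.008, 0.0042, K=0.4),
        Branch("L_main", 0.013, 0.0038, K=0.5),
        Branch("RSL", 0.010, 0.0028, K=0.6),
        Branch("RML", 0.012, 0.0026, K=0.6),
        Branch("RIL", 0.012, 0.0030, K=0.6),
        Branch("LMB", 0.010, 0.0026, K=0.6),
        Branch("LSL", 0.012, 0.0025, K=0.6),
        Branch("LML", 0.013, 0.0023, K=0.6),
        Branch("LIL", 0.012, 0.0027, K=0.6),
    ]
    children = {
        "trachea": ["R_main", "L_main"],
        "R_main": ["RSL", "RML", "RIL"],
        "L_main": ["LMB", "LSL", "LML", "LIL"],
    }
    return _tree(branches, children, root_resistance)


def mirror_symmetric_tree(root_resistance: float = 0.0) -> AirwayTree:
    """Identical left/right subtrees; the split must be exactly 50:50."""
    branches = [Branch("trachea", 0.045, 0.006)]
    children = {"trachea": ["R_main", "L_main"]}
    for side in ("R", "L"):
        branches.append(Branch(f"{side}_main", 0.010, 0.004, K=0.5))
        children[f"{side}_main"] = [f"{side}A", f"{side}B"]
        branches.append(Branch(f"{side}A", 0.012, 0.0028, K=0.6))
        branches.append(Branch(f"{side}B", 0.012, 0.0028, K=0.6))
    return _tree(branches, children, root_resistance)
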