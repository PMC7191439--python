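"""End-to-end orchestration of the surgical-scheme comparison.

geometry -> mesh -> RANS solve -> metrics -> bronchial network, per case,
then cross-case deltas and interaction directions.  Also hosts the
grid-sensitivity (Richardson) driver.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .meshgen import build_mesh, refine
from .metrics import REPORT_COLUMNS, MetricsReport, evaluate_case
from .network import patient_like_tree, solve_network
from .scenarios import CaseSpec
from .solver import ConvergenceError, DivergenceError, solve

__all__ = ["CaseResult", "ComparisonReport", "run_case", "run_comparison",
           "grid_sensitivity"]


@dataclass
class CaseResult:
    spec: CaseSpec
    metrics: MetricsReport | None
    state: object = None
    failed: bool = False
    error: str = ""
    runtime_s: float = 0.0
    network: object = None


@dataclass
class ComparisonReport:
    """Per-case metrics plus the cross-case interaction summary."""

    results: dict                    # label -> CaseResult
    deltas: dict = field(default_factory=dict)
    interactions: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def any_failed(self) -> bool:
        return any(r.failed for r in self.results.values())

    def frame(self) -> pd.DataFrame:
        rows = [
            r.metrics.to_row() for r in self.results.values() if r.metrics is not None
        ]
        return pd.DataFrame(rows, columns=REPORT_COLUMNS)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.frame().to_csv(outdir / "metrics.csv", index=False)
        doc = {
            "cases": {k: (r.metrics.to_row() if r.metrics else {"failed": True})
                      for k, r in self.results.items()},
            "deltas": self.deltas,
            "interactions": self.interactions,
            "provenance": self.provenance,
        }
        (outdir / "comparison.json").write_text(json.dumps(doc, indent=2, default=float))
        net_rows = []
        for k, r in self.results.items():
            if r.network is not None:
                df = r.network.to_frame()
                df.insert(0, "case", k)
                net_rows.append(df)
        if net_rows:
            pd.concat(net_rows).to_csv(outdir / "flow_split.csv", index=False)
        for k, r in self.results.items():
            if r.state is not None and r.state.history:
                pd.DataFrame(r.state.history).to_csv(
                    outdir / f"history_{k}.csv", index=False
                )


def run_case(spec: CaseSpec, with_network: bool = True) -> CaseResult:
    """Solve one case; a convergence failure is recorded, not raised."""
    t0 = time.perf_counter()
    profile = spec.build_profile()
    mesh = build_mesh(profile, spec.mesh)
    try:
        state = solve(mesh, spec.bc, spec.fluid, spec.settings)
    except (ConvergenceError, DivergenceError) as exc:
        return CaseResult(
            spec=spec, metrics=None, failed=True, error=str(exc),
            runtime_s=time.perf_counter() - t0,
        )
    report = evaluate_case(state, profile, case=spec.label)
    net = None
    if with_network and spec.bc.inlet_flow_m3s > 0:
        # secant tracheal resistance from the CFD solution feeds the network
        dp_anat = report.energy_loss_W / spec.bc.inlet_flow_m3s**2  # Pa s/m^3
        net = solve_network(
            patient_like_tree(root_resistance=max(dp_anat, 0.0)),
            spec.bc.inlet_flow_m3s, mu=spec.fluid.mu, rho=spec.fluid.rho,
        )
    return CaseResult(
        spec=spec, metrics=report, state=state, network=net,
        runtime_s=time.perf_counter() - t0,
    )


def run_comparison(cases, outdir=None, with_network: bool = True) -> ComparisonReport:
    """Run a list of CaseSpec records and summarise cross-case effects.

    With the four M1-M4 cases present the interaction summary records the
    directions the staged-correction comparison hinges on; with a single
    case it degenerates to that case's metrics alone.
    """
    results = {}
    for spec in cases:
        results[spec.label] = run_case(spec, with_network=with_network)
    report = ComparisonReport(results=results)
    report.provenance = {
        "n_cases": len(cases),
        "labels": [c.label for c in cases],
        "mesh": cases[0].to_config()["mesh"] if cases else {},
        "solver": cases[0].to_config()["solver"] if cases else {},
    }

    ok = {k: r.metrics for k, r in results.items() if r.metrics is not None}
    if {"M1", "M2", "M3", "M4"} <= set(ok):
        m = {k: ok[k] for k in ("M1", "M2", "M3", "M4")}
        lam = {k: v.loss_rate for k, v in m.items()}
        report.deltas = {
            "dP_S2_change_M1_to_M2_Pa": m["M2"].pressure_drop_Pa["S2"]
            - m["M1"].pressure_drop_Pa["S2"],
            "dP_S1_change_M1_to_M3_Pa": m["M3"].pressure_drop_Pa["S1"]
            - m["M1"].pressure_drop_Pa["S1"],
            "lambda": lam,
            "lambda_ratio_M1_over_M3": lam["M1"] / lam["M3"] if lam["M3"] else np.inf,
            "wss_max_S1_Pa": {k: v.wss_max_Pa["S1"] for k, v in m.items()},
            "wss_max_S2_Pa": {k: v.wss_max_Pa["S2"] for k, v in m.items()},
        }
        report.interactions = {
            "correcting_S1_raises_dP_at_S2": bool(
                report.deltas["dP_S2_change_M1_to_M2_Pa"] > 0
            ),
            "correcting_S2_lowers_dP_at_S1": bool(
                report.deltas["dP_S1_change_M1_to_M3_Pa"] < 0
            ),
            "lambda_ordering_M4_le_M3_lt_M2_le_M1": bool(
                lam["M4"] <= lam["M3"] < lam["M2"] <= lam["M1"] * (1 + 1e-9)
            ),
            "wss_S2_exceeds_S1_in_M1": bool(
                m["M1"].wss_max_Pa["S2"] > m["M1"].wss_max_Pa["S1"]
            ),
        }
    if outdir is not None:
        report.write(outdir)
    return report


def grid_sensitivity(spec: CaseSpec, levels: int = 3,
                     metric="EL_W", reference: float | None = None):
    """Refinement study: metric per level plus observed convergence order.

    Each level doubles both cell counts and halves the first-layer height.
    ``metric`` is either a MetricsReport row key or a callable mapping a
    CaseResult to a float.  The observed order comes from Richardson
    differences of successive levels, or from errors against ``reference``
    when an exact value is available.  A level is recommended once the
    successive relative change falls below 1%.
    """
    if levels < 3:
        raise ValueError("need at least 3 refinement levels")
    rows = []
    params = spec.mesh
    for lev in range(levels):
        p = params if lev == 0 else refine(params, 2**lev)
        res = run_case(replace(spec, mesh=p), with_network=False)
        if res.failed:
            raise RuntimeError(f"level {lev} failed: {res.error}")
        value = metric(res) if callable(metric) else res.metrics.to_row()[metric]
        rows.append({
            "level": lev,
            "n_cells": p.n_axial * p.n_radial,
            "value": float(value),
            "runtime_s": res.runtime_s,
        })
    df = pd.DataFrame(rows)
    vals = df["value"].to_numpy()
    if reference is not None:
        err = np.abs(vals - reference)
        with np.errstate(divide="ignore"):
            orders = np.log2(err[:-1] / err[1:])
        col = [np.nan] + list(orders)
    else:
        d = np.abs(np.diff(vals))
        with np.errstate(divide="ignore", invalid="ignore"):
            orders = np.log2(d[:-1] / d[1:])
        col = [np.nan, np.nan] + list(orders)
    df["observed_order"] = col
    rel_change = np.abs(np.diff(vals)) / np.maximum(np.abs(vals[1:]), 1e-300)
    recommended = next(
        (i + 1 for i, rc in enumerate(rel_change) if rc < 0.01), levels - 1
    )
    return df, float(orders[-1]) if len(orders) else np.nan, recommended
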