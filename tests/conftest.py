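"""Shared fixtures: the expensive CFD runs are solved once per session."""

import time
from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

from tracheoflow import (
    make_patient_like_suite,
    make_validation_suite,
    refine,
    run_case,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def validation():
    return make_validation_suite()


@pytest.fixture(scope="session")
def poiseuille_study(validation):
    """Three-level refinement of the laminar pipe (analytic oracle case)."""
    spec = validation["poiseuille"]
    t0 = time.perf_counter()
    results = []
    for lev in range(3):
        mesh = spec.mesh if lev == 0 else refine(spec.mesh, 2**lev)
        res = run_case(replace(spec, mesh=mesh), with_network=False)
        assert not res.failed, res.error
        results.append(res)
    return {"results": results, "runtime_s": time.perf_counter() - t0}


@pytest.fixture(scope="session")
def turbulent_pipe_result(validation):
    t0 = time.perf_counter()
    res = run_case(validation["turbulent_pipe"], with_network=False)
    assert not res.failed, res.error
    return {"result": res, "runtime_s": time.perf_counter() - t0}


@pytest.fixture(scope="session")
def patient_results():
    """The four surgical-scheme cases M1-M4 at default resolution."""
    t0 = time.perf_counter()
    out = {}
    for spec in make_patient_like_suite():
        res = run_case(spec)
        out[spec.label] = res
    return {"results": out, "runtime_s": time.perf_counter() - t0}


@pytest.fixture(scope="session")
def sweep_results(validation):
    out = []
    for spec in validation["severity_sweep"]:
        res = run_case(spec, with_network=False)
        assert not res.failed, res.error
        out.append(res)
    return out


@pytest.fixture(scope="session")
def converged_states(poiseuille_study, turbulent_pipe_result, patient_results,
                     sweep_results):
    """Every converged FlowState the session produced, for invariant checks."""
    states = [r.state for r in poiseuille_study["results"]]
    states.append(turbulent_pipe_result["result"].state)
    states += [r.state for r in patient_results["results"].values()
               if not r.failed]
    states += [r.state for r in sweep_results]
    return states
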