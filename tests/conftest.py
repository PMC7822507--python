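"""Shared fixtures: published truth models, small fast designs, one trial."""

from __future__ import annotations

import numpy as np
import pytest

from graftrisk.dataio import SubjectCourse
from graftrisk.nlme_fit import (
    PopPKModel,
    RandomEffectsSpec,
    ResidualSpec,
    compile_design,
    simulate_observations,
)
from graftrisk.pk_model import ConcObservation, DoseEvent, StructuralParams
from graftrisk.study_sim import MPA_TRUTH, TAC_TRUTH, TrialConfig, simulate_trial


@pytest.fixture(scope="session")
def tac_truth():
    return TAC_TRUTH


@pytest.fixture(scope="session")
def mpa_truth():
    return MPA_TRUTH


@pytest.fixture(scope="session")
def trial():
    """One default 58-subject synthetic trial, shared across tests."""
    return simulate_trial(TrialConfig(), seed=11)


def make_small_model(omega_cl: float = 0.09, sigma: float = 0.15,
                     kind: str = "additive_log", labels=("cl",)) -> PopPKModel:
    """A quick-to-fit one-random-effect model on a short dosing course."""
    variances = {l: omega_cl for l in labels}
    return PopPKModel(
        typical=StructuralParams(cl=10.0, vc=50.0, q=15.0, vp=200.0, ka=1.5,
                                 tlag=0.2),
        random=RandomEffectsSpec.diagonal(**variances),
        residual=ResidualSpec(kind, sigma=sigma),
    )


def make_small_courses(n_subjects: int, rng: np.random.Generator,
                       rich: bool = True) -> list[SubjectCourse]:
    """Twice-daily dosing over 3 days with day-3 sampling (fast design)."""
    times = (72.0 + np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 11.5])
             if rich else 72.0 + np.array([0.0, 2.0]))
    courses = []
    for i in range(n_subjects):
        weight = float(np.exp(np.log(70.0) + 0.2 * rng.standard_normal()))
        doses = [DoseEvent(f"T{i}", 12.0 * j, 5.0) for j in range(7)]
        obs = [ConcObservation(f"T{i}", float(t), 1.0) for t in times]
        cov = {"GFR": float(rng.uniform(10, 90)),
               "AGE": float(rng.uniform(25, 65))}
        courses.append(SubjectCourse(f"T{i}", weight, doses, obs, cov))
    return courses


def simulate_small(model: PopPKModel, n_subjects: int, seed: int,
                   rich: bool = True):
    """Simulate observations for a small design; returns (courses, design)."""
    rng = np.random.default_rng(seed)
    courses = make_small_courses(n_subjects, rng, rich=rich)
    design = compile_design(courses)
    y = simulate_observations(model, design, rng)
    k = 0
    for c in courses:
        new = []
        for o in c.observations:
            new.append(ConcObservation(o.subject_id, o.time, float(y[k]),
                                       o.occasion))
            k += 1
        c.observations = new
    return courses, compile_design(courses)
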