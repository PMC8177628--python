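"""Shared fixtures: toy models, normalized compositions, measurement sets,
and affine maps, all generated programmatically."""

from __future__ import annotations

import pytest

from multibof.bof import (
    composition_from_reaction,
    mean_bofs,
    normalize_unit_mass,
)
from multibof.fba import EnvironmentPoint
from multibof.methods import BOFMeasurement, MeasurementSet, fit_affine_map
from multibof.model_io import TOY_GROUPS, ToySpec, make_toy_model

DIMS = ["EX_glc__D_e", "EX_nh4_e"]


@pytest.fixture()
def core_model():
    return make_toy_model(ToySpec(), seed=1)


@pytest.fixture()
def chain_model():
    return make_toy_model(ToySpec(topology="chain"), seed=1)


@pytest.fixture()
def bof_a(core_model):
    bof = normalize_unit_mass(
        composition_from_reaction(core_model, "BIOMASS_A", TOY_GROUPS, label="A")
    )
    bof.label = "A"
    return bof


@pytest.fixture()
def bof_b(core_model):
    bof = normalize_unit_mass(
        composition_from_reaction(core_model, "BIOMASS_B", TOY_GROUPS, label="B")
    )
    bof.label = "B"
    return bof


def _mix(bof_a, bof_b, weight_a, label):
    mixed = normalize_unit_mass(
        mean_bofs(bof_a.scaled(2.0 * weight_a), bof_b.scaled(2.0 * (1.0 - weight_a)))
    )
    mixed.label = label
    return mixed


@pytest.fixture()
def measurement_set(bof_a, bof_b):
    """Three affinely independent environment points with distinct BOFs."""
    mid = _mix(bof_a, bof_b, 0.5, "MID")
    return MeasurementSet(
        measurements=[
            BOFMeasurement(
                EnvironmentPoint({DIMS[0]: 10.0, DIMS[1]: 8.0}, "upper_bound"), bof_a
            ),
            BOFMeasurement(
                EnvironmentPoint({DIMS[0]: 10.0, DIMS[1]: 1.0}, "upper_bound"), bof_b
            ),
            BOFMeasurement(
                EnvironmentPoint({DIMS[0]: 2.0, DIMS[1]: 4.0}, "upper_bound"), mid
            ),
        ],
        dimensions=list(DIMS),
    )


@pytest.fixture()
def hip_map(measurement_set, bof_a):
    return fit_affine_map(measurement_set, bof_a)


@pytest.fixture()
def contractive_map(bof_a, bof_b):
    """A map whose HIP-I iteration contracts quickly (compositions vary less
    steeply with the nitrogen coordinate)."""
    lo = _mix(bof_a, bof_b, 0.8, "LO")
    mid = _mix(bof_a, bof_b, 0.9, "MID")
    ms = MeasurementSet(
        measurements=[
            BOFMeasurement(
                EnvironmentPoint({DIMS[0]: 10.0, DIMS[1]: 8.0}, "upper_bound"), bof_a
            ),
            BOFMeasurement(
                EnvironmentPoint({DIMS[0]: 10.0, DIMS[1]: 1.0}, "upper_bound"), lo
            ),
            BOFMeasurement(
                EnvironmentPoint({DIMS[0]: 2.0, DIMS[1]: 4.0}, "upper_bound"), mid
            ),
        ],
        dimensions=list(DIMS),
    )
    return fit_affine_map(ms, bof_a)
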