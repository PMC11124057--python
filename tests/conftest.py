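"""Shared fixtures: one synthetic study bundle built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from desolv.features import (
    DescriptorEngine,
    build_feature_table,
    r2_profile,
    select_sigma_points,
    target_vector,
)
from desolv.simulate import (
    GeneratorConfig,
    gen_fusion_data,
    gen_sigma_profiles,
    gen_solubility_dataset,
)


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def profiles(gen_config):
    return gen_sigma_profiles(gen_config)


@pytest.fixture(scope="session")
def fusion(gen_config):
    return gen_fusion_data(gen_config)


@pytest.fixture(scope="session")
def dataset(gen_config, profiles, fusion):
    records, truth = gen_solubility_dataset(gen_config, profiles, fusion)
    return records, truth


@pytest.fixture(scope="session")
def engine(profiles, fusion):
    return DescriptorEngine(profiles, fusion)


@pytest.fixture(scope="session")
def relpots(dataset, engine):
    records, _ = dataset
    return {
        r.record_id: engine.relative_potential(r.solute, r.system, r.T)
        for r in records
    }


@pytest.fixture(scope="session")
def selection(dataset, relpots):
    records, _ = dataset
    non_des = [r for r in records if not r.is_des]
    des = [r for r in records if r.is_des]
    return select_sigma_points(
        r2_profile(non_des, relpots), r2_profile(des, relpots)
    )


@pytest.fixture(scope="session")
def feature_table(dataset, engine, selection):
    records, _ = dataset
    return build_feature_table(records, engine, selection)


@pytest.fixture(scope="session")
def targets(dataset):
    records, _ = dataset
    return target_vector(records)
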