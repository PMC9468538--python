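"""Shared fixtures: one synthetic database generated once per session."""

from __future__ import annotations

import pytest

from mqtlhot import (
    GeneratorConfig,
    generate_database,
    load_genetic_map,
    load_ld_decay,
    load_mta,
    load_studies,
    load_anchor_table,
    project_database,
    standardize,
)

SESSION_SEED = 11


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """Default-condition synthetic database: (config, file paths, ground truth)."""
    cfg = GeneratorConfig(seed=SESSION_SEED)
    paths, truth = generate_database(cfg, tmp_path_factory.mktemp("sim"))
    return cfg, paths, truth


@pytest.fixture(scope="session")
def sim_loaded(sim):
    """The same database loaded into memory objects."""
    cfg, paths, truth = sim
    return {
        "cfg": cfg,
        "truth": truth,
        "paths": paths,
        "studies": load_studies(paths["studies"]),
        "mta": load_mta(paths["mta"]),
        "map": load_genetic_map(paths["map"], name="consensus"),
        "ld": load_ld_decay(paths["ld_decay"]),
        "anchors_svevo": load_anchor_table(paths["anchors_Svevo"], "Svevo"),
        "anchors_cs": load_anchor_table(paths["anchors_CS"], "CS"),
    }


@pytest.fixture(scope="session")
def sim_standardized(sim_loaded):
    """Projected and CI-standardized MTAs of the session database."""
    projected = project_database(
        sim_loaded["mta"], None, sim_loaded["map"], sim_loaded["ld"]
    )
    return [standardize(p) for p in projected]
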