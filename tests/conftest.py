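from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

from nutridbk import PipelineConfig, Source
from nutridbk.fixtures import FixtureSpec, generate_fixture
from nutridbk.pipeline import run_full_pipeline

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

#: one fixed seed for the shared synthetic databank used across the suite
SUITE_SEED = 11


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """A generated toy databank at the default (study-shaped) scale."""
    out = tmp_path_factory.mktemp("fixture")
    spec = FixtureSpec(seed=SUITE_SEED)
    manifest = generate_fixture(spec, out)
    return SimpleNamespace(dir=out, spec=spec, manifest=manifest)


@pytest.fixture(scope="session")
def pipeline_artifacts(fixture_set, tmp_path_factory):
    """Full two-stage pipeline run (permissive: the deliberate unmatched
    recipe is dropped with a warning instead of aborting the run)."""
    out = tmp_path_factory.mktemp("pipeline_out")
    fx = fixture_set.dir
    cfg = PipelineConfig.from_yaml(fx / "config.yaml").with_overrides(on_unmatched="exclude")
    artifacts = run_full_pipeline(
        cfg,
        {Source(k): fx / v for k, v in fixture_set.manifest["fct_files"].items()},
        fx / "recipes.csv",
        fx / "ingredient_mapping.csv",
        out,
        gapfill_mapping_path=fx / "gapfill_mapping.csv",
        retention_factors_path=fx / "retention_factors.csv",
        retention_assignment_path=fx / "retention_assignment.csv",
    )
    artifacts["out_dir"] = out
    artifacts["config"] = cfg
    return artifacts
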