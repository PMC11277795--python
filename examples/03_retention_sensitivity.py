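"""With/without-retention sensitivity analysis over a whole databank.

Generates the default study-shaped synthetic databank (four sources,
~200 recipes, 42.62% of ingredient lines with a retention assignment),
computes every recipe's nutrients twice — raw, and with each food's
cooking-loss retention factors applied — and prints the paired
per-nutrient comparison: medians of both arms, the mean decrease, and
the two-sided Wilcoxon signed-rank p-value.
"""

import tempfile
from pathlib import Path

from nutridbk import PipelineConfig, Source
from nutridbk.fixtures import FixtureSpec, generate_fixture
from nutridbk.pipeline import run_full_pipeline

with tempfile.TemporaryDirectory() as td:
    fx = Path(td) / "fixture"
    manifest = generate_fixture(FixtureSpec(seed=1), fx)
    cfg = PipelineConfig.from_yaml(fx / "config.yaml").with_overrides(on_unmatched="exclude")
    artifacts = run_full_pipeline(
        cfg,
        {Source(k): fx / v for k, v in manifest["fct_files"].items()},
        fx / "recipes.csv",
        fx / "ingredient_mapping.csv",
        Path(td) / "out",
        gapfill_mapping_path=fx / "gapfill_mapping.csv",
        retention_factors_path=fx / "retention_factors.csv",
        retention_assignment_path=fx / "retention_assignment.csv",
    )

comparison = artifacts["comparison"]
print(comparison.head(6).to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()
ranges = artifacts["retention_ranges"]
for nutrient in ("calcium_mg", "vitc_mg"):
    lo, hi = ranges[nutrient]
    print(f"retention factor range for {nutrient}: {lo:.0%} - {hi:.0%}")
# Every covered nutrient decreases (factors are <= 1), the shifts are
# small relative to the medians, and the paired signed-rank p-values are
# far below 0.01 because the decrease is systematic across recipes.
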