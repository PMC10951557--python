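"""Seeded end-to-end fixture and its committed golden outputs.

Run ``python tests/golden_fixture.py`` from the repository root to
regenerate ``tests/golden/`` after an intentional behaviour change.
"""

from pathlib import Path

from ccre.pipeline import RunConfig
from ccre.synth import TraitSimConfig

GOLDEN_DIR = Path(__file__).parent / "golden"

# files compared byte-for-byte by the determinism criterion
GOLDEN_FILES = (
    "climate_changes.csv",
    "effect_sizes.csv",
    "pairwise_regressions.csv",
    "importance_matrix.csv",
    "best_models.csv",
    "models_leaf_area.csv",
    "economics_regressions.csv",
    "economics_scores.csv",
    "overall_species_change.csv",
    "ancillary_regressions.csv",
    "simulation_truth.csv",
    "collinearity_flags.csv",
)


def golden_config() -> RunConfig:
    return RunConfig(
        seed=2024,
        n_species=20,
        analysis_traits=("leaf_area",),
        horn_iterations=200,
        traits=TraitSimConfig(
            slopes={"mean_temp": 0.05, "max_heatwave_dur": 0.1},
            species_sd_tau=0.03,
            missing_prob=0.05,
        ),
    )


if __name__ == "__main__":
    from ccre.pipeline import run_all

    run_all(golden_config(), out_dir=GOLDEN_DIR)
    print(f"golden outputs written to {GOLDEN_DIR}")
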