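"""Shared configuration for the numbered analysis scripts.

All scripts drive the same deterministic run: a 504-participant
synthetic cohort with the full 18-set layout at desk-scale feature
dimensions (40-column task contrasts, 300-pair connectivity matrices
reduced to 20 components, structural sets at their native sizes),
tuned on the reduced 7 x 5 hyperparameter grid.

Stages are pure functions of the configuration seed, so a later script
re-derives any earlier stage it needs bit-identically; outputs land in
``results/run`` next to this directory.
"""

from pathlib import Path

from brainage_eval.config import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "run"

SEED = 1


def study_config(seed: int = SEED) -> RunConfig:
    return RunConfig(
        seed=seed,
        cohort={
            "preset": "study",
            "n_participants": 504,
            "contrast_dim": 40,
            "connectivity_dim": 300,
        },
        grid="reduced",
        n_components=20,
        importance=True,
        out_dir=str(RUN_DIR),
    )
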