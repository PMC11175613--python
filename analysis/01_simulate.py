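"""Stage 1: generate the synthetic cohort and write it under results/run/data."""

from pathlib import Path

from common import study_config
from brainage_eval.pipeline import simulate_stage


def main() -> None:
    cfg = study_config()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, features, truth = simulate_stage(cfg, out)
    print(f"cohort: {len(cohort)} participants, {len(features.names)} feature sets")
    print(f"ground-truth age-cognition R2: {truth.expected_r2_age_cognition:.4f}")
    print(f"written under {out / 'data'}")


if __name__ == "__main__":
    main()
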