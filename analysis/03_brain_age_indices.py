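"""Stage 3: Brain Age indices (gap, corrected, corrected gap) and Brain
Cognition per participant per model, writing indices.csv."""

from pathlib import Path

import pandas as pd

from common import study_config
from brainage_eval.pipeline import indices_stage, predict_stage, simulate_stage


def main() -> None:
    cfg = study_config()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, features, _ = simulate_stage(cfg, out)
    results, models, scheme = predict_stage(cfg, out, cohort, features)
    indices_stage(out, cohort, results, models, scheme)
    idx = pd.read_csv(out / "indices.csv")
    print(f"index table: {idx['model'].nunique()} models x {len(cohort)} participants")
    best = idx[idx["model"] == "stacked_all"]
    corr = best[["age", "brain_age_gap", "corrected_brain_age_gap"]].corr()["age"]
    print("stacked_all gap-age correlations:")
    print(corr.drop("age").round(3).to_string())


if __name__ == "__main__":
    main()
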