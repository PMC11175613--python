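"""Stage 2: nested-CV Elastic Net prediction of age and cognition for
all 26 models (18 feature sets + 8 stacks), writing predictions.csv,
metrics.csv, importance.csv and importance_stability.csv."""

from pathlib import Path

import pandas as pd

from common import study_config
from brainage_eval.pipeline import predict_stage, simulate_stage


def main() -> None:
    cfg = study_config()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, features, _ = simulate_stage(cfg, out)
    results, _, _ = predict_stage(cfg, out, cohort, features)
    metrics = pd.read_csv(out / "metrics.csv")
    pooled = (
        metrics.groupby(["target", "model"])["r2"].mean()
        .groupby(level="target", group_keys=False).nlargest(3)
    )
    print("top mean per-fold R2 by target:")
    print(pooled.round(3).to_string())


if __name__ == "__main__":
    main()
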