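"""Stage 4: simple regressions and 2-/3-block commonality analyses of
fluid cognition, writing simple_regression.csv, commonality2.csv and
commonality3.csv."""

from pathlib import Path

import pandas as pd

from common import study_config
from brainage_eval.pipeline import (
    commonality_stage,
    indices_stage,
    predict_stage,
    simulate_stage,
)


def main() -> None:
    cfg = study_config()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, features, _ = simulate_stage(cfg, out)
    results, models, scheme = predict_stage(cfg, out, cohort, features)
    tables = indices_stage(out, cohort, results, models, scheme)
    commonality_stage(cfg, out, tables)
    c2 = pd.read_csv(out / "commonality2.csv")
    c3 = pd.read_csv(out / "commonality3.csv")
    print("max unique effect per Brain Age index:")
    print(c2.groupby("index")["unique_index"].max().round(4).to_string())
    print(f"max unique effect of Brain Cognition: "
          f"{c3['unique_brain_cognition'].max():.4f}")


if __name__ == "__main__":
    main()
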