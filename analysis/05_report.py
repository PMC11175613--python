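"""Stage 5: run everything end to end (deterministic re-derivation of
stages 1-4) and produce the summary tables performance_summary.csv and
index_summary.csv under results/run."""

from common import study_config
from brainage_eval.pipeline import run_all, report


def main() -> None:
    cfg = study_config()
    run_dir = run_all(cfg)
    out = report(run_dir)
    perf = out["performance"]
    print("model performance (mean per-fold metrics):")
    for target, grp in perf.groupby("target"):
        print(f"\n== {target} ==")
        print(grp.head(5).to_string(index=False))
    print("\nindex summary (variance in fluid cognition):")
    print(out["index_summary"].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
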