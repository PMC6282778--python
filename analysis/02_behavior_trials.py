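"""Segment the canonical session into trials and summarize behaviour.

Writes results/trials.tsv (one row per trial with inclusion flags) and
prints per-condition trial counts and mean speeds — the synthetic
animal shuttles ~40 trials per block at the programmed tilt-dependent
speeds, with everything passing the 7 s inclusion rule.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _session import make_session

from slopecell import behavior


def main() -> None:
    session, _ = make_session()
    trials = behavior.apply_trial_filters(behavior.segment_trials(session))
    df = pd.DataFrame([
        {"trial_id": t.trial_id, "block_id": t.block_id, "tilt_deg": t.tilt,
         "direction": t.direction, "t_start_s": t.t_start, "t_end_s": t.t_end,
         "duration_s": t.duration, "mean_speed_cms": t.mean_speed,
         "included": t.included, "reason": t.reason or ""}
        for t in trials
    ])
    Path("results").mkdir(exist_ok=True)
    df.to_csv("results/trials.tsv", sep="\t", index=False, float_format="%.4f")
    by = df[df.included].groupby(["tilt_deg", "direction"]).agg(
        n=("trial_id", "size"), speed=("mean_speed_cms", "mean"))
    print(f"{df.included.sum()}/{len(df)} trials included")
    print(by.round(1))


if __name__ == "__main__":
    main()
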