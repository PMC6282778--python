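"""Rate maps, place-cell criteria, and the per-condition metric battery.

Writes results/metrics.tsv (one row per unit x condition) and
results/metrics_by_condition.tsv (means over the cells meeting the
place-cell criteria on each condition, i.e. the condition averages the
metric battery is designed to feed).
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from _session import make_session

from slopecell.pipeline import analyze_session


def main() -> None:
    session, _ = make_session()
    res = analyze_session(session, do_shuffles=False, do_precession=False,
                          do_within_between=False)
    mf = res.metrics_frame()
    Path("results").mkdir(exist_ok=True)
    mf.to_csv("results/metrics.tsv", sep="\t", index=False, float_format="%.4f")

    active = mf[mf.is_place_cell]
    cols = ["mean_rate_hz", "peak_rate_hz", "information_bits", "sparsity",
            "coherence_z", "n_fields", "main_field_coverage"]
    by = active.groupby(["tilt_deg", "direction"])[cols].mean()
    by.to_csv("results/metrics_by_condition.tsv", sep="\t", float_format="%.3f")
    print(f"{len(res.place_cells())} of {mf.unit_id.nunique()} units meet the "
          "place-cell criteria on at least one condition")
    print(by.round(2))


if __name__ == "__main__":
    main()
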