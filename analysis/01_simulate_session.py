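"""Generate the canonical synthetic session and archive it under scratch/.

Writes the session directory (positions, spikes, LFP, schedule) to
scratch/session_seed1/ and a record-count summary to
results/session_summary.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _session import SEED, make_session

from slopecell.session_io import write_session


def main() -> None:
    session, truth = make_session()
    out = Path("scratch/session_seed1")
    write_session(session, out)
    summary = {
        "seed": SEED,
        "n_position_samples": int(session.positions_t.size),
        "duration_s": round(float(session.positions_t[-1]), 1),
        "n_units": len(session.spike_trains),
        "n_spikes_total": int(sum(s.size for s in session.spike_trains.values())),
        "n_blocks": len(session.schedule),
        "programmed_remap_mix": {
            label: sum(1 for v in truth.remap_labels.values() if v == label)
            for label in sorted(set(truth.remap_labels.values()))
        },
    }
    Path("results").mkdir(exist_ok=True)
    Path("results/session_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"wrote session to {out}")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
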