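"""Generate a small demonstration cohort of synthetic recordings.

Writes two 15-second sessions (pupil + airflow CSVs with ground-truth
sidecar) under results/cohort_demo/.  The full-scale cohorts used by
the later analyses (40 participants, 5-minute sessions) are generated
in memory by those scripts; this demo exists so the canonical file
format can be inspected by eye.
"""

import json
from pathlib import Path

from prp.recordings import write_recording
from prp.simulate import GeneratorConfig, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort_demo"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = GeneratorConfig(n_participants=2, session_duration_s=15.0, seed=0)
    recordings, truths = generate_cohort(cfg)
    for rec in recordings:
        write_recording(rec, OUT / f"{rec.participant_id}_{rec.session_id}.csv")
    summary = {
        f"{pid}/{sid}": {
            "amplitude_z": round(t.amplitude_z, 4),
            "peak_phase_deg": round(t.peak_phase_deg, 2),
            "n_cycles": len(t.landmarks),
            "n_blinks": len(t.blink_intervals_ms),
        }
        for (pid, sid), t in truths.items()
    }
    (OUT / "ground_truth.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    print(f"wrote {len(recordings)} demo recordings to {OUT}")
    for key, s in summary.items():
        print(f"  {key}: amplitude {s['amplitude_z']} z, peak {s['peak_phase_deg']} deg, "
              f"{s['n_cycles']} cycles, {s['n_blinks']} blinks")


if __name__ == "__main__":
    main()
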