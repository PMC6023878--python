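"""Generate the default synthetic cohort and write it to results/cohort/.

Two sessions of 30 units, 40 trials per state per class, with the default
planted structure: an engaged spontaneous shift, symmetric passive vs
target-dominated engaged evoked geometry, a persistent engaged silence
code, weaker engaged phase locking, and 10% lick-locked units.
"""

import sys
from pathlib import Path

from popshift.synthetic import GeneratorConfig, generate_cohort
from popshift.data_model import write_session

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    cfg = GeneratorConfig()
    sessions, truth = generate_cohort(cfg, SEED)
    for sess in sessions:
        write_session(sess, OUT / sess.session_id)
    truth.to_json(OUT / "ground_truth.json")
    n_spk = sum(len(s.spikes) for s in sessions)
    print(f"wrote {len(sessions)} sessions, {cfg.n_units * cfg.n_sessions} units, "
          f"{n_spk} spikes -> {OUT}")
    print(f"planted lick units: {truth.lick_unit_ids}")


if __name__ == "__main__":
    main()
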