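"""Cross-validated decoding of stimulus class, passive vs engaged.

Per-100-ms-bin prototype decoding with pseudo-population resampling
(lick-responsive units excluded per 04_lick_control.py), a label-shuffle
null, temporal generalization between the early-sound / late-sound /
silence periods, and transfer of correct-trained decoders to error trials.

Expected on the default cohort: near-ceiling sound-window accuracy in both
states; silence-window accuracy high only when engaged (persistent target
code); sound-trained decoders do not generalize to the silence epoch
(orthogonal planted codes); error-trial silence accuracy drops toward the
passive level.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from popshift.data_model import read_session
from popshift.decoder import (
    build_pool,
    cross_validated_accuracy,
    decode_transfer,
    shuffled_null,
    temporal_generalization,
)

ROOT = Path(__file__).resolve().parents[1] / "results"
N_RESAMPLES = 100
N_PERM, N_CV = 40, 40
SEED = 11


def main() -> None:
    dirs = sorted((ROOT / "cohort").glob("s*"))
    sessions = [read_session(d, session_id=d.name) for d in dirs]
    retained = json.loads((ROOT / "lick_removal.json").read_text())["retained"]
    tpl = sessions[0].template
    windows = {"sound": tpl.windows["sound_window"], "silence": tpl.windows["silence_window"]}

    rows, summary = [], {}
    for state in ("passive", "engaged"):
        pool = build_pool(sessions, state=state, unit_subset=retained)
        res = cross_validated_accuracy(
            pool, bins=range(pool.n_bins), n_resamples=N_RESAMPLES, seed=SEED
        )
        for t, m, s, lo, hi in zip(res.feature_times, res.mean, res.std, *res.ci95):
            rows.append({"state": state, "time_s": t, "accuracy": m, "std": s,
                         "ci_low": lo, "ci_high": hi})
        for name, win in windows.items():
            idx = [i for i, f in enumerate(res.features) if pool.bin_starts[f[0]] >= win[0]
                   and pool.bin_starts[f[0]] < win[1]]
            summary[f"{state}_{name}_accuracy"] = float(res.mean[idx].mean())
    pd.DataFrame(rows).to_csv(ROOT / "decoding_accuracy.csv", index=False)

    eng_pool = build_pool(sessions, state="engaged", unit_subset=retained)
    null = shuffled_null(eng_pool, windows=list(windows.values()),
                         n_perm=N_PERM, n_cv=N_CV, seed=SEED)
    obs = np.array([summary[f"engaged_{w}_accuracy"] for w in windows])
    pvals, _ = null.p_value(obs)
    summary["null_mean"] = null.mean.tolist()
    summary["p_vs_null"] = pvals.tolist()

    tg_windows = [tpl.windows["early_sound"], tpl.windows["late_sound"],
                  (2.7, 2.9)]
    mat = temporal_generalization(eng_pool, tg_windows, test_windows=tg_windows,
                                  n_resamples=N_RESAMPLES, seed=SEED)
    summary["generalization_matrix"] = np.round(mat, 3).tolist()

    train = build_pool(sessions, state="engaged", outcome="correct", unit_subset=retained)
    test = build_pool(sessions, state="engaged",
                      outcome={"reference": "correct", "target": "error"},
                      unit_subset=retained, min_trials=1)
    transfer = decode_transfer(train, test, windows=list(windows.values()),
                               n_resamples=N_RESAMPLES, seed=SEED)
    summary["transfer"] = {w: float(v) for w, v in zip(windows, transfer)}

    (ROOT / "decoding_summary.json").write_text(json.dumps(summary, indent=1))
    for k, value in summary.items():
        print(f"{k}: {value}")


if __name__ == "__main__":
    main()
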