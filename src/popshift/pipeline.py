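"""End-to-end orchestration of the population analyses.

``run_full_analysis`` executes the full sequence on a synthetic cohort (or
sessions read from disk): single-unit metrics, stimulus reconstruction,
lick-unit removal, cross-validated decoding with shuffle nulls, and
decoding-axis geometry.  All stage outputs are gathered into an
:class:`AnalysisReport` whose payload is reproducible given the seeds in
the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import EpochTemplate, SessionData, bin_spikes, epoch_mean_rate, read_session
from .decoder import (
    build_pool,
    cross_validated_accuracy,
    decode_transfer,
    shuffled_null,
)
from .geometry import (
    class_averages,
    cross_state_projection,
    distance_from_baseline,
    enhancement_index_trace,
    latency_half_max,
    project_on_axis,
    spontaneous_baseline,
    uniform_weight_projection,
)
from .lick_control import LickControlParams, iterative_unit_removal
from .metrics import VS_RATE_FLOOR_HZ, modulation_index, vector_strength
from .reconstruction import ReconstructionParams, loo_reconstruction_mse
from .stats import bonferroni, wilcoxon_signed_rank_one_sample
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["DecodingParams", "RunConfig", "AnalysisReport", "run_full_analysis",
           "unit_metrics_table", "reconstruction_table"]

log = logging.getLogger("popshift")


@dataclass(frozen=True)
class DecodingParams:
    """Printed defaults of the decoding stage."""

    width: float = 0.1
    step: float | None = None
    n_train: int = 15
    n_resamples: int = 400
    n_perm: int = 100
    n_cv: int = 100


@dataclass
class RunConfig:
    """Full-run configuration: generator (or paths), stage parameters, seeds."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    session_dirs: list[str] | None = None  # read instead of simulate
    decoding: DecodingParams = field(default_factory=DecodingParams)
    reconstruction: ReconstructionParams = field(default_factory=ReconstructionParams)
    lick: LickControlParams = field(default_factory=LickControlParams)
    seed: int = 0
    exclude_lick_units: bool = True
    run_reconstruction: bool = True
    run_null: bool = True
    outdir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(_as_jsonable(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_as_jsonable(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = dict(raw)
        if "generator" in kw and isinstance(kw["generator"], dict):
            g = dict(kw["generator"])
            if "template" in g and isinstance(g["template"], dict):
                g["template"] = EpochTemplate.from_dict(g["template"])
            kw["generator"] = GeneratorConfig(**g)
        for name, typ in [
            ("decoding", DecodingParams),
            ("reconstruction", ReconstructionParams),
            ("lick", LickControlParams),
        ]:
            if name in kw and isinstance(kw[name], dict):
                kw[name] = typ(**kw[name])
        return cls(**kw)


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if isinstance(obj, EpochTemplate):
            return obj.to_dict()
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class AnalysisReport:
    """Stage outputs, statistics and provenance of one full run."""

    tables: dict[str, pd.DataFrame]
    summary: dict
    provenance: dict

    def payload(self) -> dict:
        """JSON-able payload excluding timestamps (for determinism checks)."""
        out = {
            "summary": _as_jsonable(self.summary),
            "tables": {k: v.to_dict(orient="list") for k, v in self.tables.items()},
            "provenance": {
                k: v for k, v in self.provenance.items() if k not in ("elapsed_s",)
            },
        }
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(_as_jsonable({"summary": self.summary, "provenance": self.provenance}), indent=1)
        )


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def unit_metrics_table(sessions: list[SessionData]) -> pd.DataFrame:
    """Per-unit spontaneous/evoked rates, MI(engaged, passive), and VS.

    VS rows (one per unit x state x stimulus) follow the 1 spike/s
    unit-inclusion floor; MI compares engaged vs passive epoch rates.
    """
    rows = []
    for sess in sessions:
        tpl = sess.template
        period_by_trial = dict(zip(sess.trials["trial_id"], 1.0 / sess.trials["click_rate_hz"]))
        binned = bin_spikes(sess, width=0.05)
        spont = {}
        evoked = {}
        for state in ("passive", "engaged"):
            tids = sess.select_trials(state=state)
            sub = binned.select_trials(tids)
            spont[state] = epoch_mean_rate(sub, tpl.epoch("pre_silence")).mean(axis=1)
            evoked[state] = epoch_mean_rate(sub, tpl.click_train, baseline_correct=True).mean(axis=1)
        click_a, click_b = tpl.click_train
        sp = sess.spikes
        in_click = (sp["time_s"] >= click_a) & (sp["time_s"] < click_b)
        spc = sp[in_click]
        trial_info = sess.trials.set_index("trial_id")
        for i, u in enumerate(sess.unit_ids):
            mi_spont = modulation_index(max(spont["engaged"][i], 0), max(spont["passive"][i], 0))
            mi_evoked = modulation_index(
                max(evoked["engaged"][i], 0), max(evoked["passive"][i], 0)
            )
            row = {
                "unit_id": u,
                "session_id": sess.session_id,
                "spont_passive": spont["passive"][i],
                "spont_engaged": spont["engaged"][i],
                "mi_spont": mi_spont.mi,
                "mi_evoked": mi_evoked.mi,
            }
            usp = spc[spc["unit_id"] == u]
            for state in ("passive", "engaged"):
                for stim in ("reference", "target"):
                    tids = set(sess.select_trials(state=state, stimulus=stim))
                    t = usp[usp["trial_id"].isin(tids)]["time_s"].to_numpy()
                    n_tr = len(tids)
                    rate = t.size / (n_tr * (click_b - click_a)) if n_tr else 0.0
                    if rate < VS_RATE_FLOOR_HZ or t.size == 0:
                        row[f"vs_{state}_{stim}"] = np.nan
                        continue
                    tid0 = next(iter(tids))
                    vs = vector_strength(t, period_by_trial[tid0], onset=click_a)
                    row[f"vs_{state}_{stim}"] = vs.r
            rows.append(row)
    return pd.DataFrame(rows)


def reconstruction_table(
    sessions: list[SessionData], params: ReconstructionParams
) -> pd.DataFrame:
    """Per-session LOO reconstruction MSE per (state, stimulus) and state MI."""
    rows = []
    for sess in sessions:
        res = loo_reconstruction_mse(sess, params)
        for (state, stim), mse in res.mean_mse.items():
            rows.append(
                {
                    "session_id": sess.session_id,
                    "state": state,
                    "stimulus": stim,
                    "mean_mse": mse,
                    "mi_engaged_vs_passive": res.state_mi(stim),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

def run_full_analysis(config: RunConfig) -> AnalysisReport:
    """Simulate/ingest -> metrics -> reconstruction -> lick removal ->
    decoding -> geometry, gathering tables and a JSON-able summary."""
    t0 = time.time()
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {}

    # -- data ------------------------------------------------------------
    if config.session_dirs:
        sessions = [
            read_session(d, session_id=f"s{i}") for i, d in enumerate(config.session_dirs)
        ]
        truth = None
    else:
        sessions, truth = generate_cohort(config.generator, config.seed)
    log.info("stage=data sessions=%d units=%d", len(sessions), sum(len(s.unit_ids) for s in sessions))

    # -- single-unit metrics ---------------------------------------------
    um = unit_metrics_table(sessions)
    tables["unit_metrics"] = um
    stat, p = wilcoxon_signed_rank_one_sample(um["mi_spont"].to_numpy())
    summary["spontaneous_mi"] = {
        "median": float(np.nanmedian(um["mi_spont"])),
        "wilcoxon_stat": stat,
        "p": p,
        "n": int(um["mi_spont"].notna().sum()),
    }
    log.info("stage=metrics n_units=%d", len(um))

    # -- stimulus reconstruction -----------------------------------------
    if config.run_reconstruction:
        rt = reconstruction_table(sessions, config.reconstruction)
        tables["reconstruction"] = rt
        mis = rt.drop_duplicates(["session_id", "stimulus"])["mi_engaged_vs_passive"]
        summary["reconstruction_mi"] = {"mean": float(np.mean(mis)), "n": int(len(mis))}
        log.info("stage=reconstruction cells=%d", len(rt))

    # -- lick control -----------------------------------------------------
    retained = None
    if config.exclude_lick_units and any(len(s.licks) for s in sessions):
        removal = iterative_unit_removal(sessions, config.lick, seed=config.seed + 1)
        retained = removal.retained_unit_ids
        summary["lick_control"] = {
            "removed": list(removal.removed_unit_ids),
            "p_trajectory": removal.p_trajectory,
            "final_p": removal.final_p,
        }
        log.info("stage=lick_control removed=%d", len(removal.removed_unit_ids))

    # -- decoding ---------------------------------------------------------
    dp = config.decoding
    tpl = sessions[0].template
    windows = {"sound": tpl.windows["sound_window"], "silence": tpl.windows["silence_window"]}
    pools = {
        st: build_pool(sessions, state=st, width=dp.width, step=dp.step, unit_subset=retained)
        for st in ("passive", "engaged")
    }
    acc_rows = []
    decoders = {}
    p_cmp = {}
    for wname, win in windows.items():
        for st, pool in pools.items():
            res = cross_validated_accuracy(
                pool, windows=[win], n_train=dp.n_train, n_resamples=dp.n_resamples,
                seed=config.seed + 2,
            )
            decoders[(wname, st)] = res
            ci = res.ci95
            acc_rows.append(
                {
                    "window": wname,
                    "state": st,
                    "accuracy": float(res.mean[0]),
                    "std": float(res.std[0]),
                    "ci_low": float(ci[0, 0]),
                    "ci_high": float(ci[1, 0]),
                }
            )
        a_p = decoders[(wname, "passive")].accuracies[0]
        a_e = decoders[(wname, "engaged")].accuracies[0]
        n = min(len(a_p), len(a_e))
        p_cmp[wname] = max(1.0 / n, float(np.mean(a_p[:n] >= a_e[:n])))
    tables["decoding_accuracy"] = pd.DataFrame(acc_rows)
    adj = bonferroni(np.array(list(p_cmp.values())))
    summary["decoding"] = {
        "p_engaged_gt_passive": {k: float(v) for k, v in p_cmp.items()},
        "p_bonferroni": {k: float(v) for k, v in zip(p_cmp, adj)},
        "min_p_bound": 1.0 / dp.n_resamples,
    }
    if config.run_null:
        null = shuffled_null(
            pools["engaged"], windows=list(windows.values()), n_perm=dp.n_perm,
            n_cv=dp.n_cv, n_train=dp.n_train, seed=config.seed + 3,
        )
        obs = np.array([decoders[(w, "engaged")].mean[0] for w in windows])
        pvals, counts = null.p_value(obs)
        summary["null"] = {
            "null_mean": null.mean.tolist(),
            "p_vs_null": pvals.tolist(),
            "raw_counts": counts.tolist(),
        }
    # correct -> error transfer
    has_errors = any(len(s.select_trials(state="engaged", outcome="error")) for s in sessions)
    if has_errors:
        train_pool = build_pool(
            sessions, state="engaged", width=dp.width, step=dp.step,
            outcome="correct", unit_subset=retained,
        )
        test_pool = build_pool(
            sessions, state="engaged", width=dp.width, step=dp.step,
            outcome={"reference": "correct", "target": "error"},
            unit_subset=retained, min_trials=1,
        )
        transfer = decode_transfer(
            train_pool, test_pool, windows=list(windows.values()),
            n_train=dp.n_train, n_resamples=max(dp.n_resamples // 4, 10),
            seed=config.seed + 4,
        )
        summary["transfer"] = {w: float(v) for w, v in zip(windows, transfer)}
    log.info("stage=decoding windows=%d", len(windows))

    # -- geometry ----------------------------------------------------------
    avgs = {st: class_averages(pools[st]) for st in pools}
    bases = {st: spontaneous_baseline(pools[st]) for st in pools}
    times = pools["engaged"].bin_starts + dp.width / 2.0
    geo = {}
    for wname, win in windows.items():
        w_eng = decoders[(wname, "engaged")].weights[0]
        dists = {}
        for st in pools:
            trace = project_on_axis(
                avgs[st], decoders[(wname, st)].weights[0], bases[st], times,
                mode="subtract_spontaneous",
            )
            d = distance_from_baseline(trace, win)
            dists[st] = {c: float(np.mean(d[c])) for c in d}
        asym = {st: dists[st]["target"] - dists[st]["reference"] for st in pools}
        tei = (dists["engaged"]["target"] - dists["passive"]["target"]) - (
            dists["engaged"]["reference"] - dists["passive"]["reference"]
        )
        cases = cross_state_projection(w_eng, avgs, bases, times, win)
        geo[wname] = {
            "distances": dists,
            "asymmetry": asym,
            "target_enhancement_index": float(tei),
            "cross_state_asymmetry": {k: float(np.mean(v)) for k, v in cases.items()},
        }
    uni = uniform_weight_projection(avgs, bases)
    sound_bins = pools["engaged"].window_bins(windows["sound"])
    geo["uniform_weight_tei_sound"] = float(uni[:, sound_bins].mean())
    # latency of the projected engaged target trace on each axis
    for wname in windows:
        trace = project_on_axis(
            avgs["engaged"], decoders[(wname, "engaged")].weights[0], bases["engaged"],
            times, mode="subtract_spontaneous",
        )
        lat = latency_half_max(
            times, trace.mean("target"), response_window=(tpl.click_train[0], tpl.trial_span),
            baseline_window=tpl.epoch("pre_silence"), onset=tpl.click_train[0],
        )
        geo[f"latency_{wname}_axis_s"] = float(lat.latency) if lat.defined else None
    summary["geometry"] = geo
    log.info("stage=geometry done")

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "elapsed_s": time.time() - t0,
        "n_sessions": len(sessions),
        "n_units": int(sum(len(s.unit_ids) for s in sessions)),
    }
    report = AnalysisReport(tables=tables, summary=summary, provenance=provenance)
    if config.outdir:
        report.write(config.outdir)
    return report
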