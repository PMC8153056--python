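"""End-to-end orchestration: detection, QC, preprocessing, statistics.

``run_pipeline`` drives a whole study from on-disk subject recordings (or
a synthetic study generated on the fly) to a report bundle of TSV/JSON
results: R-peak detection and block QC, the preprocessing cascade,
behavioral indices, cluster contrasts (delay and attention main effects,
the attention x delay double-subtraction interaction with simple effects,
ECG controls, pre-sound controls, the first-vs-fourth-sound ANOVA), and
cardiac dynamics (post-omission IBIs, SDRR, ANOVAs, post-hoc tests with
Bayes factors).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import behavior_sdt, cardiac_events, cardio_dynamics, cluster_stats
from . import hep_preprocess as prep
from . import io as cio
from .containers import ContinuousRecording, EpochSet, Evoked, SensorLayout
from .synthgen import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

ATTENTIONS = ("internal", "external")
DELAYS = ("short", "long")


@dataclass
class PipelineConfig:
    data_dir: str = "study"
    out_dir: str = "report"
    simulate: Optional[SimulationConfig] = None
    seed: int = 0
    n_perm: int = 1000
    z_threshold: float = 3.0
    eeg_band: tuple[float, float] = (0.5, 40.0)
    ecg_band: tuple[float, float] = (0.5, 150.0)
    epoch_window: tuple[float, float] = (-0.3, 0.8)
    adjacency_dist: float = 0.15
    min_cluster_channels: int = 4
    min_cluster_times: int = 2
    ecg_min_cluster_channels: int = 1     # two-lead ECG cannot span 4 sensors
    run_ica: bool = True
    run_cfa: bool = True
    run_controls: bool = True
    exclusion_fraction: float = 1.0 / 3.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if sim is not None:
            beh = sim.pop("behavior", None)
            from .synthgen import BehaviorParams
            sim = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in sim.items()}
            if "omission_effect_uv" in sim:
                sim["omission_effect_uv"] = {
                    tuple(k.split("/")): v
                    for k, v in sim["omission_effect_uv"].items()}
            cfg.simulate = SimulationConfig(
                **sim, **({"behavior": BehaviorParams(**beh)} if beh else {}))
        return cfg

    def digest(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, np.ndarray):
                return o.tolist()
            return o
        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class SubjectResult:
    subject: str
    excluded: bool
    n_trials_rejected: int
    n_blocks_rejected: int
    bad_channels: list
    # omission-locked and R-locked evokeds per (attention, delay)
    evoked_omission: dict
    evoked_rlocked: dict
    evoked_ecg_omission: dict
    evoked_ecg_rlocked: dict
    evoked_presound: dict          # (attention, delay) -> Evoked (first R post cue)
    evoked_sound_pos: dict         # (delay, position 1|4) -> Evoked
    indices: Optional[behavior_sdt.SDTIndices]
    ibi_table: pd.DataFrame
    sdrr_table: pd.DataFrame
    mean_ibi_table: pd.DataFrame


def _block_bounds(events: pd.DataFrame) -> list[tuple[float, float]]:
    bounds = []
    trials = events[events["kind"] == "cue"]
    for b in sorted(trials["block"].unique()):
        blk = events[(events["block"] == b) & (events["kind"] != "rpeak")]
        bounds.append((blk["onset_s"].min() - 0.5, blk["onset_s"].max() + 1.5))
    return bounds


def _trigger_events(events: pd.DataFrame, targets: pd.DataFrame,
                    rpeak_times: np.ndarray, fs: float,
                    margin: dict[str, float]) -> pd.DataFrame:
    """R-peak rows for the beats that triggered the given target events."""
    rows = []
    for _, ev in targets.iterrows():
        cutoff = ev["onset_s"] - margin.get(ev["delay"], 0.0)
        k = int(np.searchsorted(rpeak_times, cutoff + 1e-9) - 1)
        if k < 0:
            continue
        row = ev.to_dict()
        row.update(sample=int(round(rpeak_times[k] * fs)),
                   onset_s=rpeak_times[k], kind="rpeak")
        rows.append(row)
    return pd.DataFrame(rows)


def _cell_average(epochs: EpochSet, lowpass: Optional[float] = 20.0) -> dict:
    out = {}
    for (att, dly) in [(a, d) for a in ATTENTIONS for d in DELAYS]:
        mask = ((epochs.metadata["attention"] == att)
                & (epochs.metadata["delay"] == dly)).to_numpy()
        if mask.sum() == 0:
            continue
        out[(att, dly)] = prep.robust_average(
            epochs.select(mask), condition=f"{att}/{dly}", lowpass_hz=lowpass)
    return out


def preprocess_subject(
    recording: ContinuousRecording,
    events: pd.DataFrame,
    behavior: pd.DataFrame,
    layout: SensorLayout,
    cfg: PipelineConfig,
    subject: str = "sub",
) -> SubjectResult:
    """Single-subject detection, QC, preprocessing, averaging, indices."""
    fs = recording.fs
    log = {"subject": subject}

    # --- cardiac chain: detect, QC blocks
    from ._filters import bandpass as _bp
    ecg_rec = recording.pick("ecg")
    ecg_f = ecg_rec.copy()
    ecg_f.data = _bp(ecg_rec.data, fs, *cfg.ecg_band)
    rpeaks = cardiac_events.detect_rpeaks_offline(ecg_f.data[0], fs)
    rpeak_times = rpeaks / fs
    bounds = _block_bounds(events)
    keep_blocks = cardiac_events.qc_blocks(rpeak_times, bounds)
    n_blocks_rej = int((~keep_blocks).sum())
    kept_blocks = {b for b, k in enumerate(keep_blocks) if k}

    # --- event reconstruction with detected beats
    nonr = events[events["kind"] != "rpeak"]
    det_rows = pd.DataFrame({
        "sample": rpeaks, "onset_s": rpeak_times, "kind": "rpeak",
        "trial": -1, "block": -1, "attention": "", "delay": "",
        "omission_trial": 0})
    events_d = pd.concat([nonr, det_rows], ignore_index=True) \
        .sort_values("sample", kind="stable").reset_index(drop=True)

    omissions = nonr[(nonr["kind"] == "omission")
                     & (nonr["block"].isin(kept_blocks))]
    margin = {d: cardiac_events.DELAY_MEANS[d] - 0.096 for d in DELAYS}
    trig_r = _trigger_events(events_d, omissions, rpeak_times, fs, margin)

    # --- EEG chain
    eeg_idx = [i for i, k in enumerate(recording.ch_kinds) if k != "ecg"]
    eeg_rec = ContinuousRecording(
        recording.data[eeg_idx], fs,
        [recording.ch_names[i] for i in eeg_idx],
        [recording.ch_kinds[i] for i in eeg_idx])
    eeg_rec = prep.filter_continuous(eeg_rec, *cfg.eeg_band)

    tmin, tmax = cfg.epoch_window
    if trig_r.empty:
        raise RuntimeError(f"{subject}: no omission-trigger R-peaks resolvable")
    # R-locked epochs lock on the omission-trigger beats (condition-labeled)
    ep_r = prep.make_epochs(eeg_rec, events_d, "rpeak", tmin, tmax,
                            lock_events=trig_r)
    ep_om = prep.make_epochs(eeg_rec, events_d, "omission", tmin, tmax)
    ep_om = ep_om.select(ep_om.metadata["block"].isin(kept_blocks).to_numpy())

    # mastoid reference before artifact scanning
    ep_r = prep.rereference(ep_r, "mastoids")
    ep_om = prep.rereference(ep_om, "mastoids")

    # --- three-stage cascade (channels -> trials -> ERP channels) on the
    # R-locked epochs; identical rejections applied to both epoch sets
    rep1 = prep.scan_artifacts("channels_raw", ep_r, cfg.z_threshold)
    bad_channels = [c for c in rep1.flagged if not c.startswith("M")]
    work = ep_r.drop_channels(bad_channels) if bad_channels else ep_r
    rep2 = prep.scan_artifacts("trials", work, cfg.z_threshold)
    bad_trials = set(work.metadata.loc[list(rep2.flagged), "trial"]) \
        if rep2.flagged else set()
    if bad_trials:
        work = work.select(~work.metadata["trial"].isin(bad_trials).to_numpy())
    rep3 = prep.scan_artifacts("channels_erp", work, cfg.z_threshold)
    bad_channels += [c for c in rep3.flagged if not c.startswith("M")]

    def clean(ep: EpochSet) -> EpochSet:
        out = ep.select(~ep.metadata["trial"].isin(bad_trials).to_numpy())
        if cfg.run_ica:
            sub = out.drop_channels(bad_channels) if bad_channels else out
            try:
                cleaned, _ = prep.remove_stationary_artifacts(sub, layout)
                if bad_channels:
                    keep = [i for i, n in enumerate(out.ch_names)
                            if n not in set(bad_channels)]
                    out = out.copy()
                    out.data[:, keep] = cleaned.data
                else:
                    out = cleaned
            except ValueError as err:
                logger.warning("decomposition skipped: %s", err)
        if bad_channels:
            out = prep.interpolate_channels(out, layout, bad_channels)
        return prep.rereference(out, "average")

    ep_r, ep_om = clean(ep_r), clean(ep_om)
    n_trials_rej = len(bad_trials)
    frac = n_trials_rej / max(len(omissions), 1)
    excluded = frac > cfg.exclusion_fraction

    # --- resting template and CFA correction
    if cfg.run_cfa:
        first_cue = nonr.loc[nonr["kind"] == "cue", "onset_s"].min()
        rest_r = det_rows[det_rows["onset_s"] < first_cue - 1.0]
        if len(rest_r) >= 3:
            ep_rest = prep.make_epochs(eeg_rec, events_d, "rpeak", tmin, tmax,
                                       lock_events=rest_r)
            ep_rest = prep.rereference(ep_rest, "mastoids")
            if bad_channels:
                ep_rest = prep.interpolate_channels(ep_rest, layout, bad_channels)
            ep_rest = prep.rereference(ep_rest, "average")
            resting = prep.robust_average(ep_rest, "rest", lowpass_hz=None)
            ep_r = prep.cfa_correct(ep_r, resting)
            ep_om = prep.cfa_correct(ep_om, resting)
        else:
            logger.warning("%s: no rest period found; CFA correction skipped",
                           subject)

    evoked_om = _cell_average(ep_om)
    evoked_r = _cell_average(ep_r)

    # --- ECG epochs through the identical averaging path
    ecg_ep_r = prep.make_epochs(ecg_f, events_d, "rpeak", tmin, tmax,
                                lock_events=trig_r)
    ecg_ep_om = prep.make_epochs(ecg_f, events_d, "omission", tmin, tmax)
    ecg_ep_om = ecg_ep_om.select(
        ecg_ep_om.metadata["block"].isin(kept_blocks).to_numpy())
    evoked_ecg_r = _cell_average(ecg_ep_r)
    evoked_ecg_om = _cell_average(ecg_ep_om)

    # --- control evokeds
    evoked_presound: dict = {}
    evoked_sound_pos: dict = {}
    if cfg.run_controls:
        cues = nonr[(nonr["kind"] == "cue") & (nonr["block"].isin(kept_blocks))]
        pre_rows = []
        for _, cue in cues.iterrows():
            k = int(np.searchsorted(rpeak_times, cue["onset_s"]))
            if k >= len(rpeak_times):
                continue
            row = cue.to_dict()
            row.update(sample=int(round(rpeak_times[k] * fs)),
                       onset_s=rpeak_times[k], kind="rpeak")
            pre_rows.append(row)
        if pre_rows:
            ep_pre = prep.make_epochs(eeg_rec, events_d, "rpeak", tmin, tmax,
                                      lock_events=pd.DataFrame(pre_rows))
            ep_pre = prep.rereference(ep_pre, "mastoids")
            if bad_channels:
                ep_pre = prep.interpolate_channels(ep_pre, layout, bad_channels)
            ep_pre = prep.rereference(ep_pre, "average")
            evoked_presound = _cell_average(ep_pre)
        tones = nonr[(nonr["kind"] == "tone") & (nonr["block"].isin(kept_blocks))]
        for pos in (1, 4):
            nth = (tones.sort_values("sample").groupby("trial", sort=True)
                   .nth(pos - 1).reset_index(drop=True))
            trig_n = _trigger_events(events_d, nth, rpeak_times, fs, margin)
            if trig_n.empty:
                continue
            ep_n = prep.make_epochs(eeg_rec, events_d, "rpeak", tmin, tmax,
                                    lock_events=trig_n)
            ep_n = prep.rereference(ep_n, "mastoids")
            if bad_channels:
                ep_n = prep.interpolate_channels(ep_n, layout, bad_channels)
            ep_n = prep.rereference(ep_n, "average")
            for dly in DELAYS:
                mask = (ep_n.metadata["delay"] == dly).to_numpy()
                if mask.sum():
                    evoked_sound_pos[(dly, pos)] = prep.robust_average(
                        ep_n.select(mask), f"{dly}/sound{pos}")

    # --- behavior and cardiac dynamics (kept blocks only)
    beh = behavior[behavior["block"].isin(kept_blocks)] \
        if "block" in behavior else behavior
    indices = None
    try:
        indices = behavior_sdt.interoceptive_indices(beh)
    except (ValueError, RuntimeError) as err:
        logger.warning("%s: behavioral indices failed: %s", subject, err)

    ibi = cardio_dynamics.omission_ibi_table(
        events_d[events_d["kind"] == "omission"]
        .loc[lambda d: d["block"].isin(kept_blocks)],
        rpeak_times, subject=subject)

    # mean IBI and SDRR per attention x delay over within-condition beats
    sd_rows, mean_rows = [], []
    for att in ATTENTIONS:
        for dly in DELAYS:
            cond_tr = nonr[(nonr["attention"] == att) & (nonr["delay"] == dly)
                           & (nonr["kind"] == "cue")
                           & (nonr["block"].isin(kept_blocks))]
            vals = []
            for _, cue in cond_tr.iterrows():
                resp = nonr[(nonr["trial"] == cue["trial"])
                            & (nonr["kind"] == "response")]
                t1 = resp["onset_s"].iloc[0] if len(resp) else cue["onset_s"] + 10
                sel = rpeak_times[(rpeak_times >= cue["onset_s"])
                                  & (rpeak_times <= t1)]
                vals.extend(np.diff(sel) * 1e3)
            if len(vals) >= 2:
                sd_rows.append({"subject": subject, "attention": att,
                                "delay": dly,
                                "sdrr_ms": cardio_dynamics.sdrr(vals)})
                mean_rows.append({"subject": subject, "attention": att,
                                  "delay": dly,
                                  "ibi_ms": float(np.mean(vals))})

    return SubjectResult(
        subject=subject, excluded=excluded,
        n_trials_rejected=n_trials_rej, n_blocks_rejected=n_blocks_rej,
        bad_channels=bad_channels,
        evoked_omission=evoked_om, evoked_rlocked=evoked_r,
        evoked_ecg_omission=evoked_ecg_om, evoked_ecg_rlocked=evoked_ecg_r,
        evoked_presound=evoked_presound, evoked_sound_pos=evoked_sound_pos,
        indices=indices, ibi_table=ibi,
        sdrr_table=pd.DataFrame(sd_rows), mean_ibi_table=pd.DataFrame(mean_rows),
    )


# ---------------------------------------------------------------------------
# group level

def _crop(ev: Evoked, window: tuple[float, float]) -> np.ndarray:
    m = (ev.times >= window[0] - 1e-9) & (ev.times < window[1] - 1e-9)
    return ev.data[:, m]


def _stack_cells(results: list[SubjectResult], attr: str,
                 window) -> np.ndarray:
    """subjects x attention x delay x channels x time array from evokeds.

    ``window`` may be a fixed (t0, t1) tuple or a callable(delay) -> window
    for condition-specific windows.
    """
    per_sub = []
    for r in results:
        cells = getattr(r, attr)
        mats = []
        for att in ATTENTIONS:
            row = []
            for dly in DELAYS:
                w = window(dly) if callable(window) else window
                row.append(_crop(cells[(att, dly)], w))
            mats.append(row)
        n_t = min(m.shape[1] for row in mats for m in row)
        per_sub.append([[m[:, :n_t] for m in row] for row in mats])
    n_t = min(m.shape[1] for s in per_sub for row in s for m in row)
    return np.asarray([[[m[:, :n_t] for m in row] for row in s]
                       for s in per_sub])


def _cluster_rows(name: str, res: cluster_stats.ClusterTestResult,
                  times: np.ndarray, ch_names: list[str]) -> list[dict]:
    rows = []
    for i, cl in enumerate(res.clusters):
        rows.append({
            "contrast": name, "cluster": i,
            "polarity": "pos" if cl.polarity > 0 else "neg",
            "mass": cl.mass, "p": cl.p,
            "n_channels": cl.n_channels, "n_times": cl.time_extent,
            "t_start": float(times[cl.times.min()]),
            "t_end": float(times[cl.times.max()]),
            "channels": ",".join(sorted({ch_names[c] for c in cl.channels})),
        })
    if not rows:
        rows.append({"contrast": name, "cluster": -1, "polarity": "",
                     "mass": 0.0, "p": 1.0, "n_channels": 0, "n_times": 0,
                     "t_start": np.nan, "t_end": np.nan, "channels": ""})
    return rows


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full analysis; returns the report directory path."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logh = logging.FileHandler(out / "run.log", mode="w")
    logh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cardioaudio")
    root.addHandler(logh)
    root.setLevel(logging.INFO)
    try:
        return _run_pipeline(cfg, out)
    finally:
        root.removeHandler(logh)
        logh.close()


def _run_pipeline(cfg: PipelineConfig, out: Path) -> Path:
    logger.info("config digest %s, seed %d", cfg.digest(), cfg.seed)
    data_dir = Path(cfg.data_dir)
    if cfg.simulate is not None:
        logger.info("generating synthetic study in %s", data_dir)
        simulate_dataset(cfg.simulate, data_dir)

    layout = cio.read_layout(data_dir / "layout.tsv")
    sub_dirs = sorted(p for p in data_dir.iterdir()
                      if p.is_dir() and p.name.startswith("sub-"))
    if not sub_dirs:
        raise FileNotFoundError(f"no subject directories in {data_dir}")

    results: list[SubjectResult] = []
    for sdir in sub_dirs:
        rec = cio.read_edf(sdir / "recording.edf")
        missing = [n for n, k in zip(rec.ch_names, rec.ch_kinds)
                   if k != "ecg" and n not in set(layout.ch_names)]
        if missing:
            raise ValueError(f"layout missing recorded channels: {missing}")
        events = cio.read_events(sdir / "events.tsv", rec.fs)
        behavior = cio.read_behavior(sdir / "behavior.tsv")
        logger.info("preprocessing %s", sdir.name)
        res = preprocess_subject(rec, events, behavior, layout, cfg, sdir.name)
        logger.info("%s: %d trials rejected, %d blocks rejected, bad %s%s",
                    res.subject, res.n_trials_rejected, res.n_blocks_rejected,
                    res.bad_channels, " EXCLUDED" if res.excluded else "")
        results.append(res)
    kept = [r for r in results if not r.excluded]
    if len(kept) < 2:
        raise RuntimeError("fewer than 2 subjects survive exclusion")

    # ---- behavioral indices
    idx_rows = [dict(subject=r.subject, **r.indices.to_dict())
                for r in kept if r.indices is not None]
    idx_df = pd.DataFrame(idx_rows)
    if len(idx_df):
        for col in ("d_internal", "meta_d", "sensibility"):
            idx_df[f"group_{col}"] = behavior_sdt.median_split(idx_df[col])
    idx_df.to_csv(out / "behavior_indices.tsv", sep="\t", index=False)

    beh_stats = {}
    if len(idx_df) >= 4:
        from scipy.stats import pearsonr, ttest_1samp
        for col in ("d_internal", "d_external"):
            t, p = ttest_1samp(idx_df[col], 0.0)
            beh_stats[col] = {
                "t": float(t), "p": float(p), "n": int(len(idx_df)),
                "bf10": cardio_dynamics.jzs_bf10_ttest(float(t), len(idx_df))}
        r, p = pearsonr(idx_df["d_internal"], idx_df["d_external"])
        beh_stats["corr_internal_external"] = {
            "r": float(r), "p": float(p),
            "bf10": cardio_dynamics.corr_bf10(float(r), len(idx_df))}
    cio.write_json(beh_stats, out / "behavior_stats.json")

    # ---- cluster contrasts
    eeg_names = kept[0].evoked_omission[("internal", "short")].ch_names
    adj = cluster_stats.build_adjacency(layout.subset(eeg_names),
                                        cfg.adjacency_dist)
    rows = []
    kw = dict(n_perm=cfg.n_perm, min_channels=cfg.min_cluster_channels,
              min_times=cfg.min_cluster_times)

    r_window = cluster_stats.condition_windows("R_locked", "short")
    r_cells = _stack_cells(kept, "evoked_rlocked", r_window)
    times_r = kept[0].evoked_rlocked[("internal", "short")].times
    times_r = times_r[(times_r >= r_window[0]) & (times_r < r_window[1])]
    delay_me = cluster_stats.cluster_permutation_test(
        r_cells[:, :, 0].mean(axis=1), r_cells[:, :, 1].mean(axis=1),
        "paired", adj, seed=cfg.seed, **kw)
    rows += _cluster_rows("main_effect_delay_Rlocked", delay_me, times_r, eeg_names)
    att_me = cluster_stats.cluster_permutation_test(
        r_cells[:, 0].mean(axis=1), r_cells[:, 1].mean(axis=1),
        "paired", adj, seed=cfg.seed + 10, **kw)
    rows += _cluster_rows("main_effect_attention_Rlocked", att_me, times_r, eeg_names)

    om_window = cluster_stats.condition_windows(
        "omission_locked", "short", relative_to_omission=True)
    om_cells = _stack_cells(kept, "evoked_omission", om_window)
    times_om = kept[0].evoked_omission[("internal", "short")].times
    times_om = times_om[(times_om >= om_window[0]) & (times_om < om_window[1])]
    inter = cluster_stats.interaction_contrast(
        om_cells, adj, n_perm=cfg.n_perm, seed=cfg.seed + 20,
        min_channels=cfg.min_cluster_channels, min_times=cfg.min_cluster_times)
    rows += _cluster_rows("interaction_omission", inter.interaction,
                          times_om, eeg_names)
    if inter.simple_internal is not None:
        rows += _cluster_rows("simple_internal_omission", inter.simple_internal,
                              times_om, eeg_names)
        rows += _cluster_rows("simple_external_omission", inter.simple_external,
                              times_om, eeg_names)

    # ECG controls through the identical code path
    ecg_names = kept[0].evoked_ecg_omission[("internal", "short")].ch_names
    ecg_adj = cluster_stats.AdjacencyGraph(
        ecg_names, ~np.eye(len(ecg_names), dtype=bool))
    ecg_kw = dict(n_perm=cfg.n_perm,
                  min_channels=cfg.ecg_min_cluster_channels,
                  min_times=cfg.min_cluster_times)
    ecg_r = _stack_cells(kept, "evoked_ecg_rlocked", r_window)
    ecg_delay = cluster_stats.cluster_permutation_test(
        ecg_r[:, :, 0].mean(axis=1), ecg_r[:, :, 1].mean(axis=1),
        "paired", ecg_adj, seed=cfg.seed + 30, **ecg_kw)
    rows += _cluster_rows("ecg_control_delay_Rlocked", ecg_delay, times_r, ecg_names)
    ecg_om = _stack_cells(kept, "evoked_ecg_omission", om_window)
    ecg_inter = cluster_stats.interaction_contrast(
        ecg_om, ecg_adj, n_perm=cfg.n_perm, seed=cfg.seed + 40,
        min_channels=cfg.ecg_min_cluster_channels,
        min_times=cfg.min_cluster_times)
    rows += _cluster_rows("ecg_control_interaction", ecg_inter.interaction,
                          times_om, ecg_names)

    controls = {}
    if cfg.run_controls and all(r.evoked_presound for r in kept):
        # pre-sound interaction in the condition-specific post-R windows
        pre_cells = _stack_cells(
            kept, "evoked_presound",
            lambda d: cluster_stats.condition_windows("omission_locked", d))
        pre_inter = cluster_stats.interaction_contrast(
            pre_cells, adj, n_perm=cfg.n_perm, seed=cfg.seed + 50,
            run_simple_effects=False,
            min_channels=cfg.min_cluster_channels,
            min_times=cfg.min_cluster_times)
        rows += _cluster_rows("presound_interaction", pre_inter.interaction,
                              times_om, eeg_names)

        # first-vs-fourth-sound 2x2 ANOVA on delay-effect cluster means
        sig = delay_me.significant()
        if sig and all(r.evoked_sound_pos for r in kept):
            anova_out = {}
            for cl in sig[:2]:
                pol = "pos" if cl.polarity > 0 else "neg"
                long_rows = []
                for r in kept:
                    for dly in DELAYS:
                        for pos in (1, 4):
                            ev = r.evoked_sound_pos.get((dly, pos))
                            if ev is None:
                                continue
                            cropped = Evoked(_crop(ev, r_window),
                                             times_r, ev.fs, ev.ch_names,
                                             ev.condition, ev.n_epochs)
                            long_rows.append({
                                "subject": r.subject, "delay": dly,
                                "position": str(pos),
                                "mean_uv": cluster_stats.extract_cluster_mean(
                                    cropped, cl)})
                long_df = pd.DataFrame(long_rows)
                aov = cardio_dynamics.rm_anova(long_df, "mean_uv",
                                               ["delay", "position"])
                piv = long_df.pivot_table(index="subject", columns=["delay",
                                          "position"], values="mean_uv")
                post = {}
                for pos in ("1", "4"):
                    ph = cardio_dynamics.posthoc_pair(
                        piv[("short", pos)], piv[("long", pos)])
                    post[f"delay_at_sound{pos}"] = {
                        "test": ph.test, "statistic": ph.statistic,
                        "p": ph.p, "bf10": ph.bf10}
                anova_out[pol] = {"anova": aov.to_dict("records"),
                                  "posthoc": post}
            controls["first_vs_fourth_sound"] = anova_out
    cio.write_json(controls, out / "hep_controls.json")

    clusters_df = pd.DataFrame(rows)
    clusters_df.to_csv(out / "clusters.tsv", sep="\t", index=False)
    cio.write_json({"contrasts": rows}, out / "clusters.json")

    # ---- cardiac dynamics
    ibi_all = pd.concat([r.ibi_table for r in kept], ignore_index=True)
    ibi_all.to_csv(out / "ibi_table.tsv", sep="\t", index=False)
    cardiac = {}
    post_tbl = ibi_all[ibi_all["position"].isin(["omission to 1", "1 to 2"])]
    if post_tbl["ibi_ms"].notna().all() and len(kept) >= 3:
        aov3 = cardio_dynamics.rm_anova(post_tbl, "ibi_ms",
                                        ["attention", "delay", "position"])
        cardiac["post_omission_anova"] = aov3.to_dict("records")
        piv = post_tbl.pivot_table(index="subject",
                                   columns=["attention", "delay", "position"],
                                   values="ibi_ms")
        post = {}
        for att in ATTENTIONS:
            for dly in DELAYS:
                ph = cardio_dynamics.posthoc_pair(
                    piv[(att, dly, "omission to 1")], piv[(att, dly, "1 to 2")])
                post[f"{att}_{dly}_om1_vs_12"] = {
                    "test": ph.test, "statistic": ph.statistic, "p": ph.p,
                    "bf10": ph.bf10}
        cardiac["posthoc"] = post
    mean_ibi = pd.concat([r.mean_ibi_table for r in kept], ignore_index=True)
    if len(mean_ibi) and len(kept) >= 3:
        cardiac["mean_ibi_anova"] = cardio_dynamics.rm_anova(
            mean_ibi, "ibi_ms", ["attention", "delay"]).to_dict("records")
    sdrr_all = pd.concat([r.sdrr_table for r in kept], ignore_index=True)
    sdrr_all.to_csv(out / "sdrr_table.tsv", sep="\t", index=False)
    if len(sdrr_all) and len(kept) >= 3:
        cardiac["sdrr_anova"] = cardio_dynamics.rm_anova(
            sdrr_all, "sdrr_ms", ["attention", "delay"]).to_dict("records")
    cio.write_json(cardiac, out / "cardiac_dynamics.json")

    summary = {
        "config_digest": cfg.digest(), "seed": cfg.seed,
        "n_subjects": len(results), "n_excluded": len(results) - len(kept),
        "per_subject": [{
            "subject": r.subject, "excluded": r.excluded,
            "trials_rejected": r.n_trials_rejected,
            "blocks_rejected": r.n_blocks_rejected,
            "bad_channels": r.bad_channels} for r in results],
    }
    cio.write_json(summary, out / "summary.json")
    logger.info("report written to %s", out)
    return out
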