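"""Pipeline orchestration: simulate-or-load, analyze, decode, summarize.

``run_pipeline`` executes the stages in order — load or simulate the
cohort, validate, PETH modulation analysis, within-press dynamics,
pseudo-population decoding, behavioral metrics — and writes each stage's
tidy tables into the run directory together with a machine-readable
summary, the fully-resolved configuration, and a MANIFEST marking which
stages completed. Re-running with the same configuration reproduces every
output bit-identically; all randomness derives from the configured seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, decoding, io, peth, press_dynamics
from .config import RunConfig
from .core import Dataset, Group, filter_units, label_press_outcomes
from .simulate import (
    DEFAULT_EFFECTS,
    BehaviorParams,
    GroupEffect,
    UnitPrior,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

STAGES = ("dataset", "peth", "press_dynamics", "decoding", "behavior")


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df


def simulate_stage(config: RunConfig, out: Path):
    sim = config.simulate
    behavior_params = BehaviorParams(
        criterion_ms=sim.criterion_ms,
        log_duration_mu=float(np.log(sim.log_duration_median_ms)),
        log_duration_sigma=sim.log_duration_sigma,
        mean_ipi_ms=sim.mean_ipi_ms,
        max_rewards=sim.max_rewards,
        max_session_ms=sim.max_session_min * 60_000.0,
    )
    effects = {
        Group.AIR: GroupEffect(1.0, 1.0),
        Group.CIE: GroupEffect(
            press_gain_multiplier=sim.cie_press_gain_multiplier,
            outcome_gain_multiplier=sim.cie_outcome_gain_multiplier,
        ),
    }
    dataset, truth = simulate_cohort(
        n_mice_per_group=sim.n_mice_per_group,
        units_per_mouse=sim.units_per_mouse,
        behavior=behavior_params,
        unit_prior=UnitPrior(),
        effects=effects,
        seed=config.seed,
    )
    io.write_dataset(dataset, out / "session_table.csv", out / "spike_table.csv")
    truth.table().to_csv(out / "ground_truth.csv", index=False)
    return dataset, truth


def load_stage(config: RunConfig) -> Dataset:
    return io.load_dataset(config.session_table, config.spike_table)


def peth_stage(dataset: Dataset, config: RunConfig, out: Path) -> pd.DataFrame:
    """Per-unit modulation detection, z-traces, epoch summaries, group traces."""
    p = config.peth
    mod_rows, z_rows, epoch_rows = [], [], []
    group_inputs: dict[str, list] = {}
    for unit in dataset.units:
        session = dataset.session(unit.session_id)
        base = peth.unit_baseline(unit, session, sigma_bins=p.smooth_sigma_bins)
        results = []
        for event_type in ("press_onset", "press_offset", "reward"):
            events = peth.event_times_for(session, event_type)
            if events.size == 0:
                continue
            smoothed = peth.smooth_peth(
                peth.bin_spikes(unit, events, event_type=event_type),
                sigma_bins=p.smooth_sigma_bins,
            )
            mod = peth.detect_modulation(
                smoothed, base,
                window_ms=p.detection_window_ms,
                min_bins=p.min_consecutive_bins,
            )
            results.append(mod)
            z = peth.zscore_peth(smoothed, base)
            mod_rows.append(
                dict(
                    unit_id=unit.unit_id,
                    session_id=session.session_id,
                    group=session.group.value,
                    event_type=event_type,
                    direction=mod.direction,
                    onset_ms=mod.onset_latency_ms,
                    has_up_run=mod.has_up_run,
                    has_down_run=mod.has_down_run,
                )
            )
            for c, zv in zip(z.bin_centers_ms, z.z_per_bin):
                z_rows.append(
                    dict(
                        unit_id=unit.unit_id,
                        group=session.group.value,
                        event_type=event_type,
                        bin_center_ms=c,
                        z=zv,
                    )
                )
            epoch_name = {
                "press_onset": "pre_onset",
                "press_offset": "post_offset",
                "reward": "post_reward",
            }[event_type]
            summ = peth.epoch_summary(z, epoch_name)
            for bi, v in enumerate(summ.bin_means):
                epoch_rows.append(
                    dict(
                        unit_id=unit.unit_id,
                        group=session.group.value,
                        epoch=epoch_name,
                        bin_index=bi,
                        mean_z=v,
                    )
                )
            group_inputs.setdefault(event_type, []).append(
                (z, session.group.value)
            )
        cat = peth.classify_unit_events(results)
        mod_rows.append(
            dict(
                unit_id=unit.unit_id,
                session_id=session.session_id,
                group=session.group.value,
                event_type="category",
                direction="+".join(sorted(cat)) if cat else "unmodulated",
                onset_ms=None,
                has_up_run=None,
                has_down_run=None,
            )
        )
    mod_df = pd.DataFrame(mod_rows)
    mod_df.to_csv(out / "modulation_table.csv", index=False)
    pd.DataFrame(z_rows).to_csv(out / "z_traces.csv", index=False)
    pd.DataFrame(epoch_rows).to_csv(out / "epoch_summaries.csv", index=False)

    trace_rows = []
    for event_type, pairs in group_inputs.items():
        traces = peth.group_average([z for z, _ in pairs], [g for _, g in pairs])
        for g, tr in traces.items():
            for c, m, s in zip(tr.bin_centers_ms, tr.mean, tr.sem):
                trace_rows.append(
                    dict(
                        group=g,
                        event_type=event_type,
                        bin_center_ms=c,
                        mean_z=m,
                        sem_z=s,
                        n_units=tr.n_units,
                    )
                )
    pd.DataFrame(trace_rows).to_csv(out / "group_traces.csv", index=False)
    return mod_df


def press_dynamics_stage(dataset: Dataset, out: Path) -> pd.DataFrame:
    quartile_rows, prop_rows, profile_rows, presence_rows = [], [], [], []
    qa_by_session = {}
    for s in dataset.sessions:
        if s.n_presses < 4:
            logger.warning("session %s: <4 presses; quartiles skipped", s.session_id)
            continue
        qa = press_dynamics.assign_quartiles(s)
        qa_by_session[s.session_id] = qa
        for i, (d, q) in enumerate(zip(s.durations_ms, qa.labels)):
            quartile_rows.append(
                dict(
                    session_id=s.session_id,
                    press_index=i,
                    duration_ms=d,
                    quartile=int(q),
                )
            )
    for unit in dataset.units:
        session = dataset.session(unit.session_id)
        if session.n_presses == 0:
            continue
        presence_rows.append(
            dict(
                unit_id=unit.unit_id,
                group=session.group.value,
                presence_fraction=press_dynamics.spike_presence_fraction(
                    unit, session
                ),
            )
        )
        _, unit_mean = press_dynamics.segment_spike_proportions(unit, session)
        prop_rows.append(
            dict(
                unit_id=unit.unit_id,
                group=session.group.value,
                seg1=unit_mean[0],
                seg2=unit_mean[1],
                seg3=unit_mean[2],
                seg4=unit_mean[3],
            )
        )
        qa = qa_by_session.get(session.session_id)
        if qa is None:
            continue
        for prof in press_dynamics.quartile_segment_profiles(unit, session, qa):
            for seg, v in enumerate(prof.mean_z, start=1):
                profile_rows.append(
                    dict(
                        unit_id=unit.unit_id,
                        group=session.group.value,
                        quartile=prof.quartile,
                        segment=seg,
                        mean_z=v,
                        n_presses=prof.n_presses,
                    )
                )
    pd.DataFrame(quartile_rows).to_csv(out / "press_quartiles.csv", index=False)
    presence_df = pd.DataFrame(presence_rows)
    presence_df.to_csv(out / "spike_presence.csv", index=False)
    pd.DataFrame(prop_rows).to_csv(out / "segment_proportions.csv", index=False)
    pd.DataFrame(profile_rows).to_csv(out / "quartile_profiles.csv", index=False)
    return presence_df


def decoding_stage(dataset: Dataset, config: RunConfig, out: Path) -> pd.DataFrame:
    d = config.decoding
    rows = []
    for group in (Group.AIR, Group.CIE):
        subset = Dataset(
            sessions=tuple(s for s in dataset.sessions if s.group == group),
            units=tuple(
                u
                for u in dataset.units
                if dataset.session(u.session_id).group == group
            ),
            provenance=dataset.provenance,
        )
        if not subset.units:
            continue
        for alignment in d.alignments:
            try:
                n_per_class = None
                if d.n_per_class_cap is not None:
                    probe = decoding.build_pseudopopulation(
                        subset, alignment=alignment, seed=0,
                        min_successes=d.min_successes,
                    )
                    n_per_class = min(probe.n_per_class, d.n_per_class_cap)

                def builder(rng, _subset=subset, _al=alignment, _n=n_per_class):
                    return decoding.build_pseudopopulation(
                        _subset, alignment=_al, n_per_class=_n, seed=rng,
                        min_successes=d.min_successes,
                    )

                res = decoding.decode_timecourse(
                    builder,
                    n_runs=d.n_runs,
                    n_splits=d.n_splits,
                    seed=config.seed + 17,
                    step_ms=d.step_ms,
                    width_ms=d.width_ms,
                    C=d.svm_c,
                )
                nulls = decoding.null_distributions(
                    builder,
                    n_nulls=d.n_nulls,
                    n_runs=d.n_runs,
                    n_splits=d.n_splits,
                    seed=config.seed + 23,
                    step_ms=d.step_ms,
                    width_ms=d.width_ms,
                    C=d.svm_c,
                )
                res = decoding.significance_mask(res, nulls)
            except ValueError as err:
                logger.warning(
                    "decoding skipped for %s/%s: %s", group.value, alignment, err
                )
                continue
            null_means = nulls.reshape(-1, nulls.shape[-1]).mean(axis=0)
            for i, t in enumerate(res.time_centers_ms):
                rows.append(
                    dict(
                        group=group.value,
                        alignment=alignment,
                        time_center_ms=t,
                        mean_accuracy=res.accuracy[i],
                        null_mean=null_means[i],
                        p_raw=res.p_raw[i],
                        significant_raw=bool(res.significant_raw[i]),
                        significant_bh=bool(res.significant_bh[i]),
                        n_units=res.n_units,
                        n_per_class=res.n_per_class,
                    )
                )
    columns = [
        "group", "alignment", "time_center_ms", "mean_accuracy", "null_mean",
        "p_raw", "significant_raw", "significant_bh", "n_units", "n_per_class",
    ]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(out / "accuracy_curve.csv", index=False)
    return df


def behavior_stage(dataset: Dataset, out: Path) -> pd.DataFrame:
    rows = []
    for s in dataset.sessions:
        m = behavior.session_metrics(s)
        rows.append(
            dict(
                session_id=m.session_id,
                mouse_id=s.mouse_id,
                group=s.group.value,
                total_presses=m.total_presses,
                percent_rewarded=m.percent_rewarded,
                response_rate_per_min=m.response_rate_per_min,
            )
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "session_metrics.csv", index=False)
    return df


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; return the run directory.

    Partial failures leave completed stages' tables in place, recorded in
    the MANIFEST.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    config.save(out / "effective_config.yaml")
    manifest: dict[str, str] = {stage: "pending" for stage in STAGES}
    summary: dict = {"seed": config.seed}

    def write_state():
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))

    try:
        if config.session_table and config.spike_table:
            dataset = load_stage(config)
        else:
            dataset, _ = simulate_stage(config, out)
        dataset.validate(enforce_task_limits=False)
        dataset = Dataset(
            sessions=tuple(label_press_outcomes(s) for s in dataset.sessions),
            units=dataset.units,
            provenance=dataset.provenance,
        )
        dataset = filter_units(dataset, config.min_spikes_per_unit)
        summary["n_sessions"] = len(dataset.sessions)
        summary["n_units"] = len(dataset.units)
        manifest["dataset"] = "complete"
        write_state()

        mod_df = peth_stage(dataset, config, out)
        per_event = mod_df[mod_df.event_type != "category"]
        summary["fraction_modulated_by_group"] = {
            g: float((grp.direction != "none").groupby(grp.unit_id).any().mean())
            for g, grp in per_event.groupby("group")
        }
        manifest["peth"] = "complete"
        write_state()

        presence_df = press_dynamics_stage(dataset, out)
        if len(presence_df):
            summary["mean_presence_fraction"] = {
                g: float(grp.presence_fraction.mean())
                for g, grp in presence_df.groupby("group")
            }
        manifest["press_dynamics"] = "complete"
        write_state()

        acc_df = decoding_stage(dataset, config, out)
        if len(acc_df):
            post = acc_df[
                (acc_df.alignment == "press_offset")
                & (acc_df.time_center_ms > 0)
                & (acc_df.time_center_ms <= 1000)
            ]
            summary["post_offset_accuracy"] = {
                g: float(grp.mean_accuracy.mean()) for g, grp in post.groupby("group")
            }
        manifest["decoding"] = "complete"
        write_state()

        metrics_df = behavior_stage(dataset, out)
        summary["mean_percent_rewarded"] = float(metrics_df.percent_rewarded.mean())
        manifest["behavior"] = "complete"
        write_state()
    finally:
        write_state()

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out


def make_report(run_dir) -> Path:
    """Render summary panels from the tidy tables alone.

    Missing optional tables drop their panel with a warning; a missing
    required table raises a named error. Regeneration is idempotent.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    report_dir = run_dir / "report"
    report_dir.mkdir(exist_ok=True)
    panels = []

    mod_path = run_dir / "modulation_table.csv"
    if not mod_path.exists():
        raise FileNotFoundError("modulation_table.csv is required for the report")

    traces = pd.read_csv(run_dir / "group_traces.csv")
    fig, axes = plt.subplots(1, 3, figsize=(12, 3), sharey=True)
    for ax, ev in zip(axes, ("press_onset", "press_offset", "reward")):
        sub = traces[traces.event_type == ev]
        for g, grp in sub.groupby("group"):
            ax.plot(grp.bin_center_ms / 1000.0, grp.mean_z, label=g)
            ax.fill_between(
                grp.bin_center_ms / 1000.0,
                grp.mean_z - grp.sem_z,
                grp.mean_z + grp.sem_z,
                alpha=0.3,
            )
        ax.set_title(ev)
        ax.set_xlabel("time (s)")
    axes[0].set_ylabel("z")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(report_dir / "group_traces.png", dpi=100)
    plt.close(fig)
    panels.append("group_traces")

    mod = pd.read_csv(mod_path)
    cats = mod[mod.event_type == "category"]
    fig, ax = plt.subplots(figsize=(8, 3))
    counts = cats.groupby(["group", "direction"]).size().unstack(fill_value=0)
    counts.T.plot.bar(ax=ax)
    ax.set_ylabel("units")
    fig.tight_layout()
    fig.savefig(report_dir / "category_counts.png", dpi=100)
    plt.close(fig)
    panels.append("category_counts")

    ep = pd.read_csv(run_dir / "epoch_summaries.csv")
    fig, axes = plt.subplots(1, 3, figsize=(12, 3), sharey=True)
    for ax, name in zip(axes, ("pre_onset", "post_offset", "post_reward")):
        sub = ep[ep.epoch == name]
        for g, grp in sub.groupby("group"):
            means = grp.groupby("bin_index").mean_z.mean()
            ax.plot(means.index, means.values, marker="o", label=g)
        ax.set_title(name)
        ax.set_xlabel("250-ms bin")
    axes[0].set_ylabel("mean z")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(report_dir / "epoch_summaries.png", dpi=100)
    plt.close(fig)
    panels.append("epoch_summaries")

    qp_path = run_dir / "quartile_profiles.csv"
    if qp_path.exists():
        qp = pd.read_csv(qp_path)
        fig, ax = plt.subplots(figsize=(6, 3))
        for q, grp in qp.groupby("quartile"):
            means = grp.groupby("segment").mean_z.mean()
            ax.plot(means.index, means.values, marker="o", label=f"Q{q}")
        ax.set_xlabel("duration segment")
        ax.set_ylabel("mean z")
        ax.legend()
        fig.tight_layout()
        fig.savefig(report_dir / "quartile_profiles.png", dpi=100)
        plt.close(fig)
        panels.append("quartile_profiles")

    acc_path = run_dir / "accuracy_curve.csv"
    if acc_path.exists() and acc_path.stat().st_size > 2:
        acc = pd.read_csv(acc_path)
        if len(acc):
            fig, axes = plt.subplots(
                1, acc.alignment.nunique(), figsize=(10, 3), squeeze=False
            )
            for ax, (al, sub) in zip(axes[0], acc.groupby("alignment")):
                for g, grp in sub.groupby("group"):
                    ax.plot(grp.time_center_ms / 1000.0, grp.mean_accuracy, label=g)
                    ax.plot(
                        grp.time_center_ms / 1000.0, grp.null_mean, ls="--", alpha=0.5
                    )
                ax.axhline(0.5, color="gray", lw=0.5)
                ax.set_title(al)
                ax.set_xlabel("time (s)")
                ax.set_ylabel("accuracy")
                ax.legend()
            fig.tight_layout()
            fig.savefig(report_dir / "accuracy_curves.png", dpi=100)
            plt.close(fig)
            panels.append("accuracy_curves")
    else:
        logger.warning("decoding table absent; accuracy panel skipped")

    (report_dir / "report.md").write_text(
        "# Run report\n\n" + "\n".join(f"![{p}]({p}.png)" for p in panels) + "\n"
    )
    return report_dir
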