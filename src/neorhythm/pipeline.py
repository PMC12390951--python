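"""End-to-end orchestration: stimuli -> simulate -> preprocess -> analyze.

Each stage writes into its own subdirectory of the run directory and the
manifest records the configuration, seeds and stage bookkeeping (trials
rejected per rule, channels excluded), so a run is fully reproducible from
its manifest.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from hashlib import sha256
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .config import RunConfig, _plainify
from .montage import build_montage
from .preprocess import preprocess_session, stack_cohort
from .stats import (
    anova_suite,
    drop_incomplete_participants,
    rising_slope,
    roi_aggregate,
    spatial_cluster_test,
    temporal_cluster_test,
)
from .stimuli import build_protocol, render_stimulus_sets, validate_stimulus_sets
from .synth import simulate_cohort

CONDITIONS = ("rhythmic", "arrhythmic")


@dataclass
class RunResult:
    outdir: Path
    stimulus_validation: dict
    n_retained_channels: int
    spatial_clusters: object
    anova: object
    roi_table: pd.DataFrame
    temporal_clusters: dict = field(default_factory=dict)


def stage_stimuli(cfg: RunConfig, outdir: Path) -> dict:
    """Generate, validate and (optionally) write the full stimulus set."""
    outdir.mkdir(parents=True, exist_ok=True)
    rhythmic, arrhythmic = render_stimulus_sets(seed=cfg.seed, config=cfg.stimulus)
    validation = validate_stimulus_sets(rhythmic, arrhythmic)
    if cfg.write_wav:
        for stim in rhythmic + arrhythmic:
            tag = f"{stim.condition}_base{stim.base_id}_t{stim.tempo_unit_ms}_p{stim.pitch_hz}"
            nio.write_wav(stim, outdir / f"{tag}.wav")
            nio.write_stimulus_sidecar(stim, outdir / f"{tag}.csv")
    protocol = build_protocol(rhythmic + arrhythmic, seed=cfg.seed, config=cfg.stimulus)
    nio.write_protocol_csv(protocol, outdir / "protocol.csv")
    pd.DataFrame(
        [
            dict(condition=s.condition, base_id=s.base_id, tempo_ms=s.tempo_unit_ms,
                 pitch_hz=s.pitch_hz, n_tones=len(s.onsets_s), duration_s=s.duration_s)
            for s in rhythmic + arrhythmic
        ]
    ).to_csv(outdir / "stimulus_table.csv", index=False)
    return validation


def stage_analyze(stack, retained, times, montage, cfg: RunConfig, stats_dir: Path):
    """Group statistics on a stacked cohort; writes the stats CSVs + figures."""
    stats_dir = Path(stats_dir)
    stats_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    slopes = rising_slope(stack, times)
    idx = np.flatnonzero(retained)
    spatial = spatial_cluster_test(
        slopes.slope[:, idx, 0], slopes.slope[:, idx, 1],
        montage, cfg.cluster, seed=rng, channel_indices=idx,
    )
    nio.cluster_result_to_frame(spatial, "slope_rhythmic_vs_arrhythmic").to_csv(
        stats_dir / "spatial_clusters.csv", index=False
    )

    # temporal tests per condition vs baseline, on the grand average over
    # retained channels (keeps the run fast)
    temporal = {}
    rows = []
    post = times >= 0
    base = times < 0
    for ci, cond in enumerate(CONDITIONS):
        roi_series = np.nanmean(stack[:, idx, ci, :], axis=1)
        contrast = roi_series[:, post] - roi_series[:, base].mean(axis=1, keepdims=True)
        res = temporal_cluster_test(contrast, 0.0, cfg.cluster, seed=rng)
        temporal[cond] = res
        rows.append(nio.cluster_result_to_frame(res, f"{cond}_vs_baseline"))
    nonempty = [f for f in rows if not f.empty]
    (pd.concat(nonempty) if nonempty else rows[0]).to_csv(
        stats_dir / "temporal_clusters.csv", index=False
    )

    roi_table = roi_aggregate(stack, times, montage, retained)
    roi_table.to_csv(stats_dir / "roi_table.csv", index=False)
    suite = anova_suite(drop_incomplete_participants(roi_table))
    suite.three_way.table.to_csv(stats_dir / "anova_three_way.csv", index=False)
    pd.concat(
        [r.table.assign(subset=k) for k, r in suite.by_condition.items()]
        + [r.table.assign(subset=k) for k, r in suite.by_roi.items()]
    ).to_csv(stats_dir / "anova_followups.csv", index=False)
    suite.posthoc_roi.to_csv(stats_dir / "anova_posthoc_roi.csv", index=False)
    _write_figures(stats_dir, slopes, idx, montage, roi_table)
    return slopes, spatial, temporal, roi_table, suite


def run_all(cfg: RunConfig) -> RunResult:
    """Run the full pipeline into ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    validation = stage_stimuli(cfg, outdir / "stimuli")

    montage = build_montage()
    sessions_dir = outdir / "sessions"
    sessions_dir.mkdir(exist_ok=True)
    nio.write_montage_json(montage, sessions_dir / "montage.json")
    sessions = simulate_cohort(
        n_participants=cfg.synth.n_participants,
        effect="default" if cfg.synth.effect_fraction else "null",
        seed=cfg.seed,
        cfg=cfg.synth,
        montage=montage,
        stimulus_config=cfg.stimulus,
        preprocess_config=cfg.preprocess,
    )
    for s in sessions:
        nio.write_snirf(s, sessions_dir / f"{s.participant_id}.snirf")
        nio.write_events_tsv(s.events, sessions_dir / f"{s.participant_id}_events.tsv")

    deriv = outdir / "derivatives"
    deriv.mkdir(exist_ok=True)
    averages = []
    qc = []
    for s in sessions:
        avg, _ = preprocess_session(s, cfg.preprocess)
        averages.append(avg)
        qc.append(
            dict(
                participant=s.participant_id,
                excluded_channels=int(avg.excluded.any(axis=1).sum()),
                **{f"n_{k}": v for k, v in avg.rejection_summary.items()},
            )
        )
    pd.DataFrame(qc).to_csv(deriv / "qc_report.csv", index=False)
    stack, retained, times = stack_cohort(averages, cfg.preprocess)

    stats_dir = outdir / "stats"
    slopes, spatial, temporal, roi_table, suite = stage_analyze(
        stack, retained, times, montage, cfg, stats_dir
    )
    report = _report(cfg, validation, retained, spatial, temporal, suite)
    (outdir / "report.json").write_text(json.dumps(_plainify(report), indent=1))
    (outdir / "report.md").write_text(_report_md(report))
    manifest = dict(
        config=cfg.to_dict(),
        config_sha256=sha256(json.dumps(_plainify(cfg.to_dict()), sort_keys=True).encode()).hexdigest(),
        python=platform.python_version(),
        numpy=np.__version__,
    )
    (outdir / "manifest.json").write_text(json.dumps(_plainify(manifest), indent=1))
    return RunResult(
        outdir=outdir,
        stimulus_validation=validation,
        n_retained_channels=int(retained.sum()),
        spatial_clusters=spatial,
        anova=suite,
        roi_table=roi_table,
        temporal_clusters=temporal,
    )


def _report(cfg, validation, retained, spatial, temporal, suite) -> dict:
    sig = spatial.significant(cfg.cluster.alpha_final)
    cond_eff = suite.three_way["condition"]
    inter = suite.three_way["condition x roi x hemisphere"]
    return dict(
        stimulus_validation=validation,
        n_retained_channels=int(retained.sum()),
        spatial_significant_clusters=[
            dict(size=int(c.members.size), t_sum=c.t_sum, p=c.p_perm) for c in sig
        ],
        temporal_significant_clusters={
            cond: [dict(size=int(c.members.size), t_sum=c.t_sum, p=c.p_perm)
                   for c in res.significant(cfg.cluster.alpha_final)]
            for cond, res in temporal.items()
        },
        anova=dict(
            condition=dict(F=cond_eff.F, df=(cond_eff.df_num, cond_eff.df_den),
                           p=cond_eff.p, eta_p2=cond_eff.eta_p2),
            condition_x_roi_x_hemisphere=dict(F=inter.F, df=(inter.df_num, inter.df_den),
                                              p=inter.p, eta_p2=inter.eta_p2),
        ),
        significant_condition_effect=bool(cond_eff.p < cfg.cluster.alpha_final),
    )


def _report_md(report: dict) -> str:
    lines = ["# neorhythm run report", ""]
    v = report["stimulus_validation"]
    lines += [
        "## Stimulus matching",
        f"- paired t-test on duration: p = {v['p_duration']:.3f}",
        f"- paired t-test on 0-10 Hz envelope power: p = {v['p_power']:.3f}",
        "",
        "## Group analysis",
        f"- retained channels: {report['n_retained_channels']}",
        f"- significant spatial slope clusters: {len(report['spatial_significant_clusters'])}",
    ]
    a = report["anova"]["condition"]
    lines.append(
        f"- rANOVA condition effect: F({a['df'][0]}, {a['df'][1]}) = {a['F']:.3f}, "
        f"p = {a['p']:.4f}, partial eta^2 = {a['eta_p2']:.3f}"
    )
    i = report["anova"]["condition_x_roi_x_hemisphere"]
    lines.append(
        f"- condition x ROI x hemisphere: F({i['df'][0]}, {i['df'][1]}) = {i['F']:.3f}, "
        f"p = {i['p']:.4f}, partial eta^2 = {i['eta_p2']:.3f}"
    )
    return "\n".join(lines) + "\n"


def _write_figures(stats_dir: Path, slopes, idx, montage, roi_table) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mids = montage.midpoints_mm[idx]
    with np.errstate(invalid="ignore"):
        norm = np.nanmean(slopes.normalized[:, idx], axis=0)
    fig, ax = plt.subplots(figsize=(7, 4))
    sc = ax.scatter(mids[:, 0], mids[:, 1], c=norm, cmap="coolwarm", vmin=-0.3, vmax=0.3)
    fig.colorbar(sc, label="normalized slope (RC-AC)/(RC+AC)")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title("Normalized rising slope by channel midpoint")
    fig.savefig(stats_dir / "slope_map.png", dpi=110)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 4))
    g = roi_table.groupby(["roi", "hemisphere", "condition"])["hbo"].mean().unstack("condition")
    g.plot.bar(ax=ax)
    ax.set_ylabel("mean HbO 8-12 s (z)")
    fig.tight_layout()
    fig.savefig(stats_dir / "roi_bars.png", dpi=110)
    plt.close(fig)
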