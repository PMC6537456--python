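"""End-to-end analysis: rendered sessions -> per-subject time-courses ->
cohort summary with repeated-measures inference.

``analyze_cohort`` composes every extraction module: voluntary and evoked
torque metrics, voluntary activation, EMG normalization, clip-averaged
shear modulus (gated by the relaxation check), then cohort statistics:
absolute mean +/- SD per time point, mean per-subject relative changes,
one-way RM-ANOVA and Fisher LSD contrasts against control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import GeneratorConfig
from .cohort import TRIAL, Cohort, RenderedSession, TrialTimeline
from .elastography import clip_modulus
from .emg import check_relaxation, emg_rms, mwave_p2p, normalized_rms
from .errors import MyofatigueError
from .signals import RESTING, SINGLE, SUPERIMPOSED
from .stats import fisher_lsd, relative_change, rm_anova_oneway
from .torque import compute_val, doublet_amplitude, mvc_peak, twitch_properties

log = logging.getLogger(__name__)

#: quantities extracted per session, in reporting order
QUANTITIES = ("mvc", "val", "rms_mmax", "db_pot", "tw_pot", "mmax",
              "emd", "ct", "hrt", "mrtd", "mrtr", "mu", "passive_torque")


@dataclass
class CohortSummary:
    """Cohort-level results in tidy tables.

    values:
        per-cell extracted metrics (subject, timepoint, quantity, value).
    absolute:
        mean and SD of absolute values per quantity and time point.
    changes:
        mean/SD/SEM of per-subject percent changes from control.
    anova:
        one-way RM-ANOVA per quantity (F, df1, df2, p).
    lsd:
        Fisher LSD p-values vs control per quantity and time point.
    excluded:
        (subject, timepoint, quantity, reason) cells dropped from analysis.
    """

    values: pd.DataFrame
    absolute: pd.DataFrame
    changes: pd.DataFrame
    anova: pd.DataFrame
    lsd: pd.DataFrame
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)
    timepoints: tuple[str, ...] = ()

    def matrix(self, quantity: str) -> pd.DataFrame:
        """Subjects x time points matrix of one quantity."""
        wide = (self.values[self.values["quantity"] == quantity]
                .pivot(index="subject", columns="timepoint", values="value"))
        return wide.reindex(columns=list(self.timepoints))

    def end_change(self, quantity: str) -> float:
        """Cohort mean per-subject percent change at the last time point."""
        sel = self.changes[(self.changes["quantity"] == quantity)
                           & (self.changes["timepoint"] == self.timepoints[-1])]
        return float(sel["mean_pct"].iloc[0])


def analyze_session(session: RenderedSession,
                    timeline: TrialTimeline = TRIAL) -> dict[str, float]:
    """Extract every metric from one rendered session.

    Returns quantity -> value; the shear modulus is NaN (flagged) when the
    relaxation check fails.
    """
    torque, emg = session.torque, session.emg_vl
    sup = torque.events_of(context=SUPERIMPOSED)[0]
    pot_db = torque.events_of(context=RESTING, kind="doublet100Hz")[0]
    tw = torque.events_of(context=RESTING, kind=SINGLE)[0]

    out: dict[str, float] = {}
    out["mvc"] = mvc_peak(torque)
    db_s = doublet_amplitude(torque, sup.time, SUPERIMPOSED)
    db_p = doublet_amplitude(torque, pot_db.time, RESTING)
    out["db_pot"] = db_p
    out["val"] = compute_val(db_s, db_p)
    props = twitch_properties(torque, tw.time)
    out["tw_pot"] = props.p
    out["emd"] = props.emd
    out["ct"] = props.ct
    out["hrt"] = props.hrt
    out["mrtd"] = props.mrtd
    out["mrtr"] = props.mrtr

    rms_start = timeline.plateau_start + timeline.rms_window[0]
    rms_len = timeline.rms_window[1] - timeline.rms_window[0]
    rms = emg_rms(emg, rms_start, rms_len)
    mmax = mwave_p2p(emg, tw.time)
    out["mmax"] = mmax
    out["rms_mmax"] = normalized_rms(rms, mmax)

    relax = check_relaxation(session.passive_torque, session.passive_emg_vl,
                             session.passive_emg_bf)
    out["passive_torque"] = relax.passive_torque
    if relax.passed:
        out["mu"] = clip_modulus(session.swe).clip_mu
    else:
        out["mu"] = float("nan")
        log.warning("relaxation check failed (subject %s, %s): torque "
                    "%.2f Nm, VL %.4f mV, BF %.4f mV - modulus excluded",
                    session.subject_id, session.timepoint,
                    relax.passive_torque, relax.vl_rms, relax.bf_rms)
    return out


def analyze_cohort(cohort: Cohort,
                   timeline: TrialTimeline = TRIAL) -> CohortSummary:
    """Run the full extraction + statistics pipeline on a cohort."""
    config: GeneratorConfig = cohort.config
    tps = tuple(config.timepoints)
    rows, excluded = [], []
    for subj_sessions in cohort.sessions:
        for sess in subj_sessions:
            try:
                metrics = analyze_session(sess, timeline)
            except MyofatigueError as exc:
                excluded.append((sess.subject_id, sess.timepoint, "all",
                                 str(exc)))
                continue
            for q, v in metrics.items():
                if np.isnan(v):
                    excluded.append((sess.subject_id, sess.timepoint, q,
                                     "relaxation check failed"))
                rows.append((sess.subject_id, sess.timepoint, q, v))
    values = pd.DataFrame(rows, columns=["subject", "timepoint", "quantity",
                                         "value"])
    excluded = pd.DataFrame(excluded, columns=["subject", "timepoint",
                                               "quantity", "reason"])

    abs_rows, chg_rows, anova_rows, lsd_rows = [], [], [], []
    for q in QUANTITIES:
        wide = (values[values["quantity"] == q]
                .pivot(index="subject", columns="timepoint", values="value")
                .reindex(columns=list(tps)))
        mat = wide.to_numpy()
        for j, tp in enumerate(tps):
            col = mat[:, j]
            abs_rows.append((q, tp, np.nanmean(col), np.nanstd(col, ddof=1)))
        # per-subject percent changes (subjects with a valid control only)
        ok = ~np.isnan(mat[:, 0])
        chg = relative_change(mat[ok], control_index=0)
        for j, tp in enumerate(tps):
            col = chg[:, j]
            n_ok = np.sum(~np.isnan(col))
            chg_rows.append((q, tp, np.nanmean(col),
                             np.nanstd(col, ddof=1) if n_ok > 1 else 0.0,
                             (np.nanstd(col, ddof=1) / np.sqrt(n_ok))
                             if n_ok > 1 else 0.0))
        complete = mat[~np.isnan(mat).any(axis=1)]
        if complete.shape[0] >= 2:
            res = rm_anova_oneway(complete)
            anova_rows.append((q, res.f, res.df1, res.df2, res.p,
                               complete.shape[0]))
            lsd = fisher_lsd(complete, reference_index=0, anova=res)
            for j, tp in enumerate(tps):
                lsd_rows.append((q, tp, lsd.p[j], lsd.tested))
        else:
            anova_rows.append((q, np.nan, np.nan, np.nan, np.nan,
                               complete.shape[0]))

    return CohortSummary(
        values=values,
        absolute=pd.DataFrame(abs_rows, columns=["quantity", "timepoint",
                                                 "mean", "sd"]),
        changes=pd.DataFrame(chg_rows, columns=["quantity", "timepoint",
                                                "mean_pct", "sd_pct",
                                                "sem_pct"]),
        anova=pd.DataFrame(anova_rows, columns=["quantity", "f", "df1",
                                                "df2", "p", "n"]),
        lsd=pd.DataFrame(lsd_rows, columns=["quantity", "timepoint", "p",
                                            "tested"]),
        excluded=excluded,
        timepoints=tps,
    )


def plot_timecourses(summary: CohortSummary, out_dir,
                     quantities=("mvc", "mu", "db_pot", "tw_pot", "emd",
                                 "ct", "mrtd")) -> list[str]:
    """Write mean +/- SEM relative-change time-course figures (one per
    quantity); returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    x = np.arange(len(summary.timepoints))
    for q in quantities:
        sel = summary.changes[summary.changes["quantity"] == q]
        sel = sel.set_index("timepoint").reindex(list(summary.timepoints))
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.errorbar(x, sel["mean_pct"], yerr=sel["sem_pct"], marker="o",
                    color="k", capsize=3)
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.set_xticks(x, summary.timepoints, rotation=45)
        ax.set_ylabel(f"{q} change from control (%)")
        fig.tight_layout()
        path = out_dir / f"timecourse_{q}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(str(path))
    return paths
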