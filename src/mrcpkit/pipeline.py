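"""End-to-end study orchestration: synthesize subjects, detect onsets,
quantify morphology, classify single trials, and run the repeated-measures
statistics, with every random draw traceable to the study seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .detection import ClassifierSpec, session_detection
from .emg import OnsetDetectionParams, auto_threshold, detect_onsets, interval_outliers
from .morphology import COMPONENT_CHANNELS, session_morphology
from .stats import anova_table, rm_anova_oneway, rm_anova_twoway
from .synth import DEFAULT_AMPLITUDES, SessionConfig, generate_session

log = logging.getLogger(__name__)

#: Mean component amplitudes (µV) per session used as study defaults:
#: two pre-intervention sessions and one post-intervention session.
SESSION_AMPLITUDES = {
    "Pre1": DEFAULT_AMPLITUDES,
    "Pre2": {"Fz": (-2.0, -7.2, -8.6), "FCz": (-1.3, -9.5, -11.6), "Cz": (-1.4, -10.0, -11.8)},
    "Post": {"Fz": (-1.5, -6.2, -8.2), "FCz": (-0.8, -8.6, -11.2), "Cz": (-0.7, -9.1, -11.5)},
}

COMPONENTS = ("RP", "NS", "MP")


@dataclass
class StudyConfig:
    """A full synthetic study: `n_subjects` subjects x 3 sessions."""

    n_subjects: int = 26
    sessions: tuple = ("Pre1", "Pre2", "Post")
    session_amplitudes: dict = field(default_factory=lambda: dict(SESSION_AMPLITUDES))
    classifiers: tuple = ("random_forest", "lda", "knn")
    base: SessionConfig = field(default_factory=SessionConfig)
    subject_scale_sd: float = 0.2   # between-subject MRCP gain variability
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or len(self.sessions) < 1:
            raise ValueError("need >= 1 subject and >= 1 session")


@dataclass
class StudyReport:
    morphology: pd.DataFrame     # subject, session, channel, component, amplitude_uV
    accuracy: pd.DataFrame       # subject, session, classifier, accuracy_pct
    rejections: pd.DataFrame     # subject, session, n_kept, n_rejected, interval_outliers
    component_anovas: dict       # (channel, component) -> AnovaResult
    accuracy_anova: dict | None  # effects from the two-way RM-ANOVA


def _subject_session_seed(study_seed: int, subject: int, session: int) -> int:
    """Stable per-(subject, session) seed, independent of execution order."""
    ss = np.random.SeedSequence([study_seed, subject, session])
    return int(ss.generate_state(1)[0] % (2**31))


def run_subject_session(cfg: StudyConfig, subject: int, session_idx: int,
                        subject_scale: float):
    """Synthesize and fully analyze one subject-session."""
    name = cfg.sessions[session_idx]
    scfg = replace(
        cfg.base,
        component_amplitudes=dict(cfg.session_amplitudes[name]),
        amplitude_scale=subject_scale,
        seed=_subject_session_seed(cfg.seed, subject, session_idx),
    )
    sess = generate_session(scfg)
    params = OnsetDetectionParams()
    thr = auto_threshold(sess.emg.data[0], scfg.fs, params)
    onsets = detect_onsets(sess.emg.data[0], scfg.fs, replace(params, threshold=thr))
    n_outliers = len(interval_outliers(onsets, scfg.inter_movement_interval))
    if n_outliers:
        log.warning("subject %d %s: %d inter-onset interval outlier(s)",
                    subject, name, n_outliers)
    comps = session_morphology(sess.eeg, onsets)
    specs = [ClassifierSpec(kind=k, seed=scfg.seed) for k in cfg.classifiers]
    det = session_detection(
        sess.eeg, sess.idle, onsets, specs,
        idle_seed=scfg.seed + 1, session=name,
    )
    return comps, det, n_outliers


def run_study(cfg: StudyConfig, out_dir=None) -> StudyReport:
    """Run all stages for all synthetic subjects; deterministic under
    `cfg.seed`.  Writes the report tables to `out_dir` when given."""
    import hashlib

    cfg_hash = hashlib.sha1(repr(cfg).encode()).hexdigest()[:12]
    log.info("study config hash %s (seed %d, %d subjects)",
             cfg_hash, cfg.seed, cfg.n_subjects)
    rng_subject = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**20]))
    scales = np.clip(
        1.0 + cfg.subject_scale_sd * rng_subject.standard_normal(cfg.n_subjects),
        0.3, None,
    )
    morph_rows, acc_rows, rej_rows = [], [], []
    for s in range(cfg.n_subjects):
        for j, name in enumerate(cfg.sessions):
            comps, det, n_out = run_subject_session(cfg, s, j, scales[s])
            for (ch, comp), v in comps.values.items():
                morph_rows.append({
                    "subject": s, "session": name, "channel": ch,
                    "component": comp, "amplitude_uV": v,
                })
            for r in det:
                acc_rows.append({
                    "subject": s, "session": name, "classifier": r.classifier,
                    "accuracy_pct": r.accuracy, "n_folds": r.n_folds,
                })
            rej_rows.append({
                "subject": s, "session": name,
                "n_kept": comps.n_epochs_kept,
                "n_rejected": comps.n_epochs_rejected,
                "interval_outliers": n_out,
            })
            log.info("subject %d session %s done", s, name)

    morphology = pd.DataFrame(morph_rows)
    accuracy = pd.DataFrame(acc_rows)
    rejections = pd.DataFrame(rej_rows)

    component_anovas = {}
    if cfg.n_subjects >= 2 and len(cfg.sessions) >= 2:
        for ch in COMPONENT_CHANNELS:
            for comp in COMPONENTS:
                sub = morphology[(morphology.channel == ch) & (morphology.component == comp)]
                grid = sub.pivot_table(
                    index="subject", columns="session", values="amplitude_uV"
                )[list(cfg.sessions)].to_numpy()
                component_anovas[(ch, comp)] = rm_anova_oneway(grid, cfg.sessions)

    accuracy_anova = None
    if cfg.n_subjects >= 2 and len(cfg.sessions) >= 2 and len(cfg.classifiers) >= 2:
        grid = np.empty((cfg.n_subjects, len(cfg.sessions), len(cfg.classifiers)))
        for a, name in enumerate(cfg.sessions):
            for b, clf in enumerate(cfg.classifiers):
                sub = accuracy[(accuracy.session == name) & (accuracy.classifier == clf)]
                grid[:, a, b] = sub.sort_values("subject")["accuracy_pct"].to_numpy()
        accuracy_anova = rm_anova_twoway(grid, cfg.sessions, cfg.classifiers)

    report = StudyReport(morphology, accuracy, rejections,
                         component_anovas, accuracy_anova)
    if out_dir is not None:
        write_report(report, cfg, out_dir)
    return report


def _mean_se(x: np.ndarray) -> str:
    se = x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0
    return f"{x.mean():.1f} ± {se:.1f}"


def morphology_summary(morphology: pd.DataFrame, sessions) -> pd.DataFrame:
    """Mean ± SE component amplitudes per channel x component x session."""
    rows = []
    for ch in morphology.channel.unique():
        for comp in COMPONENTS:
            sub = morphology[(morphology.channel == ch) & (morphology.component == comp)]
            row = {"channel": ch, "component": comp}
            for s in sessions:
                row[f"{s} (uV)"] = _mean_se(sub[sub.session == s]["amplitude_uV"].to_numpy())
            rows.append(row)
    return pd.DataFrame(rows)


def accuracy_summary(accuracy: pd.DataFrame, sessions) -> pd.DataFrame:
    """Mean ± SE and range of accuracies per classifier x session."""
    rows = []
    for clf in accuracy.classifier.unique():
        row = {"classifier": clf}
        rng_row = {"classifier": f"{clf} [min-max]"}
        for s in sessions:
            x = accuracy[(accuracy.classifier == clf) & (accuracy.session == s)][
                "accuracy_pct"].to_numpy()
            row[f"{s} (%)"] = _mean_se(x)
            rng_row[f"{s} (%)"] = f"[{x.min():.1f}-{x.max():.1f}]"
        rows.append(row)
        rows.append(rng_row)
    return pd.DataFrame(rows)


def write_report(report: StudyReport, cfg: StudyConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_table(report.morphology, out / "component_amplitudes.csv")
    io.write_table(morphology_summary(report.morphology, cfg.sessions),
                   out / "component_summary.csv")
    io.write_table(report.accuracy, out / "accuracy.csv")
    if len(report.accuracy):
        io.write_table(accuracy_summary(report.accuracy, cfg.sessions),
                       out / "accuracy_summary.csv")
    io.write_table(report.rejections, out / "rejections.csv")
    if report.component_anovas:
        tab = []
        for (ch, comp), r in report.component_anovas.items():
            row = anova_table(r).iloc[0].to_dict()
            tab.append({"channel": ch, "component": comp, **row})
        io.write_table(pd.DataFrame(tab), out / "component_anovas.csv")
    if report.accuracy_anova is not None:
        io.write_table(anova_table(report.accuracy_anova), out / "accuracy_anova.csv")
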