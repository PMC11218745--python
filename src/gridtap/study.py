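"""End-to-end study driver: simulate → preprocess → ERP/classify → report.

One call simulates a cohort of subjects, runs the full offline pipeline
for both EEG systems (12-channel scalp cap; 18 ear channels plus 8
bipolar derivations), estimates every subject's somatosensory
sensitivity threshold, computes the group statistics, and writes the
report bundle.  Subject-level failures are logged and that subject is
excluded, mirroring how real cohorts lose participants; the study
continues.

Between-subject heterogeneity (ERP amplitude scale, noise level, rare
polarity inversion, sensitivity threshold) is drawn from documented
distributions in :class:`StudyConfig`; the defaults emulate the spread
seen in per-subject ERP overviews of real cohorts and are synthetic
choices, not measured facts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import AccuracyResult, ClassifierConfig, channels_for_system, \
    loocv_accuracy
from .erp import CHANNELS_OF_INTEREST, feature_table
from .group_stats import GroupResult, paired_t, pearson, rm_anova_gg
from .montage import default_montage, derive_bipolar
from .preprocess import ERPAverage, PreprocessConfig, average, bandpass, \
    baseline_correct, epoch, reject_artifacts
from .psychophysics import PsychometricFitError, SchedulerState, \
    estimate_threshold, run_discrimination_session
from .report import grand_average_figure, report_tables
from .simulate import GeneratorConfig, ParadigmConfig, PsychoSimConfig, \
    schedule_session, synthesize_recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyConfig:
    n_subjects: int = 10
    master_seed: int = 0
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    psycho: PsychoSimConfig = field(default_factory=PsychoSimConfig)
    #: log-normal sigma of the per-subject ERP amplitude scale (median 1)
    amplitude_scale_sigma: float = 0.45
    #: log-normal sigma of the per-subject noise level scale
    noise_scale_sigma: float = 0.15
    #: probability of a whole-subject ERP polarity inversion
    inversion_prob: float = 0.05
    #: between-subject SD (percent) of the true sensitivity threshold
    threshold_sd: float = 9.0
    systems: tuple[str, ...] = ("cap", "ceegrid")
    run_psychophysics: bool = True


@dataclass
class SubjectResult:
    subject: str
    averages: dict[str, ERPAverage]            # per system
    accuracies: dict[str, AccuracyResult]      # per system
    threshold_pct: float | None
    n_rejected: dict[str, int]


@dataclass
class StudyResult:
    config: StudyConfig
    subjects: list[SubjectResult]
    features: pd.DataFrame
    group: dict[str, GroupResult | None]
    posthoc: pd.DataFrame | None
    excluded: list[str]
    paths: dict[str, Path] = field(default_factory=dict)

    def accuracy(self, system: str) -> dict[str, AccuracyResult]:
        return {s.subject: s.accuracies[system] for s in self.subjects
                if system in s.accuracies}

    def mean_accuracy(self, system: str) -> float:
        vals = [a.accuracy_pct for a in self.accuracy(system).values()]
        return float(np.mean(vals)) if vals else float("nan")


def _subject_generator(cfg: StudyConfig, rng: np.random.Generator,
                       seed: int) -> GeneratorConfig:
    scale = float(np.exp(rng.normal(0.0, cfg.amplitude_scale_sigma)))
    noise_scale = float(np.exp(rng.normal(0.0, cfg.noise_scale_sigma)))
    sign = -1 if rng.random() < cfg.inversion_prob else 1
    amps = {ch: a * scale
            for ch, a in cfg.generator.erp_amplitude_by_channel.items()}
    return replace(cfg.generator,
                   erp_amplitude_by_channel=amps,
                   noise_sd_uv=cfg.generator.noise_sd_uv * noise_scale,
                   polarity_sign=sign, seed=seed)


def run_subject(cfg: StudyConfig, subject: str, paradigm_seed: int,
                gen: GeneratorConfig) -> SubjectResult:
    """Full pipeline for one simulated subject."""
    montage = default_montage()
    paradigm = replace(cfg.paradigm, seed=paradigm_seed)
    schedule = schedule_session(paradigm)
    rec = synthesize_recording(schedule, montage, gen,
                               sample_rate=paradigm.sample_rate,
                               epoch_pre_ms=cfg.preprocess.epoch_pre_ms,
                               epoch_post_ms=cfg.preprocess.epoch_post_ms)
    rec = bandpass(rec, cfg.preprocess)
    rec = derive_bipolar(rec, montage)
    eps = baseline_correct(epoch(rec, cfg.preprocess))

    scopes = {
        "cap": list(montage.scalp_channels),
        "ceegrid": list(montage.bipolar_labels),
    }
    averages: dict[str, ERPAverage] = {}
    accuracies: dict[str, AccuracyResult] = {}
    n_rejected: dict[str, int] = {}
    for system in cfg.systems:
        cleaned = reject_artifacts(eps, cfg.preprocess, channels=scopes[system])
        n_rejected[system] = int((~cleaned.kept).sum())
        averages[system] = average(cleaned)
        clf_eps = cleaned if cfg.classifier.reject_for_classification else eps
        accuracies[system] = loocv_accuracy(
            clf_eps, cfg.classifier, channels_for_system(montage, system))

    threshold: float | None = None
    if cfg.run_psychophysics:
        sub_rng = np.random.default_rng(gen.seed + 1)
        true_thr = float(np.clip(
            sub_rng.normal(cfg.psycho.true_threshold_pct, cfg.threshold_sd),
            min(cfg.psycho.intensity_grid) + 2.5,
            max(cfg.psycho.intensity_grid) - 2.5))
        observer = replace(cfg.psycho, true_threshold_pct=true_thr,
                           seed=gen.seed + 2)
        scheduler = SchedulerState(grid=cfg.psycho.intensity_grid,
                                   seed=gen.seed + 3)
        trials = run_discrimination_session(observer, scheduler)
        try:
            threshold = estimate_threshold(trials).threshold_pct
        except PsychometricFitError as exc:
            logger.warning("subject %s: no sensitivity threshold (%s)",
                           subject, exc)
    return SubjectResult(subject=subject, averages=averages,
                         accuracies=accuracies, threshold_pct=threshold,
                         n_rejected=n_rejected)


def scalp_session_accuracy(paradigm: ParadigmConfig, gen: GeneratorConfig,
                           preprocess: PreprocessConfig = PreprocessConfig(),
                           classifier: ClassifierConfig = ClassifierConfig(),
                           ) -> AccuracyResult:
    """Simulate one scalp-cap-only session and return its LOO-CV accuracy.

    The workhorse of calibration studies (chance-level validation, SNR
    sweeps) where only the 12 cap channels are needed and synthesizing
    the ear arrays would triple the cost.  Ear-channel entries in the
    generator's amplitude map are ignored.
    """
    from .montage import cap_montage

    m = cap_montage()
    amps = {ch: a for ch, a in gen.erp_amplitude_by_channel.items()
            if ch in m.channels}
    gen = replace(gen, erp_amplitude_by_channel=amps)
    schedule = schedule_session(paradigm)
    rec = synthesize_recording(schedule, m, gen,
                               sample_rate=paradigm.sample_rate,
                               epoch_pre_ms=preprocess.epoch_pre_ms,
                               epoch_post_ms=preprocess.epoch_post_ms)
    rec = bandpass(rec, preprocess)
    eps = baseline_correct(epoch(rec, preprocess))
    return loocv_accuracy(eps, classifier, channels_for_system(m, "cap"))


def run_study(cfg: StudyConfig, out_dir: str | Path | None = None) -> StudyResult:
    """Simulate and analyze a whole cohort; optionally write the report."""
    seeds = np.random.SeedSequence(cfg.master_seed).spawn(cfg.n_subjects)
    subjects: list[SubjectResult] = []
    excluded: list[str] = []
    for i, ss in enumerate(seeds):
        subject = f"S{i + 1:02d}"
        child = ss.generate_state(2)
        het_rng = np.random.default_rng(ss.spawn(1)[0])
        gen = _subject_generator(cfg, het_rng, int(child[0] % (2 ** 31)))
        try:
            subjects.append(run_subject(cfg, subject,
                                        int(child[1] % (2 ** 31)), gen))
        except Exception as exc:  # per-subject exclusion, study continues
            logger.warning("subject %s excluded: %s", subject, exc)
            excluded.append(subject)

    scalp_coi = [(c, w) for c, w in CHANNELS_OF_INTEREST if "-" not in c]
    grid_coi = [(c, w) for c, w in CHANNELS_OF_INTEREST if "-" in c]
    frames = []
    if any("cap" in s.averages for s in subjects):
        frames.append(feature_table(
            {s.subject: s.averages["cap"] for s in subjects
             if "cap" in s.averages}, tuple(scalp_coi)))
    if any("ceegrid" in s.averages for s in subjects):
        frames.append(feature_table(
            {s.subject: s.averages["ceegrid"] for s in subjects
             if "ceegrid" in s.averages}, tuple(grid_coi)))
    features = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    group: dict[str, GroupResult | None] = {}
    posthoc = None
    both = [s for s in subjects
            if "cap" in s.accuracies and "ceegrid" in s.accuracies]
    if len(both) >= 3:
        cap_acc = np.array([s.accuracies["cap"].accuracy_pct for s in both])
        grid_acc = np.array([s.accuracies["ceegrid"].accuracy_pct for s in both])
        group["accuracy_paired_t"] = paired_t(cap_acc, grid_acc)
        group["accuracy_correlation"] = pearson(cap_acc, grid_acc)
        wide = features.pivot_table(index="subject", columns="channel",
                                    values="mean_amplitude_uv")
        if {"Cz", "R2-R7"} <= set(wide.columns):
            cw = wide.loc[[s.subject for s in both]]
            group["amplitude_correlation"] = pearson(
                cw["Cz"].to_numpy(), cw["R2-R7"].to_numpy())
        coi = [c for c, _ in CHANNELS_OF_INTEREST]
        if set(coi) <= set(wide.columns) and len(wide) >= 3:
            mat = wide.loc[:, coi].dropna()
            if len(mat) >= 3:
                group["amplitude_rm_anova"], posthoc = rm_anova_gg(
                    mat.to_numpy(), coi)
        thr = [(s.accuracies, s.threshold_pct) for s in both
               if s.threshold_pct is not None]
        if len(thr) >= 3:
            t_arr = np.array([t for _, t in thr])
            group["sensitivity_vs_cap"] = pearson(
                np.array([a["cap"].accuracy_pct for a, _ in thr]), t_arr)
            group["sensitivity_vs_ceegrid"] = pearson(
                np.array([a["ceegrid"].accuracy_pct for a, _ in thr]), t_arr)

    result = StudyResult(config=cfg, subjects=subjects, features=features,
                         group=group, posthoc=posthoc, excluded=excluded)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        thresholds = {s.subject: s.threshold_pct for s in subjects}
        result.paths = report_tables(
            features,
            {s.subject: s.accuracies.get("cap") for s in subjects},
            {s.subject: s.accuracies.get("ceegrid") for s in subjects},
            thresholds, out)
        for system, coi in (("cap", scalp_coi), ("ceegrid", grid_coi)):
            avgs = {s.subject: s.averages[system] for s in subjects
                    if system in s.averages}
            if avgs:
                path = out / f"grand_average_{system}.png"
                grand_average_figure(avgs, [c for c, _ in coi], path)
                result.paths[f"grand_average_{system}"] = path
        stats_payload = {
            name: None if res is None else {
                "test": res.test, "statistic": res.statistic,
                "df": list(res.df), "p_value": res.p_value,
                "effect_size": res.effect_size,
                "effect_size_name": res.effect_size_name,
                "correction": res.correction,
            } for name, res in group.items()}
        (out / "group_stats.json").write_text(json.dumps(stats_payload, indent=1))
        import hashlib

        config_json = json.dumps(dataclasses.asdict(cfg), sort_keys=True,
                                 default=str)
        provenance = {
            "package": "gridtap", "version": __version__,
            "master_seed": cfg.master_seed,
            "config": dataclasses.asdict(cfg),
            "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
            "excluded_subjects": excluded,
        }
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=1, default=str))
        result.paths["group_stats"] = out / "group_stats.json"
        result.paths["provenance"] = out / "provenance.json"
    return result


def study_config_from_json(path: str | Path) -> StudyConfig:
    """Build a :class:`StudyConfig` from a JSON file of (nested) fields."""
    raw = json.loads(Path(path).read_text())
    sub = {
        "paradigm": ParadigmConfig, "generator": GeneratorConfig,
        "preprocess": PreprocessConfig, "classifier": ClassifierConfig,
        "psycho": PsychoSimConfig,
    }
    kwargs: dict = {}
    for key, value in raw.items():
        if key in sub:
            if "positions" in value:
                value = {**value, "positions": tuple(value["positions"])}
            if "intensity_grid" in value:
                value = {**value, "intensity_grid": tuple(value["intensity_grid"])}
            kwargs[key] = sub[key](**value)
        elif key == "systems":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return StudyConfig(**kwargs)
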