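"""End-to-end synthetic replication of the clinical study.

``run_study`` chains every stage: generate a group-structured cohort of
synthetic observers, run a 25-trial adaptive session per subject and
condition (non-dominant eye, dominant eye, binocular — in randomized order
per subject), collect CSF estimates, run the binocular summation analysis
on the estimated CSFs, compute group statistics (Wilcoxon eye comparisons,
summation-index t-tests against 1, probability-summation comparisons), and
the Monte-Carlo false-positive-risk simulation anchored at the study's own
AMB-vs-NSC AULCSF p-value.  The whole study is deterministic given the
master seed.

The default engine settings here are study-scale: a reduced parameter grid
and stimulus space (see docs/methods.md) keep the 165-session study to
about a minute on one CPU; single-session work can use the full-resolution
defaults of :mod:`qcsf.engine` via the configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as qio
from .engine import (
    LikelihoodCache,
    default_parameter_grid,
    default_stimulus_space,
    gaussian_population_prior,
    init_prior,
    rescore_session,
    run_session,
)
from .fpr import (
    DegenerateTestError,
    FPRConfig,
    FPRResult,
    eye_comparison_test,
    fpr_simulation,
    summation_vs_unity_test,
)
from .model import CSFParameters, PsychometricSpec
from .observers import (
    CONDITIONS,
    Cohort,
    generate_cohort,
)
from .summation import (
    classify_summation,
    detection_profile,
    group_summation_test,
    latent_summation_score,
    summation_index,
)


__all__ = [
    "EngineConfig",
    "AnalysisConfig",
    "StudyConfig",
    "StudyReport",
    "run_study",
    "parse_config",
    "write_report",
    "analyze_trial_log",
]


@dataclass(frozen=True)
class EngineConfig:
    """Adaptive-engine settings for the study pipeline (study-scale grid)."""

    n_trials: int = 25
    n_gain: int = 18
    n_frequency: int = 14
    n_bandwidth: int = 9
    n_truncation: int = 9
    n_stim_frequencies: int = 20
    n_stim_contrasts: int = 24
    #: dtype of the cached likelihood tables; float32 halves the memory
    #: traffic of stimulus selection with no visible effect on estimates
    table_dtype: str = "float32"
    #: rescore each session under an informative population prior after
    #: collection (collection itself always starts from a uniform prior)
    rescore_population_prior: bool = True
    #: log10 (gain, peak frequency, bandwidth, truncation) location and
    #: spread of the population prior; broad enough to cover amblyopic eyes
    prior_mean_log: tuple[float, float, float, float] = (1.86, 0.59, -0.48, -0.30)
    prior_sd_log: tuple[float, float, float, float] = (0.45, 0.30, 0.20, 0.35)

    def grid(self):
        return default_parameter_grid(
            self.n_gain, self.n_frequency, self.n_bandwidth, self.n_truncation
        )

    def space(self):
        return default_stimulus_space(
            self.n_stim_frequencies, self.n_stim_contrasts
        )


@dataclass(frozen=True)
class AnalysisConfig:
    """Summation-analysis settings."""

    aulcsf_f_lo: float = 0.64
    aulcsf_f_hi: float = 41.0
    n_profile_frequencies: int = 1000
    classification_tolerance: float = 0.01
    #: evaluate detection probabilities only where the binocular threshold
    #: is a presentable contrast (None: the full frequency range)
    max_threshold_contrast: float | None = 1.0
    #: statistic for the group-level pattern classification:
    #: "probability" (t-test of mean-first expected probability vs the
    #: criterion, the original analysis), "probit" (same test on the
    #: probit of the mean), or "latent" (per-frequency probit average)
    group_test_scale: str = "probability"


@dataclass(frozen=True)
class StudyConfig:
    """Full configuration of a synthetic study run.

    ``group_overrides`` patches fields of the default cohort's group
    specifications by group name, e.g.
    ``{"AMB": {"n_subjects": 15, "nde": {"sd_log_gain": 0.3}}}``; eye
    sub-mappings patch the corresponding ``EyeDistribution`` fields, and
    regimes are given as ``{"kind": ..., "factor": ...}``.
    """

    seed: int = 0
    engine: EngineConfig = field(default_factory=EngineConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    psychometric: PsychometricSpec = field(default_factory=PsychometricSpec)
    fpr_n_sim: int = 100_000
    fpr_band_factor: float = 2.0
    output_dir: str | None = None
    group_overrides: dict | None = None

    def group_specs(self):
        from .observers import default_group_specs

        specs = default_group_specs()
        if not self.group_overrides:
            return specs
        from .observers import EyeDistribution, Regime

        by_name = {s.name: s for s in specs}
        unknown = set(self.group_overrides) - set(by_name)
        if unknown:
            raise ValueError(
                f"unknown groups {sorted(unknown)}; valid: {sorted(by_name)}"
            )
        out = []
        for spec in specs:
            patch = dict(self.group_overrides.get(spec.name, {}))
            valid = {f.name for f in dataclasses.fields(spec)}
            bad = set(patch) - valid
            if bad:
                raise ValueError(
                    f"unknown group fields {sorted(bad)} for {spec.name}; "
                    f"valid: {sorted(valid)}"
                )
            for eye in ("nde", "de"):
                if eye in patch:
                    patch[eye] = dataclasses.replace(
                        getattr(spec, eye), **patch[eye]
                    )
            for reg in ("regime_fusing", "regime_nonfusing"):
                if reg in patch:
                    patch[reg] = Regime(**patch[reg])
            out.append(dataclasses.replace(spec, **patch))
        return out


@dataclass
class StudyReport:
    """All study outputs: tables, group summaries, tests, FPR, pattern."""

    config: StudyConfig
    cohort: Cohort
    trial_log: pd.DataFrame
    estimates: pd.DataFrame
    summation: pd.DataFrame
    group_summary: pd.DataFrame
    tests: dict
    fpr: FPRResult | None
    pattern: dict


_CONFIG_SECTIONS = {
    "seed": None,
    "engine": EngineConfig,
    "analysis": AnalysisConfig,
    "psychometric": PsychometricSpec,
    "fpr_n_sim": None,
    "fpr_band_factor": None,
    "output_dir": None,
    "group_overrides": None,
}


def _build_section(cls, payload: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(
            f"unknown keys {sorted(unknown)} in config section "
            f"{section!r}; valid keys: {sorted(valid)}"
        )
    return cls(**payload)


def parse_config(path) -> StudyConfig:
    """Parse a YAML study configuration; absent keys take defaults.

    Unknown keys raise ``ValueError`` listing the valid keys (no silent
    typos).
    """
    text = Path(path).read_text()
    payload = yaml.safe_load(text) or {}
    if not isinstance(payload, dict):
        raise ValueError("config must be a mapping")
    unknown = set(payload) - set(_CONFIG_SECTIONS)
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: "
            f"{sorted(_CONFIG_SECTIONS)}"
        )
    kwargs = {}
    for key, value in payload.items():
        cls = _CONFIG_SECTIONS[key]
        if cls is None:
            kwargs[key] = value
        else:
            if not isinstance(value, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            kwargs[key] = _build_section(cls, value, key)
    return StudyConfig(**kwargs)


def _estimates_row(sid: str, cond: str, result) -> dict:
    p = result.estimates
    return {
        "subject_id": sid,
        "condition": cond,
        "peak_gain": p.peak_gain,
        "peak_frequency_cpd": p.peak_frequency,
        "bandwidth": p.bandwidth,
        "truncation": p.truncation,
        "aulcsf": result.aulcsf_estimate,
        "csf_acuity_cpd": result.csf_acuity_estimate,
        "ci_width_683": result.ci_width,
    }


def _params_from_row(row) -> CSFParameters:
    return CSFParameters(
        peak_gain=float(row["peak_gain"]),
        peak_frequency=float(row["peak_frequency_cpd"]),
        bandwidth=float(row["bandwidth"]),
        truncation=float(row["truncation"]),
    )


def _summation_table(
    estimates: pd.DataFrame,
    meta: pd.DataFrame,
    spec: PsychometricSpec,
    analysis: AnalysisConfig,
) -> pd.DataFrame:
    """Per-subject summation analysis from estimated CSFs.

    ``meta`` maps subject_id to group and fusion status.
    """
    est = estimates.set_index(["subject_id", "condition"])
    rows = []
    for rec in meta.itertuples():
        sid = rec.subject_id
        nde = _params_from_row(est.loc[(sid, "NDE")])
        de = _params_from_row(est.loc[(sid, "DE")])
        bino = _params_from_row(est.loc[(sid, "BIN")])
        aul_nde = float(est.loc[(sid, "NDE"), "aulcsf"])
        aul_de = float(est.loc[(sid, "DE"), "aulcsf"])
        aul_bin = float(est.loc[(sid, "BIN"), "aulcsf"])
        profile = detection_profile(
            nde,
            de,
            bino,
            spec,
            n_frequencies=analysis.n_profile_frequencies,
            freq_range=(analysis.aulcsf_f_lo, analysis.aulcsf_f_hi),
            max_threshold_contrast=analysis.max_threshold_contrast,
        )
        rows.append(
            {
                "subject_id": sid,
                "group": rec.group,
                "fuses": int(rec.fuses),
                "aulcsf_nde": aul_nde,
                "aulcsf_de": aul_de,
                "aulcsf_bin": aul_bin,
                "summation_index": summation_index(aul_bin, aul_de),
                "p_nde": profile.p_nde,
                "p_de": profile.p_de,
                "p_expected": profile.p_expected,
                "classification": classify_summation(
                    profile, tolerance=analysis.classification_tolerance
                ),
                "z_expected": latent_summation_score(
                    profile, spec.guess_rate, spec.lapse_rate
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=list(qio.SUMMATION_COLUMNS) + ["z_expected"]
    )


def _group_tests(
    summation: pd.DataFrame,
    estimates: pd.DataFrame,
    spec: PsychometricSpec,
    group_test_scale: str = "probability",
) -> tuple[dict, dict]:
    """Group-level statistics and the qualitative summation pattern."""
    tests: dict = {}
    pattern: dict = {}
    observed = spec.criterion_p
    subsets = {
        "AMB": summation[summation["group"] == "AMB"],
        "AMB_fusing": summation[
            (summation["group"] == "AMB") & (summation["fuses"] == 1)
        ],
        "SWA_fusing": summation[
            (summation["group"] == "SWA") & (summation["fuses"] == 1)
        ],
        "SWA_nonfusing": summation[
            (summation["group"] == "SWA") & (summation["fuses"] == 0)
        ],
        "NSC": summation[summation["group"] == "NSC"],
    }
    from scipy import stats as sps
    from .summation import _probit

    z_target = float(_probit(observed, spec.guess_rate))
    for name, sub in subsets.items():
        if len(sub) < 2:
            continue
        # probability-scale one-sample t-test (the original analysis)
        prob_res = group_summation_test(
            sub["p_expected"].to_numpy(), observed
        )
        tests[f"summation_vs_probability/{name}"] = prob_res
        # the per-frequency latent score, unbiased under symmetric
        # threshold-estimation noise (see latent_summation_score)
        z = sub["z_expected"].to_numpy()
        t, p = sps.ttest_1samp(z, popmean=z_target)
        if p < 0.05:
            lat_cls = "supra" if z.mean() < z_target else "sub"
        else:
            lat_cls = "consistent"
        tests[f"summation_latent/{name}"] = {
            "classification": lat_cls, "mean_z": float(z.mean()),
            "t": float(t), "p": float(p), "n": int(z.size),
        }
        if group_test_scale == "latent":
            pattern[name] = lat_cls
        elif group_test_scale == "probit":
            pattern[name] = group_summation_test(
                sub["p_expected"].to_numpy(), observed,
                scale="probit", guess=spec.guess_rate,
            )["classification"]
        else:
            pattern[name] = prob_res["classification"]
        try:
            tests[f"summation_index_vs_1/{name}"] = summation_vs_unity_test(
                sub["summation_index"].to_numpy()
            )
        except DegenerateTestError as err:
            tests[f"summation_index_vs_1/{name}"] = {"degenerate": str(err)}
    # within-group NDE vs DE AULCSF, paired Wilcoxon
    est = estimates.merge(
        summation[["subject_id", "group"]], on="subject_id", how="left"
    )
    for gname in est["group"].dropna().unique():
        sub = est[est["group"] == gname]
        wide = sub.pivot(
            index="subject_id", columns="condition", values="aulcsf"
        )
        try:
            tests[f"aulcsf_nde_vs_de/{gname}"] = eye_comparison_test(
                wide["NDE"].to_numpy(), wide["DE"].to_numpy(), paired=True
            )
        except DegenerateTestError as err:
            tests[f"aulcsf_nde_vs_de/{gname}"] = {"degenerate": str(err)}
    return tests, pattern


def run_study(config: StudyConfig | None = None) -> StudyReport:
    """Run the full synthetic study; deterministic given ``config.seed``."""
    config = config or StudyConfig()
    spec = config.psychometric
    root = np.random.SeedSequence(config.seed)
    _, session_root, order_root, fpr_seed = root.spawn(4)
    cohort = generate_cohort(
        config.group_specs(), seed=config.seed, psychometric=spec
    )
    grid = config.engine.grid()
    space = config.engine.space()
    cache = LikelihoodCache(
        grid, space, spec, dtype=np.dtype(config.engine.table_dtype)
    )
    prior = init_prior(grid)
    pop_prior = None
    if config.engine.rescore_population_prior:
        pop_prior = gaussian_population_prior(
            grid, config.engine.prior_mean_log, config.engine.prior_sd_log
        )

    n_obs = len(cohort.observers)
    session_seeds = session_root.spawn(n_obs * len(CONDITIONS))
    order_rngs = [np.random.default_rng(s) for s in order_root.spawn(n_obs)]

    est_rows = []
    log_sessions: dict[tuple[str, str], tuple] = {}
    meta_rows = []
    for i, obs in enumerate(cohort.observers):
        order = list(order_rngs[i].permutation(np.array(CONDITIONS)))
        for j, cond in enumerate(order):
            seed = session_seeds[i * len(CONDITIONS) + j]
            result = run_session(
                obs.responder(cond),
                n_trials=config.engine.n_trials,
                prior=prior,
                spec=spec,
                seed=seed,
                cache=cache,
            )
            if pop_prior is not None:
                result = rescore_session(
                    result.trials, pop_prior, spec, cache=cache
                )
            est_rows.append(_estimates_row(obs.subject_id, cond, result))
            log_sessions[(obs.subject_id, cond)] = result.trials
        meta_rows.append(
            {"subject_id": obs.subject_id, "group": obs.group,
             "fuses": int(obs.fuses)}
        )

    estimates = pd.DataFrame(est_rows, columns=list(qio.ESTIMATES_COLUMNS))
    meta = pd.DataFrame(meta_rows)
    trial_rows = [
        {
            "subject_id": sid,
            "condition": cond,
            "trial_index": t.trial_index,
            "frequency_cpd": t.stimulus.frequency,
            "contrast": t.stimulus.contrast,
            "correct": int(t.correct),
        }
        for (sid, cond), trials in log_sessions.items()
        for t in trials
    ]
    trial_log = pd.DataFrame(trial_rows, columns=list(qio.TRIAL_LOG_COLUMNS))

    summation = _summation_table(estimates, meta, spec, config.analysis)
    tests, pattern = _group_tests(
        summation, estimates, spec, config.analysis.group_test_scale
    )

    merged = estimates.merge(meta, on="subject_id")
    group_summary = (
        merged.groupby(["group", "condition"])
        .agg(
            n=("aulcsf", "size"),
            aulcsf_mean=("aulcsf", "mean"),
            aulcsf_sd=("aulcsf", "std"),
            peak_gain_mean=("peak_gain", "mean"),
            peak_frequency_mean=("peak_frequency_cpd", "mean"),
            acuity_mean=("csf_acuity_cpd", "mean"),
            ci_width_mean=("ci_width_683", "mean"),
        )
        .reset_index()
    )

    # FPR anchored at the study's own AMB-NDE vs NSC-eyes AULCSF comparison
    amb_nde = merged.query("group == 'AMB' and condition == 'NDE'")["aulcsf"]
    nsc_eyes = merged.query(
        "group == 'NSC' and condition in ('NDE', 'DE')"
    )["aulcsf"]
    fpr_result = None
    if len(amb_nde) >= 2 and len(nsc_eyes) >= 2:
        from scipy import stats as sps

        t, p = sps.ttest_ind(amb_nde, nsc_eyes, equal_var=False)
        tests["aulcsf_amb_nde_vs_nsc"] = {
            "test": "welch-t", "statistic": float(t), "p": float(p),
        }
        anchor = float(np.clip(p, 1e-12, 0.999))
        fpr_result = fpr_simulation(
            FPRConfig(
                null_mean=float(nsc_eyes.mean()),
                null_sd=float(nsc_eyes.std()),
                alt_mean=float(amb_nde.mean()),
                alt_sd=float(amb_nde.std()),
                n_test=len(amb_nde),
                n_ref=len(nsc_eyes),
                n_sim=config.fpr_n_sim,
                observed_p=anchor,
                band_factor=config.fpr_band_factor,
                seed=int(fpr_seed.generate_state(1)[0] % (2**31)),
            )
        )

    report = StudyReport(
        config=config,
        cohort=cohort,
        trial_log=trial_log,
        estimates=estimates,
        summation=summation,
        group_summary=group_summary,
        tests=tests,
        fpr=fpr_result,
        pattern=pattern,
    )
    if config.output_dir is not None:
        write_report(report, config.output_dir)
    return report


def analyze_trial_log(
    trial_log: pd.DataFrame,
    meta: pd.DataFrame,
    config: StudyConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimates + summation tables from an existing trial log.

    ``meta`` must carry subject_id, group and fuses columns.  Sessions are
    rescored on the configured grid, under the same prior policy as
    ``run_study`` (the population prior when enabled, else uniform).
    """
    config = config or StudyConfig()
    spec = config.psychometric
    grid = config.engine.grid()
    if config.engine.rescore_population_prior:
        prior = gaussian_population_prior(
            grid, config.engine.prior_mean_log, config.engine.prior_sd_log
        )
    else:
        prior = init_prior(grid)
    cache = LikelihoodCache(
        grid, config.engine.space(), spec,
        dtype=np.dtype(config.engine.table_dtype),
    )
    est_rows = []
    for (sid, cond), _ in trial_log.groupby(["subject_id", "condition"]):
        records = qio.trial_records(trial_log, sid, cond)
        result = rescore_session(records, prior, spec, cache=cache)
        est_rows.append(_estimates_row(sid, cond, result))
    estimates = pd.DataFrame(est_rows, columns=list(qio.ESTIMATES_COLUMNS))
    summation = _summation_table(estimates, meta, spec, config.analysis)
    return estimates, summation


def write_report(report: StudyReport, outdir) -> None:
    """Write the CSV bundle and a human-readable summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    qio.write_trial_log(report.trial_log, out / "trial_log.csv")
    qio.write_estimates(report.estimates, out / "estimates.csv")
    qio.write_summation(report.summation, out / "summation.csv")
    qio.write_cohort_manifest(report.cohort, out / "cohort_manifest.csv")
    report.group_summary.to_csv(out / "group_summary.csv", index=False)

    lines = [f"synthetic study, master seed {report.config.seed}", ""]
    lines.append("group-level summation pattern:")
    for k, v in report.pattern.items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append("tests:")
    for k, v in report.tests.items():
        lines.append(f"  {k}: {v}")
    if report.fpr is not None:
        lines.append("")
        lines.append(f"fpr: {report.fpr.as_dict()}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    (out / "config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(report.config))
    )
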