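"""Synthetic two-group, two-visit cohort generator with known ground truth.

The study population this emulates is a prenatal intervention trial: an
intervention group and a control group, each recorded at a first and a
last visit, with begin/end 10-minute analysis windows per recording and
maternal age, BMI and gestational age as covariates.

Two generation routes are provided:

* :func:`generate_cohort` produces raw RR-interval recordings from an
  additive sinusoid + AR(1) model (LF/HF oscillations on a mean RR, with
  autoregressive beat-to-beat noise).  Complexity is tuned through a latent
  z-score per recording that lowers the AR coefficient and raises the noise
  SD (both raise the entropy rate); group effects and covariate effects act
  on that latent score.  Artifacts are ectopic-like RR halvings/doublings
  plus beat dropouts, flagged so the SQI can see them.

* :func:`generate_metric_matrix` bypasses the signal stages and draws
  subjects-by-metrics matrices from a linear latent-factor model, for
  direct testing of the harmonization / PCA / mixed-model stages.

All randomness flows from explicit integer seeds; identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .signal_prep import RRSeries

__all__ = [
    "TrialDesign",
    "RRGenParams",
    "GroundTruth",
    "generate_rr_series",
    "generate_cohort",
    "generate_metric_matrix",
    "write_cohort",
]

GROUPS = ("intervention", "control")
VISITS = ("first", "last")
WINDOWS = ("begin", "end")

#: hard floor on generated RR intervals, ms
RR_FLOOR_MS = 200.0


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(f"parameter {name!r} must be finite, got {value}")
    return value


@dataclass
class TrialDesign:
    """Cohort layout: group sizes, visit labels and covariate draws.

    Covariate ranges follow the study population: maternal age 25-42 y,
    BMI 18-30 kg/m2, gestational age 16-22 weeks at the first visit and
    12-18 weeks later at the last.
    """

    n_per_group: int = 14
    groups: tuple[str, str] = GROUPS
    visits: tuple[str, str] = VISITS
    windows: tuple[str, str] = WINDOWS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")

    @property
    def n_subjects(self) -> int:
        return self.n_per_group * len(self.groups)

    def draw_covariates(self) -> pd.DataFrame:
        """Subject table with group labels and covariates; seeded."""
        rng = np.random.default_rng(self.seed)
        rows = []
        for g in self.groups:
            for i in range(self.n_per_group):
                ga_first = rng.uniform(16.0, 22.0)
                rows.append({
                    "subject": f"{g[:3]}{i + 1:02d}",
                    "group": g,
                    "maternal_age": rng.uniform(25.0, 42.0),
                    "bmi": rng.uniform(18.0, 30.0),
                    "ga_first": ga_first,
                    "ga_last": ga_first + rng.uniform(12.0, 18.0),
                })
        return pd.DataFrame(rows)


@dataclass
class RRGenParams:
    """Parameters of the additive sinusoid + AR(1) RR model.

    ``lf_freq``/``hf_freq`` must lie in the conventional LF (0.04-0.15 Hz)
    and HF (0.15-0.4 Hz) bands; ``ar_coeff`` controls beat-to-beat
    predictability (higher -> more predictable -> lower entropy) and
    ``noise_sd`` the fluctuation scale.
    """

    mean_rr: float = 800.0
    lf_amp: float = 25.0
    hf_amp: float = 15.0
    lf_freq: float = 0.1
    hf_freq: float = 0.25
    ar_coeff: float = 0.5
    noise_sd: float = 20.0
    duration: float = 2700.0
    artifact_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mean_rr", "lf_amp", "hf_amp", "lf_freq", "hf_freq",
                     "ar_coeff", "noise_sd", "duration", "artifact_rate"):
            setattr(self, name, _check_finite(name, getattr(self, name)))
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not -1.0 < self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in (-1, 1)")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must lie in [0, 1)")
        if self.lf_freq and not 0.04 <= self.lf_freq <= 0.15:
            raise ValueError("lf_freq must lie in the LF band [0.04, 0.15] Hz")
        if self.hf_freq and not 0.15 <= self.hf_freq <= 0.4:
            raise ValueError("hf_freq must lie in the HF band [0.15, 0.4] Hz")


@dataclass
class GroundTruth:
    """Simulation ground truth recorded alongside every generated dataset.

    Effects are in z-units of the complexity-controlling latent score (RR
    route) or of the metric columns (matrix route).  ``covariate_betas``
    maps covariate name -> slope per SD of the covariate.
    """

    group_baseline_shift: float = 0.0
    group_time_interaction: float = 0.0
    covariate_betas: dict = field(default_factory=dict)
    latent_factor_count: int = 3
    noise_sd: float = 0.5

    def latent_z(self, group: str, visit: str, cov_z: dict[str, float]) -> float:
        """Deterministic part of the complexity latent score."""
        z = 0.0
        if group == "intervention":
            z += self.group_baseline_shift
            if visit == "last":
                z += self.group_time_interaction
        for name, beta in self.covariate_betas.items():
            z += beta * cov_z.get(name, 0.0)
        return z

    def to_dict(self) -> dict:
        return asdict(self)


def generate_rr_series(
    params: RRGenParams,
    seed: int,
    subject: str = "",
    visit: str = "",
) -> RRSeries:
    """One RR recording from the sinusoid + AR(1) model.

    RR_i = mean_rr + lf_amp sin(2 pi f_lf t_i) + hf_amp sin(2 pi f_hf t_i)
    + e_i, with e_i an AR(1) process of stationary SD ``noise_sd``.
    Artifacts (rate per beat) are ectopic-like halvings/doublings of RR,
    flagged, plus dropouts realised as two intervals merged into one
    (implausibly long, hence visible to the SQI).
    """
    rng = np.random.default_rng(seed)
    n_max = int(np.ceil(params.duration / (RR_FLOOR_MS / 1000.0))) + 2
    rr = np.empty(n_max)
    times = np.empty(n_max)
    innov_sd = params.noise_sd * np.sqrt(1.0 - params.ar_coeff ** 2)
    e = rng.standard_normal() * params.noise_sd
    t = 0.0
    i = 0
    while t < params.duration and i < n_max:
        val = (params.mean_rr
               + params.lf_amp * np.sin(2 * np.pi * params.lf_freq * t)
               + params.hf_amp * np.sin(2 * np.pi * params.hf_freq * t)
               + e)
        val = max(val, RR_FLOOR_MS)
        t += val / 1000.0
        rr[i] = val
        times[i] = t
        e = params.ar_coeff * e + rng.standard_normal() * innov_sd
        i += 1
    rr, times = rr[:i], times[:i]
    flags = np.zeros(i, dtype=bool)

    if params.artifact_rate > 0.0 and i > 3:
        hit = rng.random(i) < params.artifact_rate
        kind = rng.integers(0, 3, size=i)  # 0 halve, 1 double, 2 dropout
        halve = hit & (kind == 0)
        rr[halve] *= 0.5
        flags |= halve
        double = hit & (kind == 1)
        rr[double] *= 2.0
        flags |= double
        drop = np.flatnonzero(hit & (kind == 2))
        drop = drop[(drop > 0)]
        if drop.size:
            # merge dropped beat into its successor: beat undetected
            rr2 = rr.copy()
            keep = np.ones(i, dtype=bool)
            for j in drop:
                if j + 1 < i and keep[j]:
                    rr2[j + 1] = rr2[j + 1] + rr2[j]
                    keep[j] = False
            rr = rr2[keep]
            flags = (flags | ~keep)[keep] | (rr > 1800.0)
            times = times[keep]
        # recompute beat times from the (possibly merged) intervals
        times = np.cumsum(rr) / 1000.0
    return RRSeries(times, rr, artifact_flags=flags, subject=subject, visit=visit)


def _complexity_adjusted(params: RRGenParams, z: float,
                         duration: float) -> RRGenParams:
    """Map a latent complexity z-score onto the RR model parameters.

    Higher z -> lower AR coefficient and larger noise SD, both of which
    raise the entropy rate of the smoothed HR; the mapping is monotone
    and bounded.
    """
    ar = float(np.clip(params.ar_coeff - 0.15 * z, 0.02, 0.98))
    noise = float(max(params.noise_sd * (1.0 + 0.2 * z), 1.0))
    return RRGenParams(
        mean_rr=params.mean_rr, lf_amp=params.lf_amp, hf_amp=params.hf_amp,
        lf_freq=params.lf_freq, hf_freq=params.hf_freq, ar_coeff=ar,
        noise_sd=noise, duration=duration, artifact_rate=params.artifact_rate,
    )


def generate_cohort(
    design: TrialDesign,
    rr_params: Optional[RRGenParams] = None,
    truth: Optional[GroundTruth] = None,
    durations: Optional[dict[str, float]] = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], RRSeries], GroundTruth]:
    """Full cohort: one recording per subject per visit, plus ground truth.

    Intervention recordings carry the baseline complexity shift at both
    visits and additionally the group-by-time interaction at the last
    visit.  ``durations`` maps group -> recording length in seconds
    (defaults: intervention 6300 s, control 2700 s, mirroring the
    different session lengths of the two arms).
    """
    rr_params = rr_params or RRGenParams()
    truth = truth or GroundTruth()
    durations = durations or {"intervention": 6300.0, "control": 2700.0}
    cohort = design.draw_covariates()
    # standardized covariates for the linear coupling
    cov_z = {}
    for c in ("maternal_age", "bmi", "ga_first", "ga_last"):
        col = cohort[c]
        sd = col.std(ddof=0)
        cov_z[c] = (col - col.mean()) / (sd if sd > 0 else 1.0)

    ss = np.random.SeedSequence(design.seed)
    child_seeds = ss.generate_state(design.n_subjects * len(design.visits)) % (2 ** 31)
    noise_rng = np.random.default_rng(ss.generate_state(1)[0] % (2 ** 31))

    recordings: dict[tuple[str, str], RRSeries] = {}
    k = 0
    for idx, row in cohort.iterrows():
        for visit in design.visits:
            ga = row["ga_first"] if visit == "first" else row["ga_last"]
            covs = {"maternal_age": cov_z["maternal_age"][idx],
                    "bmi": cov_z["bmi"][idx],
                    "gestational_age": cov_z["ga_first" if visit == "first"
                                             else "ga_last"][idx]}
            z = truth.latent_z(row["group"], visit, covs)
            z += noise_rng.standard_normal() * truth.noise_sd
            p = _complexity_adjusted(rr_params, z,
                                     durations.get(row["group"], rr_params.duration))
            recordings[(row["subject"], visit)] = generate_rr_series(
                p, int(child_seeds[k]), subject=row["subject"], visit=visit)
            k += 1
    return cohort, recordings, truth


def generate_metric_matrix(
    design: TrialDesign,
    truth: GroundTruth,
    metric_names: Optional[list[str]] = None,
    complexity_metrics: Optional[list[str]] = None,
    timepoints: tuple[str, ...] = ("first_begin", "first_end",
                                   "last_begin", "last_end"),
    seed: Optional[int] = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Subjects-by-metrics matrices from a linear latent-factor model.

    Each timepoint's matrix is F L' + covariate effects + group effects +
    noise, with k = ``latent_factor_count`` standard-normal factors and
    loadings shared across timepoints within a draw.  Loadings are scaled
    by 1/sqrt(k) so that every column has unit factor variance: the
    ground-truth effects are then genuine z-unit shifts of the metric
    scale.  A subject's factor values are correlated across timepoints
    (half stable subject trait, half per-timepoint innovation), giving
    the repeated-measures design a real within-subject component.  Group
    effects (baseline shift; interaction at last-visit timepoints) are
    applied to the complexity-domain columns.  Returns (matrices keyed by
    timepoint, cohort table).
    """
    if metric_names is None:
        from .hrv_battery import METRIC_REGISTRY
        metric_names = list(METRIC_REGISTRY)
        complexity_metrics = [m for m, s in METRIC_REGISTRY.items()
                              if s.domain == "complexity"]
    if complexity_metrics is None:
        complexity_metrics = metric_names
    n_metrics = len(metric_names)
    kf = truth.latent_factor_count
    if kf < 1:
        raise ValueError("latent_factor_count must be at least 1")
    if kf > n_metrics:
        raise ValueError("latent_factor_count exceeds the metric count")
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cohort = design.draw_covariates()
    n = len(cohort)
    loadings = rng.standard_normal((n_metrics, kf)) / np.sqrt(kf)
    stable = rng.standard_normal((n, kf))  # per-subject trait factors
    is_cx = np.array([m in set(complexity_metrics) for m in metric_names])

    cov_z = {}
    for c in ("maternal_age", "bmi"):
        col = cohort[c].to_numpy()
        sd = col.std()
        cov_z[c] = (col - col.mean()) / (sd if sd > 0 else 1.0)

    matrices = {}
    grp = (cohort["group"] == "intervention").to_numpy(dtype=float)
    for tp in timepoints:
        visit = "first" if tp.startswith("first") else "last"
        ga_col = cohort["ga_first" if visit == "first" else "ga_last"].to_numpy()
        sd = ga_col.std()
        ga_z = (ga_col - ga_col.mean()) / (sd if sd > 0 else 1.0)
        factors = np.sqrt(0.5) * stable + np.sqrt(0.5) * rng.standard_normal((n, kf))
        x = factors @ loadings.T
        x += rng.standard_normal((n, n_metrics)) * truth.noise_sd
        shift = truth.group_baseline_shift + (
            truth.group_time_interaction if visit == "last" else 0.0)
        x[:, is_cx] += shift * grp[:, None]
        covs = {"maternal_age": cov_z["maternal_age"], "bmi": cov_z["bmi"],
                "gestational_age": ga_z}
        for name, beta in truth.covariate_betas.items():
            if name in covs:
                x += beta * covs[name][:, None]
        matrices[tp] = pd.DataFrame(x, index=cohort["subject"],
                                    columns=metric_names)
    return matrices, cohort


def write_cohort(out_dir, cohort: pd.DataFrame,
                 recordings: dict[tuple[str, str], RRSeries],
                 truth: GroundTruth) -> None:
    """Write recordings as two-column CSVs plus cohort CSV and truth YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "cohort.csv", index=False)
    with open(out / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(truth.to_dict(), fh)
    for (subject, visit), rec in recordings.items():
        rec.to_frame().to_csv(out / f"{subject}_{visit}.csv", index=False)
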