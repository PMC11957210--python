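"""Synthetic cohort generation with ground truth.

Generates case/control cohorts whose statistical structure matches what the
analysis pipeline assumes: per-plate scale factors, LOD-censored positive
abundances on an exponential scale, a configurable fraction of analytes with
planted case/control mean shifts (in SD units) on top of age/sex nuisance
effects, bimodal biomarker variables, exponential conversion times with
protein-dependent hazards, and piecewise-linear CDR-SB trajectories with
group-dependent slopes.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from plasmad.datamodel import ProteomicsMatrix


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration field."""


@dataclasses.dataclass
class MixtureSpec:
    """Two-component Gaussian mixture for a biomarker variable."""

    means: tuple[float, float] = (0.0, 4.0)       # (negative, positive) component
    sds: tuple[float, float] = (1.0, 1.0)
    positivity_direction: str = "high_is_positive"

    def validate(self) -> None:
        if any(s <= 0 for s in self.sds):
            raise ConfigError("mixture sds must be > 0")
        if self.positivity_direction not in ("high_is_positive", "low_is_positive"):
            raise ConfigError(f"bad positivity_direction {self.positivity_direction!r}")


@dataclasses.dataclass
class SimulationConfig:
    """Knobs for :func:`simulate_cohort`.

    ``cohorts`` maps cohort name -> (n_controls, n_cases).  Planted effects
    are expressed in units of the per-analyte residual SD on the log scale,
    so that after z-score normalization the estimated status coefficient is
    (approximately) the planted value.
    """

    cohorts: dict = dataclasses.field(default_factory=lambda: {"K1": (600, 400)})
    n_analytes: int = 1000
    fraction_nonnull: float = 0.05
    effect_size_sd_units: float = 0.4      # magnitude; signs alternate
    effect_sizes: np.ndarray | None = None  # explicit per-planted-analyte signed effects
    planted_effects: pd.Series | None = None  # full per-analyte truth; shares ids across stages
    age_mean: float = 72.0
    age_sd: float = 8.0
    case_age_shift: float = 0.0
    female_prop: float = 0.55
    n_plates: int = 4
    plate_scale_sd: float = 0.05           # SD of log per-(analyte, plate) scale factor
    lod_quantile: float = 0.0              # quantile of null log-abundance used as LOD
    missing_rate: float = 0.0
    analyte_log_sd: float = 0.1            # residual SD on the natural-log scale (keeps raw CV < 0.15)
    age_effect_sd: float = 0.05            # SD-units per SD of age, per analyte
    sex_effect_sd: float = 0.05
    biomarkers: dict = dataclasses.field(default_factory=dict)  # column -> MixtureSpec
    p_biomarker_pos_case: float = 0.8
    p_biomarker_pos_control: float = 0.25
    baseline_hazard: float = 0.03          # per-year conversion hazard for controls
    hazard_analytes: tuple = ()            # analyte ids whose z-value enters the log-hazard
    hazard_coefs: tuple = ()
    followup_mean_years: float = 6.0
    followup_max_years: float = 15.0
    slope_mean: dict = dataclasses.field(
        default_factory=lambda: {"negative": 0.1, "positive": 1.2}
    )
    slope_noise_sd: float = 0.15
    visits_per_year: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.fraction_nonnull <= 1.0:
            raise ConfigError("fraction_nonnull must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ConfigError("lod_quantile must be in [0, 1)")
        for field in ("age_sd", "analyte_log_sd"):
            if getattr(self, field) <= 0:
                raise ConfigError(f"{field} must be > 0")
        if self.n_plates < 1 or self.n_analytes < 1:
            raise ConfigError("n_plates and n_analytes must be >= 1")
        if len(self.hazard_analytes) != len(self.hazard_coefs):
            raise ConfigError("hazard_analytes and hazard_coefs differ in length")
        for spec in self.biomarkers.values():
            spec.validate()


@dataclasses.dataclass
class TruthRecord:
    """Ground truth accompanying one simulated study."""

    planted_effect: pd.Series      # per analyte, SD units; exactly 0 for nulls
    subjects: pd.DataFrame         # latent_group, converter, conversion_time, event,
    #                                followup, biomarker components, true slope


@dataclasses.dataclass
class SimulatedStudy:
    matrix: ProteomicsMatrix
    samples: pd.DataFrame
    cdr_visits: pd.DataFrame
    truth: TruthRecord


def _planted_effects(config: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    if config.planted_effects is not None:
        truth = config.planted_effects.astype(float)
        config.n_analytes = len(truth)
        return truth.rename("planted_effect")
    analyte_ids = [f"A{i:05d}" for i in range(1, config.n_analytes + 1)]
    effects = np.zeros(config.n_analytes)
    n_nonnull = int(round(config.fraction_nonnull * config.n_analytes))
    if n_nonnull:
        idx = rng.choice(config.n_analytes, size=n_nonnull, replace=False)
        if config.effect_sizes is not None:
            vals = np.asarray(config.effect_sizes, dtype=float)
            if len(vals) != n_nonnull:
                raise ConfigError(
                    f"effect_sizes has {len(vals)} entries but {n_nonnull} analytes planted"
                )
        else:
            signs = np.where(np.arange(n_nonnull) % 2 == 0, 1.0, -1.0)
            vals = signs * config.effect_size_sd_units
        effects[np.sort(idx)] = vals
    return pd.Series(effects, index=analyte_ids, name="planted_effect")


def simulate_cohort(config: SimulationConfig) -> SimulatedStudy:
    """Generate one study (matrix + metadata + CDR visits) with ground truth.

    Log-abundance model per subject i, analyte j on plate p:

        log y_ij = b_j + log sf_jp + sigma_j * (beta_j s_i + a_j age*_i + c_j f_i + e_ij)

    with s_i the AD indicator, age*_i standardized age, f_i the female
    indicator, e_ij standard normal, and beta_j the planted effect in SD
    units.  Values below the per-(analyte, plate) LOD (the ``lod_quantile``
    of the null distribution) are censored to missing.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    effects = _planted_effects(config, rng)
    analyte_ids = list(effects.index)
    m = config.n_analytes

    rows = []
    for cohort, (n_co, n_ad) in config.cohorts.items():
        for status, n in (("CO", n_co), ("AD", n_ad)):
            for _ in range(n):
                rows.append((cohort, status))
    n_total = len(rows)
    sample_ids = [f"S{i:05d}" for i in range(1, n_total + 1)]
    cohort_arr = np.array([r[0] for r in rows])
    status_arr = np.array([r[1] for r in rows])
    is_ad = (status_arr == "AD").astype(float)

    age = rng.normal(config.age_mean, config.age_sd, n_total)
    age = age + config.case_age_shift * is_ad
    age = np.clip(age, 30.0, 105.0)
    female = rng.random(n_total) < config.female_prop
    sex = np.where(female, "female", "male")
    plates = np.array([f"P{p + 1}" for p in rng.integers(0, config.n_plates, n_total)])
    plate_labels = [f"P{p + 1}" for p in range(config.n_plates)]

    base = rng.normal(np.log(1000.0), 1.0, m)
    sigma = np.full(m, config.analyte_log_sd)
    age_coef = rng.normal(0.0, config.age_effect_sd, m)
    sex_coef = rng.normal(0.0, config.sex_effect_sd, m)
    log_sf = rng.normal(0.0, config.plate_scale_sd, (m, config.n_plates))
    sf = pd.DataFrame(np.exp(log_sf), index=analyte_ids, columns=plate_labels)

    age_std = (age - config.age_mean) / config.age_sd
    linpred = (
        np.outer(age_std, age_coef)
        + np.outer(female.astype(float), sex_coef)
        + rng.standard_normal((n_total, m))
    )
    # planted effects are in units of the *total* null SD (nuisance + plate +
    # residual), which is what per-cluster z-scoring standardizes away
    pf = config.female_prop
    plate_var = np.var(log_sf, axis=1)
    total_sd = np.sqrt(
        sigma**2 * (1.0 + age_coef**2 + pf * (1.0 - pf) * sex_coef**2) + plate_var
    )
    status_shift = np.outer(is_ad, effects.to_numpy() * total_sd)
    plate_idx = np.array([plate_labels.index(p) for p in plates])
    log_y = base[None, :] + log_sf.T[plate_idx, :] + status_shift + sigma[None, :] * linpred
    values = np.exp(log_y)

    # LOD: per-(analyte, plate) floor at the configured quantile of the null
    # (CO, age/sex-marginal) log-abundance distribution; sub-LOD cells are
    # censored to missing but the LOD value itself is carried for QC.
    null_sd = sigma * np.sqrt(1.0 + config.age_effect_sd**2 + 0.25 * config.sex_effect_sd**2)
    if config.lod_quantile > 0:
        z_q = stats.norm.ppf(config.lod_quantile)
        log_lod = base[:, None] + log_sf + (null_sd * z_q)[:, None]
    else:
        log_lod = np.full((m, config.n_plates), -np.inf)
    lod = pd.DataFrame(
        np.where(np.isfinite(log_lod), np.exp(log_lod), 0.0),
        index=analyte_ids,
        columns=plate_labels,
    )
    below = values < lod.to_numpy().T[plate_idx, :]
    values = np.where(below, np.nan, values)
    if config.missing_rate > 0:
        values = np.where(rng.random(values.shape) < config.missing_rate, np.nan, values)

    matrix = ProteomicsMatrix(
        values=pd.DataFrame(values, index=sample_ids, columns=analyte_ids),
        plate_of_sample=pd.Series(plates, index=sample_ids, name="plate"),
        scale_factor=sf,
        lod=lod,
    )

    samples = pd.DataFrame(
        {
            "age_at_draw": age,
            "sex": sex,
            "cohort": cohort_arr,
            "dataset_cluster": cohort_arr,
            "clinical_status": status_arr,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # latent biomarker positivity: enriched among cases
    p_pos = np.where(is_ad == 1.0, config.p_biomarker_pos_case, config.p_biomarker_pos_control)
    latent_pos = rng.random(n_total) < p_pos
    for col, spec in config.biomarkers.items():
        lo, hi = int(np.argmin(spec.means)), int(np.argmax(spec.means))
        if spec.positivity_direction == "low_is_positive":
            pos_comp, neg_comp = lo, hi
        else:
            pos_comp, neg_comp = hi, lo
        mu = np.where(latent_pos, spec.means[pos_comp], spec.means[neg_comp])
        sd_arr = np.where(latent_pos, spec.sds[pos_comp], spec.sds[neg_comp])
        samples[col] = rng.normal(mu, sd_arr)

    # conversion hazard (controls only): exponential with log-hazard linear in
    # designated analytes' latent z-values (pre-noise linear predictor)
    log_h = np.full(n_total, np.log(config.baseline_hazard))
    for aid, coef in zip(config.hazard_analytes, config.hazard_coefs):
        j = analyte_ids.index(aid)
        log_h = log_h + coef * linpred[:, j]
    conv_time = rng.exponential(1.0 / np.exp(log_h))
    followup = np.minimum(
        rng.exponential(config.followup_mean_years, n_total), config.followup_max_years
    )
    followup = np.maximum(followup, 0.5)
    is_co = is_ad == 0.0
    converter = is_co & (conv_time <= followup)
    event_time = np.where(converter, conv_time, followup)

    latent_group = np.where(is_ad == 1.0, "positive", np.where(converter, "positive", "negative"))
    slope_mu = np.array([config.slope_mean[g] for g in latent_group])
    slope = np.maximum(rng.normal(slope_mu, config.slope_noise_sd), 0.0)

    cdr_rows = []
    for i, sid in enumerate(sample_ids):
        n_visits = max(2, int(np.ceil(followup[i] * config.visits_per_year)) + 1)
        times = np.linspace(0.0, followup[i], n_visits)
        if is_ad[i] == 1.0:
            sb0 = 4.0
            sb = sb0 + slope[i] * times
            cdr_g = np.full(n_visits, 1.0)
        elif converter[i]:
            onset = conv_time[i]
            sb = np.where(times >= onset, slope[i] * (times - onset) + 0.5, 0.0)
            cdr_g = np.where(times >= onset, 0.5, 0.0)
        else:
            sb = np.zeros(n_visits)
            cdr_g = np.zeros(n_visits)
        for t, g, s in zip(times, cdr_g, sb):
            cdr_rows.append((sid, age[i] + t, float(g), float(max(s, 0.0))))
    cdr_visits = pd.DataFrame(cdr_rows, columns=["sample_id", "visit_age", "cdr_global", "cdr_sb"])

    truth_subjects = pd.DataFrame(
        {
            "latent_group": latent_group,
            "latent_biomarker_positive": latent_pos,
            "converter": converter,
            "conversion_time": np.where(is_co, conv_time, np.nan),
            "event": converter.astype(int),
            "followup": followup,
            "duration": np.where(is_co, event_time, np.nan),
            "true_slope": slope,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SimulatedStudy(
        matrix=matrix,
        samples=samples,
        cdr_visits=cdr_visits,
        truth=TruthRecord(planted_effect=effects, subjects=truth_subjects),
    )


def simulate_external_study(
    truth_effects: pd.Series,
    concordance_prob: float,
    noise_sd: float = 0.1,
    seed: int = 0,
    effect_kind: str = "mean_difference",
    analyte_ids=None,
) -> pd.DataFrame:
    """Generate an external result table whose effect signs match the internal
    truth with probability ``concordance_prob``.

    ``effect_kind="ln_hazard_ratio"`` labels the effect column accordingly;
    values are on the ln(HR) scale in that case (same sign semantics).
    """
    if not 0.0 <= concordance_prob <= 1.0:
        raise ConfigError("concordance_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if analyte_ids is None:
        analyte_ids = list(truth_effects.index)
    unknown = [a for a in analyte_ids if a not in truth_effects.index]
    if unknown:
        raise KeyError(f"unknown analyte ids: {unknown[:5]}")
    truth = truth_effects.loc[analyte_ids].to_numpy(dtype=float)
    internal_sign = np.sign(truth)
    internal_sign[internal_sign == 0] = rng.choice([-1.0, 1.0], size=(internal_sign == 0).sum())
    concordant = rng.random(len(analyte_ids)) < concordance_prob
    sign = np.where(concordant, internal_sign, -internal_sign)
    magnitude = np.abs(truth) + np.abs(rng.normal(0.0, noise_sd, len(analyte_ids)))
    magnitude = np.maximum(magnitude, 1e-8)
    effect = sign * magnitude
    se = np.full(len(analyte_ids), max(noise_sd, 1e-8))
    p = 2.0 * stats.norm.sf(np.abs(effect) / se)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "analyte_id": analyte_ids,
            "effect": effect,
            "p": p,
            "effect_kind": effect_kind,
        }
    )
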