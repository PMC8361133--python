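"""Seeded synthetic PD cohort generator.

Generates per-patient MIBG uptake ratios, demographics, orthostatic BP
targets, questionnaire totals and a raw tilt-test series under a structural
model that mirrors the mediation paths the analysis assumes:

* delayed H/M ratio is drawn from a two-component mixture (~70% abnormal,
  component means/SDs 1.34/0.18 and 2.04/0.16); the early ratio is the
  delayed ratio plus a group-specific offset and noise, reproducing the
  positive washout of the denervated group and the negative washout of the
  preserved group;
* orthostatic delta-BP-min targets follow
  ``delta = intercept + theta_ab * (H/M - mean) + covariate terms + noise``
  with correlated systolic/diastolic residuals (shared orthostatic factor);
* a latent disease burden follows
  ``L = theta_ac * (H/M - mean) + theta_bc * (delta_sbp_min - mean)
  + covariate terms + noise`` and each questionnaire total is a clamped,
  rounded affine function of the standardized burden;
* a tilt series is constructed to realize the rounded BP targets exactly,
  so the tilt classifier round-trips the generator (same deltas, same
  SH/OH/OHT flags).

Path defaults are the published point estimates (a->b -11.665 mmHg per H/M
unit for SBP, -5.270 for DBP; b->c 0.002 burden-z per mmHg; a->c -0.441
burden-z per H/M unit); marginal means and SDs default to the cohort table
of the source study.  Group labels for analysis are always re-derived from
the sampled delayed H/M via the cutoff (1.78), never taken from the mixture
component, because the components overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .tilt import TiltTestRecord

logger = logging.getLogger(__name__)

#: instrument -> (cohort mean, cohort SD, minimum total, maximum total)
INSTRUMENTS: dict[str, tuple[float, float, int, int]] = {
    "updrs_ii": (6.1, 4.1, 0, 52),
    "updrs_iii": (15.8, 8.6, 0, 108),
    "nmss": (25.0, 22.0, 0, 360),
    "madrs": (5.0, 4.8, 0, 60),
    "ess": (2.8, 3.0, 0, 24),
    "pdss2": (7.4, 6.8, 0, 60),
    "rbdsq": (3.2, 2.6, 0, 13),
    "scopa_aut": (8.1, 6.7, 0, 63),  # sexual-dysfunction items excluded
    "ohq_i": (3.5, 5.5, 0, 60),
    "ohq_ii": (3.0, 5.0, 0, 40),
}


@dataclass
class SimulationParams:
    """Structural and marginal parameters of the synthetic cohort.

    Defaults reproduce the study conditions: n = 227 early PD patients,
    69.6% with abnormal MIBG, published H/M mixture components, age
    69.6 +/- 9.2 y, disease duration 1.1 +/- 1.0 y (truncated at 0.1), and
    the published path coefficients.  Residual SDs are chosen so the
    marginal SDs of delta-BP-min (13.3 / 7.8 mmHg) and of the burden scale
    (0.7 z) match the cohort table after the structural contributions.
    """

    n_patients: int = 227
    p_abnormal: float = 0.696
    hm_abnormal_mean: float = 1.34
    hm_abnormal_sd: float = 0.18
    hm_normal_mean: float = 2.04
    hm_normal_sd: float = 0.16
    early_offset_normal: float = -0.08
    early_offset_abnormal: float = 0.07
    early_noise_sd: float = 0.08
    mibg_cutoff: float = 1.78
    # structural paths
    theta_ab_sbp: float = -11.665  # mmHg per H/M unit
    theta_ab_dbp: float = -5.270
    theta_bc: float = 0.002        # burden z per mmHg of delta-SBP-min
    theta_ac: float = -0.441       # burden z per H/M unit
    # covariates and their effects on mediator / burden
    age_mean: float = 69.6
    age_sd: float = 9.2
    duration_mean: float = 1.1
    duration_sd: float = 1.0
    duration_min: float = 0.1
    age_effect_b: float = 0.10     # mmHg per year
    duration_effect_b: float = 0.5
    age_effect_c: float = 0.005    # burden z per year
    duration_effect_c: float = 0.05
    # mediator marginals
    delta_sbp_min_mean: float = 10.6
    delta_dbp_min_mean: float = 2.8
    noise_sd_b_sbp: float = 12.0
    noise_sd_b_dbp: float = 7.3
    delta_corr: float = 0.6
    gap_sbp_mean: float = 9.7
    gap_sbp_sd: float = 6.0
    gap_dbp_mean: float = 7.1
    gap_dbp_sd: float = 5.0
    # burden and questionnaires
    noise_sd_burden: float = 0.65
    questionnaire_loading: float = 0.6
    # supine BP
    supine_sbp_mean: float = 124.1
    supine_sbp_sd: float = 16.5
    supine_dbp_mean: float = 71.0
    supine_dbp_sd: float = 9.1
    supine_corr: float = 0.5
    # demographics
    p_female: float = 0.463
    bmi_mean: float = 23.7
    bmi_sd: float = 3.1
    seed: int | None = None

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name in ("p_abnormal", "p_female"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name, v in asdict(self).items():
            if name.endswith("_sd") and v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if not -1 < self.delta_corr < 1 or not -1 < self.supine_corr < 1:
            raise ValueError("correlations must be in (-1, 1)")

    @property
    def hm_mixture_mean(self) -> float:
        return (self.p_abnormal * self.hm_abnormal_mean
                + (1 - self.p_abnormal) * self.hm_normal_mean)


def construct_tilt_series(
    patient_id: str,
    supine_sbp: int,
    supine_dbp: int,
    delta_sbp_min: int,
    delta_dbp_min: int,
    delta_sbp_max: int,
    delta_dbp_max: int,
    rng: np.random.Generator | None = None,
) -> TiltTestRecord:
    """Build a tilt series that the classifier maps back to these targets.

    Four supine measurements average exactly to the supine target; the
    3-min tilted measurement carries both channel minima, the 20-min one
    both maxima, and the 5/10/15-min values lie between the extremes (so
    pool minima/maxima are untouched).  Targets must be integers with
    ``delta_min >= delta_max`` per channel; infeasible targets (implied BP
    outside (0, 300) or diastolic not below systolic) are hard errors.
    """
    tgt = dict(
        supine_sbp=supine_sbp, supine_dbp=supine_dbp,
        delta_sbp_min=delta_sbp_min, delta_dbp_min=delta_dbp_min,
        delta_sbp_max=delta_sbp_max, delta_dbp_max=delta_dbp_max,
    )
    for k, v in tgt.items():
        if float(v) != int(v):
            raise ValueError(f"{k} must be an integer mmHg target, got {v}")
        tgt[k] = int(v)
    S, D = tgt["supine_sbp"], tgt["supine_dbp"]
    if tgt["delta_sbp_min"] < tgt["delta_sbp_max"] or tgt["delta_dbp_min"] < tgt["delta_dbp_max"]:
        raise ValueError(
            f"patient {patient_id}: delta_min must be >= delta_max per channel, got {tgt}"
        )
    s_lo, s_hi = S - tgt["delta_sbp_min"], S - tgt["delta_sbp_max"]
    d_lo, d_hi = D - tgt["delta_dbp_min"], D - tgt["delta_dbp_max"]
    supine = {0: (S + 4, D + 3), 5: (S + 2, D + 2), 10: (S - 2, D - 2),
              15: (S + 1, D + 1), 20: (S - 1, D - 1)}
    if d_hi >= s_lo:
        raise ValueError(
            f"patient {patient_id}: infeasible targets, tilted DBP ceiling {d_hi} "
            f"reaches SBP floor {s_lo}"
        )

    def interior(lo: int, hi: int) -> int:
        if hi - lo < 2:
            return lo
        if rng is None:
            return (lo + hi) // 2
        return int(rng.integers(lo + 1, hi))

    tilted = {
        0: (S, D),
        3: (s_lo, d_lo),
        5: (interior(s_lo, s_hi), interior(d_lo, d_hi)),
        10: (interior(s_lo, s_hi), interior(d_lo, d_hi)),
        15: (interior(s_lo, s_hi), interior(d_lo, d_hi)),
        20: (s_hi, d_hi),
    }
    for t, (sbp, dbp) in list(supine.items()) + list(tilted.items()):
        if not 0 < dbp < sbp < 300:
            raise ValueError(
                f"patient {patient_id}: infeasible targets imply BP {sbp}/{dbp} "
                f"at {t} min"
            )
    return TiltTestRecord(patient_id, supine, tilted)


def _correlated_normal(rng, n, sd1, sd2, corr):
    z = rng.standard_normal((n, 2))
    e1 = z[:, 0] * sd1
    e2 = (corr * z[:, 0] + np.sqrt(1 - corr**2) * z[:, 1]) * sd2
    return e1, e2


def generate_cohort(
    params: SimulationParams | None = None,
    seed: int | None = None,
    include_tilt: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Generate a cohort table and (optionally) its long tilt-test table.

    Identical ``seed`` (argument wins over ``params.seed``) gives identical
    output.  The cohort table carries the generator's realized BP targets
    in ``*_target`` columns; the classifier reproduces them exactly from
    the tilt table.  ``include_tilt=False`` skips series construction for
    statistics-only workloads.
    """
    params = params or SimulationParams()
    params.validate()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    n = params.n_patients

    abnormal = rng.random(n) < params.p_abnormal
    delayed = np.where(
        abnormal,
        rng.normal(params.hm_abnormal_mean, params.hm_abnormal_sd, n),
        rng.normal(params.hm_normal_mean, params.hm_normal_sd, n),
    )
    delayed = np.clip(delayed, 0.4, None)
    offset = np.where(abnormal, params.early_offset_abnormal, params.early_offset_normal)
    early = np.clip(delayed + offset + rng.normal(0, params.early_noise_sd, n), 0.4, None)

    age = rng.normal(params.age_mean, params.age_sd, n)
    duration = np.clip(
        rng.normal(params.duration_mean, params.duration_sd, n),
        params.duration_min, None,
    )
    female = rng.random(n) < params.p_female
    bmi = rng.normal(params.bmi_mean, params.bmi_sd, n)

    sup_s, sup_d = _correlated_normal(
        rng, n, params.supine_sbp_sd, params.supine_dbp_sd, params.supine_corr
    )
    sup_s = np.round(sup_s + params.supine_sbp_mean).astype(int)
    sup_d = np.round(sup_d + params.supine_dbp_mean).astype(int)
    sup_d = np.minimum(sup_d, sup_s - 15)  # keep pulse pressure physiological

    hm_c = delayed - params.hm_mixture_mean
    age_c = age - params.age_mean
    dur_c = duration - params.duration_mean
    e_s, e_d = _correlated_normal(
        rng, n, params.noise_sd_b_sbp, params.noise_sd_b_dbp, params.delta_corr
    )
    d_s = (params.delta_sbp_min_mean + params.theta_ab_sbp * hm_c
           + params.age_effect_b * age_c + params.duration_effect_b * dur_c + e_s)
    d_d = (params.delta_dbp_min_mean + params.theta_ab_dbp * hm_c
           + 0.6 * (params.age_effect_b * age_c + params.duration_effect_b * dur_c)
           + e_d)
    gap_s = np.abs(rng.normal(params.gap_sbp_mean, params.gap_sbp_sd, n))
    gap_d = np.abs(rng.normal(params.gap_dbp_mean, params.gap_dbp_sd, n))
    ds_max = d_s - gap_s
    dd_max = d_d - gap_d

    d_s = np.round(d_s).astype(int)
    d_d = np.round(d_d).astype(int)
    ds_max = np.round(ds_max).astype(int)
    dd_max = np.round(dd_max).astype(int)

    # feasibility repairs (rare tails); counted for diagnostics
    before = np.stack([d_s, d_d, ds_max, dd_max])
    # tilted SBP values must land in [40, 280]
    d_s = np.clip(d_s, sup_s - 280, sup_s - 40)
    ds_max = np.clip(ds_max, sup_s - 280, sup_s - 40)
    # tilted DBP values must stay >= 25
    d_d = np.minimum(d_d, sup_d - 25)
    dd_max = np.minimum(dd_max, sup_d - 25)
    # tilted DBP ceiling must stay below the tilted SBP floor
    dd_max = np.maximum(dd_max, sup_d - (sup_s - d_s - 5))
    # restore per-channel ordering delta_min >= delta_max
    d_s = np.maximum(d_s, ds_max)
    d_d = np.maximum(d_d, dd_max)
    repairs = int(np.sum(before != np.stack([d_s, d_d, ds_max, dd_max])))
    if repairs:
        logger.info("feasibility-repaired %d delta targets across %d patients",
                    repairs, n)

    latent = (params.theta_ac * hm_c
              + params.theta_bc * (d_s - d_s.mean())
              + params.age_effect_c * age_c + params.duration_effect_c * dur_c
              + rng.normal(0, params.noise_sd_burden, n))

    lz = (latent - latent.mean()) / latent.std(ddof=1)
    lam = params.questionnaire_loading
    cohort = {
        "patient_id": [f"P{i + 1:05d}" for i in range(n)],
        "age": np.round(age, 1),
        "duration": np.round(duration, 1),
        "sex_female": female.astype(int),
        "bmi": np.round(bmi, 1),
        "early_hm": np.round(early, 2),
        "delayed_hm": np.round(delayed, 2),
        "latent_burden": latent,
        "supine_sbp_target": sup_s,
        "supine_dbp_target": sup_d,
        "delta_sbp_min_target": d_s,
        "delta_dbp_min_target": d_d,
        "delta_sbp_max_target": ds_max,
        "delta_dbp_max_target": dd_max,
    }
    clamped = 0
    for name, (mu, sd, lo, hi) in INSTRUMENTS.items():
        raw = mu + sd * (lam * lz + np.sqrt(1 - lam**2) * rng.standard_normal(n))
        clipped = np.clip(raw, lo, hi)
        clamped += int(np.sum(clipped != raw))
        cohort[name] = np.round(clipped).astype(int)
    if clamped:
        logger.info("clamped %d questionnaire draws to instrument ranges (%.1f%%)",
                    clamped, 100 * clamped / (n * len(INSTRUMENTS)))
    # descriptive-only scales
    cohort["updrs_i"] = np.round(np.clip(rng.normal(1.6, 1.4, n), 0, 16)).astype(int)
    cohort["hy_stage"] = rng.choice(
        [1, 2, 3, 4], size=n, p=[0.242, 0.643, 0.111, 0.004]
    )
    cohort["mmse"] = np.round(np.clip(rng.normal(26.8, 3.0, n), 0, 30)).astype(int)
    cohort["cdr"] = rng.choice([0.0, 0.5, 1.0], size=n, p=[0.2, 0.7, 0.1])
    cohort_df = pd.DataFrame(cohort)

    tilt_df = None
    if include_tilt:
        rows = []
        for i in range(n):
            rec = construct_tilt_series(
                cohort_df["patient_id"].iat[i],
                int(sup_s[i]), int(sup_d[i]),
                int(d_s[i]), int(d_d[i]), int(ds_max[i]), int(dd_max[i]),
                rng=rng,
            )
            for phase, series in (("supine", rec.supine), ("tilt", rec.tilted)):
                for t, (sbp, dbp) in sorted(series.items()):
                    rows.append((rec.patient_id, phase, t, int(sbp), int(dbp)))
        tilt_df = pd.DataFrame(
            rows, columns=["patient_id", "phase", "time_min", "sbp", "dbp"]
        )
    return cohort_df, tilt_df


class CohortSimulator:
    """Thin object wrapper bundling :class:`SimulationParams` with a seed."""

    def __init__(self, params: SimulationParams | None = None):
        self.params = params or SimulationParams()

    def generate(self, seed: int | None = None, include_tilt: bool = True):
        return generate_cohort(self.params, seed=seed, include_tilt=include_tilt)
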