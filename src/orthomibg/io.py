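"""CSV readers/writers, pipeline configuration and the end-to-end driver.

The pipeline sequence mirrors the analysis order: tilt classification ->
MIBG metrics -> composite scores -> two-group comparison table ->
mediation models (every configured predictor x mediator x outcome
combination).  All randomness flows from one top-level seed; per-model
substreams are derived deterministically, so two runs with identical
config and inputs produce identical report bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .composites import GLOBAL_DEFAULT, CompositeScorer
from .mediation import MediationModel
from .mibg import DEFAULT_CUTOFF, MibgScorer
from .stats import compare_groups
from .tilt import TiltProfiler, TiltTestRecord, ValidationError, records_from_long

logger = logging.getLogger(__name__)

TILT_COLUMNS = ("patient_id", "phase", "time_min", "sbp", "dbp")

DEFAULT_COMPARE_VARS = (
    "age", "duration", "sex_female", "bmi",
    "updrs_ii", "updrs_iii", "mmse",
    "early_hm", "delayed_hm", "washout_rate",
    "delta_sbp_min", "delta_dbp_min", "delta_sbp_max", "delta_dbp_max",
    "sh", "oh", "oht",
    "nmss", "madrs", "ess", "pdss2", "rbdsq", "scopa_aut", "ohq_i", "ohq_ii",
    "global_z", "motor_z", "sleep_z", "autonomic_z",
)


def read_cohort(path, required: tuple[str, ...] = ("patient_id",)) -> pd.DataFrame:
    """Read the per-patient cohort CSV, checking the required header."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"cohort file {path} missing required column(s): {missing}; "
            f"found {list(df.columns)}"
        )
    return df


def read_tilt(path) -> tuple[pd.DataFrame, list[TiltTestRecord]]:
    """Read the long tilt-test CSV and validate it into records.

    Non-numeric BP entries are reported with their (1-based, header
    included) line numbers.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in TILT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"tilt file {path} missing required column(s): {missing}"
        )
    for col in ("time_min", "sbp", "dbp"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()
            raise ValidationError(
                f"tilt file {path}: non-numeric '{col}' value(s) at line(s) {lines}"
            )
        df[col] = coerced
    return df, records_from_long(df)


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Paths, thresholds and model grid for one pipeline run."""

    cohort_path: str = "cohort.csv"
    tilt_path: str = "tilt_long.csv"
    out_dir: str = "results"
    mibg_cutoff: float = DEFAULT_CUTOFF
    sh_cutoffs: tuple[float, float] = (140.0, 90.0)
    oh_thresholds: tuple[float, float] = (20.0, 10.0)
    oh_sh_thresholds: tuple[float, float] = (30.0, 15.0)
    oht_rise_thresholds: tuple[float, float] = (20.0, 10.0)
    global_instruments: tuple[str, ...] = GLOBAL_DEFAULT
    predictors: tuple[str, ...] = ("delayed_hm", "early_hm", "washout_rate")
    mediators: tuple[str, ...] = ("delta_sbp_min", "delta_dbp_min")
    outcomes: tuple[str, ...] = ("global_z", "motor_z", "sleep_z", "autonomic_z")
    covariates: tuple[str, ...] = ("age", "duration")
    compare_vars: tuple[str, ...] = DEFAULT_COMPARE_VARS
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mibg_cutoff <= 0:
            raise ValidationError("mibg_cutoff must be positive")
        for name in ("sh_cutoffs", "oh_thresholds", "oh_sh_thresholds",
                     "oht_rise_thresholds"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValidationError(f"{name} must be positive")


def _round_effects(report: dict, ndigits: int = 3) -> dict:
    out = json.loads(json.dumps(report))
    for model in out:
        for eff in model["effects"].values():
            for k, v in eff.items():
                if isinstance(v, float):
                    eff[k] = round(v, ndigits)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle to ``out_dir``.

    Returns the in-memory bundle: scored cohort, orthostatic profiles, the
    two-group comparison table and a list of mediation reports.
    """
    config.validate()
    logging.getLogger("orthomibg").setLevel(config.log_level.upper())
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort(config.cohort_path)
    if cohort.empty:
        raise ValidationError(f"cohort file {config.cohort_path} has no rows")
    tilt_df, records = read_tilt(config.tilt_path)

    profiler = TiltProfiler(
        sh_cutoffs=config.sh_cutoffs,
        oh_thresholds=config.oh_thresholds,
        oh_sh_thresholds=config.oh_sh_thresholds,
        oht_rise_thresholds=config.oht_rise_thresholds,
    )
    profiles = profiler.fit().transform(records)
    scored = cohort.merge(profiles, on="patient_id", how="inner", validate="1:1")
    scored = MibgScorer(cutoff=config.mibg_cutoff).fit_transform(scored)
    scorer = CompositeScorer(global_instruments=config.global_instruments)
    scored = scorer.fit(scored).transform(scored)
    for flag in ("sh", "oh", "oht"):
        scored[flag] = scored[flag].astype(int)

    compare_vars = [v for v in config.compare_vars if v in scored.columns]
    table1 = compare_groups(scored, "mibg_class", compare_vars)

    reports = []
    for idx, (outcome, mediator, predictor) in enumerate(
        (o, m, p)
        for o in config.outcomes
        for m in config.mediators
        for p in config.predictors
    ):
        model = MediationModel(
            predictor=predictor, mediator=mediator, outcome=outcome,
            covariates=config.covariates, n_boot=config.n_boot,
            ci_level=config.ci_level,
            random_state=int(np.random.SeedSequence([config.seed, idx])
                             .generate_state(1)[0] % (2**31)),
        )
        model.fit(scored)
        reports.append(model.result_.to_dict())
        logger.info("mediation %s ~ %s via %s done", outcome, predictor, mediator)

    write_profiles(profiles, out_dir / "profiles.csv")
    scored.to_csv(out_dir / "cohort_scored.csv", index=False)
    table1.to_csv(out_dir / "table1.csv", index=False)
    with open(out_dir / "mediation.json", "w") as fh:
        json.dump(_round_effects(reports), fh, indent=2)
    run_log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "n_patients": int(len(scored)),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    return {
        "cohort": scored,
        "profiles": profiles,
        "table1": table1,
        "mediation": reports,
        "run_log": run_log,
    }
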