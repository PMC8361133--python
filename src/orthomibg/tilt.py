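"""Head-up tilt-test blood-pressure profiling.

A patient lies supine for 20 min with brachial BP read every 5 min, then is
tilted to 60 degrees with readings at 0, 3, 5, 10, 15 and 20 min.  From that
series this module derives

* the average supine BP (5/10/15/20-min readings; the 0-min reading is
  discarded as an accommodation artifact),
* orthostatic BP changes ``delta = supine average - tilted value``, where a
  positive delta is a drop on standing,
* three binary phenotypes:

  - **SH** (supine hypertension): average supine BP >= 140/90 mmHg,
  - **OH** (orthostatic hypotension): a drop >= 20/10 mmHg (>= 30/15 under
    SH) within 5 min of tilt, i.e. over the 3/5-min pool only,
  - **OHT** (orthostatic hypertension): a rise >= 20/10 mmHg at any tilted
    time 3-20 min; for non-SH patients a tilted BP >= 140/90 also qualifies.

Systolic and diastolic extrema are selected independently per channel, so the
lowest SBP and lowest DBP may come from different time points.  All
thresholds are inclusive as written ("and/or" criteria are disjunctions).
OH and OHT are not mutually exclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

SUPINE_REQUIRED: tuple[int, ...] = (5, 10, 15, 20)
#: tilted time points eligible for the OH (minimum-BP) pool
MIN_POOL: tuple[int, ...] = (3, 5)
#: tilted time points eligible for the OHT (maximum-BP) pool
MAX_POOL: tuple[int, ...] = (3, 5, 10, 15, 20)


class ValidationError(ValueError):
    """Raised when an input series or table violates a structural contract."""


def _check_measurement(time_min: int, sbp: float, dbp: float, who: str) -> None:
    if not 0 < dbp < sbp < 300:
        raise ValidationError(
            f"{who}: implausible BP ({sbp}/{dbp}) at {time_min} min; "
            "require 0 < dbp < sbp < 300 mmHg"
        )


@dataclass(frozen=True)
class TiltTestRecord:
    """One patient's timed supine and tilted BP measurements.

    ``supine`` and ``tilted`` map time (min) to an ``(sbp, dbp)`` pair.
    Duplicate time points within a phase and physiologically impossible
    values are rejected at construction; completeness of the supine series
    and of the tilted pools is enforced by the operations that need them.
    """

    patient_id: str
    supine: Mapping[int, tuple[float, float]]
    tilted: Mapping[int, tuple[float, float]]

    def __post_init__(self) -> None:
        for phase, series in (("supine", self.supine), ("tilted", self.tilted)):
            for t, (sbp, dbp) in series.items():
                _check_measurement(t, sbp, dbp, f"patient {self.patient_id} ({phase})")
        if not any(t in self.tilted for t in MIN_POOL):
            raise ValidationError(
                f"patient {self.patient_id}: no tilted measurement at 3 or 5 min"
            )

    @classmethod
    def from_rows(
        cls,
        patient_id: str,
        supine_rows: Iterable[tuple[int, float, float]],
        tilted_rows: Iterable[tuple[int, float, float]],
    ) -> "TiltTestRecord":
        """Build a record from ``(time_min, sbp, dbp)`` rows, rejecting duplicates."""
        phases = {}
        for name, rows in (("supine", supine_rows), ("tilted", tilted_rows)):
            series: dict[int, tuple[float, float]] = {}
            for t, sbp, dbp in rows:
                t = int(t)
                if t in series:
                    raise ValidationError(
                        f"patient {patient_id}: duplicate {name} time point {t} min"
                    )
                series[t] = (float(sbp), float(dbp))
            phases[name] = series
        return cls(patient_id, phases["supine"], phases["tilted"])


@dataclass(frozen=True)
class OrthostaticProfile:
    """Derived orthostatic quantities and phenotype flags for one patient.

    Deltas follow the drop-positive sign convention; ``delta_*_min`` comes
    from the 3/5-min pool, ``delta_*_max`` from the 3-20-min pool, so
    ``delta_*_min >= delta_*_max`` always holds.
    """

    patient_id: str
    supine_avg_sbp: float
    supine_avg_dbp: float
    delta_sbp_min: float
    delta_dbp_min: float
    delta_sbp_max: float
    delta_dbp_max: float
    sh: bool
    oh: bool
    oht: bool

    FIELDS = (
        "supine_avg_sbp", "supine_avg_dbp",
        "delta_sbp_min", "delta_dbp_min", "delta_sbp_max", "delta_dbp_max",
        "sh", "oh", "oht",
    )


def supine_average(record: TiltTestRecord) -> tuple[float, float]:
    """Average supine SBP/DBP over the 5, 10, 15 and 20-min readings.

    The 0-min supine reading, if present, is ignored.  Missing any of the
    four required time points is a hard error naming the missing points.
    """
    missing = [t for t in SUPINE_REQUIRED if t not in record.supine]
    if missing:
        raise ValidationError(
            f"patient {record.patient_id}: missing supine measurement(s) at "
            f"{missing} min (need all of {list(SUPINE_REQUIRED)})"
        )
    sbp = sum(record.supine[t][0] for t in SUPINE_REQUIRED) / len(SUPINE_REQUIRED)
    dbp = sum(record.supine[t][1] for t in SUPINE_REQUIRED) / len(SUPINE_REQUIRED)
    return sbp, dbp


def classify_sh(
    supine_avg_sbp: float,
    supine_avg_dbp: float,
    *,
    sbp_cutoff: float = 140.0,
    dbp_cutoff: float = 90.0,
) -> bool:
    """Supine hypertension: average supine SBP >= 140 or DBP >= 90 mmHg."""
    return supine_avg_sbp >= sbp_cutoff or supine_avg_dbp >= dbp_cutoff


def _pool_values(record: TiltTestRecord, pool: tuple[int, ...], label: str):
    times = [t for t in pool if t in record.tilted]
    if not times:
        raise ValidationError(
            f"patient {record.patient_id}: no tilted measurement in the "
            f"{label} pool {list(pool)}"
        )
    if len(times) < len(pool):
        logger.warning(
            "patient %s: %s pool incomplete, using available time points %s",
            record.patient_id, label, times,
        )
    sbps = [record.tilted[t][0] for t in times]
    dbps = [record.tilted[t][1] for t in times]
    return sbps, dbps


def delta_min(
    record: TiltTestRecord, supine_avg: tuple[float, float]
) -> tuple[float, float]:
    """Drop to the lowest tilted BP at 3 or 5 min, per channel.

    ``delta = supine average - pool minimum``; positive means the BP fell.
    """
    sbps, dbps = _pool_values(record, MIN_POOL, "early (OH)")
    return supine_avg[0] - min(sbps), supine_avg[1] - min(dbps)


def classify_oh(
    delta_sbp_min: float,
    delta_dbp_min: float,
    sh: bool,
    *,
    thresholds: tuple[float, float] = (20.0, 10.0),
    sh_thresholds: tuple[float, float] = (30.0, 15.0),
) -> bool:
    """Orthostatic hypotension from the early-pool drop.

    A drop of >= 20/10 mmHg qualifies; under supine hypertension the cutoffs
    rise to >= 30/15 mmHg.  Systolic and diastolic arms are a disjunction.
    """
    s_cut, d_cut = sh_thresholds if sh else thresholds
    return delta_sbp_min >= s_cut or delta_dbp_min >= d_cut


def delta_max(
    record: TiltTestRecord, supine_avg: tuple[float, float]
) -> tuple[float, float]:
    """Change to the highest tilted BP over 3-20 min, per channel.

    Negative values indicate a rise above the supine average.  The tilted
    0-min reading is excluded from the pool.
    """
    sbps, dbps = _pool_values(record, MAX_POOL, "full (OHT)")
    return supine_avg[0] - max(sbps), supine_avg[1] - max(dbps)


def classify_oht(
    delta_sbp_max: float,
    delta_dbp_max: float,
    highest_tilted_sbp: float,
    highest_tilted_dbp: float,
    sh: bool,
    *,
    rise_thresholds: tuple[float, float] = (20.0, 10.0),
    bp_cutoffs: tuple[float, float] = (140.0, 90.0),
) -> bool:
    """Orthostatic hypertension from the full-pool maxima.

    A rise of >= 20/10 mmHg (delta <= -20/-10) qualifies for everyone; a
    patient without supine hypertension also qualifies when the highest
    tilted BP reaches 140/90 mmHg.
    """
    rise = (delta_sbp_max <= -rise_thresholds[0]) or (
        delta_dbp_max <= -rise_thresholds[1]
    )
    if sh:
        return rise
    return rise or highest_tilted_sbp >= bp_cutoffs[0] or highest_tilted_dbp >= bp_cutoffs[1]


def profile(record: TiltTestRecord, **thresholds) -> OrthostaticProfile:
    """Full orthostatic profile: supine averages, four deltas, SH/OH/OHT.

    Keyword thresholds are forwarded to the three classifiers (``sbp_cutoff``,
    ``dbp_cutoff``, ``oh_thresholds``, ``oh_sh_thresholds``,
    ``oht_rise_thresholds``, ``oht_bp_cutoffs``).
    """
    try:
        avg = supine_average(record)
        sh = classify_sh(
            *avg,
            sbp_cutoff=thresholds.get("sbp_cutoff", 140.0),
            dbp_cutoff=thresholds.get("dbp_cutoff", 90.0),
        )
        d_min = delta_min(record, avg)
        d_max = delta_max(record, avg)
        oh = classify_oh(
            *d_min,
            sh,
            thresholds=thresholds.get("oh_thresholds", (20.0, 10.0)),
            sh_thresholds=thresholds.get("oh_sh_thresholds", (30.0, 15.0)),
        )
        oht = classify_oht(
            *d_max,
            avg[0] - d_max[0],
            avg[1] - d_max[1],
            sh,
            rise_thresholds=thresholds.get("oht_rise_thresholds", (20.0, 10.0)),
            bp_cutoffs=thresholds.get("oht_bp_cutoffs", (140.0, 90.0)),
        )
    except ValidationError:
        raise
    except Exception as exc:  # pragma: no cover - defensive context wrapper
        raise ValidationError(f"patient {record.patient_id}: {exc}") from exc
    return OrthostaticProfile(
        patient_id=record.patient_id,
        supine_avg_sbp=avg[0],
        supine_avg_dbp=avg[1],
        delta_sbp_min=d_min[0],
        delta_dbp_min=d_min[1],
        delta_sbp_max=d_max[0],
        delta_dbp_max=d_max[1],
        sh=sh,
        oh=oh,
        oht=oht,
    )


def records_from_long(df: pd.DataFrame) -> list[TiltTestRecord]:
    """Build records from a long table (patient_id, phase, time_min, sbp, dbp)."""
    required = {"patient_id", "phase", "time_min", "sbp", "dbp"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"tilt table missing column(s): {sorted(missing)}")
    bad_phase = set(df["phase"].unique()) - {"supine", "tilt"}
    if bad_phase:
        raise ValidationError(f"tilt table has unknown phase value(s): {sorted(bad_phase)}")
    dup = df.duplicated(subset=["patient_id", "phase", "time_min"], keep=False)
    if dup.any():
        key = df.loc[dup, ["patient_id", "phase", "time_min"]].iloc[0]
        raise ValidationError(
            "duplicate tilt measurement for key "
            f"(patient_id={key['patient_id']}, phase={key['phase']}, "
            f"time_min={key['time_min']})"
        )
    records = []
    for pid, g in df.groupby("patient_id", sort=False):
        sup = g[g["phase"] == "supine"]
        til = g[g["phase"] == "tilt"]
        records.append(
            TiltTestRecord.from_rows(
                str(pid),
                zip(sup["time_min"], sup["sbp"], sup["dbp"]),
                zip(til["time_min"], til["sbp"], til["dbp"]),
            )
        )
    return records


class TiltProfiler(TransformerMixin, BaseEstimator):
    """Transformer from a long tilt-test table to per-patient profiles.

    Stateless: :meth:`fit` only validates parameters.  :meth:`transform`
    accepts either a long DataFrame (patient_id, phase, time_min, sbp, dbp)
    or an iterable of :class:`TiltTestRecord` and returns one row per patient
    with the nine :class:`OrthostaticProfile` fields.

    Parameters mirror the published thresholds and default to them:
    SH >= 140/90, OH >= 20/10 (30/15 under SH), OHT rise >= 20/10 with the
    140/90 tilted-BP arm for non-SH patients.
    """

    def __init__(
        self,
        sh_cutoffs: tuple[float, float] = (140.0, 90.0),
        oh_thresholds: tuple[float, float] = (20.0, 10.0),
        oh_sh_thresholds: tuple[float, float] = (30.0, 15.0),
        oht_rise_thresholds: tuple[float, float] = (20.0, 10.0),
        oht_bp_cutoffs: tuple[float, float] = (140.0, 90.0),
    ):
        self.sh_cutoffs = sh_cutoffs
        self.oh_thresholds = oh_thresholds
        self.oh_sh_thresholds = oh_sh_thresholds
        self.oht_rise_thresholds = oht_rise_thresholds
        self.oht_bp_cutoffs = oht_bp_cutoffs

    def fit(self, X=None, y=None):
        for name in ("sh_cutoffs", "oh_thresholds", "oh_sh_thresholds",
                     "oht_rise_thresholds", "oht_bp_cutoffs"):
            pair = getattr(self, name)
            if len(pair) != 2 or any(v <= 0 for v in pair):
                raise ValidationError(f"{name} must be a pair of positive thresholds")
        return self

    def transform(self, X) -> pd.DataFrame:
        self.fit()
        records = records_from_long(X) if isinstance(X, pd.DataFrame) else list(X)
        rows = []
        for rec in records:
            prof = profile(
                rec,
                sbp_cutoff=self.sh_cutoffs[0],
                dbp_cutoff=self.sh_cutoffs[1],
                oh_thresholds=self.oh_thresholds,
                oh_sh_thresholds=self.oh_sh_thresholds,
                oht_rise_thresholds=self.oht_rise_thresholds,
                oht_bp_cutoffs=self.oht_bp_cutoffs,
            )
            rows.append(
                {"patient_id": prof.patient_id,
                 **{f: getattr(prof, f) for f in OrthostaticProfile.FIELDS}}
            )
        return pd.DataFrame(rows)
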