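"""Composite severity z-scores from questionnaire totals.

Each instrument total is standardized to a cohort z-score (sample SD,
denominator n-1), then composites are unweighted means of component z's:

* motor     = mean(z(UPDRS II), z(UPDRS III))
* sleep     = mean(z(ESS), z(PDSS-2), z(RBDSQ))
* autonomic = mean(z(OHQ I), z(OHQ II), z(SCOPA-AUT))
* global    = mean over the configured instrument set (default: the two
  motor scales plus NMSS, MADRS, ESS, PDSS-2, RBDSQ, SCOPA-AUT and the two
  OHQ parts)

Higher z means worse severity on every instrument, so higher composites
mean worse burden.  The OHQ parts are scored separately by default
(``ohq_combined=True`` collapses them into a single z of the summed total).
A patient's composite is the mean of their available component z's when at
least half are present, else missing.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

MOTOR_INSTRUMENTS = ("updrs_ii", "updrs_iii")
SLEEP_INSTRUMENTS = ("ess", "pdss2", "rbdsq")
AUTONOMIC_INSTRUMENTS = ("ohq_i", "ohq_ii", "scopa_aut")
GLOBAL_DEFAULT = (
    "updrs_ii", "updrs_iii",
    "nmss", "madrs", "ess", "pdss2", "rbdsq", "scopa_aut", "ohq_i", "ohq_ii",
)


def zscore_column(values, ddof: int = 1, name: str | None = None) -> np.ndarray:
    """Standardize one instrument column to mean 0, sample SD 1.

    NaNs are ignored for the mean/SD and propagated in the output.  Zero
    variance (or fewer than two observed values) is a hard error naming the
    instrument.
    """
    x = np.asarray(values, dtype=float)
    label = name or "column"
    n_obs = np.sum(~np.isnan(x))
    if n_obs < 2:
        raise ValueError(f"cannot standardize {label}: fewer than 2 observed values")
    mu = np.nanmean(x)
    sd = np.nanstd(x, ddof=ddof)
    if sd <= 0 or not math.isfinite(sd):
        raise ValueError(f"cannot standardize {label}: zero variance")
    return (x - mu) / sd


class CompositeScorer(TransformerMixin, BaseEstimator):
    """Fit cohort standardization constants; transform to composite columns.

    ``fit`` learns per-instrument means and sample SDs (``means_``,
    ``sds_``) over the fitted cohort; ``transform`` appends ``motor_z``,
    ``sleep_z``, ``autonomic_z`` and ``global_z``.  Standardizing against a
    fitted cohort keeps the scorer usable inside pipelines and on held-out
    rows, though in the typical cross-sectional analysis fit and transform
    see the same table.

    Parameters
    ----------
    global_instruments : instrument columns averaged into ``global_z``.
    ohq_combined : score the OHQ as one z of (Part I + Part II) instead of
        two separate z's, in both the autonomic and global composites.
    min_fraction : minimum fraction of component z's that must be observed
        for a patient's composite; below it the composite is NaN.
    ddof : delta degrees of freedom of the SD (1 = sample SD).
    """

    def __init__(
        self,
        global_instruments: Sequence[str] = GLOBAL_DEFAULT,
        ohq_combined: bool = False,
        min_fraction: float = 0.5,
        ddof: int = 1,
    ):
        self.global_instruments = global_instruments
        self.ohq_combined = ohq_combined
        self.min_fraction = min_fraction
        self.ddof = ddof

    def _component_sets(self) -> dict[str, tuple[str, ...]]:
        def fix(cols):
            if not self.ohq_combined:
                return tuple(cols)
            out, seen_ohq = [], False
            for c in cols:
                if c in ("ohq_i", "ohq_ii"):
                    if not seen_ohq:
                        out.append("ohq_total")
                        seen_ohq = True
                else:
                    out.append(c)
            return tuple(out)

        return {
            "motor_z": MOTOR_INSTRUMENTS,
            "sleep_z": SLEEP_INSTRUMENTS,
            "autonomic_z": fix(AUTONOMIC_INSTRUMENTS),
            "global_z": fix(tuple(self.global_instruments)),
        }

    def _prepare(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.ohq_combined and "ohq_total" not in X.columns:
            X = X.copy()
            X["ohq_total"] = X["ohq_i"] + X["ohq_ii"]
        return X

    def fit(self, X: pd.DataFrame, y=None):
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        X = self._prepare(X)
        sets = self._component_sets()
        needed = sorted({c for cols in sets.values() for c in cols})
        missing = [c for c in needed if c not in X.columns]
        if missing:
            raise ValueError(f"cohort table missing instrument column(s): {missing}")
        self.instruments_ = tuple(needed)
        self.means_ = {}
        self.sds_ = {}
        for c in needed:
            x = X[c].to_numpy(float)
            zscore_column(x, ddof=self.ddof, name=c)  # raises on degenerate column
            self.means_[c] = float(np.nanmean(x))
            self.sds_[c] = float(np.nanstd(x, ddof=self.ddof))
        logger.info("composite membership: %s", sets)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "means_"):
            raise RuntimeError("CompositeScorer must be fitted before transform")
        X = self._prepare(X)
        out = X.copy()
        zcols = {
            c: (X[c].to_numpy(float) - self.means_[c]) / self.sds_[c]
            for c in self.instruments_
        }
        for name, cols in self._component_sets().items():
            z = np.column_stack([zcols[c] for c in cols])
            observed = np.sum(~np.isnan(z), axis=1)
            with np.errstate(invalid="ignore"):
                comp = np.nanmean(z, axis=1)
            comp[observed < np.ceil(self.min_fraction * len(cols))] = np.nan
            out[name] = comp
        return out


def _mean_of_z(df: pd.DataFrame, cols: Sequence[str], min_fraction: float = 0.5) -> pd.Series:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing instrument column(s): {missing}")
    z = np.column_stack([zscore_column(df[c], name=c) for c in cols])
    observed = np.sum(~np.isnan(z), axis=1)
    with np.errstate(invalid="ignore"):
        comp = np.nanmean(z, axis=1)
    comp[observed < np.ceil(min_fraction * len(cols))] = np.nan
    return pd.Series(comp, index=df.index)


def motor_composite(df: pd.DataFrame) -> pd.Series:
    """Mean of z(UPDRS II) and z(UPDRS III), standardized within ``df``."""
    return _mean_of_z(df, MOTOR_INSTRUMENTS)


def sleep_composite(df: pd.DataFrame) -> pd.Series:
    return _mean_of_z(df, SLEEP_INSTRUMENTS)


def autonomic_composite(df: pd.DataFrame, ohq_combined: bool = False) -> pd.Series:
    if ohq_combined:
        df = df.copy()
        df["ohq_total"] = df["ohq_i"] + df["ohq_ii"]
        return _mean_of_z(df, ("ohq_total", "scopa_aut"))
    return _mean_of_z(df, AUTONOMIC_INSTRUMENTS)


def global_composite(
    df: pd.DataFrame, instruments: Sequence[str] = GLOBAL_DEFAULT
) -> pd.Series:
    """Unweighted mean of the configured instrument z-scores."""
    return _mean_of_z(df, tuple(instruments))
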