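"""Cardiac 123I-MIBG scintigraphy uptake metrics.

Myocardial MIBG uptake indexes postganglionic cardiac sympathetic
innervation.  From heart and mediastinum region-of-interest counts (or from
pre-computed ratios) this module derives the heart-to-mediastinum (H/M)
ratio at the early (30-min) and delayed (2-h) time points, the washout rate

    WR = 100 * (early H/M - delayed H/M) / early H/M   [percent],

and the denervation flag: a delayed H/M ratio strictly below the
site-calibrated reference limit (default 1.78) is abnormal.  WR is negative
when delayed uptake exceeds early uptake, as is typical with preserved
innervation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

DEFAULT_CUTOFF = 1.78

COUNT_COLUMNS = {
    "early": ("heart_early", "mediastinum_early"),
    "delayed": ("heart_delayed", "mediastinum_delayed"),
}


def hm_ratio(heart_uptake: float, mediastinum_uptake: float) -> float:
    """Heart-to-mediastinum uptake ratio from ROI counts."""
    if heart_uptake <= 0 or mediastinum_uptake <= 0:
        raise ValueError(
            f"ROI uptakes must be positive, got heart={heart_uptake}, "
            f"mediastinum={mediastinum_uptake}"
        )
    return heart_uptake / mediastinum_uptake


def washout_rate(early_hm: float, delayed_hm: float) -> float:
    """Percent washout between the early and delayed H/M ratios."""
    if early_hm <= 0:
        raise ValueError(f"early H/M ratio must be positive, got {early_hm}")
    return 100.0 * (early_hm - delayed_hm) / early_hm


def classify_mibg(delayed_hm: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """``"abnormal"`` iff the delayed H/M ratio is strictly below ``cutoff``."""
    if delayed_hm <= 0:
        raise ValueError(f"delayed H/M ratio must be positive, got {delayed_hm}")
    return "abnormal" if delayed_hm < cutoff else "normal"


@dataclass(frozen=True)
class MibgResult:
    early_hm: float
    delayed_hm: float
    washout_rate: float
    abnormal: bool
    cutoff: float = DEFAULT_CUTOFF


def mibg_result(early_hm: float, delayed_hm: float, cutoff: float = DEFAULT_CUTOFF) -> MibgResult:
    """Bundle the derived metrics for one patient."""
    return MibgResult(
        early_hm=early_hm,
        delayed_hm=delayed_hm,
        washout_rate=washout_rate(early_hm, delayed_hm),
        abnormal=classify_mibg(delayed_hm, cutoff) == "abnormal",
        cutoff=cutoff,
    )


class MibgScorer(TransformerMixin, BaseEstimator):
    """Adds ``washout_rate`` and ``mibg_class`` columns to a cohort table.

    The input may carry ``early_hm``/``delayed_hm`` ratio columns directly
    (the usual reporting granularity) or per-phase ROI count pairs
    (``heart_early``/``mediastinum_early`` and the delayed analogues), from
    which the ratios are computed first.  Stateless apart from the cutoff.
    """

    def __init__(self, cutoff: float = DEFAULT_CUTOFF):
        self.cutoff = cutoff

    def fit(self, X=None, y=None):
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit()
        out = X.copy()
        for phase in ("early", "delayed"):
            ratio_col = f"{phase}_hm"
            if ratio_col not in out.columns:
                heart, med = COUNT_COLUMNS[phase]
                if heart not in out.columns or med not in out.columns:
                    raise ValueError(
                        f"need either '{ratio_col}' or ROI count columns "
                        f"'{heart}'/'{med}'"
                    )
                h = out[heart].to_numpy(float)
                m = out[med].to_numpy(float)
                if np.any(h <= 0) or np.any(m <= 0):
                    raise ValueError(f"non-positive ROI counts in {phase} phase")
                out[ratio_col] = h / m
        early = out["early_hm"].to_numpy(float)
        delayed = out["delayed_hm"].to_numpy(float)
        if np.any(early <= 0) or np.any(delayed <= 0):
            raise ValueError("H/M ratios must be positive")
        out["washout_rate"] = 100.0 * (early - delayed) / early
        out["mibg_class"] = np.where(delayed < self.cutoff, "abnormal", "normal")
        return out
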