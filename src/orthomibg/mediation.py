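"""Simple mediation analysis with covariates and percentile-bootstrap CIs.

The model is the classic two-equation linear mediation, here with predictor
``a`` (e.g. delayed H/M ratio), mediator ``b`` (e.g. orthostatic delta-SBP),
outcome ``c`` (a composite severity score) and covariates (age, disease
duration by default):

    M1:  b = i1 + alpha * a            + gamma1' * cov + e1
    M2:  c = i2 + tau'  * a + beta * b + gamma2' * cov + e2

Effects are decomposed as

    indirect = alpha * beta        (a -> b -> c, product of coefficients)
    direct   = tau'                (a -> c)
    total    = tau' + alpha * beta (identical to the coefficient of a in
                                    c ~ a + cov, exactly, in linear models)

Standard errors use the maximum-likelihood residual variance (SSR / n, the
path-analysis convention; SSR / (n - p) available via ``ml_variance=False``),
with the first-order delta-method (Sobel) SE for the indirect effect.
z = estimate / SE with two-sided normal p-values.  Inference authority rests
with the percentile bootstrap: cases (rows) are resampled jointly with
replacement, all five effects recomputed per resample, and the CI taken from
the empirical quantiles.  Completely standardized betas rescale each path by
the sample SDs of the variables it joins; indirect and total betas follow
the product/sum identities.

The predictor, mediator and covariates are mean-centered before fitting
(multicollinearity hygiene); slopes, effects, betas and bootstrap CIs are
invariant to the centering, only intercepts move.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

EFFECT_LABELS = ("indirect", "a_to_b", "b_to_c", "direct", "total")


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns of X exactly explained by the others (R^2 == 1)."""
    offenders = []
    n, p = X.shape
    for j in range(p):
        others = np.delete(X, j, axis=1)
        xj = X[:, j]
        coef, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ coef
        denom = np.sum((xj - xj.mean()) ** 2)
        if denom == 0 or np.sum(resid**2) <= 1e-10 * max(denom, 1.0):
            offenders.append(names[j])
    return offenders


def ols_fit(
    design,
    response,
    *,
    add_intercept: bool = True,
    ml_variance: bool = True,
    names: list[str] | None = None,
):
    """Least-squares fit with ML (divide-by-n) coefficient standard errors.

    Returns ``(coefficients, se, residual_variance)`` with the intercept
    first when ``add_intercept``.  Requires more rows than columns and a
    full-column-rank design; a rank-deficient design raises naming the
    offending columns.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(response, dtype=float)
    names = list(names) if names else [f"x{j}" for j in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["intercept"] + names
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than columns ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        offenders = _collinear_columns(X, names)
        raise ValueError(f"collinear design: columns {offenders}")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    sigma2 = rss / n if ml_variance else rss / (n - p)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    return coef, se, sigma2


def standardize_effects(
    alpha: float, beta_b: float, tau_prime: float,
    sd_a: float, sd_b: float, sd_c: float,
) -> dict[str, float]:
    """Completely standardized path coefficients.

    ``a_to_b`` is rescaled by SD(a)/SD(b), ``b_to_c`` by SD(b)/SD(c),
    ``direct`` by SD(a)/SD(c); indirect and total follow the product/sum
    identities.  All three SDs must be positive.
    """
    for label, sd in (("predictor", sd_a), ("mediator", sd_b), ("outcome", sd_c)):
        if not sd > 0:
            raise ValueError(f"zero SD for {label}; cannot standardize effects")
    b_ab = alpha * sd_a / sd_b
    b_bc = beta_b * sd_b / sd_c
    b_dir = tau_prime * sd_a / sd_c
    return {
        "a_to_b": b_ab,
        "b_to_c": b_bc,
        "direct": b_dir,
        "indirect": b_ab * b_bc,
        "total": b_dir + b_ab * b_bc,
    }


@dataclass(frozen=True)
class EffectEstimate:
    """One labeled mediation effect with inference on the outcome scale."""

    label: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    beta: float
    z: float
    p: float


@dataclass(frozen=True)
class MediationResult:
    """Five labeled effects plus bookkeeping for one fitted mediation model."""

    effects: dict[str, EffectEstimate]
    n_used: int
    boot_seed: int | None
    predictor: str = ""
    mediator: str = ""
    outcome: str = ""
    covariates: tuple[str, ...] = ()

    def __getitem__(self, label: str) -> EffectEstimate:
        return self.effects[label]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"effect": e.label, "estimate": e.estimate, "se": e.se,
             "ci_low": e.ci_low, "ci_high": e.ci_high,
             "beta": e.beta, "z": e.z, "p": e.p}
            for e in (self.effects[k] for k in EFFECT_LABELS)
        ]
        return pd.DataFrame(rows).set_index("effect")

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "covariates": list(self.covariates),
            "n_used": self.n_used,
            "boot_seed": self.boot_seed,
            "effects": {
                k: {f: getattr(self.effects[k], f)
                    for f in ("estimate", "se", "ci_low", "ci_high", "beta", "z", "p")}
                for k in EFFECT_LABELS
            },
        }


def _boot_indices(seed, i: int, attempt: int, n: int) -> np.ndarray:
    """Counter-based per-resample index stream: reproducible and order-free."""
    rng = np.random.default_rng([int(seed), i, attempt])
    return rng.integers(0, n, size=n)


def _batched_effects(a, b, c, cov, indices) -> np.ndarray:
    """All five effects for each row of ``indices`` (one resample per row).

    Solves the two normal-equation systems for every resample in a batch;
    raises ``np.linalg.LinAlgError`` if any resample is singular.
    """
    nb, n = indices.shape
    ab = a[indices]
    bb_ = b[indices]
    cb = c[indices]
    ones = np.ones((nb, n))
    cols1 = [ones, ab] + [cov[:, j][indices] for j in range(cov.shape[1])]
    X1 = np.stack(cols1, axis=2)
    cols2 = [ones, ab, bb_] + [cov[:, j][indices] for j in range(cov.shape[1])]
    X2 = np.stack(cols2, axis=2)

    def solve(X, y):
        G = np.einsum("bij,bik->bjk", X, X)
        h = np.einsum("bij,bi->bj", X, y)
        return np.linalg.solve(G, h[..., None])[..., 0]

    beta1 = solve(X1, bb_)
    beta2 = solve(X2, cb)
    alpha = beta1[:, 1]
    tau = beta2[:, 1]
    beta_b = beta2[:, 2]
    indirect = alpha * beta_b
    out = np.empty((nb, 5))
    out[:, 0] = indirect
    out[:, 1] = alpha
    out[:, 2] = beta_b
    out[:, 3] = tau
    out[:, 4] = tau + indirect
    return out


class MediationModel(BaseEstimator):
    """Covariate-adjusted simple mediation estimator.

    Parameters
    ----------
    predictor, mediator, outcome : column names of a, b and c.
    covariates : columns partialled out of both model equations
        (default ``("age", "duration")``).
    n_boot : percentile-bootstrap resamples (default 1000).
    ci_level : CI coverage (default 0.95).
    random_state : integer seed driving the per-resample index streams.
    ml_variance : ML (divide-by-n) residual variance for SEs; set False for
        the unbiased divide-by-(n-p) variant (estimates are unaffected).
    max_retries : redraw budget for degenerate bootstrap resamples.

    Fitted attributes: ``effects_`` (label -> :class:`EffectEstimate`),
    ``result_`` (:class:`MediationResult`), ``n_used_``.
    """

    MIN_ROWS = 10

    def __init__(
        self,
        predictor: str = "delayed_hm",
        mediator: str = "delta_sbp_min",
        outcome: str = "global_z",
        covariates: tuple[str, ...] = ("age", "duration"),
        n_boot: int = 1000,
        ci_level: float = 0.95,
        random_state: int | None = None,
        ml_variance: bool = True,
        max_retries: int = 100,
        boot_chunk: int = 250,
    ):
        self.predictor = predictor
        self.mediator = mediator
        self.outcome = outcome
        self.covariates = covariates
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.random_state = random_state
        self.ml_variance = ml_variance
        self.max_retries = max_retries
        self.boot_chunk = boot_chunk

    def _validate_spec(self):
        names = [self.predictor, self.mediator, self.outcome, *self.covariates]
        if len(set(names)) != len(names):
            raise ValueError(f"model variables must be pairwise distinct, got {names}")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")

    def fit(self, X: pd.DataFrame, y=None):
        self._validate_spec()
        cols = [self.predictor, self.mediator, self.outcome, *self.covariates]
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise ValueError(f"data table missing column(s): {missing}")
        data = X[cols].apply(pd.to_numeric, errors="coerce").dropna()
        n = len(data)
        if n < self.MIN_ROWS:
            raise ValueError(f"need at least {self.MIN_ROWS} complete cases, got {n}")
        for c in cols:
            if data[c].std(ddof=1) <= 0:
                raise ValueError(f"degenerate (constant) variable: {c}")

        a = data[self.predictor].to_numpy(float)
        b = data[self.mediator].to_numpy(float)
        c_ = data[self.outcome].to_numpy(float)
        cov = data[list(self.covariates)].to_numpy(float)
        if cov.size == 0:
            cov = np.empty((n, 0))
        # mean-center predictor, mediator and covariates (not the outcome)
        a = a - a.mean()
        b_c = b - b.mean()
        cov = cov - cov.mean(axis=0)

        names1 = [self.predictor, *self.covariates]
        coef1, se1, _ = ols_fit(
            np.column_stack([a, cov]), b_c, ml_variance=self.ml_variance, names=names1
        )
        alpha, se_alpha = coef1[1], se1[1]
        names2 = [self.predictor, self.mediator, *self.covariates]
        coef2, se2, _ = ols_fit(
            np.column_stack([a, b_c, cov]), c_, ml_variance=self.ml_variance, names=names2
        )
        tau, se_tau = coef2[1], se2[1]
        beta_b, se_beta_b = coef2[2], se2[2]
        coef3, se3, _ = ols_fit(
            np.column_stack([a, cov]), c_, ml_variance=self.ml_variance, names=names1
        )
        total, se_total = coef3[1], se3[1]

        indirect = alpha * beta_b
        se_indirect = float(np.sqrt(beta_b**2 * se_alpha**2 + alpha**2 * se_beta_b**2))
        estimates = {
            "indirect": (indirect, se_indirect),
            "a_to_b": (alpha, se_alpha),
            "b_to_c": (beta_b, se_beta_b),
            "direct": (tau, se_tau),
            "total": (total, se_total),
        }
        betas = standardize_effects(
            alpha, beta_b, tau,
            data[self.predictor].std(ddof=1),
            data[self.mediator].std(ddof=1),
            data[self.outcome].std(ddof=1),
        )

        seed = 0 if self.random_state is None else int(self.random_state)
        cis = self._bootstrap(a, b_c, c_, cov, seed)

        effects = {}
        for label in EFFECT_LABELS:
            est, se = estimates[label]
            z = est / se if se > 0 else np.nan
            p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
            lo, hi = cis[label]
            effects[label] = EffectEstimate(
                label=label, estimate=float(est), se=float(se),
                ci_low=float(lo), ci_high=float(hi),
                beta=float(betas[label]), z=float(z), p=p,
            )
        self.effects_ = effects
        self.n_used_ = n
        self.result_ = MediationResult(
            effects=effects, n_used=n, boot_seed=seed,
            predictor=self.predictor, mediator=self.mediator,
            outcome=self.outcome, covariates=tuple(self.covariates),
        )
        return self

    def _bootstrap(self, a, b, c, cov, seed) -> dict[str, tuple[float, float]]:
        """Percentile CIs over case resamples, deterministic given ``seed``."""
        n = len(a)
        nb = int(self.n_boot)
        dist = np.empty((nb, 5))
        chunk = max(1, int(self.boot_chunk))
        for start in range(0, nb, chunk):
            stop = min(start + chunk, nb)
            idx = np.stack([_boot_indices(seed, i, 0, n) for i in range(start, stop)])
            try:
                dist[start:stop] = _batched_effects(a, b, c, cov, idx)
            except np.linalg.LinAlgError:
                # rare degenerate resample: redraw offenders individually
                for i in range(start, stop):
                    dist[i] = self._one_resample(a, b, c, cov, seed, i, n)
        alpha_tail = 100 * (1 - self.ci_level) / 2
        lo = np.percentile(dist, alpha_tail, axis=0)
        hi = np.percentile(dist, 100 - alpha_tail, axis=0)
        return {lab: (lo[j], hi[j]) for j, lab in enumerate(EFFECT_LABELS)}

    def _one_resample(self, a, b, c, cov, seed, i, n) -> np.ndarray:
        for attempt in range(self.max_retries + 1):
            idx = _boot_indices(seed, i, attempt, n)[None, :]
            try:
                return _batched_effects(a, b, c, cov, idx)[0]
            except np.linalg.LinAlgError:
                logger.warning("bootstrap resample %d attempt %d degenerate; redrawing",
                               i, attempt)
        raise RuntimeError(
            f"bootstrap resample {i} degenerate after {self.max_retries} redraws"
        )


def mediate(
    data: pd.DataFrame,
    predictor: str,
    mediator: str,
    outcome: str,
    covariates: tuple[str, ...] = ("age", "duration"),
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int | None = None,
    **kwargs,
) -> MediationResult:
    """Functional wrapper over :class:`MediationModel`; returns the result."""
    model = MediationModel(
        predictor=predictor, mediator=mediator, outcome=outcome,
        covariates=covariates, n_boot=n_boot, ci_level=ci_level,
        random_state=seed, **kwargs,
    )
    return model.fit(data).result_


def bootstrap_ci(
    data: pd.DataFrame,
    predictor: str,
    mediator: str,
    outcome: str,
    covariates: tuple[str, ...] = ("age", "duration"),
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Percentile-bootstrap CIs for the five effects, keyed by label."""
    result = mediate(
        data, predictor, mediator, outcome, covariates=covariates,
        n_boot=n_boot, ci_level=ci_level, seed=seed,
    )
    return {k: (result[k].ci_low, result[k].ci_high) for k in EFFECT_LABELS}
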