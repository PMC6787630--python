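"""Calibrator-pool adequacy via noncentral-t power analysis.

A pool of n healthy controls "equalizes" a gene's physiological expression
variability when the gene's noncentrality statistic

    λ = (mean / SD) · √n = √n / CV

exceeds the reference value λref — the noncentrality at which a two-tailed
one-sample t-test with df = n − 1 reaches power 1 − β at level α (defaults
α = 0.05, β = 0.2). The λref(n) curve decreases toward the normal-theory
limit z_{1−α/2} + z_{1−β} ≈ 2.8016; fitting a one-phase exponential decay
to it and reading off where the curve meets the fitted plateau yields the
recommended pool size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .errors import ComputationError, ValidationError

logger = logging.getLogger(__name__)

#: df → ∞ limit of λref at α = 0.05, power = 0.8
NORMAL_LIMIT_ALPHA05_POWER80 = 2.8016


@dataclass(frozen=True)
class PowerSettings:
    """Two-tailed one-sample t-test error rates (α type-I, β type-II)."""

    alpha: float = 0.05
    beta: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.beta < 1:
            raise ValidationError(f"beta must be in (0, 1), got {self.beta}")

    @property
    def power(self) -> float:
        return 1.0 - self.beta


DEFAULT_SETTINGS = PowerSettings()


@dataclass(frozen=True)
class GeneVariabilitySummary:
    """Per-gene summary over a control cohort: n, mean, sample SD, CV = SD/mean."""

    gene: str
    n: int
    mean: float
    sd: float
    cv: float


def _nct_cdf(t: float, df: float, nc: float) -> float:
    # scipy's Boost-backed noncentral-t CDF returns NaN for df = 1 at
    # moderate noncentrality; fall back to quadrature of the scale-mixture
    # representation P(T' <= t) = E_V[ Phi(t*sqrt(V/df) - nc) ], V ~ chi2_df.
    v = stats.nct.cdf(t, df, nc)
    if np.isfinite(v):
        return float(v)

    def integrand(w: float) -> float:
        return stats.norm.cdf(t * math.sqrt(w / df) - nc) * stats.chi2.pdf(w, df)

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return float(val)


def noncentral_t_power(
    lam: float, df: int, settings: PowerSettings = DEFAULT_SETTINGS
) -> float:
    """Power of a two-tailed one-sample t-test at noncentrality ``lam``.

    power = P(|T'(df, λ)| > t_crit) with t_crit the central-t two-tailed
    critical value at ``settings.alpha``. At λ = 0 this equals α.
    """
    if df < 1:
        raise ValidationError(f"df must be >= 1, got {df}")
    tcrit = stats.t.ppf(1.0 - settings.alpha / 2.0, df)
    return 1.0 - _nct_cdf(tcrit, df, lam) + _nct_cdf(-tcrit, df, lam)


@lru_cache(maxsize=4096)
def _lambda_ref_cached(n: int, alpha: float, beta: float) -> float:
    settings = PowerSettings(alpha=alpha, beta=beta)
    target = settings.power

    def objective(lam: float) -> float:
        return noncentral_t_power(lam, n - 1, settings) - target

    hi = 5.0
    while objective(hi) < 0.0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - unreachable for sane settings
            raise ComputationError("could not bracket lambda_ref")
    return float(optimize.brentq(objective, 1e-9, hi, xtol=1e-10))


def lambda_ref(n: int, settings: PowerSettings = DEFAULT_SETTINGS) -> float:
    """The λ at which the two-tailed one-sample t-test (df = n−1) has the
    requested power; found by bracketed root-finding (|Δpower| < 1e-8)."""
    if n < 2:
        raise ValidationError(f"n must be >= 2, got {n}")
    return _lambda_ref_cached(int(n), settings.alpha, settings.beta)


def gene_variability(values, gene: str) -> GeneVariabilitySummary:
    """Mean, sample SD (n−1 denominator) and CV of a gene's expression values."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValidationError(f"{gene}: need >= 2 finite values, got {arr.size}")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if mean > 0:
        cv = sd / mean
    else:
        logger.warning("%s: mean <= 0, CV undefined", gene)
        cv = float("nan")
    return GeneVariabilitySummary(gene=gene, n=int(arr.size), mean=mean, sd=sd, cv=cv)


def lambda_statistic(summary: GeneVariabilitySummary, n: int | None = None) -> float:
    """λ = (mean/SD)·√n; n defaults to the summary's own cohort size."""
    n = summary.n if n is None else int(n)
    if n < 2:
        raise ValidationError(f"n must be >= 2, got {n}")
    if summary.sd < 0:
        raise ValidationError("sd must be >= 0")
    if summary.sd == 0:
        logger.warning("%s: sd = 0, lambda is infinite", summary.gene)
        return float("inf")
    return summary.mean / summary.sd * math.sqrt(n)


def project_lambda(summary: GeneVariabilitySummary, n_new: int) -> float:
    """λ a cohort of size ``n_new`` would have if mean and SD stayed at the
    summary's observed values (i.e. assuming the CV does not change)."""
    return lambda_statistic(summary, n=n_new)


@dataclass(frozen=True)
class AdequacyReport:
    """Per-gene λ vs. λref verdicts for a candidate control-pool size."""

    settings: PowerSettings
    n: int
    lambda_ref: float
    table: pd.DataFrame  # gene, n, mean, sd, cv, lambda, lambda_ref, adequate
    overall_adequate: bool

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def adequacy_report(
    summaries: list[GeneVariabilitySummary],
    n: int | None = None,
    settings: PowerSettings = DEFAULT_SETTINGS,
) -> AdequacyReport:
    """Judge whether an n-control pool equalizes every panel gene.

    A gene is adequately represented iff its λ strictly exceeds λref(n)
    (a tie counts as inadequate); the cohort passes only if all genes do.
    ``n`` defaults to the summaries' common cohort size; passing a different
    n projects each gene's λ to that size at fixed CV.
    """
    if not summaries:
        raise ValidationError("need at least one gene summary")
    if n is None:
        sizes = {s.n for s in summaries}
        if len(sizes) > 1:
            raise ValidationError(
                f"summaries come from different cohort sizes {sorted(sizes)}; pass n"
            )
        n = sizes.pop()
    lref = lambda_ref(n, settings)
    rows = []
    for s in summaries:
        lam = lambda_statistic(s, n=n)
        rows.append(
            {
                "gene": s.gene,
                "n": n,
                "mean": s.mean,
                "sd": s.sd,
                "cv": s.cv,
                "lambda": lam,
                "lambda_ref": lref,
                "adequate": bool(lam > lref),
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    return AdequacyReport(
        settings=settings,
        n=int(n),
        lambda_ref=lref,
        table=table,
        overall_adequate=bool(table["adequate"].all()),
    )


def summaries_from_frame(stats_df: pd.DataFrame, n: int) -> list[GeneVariabilitySummary]:
    """Build per-gene summaries from a frame with ``mean`` and ``sd`` columns
    indexed by gene symbol (e.g. the shipped reference tables)."""
    out = []
    for gene, row in stats_df.iterrows():
        mean, sd = float(row["mean"]), float(row["sd"])
        out.append(
            GeneVariabilitySummary(
                gene=str(gene), n=int(n), mean=mean, sd=sd,
                cv=sd / mean if mean > 0 else float("nan"),
            )
        )
    return out


@dataclass(frozen=True)
class DecayFit:
    """One-phase exponential decay y(n) = plateau + (y0 − plateau)·e^{−k(n−n_min)}."""

    y0: float
    k: float
    plateau: float
    rss: float


@dataclass(frozen=True)
class PlanResult:
    """λref curve over a pool-size grid, its decay fit, and the recommended n."""

    n_grid: np.ndarray
    lambda_ref_curve: np.ndarray
    fit: DecayFit
    recommended_n: int
    settings: PowerSettings = DEFAULT_SETTINGS

    def to_dict(self) -> dict:
        return {
            "alpha": self.settings.alpha,
            "power": self.settings.power,
            "n_grid": [int(v) for v in self.n_grid],
            "lambda_ref_curve": [float(v) for v in self.lambda_ref_curve],
            "fit": {
                "y0": self.fit.y0,
                "k": self.fit.k,
                "plateau": self.fit.plateau,
                "rss": self.fit.rss,
            },
            "recommended_n": int(self.recommended_n),
        }


def fit_exponential_decay(
    n_grid: np.ndarray, y: np.ndarray, n_min: int | None = None
) -> DecayFit:
    """Unweighted least-squares fit of a one-phase decay to a curve.

    The exponential is anchored at the grid's first point to decouple y0
    from the rate k; initial values are y0 = y[0], plateau = y[-1], k = 0.2.
    """
    n_grid = np.asarray(n_grid, dtype=float)
    y = np.asarray(y, dtype=float)
    n0 = float(n_grid[0] if n_min is None else n_min)

    def model(n, plateau, y0, k):
        return plateau + (y0 - plateau) * np.exp(-k * (n - n0))

    try:
        popt, _ = optimize.curve_fit(
            model, n_grid, y, p0=[y[-1], y[0], 0.2], maxfev=20000
        )
    except RuntimeError as exc:
        raise ComputationError(f"exponential-decay fit did not converge: {exc}") from exc
    plateau, y0, k = (float(v) for v in popt)
    rss = float(np.sum((model(n_grid, plateau, y0, k) - y) ** 2))
    return DecayFit(y0=y0, k=k, plateau=plateau, rss=rss)


def plan_sample_size(
    n_max: int = 40,
    n_min: int = 2,
    settings: PowerSettings = DEFAULT_SETTINGS,
) -> PlanResult:
    """Recommend a calibrator-pool size from the plateau of the λref curve.

    λref is computed on n = n_min..n_max, a one-phase exponential decay is
    fitted by unweighted least squares, and the recommended pool size is the
    grid n whose λref is closest (in absolute value) to the fitted plateau,
    ties going to the smaller n.
    """
    if n_max < 5:
        raise ValidationError(f"n_max must be >= 5, got {n_max}")
    if not 2 <= n_min < n_max:
        raise ValidationError(f"need 2 <= n_min < n_max, got n_min={n_min}")
    n_grid = np.arange(n_min, n_max + 1)
    curve = np.array([lambda_ref(int(n), settings) for n in n_grid])
    try:
        fit = fit_exponential_decay(n_grid, curve, n_min=n_min)
    except ComputationError as exc:
        exc.lambda_ref_curve = (n_grid, curve)  # let callers inspect the curve
        raise
    dist = np.abs(curve - fit.plateau)
    recommended = int(n_grid[int(np.argmin(dist))])  # argmin ties -> smaller n
    return PlanResult(
        n_grid=n_grid,
        lambda_ref_curve=curve,
        fit=fit,
        recommended_n=recommended,
        settings=settings,
    )
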