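"""Bootstrap model-comparison statistics.

Two models' predictions are compared on the same evaluation units (exams
or images) by paired bootstrap: each replicate resamples unit indices
with replacement, applies the *same* indices to both models, computes the
metric for each, and records the difference Δ = metric_b - metric_a.
Normality of the Δ distribution is checked with a Kolmogorov-Smirnov
test (sample-standardized), the test statistic is Z = Δ/σ with σ the
empirical SD of the bootstrap Δ values, the two-sided p-value is
2·Φ(-|Z|), and the 95% CI is the 2.5th/97.5th percentile of the Δ
values.  A paired t-test utility covers test-retest designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapComparison",
    "bootstrap_deltas",
    "ks_normality",
    "z_test",
    "percentile_ci",
    "compare_models",
    "paired_ttest",
]


@dataclass
class BootstrapComparison:
    """Result of one paired-bootstrap model comparison.

    ``delta_point`` is the metric difference on the full unresampled set
    (model B minus model A); ``sigma`` the empirical SD of the bootstrap
    Δ values; ``z`` = delta_point / sigma; ``delta_boot_mean`` the mean of
    the bootstrap Δ values (reported alongside for reference).
    """

    metric_name: str
    delta_point: float
    deltas: np.ndarray
    sigma: float
    z: float
    p_two_sided: float
    ci: tuple[float, float]
    ks_p: float | None
    n_boot: int
    unit: str
    seed: int | None = None
    delta_boot_mean: float = float("nan")
    n_redrawn: int = 0

    def summary(self) -> str:
        ks = "n/a (degenerate)" if self.ks_p is None else f"{self.ks_p:.3f}"
        return (
            f"Δ{self.metric_name} ({self.unit}-level, {self.n_boot} bootstrap sets)\n"
            f"  Δ point estimate : {self.delta_point:+.4f}\n"
            f"  bootstrap mean Δ : {self.delta_boot_mean:+.4f}\n"
            f"  σ (bootstrap SD) : {self.sigma:.4f}\n"
            f"  Z = Δ/σ          : {self.z:+.3f}\n"
            f"  two-sided P      : {self.p_two_sided:.4g}\n"
            f"  95% CI           : ({self.ci[0]:+.4f}, {self.ci[1]:+.4f})\n"
            f"  KS normality P   : {ks}\n"
        )


def bootstrap_deltas(
    metric_fn,
    preds_a,
    preds_b,
    references,
    n_boot: int,
    rng: np.random.Generator,
    max_redraws: int = 1000,
    counters: dict | None = None,
) -> np.ndarray:
    """Paired bootstrap Δ = metric(b) - metric(a) over ``n_boot`` resamples.

    ``preds_a``, ``preds_b`` and ``references`` are aligned sequences over
    the same units.  A replicate whose resample makes the metric undefined
    (e.g. a single reference class for AUC) is redrawn; the redraw count
    is logged and recorded in ``counters``.
    """
    n = len(references)
    if not (len(preds_a) == len(preds_b) == n):
        raise ValueError("predictions and references must be aligned")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    deltas = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            try:
                ma = metric_fn([preds_a[i] for i in idx], [references[i] for i in idx])
                mb = metric_fn([preds_b[i] for i in idx], [references[i] for i in idx])
            except ValueError:
                redrawn += 1
                continue
            deltas[b] = mb - ma
            break
        else:
            raise RuntimeError("could not draw a valid bootstrap resample")
    if redrawn:
        logger.info("redrew %d degenerate bootstrap resamples", redrawn)
    if counters is not None:
        counters["n_redrawn"] = counters.get("n_redrawn", 0) + redrawn
    return deltas


def ks_normality(deltas) -> float | None:
    """KS test of sample-standardized deltas against the standard normal.

    Returns the asymptotic p-value, or None (degenerate) for zero
    variance.  Mean and SD are estimated from the sample, as in the usual
    "standard KS test for normality" reading (the Lilliefors caveat — the
    p-value is anti-conservative — is accepted and documented).
    """
    deltas = np.asarray(deltas, dtype=np.float64)
    if deltas.size < 8:
        raise ValueError("need at least 8 values for the normality check")
    sd = deltas.std(ddof=1)
    if sd == 0:
        return None
    z = (deltas - deltas.mean()) / sd
    return float(stats.kstest(z, "norm").pvalue)


def z_test(delta_point: float, sigma: float) -> tuple[float, float]:
    """Z = Δ/σ and the two-sided normal p-value 2·Φ(-|Z|)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        if delta_point == 0:
            return 0.0, 1.0
        logger.warning("zero bootstrap SD with nonzero delta; p set to 0")
        return float("inf") if delta_point > 0 else float("-inf"), 0.0
    z = delta_point / sigma
    return float(z), float(2.0 * stats.norm.cdf(-abs(z)))


def percentile_ci(values, lo: float = 2.5, hi: float = 97.5) -> tuple[float, float]:
    """Empirical percentile interval (linear interpolation)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    lower, upper = np.percentile(values, [lo, hi])
    return float(lower), float(upper)


def compare_models(
    preds_a,
    preds_b,
    references,
    metric_fn,
    metric_name: str = "metric",
    unit: str = "exam",
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> BootstrapComparison:
    """Full paired-bootstrap comparison of model B against model A.

    Composes :func:`bootstrap_deltas`, :func:`ks_normality`,
    :func:`z_test` and :func:`percentile_ci`.  A failed normality check
    logs a warning but does not block the Z-based p-value.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    counters: dict = {}
    deltas = bootstrap_deltas(
        metric_fn, preds_a, preds_b, references, n_boot, rng, counters=counters
    )
    delta_point = float(metric_fn(preds_b, references) - metric_fn(preds_a, references))
    sigma = float(deltas.std(ddof=1)) if n_boot > 1 else 0.0
    z, p = z_test(delta_point, sigma)
    ci = percentile_ci(deltas)
    ks_p = ks_normality(deltas) if n_boot >= 8 else None
    if ks_p is not None and ks_p < 0.05:
        logger.warning(
            "bootstrap Δ%s distribution fails the KS normality check (p=%.3g)",
            metric_name,
            ks_p,
        )
    return BootstrapComparison(
        metric_name=metric_name,
        delta_point=delta_point,
        deltas=deltas,
        sigma=sigma,
        z=z,
        p_two_sided=p,
        ci=ci,
        ks_p=ks_p,
        n_boot=n_boot,
        unit=unit,
        seed=seed,
        delta_boot_mean=float(deltas.mean()),
        n_redrawn=counters.get("n_redrawn", 0),
    )


def paired_ttest(values_a, values_b) -> tuple[float, float]:
    """Paired t statistic (df = n-1) and two-sided p-value.

    Raises on zero-variance differences (degenerate design) rather than
    returning a misleading p-value.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size != b.size or a.size < 2:
        raise ValueError("need two aligned samples of length >= 2")
    d = b - a
    if d.std(ddof=1) == 0:
        raise ValueError("zero-variance differences; paired t-test degenerate")
    res = stats.ttest_rel(b, a)
    return float(res.statistic), float(res.pvalue)
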