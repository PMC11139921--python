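"""Triploid-block phenotype statistics.

Per-plant collapsed-seed percentages, one-way ANOVA across genotypes, and
Dunnett many-to-one post hoc comparisons against a reference genotype
(the *jas-3*-like triploid-block background).  The Dunnett family-wise
adjustment uses the max-modulus distribution of the equicorrelated
multivariate t implied by the shared reference group, evaluated by seeded
Monte-Carlo integration.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import stage_rng
from .core import SeedCountRecord

logger = logging.getLogger(__name__)

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    """Significance stars: ns (p >= 0.05), * (< 0.05), ** (< 0.01), *** (< 0.001)."""
    for level, label in STAR_LEVELS:
        if p < level:
            return label
    return "ns"


def collapse_percentage(record: SeedCountRecord) -> float:
    """Percent collapsed seeds of one plant; undefined at zero total."""
    if record.total == 0:
        raise ValueError(f"plant {record.plant_id}: no seeds counted")
    return 100.0 * record.n_collapsed / record.total


def percentages_by_genotype(records: Sequence[SeedCountRecord]) -> dict[str, list[float]]:
    """Per-genotype collapse percentages; zero-total plants are excluded
    with a log entry."""
    out: dict[str, list[float]] = {}
    for rec in records:
        if rec.total == 0:
            logger.warning("excluding plant %s: zero seeds counted", rec.plant_id)
            continue
        out.setdefault(rec.genotype, []).append(collapse_percentage(rec))
    return out


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    ss_between: float
    ss_within: float


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Standard one-way between/within decomposition with the F reference."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    n_total = sum(len(a) for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    if df_within < 1:
        raise ValueError("need at least one within-group degree of freedom")
    grand = np.concatenate(arrays).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0:
        if ssb == 0:
            return AnovaResult(0.0, df_between, df_within, 1.0, 0.0, 0.0)
        raise ValueError("degenerate variance: zero within-group variance with differing means")
    f = (ssb / df_between) / (ssw / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), df_between, df_within, p, float(ssb), float(ssw))


@dataclass
class DunnettResult:
    reference: str
    df: int
    pooled_sd: float
    table: pd.DataFrame  # group, n, mean, diff, t, p_adj, stars
    critical_value_05: float


def dunnett_null_max_t(
    ns: Sequence[int], n_ref: int, df: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo sample of max_i |T_i| under the Dunnett null.

    T_i = (lambda_i Z0 + sqrt(1 - lambda_i^2) Z_i) / sqrt(W/df) with shared
    Z0 (the reference-group noise) and W ~ chi2_df (the pooled variance),
    lambda_i = sqrt(n_i / (n_i + n_ref)); this is the multivariate t with
    the correlation structure implied by the shared reference.
    """
    lam = np.sqrt(np.asarray(ns, dtype=float) / (np.asarray(ns, dtype=float) + n_ref))
    z0 = rng.standard_normal(n_draws)
    z = rng.standard_normal((n_draws, len(lam)))
    s = np.sqrt(rng.chisquare(df, n_draws) / df)
    t = (lam[None, :] * z0[:, None] + np.sqrt(1 - lam**2)[None, :] * z) / s[:, None]
    return np.abs(t).max(axis=1)


def dunnett_test(
    groups: Mapping[str, Sequence[float]],
    reference: str,
    n_draws: int = 100_000,
    seed: int = 0,
) -> DunnettResult:
    """Two-sided Dunnett comparisons of every group against the reference.

    Uses the pooled within-group variance from the one-way ANOVA and a
    seeded Monte-Carlo evaluation of the family-wise max-modulus reference
    distribution (n_draws >= 1e5 gives p values stable to about +/-0.005).
    """
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    if len(groups) < 2:
        raise ValueError("need the reference plus at least one comparison group")
    if n_draws < 1000:
        raise ValueError("n_draws too small for a stable Monte-Carlo p")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    anova = one_way_anova(arrays)
    if anova.ss_within == 0:
        raise ValueError("degenerate variance: all within-group variances are zero")
    s2 = anova.ss_within / anova.df_within
    ref = arrays[reference]
    others = [g for g in groups if g != reference]
    ns = [len(arrays[g]) for g in others]
    rng = stage_rng(seed, "dunnett")
    null_max = dunnett_null_max_t(ns, len(ref), anova.df_within, n_draws, rng)
    crit = float(np.quantile(null_max, 0.95))
    rows = []
    for g, n_g in zip(others, ns):
        diff = arrays[g].mean() - ref.mean()
        se = np.sqrt(s2 * (1.0 / n_g + 1.0 / len(ref)))
        t = diff / se
        p_adj = float((null_max >= abs(t)).mean())
        if diff == 0:
            p_adj = 1.0
        rows.append(
            {
                "group": g,
                "n": n_g,
                "mean": float(arrays[g].mean()),
                "diff": float(diff),
                "t": float(t),
                "p_adj": p_adj,
                "stars": stars(p_adj),
            }
        )
    table = pd.DataFrame(rows)
    return DunnettResult(
        reference=reference,
        df=anova.df_within,
        pooled_sd=float(np.sqrt(s2)),
        table=table,
        critical_value_05=crit,
    )


def boxplot_stats(values: Sequence[float]) -> dict[str, float]:
    """Box/whisker summary: median, quartiles, whiskers at Q1 - 1.5 IQR and
    Q3 + 1.5 IQR."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
    }


def transform_percentages(values: Sequence[float], method: str) -> list[float]:
    """Optional variance-stabilizing transform of collapse percentages:
    "none" (raw percentage scale, the default presentation), "arcsine"
    (arcsin sqrt of the proportion) or "logit" (with a 0.5-percentage-point
    clamp against the boundaries)."""
    v = np.asarray(values, dtype=float)
    if method == "none":
        return v.tolist()
    if method == "arcsine":
        return np.arcsin(np.sqrt(np.clip(v / 100.0, 0.0, 1.0))).tolist()
    if method == "logit":
        p = np.clip(v / 100.0, 0.005, 0.995)
        return np.log(p / (1 - p)).tolist()
    raise ValueError(f"unknown transform {method!r}")


def analyze_seed_counts(
    records: Sequence[SeedCountRecord],
    reference: str,
    n_draws: int = 100_000,
    seed: int = 0,
    transform: str = "none",
) -> tuple[pd.DataFrame, AnovaResult, DunnettResult]:
    """Per-plant percentages, one-way ANOVA, and Dunnett table in one call.

    The tests run on the raw percentage scale by default; ``transform``
    switches them to arcsine or logit scale (percentages are still reported
    untransformed).
    """
    groups = percentages_by_genotype(records)
    analysis_groups = {g: transform_percentages(v, transform) for g, v in groups.items()}
    pct = pd.DataFrame(
        [
            (g, i + 1, v)
            for g, vals in groups.items()
            for i, v in enumerate(vals)
        ],
        columns=["genotype", "plant", "percent_collapsed"],
    )
    anova = one_way_anova(analysis_groups)
    dunnett = dunnett_test(analysis_groups, reference, n_draws=n_draws, seed=seed)
    return pct, anova, dunnett
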