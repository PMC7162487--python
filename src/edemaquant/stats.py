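"""Group comparison layer: mean±SD±SEM, Levene-gated one-way ANOVA.

Endpoints (MAP reduction, ULE, DLE) are compared across the treatment
arms with a one-way ANOVA.  Homogeneity of variance is assessed with the
mean-centered Levene test; post-hoc pairwise comparisons then use the
Bonferroni adjustment when variances are homogeneous and Tamhane's T2
(Welch t with Satterthwaite degrees of freedom, Sidak-style multiplicity
adjustment) when they are not — the dispatch SPSS performs.  An ANOVA
from summary statistics (group means, SDs, ns) is provided so published
group tables can be re-analyzed without raw data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "PairwiseComparison",
    "AnovaReport",
    "describe",
    "levene_mean_centered",
    "oneway_anova",
    "anova_from_summary",
    "tamhane_t2",
    "bonferroni_pairwise",
    "posthoc_dispatch",
    "format_p",
]

#: p-values below this are reported as "< 1e-300" (CDF underflow).
P_FLOOR = 1e-300


@dataclass(frozen=True)
class GroupSample:
    """One endpoint's per-subject values for a single treatment arm."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.size < 2:
            raise ValueError(f"group {self.label!r} needs n >= 2")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"group {self.label!r} has non-finite values")
        object.__setattr__(self, "values", tuple(float(v) for v in vals))

    @property
    def n(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values)


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    mean_diff: float
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float


@dataclass
class AnovaReport:
    """Full record of one endpoint's group comparison."""

    endpoint: str
    descriptives: list[dict]  # label, n, mean, sd, sem
    levene_stat: float
    levene_p: float
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    posthoc_method: str  # "Bonferroni" | "Tamhane"
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    alpha: float = 0.05


def describe(sample: GroupSample) -> tuple[int, float, float, float]:
    """(n, mean, SD, SEM) with the n-1 SD denominator and SEM = SD/sqrt(n)."""
    v = sample.as_array()
    sd = float(v.std(ddof=1))
    return sample.n, float(v.mean()), sd, sd / math.sqrt(sample.n)


def levene_mean_centered(groups: list[GroupSample]) -> tuple[float, float]:
    """Classic Levene test: ANOVA on absolute deviations from group means.

    Mean centering (not the median-centered Brown-Forsythe variant).
    Returns (statistic, p) from F(k-1, N-k).  If every group is
    constant the deviations are identically zero and (0, 1) is returned.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    arrays = [g.as_array() for g in groups]
    if all(np.ptp(a) == 0 for a in arrays):
        return 0.0, 1.0
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = sps.levene(*arrays, center="mean")
    if not np.isfinite(stat):
        # zero within-group deviation spread with real between-group spread
        return math.inf, 0.0
    return float(stat), float(p)


def oneway_anova(groups: list[GroupSample]) -> tuple[float, int, int, float]:
    """Raw-data one-way ANOVA: (F, df_between, df_within, p).

    Degenerate inputs: zero variance both between and within groups
    gives F = 0, p = 1; zero within-group variance with real separation
    gives F = +inf, p = 0.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    arrays = [g.as_array() for g in groups]
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df_b, df_w = k - 1, n_total - k

    grand = np.concatenate(arrays).mean()
    ss_b = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_w = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_w == 0.0:
        if ss_b == 0.0:
            return 0.0, df_b, df_w, 1.0
        return math.inf, df_b, df_w, 0.0
    f = (ss_b / df_b) / (ss_w / df_w)
    return float(f), df_b, df_w, float(sps.f.sf(f, df_b, df_w))


def anova_from_summary(means, sds, ns) -> tuple[float, int, int, float]:
    """One-way ANOVA reconstructed from per-group summary statistics.

    SS_between = sum n_i (mean_i - grand)^2 with the n-weighted grand
    mean; MS_within pools the (n_i - 1) s_i^2.  Algebraically identical
    to :func:`oneway_anova` on the raw data the summaries came from.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if not (means.size == sds.size == ns.size):
        raise ValueError("means, sds, ns must have equal length")
    if means.size < 2:
        raise ValueError("at least two groups are required")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")

    k = means.size
    df_b = k - 1
    df_w = int(ns.sum()) - k
    grand = (ns * means).sum() / ns.sum()
    ss_b = (ns * (means - grand) ** 2).sum()
    ss_w = ((ns - 1) * sds**2).sum()
    if ss_w == 0.0:
        if ss_b == 0.0:
            return 0.0, df_b, df_w, 1.0
        return math.inf, df_b, df_w, 0.0
    f = (ss_b / df_b) / (ss_w / df_w)
    return float(f), df_b, df_w, float(sps.f.sf(f, df_b, df_w))


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, Satterthwaite df, two-sided p."""
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


def tamhane_t2(groups: list[GroupSample]) -> list[PairwiseComparison]:
    """Tamhane's T2 pairwise comparisons for unequal variances.

    Welch t with Satterthwaite df per pair; the per-pair p is then
    Sidak-adjusted over the m = k(k-1)/2 comparisons,
    p_adj = 1 - (1 - p)^m, capped at 1.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i].as_array(), groups[j].as_array()
            t, df, p = _welch(a, b)
            p_adj = min(1.0, 1.0 - (1.0 - p) ** m) if p > 0 else 0.0
            # expm1 keeps precision for tiny p
            if 0 < p < 1e-8:
                p_adj = min(1.0, -math.expm1(m * math.log1p(-p)))
            out.append(
                PairwiseComparison(
                    (groups[i].label, groups[j].label),
                    float(a.mean() - b.mean()), t, df, p, p_adj,
                )
            )
    return out


def bonferroni_pairwise(groups: list[GroupSample]) -> list[PairwiseComparison]:
    """Pairwise pooled-variance t tests with Bonferroni adjustment.

    The variance is pooled within each pair; p is multiplied by the
    number of comparisons and capped at 1.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a, b = groups[i].as_array(), groups[j].as_array()
            na, nb = a.size, b.size
            df = na + nb - 2
            sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
            if sp2 == 0.0:
                t, p = 0.0, 1.0
                if a.mean() != b.mean():
                    t, p = math.inf, 0.0
            else:
                t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
                p = 2.0 * float(sps.t.sf(abs(t), df))
            out.append(
                PairwiseComparison(
                    (groups[i].label, groups[j].label),
                    float(a.mean() - b.mean()), float(t), float(df),
                    min(p, 1.0), min(1.0, m * p),
                )
            )
    return out


def posthoc_dispatch(
    groups: list[GroupSample], alpha: float = 0.05, endpoint: str = ""
) -> AnovaReport:
    """Full endpoint analysis with the variance-gated post-hoc choice.

    Runs the mean-centered Levene test; Tamhane's T2 is used when
    levene_p < alpha, Bonferroni otherwise.
    """
    lev_stat, lev_p = levene_mean_centered(groups)
    f, df_b, df_w, p = oneway_anova(groups)
    if lev_p < alpha:
        method, pairs = "Tamhane", tamhane_t2(groups)
    else:
        method, pairs = "Bonferroni", bonferroni_pairwise(groups)
    desc = []
    for g in groups:
        n, mean, sd, sem = describe(g)
        desc.append({"label": g.label, "n": n, "mean": mean, "sd": sd, "sem": sem})
    return AnovaReport(
        endpoint=endpoint,
        descriptives=desc,
        levene_stat=lev_stat,
        levene_p=lev_p,
        f_stat=f,
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        posthoc_method=method,
        pairwise=pairs,
        alpha=alpha,
    )


def format_p(p: float) -> str:
    """Scientific-notation p with an explicit underflow floor."""
    if p < P_FLOOR:
        return "< 1e-300"
    if p >= 0.001:
        return f"{p:.3f}"
    return f"{p:.2e}"
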