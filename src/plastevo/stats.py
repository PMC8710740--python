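"""Statistical battery for divergence-time / structural-variation analyses.

Rank and product-moment correlations, the tie-corrected Kruskal-Wallis test
with Holm-adjusted pairwise rank-sum follow-ups, and per-clade genome-size
summaries. Everything routes through scipy.stats: Spearman uses mid-ranks
with the t-approximation on n-2 df; Kruskal-Wallis applies the standard tie
correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .plastome import SizeRecord


class StatsError(ValueError):
    pass


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p: float
    method: str = "spearman"


@dataclass
class PairwiseResult:
    groups: tuple[str, str]
    statistic: float
    p_adjusted: float
    p_raw: float


@dataclass
class GroupTestResult:
    H: float
    df: int
    p: float
    pairwise: list[PairwiseResult] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def _clean_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatsError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise StatsError(f"need >= 3 complete pairs, have {len(x)}")
    return x, y


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation; mid-ranks for ties, t-approximation p.

    Pairs with a missing value (NaN) are dropped.
    """
    x, y = _clean_pairs(x, y)
    res = sps.spearmanr(x, y)
    return CorrelationResult(
        rho=float(res.statistic), n=len(x), p=float(res.pvalue), method="spearman"
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation; NaN pairs dropped."""
    x, y = _clean_pairs(x, y)
    res = sps.pearsonr(x, y)
    return CorrelationResult(
        rho=float(res.statistic), n=len(x), p=float(res.pvalue), method="pearson"
    )


def holm(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (monotone, capped at 1)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p_values[i])
        adj[i] = min(1.0, running)
    return adj


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H with pairwise rank-sum follow-ups.

    The omnibus p comes from the chi-square approximation with k-1 df;
    pairwise comparisons are two-sided Wilcoxon rank-sum tests with Holm
    adjustment across all pairs.
    """
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise StatsError("every group needs at least one observation")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(len(groups))]
    arrays = [np.asarray(g, dtype=float) for g in groups]
    kw = sps.kruskal(*arrays)
    pairs = []
    raw_ps = []
    combos = [
        (i, j) for i in range(len(arrays)) for j in range(i + 1, len(arrays))
    ]
    for i, j in combos:
        r = sps.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
        pairs.append((labels[i], labels[j], float(r.statistic), float(r.pvalue)))
        raw_ps.append(float(r.pvalue))
    adj = holm(raw_ps)
    pairwise = [
        PairwiseResult(groups=(a, b), statistic=s, p_adjusted=pa, p_raw=pr)
        for (a, b, s, pr), pa in zip(pairs, adj)
    ]
    return GroupTestResult(
        H=float(kw.statistic),
        df=len(groups) - 1,
        p=float(kw.pvalue),
        pairwise=pairwise,
    )


@dataclass
class CladeSummary:
    clade: str
    n: int
    mean: float
    mean_bp: int  # rounded to nearest integer bp for reporting
    min: float
    max: float


_FIELD = {"total": "total_bp", "coding": "coding_bp", "noncoding": "noncoding_bp"}
KNOWN_CLADES = ("I", "II", "III", "IV", "outgroup")


def clade_summary(
    records: Iterable[SizeRecord], field_name: str = "total"
) -> list[CladeSummary]:
    """Per-clade n/mean/min/max for one size field; outgroup rows excluded.

    Reported means are rounded to the nearest bp; the raw mean is retained
    alongside. Clades appear in the order I, II, III, IV.
    """
    if field_name not in _FIELD:
        raise StatsError(f"unknown field {field_name!r}")
    attr = _FIELD[field_name]
    by_clade: dict[str, list[float]] = {}
    for r in records:
        if r.clade not in KNOWN_CLADES:
            raise StatsError(f"unknown clade label {r.clade!r} ({r.species})")
        if r.clade == "outgroup":
            continue
        by_clade.setdefault(r.clade, []).append(float(getattr(r, attr)))
    out = []
    for clade in ("I", "II", "III", "IV"):
        vals = by_clade.get(clade)
        if not vals:
            continue
        mean = float(np.mean(vals))
        out.append(
            CladeSummary(
                clade=clade,
                n=len(vals),
                mean=mean,
                # half-up, the convention used in printed size tables
                mean_bp=int(math.floor(mean + 0.5)),
                min=min(vals),
                max=max(vals),
            )
        )
    return out


def divergence_correlations(nodes) -> dict[str, CorrelationResult]:
    """Correlations linking indel accumulation to node age and genome size.

    ``nodes`` is a DataFrame with columns divergence_time, indel_count and
    cp_size (missing counts as NaN). Two product-moment correlations are
    reported: node age vs cumulative indel count, and node genome size vs
    the per-MY indel accumulation rate (count / age), which removes the
    strong age dependence before asking whether larger genomes accumulate
    indels faster. Spearman analogues are included for rank-based
    sensitivity.
    """
    t = np.asarray(nodes["divergence_time"], dtype=float)
    c = np.asarray(nodes["indel_count"], dtype=float)
    s = (
        np.asarray(nodes["cp_size"], dtype=float)
        if "cp_size" in nodes
        else np.full_like(t, np.nan)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(t > 0, c / t, np.nan)
    out = {
        "time_vs_indels": pearson(t, c),
        "time_vs_indels_spearman": spearman(t, c),
    }
    try:
        out["size_vs_indel_rate"] = pearson(s, rate)
        out["size_vs_indels_spearman"] = spearman(s, c)
    except StatsError:
        pass  # size column absent or too sparse: report the time statistics only
    return out
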