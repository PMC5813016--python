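"""Group statistics for per-cell puncta endpoints.

Per-cell endpoint values are square-root transformed (variance
stabilization for count-like data, where groupwise variances otherwise
scale with the mean), averaged within recording batch, and compared by
one-way ANOVA with treatment as a factor.  Variance homogeneity is
assessed with Bartlett's test.  Post-hoc comparisons against the control
group use Dunnett's procedure; other families of comparisons use
Benjamini-Hochberg FDR adjustment.  All tests are two-tailed at the 5%
level.

The analysis unit is the batch mean (not the cell), avoiding
pseudo-replication across cells recorded in the same well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupData",
    "AnovaResult",
    "DegenerateVarianceError",
    "stabilize",
    "bartlett",
    "anova_oneway",
    "dunnett",
    "bh_fdr",
    "batch_means",
    "analyze_endpoint",
]


class DegenerateVarianceError(ValueError):
    """Bartlett's statistic is undefined when a group has zero variance."""


@dataclass
class GroupData:
    """Per-cell endpoint values for one treatment, keyed by batch."""

    treatment_label: str
    batches: dict[str, list[float]]

    def __post_init__(self) -> None:
        if not self.batches:
            raise ValueError("need at least one batch per group")
        for vals in self.batches.values():
            if not np.all(np.isfinite(vals)):
                raise ValueError("endpoint values must be finite")


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    bartlett_stat: float | None = None
    bartlett_p: float | None = None
    comparisons: dict[str, float] = field(default_factory=dict)


def stabilize(values) -> np.ndarray:
    """Elementwise square root (requires nonnegative input)."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("values must be nonnegative for sqrt stabilization")
    return np.sqrt(v)


def bartlett(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical Bartlett test of equal variances (chi-square, k-1 df)."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
        if np.var(g, ddof=1) == 0:
            raise DegenerateVarianceError("a group has zero variance")
    stat, p = sps.bartlett(*[np.asarray(g, dtype=float) for g in groups])
    if np.isnan(p):  # exactly equal variances give statistic 0, p 1
        stat, p = max(float(stat), 0.0), float(sps.chi2.sf(max(stat, 0.0),
                                                           len(groups) - 1))
    return float(stat), float(p)


def anova_oneway(groups: list[np.ndarray]) -> AnovaResult:
    """One-way fixed-effects ANOVA on the supplied per-group samples."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    if n_total <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        # degenerate decomposition: identical constants give F = 0,
        # distinct constants a perfect separation
        F = 0.0 if ss_between == 0.0 else float("inf")
        p = 1.0 if ss_between == 0.0 else 0.0
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(F=float(F), df_between=df_b, df_within=df_w, p=p)


def dunnett(groups: dict[str, np.ndarray], control_label: str,
            seed: int = 0) -> dict[str, float]:
    """Two-sided Dunnett-adjusted p values for each treatment vs control.

    Tail probabilities come from the max-|t| null of the multivariate t
    with common within-group df, integrated with a seeded RNG so results
    are reproducible.
    """
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing")
    control = np.asarray(groups[control_label], dtype=float)
    labels = [k for k in groups if k != control_label]
    if not labels:
        raise ValueError("need at least one non-control group")
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    res = sps.dunnett(*samples, control=control, alternative="two-sided",
                      random_state=np.random.default_rng(seed))
    return {lab: float(p) for lab, p in zip(labels, res.pvalue)}


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# endpoint-level convenience chain
# ---------------------------------------------------------------------------

def batch_means(group: GroupData, transform: bool = True) -> np.ndarray:
    """Batch-level means of (sqrt-transformed) per-cell values."""
    out = []
    for _batch, vals in sorted(group.batches.items()):
        v = stabilize(vals) if transform else np.asarray(vals, dtype=float)
        out.append(float(np.mean(v)))
    return np.asarray(out)


def analyze_endpoint(groups: list[GroupData], control_label: str,
                     seed: int = 0, transform: bool = True) -> AnovaResult:
    """Full chain: sqrt -> batch means -> Bartlett -> ANOVA -> Dunnett."""
    by_label = {g.treatment_label: batch_means(g, transform=transform)
                for g in groups}
    arrays = list(by_label.values())
    try:
        b_stat, b_p = bartlett(arrays)
    except DegenerateVarianceError:
        b_stat, b_p = float("nan"), float("nan")
    res = anova_oneway(arrays)
    res.bartlett_stat, res.bartlett_p = b_stat, b_p
    res.comparisons = dunnett(by_label, control_label, seed=seed)
    return res


def endpoint_table_to_groups(endpoints: pd.DataFrame,
                             value_col: str = "puncta_count_norm"
                             ) -> list[GroupData]:
    """Convert a tidy per-field endpoint table into GroupData objects.

    Expects columns ``treatment``, ``batch`` and ``value_col``; each field
    (well-level cell recording) contributes one value to its batch.
    """
    groups = []
    for treatment, sub in endpoints.groupby("treatment", sort=True):
        batches = {str(b): list(map(float, bs[value_col]))
                   for b, bs in sub.groupby("batch", sort=True)}
        groups.append(GroupData(treatment_label=str(treatment),
                                batches=batches))
    return groups
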