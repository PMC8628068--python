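"""Group-comparison and correlation statistics used by the screens.

Thin, contract-checked wrappers: classical one-way ANOVA, Tukey HSD
pairwise contrasts (family-wise error controlled through the studentized
range distribution), and Spearman rank correlation with average ranks for
ties.  For short vectors (n < 10, the size of the feature-vs-cost screens)
the Spearman p value is computed by exact permutation instead of the
large-sample t approximation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "one_way_anova",
    "tukey_pairwise",
    "tukey_vs_control",
    "spearman",
]

#: below this sample size the Spearman p value is computed by exact permutation
EXACT_SPEARMAN_N = 10


@dataclass(frozen=True)
class StatResult:
    """One test's outcome: the statistic (F or rho), df, and p value."""

    statistic: float
    p: float
    df: Optional[tuple] = None
    adjusted: bool = False
    contrast: Optional[tuple] = None
    kind: str = ""

    def __post_init__(self):
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p value outside [0, 1]: {self.p}")


def _check_groups(groups: Sequence[Sequence[float]], min_size: int = 2):
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for i, a in enumerate(arrays):
        if a.ndim != 1 or a.size < min_size:
            raise ValueError(f"group {i} needs >= {min_size} values, got {a.size}")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {i} contains non-finite values")
    return arrays


def one_way_anova(groups: Sequence[Sequence[float]]) -> StatResult:
    """Classical (non-Welch) one-way ANOVA across k groups.

    F is the between/within mean-square ratio with df = (k - 1, N - k).
    Identical groups give F = 0, p = 1.
    """
    arrays = _check_groups(groups)
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    if np.ptp(np.concatenate(arrays)) == 0:
        # all values equal: no variance anywhere, define F = 0 (no group effect)
        return StatResult(0.0, 1.0, df=(k - 1, n_total - k), kind="anova")
    f, p = sps.f_oneway(*arrays)
    if not np.isfinite(f):  # zero within-group variance with group differences
        raise ValueError("degenerate groups: zero within-group variance")
    return StatResult(float(f), float(p), df=(k - 1, n_total - k), kind="anova")


def tukey_pairwise(
    groups: Sequence[Sequence[float]], labels: Optional[Sequence] = None
) -> list[StatResult]:
    """All pairwise group contrasts with Tukey-HSD-adjusted p values.

    The adjustment uses the studentized range distribution over the whole
    family of pairwise comparisons, so the family-wise false-positive rate
    is controlled at alpha.  The returned statistic is the difference of
    group means for each contrast.
    """
    arrays = _check_groups(groups)
    if labels is None:
        labels = list(range(len(arrays)))
    if len(labels) != len(arrays):
        raise ValueError("labels must match groups")
    res = sps.tukey_hsd(*arrays)
    out = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        out.append(
            StatResult(
                statistic=float(res.statistic[i, j]),
                p=float(min(1.0, res.pvalue[i, j])),
                adjusted=True,
                contrast=(labels[i], labels[j]),
                kind="tukey",
            )
        )
    return out


def tukey_vs_control(
    groups: Sequence[Sequence[float]],
    labels: Sequence,
    control_label,
) -> dict:
    """Tukey-adjusted contrasts of every group against one control group.

    Identical to the corresponding subset of :func:`tukey_pairwise`
    (Tukey-Kramer studentized-range adjustment over the full family of
    ``k`` groups), but evaluates only the k-1 contrasts involving the
    control, which is much cheaper for large families.
    """
    arrays = _check_groups(groups)
    labels = list(labels)
    if len(labels) != len(arrays) or control_label not in labels:
        raise ValueError("labels must match groups and include the control")
    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    df_within = int(ns.sum() - k)
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_within
    ci = labels.index(control_label)
    out = {}
    for i, lab in enumerate(labels):
        if i == ci:
            continue
        diff = means[i] - means[ci]
        se = np.sqrt(mse / 2 * (1 / ns[i] + 1 / ns[ci]))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            p = float(sps.studentized_range.sf(abs(diff) / se, k, df_within))
        out[lab] = StatResult(
            statistic=float(diff),
            p=min(1.0, p),
            adjusted=True,
            contrast=(lab, control_label),
            kind="tukey",
        )
    return out


def _rank(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, method="average")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    sx, sy = np.std(rx), np.std(ry)
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation (average ranks for ties), two-sided p.

    For n < 10 the p value is the exact permutation probability of
    |rho| at least as large as observed; for larger n the standard
    t approximation is used.  A constant input vector yields rho = NaN
    with a warning rather than an error.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    rx, ry = _rank(xa), _rank(ya)
    rho = _rho_of_ranks(rx, ry)
    if np.isnan(rho):
        warnings.warn("constant input vector: Spearman rho undefined", stacklevel=2)
        return StatResult(np.nan, np.nan, kind="spearman")
    if n < EXACT_SPEARMAN_N:
        perms = np.array(list(itertools.permutations(ry)), dtype=float)
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        num = pc @ rxc
        den = np.sqrt((rxc**2).sum() * (pc**2).sum(axis=1))
        rhos = num / den
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = float(sps.spearmanr(xa, ya).pvalue)
    return StatResult(float(rho), p, df=(n - 2,), kind="spearman")
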