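"""Multiplicative-null epistasis between plasmid carriage and host mutations.

Under the multiplicative null model, the fitness of a strain carrying both
a plasmid and a chromosomal mutation is the product of the two marginal
effects measured separately (each relative to the plasmid-free wild type).
Epistasis is the deviation from that expectation:

    epsilon = W(plasmid;mutation) - W(plasmid;-) * W(-;mutation)

where the marginal terms are medians over replicates.  Positive epsilon
means the combination is fitter than expected (the plasmid is *less*
costly in the mutant background), negative epsilon means synergistic
costs.  Replicate-level epsilon values (each replicate's W minus the
product of marginal medians) are compared against the wild-type group —
whose median epsilon is zero by construction — with a one-way ANOVA
followed by Tukey's test, giving multiplicity-adjusted p values.

Sign epistasis is called when the double-determinant strain is
significantly fitter than BOTH single-determinant strains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .fitness import median
from .stats import StatResult, tukey_vs_control

__all__ = [
    "EpistasisResult",
    "expected_fitness",
    "epistasis",
    "epistasis_replicates",
    "classify_epistasis",
    "test_sign_epistasis",
    "bootstrap_epistasis_test",
]


@dataclass(frozen=True)
class EpistasisResult:
    """Observed vs expected fitness and epistasis call for one combination."""

    plasmid: Optional[str]
    mutation: Optional[str]
    w_observed: float
    w_expected: float
    epsilon: float
    classification: str  # none | positive | negative
    adjusted_p: float
    sign_epistasis: Optional[bool] = None
    epsilon_replicates: tuple = field(default_factory=tuple)

    @property
    def genotype(self) -> tuple:
        return (self.plasmid, self.mutation)


def _check_positive(name: str, value: float):
    if not (value > 0):
        raise ValueError(f"{name} must be > 0, got {value}")


def expected_fitness(w_plasmid: float, w_mutation: float) -> float:
    """Multiplicative-null expectation: product of the two marginal effects."""
    _check_positive("w_plasmid", w_plasmid)
    _check_positive("w_mutation", w_mutation)
    return w_plasmid * w_mutation


def epistasis(w_combination: float, w_plasmid: float, w_mutation: float) -> float:
    """epsilon = observed combination fitness minus the multiplicative expectation."""
    _check_positive("w_combination", w_combination)
    return w_combination - expected_fitness(w_plasmid, w_mutation)


def epistasis_replicates(
    replicates: Sequence[float], w_plasmid_median: float, w_mutation_median: float
) -> np.ndarray:
    """Per-replicate epsilon: each replicate W minus the product of marginal medians.

    The marginals are medians (not replicate-paired); for the wild-type
    strain both marginals are 1 so the values reduce to W - 1, and the
    group's median epsilon is exactly 0 because its W median is 1 after
    self-normalization.
    """
    arr = np.asarray(list(replicates), dtype=float)
    if arr.size == 0:
        raise ValueError("empty replicate set")
    _check_positive("w_plasmid_median", w_plasmid_median)
    _check_positive("w_mutation_median", w_mutation_median)
    return arr - w_plasmid_median * w_mutation_median


def classify_epistasis(
    epsilon_groups: Dict[object, Sequence[float]],
    wildtype_key: object,
    alpha: float = 0.05,
) -> Dict[object, tuple[str, float]]:
    """Classify each genotype's epistasis against the wild-type group.

    Runs a one-way ANOVA across all epsilon groups (wild type included),
    then Tukey-adjusted contrasts of every group against the wild-type
    group.  A genotype is called positive/negative by the sign of its
    median epsilon when its Tukey contrast is significant at ``alpha``;
    otherwise "none".  The Tukey adjustment already controls the
    family-wise error, so no additional omnibus gate is applied.

    Returns a map genotype -> (classification, Tukey-adjusted p).
    """
    if wildtype_key not in epsilon_groups:
        raise ValueError(f"wild-type key {wildtype_key!r} missing from groups")
    keys = list(epsilon_groups)
    groups = [np.asarray(epsilon_groups[k], dtype=float) for k in keys]
    if len(groups) < 2:
        raise ValueError("need the wild type plus at least one other group")
    contrasts = tukey_vs_control(groups, labels=keys, control_label=wildtype_key)
    p_vs_wt = {k: c.p for k, c in contrasts.items()}
    out = {}
    for k in keys:
        if k == wildtype_key:
            continue
        p = p_vs_wt[k]
        med = median(epsilon_groups[k])
        if p < alpha:
            if med > 0:
                cls = "positive"
            elif med < 0:
                cls = "negative"
            else:
                warnings.warn(
                    f"genotype {k!r}: significant contrast with median epsilon "
                    "exactly 0; classified 'none'",
                    stacklevel=2,
                )
                cls = "none"
        else:
            cls = "none"
        out[k] = (cls, p)
    return out


def test_sign_epistasis(
    combination: Sequence[float],
    plasmid_free_mutant: Sequence[float],
    plasmid_carrying_wildtype: Sequence[float],
    alpha: float = 0.05,
) -> tuple[bool, dict]:
    """Test whether the double-determinant strain beats both single-determinant strains.

    Fitness replicates of the three strains (all at the same normalization
    level) enter a one-way ANOVA + Tukey family; sign epistasis is called
    when the combination's median exceeds both singles and both Tukey
    contrasts are significant at ``alpha``.
    """
    labels = ["combination", "mutant", "carrier"]
    groups = [
        np.asarray(combination, dtype=float),
        np.asarray(plasmid_free_mutant, dtype=float),
        np.asarray(plasmid_carrying_wildtype, dtype=float),
    ]
    for name, g in zip(labels, groups):
        if g.size == 0:
            raise ValueError(f"empty group: {name}")
    contrasts = tukey_vs_control(groups, labels=labels, control_label="combination")
    p_mut = contrasts["mutant"].p
    p_car = contrasts["carrier"].p
    med_c = median(groups[0])
    higher = med_c > median(groups[1]) and med_c > median(groups[2])
    result = bool(higher and p_mut < alpha and p_car < alpha)
    return result, {"p_vs_mutant": p_mut, "p_vs_carrier": p_car}


def bootstrap_epistasis_test(
    combination: Sequence[float],
    plasmid: Sequence[float],
    mutation: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
) -> StatResult:
    """Error-propagation cross-check for one combination's epsilon.

    Approximates the sampling distribution of
    median(combination) - median(plasmid) * median(mutation)
    by bootstrap resampling of the three replicate sets, and returns a
    normal-approximation two-sided p value for epsilon = 0.  This is an
    optional alternative to the ANOVA/Tukey classification, not the
    default path.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    c = np.asarray(combination, dtype=float)
    p = np.asarray(plasmid, dtype=float)
    m = np.asarray(mutation, dtype=float)
    eps_hat = median(c) - median(p) * median(m)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = np.median(rng.choice(c, c.size)) - np.median(
            rng.choice(p, p.size)
        ) * np.median(rng.choice(m, m.size))
    se = float(np.std(boots, ddof=1))
    if se == 0:
        pv = 0.0 if eps_hat != 0 else 1.0
    else:
        pv = float(2 * sps.norm.sf(abs(eps_hat) / se))
    return StatResult(eps_hat, min(1.0, pv), kind="epistasis-bootstrap")
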