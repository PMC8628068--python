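"""Relative fitness from head-to-head competition assays.

A test strain (GFP-negative) is competed 1:1 against a GFP-tagged common
reference; cell numbers of both competitors are measured by flow cytometry
before and after one cycle of batch growth.  The relative fitness of the
test strain is the ratio of the log fold-changes of the two competitors,

    W = ln(N_final,gfp- / N_initial,gfp-) / ln(N_final,gfp+ / N_initial,gfp+)

with W = 1 meaning neutrality.  Raw W values (level ``vs_gfp_reference``)
are then normalized in a fixed two-step cascade:

1. ``vs_plasmid_free_wildtype`` — the median W of the test strain's
   replicates is divided by the median W of the plasmid-free wild-type
   competed against the same reference, removing the cost of the GFP tag.
2. ``vs_plasmid_carrying_wildtype`` — optionally, values are further
   divided by the fitness of the plasmid-carrying wild type, to compare
   plasmid costs across mutant backgrounds.

All four counts must be expressed on a common per-timepoint scale (actual
cell numbers, or cytometry proportions multiplied by the culture size).
W is invariant to rescaling both counts of one competitor by a constant,
and to rescaling all four counts jointly; it is *not* invariant to
independent rescaling of the two timepoints, which is why proportions
alone do not determine W.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "LEVELS",
    "CompetitionRecord",
    "FitnessEstimate",
    "DegenerateRecordError",
    "relative_fitness",
    "normalize_to_plasmid_free",
    "normalize_to_plasmid_carrier",
    "percent_cost",
    "median",
]

#: Normalization levels in the (fixed) order the cascade applies them.
LEVELS = (
    "vs_gfp_reference",
    "vs_plasmid_free_wildtype",
    "vs_plasmid_carrying_wildtype",
)


class DegenerateRecordError(ValueError):
    """A competition record cannot yield a finite fitness value."""


@dataclass(frozen=True)
class CompetitionRecord:
    """One replicate's competitor cell numbers before and after competition.

    Counts may be on any common scale (events rescaled to culture size,
    CFU, ...) as long as initial and final counts within the record share
    that scale per competitor.  Optional ``latent_*`` fields carry the
    noise-free pre-sampling numbers when the record comes from the
    simulator.
    """

    n_initial_gfp_neg: float
    n_initial_gfp_pos: float
    n_final_gfp_neg: float
    n_final_gfp_pos: float
    plasmid: Optional[str] = None
    mutation: Optional[str] = None
    replicate: object = None
    latent_initial_gfp_neg: Optional[float] = None
    latent_initial_gfp_pos: Optional[float] = None
    latent_final_gfp_neg: Optional[float] = None
    latent_final_gfp_pos: Optional[float] = None

    @property
    def genotype(self) -> tuple:
        return (self.plasmid, self.mutation)

    def counts(self) -> tuple:
        return (
            self.n_initial_gfp_neg,
            self.n_initial_gfp_pos,
            self.n_final_gfp_neg,
            self.n_final_gfp_pos,
        )

    def latent_record(self) -> "CompetitionRecord":
        """Return a record whose primary counts are the latent (noise-free) ones."""
        if self.latent_initial_gfp_neg is None:
            raise ValueError("record carries no latent counts")
        return replace(
            self,
            n_initial_gfp_neg=self.latent_initial_gfp_neg,
            n_initial_gfp_pos=self.latent_initial_gfp_pos,
            n_final_gfp_neg=self.latent_final_gfp_neg,
            n_final_gfp_pos=self.latent_final_gfp_pos,
        )


@dataclass(frozen=True)
class FitnessEstimate:
    """A relative fitness value W together with its normalization level."""

    w: float
    level: str = "vs_gfp_reference"
    plasmid: Optional[str] = None
    mutation: Optional[str] = None
    replicate: object = None
    aggregate: bool = False
    replicates: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown normalization level {self.level!r}")
        # W <= 0 is a measurable outcome (the test strain declined in
        # absolute numbers), so only finiteness is enforced here; the
        # normalization steps require positive medians where they divide.
        if not math.isfinite(self.w):
            raise ValueError(f"relative fitness must be finite, got {self.w}")

    @property
    def genotype(self) -> tuple:
        return (self.plasmid, self.mutation)


def median(values: Sequence[float]) -> float:
    """Median; for an even count, the mean of the two central order statistics."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median of empty sequence")
    return float(np.median(arr))


def relative_fitness(
    record: CompetitionRecord, *, pseudocount: bool = False
) -> FitnessEstimate:
    """Compute W for one competition replicate (level ``vs_gfp_reference``).

    Parameters
    ----------
    record:
        Competitor counts on a common scale; all four must be positive.
    pseudocount:
        If True, zero counts are replaced by 1 event before computing W
        instead of raising.  Off by default because silent pseudocounts
        distort small competitions.

    Raises
    ------
    DegenerateRecordError
        If a count is zero (without ``pseudocount``), negative, or the
        reference fold-change is 1 (zero denominator).
    """
    counts = list(record.counts())
    for i, c in enumerate(counts):
        if c is None or not math.isfinite(float(c)) or c < 0:
            raise DegenerateRecordError(
                f"invalid count in record {record.replicate!r} "
                f"(genotype {record.genotype}): {counts}"
            )
        if c == 0:
            if pseudocount:
                counts[i] = 1.0
            else:
                raise DegenerateRecordError(
                    f"zero count in record {record.replicate!r} "
                    f"(genotype {record.genotype}); pass pseudocount=True "
                    "to substitute one event"
                )
    ni_neg, ni_pos, nf_neg, nf_pos = counts
    denom = math.log(nf_pos / ni_pos)
    if denom == 0.0:
        raise DegenerateRecordError(
            f"reference competitor shows no net growth in record "
            f"{record.replicate!r} (genotype {record.genotype}); W undefined"
        )
    w = math.log(nf_neg / ni_neg) / denom
    return FitnessEstimate(
        w=w,
        level="vs_gfp_reference",
        plasmid=record.plasmid,
        mutation=record.mutation,
        replicate=record.replicate,
    )


def _ws(estimates: Sequence[FitnessEstimate], level: str) -> np.ndarray:
    if len(estimates) == 0:
        raise ValueError("empty fitness estimate set")
    for e in estimates:
        if e.level != level:
            raise ValueError(
                f"expected level {level!r}, got {e.level!r} for genotype {e.genotype}"
            )
    return np.array([e.w for e in estimates], dtype=float)


def normalize_to_plasmid_free(
    test: Sequence[FitnessEstimate], control: Sequence[FitnessEstimate]
) -> FitnessEstimate:
    """Normalize a replicate set by the plasmid-free wild-type control.

    Returns an aggregate estimate whose ``w`` is median(test)/median(control)
    and whose ``replicates`` are each test replicate divided by the control
    median (replicates are not paired with control replicates).
    """
    tw = _ws(test, "vs_gfp_reference")
    cw = _ws(control, "vs_gfp_reference")
    cmed = median(cw)
    if cmed <= 0:
        raise ValueError(f"control median must be > 0, got {cmed}")
    per_rep = tuple(float(v) for v in tw / cmed)
    first = test[0]
    return FitnessEstimate(
        w=median(tw) / cmed,
        level="vs_plasmid_free_wildtype",
        plasmid=first.plasmid,
        mutation=first.mutation,
        aggregate=True,
        replicates=per_rep,
    )


def normalize_to_plasmid_carrier(
    combination: FitnessEstimate, carrier: FitnessEstimate
) -> FitnessEstimate:
    """Express a combination's fitness relative to the plasmid-carrying wild type.

    Element-wise division of the combination's aggregate value and its
    per-replicate values by the carrier's (aggregate) fitness, both at
    level ``vs_plasmid_free_wildtype``.
    """
    for e, name in ((combination, "combination"), (carrier, "carrier")):
        if e.level != "vs_plasmid_free_wildtype":
            raise ValueError(
                f"{name} must be at level 'vs_plasmid_free_wildtype', got {e.level!r}"
            )
    if carrier.w <= 0:
        raise ValueError(f"carrier fitness must be > 0, got {carrier.w}")
    return FitnessEstimate(
        w=combination.w / carrier.w,
        level="vs_plasmid_carrying_wildtype",
        plasmid=combination.plasmid,
        mutation=combination.mutation,
        aggregate=True,
        replicates=tuple(v / carrier.w for v in combination.replicates),
    )


def percent_cost(w: float) -> float:
    """Fitness cost as a percentage: (1 - W) x 100.

    Negative values denote a fitness benefit (e.g. W = 1.51 is a 51%
    advantage, reported as -51%).
    """
    if not (w > 0):
        raise ValueError(f"relative fitness must be > 0, got {w}")
    return (1.0 - w) * 100.0
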