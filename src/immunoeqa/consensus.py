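"""Assigned-value determination for proficiency-testing parameters.

A proficiency-testing provider must fix, for every sample and analyte, the
value against which participants are scored.  Three routes are supported:

* **Reference** — an organiser / reference-laboratory value is taken as
  correct outright (the rule used for DNA-based typing schemes).
* **Consensus** — qualitative parameters are assigned by participant
  consensus.  Antibody specificities use the two-sided rule: a specificity
  is *positive* when at least 75% of laboratories report it, *negative*
  when at least 95% omit it, a *non-assessable negative* (never penalised)
  when omitted by 75–95%, and has *no consensus* otherwise.
* **Robust statistics** — the only quantitative parameter (percentage
  recipient chimerism) is assigned a robust location x* and scale s* by
  the ISO 13528 Annex C "Algorithm A": start from the median and the
  scaled MAD (factor 1.483), then repeatedly winsorise at x* +/- 1.5 s*
  and recompute the mean and 1.134-scaled standard deviation of the
  winsorised values until both estimates stabilise.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .nomenclature import Genotype, genotype_concordant

__all__ = [
    "ConsensusParams",
    "RobustStats",
    "AssignedMode",
    "AntibodyStatus",
    "QualStatus",
    "AssignedValue",
    "InsufficientData",
    "EmptyPanel",
    "NoData",
    "OutOfRangeValue",
    "robust_location_scale",
    "antibody_consensus",
    "typing_assigned_value",
    "qualitative_consensus",
    "chimerism_assigned",
]


class InsufficientData(ValueError):
    pass


class EmptyPanel(ValueError):
    pass


class NoData(ValueError):
    pass


class OutOfRangeValue(ValueError):
    pass


class AssignedMode(str, enum.Enum):
    REFERENCE = "REFERENCE"
    CONSENSUS = "CONSENSUS"
    NOT_EVALUABLE = "NOT_EVALUABLE"


class AntibodyStatus(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    NON_ASSESSABLE = "NON_ASSESSABLE"
    NO_CONSENSUS = "NO_CONSENSUS"


class QualStatus(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


@dataclass(frozen=True)
class ConsensusParams:
    """Thresholds and numeric constants for assigned-value determination.

    ``pos_threshold`` is the participant fraction required for a positive
    consensus ("at least 75%"); ``neg_threshold`` the omission fraction
    required for a negative consensus ("95% not reporting").  The scale
    constants are the Algorithm A values: 1.483 rescales the median
    absolute deviation, 1.134 rescales the winsorised standard deviation,
    and winsorisation clips at 1.5 robust standard deviations.
    """

    pos_threshold: float = 0.75
    neg_threshold: float = 0.95
    typing_threshold: float = 0.75
    winsor_factor: float = 1.5
    mad_scale: float = 1.483
    winsor_sd_scale: float = 1.134
    tol: float = 1e-6
    max_iter: int = 100
    min_consensus_n: int = 3

    def __post_init__(self) -> None:
        if not (0.5 < self.pos_threshold <= self.neg_threshold <= 1.0):
            raise ValueError("need 0.5 < pos_threshold <= neg_threshold <= 1")
        if min(self.winsor_factor, self.mad_scale, self.winsor_sd_scale) <= 0:
            raise ValueError("scale constants must be positive")


@dataclass(frozen=True)
class RobustStats:
    """Robust location/scale of one quantitative parameter."""

    x_star: float
    s_star: float
    n: int
    iterations: int
    converged: bool


@dataclass(frozen=True)
class AssignedValue:
    """Per-(sample, parameter) truth used for scoring.

    ``payload`` is a :class:`Genotype`, a :class:`QualStatus`, a mapping
    specificity -> :class:`AntibodyStatus`, a :class:`RobustStats`, or a
    risk-category label, depending on the parameter kind.  ``support`` is
    the consensus fraction backing the value (1.0 for reference values).
    """

    parameter: str
    mode: AssignedMode
    payload: object = None
    support: Optional[float] = None
    n: int = 0

    def __post_init__(self) -> None:
        if self.mode is AssignedMode.NOT_EVALUABLE and self.payload is not None:
            raise ValueError("NOT_EVALUABLE assigned values carry no payload")


# ---------------------------------------------------------------------------
# robust location / scale (ISO 13528 Annex C, Algorithm A)
# ---------------------------------------------------------------------------

def robust_location_scale(
    values: Sequence[float], params: ConsensusParams = ConsensusParams()
) -> RobustStats:
    """Iterative winsorised robust mean and standard deviation.

    Initialise x* = median, s* = 1.483 * median(|x_i - x*|); then iterate
    clipping to x* +/- 1.5 s*, x* = mean(clipped), s* = 1.134 * sd(clipped)
    until both move by less than ``tol * max(s*, tol)``.  A degenerate
    scale (s* = 0, at least half the values identical) stops immediately:
    the winsorised band is empty and the estimates cannot move.
    """
    xs = [float(v) for v in values]
    if len(xs) < 1:
        raise InsufficientData("robust statistics need at least one value")
    if len(xs) == 1:
        return RobustStats(xs[0], 0.0, 1, 0, True)

    x_star = statistics.median(xs)
    s_star = params.mad_scale * statistics.median(abs(x - x_star) for x in xs)
    if s_star == 0.0:
        return RobustStats(x_star, 0.0, len(xs), 0, True)

    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        delta = params.winsor_factor * s_star
        lo, hi = x_star - delta, x_star + delta
        clipped = [min(max(x, lo), hi) for x in xs]
        new_x = statistics.fmean(clipped)
        new_s = params.winsor_sd_scale * statistics.stdev(clipped)
        move = max(abs(new_x - x_star), abs(new_s - s_star))
        x_star, s_star = new_x, new_s
        if s_star == 0.0:
            converged = True
            break
        if move < params.tol * max(s_star, params.tol):
            converged = True
            break
    return RobustStats(x_star, s_star, len(xs), it, converged)


# ---------------------------------------------------------------------------
# antibody specificity consensus
# ---------------------------------------------------------------------------

def antibody_consensus(
    per_specificity_reports: Mapping[str, tuple[int, int]],
    params: ConsensusParams = ConsensusParams(),
) -> dict[str, AntibodyStatus]:
    """Consensus status per antibody specificity.

    ``per_specificity_reports`` maps specificity -> (n_positive, n_total),
    the number of laboratories reporting the specificity as positive and
    the number of evaluable panel returns.  With the default thresholds
    the positive fraction p partitions into NEGATIVE (p <= 0.05),
    NON_ASSESSABLE (0.05 < p <= 0.25), NO_CONSENSUS (0.25 < p < 0.75) and
    POSITIVE (p >= 0.75); all boundary comparisons are inclusive per the
    "at least" wording of the rules.
    """
    out: dict[str, AntibodyStatus] = {}
    for spec, (n_pos, n_total) in per_specificity_reports.items():
        if n_total < 1:
            raise EmptyPanel(f"specificity {spec!r} has no evaluable reports")
        if not 0 <= n_pos <= n_total:
            raise ValueError(f"bad counts for {spec!r}: {n_pos}/{n_total}")
        p = n_pos / n_total
        q = 1.0 - p
        if p >= params.pos_threshold:
            out[spec] = AntibodyStatus.POSITIVE
        elif q >= params.neg_threshold:
            out[spec] = AntibodyStatus.NEGATIVE
        elif params.pos_threshold <= q < params.neg_threshold:
            out[spec] = AntibodyStatus.NON_ASSESSABLE
        else:
            out[spec] = AntibodyStatus.NO_CONSENSUS
    return out


# ---------------------------------------------------------------------------
# genotype consensus
# ---------------------------------------------------------------------------

def _mutually_concordant(a: Genotype, b: Genotype) -> bool:
    # Concordant in either direction: equal at the shared resolution.
    return genotype_concordant(a, b) or genotype_concordant(b, a)


def typing_assigned_value(
    reports: Sequence[Genotype],
    reference: Optional[Genotype] = None,
    params: ConsensusParams = ConsensusParams(),
    parameter: str = "",
) -> AssignedValue:
    """Assigned genotype: organiser reference if present, else consensus.

    Without a reference, reports are grouped into concordance classes
    (every member mutually concordant with every other at their shared
    resolution); the modal class wins if its frequency reaches
    ``typing_threshold``, and its highest-resolution member is the
    assigned genotype.  Ties or insufficient support -> NOT_EVALUABLE.
    """
    if reference is not None:
        return AssignedValue(
            parameter=parameter,
            mode=AssignedMode.REFERENCE,
            payload=reference,
            support=1.0,
            n=len(reports),
        )
    if not reports:
        raise NoData("no reports and no reference genotype")
    classes: list[list[Genotype]] = []
    for g in reports:
        placed = False
        for cls in classes:
            if all(_mutually_concordant(g, m) for m in cls):
                cls.append(g)
                placed = True
                break
        if not placed:
            classes.append([g])
    classes.sort(key=len, reverse=True)
    top = classes[0]
    support = len(top) / len(reports)
    tied = len(classes) > 1 and len(classes[1]) == len(top)
    if support < params.typing_threshold or tied:
        return AssignedValue(
            parameter=parameter, mode=AssignedMode.NOT_EVALUABLE, n=len(reports)
        )
    best = max(
        top, key=lambda g: (min(a.resolution for a in g.all_alternatives()), g.render())
    )
    return AssignedValue(
        parameter=parameter,
        mode=AssignedMode.CONSENSUS,
        payload=best,
        support=support,
        n=len(reports),
    )


def qualitative_consensus(
    calls: Sequence[QualStatus | str],
    params: ConsensusParams = ConsensusParams(),
    parameter: str = "",
) -> AssignedValue:
    """Majority consensus for a positive/negative call (crossmatch,
    antigen presence, screening): assigned when the majority status
    reaches the positive-consensus threshold."""
    if not calls:
        raise NoData("no qualitative calls")
    statuses = [QualStatus(c) for c in calls]
    n = len(statuses)
    n_pos = sum(1 for s in statuses if s is QualStatus.POSITIVE)
    frac_pos = n_pos / n
    frac_neg = 1.0 - frac_pos
    if frac_pos >= params.pos_threshold:
        return AssignedValue(
            parameter=parameter,
            mode=AssignedMode.CONSENSUS,
            payload=QualStatus.POSITIVE,
            support=frac_pos,
            n=n,
        )
    if frac_neg >= params.pos_threshold:
        return AssignedValue(
            parameter=parameter,
            mode=AssignedMode.CONSENSUS,
            payload=QualStatus.NEGATIVE,
            support=frac_neg,
            n=n,
        )
    return AssignedValue(parameter=parameter, mode=AssignedMode.NOT_EVALUABLE, n=n)


def chimerism_assigned(
    values: Sequence[float],
    params: ConsensusParams = ConsensusParams(),
    parameter: str = "",
) -> AssignedValue:
    """Robust consensus for percentage recipient chimerism.

    Values must lie in [0, 100]; fewer than ``min_consensus_n`` returns
    cannot support a consensus and the parameter is not evaluable.
    """
    for v in values:
        if not 0.0 <= float(v) <= 100.0:
            raise OutOfRangeValue(f"chimerism value {v!r} outside [0, 100]")
    if len(values) < params.min_consensus_n:
        return AssignedValue(
            parameter=parameter, mode=AssignedMode.NOT_EVALUABLE, n=len(values)
        )
    stats = robust_location_scale(values, params)
    return AssignedValue(
        parameter=parameter,
        mode=AssignedMode.CONSENSUS,
        payload=stats,
        support=None,
        n=stats.n,
    )
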