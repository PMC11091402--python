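"""Scoring of laboratory results against assigned values.

Each result becomes exactly one :class:`Evaluation` — CORRECT, ERROR (with
one error category) or NOT_EVALUABLE (no assigned value; never penalised
and never counted in a success-rate denominator).

Typing errors follow a fixed decision order so the taxonomy partitions the
error space: unparseable report -> NOMENCLATURE; unresolved null-allele
ambiguity against an expressed assigned genotype -> NULL_ALLELE; otherwise
concordance; a single distinct allele reported where the assigned genotype
is heterozygous -> HOMOZYGOSITY; anything else -> ALLELE_MISMATCH (the
"random" wrong-allele residual).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

from .consensus import (
    AssignedMode,
    AssignedValue,
    AntibodyStatus,
    OutOfRangeValue,
    QualStatus,
    RobustStats,
)
from .nomenclature import (
    Genotype,
    LocusMismatch,
    MalformedAllele,
    MalformedGenotype,
    genotype_concordant,
    parse_genotype,
    unexcluded_null,
)

__all__ = [
    "Status",
    "ErrorCategory",
    "Evaluation",
    "RiskMap",
    "RiskRule",
    "ScoringParams",
    "UnknownSpecificity",
    "UnmappedGenotype",
    "NoValidResults",
    "evaluate_typing",
    "evaluate_antibody",
    "evaluate_screening",
    "evaluate_chimerism",
    "evaluate_qualitative",
    "evaluate_risk",
    "scheme_pass",
]


class UnknownSpecificity(ValueError):
    pass


class UnmappedGenotype(KeyError):
    pass


class NoValidResults(ValueError):
    pass


class Status(str, enum.Enum):
    CORRECT = "CORRECT"
    ERROR = "ERROR"
    NOT_EVALUABLE = "NOT_EVALUABLE"


class ErrorCategory(str, enum.Enum):
    NULL_ALLELE = "NULL_ALLELE"
    HOMOZYGOSITY = "HOMOZYGOSITY"
    ALLELE_MISMATCH = "ALLELE_MISMATCH"
    NOMENCLATURE = "NOMENCLATURE"
    FALSE_POSITIVE_SPECIFICITY = "FALSE_POSITIVE_SPECIFICITY"
    FALSE_NEGATIVE_SPECIFICITY = "FALSE_NEGATIVE_SPECIFICITY"
    SCREENING = "SCREENING"
    QUANTIFICATION = "QUANTIFICATION"
    QUALITATIVE_MISMATCH = "QUALITATIVE_MISMATCH"
    RISK_INTERPRETATION = "RISK_INTERPRETATION"


@dataclass(frozen=True)
class Evaluation:
    """One scored laboratory result."""

    lab: str
    scheme: str
    year: int
    sample: str
    parameter: str
    status: Status
    category: Optional[ErrorCategory] = None

    def __post_init__(self) -> None:
        if (self.status is Status.ERROR) != (self.category is not None):
            raise ValueError("category present iff status is ERROR")


@dataclass(frozen=True)
class ScoringParams:
    """Acceptability knobs for scoring.

    ``z_limit`` is the acceptable robust z-score for the quantitative
    chimerism parameter; ``abs_tol`` (percentage points) replaces it when
    the robust scale is degenerate (s* = 0).  ``max_error_samples`` is the
    per-scheme-year pass rule: at most this many samples may contain an
    error.
    """

    z_limit: float = 2.0
    abs_tol: float = 5.0
    max_error_samples: int = 1


def _ctx(lab: str, scheme: str, year: int, sample: str) -> dict:
    return dict(lab=lab, scheme=scheme, year=year, sample=sample)


# ---------------------------------------------------------------------------
# typing
# ---------------------------------------------------------------------------

def evaluate_typing(
    report: Union[Genotype, str],
    assigned: AssignedValue,
    *,
    excluded_nulls: Iterable[str] = (),
    lab: str = "",
    scheme: str = "",
    year: int = 0,
    sample: str = "",
) -> Evaluation:
    """Score one genotype report against its assigned genotype.

    ``report`` may be a raw genotype string — parse failure is itself an
    error (NOMENCLATURE), not an exception.
    """
    base = dict(_ctx(lab, scheme, year, sample), parameter=assigned.parameter)
    if assigned.mode is AssignedMode.NOT_EVALUABLE or not isinstance(
        assigned.payload, Genotype
    ):
        return Evaluation(status=Status.NOT_EVALUABLE, **base)
    truth: Genotype = assigned.payload

    if isinstance(report, str):
        try:
            report = parse_genotype(report, excluded_nulls=excluded_nulls)
        except (MalformedGenotype, MalformedAllele):
            return Evaluation(
                status=Status.ERROR, category=ErrorCategory.NOMENCLATURE, **base
            )
    if report.locus != truth.locus:
        return Evaluation(
            status=Status.ERROR, category=ErrorCategory.NOMENCLATURE, **base
        )

    assigned_expressed = not any(a.is_null() for a in truth.all_alternatives())
    if assigned_expressed and any(unexcluded_null(c) for c in report.calls):
        return Evaluation(
            status=Status.ERROR, category=ErrorCategory.NULL_ALLELE, **base
        )

    if genotype_concordant(report, truth):
        return Evaluation(status=Status.CORRECT, **base)

    if report.is_homozygous_claim() and not truth.is_homozygous_claim():
        single = report.calls[0]
        matches_one = any(
            _allele_concordant_safe(r, t)
            for tc in truth.calls
            for r in single.alternatives
            for t in tc.alternatives
        )
        if matches_one:
            return Evaluation(
                status=Status.ERROR, category=ErrorCategory.HOMOZYGOSITY, **base
            )

    return Evaluation(
        status=Status.ERROR, category=ErrorCategory.ALLELE_MISMATCH, **base
    )


def _allele_concordant_safe(reported, truth) -> bool:
    from .nomenclature import concordant_allele

    try:
        return concordant_allele(reported, truth)
    except LocusMismatch:
        return False


# ---------------------------------------------------------------------------
# antibodies
# ---------------------------------------------------------------------------

def evaluate_antibody(
    reported_positive: Iterable[str],
    assigned_map: Mapping[str, AntibodyStatus],
    *,
    lab: str = "",
    scheme: str = "",
    year: int = 0,
    sample: str = "",
) -> list[Evaluation]:
    """Score a reported positive-specificity set against the panel consensus.

    One evaluation per panel specificity: a consensus-positive specificity
    omitted by the laboratory is a false negative; a consensus-negative
    one reported is a false positive; non-assessable negatives and
    no-consensus specificities are never penalised.
    """
    reported = {str(s).strip().upper() for s in reported_positive if str(s).strip()}
    panel = {str(s).strip().upper(): v for s, v in assigned_map.items()}
    unknown = reported - set(panel)
    if unknown:
        raise UnknownSpecificity(f"reported specificities not on panel: {sorted(unknown)}")
    out = []
    for spec in sorted(panel):
        status = panel[spec]
        base = dict(_ctx(lab, scheme, year, sample), parameter=f"specificity:{spec}")
        if status in (AntibodyStatus.NON_ASSESSABLE, AntibodyStatus.NO_CONSENSUS):
            out.append(Evaluation(status=Status.NOT_EVALUABLE, **base))
        elif status is AntibodyStatus.POSITIVE:
            if spec in reported:
                out.append(Evaluation(status=Status.CORRECT, **base))
            else:
                out.append(
                    Evaluation(
                        status=Status.ERROR,
                        category=ErrorCategory.FALSE_NEGATIVE_SPECIFICITY,
                        **base,
                    )
                )
        else:  # NEGATIVE
            if spec in reported:
                out.append(
                    Evaluation(
                        status=Status.ERROR,
                        category=ErrorCategory.FALSE_POSITIVE_SPECIFICITY,
                        **base,
                    )
                )
            else:
                out.append(Evaluation(status=Status.CORRECT, **base))
    return out


def evaluate_screening(
    reported: QualStatus | str,
    assigned: AssignedValue,
    *,
    lab: str = "",
    scheme: str = "",
    year: int = 0,
    sample: str = "",
) -> Evaluation:
    """Anti-class I/II screening call: qualitative match, SCREENING category."""
    ev = evaluate_qualitative(
        reported, assigned, lab=lab, scheme=scheme, year=year, sample=sample
    )
    if ev.status is Status.ERROR:
        ev = replace(ev, category=ErrorCategory.SCREENING)
    return ev


# ---------------------------------------------------------------------------
# chimerism
# ---------------------------------------------------------------------------

def evaluate_chimerism(
    value: float,
    assigned: AssignedValue | RobustStats,
    params: ScoringParams = ScoringParams(),
    *,
    lab: str = "",
    scheme: str = "",
    year: int = 0,
    sample: str = "",
) -> Evaluation:
    """Score a quantitative chimerism result by robust z-score.

    |z| = |value - x*| / s* must not exceed ``z_limit``; when the robust
    scale collapsed to zero an absolute tolerance of ``abs_tol``
    percentage points applies instead.
    """
    v = float(value)
    if not 0.0 <= v <= 100.0:
        raise OutOfRangeValue(f"chimerism value {v!r} outside [0, 100]")
    parameter = "chimerism"
    if isinstance(assigned, AssignedValue):
        parameter = assigned.parameter or parameter
        base = dict(_ctx(lab, scheme, year, sample), parameter=parameter)
        if assigned.mode is AssignedMode.NOT_EVALUABLE or not isinstance(
            assigned.payload, RobustStats
        ):
            return Evaluation(status=Status.NOT_EVALUABLE, **base)
        stats = assigned.payload
    else:
        stats = assigned
        base = dict(_ctx(lab, scheme, year, sample), parameter=parameter)
    if stats.s_star > 0:
        ok = abs(v - stats.x_star) / stats.s_star <= params.z_limit
    else:
        ok = abs(v - stats.x_star) <= params.abs_tol
    if ok:
        return Evaluation(status=Status.CORRECT, **base)
    return Evaluation(
        status=Status.ERROR, category=ErrorCategory.QUANTIFICATION, **base
    )


# ---------------------------------------------------------------------------
# qualitative calls
# ---------------------------------------------------------------------------

def evaluate_qualitative(
    reported: QualStatus | str,
    assigned: AssignedValue,
    *,
    category: ErrorCategory = ErrorCategory.QUALITATIVE_MISMATCH,
    lab: str = "",
    scheme: str = "",
    year: int = 0,
    sample: str = "",
) -> Evaluation:
    """Positive/negative call against its own assigned value.

    A whole-blood crossmatch is scored against the whole-blood consensus
    only — never against OR(T-cell, B-cell) — so the caller must pass the
    assigned value of the *same* parameter the laboratory reported.
    """
    base = dict(_ctx(lab, scheme, year, sample), parameter=assigned.parameter)
    if assigned.mode is AssignedMode.NOT_EVALUABLE or not isinstance(
        assigned.payload, QualStatus
    ):
        return Evaluation(status=Status.NOT_EVALUABLE, **base)
    if QualStatus(reported) is assigned.payload:
        return Evaluation(status=Status.CORRECT, **base)
    return Evaluation(status=Status.ERROR, category=category, **base)


# ---------------------------------------------------------------------------
# disease-risk interpretation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskRule:
    """One ordered pattern: all (locus, allele-prefix, min copies)
    requirements must hold for the rule's label to apply."""

    label: str
    requires: tuple[tuple[str, str, int], ...]


@dataclass(frozen=True)
class RiskMap:
    """Ordered genotype-pattern -> risk-category mapping.

    Rules are evaluated in order and the first match wins, which makes
    overlapping patterns disjoint by precedence; ``default`` applies when
    nothing matches.  Copy counting treats a homozygous genotype (single
    call) as two copies.
    """

    rules: tuple[RiskRule, ...]
    default: str

    def labels(self) -> list[str]:
        seen = dict.fromkeys([r.label for r in self.rules] + [self.default])
        return list(seen)

    @staticmethod
    def _copies(genotypes: Mapping[str, Genotype], locus: str, prefix: str) -> int:
        g = genotypes.get(locus)
        if g is None:
            raise UnmappedGenotype(locus)
        total = 0
        calls = g.calls if len(g.calls) == 2 else (g.calls[0], g.calls[0])
        for call in calls:
            if any(a.render().startswith(prefix.upper()) for a in call.alternatives):
                total += 1
        return total

    def classify(self, genotypes: Mapping[str, Genotype] | Genotype) -> str:
        if isinstance(genotypes, Genotype):
            genotypes = {genotypes.locus: genotypes}
        for rule in self.rules:
            if all(
                self._copies(genotypes, locus, prefix) >= n
                for locus, prefix, n in rule.requires
            ):
                return rule.label
        return self.default

    @classmethod
    def from_dict(cls, d: Mapping) -> "RiskMap":
        rules = tuple(
            RiskRule(
                label=r["label"],
                requires=tuple(
                    (req["locus"], req["prefix"], int(req.get("min_copies", 1)))
                    for req in r["requires"]
                ),
            )
            for r in d["rules"]
        )
        return cls(rules=rules, default=d["default"])


def evaluate_risk(
    report_genotypes: Mapping[str, Genotype] | Genotype,
    report_risk: str,
    assigned: Mapping[str, AssignedValue] | AssignedValue,
    risk_map: RiskMap,
    *,
    lab: str = "",
    scheme: str = "",
    year: int = 0,
    sample: str = "",
) -> list[Evaluation]:
    """Score a disease-association report: genotype(s) plus risk label.

    The genotype component is scored locus-by-locus with
    :func:`evaluate_typing`; the interpretation component compares the
    laboratory's risk label to ``risk_map`` applied to the *assigned*
    genotypes.  A genotype the map cannot classify makes the risk
    component NOT_EVALUABLE.
    """
    if isinstance(report_genotypes, Genotype):
        report_genotypes = {report_genotypes.locus: report_genotypes}
    if isinstance(assigned, AssignedValue):
        payload = assigned.payload
        if not isinstance(payload, Genotype):
            raise ValueError("assigned value must carry a genotype")
        assigned = {payload.locus: assigned}

    evals: list[Evaluation] = []
    assigned_genotypes: dict[str, Genotype] = {}
    for locus, av in assigned.items():
        if isinstance(av.payload, Genotype):
            assigned_genotypes[locus] = av.payload
        rep = report_genotypes.get(locus)
        if rep is not None:
            evals.append(
                evaluate_typing(
                    rep, av, lab=lab, scheme=scheme, year=year, sample=sample
                )
            )

    base = dict(_ctx(lab, scheme, year, sample), parameter="risk")
    try:
        expected = risk_map.classify(assigned_genotypes)
    except UnmappedGenotype:
        evals.append(Evaluation(status=Status.NOT_EVALUABLE, **base))
        return evals
    if str(report_risk).strip().lower() == expected.strip().lower():
        evals.append(Evaluation(status=Status.CORRECT, **base))
    else:
        evals.append(
            Evaluation(
                status=Status.ERROR,
                category=ErrorCategory.RISK_INTERPRETATION,
                **base,
            )
        )
    return evals


# ---------------------------------------------------------------------------
# per-lab scheme outcome
# ---------------------------------------------------------------------------

def scheme_pass(
    evals: Sequence[Evaluation], params: ScoringParams = ScoringParams()
) -> str:
    """PASS/FAIL for one laboratory x scheme x year.

    Default rule: PASS iff at most ``max_error_samples`` samples contain
    at least one error, after discarding NOT_EVALUABLE items.  A lab with
    no valid results has no outcome.
    """
    valid = [e for e in evals if e.status is not Status.NOT_EVALUABLE]
    if not valid:
        raise NoValidResults("no valid evaluations for this lab/scheme/year")
    errored_samples = {e.sample for e in valid if e.status is Status.ERROR}
    return "PASS" if len(errored_samples) <= params.max_error_samples else "FAIL"
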