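"""Record-level pipeline: assign values, evaluate reports, read/write files.

This is the plumbing between the statistical core and the flat-file
interfaces: laboratory reports and organiser truths travel as CSV (one
row per reported parameter), panel definitions and risk maps as JSON, and
every stage is a pure function over lists of records so the CLI stays a
thin shell.

Parameter naming convention (the ``parameter`` CSV column):

``typing:<locus>``            genotype string (``+`` copies, ``/`` ambiguities)
``abid``                      ';'-joined reported-positive specificities
``specificity:<name>``        per-specificity assigned status / evaluation
``screening:<class>``         POSITIVE/NEGATIVE antibody screening call
``xm:{whole,t,b}``            crossmatch calls (whole blood / T / B cells)
``presence``                  antigen/allele presence call (B27, B57)
``dqdp``                      two-antigen-bead DQ/DP interpretation call
``chimerism``                 % recipient (quantitative)
``chimerism_interpretation``  qualitative chimerism call
``risk``                      disease-risk category label
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .consensus import (
    AssignedMode,
    AssignedValue,
    AntibodyStatus,
    ConsensusParams,
    QualStatus,
    RobustStats,
    antibody_consensus,
    chimerism_assigned,
    qualitative_consensus,
    typing_assigned_value,
)
from .nomenclature import MalformedAllele, MalformedGenotype, parse_genotype
from .scoring import (
    ErrorCategory,
    Evaluation,
    RiskMap,
    ScoringParams,
    Status,
    evaluate_antibody,
    evaluate_chimerism,
    evaluate_qualitative,
    evaluate_screening,
    evaluate_typing,
    scheme_pass,
)
from .synthetic import (
    DEFAULT_ANTIBODY_PANELS,
    ReportRecord,
    TruthRecord,
    default_cd_risk_map,
)

__all__ = [
    "AssignedRecord",
    "REFERENCE_SCHEMES",
    "assign",
    "evaluate",
    "outcomes",
    "write_reports_csv",
    "read_reports_csv",
    "write_truth_csv",
    "read_truth_csv",
    "write_assigned_csv",
    "read_assigned_csv",
    "write_evaluations_csv",
    "read_evaluations_csv",
    "write_panel_json",
    "read_panel_json",
]

# DNA-based schemes where an organiser/reference value, when available,
# overrides participant consensus.
REFERENCE_SCHEMES = frozenset(
    {"B27", "B57", "CD", "LOW", "HI", "KIR", "HPA"}
)

REPORT_COLUMNS = ["lab", "scheme", "year", "sample", "parameter", "method", "value", "excluded_nulls"]
TRUTH_COLUMNS = ["scheme", "year", "sample", "parameter", "value"]
ASSIGNED_COLUMNS = [
    "scheme", "year", "sample", "parameter", "mode", "value", "support", "n", "x_star", "s_star",
]
EVAL_COLUMNS = ["lab", "scheme", "year", "sample", "parameter", "status", "category"]


@dataclass(frozen=True)
class AssignedRecord:
    """Flat, CSV-ready assigned value for one (sample, parameter)."""

    scheme: str
    year: int
    sample: str
    parameter: str
    mode: str
    value: str = ""
    support: str = ""
    n: str = ""
    x_star: str = ""
    s_star: str = ""


def _qualitative_parameters(parameter: str) -> bool:
    return (
        parameter == "presence"
        or parameter == "dqdp"
        or parameter == "chimerism_interpretation"
        or parameter.startswith("xm:")
        or parameter.startswith("screening:")
    )


def _fmt(x: Optional[float]) -> str:
    return "" if x is None else f"{float(x):.6g}"


# ---------------------------------------------------------------------------
# assign
# ---------------------------------------------------------------------------

def assign(
    reports: Sequence[ReportRecord],
    truths: Optional[Sequence[TruthRecord]] = None,
    params: ConsensusParams = ConsensusParams(),
    panels: Optional[Mapping[str, Sequence[str]]] = None,
    risk_maps: Optional[Mapping[str, RiskMap]] = None,
) -> list[AssignedRecord]:
    """Determine the assigned value of every reported (sample, parameter).

    For DNA-based schemes a supplied truth (organiser reference) wins
    outright; everything else is assigned by participant consensus —
    the 75%/95% antibody rules per specificity, majority consensus for
    qualitative calls, and robust location/scale for chimerism.
    """
    panels = panels or DEFAULT_ANTIBODY_PANELS
    risk_maps = dict(risk_maps) if risk_maps else {"CD": default_cd_risk_map()}

    truth_lookup: dict[tuple[str, int, str, str], str] = {}
    for t in truths or ():
        truth_lookup[(t.scheme, t.year, t.sample, t.parameter)] = t.value

    grouped: dict[tuple[str, int, str, str], list[ReportRecord]] = {}
    for r in reports:
        grouped.setdefault((r.scheme, r.year, r.sample, r.parameter), []).append(r)

    out: list[AssignedRecord] = []
    assigned_genotypes: dict[tuple[str, int, str], dict[str, object]] = {}
    risk_groups: list[tuple[str, int, str, int]] = []

    for key in sorted(grouped):
        scheme, year, sample, parameter = key
        rows = grouped[key]
        ref_value = truth_lookup.get(key) if scheme in REFERENCE_SCHEMES else None

        if parameter.startswith("typing:"):
            genos = []
            for r in rows:
                try:
                    genos.append(
                        parse_genotype(r.value, excluded_nulls=_split(r.excluded_nulls))
                    )
                except (MalformedGenotype, MalformedAllele):
                    continue  # unparseable reports cannot support a consensus
            reference = parse_genotype(ref_value) if ref_value else None
            if reference is None and not genos:
                av = AssignedValue(parameter=parameter, mode=AssignedMode.NOT_EVALUABLE, n=0)
            else:
                av = typing_assigned_value(genos, reference, params, parameter=parameter)
            if av.payload is not None:
                assigned_genotypes.setdefault((scheme, year, sample), {})[
                    parameter.split(":", 1)[1]
                ] = av.payload
            out.append(
                AssignedRecord(
                    scheme, year, sample, parameter,
                    mode=av.mode.value,
                    value=av.payload.render() if av.payload is not None else "",
                    support=_fmt(av.support),
                    n=str(av.n),
                )
            )
        elif parameter == "abid":
            panel = [str(s).upper() for s in panels.get(scheme, ())]
            n_total = len(rows)
            counts = {}
            for spec in panel:
                n_pos = sum(1 for r in rows if spec in _split(r.value))
                counts[spec] = (n_pos, n_total)
            statuses = antibody_consensus(counts, params)
            for spec in panel:
                n_pos, _ = counts[spec]
                out.append(
                    AssignedRecord(
                        scheme, year, sample, f"specificity:{spec}",
                        mode=AssignedMode.CONSENSUS.value,
                        value=statuses[spec].value,
                        support=_fmt(max(n_pos, n_total - n_pos) / n_total),
                        n=str(n_total),
                    )
                )
        elif parameter == "chimerism":
            values = [float(r.value) for r in rows]
            av = chimerism_assigned(values, params, parameter=parameter)
            stats = av.payload if isinstance(av.payload, RobustStats) else None
            out.append(
                AssignedRecord(
                    scheme, year, sample, parameter,
                    mode=av.mode.value,
                    value=_fmt(stats.x_star) if stats else "",
                    n=str(av.n),
                    x_star=_fmt(stats.x_star) if stats else "",
                    s_star=_fmt(stats.s_star) if stats else "",
                )
            )
        elif parameter == "risk":
            risk_groups.append((scheme, year, sample, len(rows)))
        elif _qualitative_parameters(parameter):
            if ref_value is not None and parameter == "presence":
                out.append(
                    AssignedRecord(
                        scheme, year, sample, parameter,
                        mode=AssignedMode.REFERENCE.value,
                        value=ref_value,
                        support=_fmt(1.0),
                        n=str(len(rows)),
                    )
                )
            else:
                av = qualitative_consensus(
                    [QualStatus(r.value) for r in rows], params, parameter=parameter
                )
                out.append(
                    AssignedRecord(
                        scheme, year, sample, parameter,
                        mode=av.mode.value,
                        value=av.payload.value if av.payload is not None else "",
                        support=_fmt(av.support),
                        n=str(av.n),
                    )
                )
        else:
            raise ValueError(f"unknown parameter kind {parameter!r}")

    # risk labels derive from the sample's assigned genotypes
    for scheme, year, sample, n in risk_groups:
        risk_map = risk_maps.get(scheme)
        genotypes = assigned_genotypes.get((scheme, year, sample), {})
        label = ""
        mode = AssignedMode.NOT_EVALUABLE.value
        if risk_map is not None and genotypes:
            try:
                label = risk_map.classify(genotypes)
                ref_based = scheme in REFERENCE_SCHEMES and truths
                mode = (
                    AssignedMode.REFERENCE.value
                    if ref_based
                    else AssignedMode.CONSENSUS.value
                )
            except KeyError:
                label = ""
        out.append(
            AssignedRecord(scheme, year, sample, "risk", mode=mode, value=label, n=str(n))
        )
    out.sort(key=lambda a: (a.scheme, a.year, a.sample, a.parameter))
    return out


def _split(joined: str) -> set[str]:
    return {p.strip().upper() for p in str(joined or "").split(";") if p.strip()}


# ---------------------------------------------------------------------------
# evaluate
# ---------------------------------------------------------------------------

def _assigned_lookup(
    assigned: Sequence[AssignedRecord],
) -> dict[tuple[str, int, str, str], AssignedRecord]:
    return {(a.scheme, int(a.year), a.sample, a.parameter): a for a in assigned}


def evaluate(
    reports: Sequence[ReportRecord],
    assigned: Sequence[AssignedRecord],
    params: ScoringParams = ScoringParams(),
) -> list[Evaluation]:
    """Score every laboratory report row against its assigned value."""
    lookup = _assigned_lookup(assigned)
    spec_maps: dict[tuple[str, int, str], dict[str, AntibodyStatus]] = {}
    for a in assigned:
        if a.parameter.startswith("specificity:"):
            spec_maps.setdefault((a.scheme, int(a.year), a.sample), {})[
                a.parameter.split(":", 1)[1]
            ] = AntibodyStatus(a.value)
    evals: list[Evaluation] = []
    for r in reports:
        ctx = dict(lab=r.lab, scheme=r.scheme, year=int(r.year), sample=r.sample)
        key = (r.scheme, int(r.year), r.sample, r.parameter)

        if r.parameter.startswith("typing:"):
            evals.append(
                evaluate_typing(
                    r.value,
                    _typing_av(lookup.get(key), r.parameter),
                    excluded_nulls=sorted(_split(r.excluded_nulls)),
                    **ctx,
                )
            )
        elif r.parameter == "abid":
            panel_map = spec_maps.get((r.scheme, int(r.year), r.sample), {})
            evals.extend(evaluate_antibody(_split(r.value), panel_map, **ctx))
        elif r.parameter == "chimerism":
            a = lookup.get(key)
            if a is None or a.mode == AssignedMode.NOT_EVALUABLE.value or not a.s_star:
                av = AssignedValue(parameter=r.parameter, mode=AssignedMode.NOT_EVALUABLE)
            else:
                stats = RobustStats(
                    float(a.x_star), float(a.s_star), int(a.n), 0, True
                )
                av = AssignedValue(
                    parameter=r.parameter, mode=AssignedMode(a.mode), payload=stats, n=int(a.n)
                )
            evals.append(evaluate_chimerism(r.value, av, params, **ctx))
        elif r.parameter == "risk":
            a = lookup.get(key)
            if a is None or a.mode == AssignedMode.NOT_EVALUABLE.value or not a.value:
                evals.append(
                    Evaluation(status=Status.NOT_EVALUABLE, parameter="risk", **ctx)
                )
            elif r.value.strip().lower() == a.value.strip().lower():
                evals.append(Evaluation(status=Status.CORRECT, parameter="risk", **ctx))
            else:
                evals.append(
                    Evaluation(
                        status=Status.ERROR,
                        category=ErrorCategory.RISK_INTERPRETATION,
                        parameter="risk",
                        **ctx,
                    )
                )
        elif r.parameter.startswith("screening:"):
            evals.append(evaluate_screening(r.value, _qual_av(lookup.get(key), r.parameter), **ctx))
        elif _qualitative_parameters(r.parameter):
            evals.append(
                evaluate_qualitative(r.value, _qual_av(lookup.get(key), r.parameter), **ctx)
            )
        else:
            raise ValueError(f"unknown parameter kind {r.parameter!r}")
    return evals


def _typing_av(a: Optional[AssignedRecord], parameter: str) -> AssignedValue:
    if a is None or a.mode == AssignedMode.NOT_EVALUABLE.value or not a.value:
        return AssignedValue(parameter=parameter, mode=AssignedMode.NOT_EVALUABLE)
    return AssignedValue(
        parameter=parameter,
        mode=AssignedMode(a.mode),
        payload=parse_genotype(a.value),
        support=float(a.support) if a.support else None,
        n=int(a.n) if a.n else 0,
    )


def _qual_av(a: Optional[AssignedRecord], parameter: str) -> AssignedValue:
    if a is None or a.mode == AssignedMode.NOT_EVALUABLE.value or not a.value:
        return AssignedValue(parameter=parameter, mode=AssignedMode.NOT_EVALUABLE)
    return AssignedValue(
        parameter=parameter,
        mode=AssignedMode(a.mode),
        payload=QualStatus(a.value),
        support=float(a.support) if a.support else None,
        n=int(a.n) if a.n else 0,
    )


def outcomes(
    evals: Sequence[Evaluation], params: ScoringParams = ScoringParams()
) -> list[dict]:
    """PASS/FAIL per (lab, scheme, year); labs with no valid results are
    dropped (no outcome)."""
    grouped: dict[tuple[str, str, int], list[Evaluation]] = {}
    for e in evals:
        grouped.setdefault((e.lab, e.scheme, e.year), []).append(e)
    rows = []
    for (lab, scheme, year), group in sorted(grouped.items()):
        valid = [e for e in group if e.status is not Status.NOT_EVALUABLE]
        if not valid:
            continue
        rows.append(
            {
                "lab": lab,
                "scheme": scheme,
                "year": year,
                "outcome": scheme_pass(group, params),
            }
        )
    return rows


# ---------------------------------------------------------------------------
# flat-file IO (deterministic: write -> read -> re-write is byte-identical)
# ---------------------------------------------------------------------------

def _write_csv(path, columns: list[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(columns)
        w.writerows(rows)


def write_reports_csv(path, reports: Sequence[ReportRecord]) -> None:
    _write_csv(
        path,
        REPORT_COLUMNS,
        (
            [r.lab, r.scheme, r.year, r.sample, r.parameter, r.method, r.value, r.excluded_nulls]
            for r in reports
        ),
    )


def read_reports_csv(path) -> list[ReportRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ReportRecord(
                    lab=row["lab"],
                    scheme=row["scheme"],
                    year=int(row["year"]),
                    sample=row["sample"],
                    parameter=row["parameter"],
                    method=row["method"],
                    value=row["value"],
                    excluded_nulls=row.get("excluded_nulls", ""),
                )
            )
    return out


def write_truth_csv(path, truths: Sequence[TruthRecord]) -> None:
    _write_csv(
        path,
        TRUTH_COLUMNS,
        ([t.scheme, t.year, t.sample, t.parameter, t.value] for t in truths),
    )


def read_truth_csv(path) -> list[TruthRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                TruthRecord(
                    scheme=row["scheme"],
                    year=int(row["year"]),
                    sample=row["sample"],
                    parameter=row["parameter"],
                    value=row["value"],
                )
            )
    return out


def write_assigned_csv(path, assigned: Sequence[AssignedRecord]) -> None:
    _write_csv(
        path,
        ASSIGNED_COLUMNS,
        (
            [a.scheme, a.year, a.sample, a.parameter, a.mode, a.value, a.support, a.n, a.x_star, a.s_star]
            for a in assigned
        ),
    )


def read_assigned_csv(path) -> list[AssignedRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                AssignedRecord(
                    scheme=row["scheme"],
                    year=int(row["year"]),
                    sample=row["sample"],
                    parameter=row["parameter"],
                    mode=row["mode"],
                    value=row["value"],
                    support=row["support"],
                    n=row["n"],
                    x_star=row["x_star"],
                    s_star=row["s_star"],
                )
            )
    return out


def write_evaluations_csv(path, evals: Sequence[Evaluation]) -> None:
    _write_csv(
        path,
        EVAL_COLUMNS,
        (
            [e.lab, e.scheme, e.year, e.sample, e.parameter, e.status.value,
             e.category.value if e.category else ""]
            for e in evals
        ),
    )


def read_evaluations_csv(path) -> list[Evaluation]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Evaluation(
                    lab=row["lab"],
                    scheme=row["scheme"],
                    year=int(row["year"]),
                    sample=row["sample"],
                    parameter=row["parameter"],
                    status=Status(row["status"]),
                    category=ErrorCategory(row["category"]) if row["category"] else None,
                )
            )
    return out


def write_panel_json(path, panels: Mapping[str, Sequence[str]], risk_maps: Optional[Mapping] = None) -> None:
    payload = {"antibody_panels": {k: list(v) for k, v in panels.items()}}
    if risk_maps:
        payload["risk_maps"] = {
            scheme: {
                "rules": [
                    {
                        "label": rule.label,
                        "requires": [
                            {"locus": lc, "prefix": px, "min_copies": n}
                            for lc, px, n in rule.requires
                        ],
                    }
                    for rule in rm.rules
                ],
                "default": rm.default,
            }
            for scheme, rm in risk_maps.items()
        }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_panel_json(path) -> tuple[dict[str, list[str]], dict[str, RiskMap]]:
    payload = json.loads(Path(path).read_text())
    panels = {k: list(v) for k, v in payload.get("antibody_panels", {}).items()}
    risk_maps = {
        scheme: RiskMap.from_dict(d) for scheme, d in payload.get("risk_maps", {}).items()
    }
    return panels, risk_maps
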