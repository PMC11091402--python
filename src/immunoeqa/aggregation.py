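"""Roll-ups of evaluations into the programme's summary statistics.

Success rates count error-free results over *valid* data: NOT_EVALUABLE
items leave both numerator and denominator.  Yearly scheme rates average
(unweighted) into scheme means, and scheme means average (unweighted,
over unrounded values) into analytical-family means — the reading under
which the published family figures are reproducible from the published
yearly table.  Percentages are rounded half-up to one decimal at
presentation only.

The module also ships the published 12-year programme summary tables
(participation, result volumes, yearly success rates, scheme registry) as
package data, used both as regression fixtures and as the defaults of the
synthetic-report generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .scoring import Evaluation, NoValidResults, Status

__all__ = [
    "SchemeYearStats",
    "SCHEME_FAMILY",
    "FAMILIES",
    "round_half_up",
    "success_rate",
    "scheme_mean",
    "family_mean",
    "family_means_from_yearly",
    "totals_table",
    "error_breakdown",
    "labs_passing_all",
    "method_frequency",
    "scheme_year_table",
    "evaluations_frame",
    "load_scheme_registry",
    "load_reference_success_rates",
    "load_reference_result_counts",
    "load_reference_participation",
]


class EmptyInput(ValueError):
    pass


class NoErrors(ValueError):
    pass


class NoLabs(ValueError):
    pass


def _data_path(name: str):
    return resources.files("immunoeqa.data").joinpath(name)


def load_scheme_registry() -> pd.DataFrame:
    """Scheme short names, analytical families and descriptions."""
    with resources.as_file(_data_path("schemes.csv")) as p:
        return pd.read_csv(p)


def load_reference_success_rates() -> pd.DataFrame:
    """Published yearly success rates (%) per scheme, long format."""
    with resources.as_file(_data_path("success_rates.csv")) as p:
        return pd.read_csv(p)


def load_reference_result_counts() -> pd.DataFrame:
    """Published yearly reported-result counts per scheme, long format."""
    with resources.as_file(_data_path("result_counts.csv")) as p:
        return pd.read_csv(p)


def load_reference_participation() -> pd.DataFrame:
    """Published yearly participating-laboratory counts per scheme."""
    with resources.as_file(_data_path("participation.csv")) as p:
        return pd.read_csv(p)


_REGISTRY = None


def _registry() -> pd.DataFrame:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_scheme_registry()
    return _REGISTRY


def _scheme_family_map() -> dict[str, str]:
    df = _registry()
    return dict(zip(df["scheme"], df["family"]))


FAMILIES = ("Serology", "Molecular typing", "Antibodies", "Chimerism", "Crossmatch")


def __getattr__(name: str):
    # SCHEME_FAMILY is loaded lazily from the packaged scheme registry.
    if name == "SCHEME_FAMILY":
        return _scheme_family_map()
    raise AttributeError(name)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (so 96.65 -> 96.7, unlike banker's)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SchemeYearStats:
    """Counts and success rate of one scheme-year."""

    scheme: str
    family: str
    year: int
    n_labs: int
    n_results: int
    n_valid: int
    n_errors: int

    @property
    def success_rate(self) -> float:
        return round_half_up(100.0 * (self.n_valid - self.n_errors) / self.n_valid)


# ---------------------------------------------------------------------------
# core statistics
# ---------------------------------------------------------------------------

def _as_frame(evals: Iterable[Evaluation] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(evals, pd.DataFrame):
        return evals
    return evaluations_frame(list(evals))


def evaluations_frame(evals: Sequence[Evaluation]) -> pd.DataFrame:
    """Evaluations as a DataFrame with the stable CSV column order."""
    return pd.DataFrame(
        {
            "lab": [e.lab for e in evals],
            "scheme": [e.scheme for e in evals],
            "year": [e.year for e in evals],
            "sample": [e.sample for e in evals],
            "parameter": [e.parameter for e in evals],
            "status": [e.status.value for e in evals],
            "category": [e.category.value if e.category else "" for e in evals],
        }
    )


def success_rate(evals: Iterable[Evaluation] | pd.DataFrame) -> float:
    """Percentage of error-free results over valid data (unrounded)."""
    df = _as_frame(evals)
    valid = df[df["status"] != Status.NOT_EVALUABLE.value]
    if len(valid) == 0:
        raise NoValidResults("no valid evaluations")
    n_correct = int((valid["status"] == Status.CORRECT.value).sum())
    return 100.0 * n_correct / len(valid)


def scheme_mean(yearly_rates: Sequence[float], *, rounded: bool = True) -> float:
    """Unweighted mean of a scheme's yearly success rates."""
    if len(yearly_rates) == 0:
        raise EmptyInput("no yearly rates")
    m = sum(float(r) for r in yearly_rates) / len(yearly_rates)
    return round_half_up(m) if rounded else m


def family_mean(scheme_means: Sequence[float], *, rounded: bool = True) -> float:
    """Unweighted mean of scheme means (not pooled over result counts).

    Pass *unrounded* scheme means; rounding is presentation-only.
    """
    if len(scheme_means) == 0:
        raise EmptyInput("no scheme means")
    m = sum(float(r) for r in scheme_means) / len(scheme_means)
    return round_half_up(m) if rounded else m


def family_means_from_yearly(
    rates: pd.DataFrame, *, rounded: bool = True
) -> pd.Series:
    """Family means from a long (scheme, year, success_rate) frame."""
    fam = _scheme_family_map()
    df = rates.copy()
    df["family"] = df["scheme"].map(fam)
    per_scheme = df.groupby(["family", "scheme"])["success_rate"].mean()
    out = per_scheme.groupby("family").mean()
    if rounded:
        out = out.map(round_half_up)
    return out


def totals_table(counts: pd.DataFrame, *, by_family: bool = False) -> pd.DataFrame:
    """Scheme x year count table with a Total column.

    ``counts`` is long-format (scheme, year, count); with ``by_family``
    rows are analytical families instead of schemes.
    """
    df = counts.copy()
    if by_family:
        df["row"] = df["scheme"].map(_scheme_family_map())
    else:
        df["row"] = df["scheme"]
    table = (
        df.pivot_table(index="row", columns="year", values="count", aggfunc="sum", fill_value=0)
        .astype(int)
    )
    table["Total"] = table.sum(axis=1)
    table = table.sort_values("Total", ascending=False)
    table.index.name = "family" if by_family else "scheme"
    return table


def error_breakdown(evals: Iterable[Evaluation] | pd.DataFrame) -> dict[str, float]:
    """Percentage of errors per category (over the ERROR count)."""
    df = _as_frame(evals)
    errors = df[df["status"] == Status.ERROR.value]
    if len(errors) == 0:
        raise NoErrors("no errors to break down")
    shares = errors["category"].value_counts(normalize=True) * 100.0
    return {str(k): float(v) for k, v in shares.sort_index().items()}


def labs_passing_all(outcomes: pd.DataFrame) -> float:
    """Percentage of laboratories with zero FAIL outcomes.

    ``outcomes`` is long-format (lab, scheme, outcome) for one year; the
    denominator is every lab with at least one outcome.
    """
    if len(outcomes) == 0:
        raise NoLabs("no lab outcomes")
    failed = outcomes[outcomes["outcome"] == "FAIL"]["lab"].unique()
    n_labs = outcomes["lab"].nunique()
    return 100.0 * (n_labs - len(failed)) / n_labs


def method_frequency(reports: pd.DataFrame) -> pd.DataFrame:
    """Modal method tag and its share (%) per scheme-year.

    Ties break lexicographically and are flagged in the ``tie`` column.
    """
    rows = []
    for (scheme, year), grp in reports.groupby(["scheme", "year"]):
        counts = grp["method"].value_counts()
        top = counts.max()
        winners = sorted(counts[counts == top].index)
        rows.append(
            {
                "scheme": scheme,
                "year": int(year),
                "method": winners[0],
                "share": round_half_up(100.0 * top / counts.sum()),
                "tie": len(winners) > 1,
            }
        )
    return pd.DataFrame(rows, columns=["scheme", "year", "method", "share", "tie"])


def scheme_year_table(evals: Iterable[Evaluation] | pd.DataFrame) -> pd.DataFrame:
    """Per scheme-year counts and success rate (presentation-rounded)."""
    df = _as_frame(evals)
    fam = _scheme_family_map()
    rows = []
    for (scheme, year), grp in df.groupby(["scheme", "year"]):
        valid = grp[grp["status"] != Status.NOT_EVALUABLE.value]
        n_err = int((valid["status"] == Status.ERROR.value).sum())
        stats = SchemeYearStats(
            scheme=scheme,
            family=fam.get(scheme, ""),
            year=int(year),
            n_labs=grp["lab"].nunique(),
            n_results=len(grp),
            n_valid=len(valid),
            n_errors=n_err,
        )
        rows.append(
            {
                "scheme": stats.scheme,
                "family": stats.family,
                "year": stats.year,
                "n_labs": stats.n_labs,
                "n_results": stats.n_results,
                "n_valid": stats.n_valid,
                "n_errors": stats.n_errors,
                "success_rate": stats.success_rate if stats.n_valid else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scheme", "family", "year", "n_labs",
            "n_results", "n_valid", "n_errors", "success_rate",
        ],
    ).sort_values(["scheme", "year"], ignore_index=True)
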