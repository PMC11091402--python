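"""Immunogenetics typing nomenclature: parsing, normalisation and concordance.

Molecular alleles follow the WHO-style colon-delimited form
``LOCUS*F1:F2[:F3[:F4]][X]`` where ``F1..F4`` are numeric field tokens
(resolution grows with field count) and ``X`` is an optional expression
suffix — ``N`` marks a null (non-expressed) allele, the others
(``L``, ``S``, ``C``, ``A``, ``Q``) mark altered expression.  Serological
antigens are one-field calls without the ``*`` separator (``HLA-A2``).

Genotypes use a small genotype-list dialect: ``+`` separates the two gene
copies and ``/`` separates ambiguous allele alternatives within a copy.
The full GL-string operators (``|``, ``^``) are deliberately rejected.

Concordance is judged at the reported resolution: a lower-resolution call
is concordant with a higher-resolution truth when its fields are a numeric
prefix of the truth's fields, so a laboratory is never penalised merely for
stopping short of allelic resolution.  An expressed call is never
concordant with a null allele (or vice versa), regardless of the numeric
fields: evidence of expression is part of the result.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Optional, Sequence

__all__ = [
    "AlleleCall",
    "AmbiguousCall",
    "Genotype",
    "MalformedAllele",
    "MalformedGenotype",
    "LocusMismatch",
    "EXPRESSION_SUFFIXES",
    "parse_allele",
    "parse_ambiguous_call",
    "parse_genotype",
    "concordant_allele",
    "genotype_concordant",
    "unexcluded_null",
]


class MalformedAllele(ValueError):
    """The allele string cannot be parsed."""


class MalformedGenotype(ValueError):
    """The genotype string cannot be parsed."""


class LocusMismatch(ValueError):
    """Comparison attempted between calls at different loci."""


EXPRESSION_SUFFIXES = frozenset("NLSCAQ")

# Short HLA locus tokens accepted without the "HLA-" prefix.
_HLA_SHORT_LOCI = frozenset(
    {
        "A", "B", "C", "E", "F", "G",
        "DRA", "DRB1", "DRB3", "DRB4", "DRB5",
        "DQA1", "DQB1", "DPA1", "DPB1",
        "DMA", "DMB", "DOA", "DOB",
    }
)

_SEROLOGY_RE = re.compile(r"^(?:HLA-)?([A-Z]{1,3}W?)(\d{1,3})$")
_FIELD_RE = re.compile(r"^\d+$")


def _canonical_locus(token: str) -> str:
    token = token.strip().upper()
    if not token:
        raise MalformedAllele("empty locus")
    if token.startswith("HLA-"):
        return token
    if token in _HLA_SHORT_LOCI:
        return f"HLA-{token}"
    # KIR genes, HPA systems, MICA/MICB etc. pass through unchanged.
    return token


@dataclass(frozen=True, eq=False)
class AlleleCall:
    """One typed allele (or serological antigen).

    ``fields`` keeps the laboratory's tokens verbatim (leading zeros
    preserved) but equality and ordering compare them numerically, so
    ``A*02:01`` and ``A*2:1`` are the same call.
    """

    locus: str
    fields: tuple[str, ...]
    expression_suffix: Optional[str] = None
    molecular: bool = True
    raw: str = ""

    def __post_init__(self) -> None:
        if not self.fields or len(self.fields) > 4:
            raise MalformedAllele(f"allele needs 1-4 fields, got {self.fields!r}")
        for tok in self.fields:
            if not _FIELD_RE.match(tok):
                raise MalformedAllele(f"non-numeric field token {tok!r}")
        if self.expression_suffix is not None and self.expression_suffix not in EXPRESSION_SUFFIXES:
            raise MalformedAllele(f"unknown expression suffix {self.expression_suffix!r}")

    # -- identity ---------------------------------------------------------
    def key(self) -> tuple:
        return (
            self.locus,
            tuple(int(f) for f in self.fields),
            self.expression_suffix or "",
            self.molecular,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleCall):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())

    def __lt__(self, other: "AlleleCall") -> bool:
        return self.key() < other.key()

    # -- queries ----------------------------------------------------------
    @property
    def resolution(self) -> int:
        return len(self.fields)

    def is_null(self) -> bool:
        return self.expression_suffix == "N"

    def truncate(self, n_fields: int) -> "AlleleCall":
        """Call restricted to its first ``n_fields`` fields (suffix kept)."""
        if not 1 <= n_fields <= len(self.fields):
            raise ValueError(f"cannot truncate {self.render()} to {n_fields} fields")
        return AlleleCall(
            locus=self.locus,
            fields=self.fields[:n_fields],
            expression_suffix=self.expression_suffix,
            molecular=self.molecular,
        )

    def render(self) -> str:
        if self.molecular:
            body = ":".join(f.zfill(2) for f in self.fields)
            return f"{self.locus}*{body}{self.expression_suffix or ''}"
        return f"{self.locus}{int(self.fields[0])}"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"AlleleCall({self.render()!r})"


def parse_allele(text: str) -> AlleleCall:
    """Parse a single molecular allele or serological antigen string."""
    if text is None or not str(text).strip():
        raise MalformedAllele("empty allele string")
    s = str(text).strip().upper()
    if "*" in s:
        locus_tok, _, body = s.partition("*")
        if not body:
            raise MalformedAllele(f"missing fields after '*' in {text!r}")
        tokens = body.split(":")
        suffix = None
        last = tokens[-1]
        if last and last[-1].isalpha():
            suffix = last[-1]
            tokens[-1] = last[:-1]
            if suffix not in EXPRESSION_SUFFIXES:
                raise MalformedAllele(f"unknown expression suffix {suffix!r} in {text!r}")
        for tok in tokens:
            if not tok:
                raise MalformedAllele(f"empty field token in {text!r}")
            if not _FIELD_RE.match(tok):
                raise MalformedAllele(f"non-numeric field token {tok!r} in {text!r}")
        if len(tokens) > 4:
            raise MalformedAllele(f"more than 4 fields in {text!r}")
        return AlleleCall(
            locus=_canonical_locus(locus_tok),
            fields=tuple(tokens),
            expression_suffix=suffix,
            molecular=True,
            raw=str(text),
        )
    m = _SEROLOGY_RE.match(s)
    if m:
        return AlleleCall(
            locus=_canonical_locus(m.group(1)),
            fields=(m.group(2),),
            expression_suffix=None,
            molecular=False,
            raw=str(text),
        )
    raise MalformedAllele(f"missing locus separator in {text!r}")


@dataclass(frozen=True, eq=False)
class AmbiguousCall:
    """One reported gene copy: a set of alternative alleles at one locus.

    ``excluded_nulls`` lists null alleles the laboratory explicitly ruled
    out; a null alternative that is *not* in this list is an unresolved
    null ambiguity.
    """

    alternatives: tuple[AlleleCall, ...]
    excluded_nulls: frozenset[AlleleCall] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise MalformedGenotype("ambiguous call needs at least one alternative")
        loci = {a.locus for a in self.alternatives}
        if len(loci) != 1:
            raise MalformedGenotype(f"mixed loci in one call: {sorted(loci)}")
        bad = [a for a in self.excluded_nulls if not a.is_null()]
        if bad:
            raise MalformedGenotype(
                f"excluded_nulls must be null-expression alleles, got {bad[0].render()}"
            )
        # canonical alternative order for stable rendering / equality
        object.__setattr__(self, "alternatives", tuple(sorted(set(self.alternatives))))

    @property
    def locus(self) -> str:
        return self.alternatives[0].locus

    def key(self) -> tuple:
        return (
            tuple(a.key() for a in self.alternatives),
            tuple(sorted(a.key() for a in self.excluded_nulls)),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AmbiguousCall):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())

    def render(self) -> str:
        return "/".join(a.render() for a in self.alternatives)

    def __repr__(self) -> str:  # pragma: no cover
        return f"AmbiguousCall({self.render()!r})"


def parse_ambiguous_call(
    text: str, excluded_nulls: Iterable[AlleleCall] = ()
) -> AmbiguousCall:
    parts = [p for p in str(text).split("/")]
    if any(not p.strip() for p in parts):
        raise MalformedGenotype(f"empty ambiguity alternative in {text!r}")
    alts = tuple(parse_allele(p) for p in parts)
    return AmbiguousCall(alternatives=alts, excluded_nulls=frozenset(excluded_nulls))


@dataclass(frozen=True, eq=False)
class Genotype:
    """A reported genotype at one locus: one or two gene copies.

    A single call marks reported homozygosity; ``reported_doubled`` is set
    when the laboratory wrote the same allele twice instead.  Both forms
    are treated as the same homozygous claim by the concordance rules.
    """

    locus: str
    calls: tuple[AmbiguousCall, ...]
    reported_doubled: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.calls) <= 2:
            raise MalformedGenotype("genotype needs 1 or 2 calls")
        if any(c.locus != self.locus for c in self.calls):
            raise MalformedGenotype("calls do not share the genotype locus")
        object.__setattr__(
            self, "calls", tuple(sorted(self.calls, key=lambda c: c.key()))
        )

    def key(self) -> tuple:
        return (self.locus, tuple(c.key() for c in self.calls))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genotype):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())

    def is_homozygous_claim(self) -> bool:
        return len(self.calls) == 1 or self.calls[0] == self.calls[1]

    def all_alternatives(self) -> list[AlleleCall]:
        return [a for c in self.calls for a in c.alternatives]

    def render(self) -> str:
        return "+".join(c.render() for c in self.calls)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Genotype({self.render()!r})"


def parse_genotype(text: str, excluded_nulls: Iterable[str] = ()) -> Genotype:
    """Parse a genotype string; ``excluded_nulls`` are allele strings the
    laboratory explicitly excluded (attached to every call that could
    carry them)."""
    if text is None or not str(text).strip():
        raise MalformedGenotype("empty genotype string")
    s = str(text).strip()
    if "|" in s or "^" in s:
        raise MalformedGenotype(
            "full GL-string operators '|' and '^' are not supported; "
            "use '+' for copies and '/' for ambiguities"
        )
    parts = s.split("+")
    if len(parts) > 2:
        raise MalformedGenotype(f"more than 2 '+'-separated copies in {text!r}")
    excl = frozenset(parse_allele(e) for e in excluded_nulls if str(e).strip())
    for e in excl:
        if not e.is_null():
            raise MalformedGenotype(
                f"excluded allele {e.render()} is not a null allele"
            )
    calls = tuple(parse_ambiguous_call(p, excluded_nulls=excl) for p in parts)
    loci = {c.locus for c in calls}
    if len(loci) != 1:
        raise MalformedGenotype(f"mixed loci in genotype {text!r}: {sorted(loci)}")
    doubled = len(calls) == 2 and calls[0] == calls[1]
    return Genotype(locus=calls[0].locus, calls=calls, reported_doubled=doubled)


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def _suffix_conflict(reported: AlleleCall, truth: AlleleCall) -> bool:
    # Null status must agree; two explicit non-null suffixes must match.
    if reported.is_null() != truth.is_null():
        return True
    if (
        reported.expression_suffix is not None
        and truth.expression_suffix is not None
        and reported.expression_suffix != truth.expression_suffix
    ):
        return True
    return False


def concordant_allele(reported: AlleleCall, truth: AlleleCall) -> bool:
    """Is the reported allele concordant with the true allele?

    True iff the reported fields are a numeric prefix of the truth's
    fields (comparison at the reported resolution) and the expression
    suffixes do not conflict.  Serological and molecular calls are never
    concordant with each other (no serology-to-DNA equivalence inference).
    """
    if reported.locus != truth.locus:
        raise LocusMismatch(f"{reported.locus} vs {truth.locus}")
    if reported.molecular != truth.molecular:
        return False
    if reported.resolution > truth.resolution:
        return False
    for r, t in zip(reported.fields, truth.fields):
        if int(r) != int(t):
            return False
    return not _suffix_conflict(reported, truth)


def _call_matches(reported: AmbiguousCall, truth: AmbiguousCall) -> bool:
    return any(
        concordant_allele(r, t)
        for r in reported.alternatives
        for t in truth.alternatives
    )


def genotype_concordant(reported: Genotype, truth: Genotype) -> bool:
    """Genotype-level concordance under the resolution-tolerant rule.

    There must be a perfect matching between the truth's two gene copies
    and the reported calls such that each truth copy is concordant with at
    least one alternative of its matched reported call.  A homozygous
    report (single call, or the same allele written twice) matches only a
    homozygous truth.
    """
    if reported.locus != truth.locus:
        raise LocusMismatch(f"{reported.locus} vs {truth.locus}")
    truth_calls: Sequence[AmbiguousCall] = truth.calls
    if len(truth_calls) == 1:
        truth_calls = (truth_calls[0], truth_calls[0])
    if reported.is_homozygous_claim():
        if not truth.is_homozygous_claim():
            return False
        return all(_call_matches(reported.calls[0], tc) for tc in truth_calls)
    r1, r2 = reported.calls
    for t1, t2 in permutations(truth_calls, 2):
        if _call_matches(r1, t1) and _call_matches(r2, t2):
            return True
    return False


def unexcluded_null(call: AmbiguousCall) -> bool:
    """Does the call carry a null-allele alternative that the laboratory
    failed to exclude explicitly?"""
    return any(a.is_null() and a not in call.excluded_nulls for a in call.alternatives)
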