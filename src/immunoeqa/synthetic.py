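"""Synthetic laboratory-report generator with seeded error injection.

The generator emulates the statistical structure of a long-running
immunogenetics EQA programme: a roster of laboratories, per-scheme sample
panels, per-scheme-year error rates (defaulting to one minus the
programme's published yearly success rates) and per-scheme error-category
mixes (defaulting to the published pooled shares, e.g. 60.1% null-allele
errors in high-resolution typing and 62.2% quantification errors in
chimerism).

Design points that make the generator a usable calibration instrument:

* **Exact recoverability.**  Correct quantitative (chimerism) reports
  reproduce the true value exactly by default (``report_noise = 0``): the
  robust scale of the clean majority degenerates to zero, the scorer's
  absolute tolerance (5 percentage points) takes over, and injected
  quantification errors shift the value far beyond it.  The expected
  recovered success rate therefore equals 100*(1 - error_rate) by
  construction.  A nonzero ``report_noise`` (bounded uniform, half-width
  in percentage points) is available for more lifelike data, but any
  within-window spread makes the sample-based |z| <= 2 rule fail a small
  fraction of honest reports — a real feature of robust z-scoring with
  ~20 participants, and the reason the calibration default removes it.
  Typing truths draw two *distinct* expressed alleles so every injected
  category (including homozygosity) is realisable.
* **Mixed item types.**  A scheme's sample may contain items of several
  types (chimerism: one quantitative value plus one interpretation call).
  Per-item injection probabilities are scaled as
  ``rate * mix_mass(type) * n_items / n_items_of_type`` so that both the
  overall per-result error rate and the category mix are matched at once.
* **Stream independence.**  Every (scheme, year) truth panel and every
  (scheme, year, lab) report stream draws from its own RNG derived from
  the master seed, so adding a scheme or lab never perturbs another's
  draws, and the same seed yields byte-identical output files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from . import aggregation
from .nomenclature import AlleleCall, parse_allele, parse_genotype
from .scoring import RiskMap

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "ReportRecord",
    "InvalidConfig",
    "DEFAULT_ALLELE_POOLS",
    "DEFAULT_NULL_ALLELES",
    "DEFAULT_SERO_POOLS",
    "DEFAULT_TYPING_LOCI",
    "DEFAULT_ANTIBODY_PANELS",
    "DEFAULT_CATEGORY_MIXES",
    "DEFAULT_METHOD_MIXES",
    "default_cd_risk_map",
    "generate_truth",
    "generate_reports",
    "simulate",
]


class InvalidConfig(ValueError):
    pass


# ---------------------------------------------------------------------------
# defaults: pools, panels, mixes
# ---------------------------------------------------------------------------

# Fictitious-but-valid expressed allele pools (uniform truth frequencies).
# First two fields are unique per locus except where a mismatch remains
# detectable at the reported resolution (checked at injection time).
DEFAULT_ALLELE_POOLS: dict[str, tuple[str, ...]] = {
    "HLA-A": ("A*01:01:01", "A*02:01:01", "A*03:01:01", "A*11:01:01", "A*24:02:01", "A*68:01:01"),
    "HLA-B": ("B*07:02:01", "B*08:01:01", "B*15:01:01", "B*27:05:02", "B*44:02:01", "B*57:01:01"),
    "HLA-DRB1": ("DRB1*01:01:01", "DRB1*03:01:01", "DRB1*04:01:01", "DRB1*07:01:01", "DRB1*15:01:01"),
    "HLA-DQA1": ("DQA1*01:01", "DQA1*02:01", "DQA1*03:01", "DQA1*05:01"),
    "HLA-DQB1": ("DQB1*02:01", "DQB1*03:01", "DQB1*03:02", "DQB1*05:01", "DQB1*06:02"),
    "KIR2DL1": ("KIR2DL1*001", "KIR2DL1*002", "KIR2DL1*003", "KIR2DL1*004"),
    "KIR3DL1": ("KIR3DL1*001", "KIR3DL1*002", "KIR3DL1*005", "KIR3DL1*015"),
    "HPA-1": ("HPA-1*001", "HPA-1*002"),
    "HPA-5": ("HPA-5*001", "HPA-5*002"),
}

# One null-expression allele per molecular locus, used by null-allele
# ambiguity injection (never drawn as truth).
DEFAULT_NULL_ALLELES: dict[str, str] = {
    "HLA-A": "A*01:04N",
    "HLA-B": "B*15:04N",
    "HLA-DRB1": "DRB1*04:09N",
    "HLA-DQA1": "DQA1*01:09N",
    "HLA-DQB1": "DQB1*03:38N",
    "KIR2DL1": "KIR2DL1*010N",
    "KIR3DL1": "KIR3DL1*019N",
    "HPA-1": "HPA-1*003N",
    "HPA-5": "HPA-5*003N",
}

DEFAULT_SERO_POOLS: dict[str, tuple[str, ...]] = {
    "HLA-A": ("HLA-A1", "HLA-A2", "HLA-A3", "HLA-A24"),
    "HLA-B": ("HLA-B7", "HLA-B8", "HLA-B27", "HLA-B44"),
}

DEFAULT_TYPING_LOCI: dict[str, tuple[str, ...]] = {
    "HI": ("HLA-A", "HLA-B", "HLA-DRB1"),
    "LOW": ("HLA-A", "HLA-B", "HLA-DRB1"),
    "KIR": ("KIR2DL1", "KIR3DL1"),
    "HPA": ("HPA-1", "HPA-5"),
    "CD": ("HLA-DQA1", "HLA-DQB1"),
    "SER": ("HLA-A", "HLA-B"),
}

DEFAULT_ANTIBODY_PANELS: dict[str, tuple[str, ...]] = {
    "ALO": ("A2", "A24", "B7", "B27", "CW6", "DR4", "DR15", "DQ2", "DQ7", "DP4"),
    "AHPA": ("HPA-1A", "HPA-1B", "HPA-3A", "HPA-5B"),
}

# Per-scheme error-category mixes (probabilities given an error occurs).
# "IDENTIFICATION" is the pooled specificity false-positive/false-negative
# bucket (direction follows the specificity's true status at injection).
DEFAULT_CATEGORY_MIXES: dict[str, dict[str, float]] = {
    "HI": {"NULL_ALLELE": 0.601, "ALLELE_MISMATCH": 0.200, "HOMOZYGOSITY": 0.199},
    "LOW": {"ALLELE_MISMATCH": 0.6, "HOMOZYGOSITY": 0.4},
    "KIR": {"ALLELE_MISMATCH": 0.401, "HOMOZYGOSITY": 0.599},
    "HPA": {"ALLELE_MISMATCH": 0.7, "HOMOZYGOSITY": 0.3},
    "SER": {"ALLELE_MISMATCH": 0.7, "HOMOZYGOSITY": 0.3},
    "CD": {"RISK_INTERPRETATION": 0.5, "ALLELE_MISMATCH": 0.3, "HOMOZYGOSITY": 0.2},
    "B27": {"QUALITATIVE_MISMATCH": 1.0},
    "B57": {"QUALITATIVE_MISMATCH": 1.0},
    "XM": {"QUALITATIVE_MISMATCH": 1.0},
    "XMFC": {"QUALITATIVE_MISMATCH": 1.0},
    "CHM": {"QUANTIFICATION": 0.622, "QUALITATIVE_MISMATCH": 0.378},
    # Published shares (89.7 / 1.4-1.9 / 5.4, midpoint for screening)
    # normalised to sum to one.
    "ALO": {"IDENTIFICATION": 0.92713, "SCREENING": 0.01705, "QUALITATIVE_MISMATCH": 0.05582},
    "AHPA": {"IDENTIFICATION": 0.90, "SCREENING": 0.10},
}

DEFAULT_METHOD_MIXES: dict[str, dict[str, float]] = {
    "HPA": {"SSO": 0.5, "SSP": 0.35, "rtPCR": 0.15},
    "KIR": {"SSO": 0.65, "SSP": 0.35},
    "LOW": {"SSO": 0.7, "SSP": 0.3},
    "B57": {"SSO": 0.5, "rtPCR": 0.3, "SSP": 0.2},
    "HI": {"NGS": 0.6, "SBT": 0.3, "SSO": 0.1},
    "B27": {"Mol. gen": 0.7, "FC": 0.3},
    "CD": {"SSO": 0.7, "rtPCR": 0.3},
    "AHPA": {"Luminex": 0.8, "ELISA": 0.2},
    "ALO": {"Luminex-SA": 0.9, "CDC": 0.1},
    "SER": {"PBMCs": 0.75, "T cells": 0.25},
    "XM": {"PBMCs": 0.6, "T/B separated": 0.4},
    "XMFC": {"Total lymph": 0.9, "T/B separated": 0.1},
    "CHM": {"STR": 0.55, "rtPCR": 0.45},
}

ALL_SCHEMES = tuple(DEFAULT_CATEGORY_MIXES)

# item types a category realises on
_CATEGORY_ITEMTYPE = {
    "NULL_ALLELE": "typing",
    "HOMOZYGOSITY": "typing",
    "ALLELE_MISMATCH": "typing",
    "NOMENCLATURE": "typing",
    "IDENTIFICATION": "specificity",
    "FALSE_POSITIVE_SPECIFICITY": "specificity",
    "FALSE_NEGATIVE_SPECIFICITY": "specificity",
    "SCREENING": "screening",
    "QUANTIFICATION": "quant",
    "QUALITATIVE_MISMATCH": "qualitative",
    "RISK_INTERPRETATION": "risk",
}


def default_cd_risk_map() -> RiskMap:
    """The packaged coeliac-disease HLA-DQ risk map."""
    import json
    from importlib import resources

    with resources.files("immunoeqa.data").joinpath("cd_risk.json").open() as fh:
        return RiskMap.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# records and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthRecord:
    scheme: str
    year: int
    sample: str
    parameter: str
    value: str


@dataclass(frozen=True)
class ReportRecord:
    lab: str
    scheme: str
    year: int
    sample: str
    parameter: str
    method: str
    value: str
    excluded_nulls: str = ""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one simulated programme run.

    Defaults are a "mini programme": up to ``max_labs`` laboratories per
    scheme-year (capped published participation), 8 samples per
    scheme-year (16 for chimerism, whose panel carries more parameters),
    three recent years, published per-scheme-year error rates and
    published per-scheme category mixes.  Every probability-bearing field
    is overridable.
    """

    years: tuple[int, ...] = (2020, 2021, 2022)
    schemes: tuple[str, ...] = ALL_SCHEMES
    labs_per_scheme_year: Optional[Mapping[str, int]] = None
    samples_per_scheme_year: Optional[Mapping[str, int]] = None
    max_labs: int = 20
    default_samples: int = 8
    error_rate: Optional[Mapping] = None  # scheme -> rate or (scheme, year) -> rate
    error_category_mix: Optional[Mapping[str, Mapping[str, float]]] = None
    method_mix: Optional[Mapping[str, Mapping[str, float]]] = None
    chimerism_truth: tuple[float, float] = (5.0, 95.0)
    report_noise: float = 0.0
    quant_shift: tuple[float, float] = (12.0, 30.0)
    truth_positive_rate: float = 0.3
    lab_error_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.schemes) - set(ALL_SCHEMES)
        if unknown:
            raise InvalidConfig(f"unknown schemes: {sorted(unknown)}")
        if not 0.0 <= self.truth_positive_rate <= 1.0:
            raise InvalidConfig("truth_positive_rate must be in [0, 1]")
        lo, hi = self.chimerism_truth
        if not (0.0 <= lo <= hi <= 100.0):
            raise InvalidConfig("chimerism_truth bounds must satisfy 0 <= lo <= hi <= 100")
        if self.report_noise < 0:
            raise InvalidConfig("report_noise must be >= 0")
        for scheme, mix in (self.error_category_mix or {}).items():
            total = sum(mix.values())
            if mix and abs(total - 1.0) > 1e-6:
                raise InvalidConfig(f"category mix for {scheme} sums to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise InvalidConfig(f"negative category probability for {scheme}")

    # -- resolved accessors ----------------------------------------------
    def n_labs(self, scheme: str, year: int) -> int:
        if self.labs_per_scheme_year and scheme in self.labs_per_scheme_year:
            return int(self.labs_per_scheme_year[scheme])
        part = _participation_lookup()
        return min(part.get((scheme, year), 10), self.max_labs)

    def n_samples(self, scheme: str) -> int:
        if self.samples_per_scheme_year and scheme in self.samples_per_scheme_year:
            return int(self.samples_per_scheme_year[scheme])
        return 16 if scheme == "CHM" else self.default_samples

    def rate(self, scheme: str, year: int) -> float:
        if self.error_rate is not None:
            if (scheme, year) in self.error_rate:
                return float(self.error_rate[(scheme, year)])
            if scheme in self.error_rate:
                return float(self.error_rate[scheme])
        return _default_rate(scheme, year)

    def mix(self, scheme: str) -> dict[str, float]:
        if self.error_category_mix and scheme in self.error_category_mix:
            return dict(self.error_category_mix[scheme])
        return dict(DEFAULT_CATEGORY_MIXES[scheme])

    def methods(self, scheme: str) -> dict[str, float]:
        if self.method_mix and scheme in self.method_mix:
            return dict(self.method_mix[scheme])
        return dict(DEFAULT_METHOD_MIXES[scheme])

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        kwargs = dict(d)
        for key in ("years", "schemes"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        for key in ("chimerism_truth", "quant_shift"):
            if key in kwargs:
                kwargs[key] = tuple(float(v) for v in kwargs[key])
        return cls(**kwargs)


_PART_CACHE: Optional[dict] = None
_RATE_CACHE: Optional[dict] = None


def _participation_lookup() -> dict:
    global _PART_CACHE
    if _PART_CACHE is None:
        df = aggregation.load_reference_participation()
        _PART_CACHE = {
            (r.scheme, int(r.year)): int(r.labs) for r in df.itertuples()
        }
    return _PART_CACHE


def _default_rate(scheme: str, year: int) -> float:
    """1 - published success rate, per scheme-year; scheme mean fallback."""
    global _RATE_CACHE
    if _RATE_CACHE is None:
        df = aggregation.load_reference_success_rates()
        by_cell = {
            (r.scheme, int(r.year)): 1.0 - float(r.success_rate) / 100.0
            for r in df.itertuples()
        }
        by_scheme = {
            s: 1.0 - float(g["success_rate"].mean()) / 100.0
            for s, g in df.groupby("scheme")
        }
        _RATE_CACHE = {"cell": by_cell, "scheme": by_scheme}
    return _RATE_CACHE["cell"].get((scheme, year), _RATE_CACHE["scheme"].get(scheme, 0.01))


# ---------------------------------------------------------------------------
# RNG streams
# ---------------------------------------------------------------------------

def _crc(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


def _truth_rng(seed: int, scheme: str, year: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _crc(scheme), int(year), 0xA]))


def _lab_rng(seed: int, scheme: str, year: int, lab_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _crc(scheme), int(year), 0xB, int(lab_idx)])
    )


def _lab_multiplier(seed: int, lab_idx: int, sigma: float) -> float:
    if sigma <= 0:
        return 1.0
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC, int(lab_idx)]))
    return float(rng.lognormal(mean=0.0, sigma=sigma))


def _choice(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    keys = sorted(weights)
    probs = np.array([weights[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


# ---------------------------------------------------------------------------
# truth generation
# ---------------------------------------------------------------------------

_SCREEN_CLASS_I_PREFIXES = ("A", "B", "CW")


def _spec_class(spec: str) -> str:
    s = spec.upper()
    if s.startswith(("DR", "DQ", "DP")):
        return "II"
    return "I"


def _sample_items(scheme: str) -> list[tuple[str, str]]:
    """(parameter, itemtype) pairs scored for one sample of a scheme."""
    if scheme in DEFAULT_TYPING_LOCI and scheme != "CD":
        return [(f"typing:{locus}", "typing") for locus in DEFAULT_TYPING_LOCI[scheme]]
    if scheme == "CD":
        return [(f"typing:{locus}", "typing") for locus in DEFAULT_TYPING_LOCI["CD"]] + [
            ("risk", "risk")
        ]
    if scheme in ("B27", "B57"):
        return [("presence", "qualitative")]
    if scheme in ("XM", "XMFC"):
        return [("xm:whole", "qualitative"), ("xm:t", "qualitative"), ("xm:b", "qualitative")]
    if scheme == "CHM":
        return [("chimerism", "quant"), ("chimerism_interpretation", "qualitative")]
    if scheme == "ALO":
        items = [(f"specificity:{s}", "specificity") for s in DEFAULT_ANTIBODY_PANELS["ALO"]]
        items += [("screening:class_i", "screening"), ("screening:class_ii", "screening")]
        items += [("dqdp", "qualitative")]
        return items
    if scheme == "AHPA":
        items = [(f"specificity:{s}", "specificity") for s in DEFAULT_ANTIBODY_PANELS["AHPA"]]
        items += [("screening:hpa", "screening")]
        return items
    raise InvalidConfig(f"no item model for scheme {scheme!r}")


def generate_truth(config: SimulationConfig) -> list[TruthRecord]:
    """Per-sample true values for every configured scheme-year.

    Typing truths draw two distinct expressed alleles per locus (no null
    is ever a truth allele; nulls exist in the pool for error injection).
    Antibody truths mark each panel specificity positive independently;
    screening truths derive from them.  Chimerism truths are uniform on
    ``chimerism_truth``.
    """
    risk_map = default_cd_risk_map()
    records: list[TruthRecord] = []
    for scheme in config.schemes:
        for year in config.years:
            rng = _truth_rng(config.seed, scheme, year)
            for s_idx in range(config.n_samples(scheme)):
                sample = f"{scheme}-{year}-S{s_idx + 1:02d}"
                records.extend(
                    _truth_for_sample(scheme, year, sample, rng, config, risk_map)
                )
    return records


def _truth_for_sample(
    scheme: str,
    year: int,
    sample: str,
    rng: np.random.Generator,
    config: SimulationConfig,
    risk_map: RiskMap,
) -> list[TruthRecord]:
    recs: list[TruthRecord] = []

    def add(parameter: str, value: str) -> None:
        recs.append(TruthRecord(scheme, year, sample, parameter, value))

    if scheme in DEFAULT_TYPING_LOCI:
        genotypes = {}
        for locus in DEFAULT_TYPING_LOCI[scheme]:
            if scheme == "SER":
                pool = DEFAULT_SERO_POOLS[locus]
            else:
                pool = DEFAULT_ALLELE_POOLS[locus]
            pair = rng.choice(len(pool), size=2, replace=False)
            alleles = sorted(pool[i] for i in pair)
            value = "+".join(alleles)
            genotypes[locus] = parse_genotype(value)
            add(f"typing:{locus}", genotypes[locus].render())
        if scheme == "CD":
            add("risk", risk_map.classify(genotypes))
        return recs

    if scheme in ("B27", "B57"):
        add("presence", "POSITIVE" if rng.random() < config.truth_positive_rate else "NEGATIVE")
        return recs

    if scheme in ("XM", "XMFC"):
        t = rng.random() < config.truth_positive_rate
        b = rng.random() < config.truth_positive_rate
        add("xm:whole", "POSITIVE" if (t or b) else "NEGATIVE")
        add("xm:t", "POSITIVE" if t else "NEGATIVE")
        add("xm:b", "POSITIVE" if b else "NEGATIVE")
        return recs

    if scheme == "CHM":
        lo, hi = config.chimerism_truth
        v = float(rng.uniform(lo, hi))
        add("chimerism", f"{v:.2f}")
        add("chimerism_interpretation", "POSITIVE" if v >= 1.0 else "NEGATIVE")
        return recs

    if scheme in ("ALO", "AHPA"):
        panel = DEFAULT_ANTIBODY_PANELS[scheme]
        positives = sorted(
            s for s in panel if rng.random() < config.truth_positive_rate
        )
        add("abid", ";".join(positives))
        if scheme == "ALO":
            add(
                "screening:class_i",
                "POSITIVE" if any(_spec_class(s) == "I" for s in positives) else "NEGATIVE",
            )
            add(
                "screening:class_ii",
                "POSITIVE" if any(_spec_class(s) == "II" for s in positives) else "NEGATIVE",
            )
            add(
                "dqdp",
                "POSITIVE"
                if any(s.upper().startswith(("DQ", "DP")) for s in positives)
                else "NEGATIVE",
            )
        else:
            add("screening:hpa", "POSITIVE" if positives else "NEGATIVE")
        return recs

    raise InvalidConfig(f"no truth model for scheme {scheme!r}")


# ---------------------------------------------------------------------------
# report generation (error injection)
# ---------------------------------------------------------------------------

def _item_probabilities(
    scheme: str, rate: float, mix: Mapping[str, float]
) -> dict[str, float]:
    """Per-item error probability by item type.

    ``p_t = rate * mass_t * N / n_t`` keeps the overall per-result error
    rate at ``rate`` while realising categories in their mix proportions
    even when a sample carries items of several types.  Probabilities
    saturate at 1, so extreme rates concentrate errors on the mix's
    dominant item type and the realised overall rate falls short of the
    nominal one.
    """
    items = _sample_items(scheme)
    n_total = len(items)
    type_counts: dict[str, int] = {}
    for _, itype in items:
        type_counts[itype] = type_counts.get(itype, 0) + 1
    masses: dict[str, float] = {t: 0.0 for t in type_counts}
    for cat, p in mix.items():
        itype = _CATEGORY_ITEMTYPE.get(cat)
        if itype is None:
            raise InvalidConfig(f"unknown error category {cat!r} in mix for {scheme}")
        if itype not in type_counts:
            raise InvalidConfig(
                f"category {cat!r} not realisable on any item of scheme {scheme}"
            )
        masses[itype] += float(p)
    probs = {}
    for itype, n_t in type_counts.items():
        probs[itype] = min(rate * masses[itype] * n_total / n_t, 1.0)
    return probs


def _typing_categories(mix: Mapping[str, float]) -> dict[str, float]:
    sub = {c: p for c, p in mix.items() if _CATEGORY_ITEMTYPE[c] == "typing"}
    total = sum(sub.values())
    return {c: p / total for c, p in sub.items()}


def _report_resolution(scheme: str, rng: np.random.Generator) -> Optional[int]:
    if scheme == "HI":
        return int(rng.choice([2, 3]))
    if scheme == "LOW":
        return 1
    return None  # full resolution as drawn


def _truncate_allele(allele: AlleleCall, n_fields: Optional[int]) -> AlleleCall:
    if n_fields is None or not allele.molecular or allele.resolution <= n_fields:
        return allele
    return allele.truncate(n_fields)


def _render_truth_genotype(truth_value: str, n_fields: Optional[int]) -> str:
    g = parse_genotype(truth_value)
    parts = []
    for call in g.calls:
        parts.append(
            "/".join(_truncate_allele(a, n_fields).render() for a in call.alternatives)
        )
    return "+".join(parts)


def _inject_typing_error(
    category: str,
    truth_value: str,
    locus: str,
    scheme: str,
    n_fields: Optional[int],
    rng: np.random.Generator,
) -> str:
    from .nomenclature import concordant_allele

    g = parse_genotype(truth_value)
    a1, a2 = (g.calls[0].alternatives[0], g.calls[-1].alternatives[0])
    r1, r2 = _truncate_allele(a1, n_fields), _truncate_allele(a2, n_fields)

    if category == "NULL_ALLELE":
        null = DEFAULT_NULL_ALLELES[locus]
        which = int(rng.integers(2))
        parts = [r1.render(), r2.render()]
        parts[which] = f"{parts[which]}/{parse_allele(null).render()}"
        return "+".join(parts)

    if category == "HOMOZYGOSITY":
        keep = r1 if int(rng.integers(2)) == 0 else r2
        return keep.render()

    if category == "ALLELE_MISMATCH":
        pool = DEFAULT_SERO_POOLS[locus] if scheme == "SER" else DEFAULT_ALLELE_POOLS[locus]
        candidates = []
        for cand in pool:
            c = _truncate_allele(parse_allele(cand), n_fields)
            if not concordant_allele(c, a1) and not concordant_allele(c, a2):
                candidates.append(c)
        if not candidates:  # degenerate pool; fall back to dropping a copy
            return r1.render()
        sub = candidates[int(rng.integers(len(candidates)))]
        which = int(rng.integers(2))
        reported = [r1.render(), r2.render()]
        reported[which] = sub.render()
        return "+".join(sorted(reported))

    raise InvalidConfig(f"cannot realise typing category {category!r}")


def generate_reports(
    truths: Sequence[TruthRecord], config: SimulationConfig
) -> list[ReportRecord]:
    """Laboratory report records with seeded error injection.

    Each scored item is erroneous with its scheme-year probability
    (modulated by the per-lab multiplier when ``lab_error_sigma`` > 0);
    the error's category follows the scheme's configured mix and is
    realised concretely on the report payload.
    """
    truth_by_sample: dict[tuple[str, int, str], dict[str, str]] = {}
    samples_by_scheme_year: dict[tuple[str, int], list[str]] = {}
    for t in truths:
        key = (t.scheme, t.year, t.sample)
        if key not in truth_by_sample:
            truth_by_sample[key] = {}
            samples_by_scheme_year.setdefault((t.scheme, t.year), []).append(t.sample)
        truth_by_sample[key][t.parameter] = t.value

    risk_map = default_cd_risk_map()
    reports: list[ReportRecord] = []
    for (scheme, year), samples in samples_by_scheme_year.items():
        mix = config.mix(scheme)
        base_rate = config.rate(scheme, year)
        n_labs = config.n_labs(scheme, year)
        for lab_idx in range(1, n_labs + 1):
            lab = f"L{lab_idx:03d}"
            rng = _lab_rng(config.seed, scheme, year, lab_idx)
            rate = min(
                base_rate * _lab_multiplier(config.seed, lab_idx, config.lab_error_sigma),
                0.95,
            )
            probs = _item_probabilities(scheme, rate, mix)
            method = _choice(rng, config.methods(scheme))
            for sample in samples:
                truth = truth_by_sample[(scheme, year, sample)]
                reports.extend(
                    _reports_for_sample(
                        lab, scheme, year, sample, method, truth,
                        mix, probs, rng, config, risk_map,
                    )
                )
    return reports


def _reports_for_sample(
    lab: str,
    scheme: str,
    year: int,
    sample: str,
    method: str,
    truth: Mapping[str, str],
    mix: Mapping[str, float],
    probs: Mapping[str, float],
    rng: np.random.Generator,
    config: SimulationConfig,
    risk_map: RiskMap,
) -> list[ReportRecord]:
    out: list[ReportRecord] = []

    def add(parameter: str, value: str, excluded: str = "") -> None:
        out.append(
            ReportRecord(lab, scheme, year, sample, parameter, method, value, excluded)
        )

    items = _sample_items(scheme)
    n_fields = _report_resolution(scheme, rng)

    # antibody specificity items mutate a shared reported-positive set
    abid_truth = set(truth.get("abid", "").split(";")) - {""}
    abid_reported = set(abid_truth)
    has_abid = any(itype == "specificity" for _, itype in items)

    for parameter, itype in items:
        err = rng.random() < probs.get(itype, 0.0)
        if itype == "typing":
            locus = parameter.split(":", 1)[1]
            truth_value = truth[parameter]
            if err:
                cats = _typing_categories(mix)
                category = _choice(rng, cats)
                add(parameter, _inject_typing_error(category, truth_value, locus, scheme, n_fields, rng))
            else:
                add(parameter, _render_truth_genotype(truth_value, n_fields))
        elif itype == "risk":
            true_label = truth["risk"]
            if err:
                others = [l for l in risk_map.labels() if l != true_label]
                add(parameter, others[int(rng.integers(len(others)))])
            else:
                add(parameter, true_label)
        elif itype == "quant":
            v = float(truth[parameter])
            if err:
                lo, hi = config.quant_shift
                shift = float(rng.uniform(lo, hi))
                v = v - shift if v > 50.0 else v + shift
            else:
                v = v + float(rng.uniform(-config.report_noise, config.report_noise))
            add(parameter, f"{min(max(v, 0.0), 100.0):.2f}")
        elif itype == "specificity":
            spec = parameter.split(":", 1)[1]
            if err:
                if spec in abid_reported:
                    abid_reported.discard(spec)  # false negative
                else:
                    abid_reported.add(spec)  # false positive
        elif itype in ("screening", "qualitative"):
            true_call = truth[parameter]
            if err:
                add(parameter, "NEGATIVE" if true_call == "POSITIVE" else "POSITIVE")
            else:
                add(parameter, true_call)
        else:  # pragma: no cover
            raise InvalidConfig(f"unhandled item type {itype!r}")

    if has_abid:
        add("abid", ";".join(sorted(abid_reported)))
    return out


def simulate(config: SimulationConfig) -> tuple[list[TruthRecord], list[ReportRecord]]:
    """Convenience wrapper: truths plus error-injected reports."""
    truths = generate_truth(config)
    return truths, generate_reports(truths, config)
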