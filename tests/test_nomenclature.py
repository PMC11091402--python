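"""Typing-string parsing, normalisation and concordance rules."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from immunoeqa.nomenclature import (
    AmbiguousCall,
    LocusMismatch,
    MalformedAllele,
    MalformedGenotype,
    concordant_allele,
    genotype_concordant,
    parse_allele,
    parse_genotype,
    unexcluded_null,
)

from conftest import genotype_concordance_oracle


class TestParseAllele:
    @pytest.mark.parametrize(
        "text, locus, fields, suffix",
        [
            ("A*24:02", "HLA-A", ("24", "02"), None),
            ("A*01:04N", "HLA-A", ("01", "04"), "N"),
            ("B*57:01:01", "HLA-B", ("57", "01", "01"), None),
            ("HLA-DQB1*03:38N", "HLA-DQB1", ("03", "38"), "N"),
            ("KIR2DL1*003", "KIR2DL1", ("003",), None),
            ("hla-a*02:01", "HLA-A", ("02", "01"), None),
        ],
    )
    def test_molecular_parse(self, text, locus, fields, suffix):
        a = parse_allele(text)
        assert (a.locus, a.fields, a.expression_suffix) == (locus, fields, suffix)
        assert a.molecular

    def test_null_flag(self):
        assert parse_allele("A*01:04N").is_null()
        assert not parse_allele("A*01:04").is_null()
        assert not parse_allele("A*24:02L").is_null()

    def test_resolution(self):
        assert parse_allele("B*57:01:01").resolution == 3

    def test_serology_parse(self):
        a = parse_allele("A2")
        assert a.locus == "HLA-A" and a.fields == ("2",) and not a.molecular
        assert parse_allele("HLA-B27").render() == "HLA-B27"

    def test_leading_zeros_compare_numerically(self):
        assert parse_allele("A*2:1") == parse_allele("A*02:01")
        assert parse_allele("A*2:1").render() == "HLA-A*02:01"

    @pytest.mark.parametrize(
        "bad", ["", "A*", "A*24::02", "A*24:02Z", "A*01:02:03:04:05", "ZZT0P", "A*xx:01"]
    )
    def test_malformed(self, bad):
        with pytest.raises(MalformedAllele):
            parse_allele(bad)


class TestParseGenotype:
    def test_two_copies(self):
        g = parse_genotype("A*02:01+A*03:01")
        assert len(g.calls) == 2 and not g.reported_doubled
        assert g.locus == "HLA-A"

    def test_ambiguity_alternatives(self):
        g = parse_genotype("A*02:01/A*02:09+A*03:01")
        sizes = sorted(len(c.alternatives) for c in g.calls)
        assert sizes == [1, 2]

    def test_single_call_not_doubled(self):
        g = parse_genotype("A*02:01")
        assert len(g.calls) == 1 and not g.reported_doubled
        assert g.is_homozygous_claim()

    def test_doubled_allele_flag(self):
        g = parse_genotype("A*02:01+A*02:01")
        assert g.reported_doubled and g.is_homozygous_claim()

    def test_rejects_full_gl_string_operators(self):
        with pytest.raises(MalformedGenotype):
            parse_genotype("A*02:01+A*03:01|A*02:01+A*11:01")
        with pytest.raises(MalformedGenotype):
            parse_genotype("A*02:01^B*07:02")

    def test_rejects_three_copies_and_mixed_loci(self):
        with pytest.raises(MalformedGenotype):
            parse_genotype("A*02:01+A*03:01+A*11:01")
        with pytest.raises(MalformedGenotype):
            parse_genotype("A*02:01+B*07:02")

    def test_excluded_null_must_be_null(self):
        with pytest.raises(MalformedGenotype):
            parse_genotype("A*02:01", excluded_nulls=["A*03:01"])


# hypothesis corpus of valid molecular alleles
_allele_strings = st.builds(
    lambda locus, fields, suffix: f"{locus}*{':'.join(fields)}{suffix}",
    st.sampled_from(["A", "B", "DRB1", "HLA-DQB1", "KIR2DL1"]),
    st.lists(
        st.integers(1, 199).map(lambda n: str(n)), min_size=1, max_size=4
    ),
    st.sampled_from(["", "N", "L", "Q"]),
)


class TestRoundTrip:
    @given(_allele_strings)
    def test_parse_render_fixed_point(self, text):
        a = parse_allele(text)
        rendered = a.render()
        assert parse_allele(rendered).render() == rendered

    @given(
        st.sampled_from(["A", "B", "DRB1"]),
        st.lists(
            st.tuples(
                st.lists(st.integers(1, 199).map(str), min_size=1, max_size=4),
                st.sampled_from(["", "N", "Q"]),
            ),
            min_size=1,
            max_size=2,
        ),
    )
    def test_genotype_render_fixed_point(self, locus, bodies):
        alleles = [f"{locus}*{':'.join(fields)}{suffix}" for fields, suffix in bodies]
        g = parse_genotype("+".join(alleles))
        rendered = g.render()
        assert parse_genotype(rendered).render() == rendered


class TestAlleleConcordance:
    def test_lower_resolution_matches_truth(self):
        assert concordant_allele(parse_allele("A*24:02"), parse_allele("A*24:02:01:01"))

    def test_field_mismatch(self):
        assert not concordant_allele(parse_allele("A*24:02"), parse_allele("A*24:03"))

    def test_higher_resolution_than_truth_is_not_prefix(self):
        assert not concordant_allele(parse_allele("A*24:02:01"), parse_allele("A*24:02"))

    def test_locus_mismatch_raises(self):
        with pytest.raises(LocusMismatch):
            concordant_allele(parse_allele("A*24:02"), parse_allele("B*07:02"))

    def test_suffix_conflict_enumeration(self):
        # expressed-vs-null conflicts in both directions; matching
        # suffixes agree; differing explicit non-null suffixes conflict
        suffixes = ["", "N", "L", "Q"]
        for s1, s2 in itertools.product(suffixes, repeat=2):
            a = parse_allele(f"A*01:04{s1}")
            b = parse_allele(f"A*01:04{s2}")
            expected = not (
                ((s1 == "N") != (s2 == "N"))
                or (s1 and s2 and s1 != s2)
            )
            assert concordant_allele(a, b) is expected, (s1, s2)

    @given(_allele_strings)
    def test_reflexive(self, text):
        a = parse_allele(text)
        assert concordant_allele(a, a)

    @given(_allele_strings, st.integers(1, 4))
    def test_truncation_recovers_reported_form(self, text, k):
        # anti-symmetry in resolution: if a (shorter) is concordant with
        # b, then b truncated to a's resolution equals a
        b = parse_allele(text)
        k = min(k, b.resolution)
        a = b.truncate(k)
        assert concordant_allele(a, b)
        assert b.truncate(a.resolution) == a


_POOL = ["A*01:01:01", "A*02:01:01", "A*24:02:01", "A*01:04N"]


def _genotypes_from_pool(pool, with_ambiguity=False):
    """All 1- and 2-call genotypes; optionally 2-alternative calls."""
    singles = [parse_genotype(a) for a in pool]
    pairs = [parse_genotype(f"{a}+{b}") for a, b in itertools.combinations_with_replacement(pool, 2)]
    out = singles + pairs
    if with_ambiguity:
        for a, b in itertools.combinations(pool, 2):
            for c in pool:
                out.append(parse_genotype(f"{a}/{b}+{c}"))
    return out


class TestGenotypeConcordance:
    def test_prefix_match_both_copies(self):
        rep = parse_genotype("A*02:01+A*03:01")
        tru = parse_genotype("A*02:01:01+A*03:01:01")
        assert genotype_concordant(rep, tru)

    def test_ambiguous_alternative_satisfies_copy(self):
        rep = parse_genotype("A*02:01/A*02:09+A*03:01")
        tru = parse_genotype("A*02:01+A*03:01")
        assert genotype_concordant(rep, tru)

    def test_homozygous_report_vs_heterozygous_truth_fails(self):
        rep = parse_genotype("A*02:01+A*02:01")
        tru = parse_genotype("A*02:01+A*68:01")
        assert not genotype_concordant(rep, tru)

    def test_homozygous_report_vs_homozygous_truth(self):
        assert genotype_concordant(
            parse_genotype("A*02:01"), parse_genotype("A*02:01:01+A*02:01:01")
        )

    def test_matches_bruteforce_enumeration(self):
        # agreement with an explicit alternative-to-copy assignment search
        genos = _genotypes_from_pool(_POOL, with_ambiguity=True)
        truths = _genotypes_from_pool([a for a in _POOL if not a.endswith("N")])
        checked = 0
        for rep in genos:
            for tru in truths:
                assert genotype_concordant(rep, tru) == genotype_concordance_oracle(rep, tru), (
                    rep.render(), tru.render(),
                )
                checked += 1
        assert checked > 300


class TestUnexcludedNull:
    def test_unresolved_null_ambiguity(self):
        g = parse_genotype("DQB1*03:01/DQB1*03:38N+DQB1*02:01")
        flagged = [unexcluded_null(c) for c in g.calls]
        assert sum(flagged) == 1

    def test_no_null_present(self):
        g = parse_genotype("DQB1*03:01+DQB1*02:01")
        assert not any(unexcluded_null(c) for c in g.calls)

    def test_explicit_exclusion_clears_flag(self):
        g = parse_genotype(
            "DQB1*03:01/DQB1*03:38N+DQB1*02:01", excluded_nulls=["DQB1*03:38N"]
        )
        assert not any(unexcluded_null(c) for c in g.calls)

    def test_alternative_order_irrelevant(self):
        g1 = parse_genotype("DQB1*03:38N/DQB1*03:01+DQB1*02:01")
        g2 = parse_genotype("DQB1*03:01/DQB1*03:38N+DQB1*02:01")
        assert g1 == g2
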