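"""Evaluation of laboratory results and the error taxonomy."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from immunoeqa.consensus import (
    AssignedMode,
    AssignedValue,
    AntibodyStatus,
    QualStatus,
    RobustStats,
)
from immunoeqa.nomenclature import parse_genotype
from immunoeqa.scoring import (
    ErrorCategory,
    Evaluation,
    NoValidResults,
    RiskMap,
    RiskRule,
    ScoringParams,
    Status,
    UnknownSpecificity,
    evaluate_antibody,
    evaluate_chimerism,
    evaluate_qualitative,
    evaluate_risk,
    evaluate_screening,
    evaluate_typing,
    scheme_pass,
)

from conftest import genotype_concordance_oracle


def _assigned_genotype(text, mode=AssignedMode.REFERENCE):
    g = parse_genotype(text)
    return AssignedValue(parameter=f"typing:{g.locus}", mode=mode, payload=g, support=1.0, n=1)


class TestEvaluateTyping:
    def test_unexcluded_null_is_the_dominant_error(self):
        ev = evaluate_typing(
            "DQB1*03:01/DQB1*03:38N+DQB1*02:01",
            _assigned_genotype("DQB1*03:01+DQB1*02:01"),
        )
        assert (ev.status, ev.category) == (Status.ERROR, ErrorCategory.NULL_ALLELE)

    def test_excluded_null_scores_correct(self):
        ev = evaluate_typing(
            "DQB1*03:01/DQB1*03:38N+DQB1*02:01",
            _assigned_genotype("DQB1*03:01+DQB1*02:01"),
            excluded_nulls=["DQB1*03:38N"],
        )
        assert ev.status is Status.CORRECT

    def test_lower_resolution_concordance_not_penalised(self):
        ev = evaluate_typing(
            "A*24:02+A*03:01", _assigned_genotype("A*24:02:01:01+A*03:01:01")
        )
        assert ev.status is Status.CORRECT

    def test_homozygosity_error(self):
        ev = evaluate_typing("A*02:01+A*02:01", _assigned_genotype("A*02:01+A*68:01"))
        assert (ev.status, ev.category) == (Status.ERROR, ErrorCategory.HOMOZYGOSITY)

    def test_single_written_allele_also_homozygosity(self):
        ev = evaluate_typing("A*02:01", _assigned_genotype("A*02:01+A*68:01"))
        assert (ev.status, ev.category) == (Status.ERROR, ErrorCategory.HOMOZYGOSITY)

    def test_wrong_allele_is_mismatch(self):
        ev = evaluate_typing("A*11:01+A*03:01", _assigned_genotype("A*02:01+A*03:01"))
        assert (ev.status, ev.category) == (Status.ERROR, ErrorCategory.ALLELE_MISMATCH)

    def test_unparseable_report_is_nomenclature_error(self):
        ev = evaluate_typing("A*zz:01+A*03:01", _assigned_genotype("A*02:01+A*03:01"))
        assert (ev.status, ev.category) == (Status.ERROR, ErrorCategory.NOMENCLATURE)

    def test_wrong_locus_is_nomenclature_error(self):
        ev = evaluate_typing("B*07:02+B*08:01", _assigned_genotype("A*02:01+A*03:01"))
        assert (ev.status, ev.category) == (Status.ERROR, ErrorCategory.NOMENCLATURE)

    def test_no_assigned_value_not_evaluable(self):
        av = AssignedValue(parameter="typing:HLA-A", mode=AssignedMode.NOT_EVALUABLE)
        ev = evaluate_typing("A*02:01+A*03:01", av)
        assert ev.status is Status.NOT_EVALUABLE and ev.category is None

    def test_report_equal_to_assigned_always_correct(self):
        pool = ["A*01:01:01", "A*02:01:01", "A*24:02:01"]
        for a, b in itertools.combinations_with_replacement(pool, 2):
            g = f"{a}+{b}"
            assert evaluate_typing(g, _assigned_genotype(g)).status is Status.CORRECT

    def test_alternative_order_never_changes_outcome(self):
        av = _assigned_genotype("A*02:01+A*03:01")
        e1 = evaluate_typing("A*02:01/A*01:04N+A*03:01", av)
        e2 = evaluate_typing("A*01:04N/A*02:01+A*03:01", av)
        assert (e1.status, e1.category) == (e2.status, e2.category)


def _decision_tree_oracle(report_text, truth_text):
    """Independent restatement of the typing decision order, using the
    brute-force concordance enumeration."""
    from immunoeqa.nomenclature import unexcluded_null

    rep = parse_genotype(report_text)
    tru = parse_genotype(truth_text)
    truth_expressed = not any(a.is_null() for a in tru.all_alternatives())
    if truth_expressed and any(unexcluded_null(c) for c in rep.calls):
        return ErrorCategory.NULL_ALLELE
    if genotype_concordance_oracle(rep, tru):
        return None  # correct
    rep_homo = len(rep.calls) == 1 or rep.calls[0] == rep.calls[1]
    tru_homo = len(tru.calls) == 1 or tru.calls[0] == tru.calls[1]
    if rep_homo and not tru_homo:
        from conftest import _allele_ok

        if any(
            _allele_ok(r, t)
            for tc in tru.calls
            for r in rep.calls[0].alternatives
            for t in tc.alternatives
        ):
            return ErrorCategory.HOMOZYGOSITY
    return ErrorCategory.ALLELE_MISMATCH


class TestDecisionTreeExhaustive:
    def test_all_pool_combinations_match_oracle(self):
        # every report x truth combination from a 4-allele pool with one
        # null: outcome is always one of the four typing outcomes and
        # agrees with the independent rule oracle
        pool = ["A*01:01", "A*02:01", "A*24:02", "A*01:04N"]
        expressed = [a for a in pool if not a.endswith("N")]
        reports = [f"{a}+{b}" for a, b in itertools.combinations_with_replacement(pool, 2)]
        reports += list(pool)
        reports += [f"{a}/{b}+{c}" for a, b in itertools.combinations(pool, 2) for c in pool]
        truths = [f"{a}+{b}" for a, b in itertools.combinations_with_replacement(expressed, 2)]
        truths += list(expressed)
        allowed = {
            (Status.CORRECT, None),
            (Status.ERROR, ErrorCategory.NULL_ALLELE),
            (Status.ERROR, ErrorCategory.HOMOZYGOSITY),
            (Status.ERROR, ErrorCategory.ALLELE_MISMATCH),
        }
        n = 0
        for rep in reports:
            for tru in truths:
                ev = evaluate_typing(rep, _assigned_genotype(tru))
                assert (ev.status, ev.category) in allowed, (rep, tru)
                expected = _decision_tree_oracle(rep, tru)
                if expected is None:
                    assert ev.status is Status.CORRECT, (rep, tru)
                else:
                    assert ev.category is expected, (rep, tru, ev.category)
                n += 1
        assert n == len(reports) * len(truths) > 300


class TestEvaluateAntibody:
    ASSIGNED = {
        "A2": AntibodyStatus.POSITIVE,
        "B7": AntibodyStatus.NEGATIVE,
        "DR4": AntibodyStatus.NON_ASSESSABLE,
        "DQ7": AntibodyStatus.NO_CONSENSUS,
    }

    def _by_param(self, evals):
        return {e.parameter.split(":", 1)[1]: e for e in evals}

    def test_false_negative_on_omitted_positive(self):
        evals = self._by_param(evaluate_antibody([], self.ASSIGNED))
        assert evals["A2"].category is ErrorCategory.FALSE_NEGATIVE_SPECIFICITY

    def test_false_positive_on_reported_negative(self):
        evals = self._by_param(evaluate_antibody(["A2", "B7"], self.ASSIGNED))
        assert evals["A2"].status is Status.CORRECT
        assert evals["B7"].category is ErrorCategory.FALSE_POSITIVE_SPECIFICITY

    def test_non_assessable_never_penalised(self):
        for reported in ([], ["DR4"]):
            evals = self._by_param(evaluate_antibody(reported, self.ASSIGNED))
            assert evals["DR4"].status is Status.NOT_EVALUABLE
            assert evals["DQ7"].status is Status.NOT_EVALUABLE

    def test_omitted_negative_correct(self):
        evals = self._by_param(evaluate_antibody(["A2"], self.ASSIGNED))
        assert evals["B7"].status is Status.CORRECT

    def test_unknown_specificity_raises(self):
        with pytest.raises(UnknownSpecificity):
            evaluate_antibody(["CW1"], self.ASSIGNED)

    def test_screening_mismatch_category(self):
        av = AssignedValue(
            parameter="screening:class_i",
            mode=AssignedMode.CONSENSUS,
            payload=QualStatus.POSITIVE,
            support=1.0,
            n=10,
        )
        ev = evaluate_screening("NEGATIVE", av)
        assert (ev.status, ev.category) == (Status.ERROR, ErrorCategory.SCREENING)


class TestEvaluateChimerism:
    STATS = RobustStats(x_star=12.1, s_star=0.3, n=15, iterations=3, converged=True)

    def test_within_two_robust_sd_correct(self):
        assert evaluate_chimerism(12.3, self.STATS).status is Status.CORRECT

    def test_exact_centre_always_correct(self):
        assert evaluate_chimerism(12.1, self.STATS).status is Status.CORRECT

    def test_gross_deviation_is_quantification_error(self):
        ev = evaluate_chimerism(30.0, self.STATS)
        assert (ev.status, ev.category) == (Status.ERROR, ErrorCategory.QUANTIFICATION)

    def test_degenerate_scale_uses_absolute_tolerance(self):
        stats = RobustStats(10.0, 0.0, 5, 0, True)
        assert evaluate_chimerism(14.0, stats).status is Status.CORRECT
        assert evaluate_chimerism(16.0, stats).status is Status.ERROR

    @given(st.floats(0, 100), st.floats(0, 100))
    def test_monotone_in_deviation(self, v1, v2):
        # increasing |value - x*| never converts ERROR into CORRECT
        d1, d2 = sorted([abs(v1 - self.STATS.x_star), abs(v2 - self.STATS.x_star)])
        near = evaluate_chimerism(min(self.STATS.x_star + d1, 100.0), self.STATS)
        far = evaluate_chimerism(min(self.STATS.x_star + d2, 100.0), self.STATS)
        if near.status is Status.ERROR:
            assert far.status is Status.ERROR

    def test_out_of_range_raises(self):
        from immunoeqa.consensus import OutOfRangeValue

        with pytest.raises(OutOfRangeValue):
            evaluate_chimerism(120.0, self.STATS)


class TestEvaluateQualitative:
    def _av(self, payload, mode=AssignedMode.CONSENSUS, parameter="xm:whole"):
        return AssignedValue(
            parameter=parameter,
            mode=mode,
            payload=payload,
            support=1.0 if payload else None,
            n=10,
        )

    def test_match_correct(self):
        ev = evaluate_qualitative("POSITIVE", self._av(QualStatus.POSITIVE))
        assert ev.status is Status.CORRECT

    def test_whole_blood_scored_against_whole_consensus_only(self):
        # lab inferred whole-blood positivity from a positive B-cell
        # crossmatch, but the whole-blood consensus is negative
        whole_av = self._av(QualStatus.NEGATIVE, parameter="xm:whole")
        ev = evaluate_qualitative("POSITIVE", whole_av)
        assert (ev.status, ev.category) == (Status.ERROR, ErrorCategory.QUALITATIVE_MISMATCH)

    def test_unassigned_not_evaluable(self):
        av = AssignedValue(parameter="xm:whole", mode=AssignedMode.NOT_EVALUABLE)
        assert evaluate_qualitative("NEGATIVE", av).status is Status.NOT_EVALUABLE


RISK_MAP = RiskMap(
    rules=(
        RiskRule("high", (("HLA-DQB1", "HLA-DQB1*02", 1), ("HLA-DQA1", "HLA-DQA1*05", 1))),
        RiskRule("moderate", (("HLA-DQB1", "HLA-DQB1*03:02", 1),)),
        RiskRule("low", (("HLA-DQB1", "HLA-DQB1*02", 1),)),
    ),
    default="very_low",
)


class TestEvaluateRisk:
    ASSIGNED = {
        "HLA-DQA1": _assigned_genotype("DQA1*05:01+DQA1*01:01"),
        "HLA-DQB1": _assigned_genotype("DQB1*02:01+DQB1*05:01"),
    }
    REPORTED = {
        "HLA-DQA1": parse_genotype("DQA1*05:01+DQA1*01:01"),
        "HLA-DQB1": parse_genotype("DQB1*02:01+DQB1*05:01"),
    }

    def test_correct_genotype_wrong_risk(self):
        evals = evaluate_risk(self.REPORTED, "very_low", self.ASSIGNED, RISK_MAP)
        by_param = {e.parameter: e for e in evals}
        assert all(
            by_param[p].status is Status.CORRECT
            for p in ("typing:HLA-DQA1", "typing:HLA-DQB1")
        )
        assert by_param["risk"].category is ErrorCategory.RISK_INTERPRETATION

    def test_matching_risk_all_correct(self):
        evals = evaluate_risk(self.REPORTED, "high", self.ASSIGNED, RISK_MAP)
        assert all(e.status is Status.CORRECT for e in evals)

    def test_unmapped_locus_not_evaluable(self):
        partial = {"HLA-DQA1": self.ASSIGNED["HLA-DQA1"]}
        evals = evaluate_risk(
            {"HLA-DQA1": self.REPORTED["HLA-DQA1"]}, "high", partial, RISK_MAP
        )
        assert {e.parameter: e.status for e in evals}["risk"] is Status.NOT_EVALUABLE

    def test_first_matching_rule_wins(self):
        genotypes = {
            "HLA-DQA1": parse_genotype("DQA1*05:01+DQA1*05:01"),
            "HLA-DQB1": parse_genotype("DQB1*02:01+DQB1*03:02"),
        }
        assert RISK_MAP.classify(genotypes) == "high"


def _mk_eval(sample, status, category=None, lab="L1"):
    return Evaluation(
        lab=lab, scheme="HI", year=2022, sample=sample, parameter="typing:HLA-A",
        status=status, category=category,
    )


class TestSchemePass:
    def test_zero_errors_pass(self):
        evals = [_mk_eval(f"S{i}", Status.CORRECT) for i in range(16)]
        assert scheme_pass(evals) == "PASS"

    def test_two_errored_samples_fail(self):
        evals = [
            _mk_eval("S1", Status.ERROR, ErrorCategory.ALLELE_MISMATCH),
            _mk_eval("S2", Status.ERROR, ErrorCategory.NULL_ALLELE),
            _mk_eval("S3", Status.CORRECT),
        ]
        assert scheme_pass(evals) == "FAIL"

    def test_one_errored_sample_passes_default_rule(self):
        evals = [
            _mk_eval("S1", Status.ERROR, ErrorCategory.ALLELE_MISMATCH),
            _mk_eval("S1", Status.ERROR, ErrorCategory.HOMOZYGOSITY),
            _mk_eval("S2", Status.CORRECT),
        ]
        assert scheme_pass(evals) == "PASS"

    def test_rule_is_configurable(self):
        evals = [
            _mk_eval("S1", Status.ERROR, ErrorCategory.ALLELE_MISMATCH),
            _mk_eval("S2", Status.CORRECT),
        ]
        assert scheme_pass(evals, ScoringParams(max_error_samples=0)) == "FAIL"

    def test_only_not_evaluable_raises(self):
        with pytest.raises(NoValidResults):
            scheme_pass([_mk_eval("S1", Status.NOT_EVALUABLE)])


class TestEvaluationInvariants:
    def test_category_iff_error(self):
        with pytest.raises(ValueError):
            Evaluation(
                lab="L1", scheme="HI", year=2022, sample="S", parameter="p",
                status=Status.CORRECT, category=ErrorCategory.NULL_ALLELE,
            )
        with pytest.raises(ValueError):
            Evaluation(
                lab="L1", scheme="HI", year=2022, sample="S", parameter="p",
                status=Status.ERROR,
            )
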