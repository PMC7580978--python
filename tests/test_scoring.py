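"""3F scoring, systemic features, and the five-way classification rules."""

import itertools

import pytest

import triplef as tf
from triplef.micro import Accordance, BacteraemiaStatus

ECOLI = "Escherichia coli"
SA = "Staphylococcus aureus"
SPN = "Streptococcus pneumoniae"


def make_encounter(
    *,
    fever=False,
    chills=False,
    organs=(),
    gu=(),
    pct=1.0,
    urine_species=(ECOLI,),
    blood_species=None,
    documented=tf.AltFocus.NONE,
    temperature=None,
):
    urine = tf.UrineCulture(
        tf.CollectionMethod.MIDSTREAM,
        [tf.Isolate(s, 1e5) for s in urine_species],
    )
    if blood_species:
        sets = [tf.BloodCultureSet("B1", [tf.Isolate(blood_species)]),
                tf.BloodCultureSet("B2")]
    else:
        sets = [tf.BloodCultureSet("B1"), tf.BloodCultureSet("B2")]
    return tf.Encounter(
        encounter_id="T", age_years=70, sex=tf.Sex.FEMALE,
        fever_at_triage=fever, chills_or_rigors_reported=chills,
        organ_dysfunctions={tf.OrganDysfunction(o) for o in organs},
        gu_symptoms={tf.GUSymptom(g) for g in gu},
        pct_ng_ml=pct, urine_culture=urine, blood_culture_sets=sets,
        documented_alt_focus=documented, triage_temperature_c=temperature,
    )


class TestFCriteria:
    def test_chills_alone_score_f1(self):
        assert tf.score_f1(make_encounter(chills=True)) is True

    def test_no_fever_indicator_scores_zero(self):
        assert tf.score_f1(make_encounter()) is False

    def test_measured_triage_temperature_thresholded(self):
        assert tf.score_f1(make_encounter(temperature=38.4)) is True
        assert tf.score_f1(make_encounter(temperature=37.5)) is False

    def test_any_organ_dysfunction_scores_f2(self):
        assert tf.score_f2(make_encounter(organs=["kidney"])) is True
        assert tf.score_f2(make_encounter()) is False

    @pytest.mark.parametrize(
        "gu, f3, lower_only",
        [
            (["dysuria"], True, True),
            (["flank_pain"], True, False),
            (["dysuria", "flank_pain"], True, False),
            ([], False, False),
        ],
    )
    def test_f3_and_lower_tract_distinction(self, gu, f3, lower_only):
        enc = make_encounter(gu=gu)
        assert tf.score_f3(enc) is f3
        assert tf.lower_gu_only(enc) is lower_only

    def test_score_is_the_sum_of_flags(self):
        full = tf.compute_triple_f(
            make_encounter(fever=True, organs=["kidney"], gu=["dysuria"])
        )
        assert (full.f1, full.f2, full.f3) == (True, True, True)
        assert full.score == 3
        assert tf.compute_triple_f(make_encounter()).score == 0


class TestSystemicFeatures:
    def test_raised_pct_alone_counts_by_default(self):
        enc = make_encounter(pct=0.8)
        assert tf.has_systemic_features(enc) is True

    def test_low_pct_and_no_clinical_signs(self):
        assert tf.has_systemic_features(make_encounter(pct=0.1)) is False

    def test_organ_failure_qualifies_regardless_of_pct(self):
        enc = make_encounter(organs=["kidney"], pct=0.05)
        assert tf.has_systemic_features(enc) is True


class TestAlternativeFocus:
    def test_documented_focus(self):
        enc = make_encounter(documented=tf.AltFocus.PNEUMONIA)
        res = tf.classify_encounter(enc)
        present, label = tf.determine_alternative_focus(enc, res.bacteraemia)
        assert present is True and label == "pneumonia"

    def test_discordant_bacteraemia_establishes_focus(self):
        enc = make_encounter(blood_species=SPN)
        res = tf.classify_encounter(enc)
        present, label = tf.determine_alternative_focus(enc, res.bacteraemia)
        assert present is True and label == "discordant bacteraemia"

    def test_no_focus_no_bacteraemia(self):
        enc = make_encounter()
        res = tf.classify_encounter(enc)
        assert tf.determine_alternative_focus(enc, res.bacteraemia) == (
            False, None
        )


class TestWorkupRule:
    @pytest.mark.parametrize(
        "flags, pct, expected",
        [
            ((True, True, False), 1.0, tf.WorkupRecommendation.OBTAIN_PUB),
            ((False, False, False), 3.0,
             tf.WorkupRecommendation.NO_BLOOD_CULTURES),  # score 0 suffices
            ((True, True, True), 0.1,
             tf.WorkupRecommendation.NO_BLOOD_CULTURES),  # low PCT suffices
            ((True, False, False), 0.25, tf.WorkupRecommendation.OBTAIN_PUB),
        ],
    )
    def test_score0_or_low_pct_omits_blood_cultures(self, flags, pct,
                                                    expected):
        triple = tf.TripleF(*flags)
        assert tf.recommend_workup(triple, pct) is expected


class TestClassificationExamples:
    def test_accordant_bacteraemia_without_symptoms_is_usb(self):
        res = tf.classify_encounter(make_encounter(blood_species=ECOLI))
        assert res.category is tf.DiagnosisCategory.BACTEREMIC_SUTI

    def test_symptomatic_systemic_no_focus_is_probable(self):
        res = tf.classify_encounter(
            make_encounter(fever=True, gu=["dysuria"])
        )
        assert res.category is tf.DiagnosisCategory.PROBABLE_SUTI

    def test_febrile_with_pneumonia_no_symptoms_is_abu(self):
        res = tf.classify_encounter(
            make_encounter(fever=True, documented=tf.AltFocus.PNEUMONIA)
        )
        assert res.category is tf.DiagnosisCategory.ABU

    def test_lower_symptoms_without_systemic_reaction_is_urocystitis(self):
        res = tf.classify_encounter(make_encounter(gu=["dysuria"], pct=0.05))
        assert res.category is tf.DiagnosisCategory.UROCYSTITIS

    def test_undifferentiated_fever_no_focus_is_possible(self):
        res = tf.classify_encounter(make_encounter(fever=True))
        assert res.category is tf.DiagnosisCategory.POSSIBLE_SUTI

    def test_s_aureus_bacteraemia_with_bacteriuria_is_alt_focus(self):
        res = tf.classify_encounter(
            make_encounter(urine_species=(SA,), blood_species=SA,
                           fever=True, gu=["dysuria"])
        )
        assert res.category is tf.DiagnosisCategory.SA_ALT_FOCUS

    def test_sterile_urine_is_a_precondition_error(self):
        with pytest.raises(ValueError):
            tf.classify_encounter(make_encounter(urine_species=()))

    def test_pct_in_systemic_option_reclassifies_quiet_encounters(self):
        enc = make_encounter(pct=0.8)  # no clinical signs, raised PCT
        assert (tf.classify_encounter(enc).category
                is tf.DiagnosisCategory.ABU)
        assert (tf.classify_encounter(enc, pct_in_systemic=True).category
                is tf.DiagnosisCategory.POSSIBLE_SUTI)


class TestPartitionProperty:
    """Exhaustive enumeration: exactly one terminal rule fires per case."""

    CASES = list(itertools.product(
        [(), ("dysuria",), ("flank_pain",)],          # GU symptoms
        [False, True],                                # fever (F1)
        [False, True],                                # organ failure (F2)
        [0.05, 1.0],                                  # PCT
        [tf.AltFocus.NONE, tf.AltFocus.PNEUMONIA],    # documented focus
        ["none", "accordant", "discordant", "sa"],    # blood cultures
    ))

    def _build(self, gu, fever, organs, pct, documented, blood):
        urine = (SA,) if blood == "sa" else (ECOLI,)
        blood_species = {
            "none": None, "accordant": ECOLI, "discordant": SPN, "sa": SA,
        }[blood]
        return make_encounter(
            gu=gu, fever=fever,
            organs=["kidney"] if organs else [],
            pct=pct, urine_species=urine, blood_species=blood_species,
            documented=documented,
        )

    @pytest.mark.parametrize("case", CASES)
    def test_exactly_one_terminal_rule(self, case):
        res = tf.classify_encounter(self._build(*case))
        terminal = [r for r in res.rationale if r.startswith("R")]
        assert len(terminal) == 1
        assert res.category in {
            tf.DiagnosisCategory.BACTEREMIC_SUTI,
            tf.DiagnosisCategory.PROBABLE_SUTI,
            tf.DiagnosisCategory.POSSIBLE_SUTI,
            tf.DiagnosisCategory.UROCYSTITIS,
            tf.DiagnosisCategory.ABU,
            tf.DiagnosisCategory.SA_ALT_FOCUS,
        }

    @pytest.mark.parametrize("case", CASES)
    def test_category_consistent_with_inputs(self, case):
        gu, fever, organs, pct, documented, blood = case
        res = tf.classify_encounter(self._build(*case))
        cat = res.category
        if blood == "sa":
            assert cat is tf.DiagnosisCategory.SA_ALT_FOCUS
        elif blood == "accordant":
            assert cat is tf.DiagnosisCategory.BACTEREMIC_SUTI
        if cat is tf.DiagnosisCategory.PROBABLE_SUTI:
            # probable SUTI excludes alternative foci and bacteraemia
            assert documented is tf.AltFocus.NONE
            assert res.bacteraemia.accordance is not Accordance.ACCORDANT
            assert gu and (fever or organs)
        if cat is tf.DiagnosisCategory.UROCYSTITIS:
            assert gu == ("dysuria",) and not fever and not organs
        if cat is tf.DiagnosisCategory.ABU:
            assert res.bacteraemia.accordance is not Accordance.ACCORDANT


class TestFixtureMarginals:
    def test_f_criterion_marginals(self, classified):
        """F1 140, F2 115, F3 54 across the 183 analyzable encounters."""
        f1 = sum(r.triple_f.f1 for r in classified)
        f2 = sum(r.triple_f.f2 for r in classified)
        f3 = sum(r.triple_f.f3 for r in classified)
        assert (f1, f2, f3) == (140, 115, 54)

    def test_fourteen_score_zero_encounters(self, classified):
        assert sum(r.triple_f.score == 0 for r in classified) == 14

    def test_probable_suti_never_has_focus_or_accordant_bacteraemia(
        self, classified
    ):
        for r in classified:
            if r.category is tf.DiagnosisCategory.PROBABLE_SUTI:
                assert not r.alternative_focus_present
                assert r.bacteraemia.accordance is not Accordance.ACCORDANT
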