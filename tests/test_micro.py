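"""Urine significance, blood-culture adjudication and accordance rules."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import triplef as tf
from triplef.micro import (
    Accordance,
    BacteraemiaStatus,
    UrineStatusValue,
    organism_accordance_table,
)

ECOLI = "Escherichia coli"


def _uc(*isolates):
    return tf.UrineCulture(tf.CollectionMethod.MIDSTREAM, list(isolates))


class TestUrineSignificance:
    @pytest.mark.parametrize(
        "isolates, expected",
        [
            # pure uropathogen at/above 10^3 CFU/mL
            ([tf.Isolate(ECOLI, 1e5)], UrineStatusValue.SIGNIFICANT),
            ([tf.Isolate(ECOLI, 1e3)], UrineStatusValue.SIGNIFICANT),
            # below the CFU threshold
            ([tf.Isolate(ECOLI, 500)], UrineStatusValue.CONTAMINATED),
            # no growth
            ([], UrineStatusValue.STERILE),
            # flora only
            ([tf.Isolate("Lactobacillus crispatus", 1e5)],
             UrineStatusValue.CONTAMINATED),
            # mixed culture of two pathogens
            ([tf.Isolate(ECOLI, 1e5),
              tf.Isolate("Enterococcus faecalis", 1e4)],
             UrineStatusValue.SIGNIFICANT),
            # more than two pathogenic species
            ([tf.Isolate(ECOLI, 1e4),
              tf.Isolate("Klebsiella pneumoniae", 1e4),
              tf.Isolate("Proteus mirabilis", 1e4)],
             UrineStatusValue.CONTAMINATED),
        ],
    )
    def test_status_partition(self, isolates, expected):
        assert tf.classify_urine_culture(_uc(*isolates)).status is expected

    def test_mixed_culture_keeps_both_qualifying_isolates(self):
        status = tf.classify_urine_culture(
            _uc(tf.Isolate(ECOLI, 1e5),
                tf.Isolate("Enterococcus faecalis", 1e4))
        )
        assert sorted(status.organisms) == ["Enterococcus faecalis", ECOLI]

    def test_unknown_species_treated_as_non_pathogenic(self):
        status = tf.classify_urine_culture(
            _uc(tf.Isolate("Imaginarius bogus", 1e6))
        )
        assert status.status is UrineStatusValue.CONTAMINATED

    @given(
        cfus=st.lists(
            st.floats(min_value=0, max_value=1e7, allow_nan=False),
            min_size=0, max_size=4,
        ),
        species_idx=st.lists(st.integers(min_value=0, max_value=4),
                             min_size=0, max_size=4),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_every_culture_maps_to_exactly_one_status(self, cfus, species_idx):
        pool = [ECOLI, "Klebsiella pneumoniae", "Proteus mirabilis",
                "Lactobacillus crispatus", "mixed skin flora"]
        isolates = [
            tf.Isolate(pool[i], cfu)
            for i, cfu in zip(species_idx, cfus)
        ]
        status = tf.classify_urine_culture(_uc(*isolates))
        assert status.status in set(UrineStatusValue)
        if status.status is UrineStatusValue.SIGNIFICANT:
            assert 1 <= len(status.significant_isolates) <= 2
            assert all(i.cfu_per_ml >= 1_000
                       for i in status.significant_isolates)
        else:
            assert status.significant_isolates == []


def _bc_case(species, n_positive, n_sets=3):
    sets = []
    for i in range(n_sets):
        isolates = [tf.Isolate(species)] if i < n_positive else []
        sets.append(tf.BloodCultureSet(f"B{i + 1}", isolates))
    return sets


def _device_encounter(device):
    return tf.Encounter(
        encounter_id="D", age_years=70, sex=tf.Sex.MALE,
        fever_at_triage=False, chills_or_rigors_reported=False,
        organ_dysfunctions=set(), gu_symptoms=set(), pct_ng_ml=1.0,
        urine_culture=_uc(tf.Isolate(ECOLI, 1e5)),
        blood_culture_sets=[], intravascular_device=device,
    )


def _adjudication_oracle(species_class, n_positive, device):
    """Independent restatement of the contaminant-review rule table."""
    if n_positive == 0:
        return BacteraemiaStatus.NONE
    if species_class != "contaminant_review":
        return BacteraemiaStatus.TRUE_BACTERAEMIA
    if n_positive >= 2 or device:
        return BacteraemiaStatus.TRUE_BACTERAEMIA
    return BacteraemiaStatus.CONTAMINANT_ONLY


class TestAdjudication:
    SPECIES = {
        "uropathogen": ECOLI,
        "other": "Streptococcus pneumoniae",
        "contaminant_review": "Staphylococcus epidermidis",
    }

    @pytest.mark.parametrize(
        "species_class, n_positive, device",
        list(itertools.product(SPECIES, range(4), [False, True])),
    )
    def test_matches_exhaustive_rule_table(self, species_class, n_positive,
                                           device):
        sets = _bc_case(self.SPECIES[species_class], n_positive)
        got = tf.adjudicate_blood_cultures(sets, _device_encounter(device))
        assert got.status is _adjudication_oracle(
            species_class, n_positive, device
        )

    def test_viridans_streptococci_reviewed_like_cons(self):
        one = tf.adjudicate_blood_cultures(
            _bc_case("Streptococcus mitis", 1), _device_encounter(False)
        )
        two = tf.adjudicate_blood_cultures(
            _bc_case("Streptococcus mitis", 2), _device_encounter(False)
        )
        assert one.status is BacteraemiaStatus.CONTAMINANT_ONLY
        assert two.status is BacteraemiaStatus.TRUE_BACTERAEMIA

    def test_zero_sets_is_a_precondition_error(self):
        with pytest.raises(ValueError):
            tf.adjudicate_blood_cultures([], _device_encounter(False))


class TestAccordance:
    def _sig(self, *species):
        return tf.classify_urine_culture(
            _uc(*[tf.Isolate(s, 1e5) for s in species])
        )

    def _bact(self, *species):
        return tf.BacteraemiaAssessment(
            BacteraemiaStatus.TRUE_BACTERAEMIA, organisms=list(species)
        )

    def test_same_organism_is_accordant(self):
        out = tf.assess_accordance(self._sig(ECOLI), self._bact(ECOLI))
        assert out.accordance is Accordance.ACCORDANT
        assert out.dominant_uropathogen == ECOLI

    def test_mixed_urine_identifies_dominant_uropathogen(self):
        out = tf.assess_accordance(
            self._sig(ECOLI, "Enterococcus faecalis"), self._bact(ECOLI)
        )
        assert out.accordance is Accordance.ACCORDANT
        assert out.dominant_uropathogen == ECOLI

    def test_different_organism_is_discordant(self):
        out = tf.assess_accordance(
            self._sig("Enterococcus faecalis"),
            self._bact("Streptococcus pneumoniae"),
        )
        assert out.accordance is Accordance.DISCORDANT
        assert out.dominant_uropathogen is None

    def test_negative_blood_cultures_not_applicable(self):
        out = tf.assess_accordance(
            self._sig(ECOLI),
            tf.BacteraemiaAssessment(BacteraemiaStatus.NONE),
        )
        assert out.accordance is Accordance.NOT_APPLICABLE

    def test_accordance_requires_significant_urine(self):
        sterile = tf.classify_urine_culture(_uc())
        with pytest.raises(ValueError):
            tf.assess_accordance(sterile, self._bact(ECOLI))


class TestAccordanceTable:
    def _pair(self, urine_species, blood_species):
        urine = tf.classify_urine_culture(
            _uc(*[tf.Isolate(s, 1e5) for s in urine_species])
        )
        if blood_species:
            blood = tf.BacteraemiaAssessment(
                BacteraemiaStatus.TRUE_BACTERAEMIA,
                organisms=list(blood_species),
            )
        else:
            blood = tf.BacteraemiaAssessment(BacteraemiaStatus.NONE)
        return urine, tf.assess_accordance(urine, blood)

    def test_direct_count_oracle(self):
        pairs = [
            self._pair([ECOLI], [ECOLI]),
            self._pair([ECOLI], [ECOLI]),
            self._pair([ECOLI], ["Streptococcus pneumoniae"]),
            self._pair(["Proteus mirabilis"], ["Proteus mirabilis"]),
        ]
        table = organism_accordance_table(pairs)
        assert table[ECOLI] == pytest.approx(2 / 3)
        assert table["Proteus mirabilis"] == 1.0

    def test_never_bacteremic_organism_is_omitted(self):
        table = organism_accordance_table(
            [self._pair(["Enterococcus faecium"], [])]
        )
        assert "Enterococcus faecium" not in table


def test_fixture_bacteraemia_counts(classified):
    """65 true bacteraemias split 49 accordant / 16 discordant."""
    bact = [r for r in classified
            if r.bacteraemia.status is BacteraemiaStatus.TRUE_BACTERAEMIA]
    assert len(bact) == 65
    acc = sum(r.bacteraemia.accordance is Accordance.ACCORDANT for r in bact)
    disc = sum(r.bacteraemia.accordance is Accordance.DISCORDANT for r in bact)
    assert (acc, disc) == (49, 16)
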