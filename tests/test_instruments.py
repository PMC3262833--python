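import itertools

import pytest

from strokeclass import (
    ASPECTS_REGIONS,
    CohortTable,
    CombinedClass,
    ImagingFindings,
    InstrumentClass,
    OcclusionSite,
    aspects_score,
    classify_aspects,
    classify_basis,
    classify_cohort,
    classify_combined,
    classify_nihss,
)
from strokeclass.instruments import (
    ASPECTSMajorClassifier,
    BASISMajorClassifier,
    NIHSSMajorClassifier,
)

from conftest import make_record

MAJOR, NONMAJOR = InstrumentClass.MAJOR, InstrumentClass.NONMAJOR


def findings(sites=(), regions=(), pons=False, thal=False):
    return ImagingFindings(
        occlusion_sites=frozenset(OcclusionSite(s) for s in sites),
        anterior_hypodense_regions=frozenset(regions),
        bilateral_pons_hypodensity=pons,
        bilateral_thalamus_hypodensity=thal,
    )


class TestAspects:
    @pytest.mark.parametrize(
        "regions, score",
        [((), 10), (("I", "M1c", "M2c"), 7), (tuple(ASPECTS_REGIONS), 0), (("C",), 9)],
    )
    def test_score_deducts_one_point_per_region(self, regions, score):
        assert aspects_score(findings(regions=regions)) == score

    def test_posterior_flags_do_not_affect_score(self):
        assert aspects_score(findings(pons=True, thal=True)) == 10

    @pytest.mark.parametrize(
        "n_regions, expected",
        [(3, MAJOR), (2, NONMAJOR), (0, NONMAJOR), (10, MAJOR)],
    )
    def test_dichotomy_at_score_7(self, n_regions, expected):
        # score 7 (3 regions) is major, score 8 (2 regions) is not
        assert classify_aspects(findings(regions=ASPECTS_REGIONS[:n_regions])) is expected


class TestBasis:
    @pytest.mark.parametrize("site", ["DISTAL_ICA", "MCA_M1", "MCA_M2", "BASILAR"])
    def test_each_qualifying_occlusion_is_major(self, site):
        assert classify_basis(findings(sites=[site])) is MAJOR

    def test_other_occlusion_alone_is_nonmajor(self):
        assert classify_basis(findings(sites=["OTHER"])) is NONMAJOR

    def test_parenchymal_criterion_without_occlusion(self):
        assert classify_basis(findings(regions=("I", "M1c", "M2c"))) is MAJOR

    @pytest.mark.parametrize("flag", ["pons", "thal"])
    def test_bilateral_posterior_hypodensity_is_major(self, flag):
        assert classify_basis(findings(**{flag: True})) is MAJOR

    def test_empty_findings_are_nonmajor(self):
        assert classify_basis(findings()) is NONMAJOR


class TestNihss:
    @pytest.mark.parametrize("score, expected", [(0, NONMAJOR), (10, NONMAJOR), (11, MAJOR), (42, MAJOR)])
    def test_strict_dichotomy_above_10(self, score, expected):
        assert classify_nihss(score) is expected

    @pytest.mark.parametrize("score", [-1, 43])
    def test_out_of_range_rejected(self, score):
        with pytest.raises(ValueError):
            classify_nihss(score)


class TestCombined:
    @pytest.mark.parametrize(
        "nihss_cls, basis_cls, expected",
        [
            (MAJOR, MAJOR, CombinedClass.CONCORDANT_MAJOR),
            (NONMAJOR, NONMAJOR, CombinedClass.CONCORDANT_MINOR),
            (MAJOR, NONMAJOR, CombinedClass.DISCORDANT),
            (NONMAJOR, MAJOR, CombinedClass.DISCORDANT),
        ],
    )
    def test_three_state_rule(self, nihss_cls, basis_cls, expected):
        assert classify_combined(nihss_cls, basis_cls) is expected


def _all_findings_reduced():
    """All 2^10 region subsets x reduced occlusion configs x posterior flags."""
    site_options = [
        frozenset(),
        frozenset({OcclusionSite.MCA_M1}),
        frozenset({OcclusionSite.OTHER}),
        frozenset({OcclusionSite.BASILAR, OcclusionSite.OTHER}),
    ]
    for k in range(11):
        for regions in itertools.combinations(ASPECTS_REGIONS, k):
            for sites in site_options:
                for pons, thal in ((False, False), (True, False), (False, True)):
                    yield ImagingFindings(
                        occlusion_sites=sites,
                        anterior_hypodense_regions=frozenset(regions),
                        bilateral_pons_hypodensity=pons,
                        bilateral_thalamus_hypodensity=thal,
                    )


class TestInstrumentInvariants:
    def test_aspects_major_implies_basis_major_exhaustive(self):
        for f in _all_findings_reduced():
            if classify_aspects(f) is MAJOR:
                assert classify_basis(f) is MAJOR, f

    def test_basis_monotone_under_added_findings(self):
        # adding an occlusion site, a region, or a flag never demotes MAJOR
        base = findings(regions=("I", "M1c", "M2c"))
        assert classify_basis(base) is MAJOR
        richer = ImagingFindings(
            occlusion_sites=frozenset({OcclusionSite.MCA_M2}),
            anterior_hypodense_regions=base.anterior_hypodense_regions | {"C"},
            bilateral_pons_hypodensity=True,
            bilateral_thalamus_hypodensity=False,
        )
        assert classify_basis(richer) is MAJOR


class TestClassifyCohort:
    def test_empty_cohort_gives_empty_frame(self):
        frame = classify_cohort(CohortTable([]))
        assert len(frame) == 0
        assert "combined_class" in frame.columns

    def test_missing_mrs_is_an_error(self):
        with pytest.raises(ValueError, match="exclude_unanalyzable"):
            classify_cohort(CohortTable([make_record(mrs=None)]))

    def test_small_cohort_classes(self, small_cohort):
        frame = classify_cohort(small_cohort).set_index("patient_id")
        assert frame.loc["P0", "combined_class"] == "CONCORDANT_MAJOR"
        assert frame.loc["P1", "combined_class"] == "CONCORDANT_MINOR"
        assert frame.loc["P2", "combined_class"] == "DISCORDANT"
        assert frame.loc["P4", "aspects_major"] and frame.loc["P4", "basis_major"]
        assert frame.loc["P5", "basis_major"] and not frame.loc["P5", "aspects_major"]
        assert frame.loc["P0", "poor_outcome"] and not frame.loc["P1", "poor_outcome"]

    def test_combined_classes_partition_cohort(self, small_cohort):
        frame = classify_cohort(small_cohort)
        assert frame["combined_class"].value_counts().sum() == len(small_cohort)

    def test_aspects_majors_subset_of_basis_majors(self, small_cohort):
        frame = classify_cohort(small_cohort)
        assert frame["aspects_major"].sum() <= frame["basis_major"].sum()
        assert (frame["aspects_major"] <= frame["basis_major"]).all()


class TestSklearnWrappers:
    def test_rule_classifiers_match_functions(self, small_cohort):
        X = small_cohort.to_frame()
        frame = classify_cohort(small_cohort)
        for cls, col in (
            (ASPECTSMajorClassifier, "aspects_major"),
            (BASISMajorClassifier, "basis_major"),
            (NIHSSMajorClassifier, "nihss_major"),
        ):
            pred = cls().fit(X).predict(X)
            assert (pred == frame[col].to_numpy().astype(int)).all()

    def test_wrappers_parse_csv_style_cells(self, small_cohort):
        X = small_cohort.to_frame()
        X["occlusion_sites"] = X["occlusion_sites"].map(
            lambda s: ";".join(sorted(x.value for x in s))
        )
        X["anterior_hypodense_regions"] = X["anterior_hypodense_regions"].map(
            lambda s: ";".join(sorted(s))
        )
        pred = BASISMajorClassifier().fit(X).predict(X)
        assert list(pred) == [1, 0, 0, 1, 1, 1]

    def test_get_params_round_trip(self):
        est = NIHSSMajorClassifier()
        est.set_params(**est.get_params())
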