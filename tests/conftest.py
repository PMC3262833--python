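import pytest

from strokeclass import (
    CohortTable,
    ImagingFindings,
    OcclusionSite,
    PatientRecord,
    Sex,
)


def make_record(
    pid="P0",
    age=70.0,
    sex=Sex.FEMALE,
    nihss=4,
    mrs=1,
    sites=(),
    regions=(),
    pons=False,
    thal=False,
    **flags,
):
    return PatientRecord(
        patient_id=pid,
        age=age,
        sex=sex,
        nihss_admission=nihss,
        findings=ImagingFindings(
            occlusion_sites=frozenset(OcclusionSite(s) if isinstance(s, str) else s for s in sites),
            anterior_hypodense_regions=frozenset(regions),
            bilateral_pons_hypodensity=pons,
            bilateral_thalamus_hypodensity=thal,
        ),
        mrs_6mo=mrs,
        **flags,
    )


@pytest.fixture
def small_cohort():
    """Six hand-coded patients spanning all combined classes."""
    return CohortTable(
        [
            make_record("P0", nihss=18, mrs=5, sites=["MCA_M1"]),            # concordant-major
            make_record("P1", nihss=2, mrs=0),                               # concordant-minor
            make_record("P2", nihss=15, mrs=4),                              # NIHSS-only major
            make_record("P3", nihss=3, mrs=1, sites=["DISTAL_ICA"]),         # BASIS-only major
            make_record("P4", nihss=6, mrs=3, regions=["I", "M1c", "M2c"]),  # ASPECTS+ => BASIS+
            make_record("P5", nihss=9, mrs=2, pons=True),                    # posterior BASIS+
        ],
        provenance="unit fixture",
    )
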