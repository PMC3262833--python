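"""Stroke severity-classification instruments.

Three dichotomous instruments label a stroke MAJOR or NONMAJOR:

* **ASPECTS** — one point is deducted from a maximum of 10 for each anterior
  circulation region showing acute hypodensity on NCCT; a score of 7 or less
  (3+ affected regions) is ASPECTS-major.
* **BASIS** — major if CTA shows occlusion of the distal ICA, proximal MCA
  (M1 or M2) or basilar artery, or if the anterior parenchymal criterion is
  met (ASPECTS <= 7), or if bilateral pons or bilateral thalamus
  hypodensities mark a posterior-circulation infarct.
* **NIHSS** — major if the admission NIHSS is strictly greater than 10.

The combined NIHSS/BASIS instrument stratifies patients into concordant-major
(both major), concordant-minor (both non-major) and discordant.  Because the
anterior parenchymal criterion is shared, ASPECTS-major always implies
BASIS-major.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort import (
    QUALIFYING_SITES,
    CohortTable,
    ImagingFindings,
    OcclusionSite,
)

__all__ = [
    "InstrumentClass",
    "CombinedClass",
    "ASPECTS_MAJOR_THRESHOLD",
    "NIHSS_MAJOR_THRESHOLD",
    "aspects_score",
    "classify_aspects",
    "classify_basis",
    "classify_nihss",
    "classify_combined",
    "classify_cohort",
    "ASPECTSMajorClassifier",
    "BASISMajorClassifier",
    "NIHSSMajorClassifier",
]


class InstrumentClass(Enum):
    MAJOR = "MAJOR"
    NONMAJOR = "NONMAJOR"


class CombinedClass(Enum):
    CONCORDANT_MAJOR = "CONCORDANT_MAJOR"
    DISCORDANT = "DISCORDANT"
    CONCORDANT_MINOR = "CONCORDANT_MINOR"


#: ASPECTS at or below this score (i.e. 3+ hypodense regions) is major.
ASPECTS_MAJOR_THRESHOLD = 7
#: NIHSS strictly above this score is major.
NIHSS_MAJOR_THRESHOLD = 10


def aspects_score(findings: ImagingFindings) -> int:
    """10 minus the number of distinct hypodense anterior regions.

    Posterior findings (bilateral pons/thalamus flags) do not enter the
    score; a purely posterior stroke scores 10.
    """
    return 10 - len(findings.anterior_hypodense_regions)


def classify_aspects(findings: ImagingFindings) -> InstrumentClass:
    if aspects_score(findings) <= ASPECTS_MAJOR_THRESHOLD:
        return InstrumentClass.MAJOR
    return InstrumentClass.NONMAJOR


def classify_basis(findings: ImagingFindings) -> InstrumentClass:
    """BASIS rule: qualifying arterial occlusion, ASPECTS <= 7, or bilateral
    posterior hypodensities."""
    if findings.occlusion_sites & QUALIFYING_SITES:
        return InstrumentClass.MAJOR
    if aspects_score(findings) <= ASPECTS_MAJOR_THRESHOLD:
        return InstrumentClass.MAJOR
    if findings.bilateral_pons_hypodensity or findings.bilateral_thalamus_hypodensity:
        return InstrumentClass.MAJOR
    return InstrumentClass.NONMAJOR


def classify_nihss(nihss_admission: int) -> InstrumentClass:
    if not 0 <= nihss_admission <= 42:
        raise ValueError(f"NIHSS {nihss_admission} outside 0..42")
    if nihss_admission > NIHSS_MAJOR_THRESHOLD:
        return InstrumentClass.MAJOR
    return InstrumentClass.NONMAJOR


def classify_combined(
    nihss_class: InstrumentClass, basis_class: InstrumentClass
) -> CombinedClass:
    if nihss_class is InstrumentClass.MAJOR and basis_class is InstrumentClass.MAJOR:
        return CombinedClass.CONCORDANT_MAJOR
    if nihss_class is InstrumentClass.NONMAJOR and basis_class is InstrumentClass.NONMAJOR:
        return CombinedClass.CONCORDANT_MINOR
    return CombinedClass.DISCORDANT


def classify_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Apply all four instruments to every record.

    Requires complete records (run
    :func:`strokeclass.cohort.exclude_unanalyzable` first).  Returns one row
    per patient with ``aspects_score``, boolean ``*_major`` columns, the
    combined class and the ``poor_outcome`` dichotomy (mRS > 2).
    """
    rows = []
    for r in cohort:
        if r.mrs_6mo is None or r.nihss_admission is None:
            raise ValueError(
                f"record {r.patient_id!r} has missing mRS or NIHSS; "
                "run exclude_unanalyzable first"
            )
        n_cls = classify_nihss(r.nihss_admission)
        b_cls = classify_basis(r.findings)
        rows.append(
            {
                "patient_id": r.patient_id,
                "aspects_score": aspects_score(r.findings),
                "aspects_major": classify_aspects(r.findings) is InstrumentClass.MAJOR,
                "basis_major": b_cls is InstrumentClass.MAJOR,
                "nihss_major": n_cls is InstrumentClass.MAJOR,
                "combined_class": classify_combined(n_cls, b_cls).value,
                "poor_outcome": r.mrs_6mo > 2,
            }
        )
    columns = [
        "patient_id",
        "aspects_score",
        "aspects_major",
        "basis_major",
        "nihss_major",
        "combined_class",
        "poor_outcome",
    ]
    return pd.DataFrame(rows, columns=columns)


def _findings_from_cell(sites, regions, pons, thal) -> ImagingFindings:
    if isinstance(sites, str):
        sites = frozenset(OcclusionSite(t) for t in sites.split(";") if t)
    if isinstance(regions, str):
        regions = frozenset(t for t in regions.split(";") if t)
    return ImagingFindings(
        occlusion_sites=frozenset(sites),
        anterior_hypodense_regions=frozenset(regions),
        bilateral_pons_hypodensity=bool(pons),
        bilateral_thalamus_hypodensity=bool(thal),
    )


class _RuleClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-compatible wrapper around a fixed clinical rule.

    These classifiers have no free parameters: ``fit`` only records metadata
    so they can sit in sklearn pipelines and be cross-validated against
    learned models.  ``X`` is a cohort frame as produced by
    ``CohortTable.to_frame()`` (set-valued cells may also be ";"-joined
    strings, as in the CSV dialect).  ``predict`` returns 1 for MAJOR.
    """

    def fit(self, X, y=None):
        X = self._as_frame(X)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("rule classifiers expect a cohort DataFrame")
        return X

    def _iter_findings(self, X: pd.DataFrame):
        for sites, regions, pons, thal in zip(
            X["occlusion_sites"],
            X["anterior_hypodense_regions"],
            X["bilateral_pons_hypodensity"],
            X["bilateral_thalamus_hypodensity"],
        ):
            yield _findings_from_cell(sites, regions, pons, thal)


class ASPECTSMajorClassifier(_RuleClassifier):
    def predict(self, X):
        X = self._as_frame(X)
        return np.array(
            [int(classify_aspects(f) is InstrumentClass.MAJOR) for f in self._iter_findings(X)]
        )


class BASISMajorClassifier(_RuleClassifier):
    def predict(self, X):
        X = self._as_frame(X)
        return np.array(
            [int(classify_basis(f) is InstrumentClass.MAJOR) for f in self._iter_findings(X)]
        )


class NIHSSMajorClassifier(_RuleClassifier):
    def predict(self, X):
        X = self._as_frame(X)
        return np.array(
            [int(classify_nihss(int(s)) is InstrumentClass.MAJOR) for s in X["nihss_admission"]]
        )
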