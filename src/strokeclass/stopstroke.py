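"""Published summary counts of the STOPStroke cohort and the contingency
tables they imply.

The STOPStroke study (Screening Technology and Outcomes Project in Stroke)
enrolled 742 consecutive suspected-ischemic-stroke patients at two centres;
649 with reliable admission NIHSS and 6-month mRS form the analyzed cohort.
Only summary counts were published, but the marginal totals pin down every
2x2 classification-versus-outcome table by arithmetic.  This module encodes
those printed counts as fixtures, reconstructs the tables with hard
consistency checks, and re-derives the published accuracy table, the
combined-instrument outcome stratification and its headline odds ratio.

Two genuine inconsistencies in the published counts are preserved rather
than silently resolved:

* the ASPECTS row of the accuracy table (sensitivity 30.0, PPV 62.8 jointly
  imply 76 true positives) conflicts with the running text's "30.8%
  (78/253)"; both variants are kept (``aspects_table_variant`` drives the
  table reproduction, ``aspects_text_variant`` the 30.8% figure);
* the published discordant-stratum odds ratio 5.4 (3.5-8.5) does not equal
  the crude odds ratio computable from the reconstructed strata (4.6); it is
  reported with a discrepancy flag, never asserted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .stats import ORResult, TwoByTwo, diagnostic_metrics, odds_ratio, percent

__all__ = [
    "COUNTS",
    "PUBLISHED_TABLE2",
    "PUBLISHED_HEADLINE",
    "FixtureSet",
    "FixtureConsistencyError",
    "build_fixtures",
    "reproduce_table2",
    "reproduce_headline",
    "reproduce_subgroups",
]

#: Printed counts, straight from the publication (inputs to all arithmetic).
COUNTS: Dict[str, int] = {
    "enrolled": 742,
    "excluded_missing_mrs": 90,
    "excluded_missing_nihss": 3,
    "analyzed": 649,
    "poor": 253,
    "good": 396,
    "nihss_major": 188,
    "nihss_minor": 461,
    "basis_major": 249,
    "basis_minor": 400,
    "aspects_major": 121,
    "aspects_minor": 528,
    "nihss_major_poor": 138,          # 54.5% (138/253)
    "basis_major_poor": 151,          # 59.7% (151/253)
    "aspects_major_poor_text": 78,    # 30.8% (78/253), running text
    "aspects_major_poor_table": 76,   # implied jointly by table cells 30.0 & 62.8
    "concordant_major": 147,
    "concordant_major_poor": 114,     # 77.6%
    "concordant_minor": 358,
    "concordant_minor_poor": 77,      # 21.5%; 78.5% (281/358) good
    "atrial_fibrillation": 137,
    "atrial_fibrillation_basis_major": 75,
    "iv_tpa": 101,
    "iv_tpa_poor": 51,                # 50.5%
    "no_tpa_poor": 180,               # 32.8% (180/548)
    "occlusion_subgroup": 200,        # BASIS-major patients with arterial occlusion
    "occlusion_subgroup_poor": 126,   # 63%
    "endovascular": 31,
    "endovascular_poor": 23,          # 74.2%
}

#: Published accuracy table (percent, one decimal) — reproduction targets.
PUBLISHED_TABLE2: Dict[str, Dict[str, float]] = {
    "nihss": {"sensitivity": 54.5, "specificity": 87.4, "ppv": 73.4, "npv": 75.1, "accuracy": 74.6},
    "basis": {"sensitivity": 59.7, "specificity": 75.3, "ppv": 60.6, "npv": 74.5, "accuracy": 69.2},
    "aspects": {"sensitivity": 30.0, "specificity": 88.6, "ppv": 62.8, "npv": 66.5, "accuracy": 65.8},
}

#: Published headline results of the combined NIHSS/BASIS instrument.
PUBLISHED_HEADLINE: Dict[str, float] = {
    "or_concordant": 12.6,
    "or_concordant_ci_low": 7.9,
    "or_concordant_ci_high": 20.0,
    "or_vs_discordant": 5.4,
    "or_vs_discordant_ci_low": 3.5,
    "or_vs_discordant_ci_high": 8.5,
    "concordant_major_poor_pct": 77.6,
    "concordant_minor_poor_pct": 21.5,
    "concordant_minor_good_pct": 78.5,
    "concordance_pct": 77.8,
    "aspects_text_sensitivity_pct": 30.8,
}


class FixtureConsistencyError(AssertionError):
    """A reconstructed margin does not match its printed source."""


@dataclass(frozen=True)
class FixtureSet:
    """Reconstructed contingency tables and subgroup counts."""

    nihss: TwoByTwo
    basis: TwoByTwo
    aspects_text_variant: TwoByTwo
    aspects_table_variant: TwoByTwo
    #: 3x2 array, rows = concordant-major / discordant / concordant-minor,
    #: columns = poor / good.
    combined: np.ndarray
    #: name -> (poor count, subgroup n)
    subgroups: Dict[str, Tuple[int, int]]
    totals: Dict[str, int]


def _two_by_two(major_poor: int, major_total: int) -> TwoByTwo:
    c = COUNTS
    return TwoByTwo(
        tp=major_poor,
        fp=major_total - major_poor,
        fn=c["poor"] - major_poor,
        tn=c["good"] - (major_total - major_poor),
    )


def _check(label: str, got: int, printed: int) -> None:
    if got != printed:
        raise FixtureConsistencyError(f"{label}: reconstructed {got} != printed {printed}")


def build_fixtures() -> FixtureSet:
    """Assemble every table from the printed counts, verifying all margins."""
    c = COUNTS
    _check("analyzed cohort", c["enrolled"] - c["excluded_missing_mrs"] - c["excluded_missing_nihss"], c["analyzed"])
    _check("outcome margin", c["poor"] + c["good"], c["analyzed"])
    for inst in ("nihss", "basis", "aspects"):
        _check(f"{inst} margin", c[f"{inst}_major"] + c[f"{inst}_minor"], c["analyzed"])

    nihss = _two_by_two(c["nihss_major_poor"], c["nihss_major"])
    basis = _two_by_two(c["basis_major_poor"], c["basis_major"])
    aspects_text = _two_by_two(c["aspects_major_poor_text"], c["aspects_major"])
    aspects_table = _two_by_two(c["aspects_major_poor_table"], c["aspects_major"])
    for label, t in (("nihss", nihss), ("basis", basis),
                     ("aspects-text", aspects_text), ("aspects-table", aspects_table)):
        _check(f"{label} total", t.n, c["analyzed"])

    discordant = c["analyzed"] - c["concordant_major"] - c["concordant_minor"]
    discordant_poor = c["poor"] - c["concordant_major_poor"] - c["concordant_minor_poor"]
    combined = np.array(
        [
            [c["concordant_major_poor"], c["concordant_major"] - c["concordant_major_poor"]],
            [discordant_poor, discordant - discordant_poor],
            [c["concordant_minor_poor"], c["concordant_minor"] - c["concordant_minor_poor"]],
        ],
        dtype=int,
    )
    _check("combined poor column", int(combined[:, 0].sum()), c["poor"])
    _check("combined good column", int(combined[:, 1].sum()), c["good"])

    subgroups = {
        "iv_tpa": (c["iv_tpa_poor"], c["iv_tpa"]),
        "no_tpa": (c["no_tpa_poor"], c["analyzed"] - c["iv_tpa"]),
        # printed as "of the 253 BASIS+ patients, 200 had arterial occlusions"
        # although BASIS+ n = 249; the 200/126 figures are used as printed.
        "occlusion": (c["occlusion_subgroup_poor"], c["occlusion_subgroup"]),
        "endovascular": (c["endovascular_poor"], c["endovascular"]),
    }
    totals = {k: c[k] for k in ("enrolled", "analyzed", "poor", "good", "nihss_major",
                                "basis_major", "aspects_major", "concordant_major",
                                "concordant_minor")}
    totals["discordant"] = discordant
    totals["concordant"] = c["concordant_major"] + c["concordant_minor"]
    return FixtureSet(nihss, basis, aspects_text, aspects_table, combined, subgroups, totals)


def reproduce_table2(fixtures: FixtureSet | None = None) -> Dict[str, Dict[str, float]]:
    """Recompute the published accuracy table from the reconstructed tables.

    Uses the table-consistent ASPECTS variant.  Raises
    :class:`FixtureConsistencyError` listing every mismatching cell if the
    half-up one-decimal percents do not all equal the printed values.
    """
    fx = fixtures or build_fixtures()
    computed = {
        "nihss": diagnostic_metrics(fx.nihss).rounded_percents(),
        "basis": diagnostic_metrics(fx.basis).rounded_percents(),
        "aspects": diagnostic_metrics(fx.aspects_table_variant).rounded_percents(),
    }
    mismatches = [
        f"{inst}/{metric}: computed {computed[inst][metric]} printed {printed}"
        for inst, row in PUBLISHED_TABLE2.items()
        for metric, printed in row.items()
        if computed[inst][metric] != printed
    ]
    if mismatches:
        raise FixtureConsistencyError("; ".join(mismatches))
    return computed


def reproduce_headline(fixtures: FixtureSet | None = None) -> dict:
    """Combined-instrument odds ratios and stratum proportions.

    ``or_concordant`` compares concordant-major to concordant-minor (the
    published 12.6, 7.9-20.0).  ``or_vs_discordant`` is the crude odds ratio
    of concordant-major versus the discordant stratum; it is returned next
    to the published 5.4 with ``or_vs_discordant_matches_published`` False,
    because the printed value is not the crude value the strata imply
    (possibly adjusted or pooled differently).
    """
    fx = fixtures or build_fixtures()
    cm_poor, cm_good = fx.combined[0]
    d_poor, d_good = fx.combined[1]
    mn_poor, mn_good = fx.combined[2]
    or_conc: ORResult = odds_ratio(TwoByTwo(int(cm_poor), int(cm_good), int(mn_poor), int(mn_good)))
    or_disc: ORResult = odds_ratio(TwoByTwo(int(cm_poor), int(cm_good), int(d_poor), int(d_good)))
    published_disc = PUBLISHED_HEADLINE["or_vs_discordant"]
    return {
        "or_concordant": or_conc,
        "or_vs_discordant": or_disc,
        "or_vs_discordant_published": published_disc,
        "or_vs_discordant_matches_published":
            round(or_disc.estimate, 1) == published_disc,
        "concordant_major_poor_pct": percent(cm_poor / (cm_poor + cm_good)),
        "concordant_minor_poor_pct": percent(mn_poor / (mn_poor + mn_good)),
        "concordant_minor_good_pct": percent(mn_good / (mn_poor + mn_good)),
        "concordance_pct": percent(fx.totals["concordant"] / fx.totals["analyzed"]),
        "aspects_text_sensitivity_pct": percent(
            fx.aspects_text_variant.tp / (fx.aspects_text_variant.tp + fx.aspects_text_variant.fn)
        ),
    }


def reproduce_subgroups(fixtures: FixtureSet | None = None) -> Dict[str, float]:
    """Poor-outcome percentages of the treatment / occlusion subgroups."""
    fx = fixtures or build_fixtures()
    return {name: percent(poor / n) for name, (poor, n) in fx.subgroups.items()}
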