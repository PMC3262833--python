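"""End-to-end analysis: classify a cohort, evaluate every instrument, and
emit one structured report.

:func:`run_full_analysis` mirrors the structure of the published analysis:
cohort summary and exclusions; per-instrument class counts and diagnostic
metrics; the combined NIHSS/BASIS stratification with its 3x2 chi-square and
odds ratios; IV tPA and endovascular subgroup outcome rates; and the
forced-entry and stepwise logistic models of poor outcome on the instrument
classes and age.  The report is a plain JSON-serializable dict tree wrapped
in :class:`AnalysisReport`; rendering and re-parsing round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTable, QUALIFYING_SITES
from .instruments import classify_cohort
from .logistic import LogisticFit, logistic_fit, stepwise_logistic
from .stats import (
    TwoByTwo,
    chi2_rxc,
    confusion,
    diagnostic_metrics,
    odds_ratio,
    percent,
    wilcoxon_ranksum,
)

__all__ = ["AnalysisReport", "run_full_analysis"]

REPORT_SCHEMA_VERSION = 1


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass
class AnalysisReport:
    """JSON-serializable analysis report; ``from_dict(to_dict(r)) == r``."""

    schema_version: int
    software_version: str
    provenance: str
    cohort: dict
    instruments: dict
    combined: dict
    subgroups: dict
    logistic: dict

    def to_dict(self) -> dict:
        return _jsonify(dataclasses.asdict(self))

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls.from_dict(json.loads(text))


def _metrics_block(table: TwoByTwo) -> dict:
    m = diagnostic_metrics(table)
    block = {
        "counts": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
        "n": table.n,
    }
    for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
        ci = getattr(m, name)
        block[name] = {
            "percent": percent(ci.estimate) if ci.defined else None,
            "ci95_percent": [percent(ci.ci_low), percent(ci.ci_high)] if ci.defined else None,
            "defined": ci.defined,
        }
    return block


def _or_block(r) -> dict:
    return {
        "estimate": round(r.estimate, 6),
        "ci95": [round(r.ci_low, 6), round(r.ci_high, 6)],
        "rounded": [round(r.estimate, 1), round(r.ci_low, 1), round(r.ci_high, 1)],
        "continuity_corrected": r.continuity_corrected,
    }


def _fit_block(fit: LogisticFit) -> dict:
    return {
        "coefficients": {k: round(float(v), 6) for k, v in fit.params.items()},
        "standard_errors": {k: round(float(v), 6) for k, v in fit.bse.items()},
        "odds_ratios": {k: round(float(v), 6) for k, v in fit.odds_ratios.items()},
        "loglik": round(fit.loglik, 6),
        "converged": fit.converged,
        "n_iter": fit.n_iter,
    }


def run_full_analysis(cohort: CohortTable, seed: Optional[int] = None) -> AnalysisReport:
    """Run the full classification-and-evaluation pipeline on a cohort whose
    records all carry an mRS and an admission NIHSS."""
    if len(cohort) == 0:
        raise ValueError("cannot analyze an empty cohort")
    cls = classify_cohort(cohort)
    frame = cohort.to_frame()
    n = len(cls)
    poor = cls["poor_outcome"].to_numpy()

    instruments = {}
    for inst in ("nihss", "basis", "aspects"):
        table = confusion(cls[f"{inst}_major"], poor)
        instruments[inst] = {
            "major_count": int(cls[f"{inst}_major"].sum()),
            **_metrics_block(table),
        }

    strata = ["CONCORDANT_MAJOR", "DISCORDANT", "CONCORDANT_MINOR"]
    combined_counts = {
        s: {
            "n": int((cls["combined_class"] == s).sum()),
            "poor": int(cls.loc[cls["combined_class"] == s, "poor_outcome"].sum()),
        }
        for s in strata
    }
    for s in strata:
        c = combined_counts[s]
        c["poor_percent"] = percent(c["poor"] / c["n"]) if c["n"] else None
    table3x2 = np.array([[combined_counts[s]["poor"],
                          combined_counts[s]["n"] - combined_counts[s]["poor"]]
                         for s in strata])
    cm, d, mn = (combined_counts[s] for s in strata)
    combined = {
        "strata": combined_counts,
        "concordance_percent": percent((cm["n"] + mn["n"]) / n),
        "chi2_3x2": None,
        "or_concordant_major_vs_minor": None,
        "or_concordant_major_vs_discordant": None,
    }
    if all(combined_counts[s]["n"] > 0 for s in strata):
        test = chi2_rxc(table3x2)
        combined["chi2_3x2"] = {"statistic": round(test.statistic, 6), "df": test.df,
                                "p_value": float(test.p_value)}
        combined["or_concordant_major_vs_minor"] = _or_block(
            odds_ratio(TwoByTwo(cm["poor"], cm["n"] - cm["poor"],
                                mn["poor"], mn["n"] - mn["poor"]))
        )
        combined["or_concordant_major_vs_discordant"] = _or_block(
            odds_ratio(TwoByTwo(cm["poor"], cm["n"] - cm["poor"],
                                d["poor"], d["n"] - d["poor"]))
        )

    tpa = frame["iv_tpa"].to_numpy(dtype=bool)
    endo = frame["ia_therapy"].to_numpy(dtype=bool)
    has_occl = np.array(
        [bool(r.findings.occlusion_sites & QUALIFYING_SITES) for r in cohort]
    )
    nihss = frame["nihss_admission"].to_numpy(dtype=float)

    def _subgroup(mask: np.ndarray) -> dict:
        k = int(mask.sum())
        return {
            "n": k,
            "poor": int(poor[mask].sum()),
            "poor_percent": percent(poor[mask].mean()) if k else None,
        }

    subgroups = {
        "iv_tpa": _subgroup(tpa),
        "no_tpa": _subgroup(~tpa),
        "endovascular": _subgroup(endo),
        "qualifying_occlusion": _subgroup(has_occl),
    }
    if 0 < endo.sum() < n:
        subgroups["endovascular"]["median_nihss"] = float(np.median(nihss[endo]))
        subgroups["endovascular"]["median_nihss_rest"] = float(np.median(nihss[~endo]))
        subgroups["endovascular"]["nihss_ranksum_p"] = float(
            wilcoxon_ranksum(nihss[endo], nihss[~endo]).p_value
        )

    design = pd.DataFrame(
        {
            "nihss_major": cls["nihss_major"].astype(float),
            "basis_major": cls["basis_major"].astype(float),
            "aspects_major": cls["aspects_major"].astype(float),
            "age": frame["age"].astype(float),
        }
    )
    forced = logistic_fit(design, poor.astype(float))
    step_fit, trace = stepwise_logistic(design, poor.astype(float))
    logistic = {
        "forced_entry": _fit_block(forced),
        "stepwise": {
            **_fit_block(step_fit),
            "selected": [c for c in design.columns if c in step_fit.params.index],
            "trace": [
                {"action": s.action, "term": s.term, "p_value": float(s.p_value)}
                for s in trace
            ],
        },
    }

    return AnalysisReport(
        schema_version=REPORT_SCHEMA_VERSION,
        software_version=__version__,
        provenance=cohort.provenance if seed is None else f"{cohort.provenance} seed={seed}",
        cohort={
            "n": n,
            "poor": int(poor.sum()),
            "poor_percent": percent(poor.mean()),
            "median_nihss": float(np.median(nihss)),
        },
        instruments=instruments,
        combined=combined,
        subgroups=subgroups,
        logistic=logistic,
    )
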