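"""Inter-study agreement statistics and their classification.

Two studies that measure the same cell lines are compared entity by entity:
per drug for sensitivity data (Pearson correlation across the common cell
lines; Cohen's kappa for binarized calls) and per gene for molecular
profiles (Pearson for expression/copy number, kappa for mutation status).

Statistics that cannot be estimated — too few complete pairs, a constant
vector, degenerate marginals — are reported as undefined (NaN), never
coerced to zero; summary fractions are computed over defined values only
and print their denominator.

Classification thresholds: Pearson rho >= 0.8 meets the inter-laboratory
reproducibility bar (GOOD), rho > 0.5 is "reasonable" (REASONABLE), else
BELOW.  Kappa is banded per Landis-Koch: <0.2 POOR, [0.2, 0.4) FAIR,
[0.4, 0.6) MODERATE, [0.6, 0.8) SUBSTANTIAL, >=0.8 ALMOST_PERFECT.

A summary may also report the fraction of entities passing the union of
the rho and kappa criteria.  Passing a union of tests is NOT evidence of
agreement — adding more sensitivity measures would eventually drive any
union to 100% — so the union fraction is always labelled non-evidential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import BinaryCallMatrix, ThresholdConfig
from .io import PairedStudy, PgxError

DEFAULT_MIN_PAIRS = 10

UNION_NOTE = ("union of tests: non-evidential "
              "(any union fraction >= each individual fraction by construction)")


def _complete_pairs(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def pearson(x: Sequence[float], y: Sequence[float],
            min_pairs: int = DEFAULT_MIN_PAIRS) -> float:
    """Pearson product-moment correlation over complete pairs.

    Returns NaN (undefined) if fewer than ``min_pairs`` complete pairs
    remain or either vector is constant.
    """
    xv, yv = _complete_pairs(np.asarray(x, float), np.asarray(y, float))
    if xv.size < max(min_pairs, 2):
        return float("nan")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return float("nan")
    return float(stats.pearsonr(xv, yv).statistic)


def cohen_kappa(a: Sequence[float], b: Sequence[float],
                min_pairs: int = DEFAULT_MIN_PAIRS) -> float:
    """Cohen's chance-corrected agreement between two binary raters.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
    p_e the chance agreement implied by the marginal proportions.
    Undefined (NaN) below ``min_pairs`` complete pairs or when p_e = 1
    (both raters constant and equal).
    """
    av, bv = _complete_pairs(np.asarray(a, float), np.asarray(b, float))
    for name, v in (("a", av), ("b", bv)):
        if not np.isin(v, (0.0, 1.0)).all():
            raise ValueError(f"non-binary values in vector {name}")
    n = av.size
    if n < max(min_pairs, 1):
        return float("nan")
    p_o = float(np.mean(av == bv))
    pa1, pb1 = float(av.mean()), float(bv.mean())
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if p_e >= 1.0 - 1e-15:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


RHO_CATEGORIES = ("BELOW", "REASONABLE", "GOOD")
KAPPA_CATEGORIES = ("POOR", "FAIR", "MODERATE", "SUBSTANTIAL", "ALMOST_PERFECT")


@dataclass
class AgreementResult:
    """Agreement statistics for one entity (a drug or a gene)."""

    entity_id: str
    n_pairs: int
    rho: float = float("nan")
    kappa: float = float("nan")
    rho_category: str | None = None
    kappa_category: str | None = None


def classify_agreement(r: AgreementResult,
                       cfg: ThresholdConfig | None = None) -> AgreementResult:
    """Fill in category labels from the configured thresholds.

    rho: GOOD at or above ``rho_good`` (boundary inclusive), REASONABLE
    strictly above ``rho_reasonable``, else BELOW.  kappa: Landis-Koch
    bands, closed on the left.
    """
    cfg = cfg or ThresholdConfig()
    if not math.isnan(r.rho):
        if r.rho >= cfg.rho_good:
            r.rho_category = "GOOD"
        elif r.rho > cfg.rho_reasonable:
            r.rho_category = "REASONABLE"
        else:
            r.rho_category = "BELOW"
    if not math.isnan(r.kappa):
        k = r.kappa
        if k < 0.2:
            r.kappa_category = "POOR"
        elif k < 0.4:
            r.kappa_category = "FAIR"
        elif k < 0.6:
            r.kappa_category = "MODERATE"
        elif k < 0.8:
            r.kappa_category = "SUBSTANTIAL"
        else:
            r.kappa_category = "ALMOST_PERFECT"
    return r


@dataclass
class ConsistencyReport:
    """Per-entity agreement results plus study-pair level summary."""

    study_pair: tuple[str, str]
    datatype: str
    results: list[AgreementResult]
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "entity_id": r.entity_id, "n_pairs": r.n_pairs,
            "rho": r.rho, "kappa": r.kappa,
            "rho_category": r.rho_category, "kappa_category": r.kappa_category,
        } for r in self.results]
        return pd.DataFrame(rows)

    def defined_rho(self) -> np.ndarray:
        v = np.array([r.rho for r in self.results], float)
        return v[~np.isnan(v)]

    def defined_kappa(self) -> np.ndarray:
        v = np.array([r.kappa for r in self.results], float)
        return v[~np.isnan(v)]


def summarize(results: list[AgreementResult],
              cfg: ThresholdConfig | None = None) -> dict:
    """Study-level summary fractions, each over defined statistics only.

    The ``fraction_pass_union`` key (rho-criterion OR kappa-criterion,
    evaluated over entities with at least one defined statistic) is
    reported because naive comparisons quote it, but it is labelled
    non-evidential: it is >= each individual fraction by construction.
    """
    cfg = cfg or ThresholdConfig()
    rho = np.array([r.rho for r in results], float)
    kap = np.array([r.kappa for r in results], float)
    rho_def, kap_def = ~np.isnan(rho), ~np.isnan(kap)

    out: dict = {"n_entities": len(results),
                 "n_rho_defined": int(rho_def.sum()),
                 "n_kappa_defined": int(kap_def.sum())}
    if rho_def.any():
        out["median_rho"] = float(np.median(rho[rho_def]))
        out["fraction_rho_gt_0.5"] = float(
            np.mean(rho[rho_def] > cfg.rho_reasonable))
        out["fraction_rho_ge_0.8"] = float(np.mean(rho[rho_def] >= cfg.rho_good))
    if kap_def.any():
        out["median_kappa"] = float(np.median(kap[kap_def]))
        out["fraction_kappa_ge_0.4"] = float(
            np.mean(kap[kap_def] >= cfg.kappa_moderate_min))

    any_def = rho_def | kap_def
    if any_def.any():
        rho_pass = rho_def & (np.nan_to_num(rho, nan=-2.0) > cfg.rho_reasonable)
        kap_pass = kap_def & (np.nan_to_num(kap, nan=-2.0) >= cfg.kappa_moderate_min)
        out["fraction_pass_union"] = float(
            np.mean((rho_pass | kap_pass)[any_def]))
        out["union_note"] = UNION_NOTE
    return out


def merge_reports(rho_report: ConsistencyReport,
                  kappa_report: ConsistencyReport,
                  cfg: ThresholdConfig | None = None) -> ConsistencyReport:
    """Join a continuous-value report and a call report entity by entity.

    Produces one AgreementResult per entity carrying BOTH the rho of the
    continuous comparison and the kappa of the corresponding binarized
    calls — the joint view on which a "passes rho OR passes kappa" union
    is well defined (same entities, same denominator).  Entities present
    in only one report are kept with the other statistic undefined.
    """
    cfg = cfg or ThresholdConfig()
    rho_by = {r.entity_id: r for r in rho_report.results}
    kap_by = {r.entity_id: r for r in kappa_report.results}
    results = []
    for entity in list(rho_by) + [e for e in kap_by if e not in rho_by]:
        rr, kr = rho_by.get(entity), kap_by.get(entity)
        merged = AgreementResult(
            entity_id=entity,
            n_pairs=max(rr.n_pairs if rr else 0, kr.n_pairs if kr else 0),
            rho=rr.rho if rr else float("nan"),
            kappa=kr.kappa if kr else float("nan"))
        results.append(classify_agreement(merged, cfg))
    return ConsistencyReport(
        study_pair=rho_report.study_pair,
        datatype=f"{rho_report.datatype}+{kappa_report.datatype}",
        results=results, summary=summarize(results, cfg))


def _paired_matrices(p: PairedStudy, datatype: str) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Return (values_a, values_b, axis) aligned entity-per-column... helper."""
    if datatype in ("AUC", "IC50"):
        ma = p.study_a.sensitivity.get(datatype)
        mb = p.study_b.sensitivity.get(datatype)
        if ma is None or mb is None:
            raise PgxError(f"datatype {datatype} not present on both sides")
        return ma.values, mb.values, "per_drug"
    ma = p.study_a.profiles.get(datatype)
    mb = p.study_b.profiles.get(datatype)
    if ma is None or mb is None:
        raise PgxError(f"datatype {datatype} not present on both sides")
    # genes x cell lines -> transpose so entities are columns
    return ma.values.T, mb.values.T, "per_gene"


def per_entity_consistency(
    p: PairedStudy,
    datatype: str,
    cfg: ThresholdConfig | None = None,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> ConsistencyReport:
    """Per-drug (sensitivity) or per-gene (profile) agreement report.

    Continuous datatypes (AUC, IC50, EXPRESSION, CNV) get Pearson rho;
    binary MUTATION gets Cohen's kappa.  Matrices must already be aligned
    on common labels (see :func:`pgxagree.io.intersect_studies`).
    """
    cfg = cfg or ThresholdConfig()
    va, vb, _axis = _paired_matrices(p, datatype)
    binary = datatype == "MUTATION"
    results = []
    for entity in va.columns:
        x, y = va[entity].to_numpy(), vb[entity].to_numpy()
        n = int(np.sum(~(np.isnan(x) | np.isnan(y))))
        r = AgreementResult(entity_id=entity, n_pairs=n)
        if binary:
            r.kappa = cohen_kappa(x, y, min_pairs=min_pairs)
        else:
            r.rho = pearson(x, y, min_pairs=min_pairs)
        results.append(classify_agreement(r, cfg))
    return ConsistencyReport(
        study_pair=(p.study_a.study_id, p.study_b.study_id),
        datatype=datatype, results=results,
        summary=summarize(results, cfg))


def calls_consistency(
    calls_a: BinaryCallMatrix,
    calls_b: BinaryCallMatrix,
    cfg: ThresholdConfig | None = None,
    min_pairs: int = DEFAULT_MIN_PAIRS,
) -> ConsistencyReport:
    """Per-drug kappa between two studies' sensitivity calls.

    Both call matrices must be aligned on the same cell lines and drugs.
    """
    cfg = cfg or ThresholdConfig()
    if list(calls_a.calls.index) != list(calls_b.calls.index) or \
            list(calls_a.calls.columns) != list(calls_b.calls.columns):
        raise PgxError("call matrices are not aligned on identical labels")
    results = []
    for drug in calls_a.drugs:
        x = calls_a.calls[drug].to_numpy()
        y = calls_b.calls[drug].to_numpy()
        n = int(np.sum(~(np.isnan(x) | np.isnan(y))))
        r = AgreementResult(entity_id=drug, n_pairs=n,
                            kappa=cohen_kappa(x, y, min_pairs=min_pairs))
        results.append(classify_agreement(r, cfg))
    return ConsistencyReport(
        study_pair=(calls_a.study_id, calls_b.study_id),
        datatype=f"CALLS_{calls_a.measure}_{calls_a.method}",
        results=results, summary=summarize(results, cfg))


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
    method: str | None = None,
) -> dict:
    """Wilcoxon rank-sum (Mann-Whitney) test between two samples.

    The statistic reported is the rank-sum W of ``x`` (midranks for ties).
    The p-value is exact (full enumeration of the permutation
    distribution) when the combined sample size is at most 16 and there
    are no ties, otherwise a normal approximation with tie correction and
    continuity correction is used; ``method`` ('exact'/'asymptotic')
    overrides the automatic switch.
    """
    xv = np.asarray(x, float)
    yv = np.asarray(y, float)
    if xv.size == 0 or yv.size == 0:
        raise ValueError("empty sample")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}.get(
        alternative)
    if alt is None:
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([xv, yv])
    has_ties = np.unique(pooled).size < pooled.size
    if method is None:
        method = "exact" if (pooled.size <= 16 and not has_ties) else "asymptotic"
    elif method == "exact" and has_ties:
        raise ValueError("exact method is only available without ties")
    res = stats.mannwhitneyu(xv, yv, alternative=alt, method=method,
                             use_continuity=True)
    m = xv.size
    w = float(res.statistic) + m * (m + 1) / 2.0  # U -> rank-sum of x
    return {"statistic": w, "p": float(res.pvalue), "method": method}


def compare_datatype_consistency(
    report_a: ConsistencyReport,
    report_b: ConsistencyReport,
    alternative: str = "greater",
) -> dict:
    """Rank-sum comparison of two per-entity correlation distributions.

    ``alternative='greater'`` tests whether ``report_a``'s consistency
    distribution is stochastically greater than ``report_b``'s (e.g.
    genomic vs pharmacological).  Reports without defined rho fall back to
    their defined kappa values.
    """
    da = report_a.defined_rho()
    if da.size == 0:
        da = report_a.defined_kappa()
    db = report_b.defined_rho()
    if db.size == 0:
        db = report_b.defined_kappa()
    if da.size == 0 or db.size == 0:
        raise PgxError("no defined statistics to compare")
    out = wilcoxon_rank_sum(da, db, alternative=alternative)
    out.update({"datatype_a": report_a.datatype, "datatype_b": report_b.datatype,
                "n_a": int(da.size), "n_b": int(db.size)})
    return out
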