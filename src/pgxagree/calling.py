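"""Binarization of continuous drug response into sensitive/insensitive calls.

Two calling methods are provided:

* **Waterfall** — per drug, sort the response values in decreasing order to
  form the response-distribution ("waterfall") curve.  If the sorted curve
  is close to linear (Pearson |r| against rank at or above a linearity
  threshold, default 0.95) the cutoff is the median; otherwise the cutoff
  sits at the curve's inflection, the point of maximal perpendicular
  distance from the chord joining the first and last points, with both axes
  min-max scaled to [0, 1] first so the notion of "inflection" is
  scale-free.  Cutoffs are always estimated on the study's FULL cell-line
  panel; restricting to the cell lines shared with another study happens
  only after calling, so the cutoff never depends on the comparison.

* **Fixed** — AUC >= 0.2 is sensitive; IC50 <= 1 uM (<= 0 on the log10
  scale) is sensitive.

Call matrices store 1 = sensitive, 0 = insensitive, NaN = missing, plus the
per-drug cutoff used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SensitivityMatrix

SENSITIVE = 1.0
INSENSITIVE = 0.0


@dataclass
class ThresholdConfig:
    """All agreement and calling thresholds in one place.

    auc_sensitive_min
        AUC at or above this (fraction) is a sensitive call. Default 0.2.
    ic50_sensitive_max_um
        IC50 at or below this (micromolar) is a sensitive call. Default 1.0.
    rho_reasonable, rho_good
        Pearson correlation above 0.5 counts as "reasonable" consistency;
        at or above 0.8 meets the inter-laboratory reproducibility bar.
    kappa_moderate_min, kappa_substantial_min
        Landis-Koch band edges used in summaries (0.4 moderate, 0.6
        substantial).
    waterfall_linearity_min
        |r| of the sorted response curve against rank at or above which the
        distribution is treated as linear (median cutoff). Default 0.95.
    """

    auc_sensitive_min: float = 0.2
    ic50_sensitive_max_um: float = 1.0
    rho_reasonable: float = 0.5
    rho_good: float = 0.8
    kappa_moderate_min: float = 0.4
    kappa_substantial_min: float = 0.6
    waterfall_linearity_min: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc_sensitive_min <= 1.0:
            raise ValueError("auc_sensitive_min must be in [0, 1]")
        if self.ic50_sensitive_max_um <= 0:
            raise ValueError("ic50_sensitive_max_um must be positive")
        for name in ("rho_reasonable", "rho_good"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1]")
        for name in ("kappa_moderate_min", "kappa_substantial_min",
                     "waterfall_linearity_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class WaterfallCutoff:
    """Cutoff for one drug plus how it was obtained."""

    cutoff: float
    linear: bool
    degenerate: bool
    r_linearity: float


@dataclass
class BinaryCallMatrix:
    """Sensitive/insensitive calls with per-drug cutoff provenance."""

    study_id: str
    measure: str
    method: str  # WATERFALL or FIXED
    calls: pd.DataFrame  # cell lines x drugs; {1, 0, NaN}
    per_drug_cutoff: dict[str, float]

    @property
    def cell_lines(self) -> list[str]:
        return list(self.calls.index)

    @property
    def drugs(self) -> list[str]:
        return list(self.calls.columns)


def waterfall_cutoff(
    values: np.ndarray,
    linearity_min: float = 0.95,
    cutoff_bounds: tuple[float, float] | None = None,
) -> WaterfallCutoff:
    """Inflection-point cutoff of a single drug's response distribution.

    Parameters
    ----------
    values
        Response values across the full cell-line panel; NaN allowed.
    linearity_min
        Linear/nonlinear branch threshold on |r|(sorted value, rank).
    cutoff_bounds
        Optional (lo, hi) interval the cutoff is clamped into.

    Returns
    -------
    WaterfallCutoff
        The cutoff in the measure's units, with branch flags.  Ties in
        chord distance resolve to the smallest rank (most sensitive side).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        raise ValueError(f"waterfall cutoff needs >=3 values, got {v.size}")
    y = np.sort(v)[::-1]
    if y[0] == y[-1]:
        return WaterfallCutoff(cutoff=float(y[0]), linear=False,
                               degenerate=True, r_linearity=float("nan"))
    n = y.size
    ranks = np.arange(n, dtype=float)
    r_lin = abs(float(np.corrcoef(ranks, y)[0, 1]))
    if r_lin >= linearity_min:
        cut = float(np.median(y))
        linear = True
    else:
        # point-to-chord distance after min-max scaling both axes to [0,1];
        # chord runs (0, 1) -> (1, 0), so distance ∝ |1 - x - y|
        x01 = ranks / (n - 1)
        y01 = (y - y[-1]) / (y[0] - y[-1])
        dist = np.abs(1.0 - x01 - y01) / math.sqrt(2.0)
        idx = int(np.argmax(dist))  # argmax takes the first (smallest rank) tie
        cut = float(y[idx])
        linear = False
    if cutoff_bounds is not None:
        lo, hi = cutoff_bounds
        cut = min(max(cut, lo), hi)
    return WaterfallCutoff(cutoff=cut, linear=linear, degenerate=False,
                           r_linearity=r_lin)


def _emit_calls(values: pd.DataFrame, cutoffs: dict[str, float],
                measure: str) -> pd.DataFrame:
    calls = pd.DataFrame(np.nan, index=values.index, columns=values.columns)
    for drug in values.columns:
        cut = cutoffs.get(drug)
        col = values[drug]
        if cut is None or math.isnan(cut):
            continue
        if measure == "AUC":
            sens = col >= cut
        else:  # IC50 on log10 scale: lower is more sensitive
            sens = col <= cut
        calls[drug] = np.where(col.isna(), np.nan,
                               np.where(sens, SENSITIVE, INSENSITIVE))
    return calls


def call_waterfall(
    m: SensitivityMatrix,
    cfg: ThresholdConfig | None = None,
    restrict_to: list[str] | None = None,
    cutoff_bounds: tuple[float, float] | None = None,
) -> BinaryCallMatrix:
    """Waterfall calls for every drug of a sensitivity matrix.

    Cutoffs are computed on ALL cell lines of ``m``; ``restrict_to``
    subsets the returned calls only after calling, so the cutoff is
    independent of any cross-study intersection.
    """
    cfg = cfg or ThresholdConfig()
    if restrict_to is not None:
        unknown = set(restrict_to) - set(m.cell_lines)
        if unknown:
            raise ValueError(f"unknown cell lines in restrict_to: {sorted(unknown)[:5]}")
    cutoffs: dict[str, float] = {}
    for drug in m.drugs:
        col = m.values[drug].to_numpy()
        if np.sum(~np.isnan(col)) < 3:
            warnings.warn(f"drug {drug}: <3 values, calls left missing")
            cutoffs[drug] = float("nan")
            continue
        wf = waterfall_cutoff(col, linearity_min=cfg.waterfall_linearity_min,
                              cutoff_bounds=cutoff_bounds)
        cutoffs[drug] = wf.cutoff
    calls = _emit_calls(m.values, cutoffs, m.measure)
    if restrict_to is not None:
        calls = calls.loc[restrict_to]
    return BinaryCallMatrix(study_id=m.study_id, measure=m.measure,
                            method="WATERFALL", calls=calls,
                            per_drug_cutoff=cutoffs)


def call_fixed(m: SensitivityMatrix, cfg: ThresholdConfig | None = None) -> BinaryCallMatrix:
    """Fixed-cutoff calls: AUC >= 0.2 sensitive; IC50 <= 1 uM sensitive."""
    cfg = cfg or ThresholdConfig()
    if m.measure == "AUC":
        cut = cfg.auc_sensitive_min
    elif m.measure == "IC50":
        cut = math.log10(cfg.ic50_sensitive_max_um)
    else:  # pragma: no cover - SensitivityMatrix already validates
        raise ValueError(f"unknown measure {m.measure!r}")
    cutoffs = {drug: cut for drug in m.drugs}
    calls = _emit_calls(m.values, cutoffs, m.measure)
    return BinaryCallMatrix(study_id=m.study_id, measure=m.measure,
                            method="FIXED", calls=calls,
                            per_drug_cutoff=cutoffs)
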