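"""Diagnostic figures: per-drug scatter and consistency distributions."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .consistency import ConsistencyReport
from .io import PairedStudy


def plot_drug_scatter(pair: PairedStudy, datatype: str, drug: str,
                      path: str | Path) -> None:
    """Scatter of one drug's values in study A vs study B."""
    ma = pair.study_a.sensitivity[datatype].values[drug]
    mb = pair.study_b.sensitivity[datatype].values[drug]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(ma, mb, s=12, alpha=0.6)
    ax.set_xlabel(f"{pair.study_a.study_id} {datatype}")
    ax.set_ylabel(f"{pair.study_b.study_id} {datatype}")
    ax.set_title(drug)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_consistency_distributions(reports: dict[str, ConsistencyReport],
                                   path: str | Path) -> None:
    """Box plots of per-entity agreement statistics across data types."""
    labels, data = [], []
    for name, rep in reports.items():
        v = rep.defined_rho()
        if v.size == 0:
            v = rep.defined_kappa()
        if v.size:
            labels.append(name)
            data.append(v)
    fig, ax = plt.subplots(figsize=(1.2 * max(len(labels), 3) + 1, 4))
    if data:
        ax.boxplot(data, tick_labels=labels)
    ax.axhline(0.8, ls="--", lw=0.8, color="grey")
    ax.axhline(0.5, ls=":", lw=0.8, color="grey")
    ax.set_ylabel("per-entity agreement (rho or kappa)")
    ax.set_ylim(-1, 1)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
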