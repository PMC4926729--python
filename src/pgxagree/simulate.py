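"""Synthetic paired-study generator with controlled truth and noise.

The generator emulates the statistical situation of two screening groups
independently assaying the same cell-line panel:

* a latent true sensitivity ``s(cell, drug) ~ N(0, 1)`` shifted by
  ``effect_beta`` (latent SD units) in cell lines mutated for a causal
  gene of that drug;
* each study observes ``sqrt(R) * s + sqrt(1 - R) * eps`` with its own
  independent standard-normal noise, where the reliability ``R`` is the
  fraction of observed variance carried by the latent signal — so the
  expected between-study Pearson correlation is exactly
  ``sqrt(R_a * R_b)`` (:func:`expected_attenuation`);
* the AUC read-out squashes the latent-scale observation into [0, 1]
  through a fixed logistic (scale 1.5, nearly linear over the bulk of a
  standard normal, so the attenuation law survives the transform);
* the log10 IC50 read-out applies a fixed decreasing map — affine when
  ``auc_ic50_link='none'`` (driven by an independent latent, so AUC and
  IC50 measure unrelated quantities) or cubic when ``'monotone_nonlinear'``
  (same latent as AUC, nonlinearly distorted) — and is censored at the
  maximum tested concentration (default 8 uM);
* true mutation status is Bernoulli(prevalence) per (cell line, gene);
  each study observes it through an independent symmetric flip channel
  with probability ``mutation_flip_rate``;
* expression and copy-number features are independent latent normals
  observed with their own per-datatype reliabilities.

Randomness: one global seed; every component (truth, each study's noise for
each datatype) draws from its own deterministic substream, so adding a
datatype never perturbs the others and identical parameters give identical
output bytes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (MolecularProfile, PairedStudy, SensitivityMatrix, StudyBundle,
                 intersect_studies, write_matrix)

_AUC_SCALE = 1.5  # logistic squash scale for the AUC read-out

# fixed substream ids: adding a component must never renumber the others
_STREAMS = {
    "truth_mutation": 0, "truth_sensitivity": 1, "causal_pairs": 2,
    "auc_noise_a": 3, "auc_noise_b": 4,
    "ic50_noise_a": 5, "ic50_noise_b": 6,
    "mutation_flip_a": 7, "mutation_flip_b": 8,
    "truth_expression": 9, "expr_noise_a": 10, "expr_noise_b": 11,
    "truth_cnv": 12, "cnv_noise_a": 13, "cnv_noise_b": 14,
    "ic50_latent": 15, "study_bias_a": 16, "study_bias_b": 17,
}


def _default_reliability() -> dict[str, float]:
    # Study conditions: pharmacological read-outs reach only replicate-level
    # correlation (~0.5) while genomic layers are far more reproducible.
    return {"AUC": 0.5, "IC50": 0.5, "EXPRESSION": 0.81, "CNV": 0.9}


@dataclass
class SimulationParams:
    """Generating parameters of a synthetic study pair.

    reliability maps datatype -> R = var(latent) / var(observed) in [0, 1].
    mutation_flip_rate is the per-study symmetric miscall probability.
    effect_beta is the latent-SD shift of sensitivity in mutants of a
    causal gene.  study_bias adds a per-(study, drug) offset with this SD
    on the latent scale (protocol-level bias; 0 = pure noise model).
    """

    n_cell_lines: int = 500
    n_drugs: int = 20
    n_genes: int = 100
    reliability: dict[str, float] = field(default_factory=_default_reliability)
    mutation_prevalence: float = 0.3
    mutation_flip_rate: float = 0.1
    n_causal_pairs: int = 100
    effect_beta: float = 1.0
    auc_ic50_link: str = "monotone_nonlinear"
    ic50_max_conc: float = 8.0
    study_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cell_lines", "n_drugs", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for key, r in self.reliability.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"reliability[{key}] must be in [0, 1]")
        for name in ("mutation_prevalence", "mutation_flip_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.n_causal_pairs <= self.n_genes * self.n_drugs:
            raise ValueError("n_causal_pairs must be in [0, n_genes * n_drugs]")
        if self.auc_ic50_link not in ("none", "monotone_nonlinear"):
            raise ValueError(f"unknown auc_ic50_link {self.auc_ic50_link!r}")
        if self.ic50_max_conc <= 0:
            raise ValueError("ic50_max_conc must be positive")
        if self.study_bias < 0:
            raise ValueError("study_bias must be >= 0")

    def replace(self, **kw) -> "SimulationParams":
        out = dataclasses.replace(self, **kw)
        out.reliability = dict(kw.get("reliability", self.reliability))
        return out


@dataclass
class SyntheticStudyPair:
    """Latent truth plus the two observed studies."""

    params: SimulationParams
    truth_sensitivity: pd.DataFrame       # cells x drugs, latent scale
    truth_mutation: pd.DataFrame          # genes x cells, {0,1}
    causal_pairs: list[tuple[str, str]]   # (gene, drug)
    study_a: StudyBundle
    study_b: StudyBundle

    def paired_study(self) -> PairedStudy:
        """Align the two observed studies (labels are already common)."""
        return intersect_studies(self.study_a, self.study_b)


def expected_attenuation(r_a: float, r_b: float) -> float:
    """Expected inter-study Pearson correlation for a shared latent signal.

    Each study observes the same latent variable with reliability r (the
    latent share of observed variance), so the observed correlation is
    attenuated to sqrt(r_a * r_b).
    """
    for name, r in (("r_a", r_a), ("r_b", r_b)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    return float(np.sqrt(r_a * r_b))


def _rng(params: SimulationParams, stream: str) -> np.random.Generator:
    return np.random.default_rng([params.seed, _STREAMS[stream]])


def _logistic_auc(z: np.ndarray) -> np.ndarray:
    return np.clip(1.0 / (1.0 + np.exp(-z / _AUC_SCALE)), 0.0, 1.0)


def _ic50_map(z: np.ndarray, link: str) -> np.ndarray:
    # decreasing maps: more sensitive (higher latent) -> lower log IC50
    if link == "none":
        return 0.5 - 0.7 * z
    return 0.5 - 0.7 * z - 0.15 * z ** 3


def _observe(latent: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    return np.sqrt(r) * latent + np.sqrt(1.0 - r) * rng.standard_normal(latent.shape)


def generate_pair(params: SimulationParams) -> SyntheticStudyPair:
    """Draw one synthetic study pair, fully determined by ``params.seed``."""
    n_c, n_d, n_g = params.n_cell_lines, params.n_drugs, params.n_genes
    cells = [f"CL{i + 1:04d}" for i in range(n_c)]
    drugs = [f"D{j + 1:03d}" for j in range(n_d)]
    genes = [f"G{k + 1:04d}" for k in range(n_g)]

    mut_true = (_rng(params, "truth_mutation").random((n_c, n_g))
                < params.mutation_prevalence).astype(float)   # cells x genes

    flat = _rng(params, "causal_pairs").choice(
        n_g * n_d, size=params.n_causal_pairs, replace=False)
    causal = [(genes[i // n_d], drugs[i % n_d]) for i in sorted(flat)]

    s = _rng(params, "truth_sensitivity").standard_normal((n_c, n_d))
    for gene, drug in causal:
        s[:, drugs.index(drug)] += params.effect_beta * mut_true[:, genes.index(gene)]

    rel = params.reliability
    ic50_latent = (s if params.auc_ic50_link == "monotone_nonlinear"
                   else _rng(params, "ic50_latent").standard_normal((n_c, n_d)))

    bundles = {}
    for side in ("a", "b"):
        sid = f"STUDY_{side.upper()}"
        bundle = StudyBundle(study_id=sid)
        bias = (params.study_bias
                * _rng(params, f"study_bias_{side}").standard_normal(n_d))

        z_auc = _observe(s, rel.get("AUC", 1.0), _rng(params, f"auc_noise_{side}")) + bias
        bundle.sensitivity["AUC"] = SensitivityMatrix(
            study_id=sid, measure="AUC",
            values=pd.DataFrame(_logistic_auc(z_auc), index=cells, columns=drugs))

        z_ic = _observe(ic50_latent, rel.get("IC50", 1.0),
                        _rng(params, f"ic50_noise_{side}")) + bias
        bundle.sensitivity["IC50"] = SensitivityMatrix(
            study_id=sid, measure="IC50",
            values=pd.DataFrame(_ic50_map(z_ic, params.auc_ic50_link),
                                index=cells, columns=drugs),
            ic50_max_conc=params.ic50_max_conc)

        flips = (_rng(params, f"mutation_flip_{side}").random((n_c, n_g))
                 < params.mutation_flip_rate)
        mut_obs = np.where(flips, 1.0 - mut_true, mut_true)
        bundle.profiles["MUTATION"] = MolecularProfile(
            study_id=sid, datatype="MUTATION",
            values=pd.DataFrame(mut_obs.T, index=genes, columns=cells))
        bundles[side] = bundle

    for dtype, truth_stream, noise_stem in (
            ("EXPRESSION", "truth_expression", "expr_noise"),
            ("CNV", "truth_cnv", "cnv_noise")):
        latent = _rng(params, truth_stream).standard_normal((n_g, n_c))
        for side in ("a", "b"):
            obs = _observe(latent, rel.get(dtype, 1.0),
                           _rng(params, f"{noise_stem}_{side}"))
            bundles[side].profiles[dtype] = MolecularProfile(
                study_id=bundles[side].study_id, datatype=dtype,
                values=pd.DataFrame(obs, index=genes, columns=cells))

    return SyntheticStudyPair(
        params=params,
        truth_sensitivity=pd.DataFrame(s, index=cells, columns=drugs),
        truth_mutation=pd.DataFrame(mut_true.T, index=genes, columns=cells),
        causal_pairs=causal,
        study_a=bundles["a"], study_b=bundles["b"])


def write_fixture(pair: SyntheticStudyPair, out_dir: str | Path) -> Path:
    """Write both observed studies as CSV plus a manifest; truth separately.

    The manifest is consumable by :func:`pgxagree.io.load_manifest` and the
    CSVs round-trip bit-exactly through the readers.  Returns the manifest
    path.  Identical pairs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "truth").mkdir(exist_ok=True)

    manifest: dict = {"studies": {}}
    for key, bundle in (("a", pair.study_a), ("b", pair.study_b)):
        entry: dict = {"study_id": bundle.study_id, "sensitivity": {},
                       "profiles": {}}
        for measure, m in sorted(bundle.sensitivity.items()):
            fname = f"{key}_{measure}.csv"
            if measure == "IC50":
                # written on the stored log10(uM) scale so the round trip
                # through the reader is bit-exact
                entry["sensitivity"][measure] = {
                    "path": fname, "ic50_max_conc": m.ic50_max_conc,
                    "scale": "log10uM"}
            else:
                entry["sensitivity"][measure] = {"path": fname}
            write_matrix(m.values, out_dir / fname)
        for dtype, p in sorted(bundle.profiles.items()):
            fname = f"{key}_{dtype}.csv"
            write_matrix(p.values, out_dir / fname)
            entry["profiles"][dtype] = {"path": fname}
        manifest["studies"][key] = entry

    write_matrix(pair.truth_sensitivity, out_dir / "truth" / "sensitivity.csv")
    write_matrix(pair.truth_mutation, out_dir / "truth" / "mutation.csv")
    pd.DataFrame(pair.causal_pairs, columns=["gene", "drug"]).to_csv(
        out_dir / "truth" / "causal_pairs.csv", index=False)

    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path
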