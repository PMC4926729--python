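"""Reading, writing, harmonizing and intersecting paired study matrices.

Cell-line pharmacogenomic screens publish two kinds of matrices:

* drug sensitivity — cell lines x drugs, either an activity-area AUC in
  [0, 1] (higher = more sensitive) or an IC50 in micromolar, analysed and
  stored here on the log10(uM) scale;
* molecular profiles — genes x cell lines, continuous (expression, copy
  number) or binary (mutation presence/absence).

Cross-study comparison is only meaningful on the identifiers the studies
share, so the central operation is :func:`intersect_studies`, which subsets
and reorders every matrix of both studies onto the common cell lines, drugs
and genes.  Identifier matching is exact after :func:`harmonize_label`
(uppercase, non-alphanumerics stripped); no fuzzy or synonym matching is
attempted, and mismatches are surfaced in the drop report rather than
silently repaired.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

MEASURES = ("AUC", "IC50")
PROFILE_TYPES = ("EXPRESSION", "CNV", "MUTATION")
DATATYPES = MEASURES + PROFILE_TYPES

_NON_ALNUM = re.compile(r"[^A-Z0-9]")


class PgxError(Exception):
    """Base class for data errors in this package."""


class ParseError(PgxError):
    """A table cell could not be interpreted."""


class LabelCollisionError(PgxError):
    """Two raw labels harmonize to the same identifier."""


def harmonize_label(raw: str) -> str:
    """Canonicalize a cell-line/drug/gene identifier.

    Uppercases and strips every non-alphanumeric character, so e.g.
    ``MCF-7`` and ``MCF7`` compare equal across studies.

    Raises
    ------
    ValueError
        If the input is empty or contains no alphanumeric character.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError(f"cannot harmonize empty label {raw!r}")
    out = _NON_ALNUM.sub("", raw.upper())
    if not out:
        raise ValueError(f"label {raw!r} contains no alphanumeric characters")
    return out


def _harmonize_index(labels: Iterable[str], what: str) -> list[str]:
    mapped: dict[str, str] = {}
    out = []
    for raw in labels:
        h = harmonize_label(str(raw))
        if h in mapped:
            raise LabelCollisionError(
                f"duplicate {what} label after harmonization: "
                f"{mapped[h]!r} and {raw!r} both map to {h!r}"
            )
        mapped[h] = str(raw)
        out.append(h)
    return out


@dataclass
class SensitivityMatrix:
    """Cell-line x drug response values for one study and one measure.

    ``values`` is indexed by harmonized cell-line labels (rows) and drug
    labels (columns).  AUC is a dimensionless fraction in [0, 1]
    (activity-area convention, higher = more sensitive); IC50 is stored as
    log10(uM) and, when ``ic50_max_conc`` is set, censored at
    log10(ic50_max_conc) — values at the bound are counted in
    ``n_censored`` rather than dropped.
    """

    study_id: str
    measure: str
    values: pd.DataFrame
    ic50_max_conc: float | None = None
    n_censored: int = 0

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        self.values = self.values.astype(float)
        if self.measure == "AUC":
            v = self.values.to_numpy()
            bad = (v < 0) | (v > 1)
            if np.nansum(bad):
                raise ValueError(
                    f"{int(np.nansum(bad))} AUC values outside [0, 1] "
                    f"in study {self.study_id!r}"
                )
        elif self.ic50_max_conc is not None:
            bound = float(np.log10(self.ic50_max_conc))
            v = self.values.to_numpy()
            over = v > bound + 1e-12
            if np.nansum(over):
                self.n_censored += int(np.nansum(over))
                self.values = self.values.clip(upper=bound)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.index)

    @property
    def drugs(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, cell_lines: list[str], drugs: list[str]) -> "SensitivityMatrix":
        return SensitivityMatrix(
            study_id=self.study_id,
            measure=self.measure,
            values=self.values.loc[cell_lines, drugs],
            ic50_max_conc=self.ic50_max_conc,
            n_censored=self.n_censored,
        )


@dataclass
class MolecularProfile:
    """Gene x cell-line matrix for one study and one molecular data type.

    MUTATION matrices are restricted to {0, 1, missing}.
    """

    study_id: str
    datatype: str
    values: pd.DataFrame  # genes x cell lines

    def __post_init__(self) -> None:
        if self.datatype not in PROFILE_TYPES:
            raise ValueError(f"unknown profile datatype {self.datatype!r}")
        self.values = self.values.astype(float)
        if self.datatype == "MUTATION":
            v = self.values.to_numpy()
            ok = np.isnan(v) | (v == 0.0) | (v == 1.0)
            if not ok.all():
                raise ValueError(
                    "MUTATION values must be 0, 1 or missing; found "
                    f"{v[~ok][:5].tolist()}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, genes: list[str], cell_lines: list[str]) -> "MolecularProfile":
        return MolecularProfile(
            study_id=self.study_id,
            datatype=self.datatype,
            values=self.values.loc[genes, cell_lines],
        )


@dataclass
class StudyBundle:
    """All matrices published by one study, keyed by datatype."""

    study_id: str
    sensitivity: dict[str, SensitivityMatrix] = field(default_factory=dict)
    profiles: dict[str, MolecularProfile] = field(default_factory=dict)

    def cell_line_sets(self) -> list[set[str]]:
        sets = [set(m.cell_lines) for m in self.sensitivity.values()]
        sets += [set(p.cell_lines) for p in self.profiles.values()]
        return sets

    def drug_set(self) -> set[str] | None:
        sets = [set(m.drugs) for m in self.sensitivity.values()]
        if not sets:
            return None
        out = sets[0]
        for s in sets[1:]:
            out &= s
        return out

    def gene_set(self) -> set[str] | None:
        sets = [set(p.genes) for p in self.profiles.values()]
        if not sets:
            return None
        out = sets[0]
        for s in sets[1:]:
            out &= s
        return out


@dataclass
class PairedStudy:
    """Two studies aligned on their common cell lines, drugs and genes."""

    study_a: StudyBundle
    study_b: StudyBundle
    common_cell_lines: list[str]
    common_drugs: list[str]
    common_genes: list[str]
    drop_report: dict[str, dict[str, int]] = field(default_factory=dict)


def _read_table(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str,
                     keep_default_na=False, encoding="utf-8")
    num = df.apply(lambda col: pd.to_numeric(col.replace("", np.nan), errors="coerce"))
    bad = num.isna() & (df != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"non-numeric cell {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        )
    # convert via Python float(): correctly rounded, so write/read round-trips
    # bit-exactly (pd.to_numeric's fast path is not)
    return df.map(lambda s: float(s) if s != "" else np.nan)


def read_sensitivity_table(
    path: str | Path,
    measure: str,
    study_id: str,
    ic50_max_conc: float | None = None,
    delimiter: str = ",",
    transpose: bool = False,
    ic50_scale: str = "uM",
) -> SensitivityMatrix:
    """Read a cell-line x drug table (first column = cell-line labels).

    IC50 values are expected in micromolar and converted to log10(uM)
    (pass ``ic50_scale='log10uM'`` for files already on the log scale);
    empty cells become missing.  Set ``transpose`` if the file is stored
    drugs x cell lines.
    """
    df = _read_table(path, delimiter)
    if transpose:
        df = df.T
    df.index = _harmonize_index(df.index, "cell-line")
    df.columns = _harmonize_index(df.columns, "drug")
    if measure == "IC50" and ic50_scale == "uM":
        with np.errstate(divide="ignore", invalid="ignore"):
            arr = np.log10(df.to_numpy(dtype=float))
        if np.nansum(~np.isfinite(arr) & ~np.isnan(df.to_numpy(dtype=float))):
            raise ParseError(f"non-positive IC50 value in {path}")
        df = pd.DataFrame(arr, index=df.index, columns=df.columns)
    return SensitivityMatrix(study_id=study_id, measure=measure, values=df,
                             ic50_max_conc=ic50_max_conc)


def read_molecular_profile(
    path: str | Path,
    datatype: str,
    study_id: str,
    delimiter: str = ",",
    transpose: bool = False,
) -> MolecularProfile:
    """Read a gene x cell-line table (first column = gene labels)."""
    df = _read_table(path, delimiter)
    if transpose:
        df = df.T
    df.index = _harmonize_index(df.index, "gene")
    df.columns = _harmonize_index(df.columns, "cell-line")
    return MolecularProfile(study_id=study_id, datatype=datatype, values=df)


def write_matrix(values: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write a labelled matrix as delimited text; missing cells are empty.

    Floats are written with Python's shortest round-tripping repr so a
    write/read cycle reproduces values bit-exactly.
    """
    values.to_csv(path, sep=delimiter, na_rep="", encoding="utf-8")


def _common(sets: list[set[str]]) -> set[str]:
    out = sets[0].copy()
    for s in sets[1:]:
        out &= s
    return out


def intersect_studies(a: StudyBundle, b: StudyBundle) -> PairedStudy:
    """Align two studies on their shared cell lines, drugs and genes.

    Every matrix of both bundles is subset and reordered to the sorted
    intersection of harmonized labels.  A drop report records how many
    labels each side lost.  Raises :class:`PgxError` if fewer than two
    cell lines are shared (correlation is undefined below that).
    """
    cl_sets = a.cell_line_sets() + b.cell_line_sets()
    if not cl_sets:
        raise PgxError("no matrices to intersect")
    common_cl = sorted(_common(cl_sets))
    if len(common_cl) < 2:
        raise PgxError(
            f"only {len(common_cl)} cell line(s) in common; need at least 2"
        )

    da, db = a.drug_set(), b.drug_set()
    if da is not None and db is not None:
        common_drugs = sorted(da & db)
    else:
        common_drugs = sorted(da if da is not None else (db or set()))

    ga, gb = a.gene_set(), b.gene_set()
    if ga is not None and gb is not None:
        common_genes = sorted(ga & gb)
    else:
        common_genes = sorted(ga if ga is not None else (gb or set()))

    def _apply(bundle: StudyBundle) -> StudyBundle:
        out = StudyBundle(study_id=bundle.study_id)
        for k, m in bundle.sensitivity.items():
            out.sensitivity[k] = m.subset(common_cl, common_drugs)
        for k, p in bundle.profiles.items():
            out.profiles[k] = p.subset(common_genes, common_cl)
        return out

    report: dict[str, dict[str, int]] = {}
    for side, bundle in (("study_a", a), ("study_b", b)):
        cls = _common(bundle.cell_line_sets()) if bundle.cell_line_sets() else set()
        ds = bundle.drug_set() or set()
        gs = bundle.gene_set() or set()
        report[side] = {
            "cell_lines_dropped": len(cls - set(common_cl)),
            "drugs_dropped": len(ds - set(common_drugs)),
            "genes_dropped": len(gs - set(common_genes)),
        }

    return PairedStudy(
        study_a=_apply(a),
        study_b=_apply(b),
        common_cell_lines=common_cl,
        common_drugs=common_drugs,
        common_genes=common_genes,
        drop_report=report,
    )


def load_manifest(path: str | Path) -> tuple[StudyBundle, StudyBundle]:
    """Load a two-study manifest (YAML) into a pair of bundles.

    Schema::

        studies:
          a:
            study_id: STUDY_A
            sensitivity:
              AUC: {path: auc.csv}
              IC50: {path: ic50.csv, ic50_max_conc: 8.0}
            profiles:
              MUTATION: {path: mut.csv}
          b: ...

    Relative paths resolve against the manifest's directory.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping) or "studies" not in cfg:
        raise PgxError(f"manifest {path} lacks a 'studies' section")
    bundles = []
    for key in ("a", "b"):
        spec = cfg["studies"][key]
        bundle = StudyBundle(study_id=str(spec.get("study_id", key.upper())))
        for measure, entry in (spec.get("sensitivity") or {}).items():
            bundle.sensitivity[measure] = read_sensitivity_table(
                path.parent / entry["path"], measure=measure,
                study_id=bundle.study_id,
                ic50_max_conc=entry.get("ic50_max_conc"),
                ic50_scale=entry.get("scale", "uM"),
            )
        for dtype, entry in (spec.get("profiles") or {}).items():
            bundle.profiles[dtype] = read_molecular_profile(
                path.parent / entry["path"], datatype=dtype,
                study_id=bundle.study_id,
            )
        bundles.append(bundle)
    return bundles[0], bundles[1]
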