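"""Domain tables for the volatilomics pipeline.

Three input tables drive every analysis stage:

* a compound x sample abundance matrix (peak areas or concentrations),
* a per-compound annotation table (chemical class, aroma descriptors,
  odor threshold, pathway memberships),
* a sample design table mapping samples to time points, aging stages and
  replicate indices, with pooled QC samples flagged.

Unobserved abundances are *missing*, never zero; the half-minimum fill
(:func:`fill_missing_half_min`) is applied once, before any log transform.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PEAK_AREA = "peak_area"
CONCENTRATION = "concentration"

#: Stage label reserved for pooled quality-control samples.
QC_STAGE = "QC"


class TableFormatError(ValueError):
    """Malformed input table (duplicate ids, bad header, ...)."""


class ValidationError(ValueError):
    """Well-formed table with invalid content (negative area, zero threshold, ...)."""


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


@dataclass
class FeatureTable:
    """Compound x sample abundance matrix.

    ``values`` is indexed by compound id (rows) and sample id (columns);
    missing cells are NaN.  ``value_kind`` records whether entries are raw
    peak areas (arbitrary units) or concentrations (ug/g).
    """

    values: pd.DataFrame
    value_kind: str = PEAK_AREA

    def __post_init__(self) -> None:
        if self.value_kind not in (PEAK_AREA, CONCENTRATION):
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        self.values.index.name = "compound_id"
        self.values.columns.name = None
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique())
            raise TableFormatError(f"duplicate compound ids: {dups}")
        if cols.duplicated().any():
            dups = sorted(cols[cols.duplicated()].unique())
            raise TableFormatError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            bad = self.values.index[(self.values < 0).any(axis=1)][0]
            raise ValidationError(f"negative abundance for compound {bad!r}")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset(self, compounds: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "FeatureTable":
        v = self.values
        if compounds is not None:
            v = v.loc[[c for c in v.index if c in set(compounds)]]
        if samples is not None:
            v = v[[s for s in v.columns if s in set(samples)]]
        return FeatureTable(v.copy(), self.value_kind)


@dataclass
class AnnotationTable:
    """Per-compound chemistry and aroma metadata.

    ``table`` is indexed by compound id with columns ``compound_class``
    (str), ``aroma_descriptors`` (frozenset of lower-case strings),
    ``odor_threshold`` (float ug/g, NaN when unknown) and ``pathway_ids``
    (frozenset of strings).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table.index.name = "compound_id"
        if self.table.index.duplicated().any():
            dups = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise TableFormatError(f"duplicate compound ids in annotations: {dups}")
        thr = self.table["odor_threshold"]
        bad = thr[thr.notna() & (thr <= 0)]
        if len(bad):
            raise ValidationError(
                f"non-positive odor threshold for {sorted(bad.index)}")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.table.index)

    def thresholds(self) -> pd.Series:
        return self.table["odor_threshold"]

    def descriptors(self, compound_id: str) -> frozenset:
        return self.table.at[compound_id, "aroma_descriptors"]

    def pathway_map(self) -> dict[str, set[str]]:
        """Invert per-compound pathway sets into pathway -> compound sets."""
        out: dict[str, set[str]] = {}
        for cid, pws in self.table["pathway_ids"].items():
            for pw in pws:
                out.setdefault(pw, set()).add(cid)
        return out

    def subset(self, compounds: Iterable[str]) -> "AnnotationTable":
        keep = [c for c in self.table.index if c in set(compounds)]
        return AnnotationTable(self.table.loc[keep].copy())


@dataclass
class StageDesign:
    """Sample -> time point -> aging stage mapping, QC samples included.

    ``table`` is indexed by sample id with columns ``time_point``,
    ``stage`` and ``replicate_index``.  QC samples carry stage ``"QC"``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table.index.name = "sample_id"
        if self.table.index.duplicated().any():
            raise TableFormatError("duplicate sample ids in design")
        counts = self.table[self.table["stage"] != QC_STAGE]["stage"].value_counts()
        thin = counts[counts < 2]
        if len(thin):
            raise ValidationError(
                f"stages with fewer than 2 samples: {sorted(thin.index)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def stages(self) -> list[str]:
        """Non-QC stage labels in order of first appearance."""
        seen = self.table.loc[self.table["stage"] != QC_STAGE, "stage"]
        return list(dict.fromkeys(seen))

    def samples_of_stage(self, stage: str) -> list[str]:
        return list(self.table.index[self.table["stage"] == stage])

    def biological_samples(self) -> list[str]:
        return list(self.table.index[self.table["stage"] != QC_STAGE])

    def qc_samples(self) -> list[str]:
        return list(self.table.index[self.table["stage"] == QC_STAGE])

    def subset(self, samples: Iterable[str]) -> "StageDesign":
        keep = [s for s in self.table.index if s in set(samples)]
        return StageDesign(self.table.loc[keep].copy())


@dataclass
class InternalStandardParams:
    """Spike-in bookkeeping for internal-standard semi-quantification.

    The deuterated internal standard (3-hexanone-2,2,4,4-d4 in the study
    this package models) is added at volume ``v_s`` (uL) and concentration
    ``c_s`` (ug/mL) to ``sample_mass`` (g) of ground material;
    ``is_peak_area`` holds the standard's observed peak area per sample.
    """

    v_s: float = 10.0
    c_s: float = 10.0
    sample_mass: float = 0.5
    is_peak_area: pd.Series = field(default_factory=pd.Series)

    def __post_init__(self) -> None:
        for name, v in (("v_s", self.v_s), ("c_s", self.c_s),
                        ("sample_mass", self.sample_mass)):
            if not v > 0:
                raise ValidationError(f"{name} must be strictly positive, got {v}")


# ---------------------------------------------------------------------------
# Readers / writers

def read_feature_table(path: str | Path, value_kind: str = PEAK_AREA,
                       sep: str | None = None,
                       missing_tokens: tuple[str, ...] = ("", "NA", "NaN", "nan")) -> FeatureTable:
    """Read a delimited compound x sample matrix.

    First column holds compound ids, the header row sample ids.  Cells
    matching ``missing_tokens`` become missing (NaN), never zero.
    """
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(missing_tokens),
                     keep_default_na=False, encoding="utf-8")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise TableFormatError(f"non-numeric abundance cell in {path}: {exc}") from exc
    return FeatureTable(df, value_kind)


def write_feature_table(ft: FeatureTable, path: str | Path, sep: str = ",") -> None:
    ft.values.to_csv(Path(path), sep=sep, index_label="compound_id",
                     na_rep="NA", encoding="utf-8")


def read_annotations(path: str | Path, sep: str | None = None,
                     sub_sep: str = ";", lowercase: bool = True) -> AnnotationTable:
    """Read a compound annotation table.

    Expected columns: ``compound_id``, ``compound_class``,
    ``aroma_descriptors``, ``odor_threshold``, ``pathway_ids``; multi-valued
    fields are ``sub_sep``-joined.  Descriptor and pathway strings are
    trimmed and (by default) lower-cased.
    """
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col="compound_id", dtype=str,
                     keep_default_na=False, encoding="utf-8")
    df.index = df.index.astype(str)

    def _split(cell: str, lower: bool) -> frozenset:
        parts = (p.strip() for p in str(cell).split(sub_sep))
        parts = (p.lower() if lower else p for p in parts if p)
        return frozenset(parts)

    out = pd.DataFrame(index=df.index)
    out["compound_class"] = df.get("compound_class", "").str.strip().str.lower()
    out["aroma_descriptors"] = [
        _split(c, lowercase) for c in df.get("aroma_descriptors", "")]
    out["odor_threshold"] = pd.to_numeric(df.get("odor_threshold", ""),
                                          errors="coerce")
    out["pathway_ids"] = [_split(c, False) for c in df.get("pathway_ids", "")]
    return AnnotationTable(out)


def write_annotations(ann: AnnotationTable, path: str | Path, sep: str = ",",
                      sub_sep: str = ";") -> None:
    df = ann.table.copy()
    df["aroma_descriptors"] = [sub_sep.join(sorted(s)) for s in df["aroma_descriptors"]]
    df["pathway_ids"] = [sub_sep.join(sorted(s)) for s in df["pathway_ids"]]
    df.to_csv(Path(path), sep=sep, index_label="compound_id", na_rep="",
              encoding="utf-8")


def read_design(path: str | Path, sep: str | None = None) -> StageDesign:
    path = Path(path)
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col="sample_id", encoding="utf-8")
    df.index = df.index.astype(str)
    df["replicate_index"] = df["replicate_index"].astype(int)
    return StageDesign(df[["time_point", "stage", "replicate_index"]])


def write_design(design: StageDesign, path: str | Path, sep: str = ",") -> None:
    design.table.to_csv(Path(path), sep=sep, index_label="sample_id",
                        encoding="utf-8")


# ---------------------------------------------------------------------------
# Alignment and missing-value policy

@dataclass
class AlignedBundle:
    """Feature, annotation and design tables restricted to common universes."""

    features: FeatureTable
    annotations: AnnotationTable
    design: StageDesign
    dropped_compounds: dict[str, int] = field(default_factory=dict)
    dropped_samples: dict[str, int] = field(default_factory=dict)


def align(ft: FeatureTable, ann: AnnotationTable, design: StageDesign) -> AlignedBundle:
    """Intersect compound and sample universes across the three tables.

    Compounds present in only one of features/annotations and samples
    absent from the design are dropped with a logged count.  Aligning an
    already-aligned bundle is a no-op.
    """
    compounds = [c for c in ft.compound_ids if c in set(ann.compound_ids)]
    samples = [s for s in ft.sample_ids if s in set(design.sample_ids)]
    if not compounds or not samples:
        raise ValidationError("alignment produced an empty compound or sample set")

    dropped_c = {
        "features_without_annotation": len(ft.compound_ids) - len(compounds),
        "annotations_without_feature": len(ann.compound_ids) - len(compounds),
    }
    dropped_s = {
        "features_without_design": len(ft.sample_ids) - len(samples),
        "design_without_feature": len(design.sample_ids) - len(samples),
    }
    for k, v in {**dropped_c, **dropped_s}.items():
        if v:
            logger.warning("align: dropped %d %s", v, k.replace("_", " "))
    return AlignedBundle(
        features=ft.subset(compounds, samples),
        annotations=ann.subset(compounds),
        design=design.subset(samples),
        dropped_compounds=dropped_c,
        dropped_samples=dropped_s,
    )


def fill_missing_half_min(ft: FeatureTable) -> FeatureTable:
    """Replace missing cells with half the compound's minimum positive value.

    The standard metabolomics minimum-fill: keeps log2 fold changes finite
    while leaving observed cells untouched.  A compound with no positive
    observation at all is filled with the global half-minimum.
    """
    v = ft.values.copy()
    pos = v.where(v > 0)
    row_min = pos.min(axis=1)
    global_fill = pos.min().min()
    if not np.isfinite(global_fill):
        raise ValidationError("cannot fill: table has no positive values")
    fill = (row_min / 2.0).fillna(global_fill / 2.0)
    n = int(v.isna().to_numpy().sum())
    if n:
        logger.info("fill_missing_half_min: filled %d missing cells", n)
    out = v.apply(lambda col: col.fillna(fill))
    return FeatureTable(out, ft.value_kind)
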