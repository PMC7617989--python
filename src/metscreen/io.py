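"""Reading, validation and writing of screen tables.

Handles the four tabular inputs of a pooled screen analysis: the sgRNA
library annotation (guide -> gene, protospacer), the guide-by-sample count
matrix, the sample metadata (sample -> mouse, tissue) and an optional
gene-level annotation table with arbitrary numeric score columns.

All files are delimited text (tab by default), UTF-8, with ``#``-prefixed
comment lines skipped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GuideLibrary",
    "SampleMeta",
    "CountMatrix",
    "read_library",
    "read_counts",
    "read_sample_meta",
    "read_annotation",
    "write_counts",
    "write_table",
    "TISSUES",
    "CONTROL_LABEL",
]

TISSUES = ("T0", "lung", "brain")

#: default sentinel in the gene column marking non-targeting control guides
CONTROL_LABEL = "CONTROL"

_VALID_BASES = frozenset("ACGT")


class ScreenIOError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass(frozen=True)
class GuideLibrary:
    """sgRNA library annotation.

    Parameters
    ----------
    table : DataFrame indexed by ``guide_id`` with columns ``gene`` and
        ``protospacer``.
    control_mask : boolean Series aligned to ``table`` marking control guides.
    """

    table: pd.DataFrame
    control_mask: pd.Series

    @property
    def guide_ids(self) -> pd.Index:
        return self.table.index

    @property
    def genes(self) -> pd.Series:
        """Gene symbol per guide (control sentinel included)."""
        return self.table["gene"]

    @property
    def control_guides(self) -> pd.Index:
        return self.table.index[self.control_mask]

    @property
    def targeting_guides(self) -> pd.Index:
        return self.table.index[~self.control_mask]

    @property
    def n_controls(self) -> int:
        return int(self.control_mask.sum())

    def targeting_genes(self) -> pd.Index:
        return pd.Index(sorted(self.table.loc[~self.control_mask, "gene"].unique()))

    def guides_per_gene(self) -> pd.Series:
        """Number of library guides per targeting gene."""
        return self.table.loc[~self.control_mask].groupby("gene").size()

    def require_controls(self) -> None:
        if self.n_controls == 0:
            raise ScreenIOError(
                "library contains no control guides; control-referenced "
                "log2 fold changes are undefined"
            )


@dataclass(frozen=True)
class SampleMeta:
    """Sample metadata: one row per sample with mouse id and tissue."""

    table: pd.DataFrame  # index sample_id; columns mouse_id, tissue (+ extras)

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def tissue(self) -> pd.Series:
        return self.table["tissue"]

    @property
    def mouse_id(self) -> pd.Series:
        return self.table["mouse_id"]

    def samples_of(self, tissue: str) -> pd.Index:
        return self.table.index[self.table["tissue"] == tissue]

    def require_brain_and_lung(self) -> None:
        for t in ("lung", "brain"):
            if len(self.samples_of(t)) == 0:
                raise ScreenIOError(
                    f"brain-vs-lung analysis requires at least one {t} sample"
                )


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer guide-by-sample read counts."""

    counts: pd.DataFrame  # index guide_id, columns sample_id, dtype int64

    @property
    def guides(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def column_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)


def _read_delimited(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ScreenIOError(f"input file not found: {path}")
    return pd.read_csv(path, sep=delimiter, comment="#", dtype=str, keep_default_na=False)


def read_library(
    path: str | Path,
    delimiter: str = "\t",
    protospacer_length: int = 20,
    guide_col: str = "guide_id",
    gene_col: str = "gene",
    seq_col: str = "protospacer",
    control_label: str = CONTROL_LABEL,
    control_id_regex: str | None = None,
) -> GuideLibrary:
    """Read and validate an sgRNA library annotation table.

    Control guides are those whose gene field equals ``control_label`` OR
    whose guide id matches ``control_id_regex`` (the two mechanisms are
    OR-ed). Duplicate guide ids or protospacers and non-ACGT protospacers
    are hard errors naming the offending row.
    """
    df = _read_delimited(path, delimiter)
    for col in (guide_col, gene_col, seq_col):
        if col not in df.columns:
            raise ScreenIOError(f"library file {path} lacks required column {col!r}")
    df = df.rename(columns={guide_col: "guide_id", gene_col: "gene", seq_col: "protospacer"})
    df["protospacer"] = df["protospacer"].str.upper()
    return build_library(
        df[["guide_id", "gene", "protospacer"]],
        protospacer_length=protospacer_length,
        control_label=control_label,
        control_id_regex=control_id_regex,
    )


def build_library(
    df: pd.DataFrame,
    protospacer_length: int = 20,
    control_label: str = CONTROL_LABEL,
    control_id_regex: str | None = None,
) -> GuideLibrary:
    """Validate an in-memory guide table and assemble a :class:`GuideLibrary`."""
    dup = df["guide_id"][df["guide_id"].duplicated()]
    if len(dup):
        raise ScreenIOError(f"duplicate guide_id(s): {sorted(dup.unique())}")
    dup_seq = df["protospacer"][df["protospacer"].duplicated()]
    if len(dup_seq):
        offenders = df.loc[df["protospacer"].isin(dup_seq), "guide_id"].tolist()
        raise ScreenIOError(f"duplicate protospacer(s) shared by guides {offenders}")
    for row_i, (gid, seq) in enumerate(zip(df["guide_id"], df["protospacer"])):
        if len(seq) != protospacer_length:
            raise ScreenIOError(
                f"row {row_i} (guide {gid}): protospacer length {len(seq)} "
                f"!= expected {protospacer_length}"
            )
        if not _VALID_BASES.issuperset(seq):
            raise ScreenIOError(
                f"row {row_i} (guide {gid}): protospacer contains non-ACGT characters"
            )
    table = df.set_index("guide_id")
    control = table["gene"].eq(control_label)
    if control_id_regex is not None:
        pat = re.compile(control_id_regex)
        control = control | table.index.to_series().map(lambda g: bool(pat.search(g)))
    empty_gene = table.index[(~control) & (table["gene"].str.len() == 0)]
    if len(empty_gene):
        raise ScreenIOError(f"targeting guides with empty gene symbol: {list(empty_gene)}")
    lib = GuideLibrary(table=table, control_mask=control)
    if lib.n_controls == 0:
        import warnings

        warnings.warn(
            "library contains no control guides; enrichment analysis will fail",
            stacklevel=2,
        )
    return lib


def read_sample_meta(path: str | Path, delimiter: str = "\t") -> SampleMeta:
    df = _read_delimited(path, delimiter)
    for col in ("sample_id", "mouse_id", "tissue"):
        if col not in df.columns:
            raise ScreenIOError(f"metadata file {path} lacks required column {col!r}")
    return build_sample_meta(df)


def build_sample_meta(df: pd.DataFrame) -> SampleMeta:
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ScreenIOError(f"duplicate sample_id(s): {sorted(dup.unique())}")
    bad = df.loc[~df["tissue"].isin(TISSUES), "sample_id"]
    if len(bad):
        raise ScreenIOError(
            f"samples with tissue outside {TISSUES}: {list(bad)}"
        )
    return SampleMeta(table=df.set_index("sample_id"))


def read_counts(
    path: str | Path,
    meta_path: str | Path,
    delimiter: str = "\t",
    library: GuideLibrary | None = None,
) -> tuple[CountMatrix, SampleMeta]:
    """Read a guide-by-sample count matrix plus its sample metadata.

    The counts file has ``guide_id`` as first column and one column per
    sample. Every sample column must have exactly one metadata row; negative
    or non-integer entries are errors with coordinates. When a library is
    supplied, guides absent from it are reported with a warning.
    """
    df = _read_delimited(path, delimiter)
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "guide_id"
    mat = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, val in enumerate(df[col]):
            try:
                f = float(val)
            except ValueError:
                raise ScreenIOError(
                    f"non-numeric count {val!r} at guide {df.index[i]}, sample {col}"
                ) from None
            if f < 0 or f != int(f):
                raise ScreenIOError(
                    f"negative or non-integer count {val!r} at guide "
                    f"{df.index[i]}, sample {col}"
                )
            mat[i, j] = int(f)
    counts = pd.DataFrame(mat, index=df.index, columns=df.columns)
    meta = read_sample_meta(meta_path, delimiter)
    missing = [s for s in counts.columns if s not in meta.sample_ids]
    if missing:
        raise ScreenIOError(f"samples missing from metadata: {missing}")
    if library is not None:
        unmatched = counts.index.difference(library.guide_ids)
        if len(unmatched):
            import warnings

            warnings.warn(
                f"{len(unmatched)} count-matrix guides absent from library "
                f"(e.g. {list(unmatched[:5])})",
                stacklevel=2,
            )
    return CountMatrix(counts=counts), meta


def write_counts(cm: CountMatrix, path: str | Path, delimiter: str = "\t") -> None:
    out = cm.counts.copy()
    out.index.name = "guide_id"
    out.to_csv(path, sep=delimiter)


def write_table(df: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    """Write an analysis output table (index excluded; NA as empty field)."""
    df.to_csv(path, sep=delimiter, index=False, na_rep="NA")


def read_annotation(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a gene annotation table: ``gene`` column plus numeric score columns.

    Missing scores may be encoded as empty fields or ``NA``; both become NaN.
    """
    path = Path(path)
    if not path.exists():
        raise ScreenIOError(f"annotation file not found: {path}")
    df = pd.read_csv(
        path, sep=delimiter, comment="#", na_values=["NA", ""], keep_default_na=True
    )
    if "gene" not in df.columns:
        raise ScreenIOError(f"annotation file {path} lacks a 'gene' column")
    dup = df["gene"][df["gene"].duplicated()]
    if len(dup):
        raise ScreenIOError(f"annotation has duplicate gene rows: {sorted(dup.unique())}")
    for col in df.columns:
        if col != "gene":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
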