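"""Reading and writing of array quantification data, layouts and matrices.

Quantification software (GenePix Pro, QuantArray, ScanArray and friends)
emits tab-delimited per-spot tables with a header section followed by a
column-labelled data block.  The canonical GenePix flavour is ATF (Axon
Text File): a first line ``ATF<TAB>1.0``, a second line with the number
of optional header records and data columns, that many ``"key=value"``
records, and then the table.  This module parses that dialect (or a
plain skip-N-lines variant), resolves column aliases, joins the spots
with the experiment layout and provides TSV round-trips for feature
matrices with a JSON audit trail.

Intensities are kept as the *median* pixel statistics by default; mean
columns can be selected through the dialect.  Coordinates are 1-based,
following the GenePix convention.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Dialect",
    "ExperimentLayout",
    "SpotTable",
    "ParseError",
    "LayoutError",
    "read_quantification_file",
    "read_layout",
    "assemble_experiment",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_quantification_file",
]

FEATURE_CLASSES = ("antigen", "control", "buffer", "tag")


class ParseError(ValueError):
    """A quantification or layout file could not be parsed."""


class LayoutError(ValueError):
    """Spots could not be reconciled with the experiment layout."""


@dataclass(frozen=True)
class Dialect:
    """Parser options for a quantification file.

    Parameters
    ----------
    header : {"atf", "skip"}
        ``"atf"`` reads an ATF preamble and derives the number of header
        records from it; ``"skip"`` skips ``skip_lines`` lines before the
        column-label row.  The dialect is always given explicitly, never
        sniffed.
    fg_column, bg_column
        Ordered alias lists; the first alias present in the file wins.
        Defaults cover the GenePix 635 nm channel plus generic names.
        Only one wavelength channel is processed per run.
    """

    header: str = "atf"
    skip_lines: int = 0
    block_column: tuple[str, ...] = ("Block",)
    row_column: tuple[str, ...] = ("Row",)
    col_column: tuple[str, ...] = ("Column", "Col")
    name_column: tuple[str, ...] = ("Name", "ID")
    fg_column: tuple[str, ...] = ("F635 Median", "FMedian", "F532 Median")
    bg_column: tuple[str, ...] = ("B635 Median", "BMedian", "B532 Median")
    flag_column: tuple[str, ...] = ("Flags", "Flag")
    diameter_column: tuple[str, ...] = ("Dia.", "Dia", "Diameter")


DEFAULT_DIALECT = Dialect()

#: Mandatory column roles; parsing fails loudly if any is unresolvable.
_MANDATORY = ("block", "row", "col", "feature", "fg", "bg")


@dataclass(frozen=True)
class ExperimentLayout:
    """Annotation joining printed features and blocks to the experiment.

    ``features`` maps each printed feature to its class (antigen /
    control / buffer / tag) and, for tagged antigens, the name of the
    purification-tag feature whose signal may later be subtracted.
    ``blocks`` maps each (slide, block) — a mini-array, the region
    allocated to one serum sample — to its sample and processing batch.
    A sample may span several blocks; blocks never share a row.
    """

    features: pd.DataFrame  # columns: feature, feature_class, tag_of
    blocks: pd.DataFrame  # columns: slide, block, sample, batch

    def __post_init__(self) -> None:
        feats = self.features
        for col in ("feature", "feature_class"):
            if col not in feats.columns:
                raise LayoutError(f"feature table lacks column {col!r}")
        bad = set(feats["feature_class"]) - set(FEATURE_CLASSES)
        if bad:
            raise LayoutError(f"unknown feature classes: {sorted(bad)}")
        blocks = self.blocks
        for col in ("slide", "block", "sample", "batch"):
            if col not in blocks.columns:
                raise LayoutError(f"block table lacks column {col!r}")
        dup = blocks.duplicated(subset=["slide", "block"])
        if dup.any():
            raise LayoutError(
                "duplicate block assignments: "
                f"{blocks.loc[dup, ['slide', 'block']].values.tolist()}"
            )
        nb = blocks.groupby("sample")["batch"].nunique()
        multi = nb[nb > 1]
        if len(multi):
            raise LayoutError(f"samples with >1 batch label: {list(multi.index)}")

    @property
    def feature_class(self) -> dict[str, str]:
        return dict(zip(self.features["feature"], self.features["feature_class"]))

    @property
    def tag_of(self) -> dict[str, str]:
        if "tag_of" not in self.features.columns:
            return {}
        sub = self.features.dropna(subset=["tag_of"])
        return {f: t for f, t in zip(sub["feature"], sub["tag_of"]) if t}

    @property
    def batch_of(self) -> dict[str, str]:
        return dict(zip(self.blocks["sample"].astype(str), self.blocks["batch"].astype(str)))

    def sample_of(self) -> pd.DataFrame:
        """(slide, block) → sample/batch mapping as a frame for joining."""
        return self.blocks[["slide", "block", "sample", "batch"]]


@dataclass
class SpotTable:
    """Long-format per-spot records with provenance.

    ``data`` holds one row per printed spot with (at least) the columns
    ``slide, block, row, col, feature, fg, bg, flag``; after
    :func:`assemble_experiment` also ``sample, batch, feature_class,
    tag_of, replicate``; after background correction also ``corrected``
    and ``negative_flag``.  ``provenance`` records source files and
    every processing step applied, for the audit trail.
    """

    data: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    def with_step(self, step: str, **params) -> "SpotTable":
        prov = [*self.provenance, {"step": step, "params": params}]
        return SpotTable(self.data, prov)

    def replace_data(self, data: pd.DataFrame, step: str, **params) -> "SpotTable":
        prov = [*self.provenance, {"step": step, "params": params}]
        return SpotTable(data, prov)


def _resolve(columns: list[str], aliases: tuple[str, ...]) -> str | None:
    for alias in aliases:
        if alias in columns:
            return alias
    return None


def _read_header(path: str, dialect: Dialect) -> int:
    """Number of lines preceding the column-label row."""
    if dialect.header == "skip":
        return dialect.skip_lines
    if dialect.header != "atf":
        raise ParseError(f"unknown header dialect {dialect.header!r}")
    with open(path, "r") as fh:
        first = fh.readline()
        if not first.upper().startswith("ATF"):
            raise ParseError(f"{path}: expected ATF preamble, got {first[:30]!r}")
        second = fh.readline().split("\t")
        try:
            n_optional = int(second[0])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: malformed ATF record-count line") from exc
    return 2 + n_optional


def read_quantification_file(
    path: str,
    dialect: Dialect = DEFAULT_DIALECT,
    slide_id: str | None = None,
) -> SpotTable:
    """Read one quantification file into a spot-table fragment.

    Parameters
    ----------
    path
        Tab-delimited file with an ATF-style preamble (or a fixed number
        of header lines per the dialect) followed by per-spot rows.
    slide_id
        Identifier attached to every record; defaults to the file's
        base name without extension.

    Returns
    -------
    SpotTable
        One record per data row, in file order, with foreground and
        background medians resolved through the dialect's alias lists.

    Raises
    ------
    ParseError
        If a mandatory column is missing, an intensity is non-numeric,
        or the data section is empty.
    """
    skip = _read_header(path, dialect)
    try:
        raw = pd.read_csv(path, sep="\t", skiprows=skip, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty data section") from exc
    raw.columns = [c.strip().strip('"') for c in raw.columns]
    if raw.empty:
        raise ParseError(f"{path}: empty data section")

    cols = list(raw.columns)
    roles = {
        "block": _resolve(cols, dialect.block_column),
        "row": _resolve(cols, dialect.row_column),
        "col": _resolve(cols, dialect.col_column),
        "feature": _resolve(cols, dialect.name_column),
        "fg": _resolve(cols, dialect.fg_column),
        "bg": _resolve(cols, dialect.bg_column),
        "flag": _resolve(cols, dialect.flag_column),
        "spot_diameter": _resolve(cols, dialect.diameter_column),
    }
    for role in _MANDATORY:
        if roles[role] is None:
            raise ParseError(
                f"{path}: no column found for mandatory role {role!r} "
                f"(aliases tried: {getattr(dialect, role + '_column', ('Name', 'ID'))})"
            )

    out = pd.DataFrame(index=raw.index)
    if slide_id is None:
        slide_id = os.path.splitext(os.path.basename(path))[0]
    out["slide"] = slide_id
    for role in ("block", "row", "col"):
        out[role] = _to_numeric(raw[roles[role]], path, roles[role], integer=True)
    out["feature"] = raw[roles["feature"]].astype(str).str.strip().str.strip('"')
    for role in ("fg", "bg"):
        out[role] = _to_numeric(raw[roles[role]], path, roles[role])
    out["flag"] = (
        _to_numeric(raw[roles["flag"]], path, roles["flag"], integer=True)
        if roles["flag"]
        else 0
    )
    if roles["spot_diameter"]:
        out["spot_diameter"] = _to_numeric(raw[roles["spot_diameter"]], path, roles["spot_diameter"])

    if (out["fg"] < 0).any() or (out["bg"] < 0).any():
        raise ParseError(f"{path}: negative raw intensity (scanner medians are nonnegative)")
    dup = out.duplicated(subset=["slide", "block", "row", "col"])
    if dup.any():
        raise ParseError(
            f"{path}: duplicate spot coordinates "
            f"{out.loc[dup, ['block', 'row', 'col']].values.tolist()[:5]}"
        )
    prov = [{"step": "read_quantification_file", "params": {"path": str(path), "header": dialect.header}}]
    return SpotTable(out.reset_index(drop=True), prov)


def _to_numeric(series: pd.Series, path: str, name: str, integer: bool = False) -> pd.Series:
    probe = pd.to_numeric(series, errors="coerce")
    bad = probe.isna() & series.notna()
    if bad.any():
        rownum = int(bad.idxmax()) + 1
        raise ParseError(
            f"{path}: non-numeric value {series[bad.idxmax()]!r} in column {name!r} (data row {rownum})"
        )
    if integer:
        return probe.astype(int)
    # astype goes through Python float(): correctly-rounded round-trip parsing
    return series.astype(float)


def read_layout(features_path: str, blocks_path: str) -> ExperimentLayout:
    """Read a plain-TSV layout: a feature table and a block→sample table.

    ``features_path`` needs columns ``feature, feature_class`` and
    optionally ``tag_of``; ``blocks_path`` needs
    ``slide, block, sample, batch``.
    """
    feats = pd.read_csv(features_path, sep="\t", dtype=str)
    blocks = pd.read_csv(blocks_path, sep="\t", dtype={"block": int}, converters=None)
    blocks["slide"] = blocks["slide"].astype(str)
    blocks["sample"] = blocks["sample"].astype(str)
    blocks["batch"] = blocks["batch"].astype(str)
    if "tag_of" in feats.columns:
        feats["tag_of"] = feats["tag_of"].replace({"": None, "NA": None, "nan": None})
    return ExperimentLayout(features=feats, blocks=blocks)


def assemble_experiment(
    fragments: list[SpotTable] | SpotTable,
    layout: ExperimentLayout,
) -> SpotTable:
    """Join spot fragments with the layout into one validated table.

    Attaches ``sample``, ``batch``, ``feature_class`` and ``tag_of`` to
    every record and assigns ``replicate`` 1..n within each
    (sample, feature) by (block, row, col) order, so technical
    replicates are numbered deterministically.

    Raises
    ------
    LayoutError
        If any block has no sample assignment, a feature has no class,
        or spot coordinates collide.
    """
    if isinstance(fragments, SpotTable):
        fragments = [fragments]
    data = pd.concat([f.data for f in fragments], ignore_index=True)
    prov = [s for f in fragments for s in f.provenance]

    dup = data.duplicated(subset=["slide", "block", "row", "col"])
    if dup.any():
        raise LayoutError(
            f"duplicate spot coordinates across fragments: "
            f"{data.loc[dup, ['slide', 'block', 'row', 'col']].values.tolist()[:5]}"
        )

    data["slide"] = data["slide"].astype(str)
    merged = data.merge(layout.sample_of(), on=["slide", "block"], how="left")
    orphan = merged["sample"].isna()
    if orphan.any():
        pairs = sorted(set(map(tuple, merged.loc[orphan, ["slide", "block"]].values)))
        raise LayoutError(f"blocks without sample assignment: {pairs}")

    feats = layout.features.set_index("feature")
    known = merged["feature"].isin(feats.index)
    if not known.all():
        missing = sorted(set(merged.loc[~known, "feature"]))
        raise LayoutError(f"features without class annotation: {missing[:10]}")
    merged["feature_class"] = feats["feature_class"].reindex(merged["feature"]).values
    if "tag_of" in feats.columns:
        merged["tag_of"] = feats["tag_of"].reindex(merged["feature"]).values
    else:
        merged["tag_of"] = None

    merged = merged.sort_values(["slide", "block", "row", "col"], kind="stable").reset_index(drop=True)
    merged["replicate"] = merged.groupby(["sample", "feature"]).cumcount() + 1
    prov.append({"step": "assemble_experiment", "params": {"n_fragments": len(fragments)}})
    return SpotTable(merged, prov)


def write_feature_matrix(
    matrix: pd.DataFrame,
    path: str,
    audit: list[dict] | None = None,
    overwrite: bool = False,
) -> None:
    """Write a features × samples matrix as TSV plus a JSON audit file.

    The TSV keeps full floating precision (``repr`` round-trippable).
    The audit record, written next to the matrix as ``<path>.audit.json``,
    lists one entry per processing step applied, so the file is
    self-describing.
    """
    if matrix.index.duplicated().any() or matrix.columns.duplicated().any():
        raise ValueError("matrix has duplicate feature or sample labels")
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    matrix.to_csv(path, sep="\t", index_label="feature", float_format="%.17g")
    if audit is not None:
        with open(str(path) + ".audit.json", "w") as fh:
            json.dump({"steps": audit}, fh, indent=2, default=str)


def read_feature_matrix(path: str) -> pd.DataFrame:
    """Read a matrix written by :func:`write_feature_matrix`."""
    return pd.read_csv(path, sep="\t", index_col="feature", float_precision="round_trip")


def write_quantification_file(
    spots: pd.DataFrame,
    path: str,
    extra_headers: dict[str, str] | None = None,
) -> None:
    """Write spots for one slide as an ATF-dialect quantification file.

    Used by the synthetic generator and for exporting corrected spot
    tables in a scanner-compatible shape.  ``spots`` needs the columns
    ``block, row, col, feature, fg, bg`` (``flag`` optional).
    """
    headers = {"Type": "GenePix Results 3", **(extra_headers or {})}
    cols = ["Block", "Row", "Column", "Name", "F635 Median", "B635 Median", "Flags"]
    flag = spots["flag"] if "flag" in spots.columns else 0
    table = pd.DataFrame(
        {
            "Block": spots["block"].astype(int),
            "Row": spots["row"].astype(int),
            "Column": spots["col"].astype(int),
            "Name": spots["feature"],
            "F635 Median": spots["fg"],
            "B635 Median": spots["bg"],
            "Flags": flag,
        }
    )
    with open(path, "w") as fh:
        fh.write("ATF\t1.0\n")
        fh.write(f"{len(headers)}\t{len(cols)}\n")
        for key, val in headers.items():
            fh.write(f'"{key}={val}"\n')
        table.to_csv(fh, sep="\t", index=False, float_format="%.17g", lineterminator="\n")
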