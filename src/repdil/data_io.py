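"""Reading and writing the two CSV input dialects used for qPCR tables.

Two layouts are supported:

* **Cq mode** — raw quantification-cycle values from a dilution-replicate
  run.  Mandatory columns ``Replicates``, ``Pairs``, ``Dilution`` followed
  by one column per amplicon, reference genes first, then genes of
  interest.
* **Precalculated mode** — linear-scale relative expression values with
  mandatory columns ``Replicates`` and ``Pairs`` followed by one column
  per gene of interest.

Both layouts may come in the point-decimal/comma-field dialect or the
European comma-decimal/semicolon-field dialect; the dialect is detected
automatically from the header line.  All output written by this package
uses the point-decimal dialect regardless of the input dialect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "Dialect",
    "POINT_DIALECT",
    "COMMA_DIALECT",
    "Dataset",
    "DialectError",
    "MalformedNameError",
    "InputFormatError",
    "detect_dialect",
    "split_replicate_name",
    "read_cq_table",
    "read_precalc_table",
    "write_table",
    "write_cq_csv",
]

#: Missing-value spellings accepted in input cells.
NA_VALUES = ["", "NA"]

CQ_MANDATORY = ["Replicates", "Pairs", "Dilution"]
PRECALC_MANDATORY = ["Replicates", "Pairs"]


class DialectError(ValueError):
    """The CSV dialect could not be determined from the header line."""


class MalformedNameError(ValueError):
    """A sample name does not follow the ``<group>_<replicate>`` convention."""


class InputFormatError(ValueError):
    """The table violates the fixed input layout."""


class Dialect(NamedTuple):
    field_sep: str
    decimal_sep: str


POINT_DIALECT = Dialect(",", ".")
COMMA_DIALECT = Dialect(";", ",")


@dataclass
class Dataset:
    """Parsed qPCR table in long (one row per well / value) form.

    ``wells`` columns in cq mode: ``group``, ``replicate_id``, ``pair_id``,
    ``dilution``, ``amplicon``, ``cq``; in precalculated mode: ``group``,
    ``replicate_id``, ``pair_id``, ``amplicon``, ``expression``.
    """

    wells: pd.DataFrame
    amplicons: list[str]
    reference_genes: list[str] = field(default_factory=list)
    mode: str = "cq"
    pairs_present: bool = False

    @property
    def genes_of_interest(self) -> list[str]:
        return [a for a in self.amplicons if a not in self.reference_genes]

    def replicate_keys(self) -> list[tuple[str, str]]:
        """(group, replicate_id) pairs in order of first appearance."""
        seen: dict[tuple[str, str], None] = {}
        for g, r in zip(self.wells["group"], self.wells["replicate_id"]):
            seen.setdefault((g, r), None)
        return list(seen)

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.wells["group"]:
            seen.setdefault(g, None)
        return list(seen)


def detect_dialect(raw_text: str) -> Dialect:
    """Infer the CSV dialect from the header line.

    A semicolon in the header implies the comma-decimal European dialect;
    a comma implies the point-decimal dialect.  A header containing both
    separators, or neither, is ambiguous and rejected.
    """
    if not raw_text.strip():
        raise DialectError("empty input: no header line to inspect")
    header = raw_text.lstrip("﻿").splitlines()[0]
    has_comma = "," in header
    has_semi = ";" in header
    if has_comma and has_semi:
        raise DialectError(
            f"ambiguous dialect: header contains both ',' and ';': {header!r}"
        )
    if has_semi:
        return COMMA_DIALECT
    if has_comma:
        return POINT_DIALECT
    raise DialectError(
        f"ambiguous dialect: header contains neither ',' nor ';': {header!r}"
    )


def split_replicate_name(name: str) -> tuple[str, str]:
    """Split ``<group>_<replicate>`` at the LAST underscore.

    Group names may themselves contain underscores; the replicate suffix
    must be non-empty and alphanumeric.
    """
    if "_" not in name:
        raise MalformedNameError(
            f"sample name {name!r} has no '_<replicate>' suffix"
        )
    group, _, suffix = name.rpartition("_")
    if not suffix or not suffix.isalnum() or not group:
        raise MalformedNameError(
            f"sample name {name!r}: replicate suffix must be non-empty "
            "alphanumeric text after the last underscore"
        )
    return group, suffix


def _read_raw(path: str | Path) -> tuple[pd.DataFrame, Dialect]:
    text = Path(path).read_text(encoding="utf-8-sig")
    dialect = detect_dialect(text)
    df = pd.read_csv(
        io.StringIO(text),
        sep=dialect.field_sep,
        decimal=dialect.decimal_sep,
        na_values=NA_VALUES,
        keep_default_na=False,
        dtype={0: str, 1: str},
        skipinitialspace=True,
    )
    df.columns = [str(c).strip() for c in df.columns]
    return df, dialect


def _split_names(series: pd.Series) -> tuple[list[str], list[str]]:
    groups, reps = [], []
    for i, name in enumerate(series):
        try:
            g, r = split_replicate_name(str(name))
        except MalformedNameError as exc:
            raise MalformedNameError(f"row {i + 2}: {exc}") from None
        groups.append(g)
        reps.append(r)
    return groups, reps


def read_cq_table(path: str | Path, reference_gene_names: list[str]) -> Dataset:
    """Parse a raw-Cq dilution-replicate CSV into a :class:`Dataset`.

    ``reference_gene_names`` designates which amplicon columns are
    reference genes; they must form a prefix of the amplicon columns
    (reference genes before genes of interest).
    """
    df, _ = _read_raw(path)
    if list(df.columns[:3]) != CQ_MANDATORY:
        raise InputFormatError(
            f"first three columns must be {CQ_MANDATORY}, got "
            f"{list(df.columns[:3])}"
        )
    amplicons = list(df.columns[3:])
    if not amplicons:
        raise InputFormatError("no amplicon columns after 'Dilution'")
    if not reference_gene_names:
        raise InputFormatError(
            "at least one reference gene must be named explicitly"
        )
    unknown = [g for g in reference_gene_names if g not in amplicons]
    if unknown:
        raise InputFormatError(
            f"reference genes {unknown} not among amplicon columns {amplicons}"
        )
    n_rg = len(reference_gene_names)
    if set(amplicons[:n_rg]) != set(reference_gene_names):
        raise InputFormatError(
            "reference-gene columns must precede genes of interest; "
            f"expected the first {n_rg} amplicon columns to be "
            f"{sorted(reference_gene_names)}"
        )

    groups, reps = _split_names(df["Replicates"])
    dil = pd.to_numeric(df["Dilution"], errors="coerce")
    if dil.isna().any():
        bad = df.loc[dil.isna(), "Dilution"].tolist()
        raise InputFormatError(f"non-numeric Dilution values: {bad}")
    if (dil <= 0).any():
        raise InputFormatError("dilution factors must be positive")

    pairs = df["Pairs"].astype("string")
    pairs_present = pairs.notna().any()

    base = pd.DataFrame(
        {
            "group": groups,
            "replicate_id": reps,
            "pair_id": pairs.where(pairs.notna(), None),
            "dilution": dil.astype(float),
        }
    )
    long = base.join(df[amplicons]).melt(
        id_vars=["group", "replicate_id", "pair_id", "dilution"],
        value_vars=amplicons,
        var_name="amplicon",
        value_name="cq",
    )
    long["cq"] = pd.to_numeric(long["cq"], errors="raise")
    # header order, then file row order within each amplicon
    long["amplicon"] = pd.Categorical(long["amplicon"], categories=amplicons)
    long = long.sort_values("amplicon", kind="stable").reset_index(drop=True)
    long["amplicon"] = long["amplicon"].astype(str)

    dup = long.duplicated(
        subset=["group", "replicate_id", "dilution", "amplicon"]
    )
    if dup.any():
        rows = long.loc[dup, ["group", "replicate_id", "dilution", "amplicon"]]
        raise InputFormatError(
            f"duplicate (group, replicate, dilution, amplicon) entries:\n{rows}"
        )

    ds = Dataset(
        wells=long,
        amplicons=amplicons,
        reference_genes=list(reference_gene_names),
        mode="cq",
        pairs_present=bool(pairs_present),
    )
    for amp in amplicons:
        if not _fit_eligible_replicates(ds, amp):
            raise InputFormatError(
                f"amplicon {amp!r} has no replicate with >=2 distinct "
                "dilutions with observed Cq; cannot fit a standard curve"
            )
    return ds


def _fit_eligible_replicates(ds: Dataset, amplicon: str) -> list[tuple[str, str]]:
    sub = ds.wells[(ds.wells["amplicon"] == amplicon) & ds.wells["cq"].notna()]
    n = sub.groupby(["group", "replicate_id"], sort=False)["dilution"].nunique()
    return [k for k, v in n.items() if v >= 2]


def read_precalc_table(path: str | Path) -> Dataset:
    """Parse a precalculated relative-expression CSV (linear scale)."""
    df, _ = _read_raw(path)
    if list(df.columns[:2]) != PRECALC_MANDATORY:
        raise InputFormatError(
            f"first two columns must be {PRECALC_MANDATORY}, got "
            f"{list(df.columns[:2])}"
        )
    genes = list(df.columns[2:])
    if not genes:
        raise InputFormatError("no gene columns after 'Pairs'")
    groups, reps = _split_names(df["Replicates"])
    pairs = df["Pairs"].astype("string")
    base = pd.DataFrame(
        {
            "group": groups,
            "replicate_id": reps,
            "pair_id": pairs.where(pairs.notna(), None),
        }
    )
    long = base.join(df[genes]).melt(
        id_vars=["group", "replicate_id", "pair_id"],
        value_vars=genes,
        var_name="amplicon",
        value_name="expression",
    )
    long["expression"] = pd.to_numeric(long["expression"], errors="raise")
    bad = long["expression"] <= 0
    if bad.any():
        rows = long.loc[bad, ["group", "replicate_id", "amplicon", "expression"]]
        raise InputFormatError(
            "relative expression values must be positive (log transform "
            f"would fail):\n{rows}"
        )
    long["amplicon"] = pd.Categorical(long["amplicon"], categories=genes)
    long = long.sort_values("amplicon", kind="stable").reset_index(drop=True)
    long["amplicon"] = long["amplicon"].astype(str)
    return Dataset(
        wells=long,
        amplicons=genes,
        reference_genes=[],
        mode="precalculated",
        pairs_present=bool(pairs.notna().any()),
    )


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as point-decimal, comma-field CSV.

    Floats are written with 12 significant digits so a write/read round
    trip reproduces values to that precision.
    """
    rows.to_csv(path, index=False, float_format="%.12g")


def _fmt(value, dialect: Dialect) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    if isinstance(value, float):
        s = f"{value:.12g}"
    else:
        s = str(value)
    if dialect.decimal_sep == ",":
        s = s.replace(".", ",")
    return s


def write_cq_csv(ds: Dataset, path: str | Path, dialect: Dialect = POINT_DIALECT) -> None:
    """Serialize a cq-mode :class:`Dataset` back to the input CSV layout.

    Supports both dialects so that synthetic datasets can exercise the
    parser's dialect auto-detection.
    """
    if ds.mode != "cq":
        raise ValueError("write_cq_csv requires a cq-mode dataset")
    wells = ds.wells.copy()
    wells["pair_id"] = wells["pair_id"].map(lambda p: "" if p is None or pd.isna(p) else str(p))
    wide = wells.pivot(
        index=["group", "replicate_id", "pair_id", "dilution"],
        columns="amplicon",
        values="cq",
    ).reset_index()
    # restore file row order: replicate appearance order, dilution ascending
    order = {k: i for i, k in enumerate(ds.replicate_keys())}
    wide["_ord"] = [order[(g, r)] for g, r in zip(wide["group"], wide["replicate_id"])]
    wide = wide.sort_values(["_ord", "dilution"], kind="stable")
    lines = [dialect.field_sep.join(CQ_MANDATORY + ds.amplicons)]
    for _, row in wide.iterrows():
        cells = [
            f"{row['group']}_{row['replicate_id']}",
            "" if row["pair_id"] is None or pd.isna(row["pair_id"]) else str(row["pair_id"]),
            _fmt(float(row["dilution"]), dialect),
        ]
        cells += [_fmt(row[a], dialect) for a in ds.amplicons]
        lines.append(dialect.field_sep.join(cells))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
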