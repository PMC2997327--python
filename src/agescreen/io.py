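"""Readers and writers for the pipeline's tab-separated artifacts.

Every external file the pipeline touches is plain UTF-8 text: expression
matrices (probe sets x samples), comparison-design tables, GMT gene-set
collections, two-column annotation/essentiality lists, three-column
cross-species similarity tables, and survival-curve tables.  Lines starting
with ``#`` are treated as comments and skipped on read; writers may emit
``#``-prefixed provenance headers.

All readers validate their input and raise :class:`FormatError` with
positional diagnostics on malformed files; ``read(write(x)) == x`` holds for
every valid object (identifiers bit-exact, numerics to float round-trip
precision).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "ComparisonDesign",
    "GeneSetCollection",
    "ProbeGeneMap",
    "SurvivalTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "read_two_column",
    "read_similarity",
    "write_similarity",
    "read_survival",
    "write_survival",
    "write_table",
]

GROUPS = ("EG1", "EG2")


class FormatError(ValueError):
    """A file violated the expected dialect or an object invariant."""


def _strip_comments(path: str | Path) -> _io.StringIO:
    """Return file content with '#' comment lines removed."""
    text = Path(path).read_text(encoding="utf-8")
    kept = [ln for ln in text.splitlines() if not ln.startswith("#")]
    return _io.StringIO("\n".join(kept) + "\n")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Normalized linear-scale intensities, probe sets x samples.

    ``values`` is a DataFrame whose index holds unique probe-set identifiers
    and whose columns hold unique sample identifiers.  Intensities are
    post-normalization, linear scale (not logged), finite and non-negative;
    log transforms happen inside the operations that need them.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate probe id {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        bad = ~np.isfinite(arr) | (arr < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"invalid intensity at probe {df.index[i]!r}, "
                f"sample {df.columns[j]!r}: {arr[i, j]!r} (must be finite and >= 0)"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a probes-x-samples TSV (first column probe ids, header samples)."""
    buf = _strip_comments(path)
    try:
        raw = pd.read_csv(buf, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse as TSV matrix: {exc}") from exc
    if raw.shape[1] == 0:
        raise FormatError(f"{path}: matrix has no sample columns")
    df = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns.astype(str))
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            probe = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric cell at probe {probe!r}, sample {col!r}"
            )
        if converted.isna().any():
            probe = raw.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise FormatError(f"{path}: missing value at probe {probe!r}, sample {col!r}")
        df[col] = converted.astype(float)
    try:
        return ExpressionMatrix(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, header: Sequence[str] = ()
) -> None:
    """Write a matrix as TSV; optional '#' provenance header lines first."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="probe_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# Comparison design
# ---------------------------------------------------------------------------

_DESIGN_COLS = ["comparison_id", "group", "treated", "control", "model"]


@dataclass
class ComparisonDesign:
    """Treated/control sample pairings split into the two experimental groups.

    Each row pairs one treated sample with one control sample and assigns the
    comparison to EG1 (oxidative stress) or EG2 (cellular aging).  The design
    houses the per-group comparison counts ``n`` used throughout occurrence
    counting and the cumulative-binomial model.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in _DESIGN_COLS if c not in df.columns]
        if missing:
            raise FormatError(f"design missing columns {missing}")
        if len(df) == 0:
            raise FormatError("no comparisons in design")
        if df["comparison_id"].duplicated().any():
            dup = df.loc[df["comparison_id"].duplicated(), "comparison_id"].iloc[0]
            raise FormatError(f"duplicate comparison_id {dup!r}")
        unknown = set(df["group"]) - set(GROUPS)
        if unknown:
            raise FormatError(
                f"unknown group label(s) {sorted(unknown)}; expected one of {GROUPS}"
            )
        self.table = df.reset_index(drop=True)

    @property
    def comparison_ids(self) -> list[str]:
        return list(self.table["comparison_id"])

    def n_group(self, group: str) -> int:
        """Number of comparisons in a group (the symbol n of the CBD model)."""
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return int((self.table["group"] == group).sum())

    @property
    def n_eg1(self) -> int:
        return self.n_group("EG1")

    @property
    def n_eg2(self) -> int:
        return self.n_group("EG2")

    @property
    def n_total(self) -> int:
        return len(self.table)

    def control_samples(self) -> list[str]:
        """Distinct control/baseline sample ids, in first-appearance order."""
        return list(dict.fromkeys(self.table["control"]))

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Check every referenced sample exists in the matrix."""
        have = set(matrix.sample_ids)
        for col in ("treated", "control"):
            dangling = set(self.table[col]) - have
            if dangling:
                raise FormatError(
                    f"design references missing {col} sample(s): "
                    f"{sorted(dangling)[:5]}"
                )

    def subset(self, group: str) -> "ComparisonDesign":
        return ComparisonDesign(self.table[self.table["group"] == group].copy())


def read_design(path: str | Path) -> ComparisonDesign:
    buf = _strip_comments(path)
    df = pd.read_csv(buf, sep="\t", dtype=str)
    try:
        return ComparisonDesign(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_design(design: ComparisonDesign, path: str | Path, header: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        design.table.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member1 <tab> member2 ..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
        name, desc, *members = parts
        members = [m for m in members if m]
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Two-column / similarity tables
# ---------------------------------------------------------------------------

@dataclass
class ProbeGeneMap:
    """(probe_id, gene_symbol) pairs; many-to-one and one-to-many allowed."""

    pairs: pd.DataFrame  # columns: probe_id, gene_symbol

    def __post_init__(self) -> None:
        df = self.pairs
        for col in ("probe_id", "gene_symbol"):
            if col not in df.columns:
                raise FormatError(f"probe-gene map missing column {col!r}")
        if df.duplicated(subset=["probe_id", "gene_symbol"]).any():
            row = df[df.duplicated(subset=["probe_id", "gene_symbol"])].iloc[0]
            raise FormatError(
                f"duplicate (probe, gene) pair ({row['probe_id']!r}, {row['gene_symbol']!r})"
            )
        self.pairs = df.reset_index(drop=True)

    def gene_of(self) -> dict[str, list[str]]:
        """probe id -> list of gene symbols."""
        out: dict[str, list[str]] = {}
        for probe, gene in zip(self.pairs["probe_id"], self.pairs["gene_symbol"]):
            out.setdefault(probe, []).append(gene)
        return out


def read_two_column(path: str | Path, columns: tuple[str, str] = ("id", "value")) -> pd.DataFrame:
    """Read a headerless or headered two-column TSV.

    If the first line equals the expected column names it is consumed as a
    header; otherwise all lines are data.  Used for probe->gene maps and
    essential-gene lists (second column optional for plain lists).
    """
    rows = []
    lines = [
        ln for ln in Path(path).read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if lines and lines[0].split("\t")[: len(columns)] == list(columns):
        lines = lines[1:]
    for lineno, line in enumerate(lines, 1):
        parts = line.split("\t")
        if len(parts) == 1:
            rows.append((parts[0], ""))
        else:
            rows.append((parts[0], parts[1]))
    return pd.DataFrame(rows, columns=list(columns))


def read_probe_gene_map(path: str | Path) -> ProbeGeneMap:
    df = read_two_column(path, columns=("probe_id", "gene_symbol"))
    return ProbeGeneMap(df)


def write_probe_gene_map(pmap: ProbeGeneMap, path: str | Path) -> None:
    pmap.pairs.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_essential_list(path: str | Path) -> set[str]:
    """Read a one/two-column TSV of essential yeast gene ids into a set."""
    df = read_two_column(path, columns=("gene_id", "note"))
    return set(df["gene_id"])


def read_similarity(path: str | Path) -> pd.DataFrame:
    """Read a three-column similarity table: human_id, yeast_id, score."""
    buf = _strip_comments(path)
    df = pd.read_csv(buf, sep="\t", dtype={0: str, 1: str})
    expected = ["human_id", "yeast_id", "score"]
    if list(df.columns[:3]) != expected:
        raise FormatError(f"{path}: similarity table needs columns {expected}")
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    if df["score"].isna().any():
        row = df[df["score"].isna()].index[0]
        raise FormatError(f"{path}: non-numeric score in data row {row + 1}")
    if df.duplicated(subset=["human_id", "yeast_id"]).any():
        raise FormatError(f"{path}: duplicate (human, yeast) pair")
    return df


def write_similarity(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Survival tables
# ---------------------------------------------------------------------------

@dataclass
class SurvivalTable:
    """Viability-vs-day records: (strain_id, replicate_id, day, viability).

    Viability is a fraction in [0, 1]; each (strain, replicate) trajectory
    must contain day 0 and at least two time points.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        needed = ["strain_id", "replicate_id", "day", "viability"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise FormatError(f"survival table missing columns {missing}")
        if (df["day"] < 0).any():
            raise FormatError("negative day in survival table")
        bad = (df["viability"] < 0) | (df["viability"] > 1)
        if bad.any():
            row = df[bad].iloc[0]
            raise FormatError(
                f"viability outside [0, 1] for strain {row['strain_id']!r} "
                f"day {row['day']}: {row['viability']}"
            )
        for (strain, rep), grp in df.groupby(["strain_id", "replicate_id"], sort=False):
            if len(grp) < 2:
                raise FormatError(f"strain {strain!r} replicate {rep!r} has < 2 time points")
            if not (grp["day"] == 0).any():
                raise FormatError(f"strain {strain!r} replicate {rep!r} lacks a day-0 point")
        self.records = df.reset_index(drop=True)

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.records["strain_id"]))

    def curves(self, strain: str) -> dict[str, pd.DataFrame]:
        """replicate id -> day-sorted (day, viability) frame for one strain."""
        sub = self.records[self.records["strain_id"] == strain]
        if sub.empty:
            raise KeyError(f"no survival records for strain {strain!r}")
        return {
            str(rep): grp.sort_values("day")[["day", "viability"]].reset_index(drop=True)
            for rep, grp in sub.groupby("replicate_id", sort=False)
        }


def read_survival(path: str | Path) -> SurvivalTable:
    buf = _strip_comments(path)
    df = pd.read_csv(
        buf, sep="\t",
        dtype={"strain_id": str, "replicate_id": str},
    )
    df["day"] = pd.to_numeric(df["day"])
    df["viability"] = pd.to_numeric(df["viability"])
    try:
        return SurvivalTable(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_survival(table: SurvivalTable, path: str | Path, header: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        table.records.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Generic result tables
# ---------------------------------------------------------------------------

def write_table(
    df: pd.DataFrame, path: str | Path, header: Sequence[str] = (), index: bool = False,
    index_label: str | None = None,
) -> None:
    """Write any result DataFrame as TSV with optional '#' header lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label, lineterminator="\n")
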