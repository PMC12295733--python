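"""Readers and writers for the external formats the pipeline touches.

Every coordinate inside the package is 0-based half-open (BED convention).
Readers that ingest other conventions convert at the boundary. Rejected
lines are always reported with their line number; nothing is dropped
silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenomeLayout",
    "IntervalRecord",
    "EccCandidate",
    "ClinicalRecord",
    "CANDIDATE_COLUMNS",
    "read_genome_layout",
    "read_interval_track",
    "read_candidate_table",
    "read_candidate_frame",
    "write_candidate_table",
    "read_repeat_table",
    "convert_rmsk_export",
    "read_gene_model",
    "read_clinical_table",
    "write_clinical_table",
    "write_feature_matrix",
    "read_feature_matrix",
    "intervals_to_frame",
    "frame_to_intervals",
]


class FormatError(ValueError):
    """Malformed input file; the message carries the offending line number."""


MISSING = "."

#: Column order of the Circle-Map ``Realign`` output table.
CIRCLEMAP_COLUMNS = (
    "chrom",
    "start",
    "end",
    "discordant_reads",
    "split_reads",
    "score",
    "mean_coverage",
    "sd_coverage",
    "start_depth_ratio",   # coverage increase at start breakpoint
    "end_depth_ratio",     # coverage increase at end breakpoint
    "uncovered_fraction",  # 1 - coverage continuity
)

#: Canonical in-package candidate-table columns.
CANDIDATE_COLUMNS = CIRCLEMAP_COLUMNS

VALID_STRANDS = {"+", "-", "."}
VALID_TISSUE_LABELS = {"tumor", "normal"}


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with their lengths in bp."""

    names: tuple[str, ...]
    lengths: Mapping[str, int]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise FormatError("duplicate chromosome names in layout")
        for name in self.names:
            if self.lengths[name] <= 0:
                raise FormatError(f"non-positive length for chromosome {name!r}")

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not declared in layout") from None

    @property
    def total_bp(self) -> int:
        return int(sum(self.lengths[n] for n in self.names))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __iter__(self):
        return iter(self.names)


@dataclass(frozen=True)
class IntervalRecord:
    """A genomic interval, 0-based half-open; strand '.' means unknown."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self, layout: GenomeLayout) -> None:
        if self.end > layout.length(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {layout.length(self.chrom)}"
            )


@dataclass(frozen=True)
class EccCandidate:
    """One eccDNA candidate call with read support and coverage statistics.

    ``start_depth_ratio`` / ``end_depth_ratio`` are the relative coverage
    increase just inside each breakpoint; ``uncovered_fraction`` is the
    fraction of zero-depth bases within the circle. Any of the three may be
    missing (``None``).
    """

    interval: IntervalRecord
    discordant_reads: int
    split_reads: int
    score: float
    mean_coverage: float = 0.0
    start_depth_ratio: float | None = None
    end_depth_ratio: float | None = None
    uncovered_fraction: float | None = None

    def __post_init__(self):
        if self.discordant_reads < 0 or self.split_reads < 0:
            raise ValueError("read counts must be non-negative")
        for attr in ("start_depth_ratio", "end_depth_ratio", "uncovered_fraction"):
            v = getattr(self, attr)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{attr}={v} outside [0, 1]")


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    tissue_label: str
    mapped_reads: int
    dfs_time: float | None = None
    dfs_event: int | None = None

    def __post_init__(self):
        if self.tissue_label not in VALID_TISSUE_LABELS:
            raise ValueError(
                f"tissue_label {self.tissue_label!r}; allowed: "
                + ", ".join(sorted(VALID_TISSUE_LABELS))
            )
        if self.mapped_reads <= 0:
            raise ValueError("mapped_reads must be positive")
        if (self.dfs_time is None) != (self.dfs_event is None):
            raise ValueError("dfs_time and dfs_event must be present together")
        if self.dfs_event is not None and self.dfs_event not in (0, 1):
            raise ValueError("dfs_event must be 0 or 1")


# ---------------------------------------------------------------------------
# chrom.sizes


def read_genome_layout(path) -> GenomeLayout:
    """Read a two-column ``chrom.sizes`` file (name, length)."""
    names: list[str] = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"line {lineno}: expected 2 columns")
            name = parts[0]
            try:
                length = int(parts[1])
            except ValueError:
                raise FormatError(
                    f"line {lineno}: non-integer length {parts[1]!r}"
                ) from None
            if length <= 0:
                raise FormatError(f"line {lineno}: non-positive length {length}")
            if name in lengths:
                raise FormatError(f"line {lineno}: duplicate chromosome {name!r}")
            names.append(name)
            lengths[name] = length
    if not names:
        raise FormatError("no chromosomes in layout file")
    return GenomeLayout(tuple(names), lengths)


def write_genome_layout(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name in layout.names:
            fh.write(f"{name}\t{layout.lengths[name]}\n")


# ---------------------------------------------------------------------------
# BED tracks


def _is_header_line(line: str) -> bool:
    return line.startswith(("#", "browser", "track"))


def read_interval_track(path, layout: GenomeLayout | None = None) -> list[IntervalRecord]:
    """Read a BED3/BED6 track; 0-based half-open, input order preserved."""
    records: list[IntervalRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or _is_header_line(line):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer coordinates") from None
            if start < 0 or end <= start:
                raise FormatError(
                    f"line {lineno}: invalid interval {chrom}:{start}-{end}"
                )
            if layout is not None:
                if chrom not in layout:
                    raise FormatError(f"line {lineno}: unknown chromosome {chrom!r}")
                if end > layout.length(chrom):
                    raise FormatError(
                        f"line {lineno}: interval end {end} exceeds length of {chrom}"
                    )
            name = parts[3] if len(parts) > 3 and parts[3] != MISSING else None
            strand = parts[5] if len(parts) > 5 else "."
            # Unicode minus occasionally shows up in hand-edited tracks.
            strand = {"−": "-"}.get(strand, strand)
            if strand not in VALID_STRANDS:
                raise FormatError(f"line {lineno}: invalid strand {strand!r}")
            records.append(IntervalRecord(chrom, start, end, name, strand))
    return records


def write_interval_track(records: Iterable[IntervalRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            name = r.name if r.name is not None else MISSING
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


def intervals_to_frame(records: Sequence[IntervalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "start": np.asarray([r.start for r in records], dtype=np.int64),
            "end": np.asarray([r.end for r in records], dtype=np.int64),
            "name": [r.name for r in records],
            "strand": [r.strand for r in records],
        }
    )


def frame_to_intervals(frame: pd.DataFrame) -> list[IntervalRecord]:
    cols = frame.columns
    return [
        IntervalRecord(
            row.chrom,
            int(row.start),
            int(row.end),
            getattr(row, "name_", None) if "name_" in cols else None,
            getattr(row, "strand", ".") if "strand" in cols else ".",
        )
        for row in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Circle-Map candidate tables


def _parse_optional_unit(value: str, lineno: int, what: str) -> float | None:
    if value == MISSING or value == "":
        return None
    try:
        v = float(value)
    except ValueError:
        raise FormatError(f"line {lineno}: non-numeric {what} {value!r}") from None
    if math.isnan(v):
        return None
    # Coverage-increase ratios from Circle-Map may dip below 0; clip at the
    # boundary so internal values live in [0, 1].
    return float(min(max(v, 0.0), 1.0))


def read_candidate_frame(
    path,
    layout: GenomeLayout | None = None,
    column_map: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Read a Circle-Map ``Realign``-style TSV into the canonical frame.

    ``column_map`` maps canonical column names to 0-based positions,
    overriding the documented 11-column Realign order. Columns beyond
    ``score`` are optional; absent values become NaN.
    """
    positions = {name: i for i, name in enumerate(CIRCLEMAP_COLUMNS)}
    if column_map:
        positions.update(column_map)
    required = ("chrom", "start", "end", "discordant_reads", "split_reads", "score")
    min_cols = max(positions[c] for c in required) + 1

    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or _is_header_line(line):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if lineno == 1:
                # Tolerate a header row naming the columns.
                try:
                    int(parts[positions["start"]])
                except (ValueError, IndexError):
                    continue
            if len(parts) < min_cols:
                raise FormatError(
                    f"line {lineno}: too few columns ({len(parts)} < {min_cols})"
                )
            try:
                chrom = parts[positions["chrom"]]
                start = int(parts[positions["start"]])
                end = int(parts[positions["end"]])
                disc = int(float(parts[positions["discordant_reads"]]))
                split = int(float(parts[positions["split_reads"]]))
                score = float(parts[positions["score"]])
            except ValueError:
                raise FormatError(f"line {lineno}: malformed numeric field") from None
            if layout is not None and chrom not in layout:
                raise FormatError(f"line {lineno}: unknown chromosome {chrom!r}")
            if start < 0 or end <= start:
                raise FormatError(
                    f"line {lineno}: invalid interval {chrom}:{start}-{end}"
                )
            if layout is not None and end > layout.length(chrom):
                raise FormatError(
                    f"line {lineno}: interval end exceeds length of {chrom}"
                )
            if disc < 0 or split < 0:
                raise FormatError(f"line {lineno}: negative read count")

            def _opt(col, kind):
                pos = positions.get(col)
                if pos is None or pos >= len(parts):
                    return None
                if kind == "unit":
                    return _parse_optional_unit(parts[pos], lineno, col)
                v = parts[pos]
                if v in (MISSING, ""):
                    return None
                try:
                    return float(v)
                except ValueError:
                    raise FormatError(
                        f"line {lineno}: non-numeric {col} {v!r}"
                    ) from None

            rows.append(
                (
                    chrom, start, end, disc, split, score,
                    _opt("mean_coverage", "float"),
                    _opt("sd_coverage", "float"),
                    _opt("start_depth_ratio", "unit"),
                    _opt("end_depth_ratio", "unit"),
                    _opt("uncovered_fraction", "unit"),
                )
            )
    frame = pd.DataFrame(rows, columns=list(CANDIDATE_COLUMNS))
    for col in ("start", "end", "discordant_reads", "split_reads"):
        frame[col] = frame[col].astype(np.int64)
    return frame


def read_candidate_table(
    path, layout: GenomeLayout | None = None, column_map=None
) -> list[EccCandidate]:
    """Like :func:`read_candidate_frame` but returning ``EccCandidate`` records."""
    frame = read_candidate_frame(path, layout, column_map)
    return candidates_from_frame(frame)


def candidates_from_frame(frame: pd.DataFrame) -> list[EccCandidate]:
    out = []
    for row in frame.itertuples(index=False):
        def _nn(v):
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        out.append(
            EccCandidate(
                IntervalRecord(row.chrom, int(row.start), int(row.end)),
                discordant_reads=int(row.discordant_reads),
                split_reads=int(row.split_reads),
                score=float(row.score),
                mean_coverage=_nn(row.mean_coverage) or 0.0,
                start_depth_ratio=_nn(row.start_depth_ratio),
                end_depth_ratio=_nn(row.end_depth_ratio),
                uncovered_fraction=_nn(row.uncovered_fraction),
            )
        )
    return out


def candidates_to_frame(candidates: Sequence[EccCandidate]) -> pd.DataFrame:
    rows = [
        (
            c.interval.chrom, c.interval.start, c.interval.end,
            c.discordant_reads, c.split_reads, c.score, c.mean_coverage, None,
            c.start_depth_ratio, c.end_depth_ratio, c.uncovered_fraction,
        )
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=list(CANDIDATE_COLUMNS))


def write_candidate_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=MISSING, float_format="%.6g")


# ---------------------------------------------------------------------------
# Repeat tables (rmsk-style)

REPEAT_COLUMNS = ("chrom", "start", "end", "repName", "repClass", "repFamily")


def read_repeat_table(path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Read a BED-like repeat table with repName/repClass/repFamily columns."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = set(REPEAT_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"repeat table missing columns: {sorted(missing)}")
    if layout is not None:
        bad = ~frame["chrom"].isin(list(layout.names))
        if bad.any():
            raise FormatError(
                f"repeat table references unknown chromosomes: "
                f"{sorted(frame.loc[bad, 'chrom'].unique())}"
            )
    if (frame["end"] <= frame["start"]).any():
        raise FormatError("repeat table contains empty or inverted intervals")
    return frame.loc[:, list(REPEAT_COLUMNS)].reset_index(drop=True)


def convert_rmsk_export(path_in, path_out) -> int:
    """Convert a raw UCSC ``rmsk.txt`` export to the package repeat table.

    Uses the standard rmsk column order (genoName at index 5, genoStart 6,
    genoEnd 7, repName 10, repClass 11, repFamily 12). Returns the number of
    rows written.
    """
    rows = []
    with open(path_in) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 13:
                raise FormatError(f"line {lineno}: rmsk export needs >= 13 columns")
            rows.append(
                (parts[5], int(parts[6]), int(parts[7]), parts[10], parts[11], parts[12])
            )
    frame = pd.DataFrame(rows, columns=list(REPEAT_COLUMNS))
    frame.to_csv(path_out, sep="\t", index=False)
    return len(frame)


# ---------------------------------------------------------------------------
# Gene models (flattened sub-feature BED)

GENE_MODEL_COLUMNS = ("chrom", "start", "end", "name", "strand", "feature")
GENE_MODEL_FEATURES = {"gene", "exon", "intron", "utr5", "utr3"}


def read_gene_model(path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = set(GENE_MODEL_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"gene model missing columns: {sorted(missing)}")
    bad_feat = ~frame["feature"].isin(GENE_MODEL_FEATURES)
    if bad_feat.any():
        raise FormatError(
            f"gene model has unknown feature types: "
            f"{sorted(frame.loc[bad_feat, 'feature'].unique())}"
        )
    if layout is not None:
        unknown = ~frame["chrom"].isin(list(layout.names))
        if unknown.any():
            raise FormatError(
                "gene on undeclared chromosome: "
                + ", ".join(sorted(frame.loc[unknown, "chrom"].unique()))
            )
    return frame.loc[:, list(GENE_MODEL_COLUMNS)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Clinical tables

CLINICAL_COLUMNS = ("sample_id", "tissue_label", "dfs_time", "dfs_event", "mapped_reads")


def read_clinical_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=[MISSING], dtype={"sample_id": str})
    missing = set(CLINICAL_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"clinical table missing columns: {sorted(missing)}")
    bad = ~frame["tissue_label"].isin(sorted(VALID_TISSUE_LABELS))
    if bad.any():
        raise FormatError(
            f"unknown tissue_label {sorted(frame.loc[bad, 'tissue_label'].unique())}; "
            f"allowed: {sorted(VALID_TISSUE_LABELS)}"
        )
    t_na, e_na = frame["dfs_time"].isna(), frame["dfs_event"].isna()
    if (t_na != e_na).any():
        offender = frame.loc[t_na != e_na, "sample_id"].iloc[0]
        raise FormatError(
            f"sample {offender}: dfs_time and dfs_event must be present together"
        )
    if (frame["mapped_reads"] <= 0).any():
        raise FormatError("mapped_reads must be positive")
    if frame["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in clinical table")
    return frame.loc[:, list(CLINICAL_COLUMNS)]


def clinical_records(frame: pd.DataFrame) -> list[ClinicalRecord]:
    out = []
    for row in frame.itertuples(index=False):
        has_dfs = not (pd.isna(row.dfs_time) or pd.isna(row.dfs_event))
        out.append(
            ClinicalRecord(
                sample_id=row.sample_id,
                tissue_label=row.tissue_label,
                mapped_reads=int(row.mapped_reads),
                dfs_time=float(row.dfs_time) if has_dfs else None,
                dfs_event=int(row.dfs_event) if has_dfs else None,
            )
        )
    return out


def write_clinical_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=MISSING, float_format="%.6g")


# ---------------------------------------------------------------------------
# Feature matrices


def write_feature_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a samples x features TSV; index is sample_id."""
    matrix.to_csv(
        path, sep="\t", index=True, index_label="sample_id",
        na_rep=MISSING, float_format="%.10g",
    )


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", na_values=[MISSING])
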