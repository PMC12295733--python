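"""Annotation catalog, derived tracks, and the interval-overlap engine.

The engine reproduces the intersection semantics of standard BED tooling
(``>= 1`` bp overlap on half-open intervals). Per category, intervals are
merged into sorted non-overlapping arrays; a query ``[s, e)`` overlaps the
set iff the last merged interval whose start is ``< e`` ends after ``s``,
which a single ``searchsorted`` resolves — O(log m) per query and fully
vectorizable over query batches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomeLayout, IntervalRecord

__all__ = [
    "CATEGORIES",
    "REPEAT_CLASS_MAP",
    "IntervalSet",
    "derive_tracks",
    "build_catalog",
    "annotate",
    "window_density",
    "per_chromosome_proportions",
]

#: The 24 annotation categories, in roster order.
CATEGORIES = (
    "gene", "exon", "intron", "utr5", "utr3",
    "gene_upstream_2kb", "gene_downstream_2kb", "intergenic",
    "enhancer", "dhs", "cpg_island", "cpg_upstream_2kb", "cpg_downstream_2kb",
    "repeat_all", "sine", "line", "ltr", "dna_repeat",
    "simple_repeat", "low_complexity", "satellite",
    "alu", "mir", "transposon",
)

#: rmsk repClass -> category name, for the seven repeat classes.
REPEAT_CLASS_MAP = {
    "SINE": "sine",
    "LINE": "line",
    "LTR": "ltr",
    "DNA": "dna_repeat",
    "Simple_repeat": "simple_repeat",
    "Low_complexity": "low_complexity",
    "Satellite": "satellite",
}

#: Interspersed transposon-derived classes forming the "transposon" category.
TRANSPOSON_CLASSES = ("sine", "line", "ltr", "dna_repeat")


class IntervalSet:
    """An immutable set of genomic intervals with fast overlap queries."""

    __slots__ = ("_starts", "_ends")

    def __init__(self, per_chrom: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        self._starts = {c: s for c, (s, _) in per_chrom.items()}
        self._ends = {c: e for c, (_, e) in per_chrom.items()}

    @classmethod
    def from_tuples(cls, intervals: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts, ends = [], []
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:  # overlap or abutment: union coverage identical
                    cur_e = max(cur_e, e)
                else:
                    starts.append(cur_s)
                    ends.append(cur_e)
                    cur_s, cur_e = s, e
            starts.append(cur_s)
            ends.append(cur_e)
            merged[chrom] = (
                np.asarray(starts, dtype=np.int64),
                np.asarray(ends, dtype=np.int64),
            )
        return cls(merged)

    @classmethod
    def from_records(cls, records: Iterable[IntervalRecord]) -> "IntervalSet":
        return cls.from_tuples((r.chrom, r.start, r.end) for r in records)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IntervalSet":
        return cls.from_tuples(
            zip(frame["chrom"], frame["start"].astype(int), frame["end"].astype(int))
        )

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls({})

    @classmethod
    def union(cls, sets: Sequence["IntervalSet"]) -> "IntervalSet":
        tuples: list[tuple[str, int, int]] = []
        for s in sets:
            tuples.extend(s.to_tuples())
        return cls.from_tuples(tuples) if tuples else cls.empty()

    def to_tuples(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self._starts):
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                out.append((chrom, int(s), int(e)))
        return out

    def to_frame(self) -> pd.DataFrame:
        tuples = self.to_tuples()
        return pd.DataFrame(tuples, columns=["chrom", "start", "end"])

    @property
    def n_intervals(self) -> int:
        return int(sum(len(s) for s in self._starts.values()))

    @property
    def total_bp(self) -> int:
        return int(
            sum((e - s).sum() for s, e in zip(self._starts.values(), self._ends.values()))
        )

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        idx = int(np.searchsorted(starts, end, side="left")) - 1
        return idx >= 0 and int(self._ends[chrom][idx]) > start

    def overlaps_many(
        self, chroms: Sequence[str], starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorized >=1 bp overlap test for a batch of query intervals."""
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        out = np.zeros(len(chroms), dtype=bool)
        for chrom in pd.unique(chroms):
            tree_starts = self._starts.get(chrom)
            if tree_starts is None:
                continue
            sel = np.flatnonzero(chroms == chrom)
            idx = np.searchsorted(tree_starts, ends[sel], side="left") - 1
            valid = idx >= 0
            hit = np.zeros(len(sel), dtype=bool)
            hit[valid] = self._ends[chrom][idx[valid]] > starts[sel[valid]]
            out[sel] = hit
        return out

    def complement(self, layout: GenomeLayout) -> "IntervalSet":
        """Gaps of this set within the layout (per declared chromosome)."""
        tuples: list[tuple[str, int, int]] = []
        for chrom in layout.names:
            L = layout.length(chrom)
            starts = self._starts.get(chrom)
            if starts is None:
                tuples.append((chrom, 0, L))
                continue
            ends = self._ends[chrom]
            pos = 0
            for s, e in zip(starts, ends):
                s, e = int(s), min(int(e), L)
                if s > pos:
                    tuples.append((chrom, pos, s))
                pos = max(pos, e)
            if pos < L:
                tuples.append((chrom, pos, L))
        return IntervalSet.from_tuples(tuples) if tuples else IntervalSet.empty()


# ---------------------------------------------------------------------------
# Derived tracks


def derive_tracks(
    gene_model: pd.DataFrame,
    cpg_track: pd.DataFrame,
    layout: GenomeLayout,
    flank_bp: int = 2000,
    stranded: bool = True,
) -> dict[str, list[tuple[str, int, int]]]:
    """Compute upstream/downstream gene windows, the intergenic complement,
    and the CpG-island flanks ("shores").

    Upstream precedes the transcription start in the gene's orientation when
    ``stranded`` (the default); windows are clipped at chromosome bounds.
    Intergenic is the complement of the merged (strand-ignored) gene spans.
    """
    genes = gene_model.loc[gene_model["feature"] == "gene"]
    unknown = set(genes["chrom"]) - set(layout.names)
    if unknown:
        raise ValueError(f"gene on undeclared chromosome: {sorted(unknown)}")

    upstream: list[tuple[str, int, int]] = []
    downstream: list[tuple[str, int, int]] = []
    for row in genes.itertuples(index=False):
        L = layout.length(row.chrom)
        left = (max(0, row.start - flank_bp), row.start)
        right = (row.end, min(L, row.end + flank_bp))
        if stranded and row.strand == "-":
            up, down = right, left
        else:
            up, down = left, right
        if up[1] > up[0]:
            upstream.append((row.chrom, up[0], up[1]))
        if down[1] > down[0]:
            downstream.append((row.chrom, down[0], down[1]))

    gene_set = IntervalSet.from_frame(genes) if len(genes) else IntervalSet.empty()
    intergenic = gene_set.complement(layout).to_tuples()

    cpg_up: list[tuple[str, int, int]] = []
    cpg_down: list[tuple[str, int, int]] = []
    for row in cpg_track.itertuples(index=False):
        L = layout.length(row.chrom)
        if row.start > 0:
            cpg_up.append((row.chrom, max(0, row.start - flank_bp), row.start))
        if row.end < L:
            cpg_down.append((row.chrom, row.end, min(L, row.end + flank_bp)))

    return {
        "gene_upstream_2kb": upstream,
        "gene_downstream_2kb": downstream,
        "intergenic": intergenic,
        "cpg_upstream_2kb": cpg_up,
        "cpg_downstream_2kb": cpg_down,
    }


def build_catalog(
    gene_model: pd.DataFrame,
    enhancer: pd.DataFrame,
    dhs: pd.DataFrame,
    cpg: pd.DataFrame,
    repeats: pd.DataFrame,
    layout: GenomeLayout,
    flank_bp: int = 2000,
    stranded: bool = True,
    dhs_flanks: bool = False,
) -> dict[str, IntervalSet]:
    """Assemble the 24-category annotation catalog.

    ``dhs_flanks`` additionally widens DHS intervals by ``flank_bp`` on each
    side (off by default; DHS regions are used as-is).
    """
    def _sub(feature: str) -> IntervalSet:
        sel = gene_model.loc[gene_model["feature"] == feature]
        return IntervalSet.from_frame(sel) if len(sel) else IntervalSet.empty()

    derived = derive_tracks(gene_model, cpg, layout, flank_bp, stranded)

    if dhs_flanks:
        widened = dhs.copy()
        widened["start"] = (widened["start"] - flank_bp).clip(lower=0)
        widened["end"] = [
            min(e + flank_bp, layout.length(c))
            for c, e in zip(widened["chrom"], widened["end"])
        ]
        dhs_set = IntervalSet.from_frame(widened)
    else:
        dhs_set = IntervalSet.from_frame(dhs) if len(dhs) else IntervalSet.empty()

    catalog: dict[str, IntervalSet] = {
        "gene": _sub("gene"),
        "exon": _sub("exon"),
        "intron": _sub("intron"),
        "utr5": _sub("utr5"),
        "utr3": _sub("utr3"),
        "enhancer": IntervalSet.from_frame(enhancer) if len(enhancer) else IntervalSet.empty(),
        "dhs": dhs_set,
        "cpg_island": IntervalSet.from_frame(cpg) if len(cpg) else IntervalSet.empty(),
    }
    for name, tuples in derived.items():
        catalog[name] = IntervalSet.from_tuples(tuples) if tuples else IntervalSet.empty()

    for rep_class, cat in REPEAT_CLASS_MAP.items():
        sel = repeats.loc[repeats["repClass"] == rep_class]
        catalog[cat] = IntervalSet.from_frame(sel) if len(sel) else IntervalSet.empty()
    catalog["repeat_all"] = (
        IntervalSet.from_frame(repeats) if len(repeats) else IntervalSet.empty()
    )
    sine_mask = repeats["repClass"] == "SINE"
    for fam, cat in (("Alu", "alu"), ("MIR", "mir")):
        sel = repeats.loc[sine_mask & (repeats["repFamily"] == fam)]
        catalog[cat] = IntervalSet.from_frame(sel) if len(sel) else IntervalSet.empty()
    catalog["transposon"] = IntervalSet.union([catalog[c] for c in TRANSPOSON_CLASSES])

    return {name: catalog[name] for name in CATEGORIES}


# ---------------------------------------------------------------------------
# Overlap classification and descriptive statistics


def annotate(ecc: pd.DataFrame, catalog: Mapping[str, IntervalSet]) -> pd.DataFrame:
    """Boolean overlap matrix: one row per eccDNA, one column per category.

    A cell is True iff the eccDNA interval shares >= 1 bp with any interval
    of the category; categories are not mutually exclusive.
    """
    chroms = ecc["chrom"].to_numpy(dtype=object)
    starts = ecc["start"].to_numpy(dtype=np.int64)
    ends = ecc["end"].to_numpy(dtype=np.int64)
    data = {
        name: iv_set.overlaps_many(chroms, starts, ends)
        for name, iv_set in catalog.items()
    }
    return pd.DataFrame(data, index=ecc.index)


def window_density(
    ecc: pd.DataFrame, layout: GenomeLayout, window_bp: int = 1_000_000
) -> pd.DataFrame:
    """Count eccDNA per fixed genomic window; a circle is assigned to the
    window containing its start coordinate."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    for chrom in layout.names:
        L = layout.length(chrom)
        n_windows = (L + window_bp - 1) // window_bp
        sel = ecc.loc[ecc["chrom"] == chrom, "start"]
        counts = np.bincount(sel.to_numpy() // window_bp, minlength=n_windows)
        for w in range(n_windows):
            rows.append((chrom, w * window_bp, min((w + 1) * window_bp, L), int(counts[w])))
    return pd.DataFrame(rows, columns=["chrom", "window_start", "window_end", "count"])


def per_chromosome_proportions(
    ecc: pd.DataFrame, layout: GenomeLayout | None = None
) -> pd.Series:
    """Fraction of eccDNA per chromosome; sums to 1."""
    if ecc.empty:
        raise ValueError("no eccDNA to summarize")
    counts = ecc["chrom"].value_counts()
    if layout is not None:
        counts = counts.reindex(list(layout.names), fill_value=0)
    return counts / counts.sum()
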