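"""Genomic interval sets (coding sequence, low-complexity regions) and
variant membership flags.

Intervals are stored per chromosome as merged, sorted 1-based inclusive
ranges. A variant belongs to a set when its reference footprint
``[pos, pos + len(ref) - 1]`` shares at least one base with an interval;
for SNPs and pure insertions this degenerates to single-base membership of
the anchor position.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge 1-based inclusive intervals; adjacent ([1,5],[6,9]) coalesce."""
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    ms, me = [], []
    for s, e in zip(starts, ends):
        if me and s <= me[-1] + 1:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.asarray(ms, dtype=np.int64), np.asarray(me, dtype=np.int64)


class IntervalSet:
    """A named union of genomic intervals, 1-based inclusive, merged per
    chromosome."""

    def __init__(self, name: str, intervals: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.name = name
        self.intervals: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (s, e) in intervals.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            if (e < s).any():
                raise ValueError(f"{name}/{chrom}: interval end before start")
            self.intervals[str(chrom)] = _merge(s, e)
        self._warned: set[str] = set()

    @property
    def total_bp(self) -> int:
        """Nonredundant bases covered (length of the union)."""
        return int(
            sum((e - s + 1).sum() for s, e in self.intervals.values())
        )

    @classmethod
    def from_records(cls, name: str, records) -> "IntervalSet":
        """Build from an iterable of (chrom, start, end), 1-based inclusive."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in records:
            by_chrom.setdefault(str(chrom), []).append((int(s), int(e)))
        return cls(
            name,
            {
                c: (np.array([x[0] for x in v]), np.array([x[1] for x in v]))
                for c, v in by_chrom.items()
            },
        )

    @classmethod
    def from_bed(cls, name: str, path: str | Path) -> "IntervalSet":
        """Load a BED file (>= 3 columns, 0-based half-open), converting to
        1-based inclusive. Input need not be sorted."""
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
                try:
                    start0, end0 = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
                if end0 <= start0:
                    raise ValueError(f"{path}:{lineno}: empty/negative BED interval")
                records.append((fields[0], start0 + 1, end0))
        return cls.from_records(name, records)

    @classmethod
    def from_gff3(cls, name: str, path: str | Path, feature: str = "CDS") -> "IntervalSet":
        """Load a GFF3 file keeping only ``feature`` rows (default CDS);
        GFF3 coordinates are already 1-based inclusive."""
        gff = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["seqid", "source", "type", "start", "end",
                   "score", "strand", "phase", "attributes"],
            dtype={"seqid": str},
        )
        gff = gff[gff["type"] == feature]
        return cls.from_records(
            name, gff[["seqid", "start", "end"]].itertuples(index=False, name=None)
        )

    def overlaps(self, chrom: str, qstart: np.ndarray, qend: np.ndarray) -> np.ndarray:
        """Vectorised overlap query for footprints on one chromosome.

        After merging, intervals are disjoint and sorted, so the only
        candidate for a query is the rightmost interval starting at or
        before the query end.
        """
        qstart = np.asarray(qstart, dtype=np.int64)
        qend = np.asarray(qend, dtype=np.int64)
        if chrom not in self.intervals:
            if chrom not in self._warned:
                log.info("%s: chromosome %s absent from interval set", self.name, chrom)
                self._warned.add(chrom)
            return np.zeros(qstart.shape, dtype=bool)
        starts, ends = self.intervals[chrom]
        idx = np.searchsorted(starts, qend, side="right") - 1
        hit = idx >= 0
        hit[hit] = ends[idx[hit]] >= qstart[hit]
        return hit


def annotate_membership(df: pd.DataFrame, iset: IntervalSet) -> np.ndarray:
    """Boolean membership flags for a classified variant table.

    Membership = the reference footprint [POS, POS + len(REF) - 1]
    intersects the set in at least one base.
    """
    pos = df["POS"].to_numpy(dtype=np.int64)
    end = pos + df["REF"].astype(str).str.len().to_numpy(dtype=np.int64) - 1
    flags = np.zeros(len(df), dtype=bool)
    for chrom, sub in pd.Series(np.arange(len(df))).groupby(df["CHROM"].astype(str).values):
        i = sub.to_numpy()
        flags[i] = iset.overlaps(chrom, pos[i], end[i])
    return flags


def annotation_summary(df: pd.DataFrame, flags: np.ndarray, label: str = "member") -> pd.DataFrame:
    """Cross-tabulate variant class (SNP vs indel) against a membership flag.

    Returns a table with counts and the percentage of each class inside the
    annotation (the report-style "x% of indels" figure); percentages are NA
    when a class has zero members.
    """
    is_indel = (
        df["is_indel"].astype(bool).to_numpy() if "is_indel" in df
        else np.zeros(len(df), bool)
    )
    rows = []
    for cls_name, mask in (("SNP", ~is_indel), ("indel", is_indel)):
        inside = int((mask & flags).sum())
        total = int(mask.sum())
        rows.append(
            {
                "class": cls_name,
                f"in_{label}": inside,
                f"out_{label}": total - inside,
                "total": total,
                "pct_in": 100.0 * inside / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)
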