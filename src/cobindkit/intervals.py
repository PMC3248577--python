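"""Peak interval algebra: I/O, replicate consensus, co-binding and
cell-line specificity classification.

A *peak* is a called binding event: a genomic interval with an optional
summit (position of maximum signal) and score. Coordinates are 0-based
half-open throughout (BED convention); MACS-style tabular files, which are
1-based with a summit offset relative to the peak start, are converted on
read. Two peaks *overlap* when they share at least one base pair. A
*consensus* (replicate-consistent) peak is one present in both biological
replicates under that definition; a *cell-line-specific* peak is present in
both replicates of one line and in no replicate of any other line.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from ._overlap import SubjectIndex

COBIND_CATEGORIES = ("CTCF_only", "CTCF_ER", "CTCF_FOXA1", "CTCF_ER_FOXA1")


class PeakParseError(ValueError):
    """Raised for malformed or invalid peak file content."""


@dataclass(frozen=True)
class Peak:
    """A called binding event on one chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    summit: int | None = None
    score: float | None = None
    name: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise PeakParseError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise PeakParseError(
                f"summit {self.summit} outside {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def anchor(self) -> int:
        """Summit if present, else the interval midpoint."""
        return self.summit if self.summit is not None else self.midpoint

    def overlaps(self, other: "Peak") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """A labelled collection of peaks kept sorted by (chrom, start)."""

    def __init__(self, peaks: Iterable[Peak] = (), label: str = ""):
        self.label = label
        self.peaks: list[Peak] = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
        self._index: SubjectIndex | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakSet) and self.peaks == other.peaks

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """(starts, ends) int64 arrays per chromosome, in sorted order."""
        out: dict[str, list[list[int]]] = defaultdict(lambda: [[], []])
        for p in self.peaks:
            out[p.chrom][0].append(p.start)
            out[p.chrom][1].append(p.end)
        return {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in out.items()
        }

    def index(self) -> SubjectIndex:
        if self._index is None:
            self._index = SubjectIndex(self.by_chrom())
        return self._index

    def overlap_mask(self, subject: "PeakSet") -> np.ndarray:
        """Per-peak boolean: overlaps >=1 peak of ``subject`` by >=1 bp."""
        idx = subject.index()
        mask = np.zeros(len(self.peaks), dtype=bool)
        by_chrom: dict[str, list[int]] = defaultdict(list)
        for i, p in enumerate(self.peaks):
            by_chrom[p.chrom].append(i)
        for chrom, rows in by_chrom.items():
            rows = np.asarray(rows)
            starts = np.asarray([self.peaks[i].start for i in rows])
            ends = np.asarray([self.peaks[i].end for i in rows])
            mask[rows] = idx.any_overlap(chrom, starts, ends)
        return mask

    def subset(self, mask) -> "PeakSet":
        return PeakSet(
            (p for p, keep in zip(self.peaks, mask) if keep), label=self.label
        )


@dataclass
class CobindClass:
    """One co-binding category of the anchor (CTCF) consensus set."""

    category: str
    members: Sequence[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def overlaps(a: Peak, b: Peak) -> bool:
    """True iff the two peaks share at least one base pair."""
    return a.overlaps(b)


def read_peaks(path, format: str = "bed", label: str | None = None) -> PeakSet:
    """Read a peak file into a sorted :class:`PeakSet`.

    ``format="bed"`` expects >=3 columns, 0-based half-open. ``format=
    "macs_tab"`` expects a MACS tabular peak file with a header naming at
    least chr/start/end/summit columns; its 1-based starts are converted to
    0-based and the summit column (offset relative to the region start) is
    converted to an absolute position.
    """
    path = Path(path)
    if label is None:
        label = path.stem
    peaks: list[Peak] = []
    if format == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise PeakParseError(f"{path}:{lineno}: expected >=3 BED columns")
                try:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise PeakParseError(f"{path}:{lineno}: {exc}") from None
                name = fields[3] if len(fields) > 3 and fields[3] != "." else None
                score = None
                if len(fields) > 4 and fields[4] not in (".", ""):
                    score = float(fields[4])
                if start >= end:
                    raise PeakParseError(
                        f"{path}:{lineno}: start {start} >= end {end}"
                    )
                peaks.append(Peak(chrom, start, end, score=score, name=name))
    elif format == "macs_tab":
        with open(path) as fh:
            header = None
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if header is None:
                    header = {h.strip().lower(): i for i, h in enumerate(fields)}
                    for col in ("chr", "start", "end", "summit"):
                        if col not in header:
                            raise PeakParseError(
                                f"{path}:{lineno}: missing column {col!r} in header"
                            )
                    continue
                try:
                    chrom = fields[header["chr"]]
                    start1 = int(fields[header["start"]])
                    end = int(fields[header["end"]])
                    summit_off = int(fields[header["summit"]])
                except (ValueError, IndexError) as exc:
                    raise PeakParseError(f"{path}:{lineno}: {exc}") from None
                start = start1 - 1  # 1-based inclusive -> 0-based half-open
                if start >= end:
                    raise PeakParseError(
                        f"{path}:{lineno}: start {start1} >= end {end}"
                    )
                score = None
                for col in ("-10*log10(pvalue)", "fold_enrichment"):
                    if col in header and len(fields) > header[col]:
                        score = float(fields[header[col]])
                        break
                peaks.append(
                    Peak(chrom, start, end, summit=start + summit_off, score=score)
                )
    else:
        raise ValueError(f"unknown peak format {format!r}")
    return PeakSet(peaks, label=label)


def write_bed(peaks: PeakSet, path) -> None:
    """Write BED6; chrom/start/end round-trip losslessly through read_peaks."""
    with open(path, "w") as fh:
        for p in peaks:
            name = p.name if p.name is not None else "."
            score = f"{p.score:g}" if p.score is not None else "0"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{score}\t.\n")


def consensus_replicates(
    rep1: PeakSet, rep2: PeakSet, anchor: str = "rep1"
) -> PeakSet:
    """Replicate-consistent peaks: present (>=1-bp overlap) in both replicates.

    Reported coordinates and summits are those of the anchor replicate
    (default replicate 1); set ``anchor="rep2"`` to anchor on the other.
    """
    if anchor == "rep2":
        rep1, rep2 = rep2, rep1
    elif anchor != "rep1":
        raise ValueError("anchor must be 'rep1' or 'rep2'")
    out = rep1.subset(rep1.overlap_mask(rep2))
    out.label = rep1.label
    return out


def classify_cobinding(
    ctcf: PeakSet, er: PeakSet, foxa1: PeakSet
) -> dict[str, CobindClass]:
    """Partition the anchor (CTCF) peaks into four co-binding categories.

    Each CTCF peak is assigned by presence/absence of >=1-bp overlap with
    the ER set and with the FOXA1 set; categories partition the anchor set.
    """
    er_hit = ctcf.overlap_mask(er)
    fox_hit = ctcf.overlap_mask(foxa1)
    classes = {c: CobindClass(c, []) for c in COBIND_CATEGORIES}
    for p, e, f in zip(ctcf.peaks, er_hit, fox_hit):
        if e and f:
            cat = "CTCF_ER_FOXA1"
        elif e:
            cat = "CTCF_ER"
        elif f:
            cat = "CTCF_FOXA1"
        else:
            cat = "CTCF_only"
        classes[cat].members.append(p)
    return classes


def overlap_fraction(a: PeakSet, b: PeakSet) -> float:
    """Percent of a-peaks overlapping >=1 b-peak (0 for an empty a)."""
    if len(a) == 0:
        return 0.0
    return 100.0 * a.overlap_mask(b).sum() / len(a)


def cell_line_specificity(
    lines: Mapping[str, tuple[PeakSet, PeakSet]],
    reference: str | None = None,
    anchor: str = "rep1",
) -> dict[str, PeakSet]:
    """Classify consensus peaks by the cell lines they appear in.

    For each line L, ``"{L}_specific"`` holds consensus peaks of L that
    overlap no peak of any replicate of any other line. ``"common"`` holds
    consensus peaks of the reference line (default: first in mapping order)
    that overlap both replicates of every other line. For every proper,
    non-singleton subset S of lines containing the reference of S (its first
    member), ``"shared_{A}_{B}"`` holds consensus peaks of the first member
    of S that overlap both replicates of all other members of S and no
    replicate of any line outside S.
    """
    names = list(lines)
    if len(names) < 2:
        raise ValueError("need at least 2 cell lines")
    for name, reps in lines.items():
        if len(reps) != 2:
            raise ValueError(f"cell line {name!r} must have exactly 2 replicates")
    if reference is None:
        reference = names[0]
    consensus = {
        name: consensus_replicates(r1, r2, anchor=anchor)
        for name, (r1, r2) in lines.items()
    }

    def in_both(peakset: PeakSet, line: str) -> np.ndarray:
        r1, r2 = lines[line]
        return peakset.overlap_mask(r1) & peakset.overlap_mask(r2)

    def in_neither(peakset: PeakSet, line: str) -> np.ndarray:
        r1, r2 = lines[line]
        return ~(peakset.overlap_mask(r1) | peakset.overlap_mask(r2))

    out: dict[str, PeakSet] = {}
    for name in names:
        cons = consensus[name]
        mask = np.ones(len(cons), dtype=bool)
        for other in names:
            if other != name:
                mask &= in_neither(cons, other)
        out[f"{name}_specific"] = cons.subset(mask)

    ref_cons = consensus[reference]
    mask = np.ones(len(ref_cons), dtype=bool)
    for other in names:
        if other != reference:
            mask &= in_both(ref_cons, other)
    out["common"] = ref_cons.subset(mask)

    if len(names) >= 3:
        # proper non-singleton subsets, anchored on their first member
        from itertools import combinations

        for size in range(2, len(names)):
            for subset in combinations(names, size):
                anchor_line = subset[0]
                cons = consensus[anchor_line]
                mask = np.ones(len(cons), dtype=bool)
                for other in subset[1:]:
                    mask &= in_both(cons, other)
                for other in names:
                    if other not in subset:
                        mask &= in_neither(cons, other)
                out["shared_" + "_".join(subset)] = cons.subset(mask)
    return out
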