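"""Binned, input-subtracted, library-normalized read signal around peaks.

Each region contributes one row: a window of ``2 * half_width`` bp centred
on the region midpoint (default 5 kb either side), divided into fixed-width
bins (default 100 bp, hence 100 bins). A bin's value is the number of
treatment read 5' starts in the bin minus the number of input (control)
reads in the same bin, each first scaled to a 10-million-read library:

    value = (1e7 / N_t) * t_count  -  (1e7 / N_c) * c_count

Values may be negative; they are kept as-is in data and only clamped when a
heat map is rendered. Reads are counted by their 5' start with no fragment
extension; an optional fixed extension is available but off by default.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .intervals import PeakSet

NORMALIZATION_READS = 10_000_000


@dataclass
class ReadTrack:
    """Sorted per-chromosome read 5'-start positions plus library size."""

    positions: dict[str, np.ndarray]
    total_reads: int
    label: str = ""

    def __post_init__(self):
        for chrom, pos in self.positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.positions[chrom] = np.sort(pos, kind="stable")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")


def load_reads(path, total_override: int | None = None, label: str | None = None) -> ReadTrack:
    """Load read 5' starts from a BED file (start field; strand ignored)."""
    path = Path(path)
    by_chrom: dict[str, list[int]] = defaultdict(list)
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                by_chrom[fields[0]].append(int(fields[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            n += 1
    return ReadTrack(
        positions={c: np.asarray(v, dtype=np.int64) for c, v in by_chrom.items()},
        total_reads=total_override if total_override is not None else max(n, 1),
        label=label if label is not None else path.stem,
    )


@dataclass
class SignalMatrix:
    values: np.ndarray  # n_regions x n_bins, float
    row_ids: list[str]
    bin_width: int
    half_width: int
    treatment_label: str = ""
    control_label: str = ""
    truncated_rows: list[int] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            cols = "\t".join(f"bin{j}" for j in range(self.n_bins))
            fh.write(f"region\t{cols}\n")
            for rid, row in zip(self.row_ids, self.values):
                fh.write(rid + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")


def _bin_counts(
    track: ReadTrack, chrom: str, window_start: int, n_bins: int, bin_width: int
) -> np.ndarray:
    """Raw read counts per bin; bins half-open [edge_k, edge_{k+1})."""
    pos = track.positions.get(chrom)
    if pos is None or len(pos) == 0:
        return np.zeros(n_bins, dtype=np.int64)
    edges = window_start + bin_width * np.arange(n_bins + 1, dtype=np.int64)
    idx = np.searchsorted(pos, edges, side="left")
    return np.diff(idx)


def build_signal_matrix(
    regions: PeakSet,
    treatment: ReadTrack,
    control: ReadTrack | None = None,
    half_width: int = 5000,
    bin_width: int = 100,
    center: str = "midpoint",
    extension: int = 0,
) -> SignalMatrix:
    """Library-normalized, input-subtracted binned signal per region.

    Windows are ``[centre - half_width, centre + half_width)`` around the
    region midpoint (``center="summit"`` uses the summit when present).
    Windows extending below position 0 are counted over the valid range
    only and the affected rows flagged in ``truncated_rows``.
    """
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    if (2 * half_width) % bin_width != 0:
        raise ValueError("2*half_width must be a multiple of bin_width")
    n_bins = 2 * half_width // bin_width
    t_scale = NORMALIZATION_READS / treatment.total_reads
    c_scale = NORMALIZATION_READS / control.total_reads if control is not None else 0.0

    if extension:
        treatment = _extend(treatment, extension)
        if control is not None:
            control = _extend(control, extension)

    values = np.zeros((len(regions), n_bins), dtype=float)
    row_ids: list[str] = []
    truncated: list[int] = []
    for i, p in enumerate(regions):
        centre = p.anchor if center == "summit" else p.midpoint
        wstart = centre - half_width
        if wstart < 0:
            truncated.append(i)
        t = _bin_counts(treatment, p.chrom, wstart, n_bins, bin_width)
        row = t_scale * t
        if control is not None:
            c = _bin_counts(control, p.chrom, wstart, n_bins, bin_width)
            row = row - c_scale * c
        values[i] = row
        row_ids.append(p.name or f"{p.chrom}:{p.start}-{p.end}")
    return SignalMatrix(
        values=values,
        row_ids=row_ids,
        bin_width=bin_width,
        half_width=half_width,
        treatment_label=treatment.label,
        control_label=control.label if control is not None else "",
        truncated_rows=truncated,
    )


def _extend(track: ReadTrack, extension: int) -> ReadTrack:
    # midpoint of a fixed-length fragment starting at the 5' read start
    return ReadTrack(
        positions={c: p + extension // 2 for c, p in track.positions.items()},
        total_reads=track.total_reads,
        label=track.label,
    )


def column_profile(m: SignalMatrix) -> np.ndarray:
    """Per-bin sum over all regions (aggregate binding profile)."""
    return m.values.sum(axis=0)


def total_intensity(m: SignalMatrix, clamp_negative: bool = False) -> float:
    """Sum of all matrix entries; optionally clamp negative bins to 0 first."""
    v = np.clip(m.values, 0, None) if clamp_negative else m.values
    return float(v.sum())


def order_rows(
    m: SignalMatrix,
    groups: Mapping[str, str] | None = None,
    category_order: Sequence[str] | None = None,
) -> np.ndarray:
    """Stable row permutation: category blocks, then descending row sum.

    ``groups`` maps region id to category; unlisted rows go last. Within a
    category rows sort by descending total signal, ties keeping input order.
    """
    sums = m.values.sum(axis=1)
    if groups is None:
        cat_rank = np.zeros(len(m.row_ids), dtype=int)
    else:
        if category_order is None:
            seen: list[str] = []
            for rid in m.row_ids:
                g = groups.get(rid)
                if g is not None and g not in seen:
                    seen.append(g)
            category_order = seen
        rank = {c: k for k, c in enumerate(category_order)}
        cat_rank = np.array(
            [rank.get(groups.get(rid), len(rank)) for rid in m.row_ids]
        )
    return np.lexsort((np.arange(len(sums)), -sums, cat_rank))


def render_heatmap(
    m: SignalMatrix,
    path,
    order: np.ndarray | None = None,
    vmax: float | None = None,
) -> None:
    """Optional PNG heat map; negative bins clamp to 0 for display only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    v = np.clip(m.values, 0, None)
    if order is not None:
        v = v[order]
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(v, aspect="auto", cmap="Reds", vmax=vmax, interpolation="nearest")
    ax.set_xlabel(f"bin ({m.bin_width} bp)")
    ax.set_ylabel("region")
    ax.set_title(m.treatment_label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
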