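"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (all-pairs loops, per-offset
rescans) so they share no code path with the vectorized implementations
they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from cobindkit.intervals import Peak, PeakSet


# ------------------------------------------------------------- generators

def random_peakset(
    rng: np.random.Generator,
    n: int,
    chroms=("chr1", "chr2"),
    chrom_len: int = 1_000_000,
    max_width: int = 2_000,
    label: str = "",
) -> PeakSet:
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        width = int(rng.integers(50, max_width))
        start = int(rng.integers(0, chrom_len - width))
        peaks.append(Peak(chrom, start, start + width, name=f"{label}{i}"))
    return PeakSet(peaks, label=label)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------- oracles

def brute_overlaps(a: Peak, b: Peak) -> bool:
    if a.chrom != b.chrom:
        return False
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    return hi - lo >= 1


def brute_hits_any(p: Peak, others: PeakSet) -> bool:
    return any(brute_overlaps(p, q) for q in others)


def brute_consensus(rep1: PeakSet, rep2: PeakSet) -> list[Peak]:
    return [p for p in rep1 if brute_hits_any(p, rep2)]


def brute_cobind_counts(ctcf: PeakSet, er: PeakSet, fox: PeakSet) -> dict:
    counts = {"CTCF_only": 0, "CTCF_ER": 0, "CTCF_FOXA1": 0, "CTCF_ER_FOXA1": 0}
    for p in ctcf:
        e = brute_hits_any(p, er)
        f = brute_hits_any(p, fox)
        if e and f:
            counts["CTCF_ER_FOXA1"] += 1
        elif e:
            counts["CTCF_ER"] += 1
        elif f:
            counts["CTCF_FOXA1"] += 1
        else:
            counts["CTCF_only"] += 1
    return counts


def brute_scan(seq: str, pwm, threshold: float = 0.85) -> list[tuple[int, str]]:
    """Per-offset PWM rescans on both strands, N windows never matching."""
    freqs = pwm.frequencies
    lo = freqs.min(axis=0).sum()
    hi = freqs.max(axis=0).sum()
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = pwm.length
    hits = []
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L].upper()
        if any(c not in idx for c in window):
            continue
        fwd = sum(freqs[idx[c], j] for j, c in enumerate(window))
        if (fwd - lo) / (hi - lo) >= threshold:
            hits.append((i, "+"))
        rc = "".join(comp[c] for c in reversed(window))
        rev = sum(freqs[idx[c], j] for j, c in enumerate(rc))
        if (rev - lo) / (hi - lo) >= threshold:
            hits.append((i, "-"))
    return sorted(hits)
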