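"""PWM motif enrichment around peak summits with a permuted-matrix null.

The statistic: take the 2-kb sequence around each summit, count matches to
a position weight matrix at a similarity score of at least 85% in 100-bp
non-overlapping windows across the region, on both strands, pooled over
all summits. To judge significance, the matrix columns are randomly
permuted many times (default 1,000) and the same windowed counts are
collected for each permuted matrix; a column permutation preserves the
matrix's per-column composition and total information content, so the null
keeps the expected genome-wide hit rate and isolates the positional and
base-order signal. The per-window p-value is the upper tail of a Gaussian
fitted to the null counts (mean, sd with denominator n-1).

The similarity score of a window is the min-max-normalized frequency sum:
``(sum_j f[b_j, j] - min) / (max - min)`` where min/max sum the column-wise
minimum/maximum frequencies, so the consensus scores exactly 1 and the
anti-consensus exactly 0. Windows containing N never match. Log-odds
scoring is available as an alternative via ``score="logodds"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

BASES = "ACGT"
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

DEFAULT_THRESHOLD = 0.85
DEFAULT_SPAN = 2000
DEFAULT_WINDOW_WIDTH = 100
DEFAULT_N_PERM = 1000

# p-value sentinel for a degenerate (zero-spread) null with observed > mean
MIN_POSITIVE_P = float(np.nextafter(0, 1))


@dataclass
class PWM:
    """Position weight matrix: rows A, C, G, T; pseudocount-1 frequencies."""

    name: str
    counts: np.ndarray  # 4 x L, non-negative

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.ndim != 2:
            raise ValueError("counts must be a 4 x L matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        col_tot = self.counts.sum(axis=0)
        return (self.counts + 1.0) / (col_tot + 4.0)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.frequencies.argmax(axis=0))


class PwmParseError(ValueError):
    pass


def read_jaspar(path) -> list[PWM]:
    """Parse a JASPAR PFM text file into PWMs (via Bio.motifs)."""
    from Bio import motifs as bio_motifs

    out: list[PWM] = []
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:  # biopython raises bare Exceptions here
            raise PwmParseError(f"{path}: {exc}") from exc
        for m in parsed:
            counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
            name = m.name or m.matrix_id or "motif"
            if m.matrix_id and m.name and m.matrix_id != m.name:
                name = f"{m.matrix_id} {m.name}"
            out.append(PWM(name=name, counts=counts))
    lengths = {p.name: p.length for p in out}
    for nm, ln in lengths.items():
        if ln < 1:
            raise PwmParseError(f"{path}: motif {nm} has zero length")
    return out


def write_jaspar(pwms: Iterable[PWM], path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.name}\n")
            for i, b in enumerate(BASES):
                row = " ".join(f"{v:g}" for v in p.counts[i])
                fh.write(f"{b} [ {row} ]\n")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 (A=0 C=1 G=2 T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    table = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
    return seq.translate(table)[::-1]


def _freq5(pwm: PWM, score: str = "similarity") -> np.ndarray:
    """4+1 x L score matrix; the fifth row (N) is a large negative number."""
    if score == "similarity":
        base = pwm.frequencies
    elif score == "logodds":
        base = np.log2(pwm.frequencies / 0.25)
    else:
        raise ValueError(f"unknown score {score!r}")
    f5 = np.vstack([base, np.full((1, pwm.length), -1e9)])
    return f5


def _score_range(pwm: PWM, score: str = "similarity") -> tuple[float, float]:
    f = _freq5(pwm, score)[:4]
    return float(f.min(axis=0).sum()), float(f.max(axis=0).sum())


def _scan_scores(enc: np.ndarray, f5: np.ndarray) -> np.ndarray:
    """Raw window scores at every offset of an encoded sequence."""
    L = f5.shape[1]
    n = len(enc)
    if n < L:
        return np.zeros(0)
    W = n - L + 1
    s = np.zeros(W)
    for j in range(L):
        s += f5[enc[j : j + W], j]
    return s


def similarity_scan(
    seq: str, pwm: PWM, threshold: float = DEFAULT_THRESHOLD, score: str = "similarity"
) -> list[tuple[int, str]]:
    """All (position, strand) with min-max similarity >= threshold.

    Positions are match starts on the forward strand for both strands; the
    reverse strand scans the reverse complement of the matrix. Windows
    containing N never match. A sequence shorter than the matrix yields an
    empty result.
    """
    enc = encode(seq)
    f5 = _freq5(pwm, score)
    lo, hi = _score_range(pwm, score)
    thr = lo + threshold * (hi - lo)
    fwd = _scan_scores(enc, f5)
    # reverse strand == complement rows, reverse columns
    f5_rc = np.vstack([f5[[3, 2, 1, 0], ::-1], f5[4:, ::-1]])
    rev = _scan_scores(enc, f5_rc)
    hits = [(int(i), "+") for i in np.nonzero(fwd >= thr)[0]]
    hits += [(int(i), "-") for i in np.nonzero(rev >= thr)[0]]
    hits.sort()
    return hits


def window_counts(
    hits: Sequence[tuple[int, str]],
    span: int = DEFAULT_SPAN,
    window_width: int = DEFAULT_WINDOW_WIDTH,
) -> np.ndarray:
    """Hit counts per non-overlapping window, strands pooled.

    A hit is assigned by its match start position; positions must lie in
    ``[0, span)``.
    """
    n_win = span // window_width
    counts = np.zeros(n_win, dtype=np.int64)
    for pos, _strand in hits:
        if not 0 <= pos < span:
            raise ValueError(f"hit position {pos} outside [0, {span})")
        counts[pos // window_width] += 1
    return counts


def permute_pwm(pwm: PWM, rng_seed=None) -> PWM:
    """Uniformly random column permutation (identity allowed)."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    perm = rng.permutation(pwm.length)
    return PWM(name=f"{pwm.name}|perm", counts=pwm.counts[:, perm])


def gaussian_p(observed: float, null_counts: Sequence[float]) -> float:
    """Upper Gaussian tail of the null at the observed count.

    ``p = 1 - Phi((observed - mean) / sd)`` with sd using denominator n-1.
    A zero-spread null gives p = 1 when observed <= mean, else the smallest
    positive float as a sentinel for "beyond any null sample".
    """
    null = np.asarray(null_counts, dtype=float)
    if len(null) < 2:
        raise ValueError("need at least 2 null samples")
    mean = null.mean()
    sd = null.std(ddof=1)
    if sd == 0:
        return 1.0 if observed <= mean else MIN_POSITIVE_P
    return float(norm.sf((observed - mean) / sd))


@dataclass
class WindowEnrichment:
    pwm_name: str
    window_index: int
    observed: int
    null_mean: float
    null_sd: float
    p_value: float


def _pooled_window_counts(
    concat: np.ndarray,
    concat_rc: np.ndarray,
    cols: list[np.ndarray],
    cols_rc: list[np.ndarray],
    perm: np.ndarray,
    thr: float,
    stride: int,
    span: int,
    window_width: int,
) -> np.ndarray:
    """Windowed match counts over all sequences for one column order."""
    L = len(perm)
    W = len(concat) - L + 1
    n_win = span // window_width
    counts = np.zeros(n_win, dtype=np.int64)
    for strand_cols, strand_perm in ((cols, perm), (cols_rc, perm[::-1])):
        s = np.zeros(W, dtype=np.float32)
        for j in range(L):
            s += strand_cols[strand_perm[j]][j : j + W]
        offs = np.nonzero(s >= thr)[0]
        pos = offs % stride  # spacer windows contain N and cannot pass
        np.add.at(counts, pos // window_width, 1)
    return counts


def motif_enrichment(
    summit_sequences: Sequence[str],
    pwms: Sequence[PWM],
    n_perm: int = DEFAULT_N_PERM,
    threshold: float = DEFAULT_THRESHOLD,
    span: int = DEFAULT_SPAN,
    window_width: int = DEFAULT_WINDOW_WIDTH,
    rng_seed=None,
) -> list[list[WindowEnrichment]]:
    """Windowed PWM-match enrichment with a permuted-matrix null.

    For each PWM: observed counts pool similarity-threshold matches from
    all sequences and both strands per window; the null repeats the count
    with ``n_perm`` column-permuted versions of the matrix; the per-window
    p-value is the Gaussian upper tail of the null at the observed count.
    Deterministic for a fixed seed.
    """
    if len(summit_sequences) == 0:
        raise ValueError("summit_sequences must be non-empty")
    for s in summit_sequences:
        if len(s) != span:
            raise ValueError(
                f"all sequences must be exactly {span} bp (got {len(s)})"
            )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    results: list[list[WindowEnrichment]] = []
    for pwm in pwms:
        L = pwm.length
        stride = span + L  # N spacer kills windows crossing sequence ends
        concat = np.full(stride * len(summit_sequences), 4, dtype=np.uint8)
        for i, s in enumerate(summit_sequences):
            concat[i * stride : i * stride + span] = encode(s)
        f5 = _freq5(pwm).astype(np.float32)
        lo, hi = _score_range(pwm)
        thr = np.float32(lo + threshold * (hi - lo))
        f5_rc_rows = f5[[3, 2, 1, 0, 4], :]  # complement rows only; column
        # reversal is expressed through the reversed permutation index
        M = f5[concat]  # N x L gather, forward
        Mc = f5_rc_rows[concat]  # N x L gather, complemented bases
        cols = [np.ascontiguousarray(M[:, k]) for k in range(L)]
        cols_rc = [np.ascontiguousarray(Mc[:, k]) for k in range(L)]
        del M, Mc

        identity = np.arange(L)
        observed = _pooled_window_counts(
            concat, concat, cols, cols_rc, identity, thr, stride, span, window_width
        )
        n_win = span // window_width
        null = np.empty((n_perm, n_win), dtype=np.int64)
        for k in range(n_perm):
            perm = rng.permutation(L)
            null[k] = _pooled_window_counts(
                concat, concat, cols, cols_rc, perm, thr, stride, span, window_width
            )
        null_mean = null.mean(axis=0)
        null_sd = null.std(axis=0, ddof=1)
        row = []
        for w in range(n_win):
            row.append(
                WindowEnrichment(
                    pwm_name=pwm.name,
                    window_index=w,
                    observed=int(observed[w]),
                    null_mean=float(null_mean[w]),
                    null_sd=float(null_sd[w]),
                    p_value=gaussian_p(observed[w], null[:, w]),
                )
            )
        results.append(row)
    return results


def enrichment_frame(results: list[list[WindowEnrichment]]):
    """Flatten motif_enrichment output into a tidy DataFrame."""
    import pandas as pd

    rows = [
        {
            "pwm": we.pwm_name,
            "window": we.window_index,
            "observed": we.observed,
            "null_mean": we.null_mean,
            "null_sd": we.null_sd,
            "p_value": we.p_value,
        }
        for per_pwm in results
        for we in per_pwm
    ]
    return pd.DataFrame(rows)


def extract_summit_sequences(
    peaks, fasta_path, span: int = DEFAULT_SPAN
) -> list[str]:
    """Sequence of length ``span`` centred on each peak's summit (or
    midpoint), N-padded at chromosome edges."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    half = span // 2
    out = []
    for p in peaks:
        centre = p.anchor
        chrom_len = len(fa[p.chrom])
        lo = centre - half
        hi = centre + (span - half)
        seq = str(fa[p.chrom][max(lo, 0) : min(hi, chrom_len)]).upper()
        seq = "N" * max(0, -lo) + seq + "N" * max(0, hi - chrom_len)
        out.append(seq)
    return out
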