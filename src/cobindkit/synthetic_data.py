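"""Seeded generator of genomes, binding truth, replicate peak files, read
pileups, gene models and expression tables.

The generator emulates the statistical structure the downstream analysis
assumes: three transcription factors (CTCF everywhere; ER and FOXA1 only in
ER-positive lines) binding a uniform-background genome; CTCF sites shared
across cell lines in configurable classes (common to all lines, shared by
the ER-positive lines only, or specific to one line); co-binding realised
by placing ER/FOXA1 site centres within a configurable offset of CTCF
summits (default uniform within ±500 bp, so co-bound factors are near but
not on the CTCF summit); two replicates per library with per-replicate
site dropout, summit jitter and private noise peaks; treatment reads as a
Gaussian mixture around summits over a uniform background, plus one shared
uniform input library; motif consensus instances planted near summits; and
an expression table in which genes whose TSS lies near a line-specific
site are preferentially differentially expressed in that line.

Everything is driven by one flat :class:`ScenarioConfig` and a seed;
identical configs produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel, write_gene_models
from .intervals import Peak, PeakSet, write_bed
from .motifs import PWM, read_jaspar

FACTORS = ("CTCF", "ER", "FOXA1")
READ_LENGTH = 36

PWM_DATA = Path(__file__).parent / "data" / "synthetic_core_motifs.jaspar"


@dataclass
class ScenarioConfig:
    """Flat configuration of one synthetic scenario (all keys overridable)."""

    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    lines: tuple[str, ...] = ("MCF7", "ZR751", "MCF10A")
    er_negative_lines: tuple[str, ...] = ("MCF10A",)
    sites_per_factor: int = 1000
    min_site_spacing: int = 1500
    # fractions of CTCF sites co-bound by each partner combination
    cobind_er_rate: float = 0.048
    cobind_foxa1_rate: float = 0.196
    cobind_triple_rate: float = 0.048
    # fraction of standalone ER sites additionally bound by FOXA1 (no CTCF)
    er_foxa1_only_rate: float = 0.15
    # CTCF site sharing classes across cell lines
    line_specific_fraction: float = 0.08
    er_positive_only_fraction: float = 0.09
    cofactor_offset_bp: int = 500
    replicate_dropout: float = 0.05
    summit_jitter_sd: float = 30.0
    peak_width_mean: float = 400.0
    peak_width_sd: float = 100.0
    noise_peaks_per_replicate: int = 100
    reads_per_library: int = 200_000
    signal_to_background: float = 2.0
    read_spread_sd: float = 100.0
    motif_plant_rate: float = 0.7
    motif_plant_offset_bp: int = 25
    n_genes: int = 400
    gene_length_min: int = 2_000
    gene_length_max: int = 20_000
    tss_window: int = 20_000
    de_near_prob: float = 0.3
    de_background_prob: float = 0.05
    de_effect_log2: float = 2.0
    expression_noise_sd: float = 0.25
    expression_replicates: int = 3
    regulated_near_prob: float = 0.4
    regulated_background_prob: float = 0.08

    def __post_init__(self):
        probs = [
            self.cobind_er_rate,
            self.cobind_foxa1_rate,
            self.cobind_triple_rate,
            self.er_foxa1_only_rate,
            self.line_specific_fraction,
            self.er_positive_only_fraction,
            self.replicate_dropout,
            self.motif_plant_rate,
            self.de_near_prob,
            self.de_background_prob,
            self.regulated_near_prob,
            self.regulated_background_prob,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all rates/probabilities must lie in [0, 1]")
        if self.cobind_er_rate + self.cobind_foxa1_rate + self.cobind_triple_rate > 1:
            raise ValueError("summed CTCF co-binding rates exceed 1")
        n_specific_classes = len(self.lines)
        if (
            self.line_specific_fraction * n_specific_classes
            + self.er_positive_only_fraction
            > 1
        ):
            raise ValueError("CTCF sharing-class fractions exceed 1")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if len(self.lines) < 2:
            raise ValueError("need at least 2 cell lines")

    @property
    def er_positive_lines(self) -> tuple[str, ...]:
        return tuple(l for l in self.lines if l not in self.er_negative_lines)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("lines", "er_negative_lines"):
            if key in d:
                d[key] = tuple(d[key])
        if "chrom_lengths" in d:
            d["chrom_lengths"] = {k: int(v) for k, v in d["chrom_lengths"].items()}
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lines"] = list(self.lines)
        d["er_negative_lines"] = list(self.er_negative_lines)
        return d


@dataclass
class BindingTruth:
    """True site centres per factor/line plus CTCF bookkeeping tables.

    ``ctcf`` columns: chrom, pos (summit), share_class (common /
    er_positive_only / <line>_specific), cobind (none / ER / FOXA1 /
    ER_FOXA1), er_pos, foxa1_pos (offset co-factor centres; -1 = absent).
    ``standalone`` columns: chrom, pos, factor_set (ER / FOXA1 / ER_FOXA1)
    for sites without CTCF.
    """

    ctcf: pd.DataFrame
    standalone: pd.DataFrame
    lines: tuple[str, ...]
    er_positive_lines: tuple[str, ...]

    def ctcf_present_mask(self, line: str) -> np.ndarray:
        cls = self.ctcf["share_class"]
        mask = cls == "common"
        if line in self.er_positive_lines:
            mask |= cls == "er_positive_only"
        return (mask | (cls == f"{line}_specific")).to_numpy()

    def sites(self, factor: str, line: str) -> pd.DataFrame:
        """(chrom, pos) site centres for a factor in a cell line."""
        if factor == "CTCF":
            sel = self.ctcf[self.ctcf_present_mask(line)]
            return sel[["chrom", "pos"]].reset_index(drop=True)
        if line not in self.er_positive_lines:
            return pd.DataFrame(columns=["chrom", "pos"])
        present = self.ctcf[self.ctcf_present_mask(line)]
        col = "er_pos" if factor == "ER" else "foxa1_pos"
        cobound = present[present[col] >= 0][["chrom", col]].rename(
            columns={col: "pos"}
        )
        want = {"ER": ("ER", "ER_FOXA1"), "FOXA1": ("FOXA1", "ER_FOXA1")}[factor]
        alone = self.standalone[self.standalone["factor_set"].isin(want)][
            ["chrom", "pos"]
        ]
        out = pd.concat([cobound, alone], ignore_index=True)
        return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def stage_rngs(cfg: ScenarioConfig) -> dict[str, np.random.Generator]:
    """Independent per-stage generators spawned from the scenario seed.

    Keys: genome, truth, peaks, motifs, reads, expression. Using one
    stream per stage keeps each stage's output invariant to changes in the
    other stages' draw counts.
    """
    names = ("genome", "truth", "peaks", "motifs", "reads", "expression")
    children = np.random.SeedSequence(cfg.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


_stage_rngs = stage_rngs


# ---------------------------------------------------------------- genome

def make_genome(cfg: ScenarioConfig, rng=None) -> dict[str, np.ndarray]:
    """I.i.d. uniform ACGT chromosome sequences as uint8 codes (0..3)."""
    rng = _rng(rng if rng is not None else cfg.seed)
    out = {}
    for chrom, length in cfg.chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"zero-length chromosome {chrom}")
        out[chrom] = rng.integers(0, 4, size=length, dtype=np.uint8)
    return out


_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def write_fasta(seqs: Mapping[str, np.ndarray], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in seqs:
            fh.write(f">{chrom}\n")
            raw = _DECODE[seqs[chrom]].tobytes().decode("ascii")
            for i in range(0, len(raw), width):
                fh.write(raw[i : i + width] + "\n")


def write_chrom_sizes(cfg: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in cfg.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, length = line.split("\t")
                out[chrom] = int(length)
    return out


# ----------------------------------------------------------- binding truth

def _draw_spaced_positions(
    cfg: ScenarioConfig, n: int, rng: np.random.Generator, margin: int = 2500
) -> pd.DataFrame:
    """n site positions across chromosomes with minimum spacing."""
    if n == 0:
        return pd.DataFrame({"chrom": pd.Series(dtype=object), "pos": pd.Series(dtype=np.int64)})
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    usable = lengths - 2 * margin
    alloc = np.floor(n * usable / usable.sum()).astype(int)
    while alloc.sum() < n:
        alloc[int(np.argmax(usable / (alloc + 1)))] += 1
    rows = []
    s = cfg.min_site_spacing
    for chrom, L, k in zip(chroms, lengths, alloc):
        if k == 0:
            continue
        free = (L - 2 * margin) - k * s
        if free <= 0:
            raise ValueError(
                f"cannot place {k} sites with spacing {s} on {chrom}"
            )
        gaps = np.sort(rng.random(k)) * free
        pos = (margin + gaps + s * np.arange(k) + s // 2).astype(np.int64)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    df = pd.concat(rows, ignore_index=True)
    return df.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31))).reset_index(drop=True)


def make_binding_truth(cfg: ScenarioConfig, rng=None) -> BindingTruth:
    """Draw CTCF sites with sharing classes and co-binding, plus standalone
    ER/FOXA1 sites, all with minimum spacing."""
    rng = _rng(rng if rng is not None else cfg.seed)
    n_ctcf = cfg.sites_per_factor
    n_cobind_er = int(round(n_ctcf * (cfg.cobind_er_rate + cfg.cobind_triple_rate)))
    n_cobind_fox = int(
        round(n_ctcf * (cfg.cobind_foxa1_rate + cfg.cobind_triple_rate))
    )
    n_er_alone = max(0, cfg.sites_per_factor - n_cobind_er)
    n_fox_alone = max(0, cfg.sites_per_factor - n_cobind_fox)
    n_er_fox = int(round(n_er_alone * cfg.er_foxa1_only_rate))
    n_fox_alone = max(0, n_fox_alone - n_er_fox)
    total = n_ctcf + n_er_alone + n_fox_alone
    loci = _draw_spaced_positions(cfg, total, rng)

    ctcf = loci.iloc[:n_ctcf].reset_index(drop=True).copy()
    # sharing classes
    classes = np.full(n_ctcf, "common", dtype=object)
    k = 0
    for line in cfg.lines:
        n_spec = int(round(n_ctcf * cfg.line_specific_fraction))
        classes[k : k + n_spec] = f"{line}_specific"
        k += n_spec
    n_erpos = int(round(n_ctcf * cfg.er_positive_only_fraction))
    classes[k : k + n_erpos] = "er_positive_only"
    perm = rng.permutation(n_ctcf)
    ctcf["share_class"] = classes[perm]
    # co-binding assignment
    cobind = np.full(n_ctcf, "none", dtype=object)
    order = rng.permutation(n_ctcf)
    n_triple = int(round(n_ctcf * cfg.cobind_triple_rate))
    n_er = int(round(n_ctcf * cfg.cobind_er_rate))
    n_fox = int(round(n_ctcf * cfg.cobind_foxa1_rate))
    cobind[order[:n_triple]] = "ER_FOXA1"
    cobind[order[n_triple : n_triple + n_er]] = "ER"
    cobind[order[n_triple + n_er : n_triple + n_er + n_fox]] = "FOXA1"
    ctcf["cobind"] = cobind
    # co-factor centres offset from the CTCF summit
    off = cfg.cofactor_offset_bp
    er_off = rng.integers(-off, off + 1, size=n_ctcf)
    fox_off = rng.integers(-off, off + 1, size=n_ctcf)
    has_er = np.isin(cobind, ("ER", "ER_FOXA1"))
    has_fox = np.isin(cobind, ("FOXA1", "ER_FOXA1"))
    ctcf["er_pos"] = np.where(has_er, ctcf["pos"] + er_off, -1)
    ctcf["foxa1_pos"] = np.where(has_fox, ctcf["pos"] + fox_off, -1)

    alone = loci.iloc[n_ctcf:].reset_index(drop=True).copy()
    factor_set = np.concatenate(
        [
            np.full(n_er_fox, "ER_FOXA1", dtype=object),
            np.full(n_er_alone - n_er_fox, "ER", dtype=object),
            np.full(n_fox_alone, "FOXA1", dtype=object),
        ]
    )
    alone["factor_set"] = factor_set
    return BindingTruth(
        ctcf=ctcf,
        standalone=alone,
        lines=cfg.lines,
        er_positive_lines=cfg.er_positive_lines,
    )


# ---------------------------------------------------------- replicate peaks

def emit_replicate_peaks(
    truth: BindingTruth, cfg: ScenarioConfig, rng=None
) -> dict[tuple[str, str, int], PeakSet]:
    """Two replicate peak sets per factor/line with dropout, jitter, width
    variation and replicate-private noise peaks."""
    rng = _rng(rng if rng is not None else cfg.seed)
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    out: dict[tuple[str, str, int], PeakSet] = {}
    for factor in FACTORS:
        for line in cfg.lines:
            sites = truth.sites(factor, line)
            for rep in (1, 2):
                peaks: list[Peak] = []
                if len(sites):
                    keep = rng.random(len(sites)) >= cfg.replicate_dropout
                    widths = np.maximum(
                        50,
                        rng.normal(
                            cfg.peak_width_mean, cfg.peak_width_sd, size=len(sites)
                        ),
                    ).astype(np.int64)
                    jitter = rng.normal(
                        0, cfg.summit_jitter_sd, size=len(sites)
                    ).astype(np.int64)
                    for i in np.nonzero(keep)[0]:
                        chrom = sites["chrom"].iloc[i]
                        clen = cfg.chrom_lengths[chrom]
                        summit = int(
                            np.clip(sites["pos"].iloc[i] + jitter[i], 1, clen - 2)
                        )
                        half = int(widths[i]) // 2
                        start = max(0, summit - half)
                        end = min(clen, start + int(widths[i]))
                        summit = min(max(summit, start), end - 1)
                        peaks.append(
                            Peak(
                                chrom,
                                start,
                                end,
                                summit=summit,
                                name=f"{factor}_{line}_rep{rep}_{len(peaks)}",
                            )
                        )
                n_noise = cfg.noise_peaks_per_replicate if len(sites) else 0
                for _ in range(n_noise):
                    ci = int(rng.choice(len(chroms), p=lengths / lengths.sum()))
                    chrom = chroms[ci]
                    clen = cfg.chrom_lengths[chrom]
                    width = int(
                        max(50, rng.normal(cfg.peak_width_mean, cfg.peak_width_sd))
                    )
                    start = int(rng.integers(0, max(1, clen - width)))
                    end = min(clen, start + width)
                    peaks.append(
                        Peak(
                            chrom,
                            start,
                            end,
                            summit=(start + end) // 2,
                            name=f"{factor}_{line}_rep{rep}_noise{_}",
                        )
                    )
                out[(factor, line, rep)] = PeakSet(
                    peaks, label=f"{factor}_{line}_rep{rep}"
                )
    return out


# ----------------------------------------------------------------- motifs

def load_default_pwms() -> list[PWM]:
    """The packaged synthetic stand-in motif collection."""
    return read_jaspar(PWM_DATA)


def plant_motifs(
    seqs: Mapping[str, np.ndarray],
    truth: BindingTruth,
    cfg: ScenarioConfig,
    rng=None,
    pwms: Sequence[PWM] | None = None,
) -> int:
    """Overwrite background bases with motif consensus instances near the
    corresponding factor's site centres. Returns the number planted.

    CTCF consensus at CTCF summits; ERE at ER centres; forkhead at FOXA1
    centres; each planted with probability ``motif_plant_rate`` at a
    uniform offset within ±``motif_plant_offset_bp`` of the centre. An
    instance that would extend past a chromosome end is skipped.
    """
    from .motifs import encode

    rng = _rng(rng if rng is not None else cfg.seed)
    if pwms is None:
        pwms = load_default_pwms()
    by_name = {p.name.split()[0]: p for p in pwms}
    jobs: list[tuple[str, int, str]] = []  # chrom, centre, consensus
    cons = {
        "CTCF": by_name["CTCF_like"].consensus,
        "ER": by_name["ERE"].consensus,
        "FOXA1": by_name["FOXA1_forkhead"].consensus,
    }
    for _, row in truth.ctcf.iterrows():
        jobs.append((row["chrom"], int(row["pos"]), cons["CTCF"]))
        if row["er_pos"] >= 0:
            jobs.append((row["chrom"], int(row["er_pos"]), cons["ER"]))
        if row["foxa1_pos"] >= 0:
            jobs.append((row["chrom"], int(row["foxa1_pos"]), cons["FOXA1"]))
    for _, row in truth.standalone.iterrows():
        fs = row["factor_set"]
        if "ER" in fs.split("_") or fs == "ER":
            jobs.append((row["chrom"], int(row["pos"]), cons["ER"]))
        if "FOXA1" in fs:
            jobs.append((row["chrom"], int(row["pos"]), cons["FOXA1"]))
    planted = 0
    off = cfg.motif_plant_offset_bp
    for chrom, centre, consensus in jobs:
        if rng.random() >= cfg.motif_plant_rate:
            continue
        delta = int(rng.integers(-off, off + 1)) if off > 0 else 0
        start = centre + delta - len(consensus) // 2
        seq = seqs[chrom]
        if start < 0 or start + len(consensus) > len(seq):
            continue  # skipped: instance would extend past the chromosome
        seq[start : start + len(consensus)] = encode(consensus)
        planted += 1
    return planted


# ------------------------------------------------------------------ reads

def simulate_reads(
    truth: BindingTruth, cfg: ScenarioConfig, rng=None
) -> dict[str, pd.DataFrame]:
    """Read 5'-start tables per treatment library plus one shared input.

    Treatment reads mix Gaussians centred on the factor's site centres
    (sd ``read_spread_sd``) with a uniform background; the ratio of signal
    to background reads is ``signal_to_background``. The input library is
    uniform only. Every library has exactly ``reads_per_library`` reads.
    """
    rng = _rng(rng if rng is not None else cfg.seed)
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=np.int64)
    probs = lengths / lengths.sum()

    def uniform_reads(n: int) -> pd.DataFrame:
        ci = rng.choice(len(chroms), size=n, p=probs)
        pos = (rng.random(n) * lengths[ci]).astype(np.int64)
        return pd.DataFrame({"chrom": np.array(chroms, dtype=object)[ci], "pos": pos})

    out: dict[str, pd.DataFrame] = {}
    for factor in FACTORS:
        for line in cfg.lines:
            sites = truth.sites(factor, line)
            if len(sites) == 0:
                continue
            n = cfg.reads_per_library
            r = cfg.signal_to_background
            n_sig = int(round(n * r / (1.0 + r)))
            idx = rng.integers(0, len(sites), size=n_sig)
            centres = sites["pos"].to_numpy()[idx]
            site_chrom = sites["chrom"].to_numpy()[idx]
            pos = np.rint(rng.normal(centres, cfg.read_spread_sd)).astype(np.int64)
            clens = np.array([cfg.chrom_lengths[c] for c in site_chrom])
            pos = np.clip(pos, 0, clens - READ_LENGTH)
            sig = pd.DataFrame({"chrom": site_chrom, "pos": pos})
            bg = uniform_reads(n - n_sig)
            df = pd.concat([sig, bg], ignore_index=True)
            out[f"{factor}_{line}"] = df
    out["input"] = uniform_reads(cfg.reads_per_library)
    return out


def write_reads_bed(reads: pd.DataFrame, path) -> None:
    df = reads.copy()
    df["end"] = df["pos"] + READ_LENGTH
    df[["chrom", "pos", "end"]].to_csv(path, sep="\t", header=False, index=False)


# ------------------------------------------------- genes and expression

def simulate_genes_and_expression(
    truth: BindingTruth, cfg: ScenarioConfig, rng=None
) -> tuple[list[GeneModel], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene models, expression matrix, DE truth, regulated-gene labels.

    Returns ``(genes, expression, de_truth, regulated)`` where
    ``expression`` is a genes x samples log2 table (columns
    ``<line>_rep<k>``), ``de_truth`` has one boolean column per line, and
    ``regulated`` has columns gene_id and direction (up/down) for the
    estrogen-regulated label set planted near ER-and-CTCF co-bound sites.
    """
    rng = _rng(rng if rng is not None else cfg.seed)
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=np.int64)
    probs = lengths / lengths.sum()

    genes: list[GeneModel] = []
    for i in range(cfg.n_genes):
        ci = int(rng.choice(len(chroms), p=probs))
        chrom = chroms[ci]
        clen = int(lengths[ci])
        glen = int(rng.integers(cfg.gene_length_min, cfg.gene_length_max + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, max(1, clen - glen)))
        end = start + glen
        # 1-3 exons; first/last exon pinned to the span ends
        n_ex = int(rng.integers(1, 4))
        if n_ex == 1 or glen < 600:
            exons = ((start, end),)
        else:
            cuts = np.sort(rng.integers(200, glen - 200, size=2 * (n_ex - 1)))
            bounds = [start] + [start + int(c) for c in cuts] + [end]
            exons = tuple(
                (bounds[2 * k], bounds[2 * k + 1]) for k in range(n_ex)
            )
            exons = tuple((s, e) for s, e in exons if e > s)
        genes.append(GeneModel(f"gene{i:05d}", chrom, strand, start, end, exons))

    # proximity of each TSS to line-specific CTCF truth sites
    near_line: dict[str, np.ndarray] = {}
    for line in cfg.lines:
        sel = truth.ctcf[truth.ctcf["share_class"] == f"{line}_specific"]
        near_line[line] = _tss_near_sites(genes, sel, cfg.tss_window)
    # proximity to ER-and-CTCF co-bound sites (for estrogen-regulated labels)
    er_ctcf = truth.ctcf[truth.ctcf["cobind"].isin(("ER", "ER_FOXA1"))]
    near_er_ctcf = _tss_near_sites(genes, er_ctcf, cfg.tss_window)

    de_truth = pd.DataFrame(index=[g.gene_id for g in genes])
    sign = {}
    for line in cfg.lines:
        p = np.where(near_line[line], cfg.de_near_prob, cfg.de_background_prob)
        de_truth[line] = rng.random(cfg.n_genes) < p
        sign[line] = np.where(rng.random(cfg.n_genes) < 0.5, 1.0, -1.0)

    baseline = rng.normal(8.0, 1.0, size=cfg.n_genes)
    cols = {}
    for line in cfg.lines:
        shift = np.where(de_truth[line], sign[line] * cfg.de_effect_log2, 0.0)
        for rep in range(1, cfg.expression_replicates + 1):
            noise = rng.normal(0, cfg.expression_noise_sd, size=cfg.n_genes)
            cols[f"{line}_rep{rep}"] = baseline + shift + noise
    expression = pd.DataFrame(cols, index=de_truth.index)
    expression.index.name = "gene_id"

    p_reg = np.where(
        near_er_ctcf, cfg.regulated_near_prob, cfg.regulated_background_prob
    )
    is_reg = rng.random(cfg.n_genes) < p_reg
    direction = np.where(rng.random(cfg.n_genes) < 0.5, "up", "down")
    regulated = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g, r in zip(genes, is_reg) if r],
            "direction": [d for d, r in zip(direction, is_reg) if r],
        }
    )
    return genes, expression, de_truth, regulated


def _tss_near_sites(
    genes: Sequence[GeneModel], sites: pd.DataFrame, window: int
) -> np.ndarray:
    by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy())
        for chrom, sub in sites.groupby("chrom")
    }
    out = np.zeros(len(genes), dtype=bool)
    for i, g in enumerate(genes):
        pos = by_chrom.get(g.chrom)
        if pos is None or len(pos) == 0:
            continue
        j = np.searchsorted(pos, g.tss)
        for k in (j - 1, j):
            if 0 <= k < len(pos) and abs(int(pos[k]) - g.tss) <= window:
                out[i] = True
                break
    return out


# --------------------------------------------------------------- scenario

def simulate_scenario(cfg: ScenarioConfig, out_dir) -> dict:
    """Generate and write every input the pipeline consumes.

    Returns a manifest dict of output paths. Identical configs give
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rngs = _stage_rngs(cfg)

    seqs = make_genome(cfg, rngs["genome"])
    truth = make_binding_truth(cfg, rngs["truth"])
    peaks = emit_replicate_peaks(truth, cfg, rngs["peaks"])
    plant_motifs(seqs, truth, cfg, rngs["motifs"])
    reads = simulate_reads(truth, cfg, rngs["reads"])
    genes, expression, de_truth, regulated = simulate_genes_and_expression(
        truth, cfg, rngs["expression"]
    )

    paths: dict[str, object] = {}
    fasta = out_dir / "genome.fa"
    write_fasta(seqs, fasta)
    paths["genome_fasta"] = str(fasta)
    sizes = out_dir / "chrom.sizes"
    write_chrom_sizes(cfg, sizes)
    paths["chrom_sizes"] = str(sizes)

    peak_dir = out_dir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    peak_paths = {}
    for (factor, line, rep), ps in peaks.items():
        p = peak_dir / f"{factor}_{line}_rep{rep}.bed"
        write_bed(ps, p)
        peak_paths[f"{factor}_{line}_rep{rep}"] = str(p)
    paths["peaks"] = peak_paths

    read_dir = out_dir / "reads"
    read_dir.mkdir(exist_ok=True)
    read_paths = {}
    for label, df in reads.items():
        p = read_dir / f"{label}.bed"
        write_reads_bed(df, p)
        read_paths[label] = str(p)
    paths["reads"] = read_paths

    gene_path = out_dir / "genes.tsv"
    write_gene_models(genes, gene_path)
    paths["genes"] = str(gene_path)
    expr_path = out_dir / "expression.tsv"
    expression.to_csv(expr_path, sep="\t")
    paths["expression"] = str(expr_path)
    reg_path = out_dir / "regulated_genes.tsv"
    regulated.to_csv(reg_path, sep="\t", index=False)
    paths["regulated_genes"] = str(reg_path)

    truth_dir = out_dir / "truth"
    truth_dir.mkdir(exist_ok=True)
    truth.ctcf.to_csv(truth_dir / "ctcf_sites.tsv", sep="\t", index=False)
    truth.standalone.to_csv(truth_dir / "standalone_sites.tsv", sep="\t", index=False)
    de_truth.to_csv(truth_dir / "de_truth.tsv", sep="\t")
    paths["truth_dir"] = str(truth_dir)
    paths["pwms"] = str(PWM_DATA)
    return paths


# ------------------------------------------------------- scenario presets

def default_scenario(seed: int = 0) -> ScenarioConfig:
    """The default end-to-end smoke scenario (2 x 5 Mb genome)."""
    return ScenarioConfig(seed=seed)


def table1_scenario(seed: int = 0) -> ScenarioConfig:
    """Three-line DE-proximity recovery scenario.

    A larger, sparser genome (2 x 20 Mb, 50 line-specific sites per line,
    2,000 genes) keeps the ±20 kb TSS windows of different lines' specific
    sites mostly disjoint so the per-line Fisher contrasts are informative.
    """
    return ScenarioConfig(
        seed=seed,
        chrom_lengths={"chr1": 20_000_000, "chr2": 20_000_000},
        sites_per_factor=1000,
        line_specific_fraction=0.05,
        n_genes=2000,
        de_near_prob=0.3,
        de_background_prob=0.05,
        expression_replicates=3,
    )


def fig3_scenario(seed: int = 0) -> ScenarioConfig:
    """Regulated-gene proximity scenario: regulated labels planted near
    ER-and-CTCF co-bound sites; ER-and-FOXA1-without-CTCF sites serve as
    the control class. Gene density is kept low enough that the ±20 kb
    windows do not saturate."""
    return ScenarioConfig(
        seed=seed,
        chrom_lengths={"chr1": 10_000_000, "chr2": 10_000_000},
        sites_per_factor=1000,
        cobind_er_rate=0.12,
        cobind_triple_rate=0.08,
        er_foxa1_only_rate=0.2,
        n_genes=600,
        regulated_near_prob=0.4,
        regulated_background_prob=0.08,
    )
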