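"""Genomic-context summaries of called 6mA sites.

Covers the standard descriptive outputs of a base-resolution methylation
map: promoter/genic/intergenic assignment (promoter = TSS +/- 1 kb),
a TSS-centred metagene density profile with an autocorrelation-based
periodicity estimate (6mA spacing tracks nucleosome positioning), the
tetramer-context breakdown (GATC vs CATC/GATG vs other), and the flanking
nucleotide-composition matrix that sequence-logo tools consume.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import Genome, revcomp
from .caller import MethylationCall

logger = logging.getLogger(__name__)

REGION_PROMOTER = "promoter"
REGION_GENIC = "genic"
REGION_INTERGENIC = "intergenic"


@dataclass(frozen=True)
class Gene:
    """A transcript model; the TSS is the strand-aware 5' end."""

    contig: str
    start: int  # 0-based half-open transcript interval
    end: int
    strand: str
    name: str = ""

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


class GffError(ValueError):
    pass


def read_gff3_genes(
    path: str | os.PathLike,
    feature_types: tuple[str, ...] = ("gene",),
) -> list[Gene]:
    """Read gene features from GFF3 (1-based inclusive -> 0-based half-open)."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise GffError(f"{path}: line {ln}: expected 9 columns, got {len(parts)}")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = parts
            if ftype not in feature_types:
                continue
            try:
                s, e = int(start) - 1, int(end)
            except ValueError:
                raise GffError(f"{path}: line {ln}: non-integer coordinates") from None
            if strand not in "+-":
                raise GffError(f"{path}: line {ln}: strand must be + or -")
            name = ""
            for field in attrs.split(";"):
                if field.startswith("ID="):
                    name = field[3:]
                    break
            genes.append(Gene(contig=contig, start=s, end=e, strand=strand, name=name))
    return genes


def read_bed_genes(path: str | os.PathLike) -> list[Gene]:
    """Read gene models from BED6 (TSS inferred from strand)."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise GffError(f"{path}: line {ln}: expected >=6 BED columns")
            contig, start, end, name, _score, strand = parts[:6]
            genes.append(
                Gene(contig=contig, start=int(start), end=int(end), strand=strand, name=name)
            )
    return genes


def read_genes(path: str | os.PathLike) -> list[Gene]:
    p = os.fspath(path)
    if p.endswith((".gff", ".gff3")):
        return read_gff3_genes(p)
    return read_bed_genes(p)


# ------------------------------------------------------- region assignment

def classify_region(
    calls: list[MethylationCall],
    genes: list[Gene],
    promoter_halfwidth: int = 1000,
) -> tuple[list[str], dict[str, float]]:
    """Label each call promoter/genic/intergenic; return labels + fractions.

    The promoter window (TSS +/- halfwidth) takes precedence over genic
    so the three labels partition the calls and their fractions sum to 1.
    Calls on contigs absent from the gene model fall through to
    intergenic with a warning.
    """
    if not genes:
        raise ValueError("empty gene model")
    promoters: dict[str, IntervalTree] = {}
    transcripts: dict[str, IntervalTree] = {}
    for g in genes:
        promoters.setdefault(g.contig, IntervalTree()).addi(
            g.tss - promoter_halfwidth, g.tss + promoter_halfwidth + 1
        )
        if g.end > g.start:
            transcripts.setdefault(g.contig, IntervalTree()).addi(g.start, g.end)

    known_contigs = set(promoters)
    warned: set[str] = set()
    labels = []
    for call in calls:
        contig, pos = call.site.contig, call.site.adenine_pos
        if contig not in known_contigs:
            if contig not in warned:
                logger.warning("contig %r absent from gene model; calls labelled intergenic", contig)
                warned.add(contig)
            labels.append(REGION_INTERGENIC)
        elif promoters[contig].overlaps(pos):
            labels.append(REGION_PROMOTER)
        elif contig in transcripts and transcripts[contig].overlaps(pos):
            labels.append(REGION_GENIC)
        else:
            labels.append(REGION_INTERGENIC)
    total = len(labels)
    fractions = {
        region: (labels.count(region) / total if total else 0.0)
        for region in (REGION_PROMOTER, REGION_GENIC, REGION_INTERGENIC)
    }
    return labels, fractions


# ---------------------------------------------------------- metagene / TSS

@dataclass
class MetageneProfile:
    """Site density in fixed bins around all TSSs, transcription-oriented."""

    bin_edges: np.ndarray  # length nbins+1, from -W to +W
    density: np.ndarray    # sites per bp per TSS
    W: int
    b: int
    n_tss: int
    n_in_window: int

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    def to_tsv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "density": self.density,
            }
        ).to_csv(path, sep="\t", index=False)


def metagene_profile(
    calls: list[MethylationCall],
    genes: list[Gene],
    W: int = 2000,
    b: int = 10,
) -> MetageneProfile:
    """Aggregate site density as a function of oriented distance to TSS.

    Each site is assigned to the nearest same-contig TSS (ties broken
    toward the lower TSS coordinate); distance is positive downstream of
    transcription (flipped for '-' genes). Density is normalized by the
    number of TSSs and the bin width, so summing density * b * n_tss
    recovers the number of sites inside the window.
    """
    if (2 * W) % b != 0:
        raise ValueError("bin size b must divide the window 2W")
    if not genes:
        raise ValueError("empty gene model")
    nbins = 2 * W // b
    counts = np.zeros(nbins, dtype=np.int64)

    tss_by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig in {g.contig for g in genes}:
        sub = sorted((g.tss, 1 if g.strand == "+" else -1) for g in genes if g.contig == contig)
        pos = np.array([t for t, _ in sub], dtype=np.int64)
        sgn = np.array([s for _, s in sub], dtype=np.int64)
        tss_by_contig[contig] = (pos, sgn)

    n_in = 0
    for call in calls:
        if call.site.contig not in tss_by_contig:
            continue
        pos, sgn = tss_by_contig[call.site.contig]
        a = call.site.adenine_pos
        j = np.searchsorted(pos, a)
        # nearest TSS among neighbours; tie -> lower coordinate (left)
        best = None
        for cand in (j - 1, j):
            if 0 <= cand < len(pos):
                d = abs(a - pos[cand])
                if best is None or d < best[0]:
                    best = (d, cand)
        _, cand = best
        d_oriented = (a - pos[cand]) * sgn[cand]
        if -W <= d_oriented < W:
            counts[(d_oriented + W) // b] += 1
            n_in += 1

    n_tss = len(genes)
    density = counts / (n_tss * b)
    edges = np.arange(-W, W + 1, b)
    return MetageneProfile(
        bin_edges=edges, density=density, W=W, b=b, n_tss=n_tss, n_in_window=n_in
    )


def estimate_periodicity(
    profile: MetageneProfile,
    search_range: tuple[int, int] = (50, 500),
) -> tuple[int | None, float]:
    """Dominant spatial period of the metagene profile, by autocorrelation.

    Returns (period_bp, strength) where strength is the normalized
    autocorrelation of the mean-subtracted profile at the best lag, in
    [-1, 1]. A flat (zero-variance) profile returns (None, nan).
    """
    v = profile.density - profile.density.mean()
    denom = float(np.dot(v, v))
    if denom <= 0 or not np.isfinite(denom):
        return None, math.nan
    b = profile.b
    lo, hi = search_range
    min_lag = max(1, math.ceil(lo / b))
    max_lag = min(math.floor(hi / b), len(v) // 2)
    if max_lag < min_lag:
        return None, math.nan
    best_lag, best_r = None, -np.inf
    for lag in range(min_lag, max_lag + 1):
        r = float(np.dot(v[:-lag], v[lag:])) / denom
        if r > best_r:
            best_lag, best_r = lag, r
    return best_lag * b, best_r


# ------------------------------------------------------- sequence context

def context_breakdown(calls: list[MethylationCall]) -> dict[str, float]:
    """Fractions of significant calls per tetramer context group.

    The non-palindromic target is pooled as 'CATC/GATG' (the two readings
    of the same duplex motif); anything else lands in 'other'.
    """
    sig = [c for c in calls if c.corrected_significant]
    if not sig:
        return {}
    counts: dict[str, int] = {}
    for call in sig:
        if call.context == "GATC":
            group = "GATC"
        elif call.context in ("CATC", "GATG"):
            group = "CATC/GATG"
        else:
            group = "other"
        counts[group] = counts.get(group, 0) + 1
    total = len(sig)
    return {g: c / total for g, c in counts.items()}


@dataclass
class CompositionMatrix:
    """Per-offset base frequencies around called 6mA positions.

    Rows are offsets -F..+F relative to the methylated A, oriented so the
    A's strand reads 5'->3'; each row's four frequencies sum to 1, and
    the centre row is A with frequency 1 by construction.
    """

    offsets: np.ndarray
    freqs: np.ndarray  # shape (2F+1, 4), columns A,C,G,T
    n_sites: int
    n_skipped: int

    BASES = ("A", "C", "G", "T")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freqs, columns=list(self.BASES))
        df.insert(0, "offset", self.offsets)
        return df

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def composition_matrix(
    calls: list[MethylationCall],
    genome: Genome,
    flank: int = 10,
) -> CompositionMatrix:
    """Accumulated nucleotide composition of the called sites' flanks.

    Windows truncated by a contig edge, or containing N, are skipped and
    counted in n_skipped.
    """
    F = flank
    base_idx = {b: i for i, b in enumerate(CompositionMatrix.BASES)}
    counts = np.zeros((2 * F + 1, 4), dtype=np.int64)
    n_used = n_skipped = 0
    for call in calls:
        seq = genome[call.site.contig]
        a = call.site.adenine_pos
        if a - F < 0 or a + F + 1 > len(seq):
            n_skipped += 1
            continue
        window = seq[a - F : a + F + 1]
        if "N" in window:
            n_skipped += 1
            continue
        if call.site.strand == "-":
            window = revcomp(window)
        for i, base in enumerate(window):
            counts[i, base_idx[base]] += 1
        n_used += 1
    freqs = counts / n_used if n_used else counts.astype(float)
    return CompositionMatrix(
        offsets=np.arange(-F, F + 1),
        freqs=freqs,
        n_sites=n_used,
        n_skipped=n_skipped,
    )
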