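"""Read 5'-end extraction and per-site evidence collection.

The assay's entire signal is where read 5' ends fall: enzyme cleavage
concentrates 5' ends at fixed offsets inside the recognition motif while
sonication scatters them uniformly. This module turns alignments (SAM/BAM,
or lightweight BED interchange) into per-position, per-strand end counts
and, per candidate site, the pair of numbers the caller consumes:

  x         - read 5' ends at the site's expected cleavage positions
  spanning  - reads covering the whole motif without terminating at an
              expected cleavage position (evidence of uncut molecules)
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pysam

from .genome import Genome
from .motifs import MotifSite

STRAND_PLUS, STRAND_MINUS = 0, 1
_STRAND_CHAR = {STRAND_PLUS: "+", STRAND_MINUS: "-"}
_STRAND_CODE = {"+": STRAND_PLUS, "-": STRAND_MINUS}


@dataclass
class ReadSet:
    """Aligned reads as per-contig coordinate arrays (start, end, strand).

    Coordinates are 0-based half-open on the forward reference; strand is
    0 for '+' and 1 for '-'. The 5' end of a plus read is its start, of a
    minus read its end-1.
    """

    reads: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)
    n_filtered: int = 0
    library_label: str = ""

    @property
    def n_reads(self) -> int:
        return sum(len(s) for s, _, _ in self.reads.values())

    def add_contig(self, contig: str, starts, ends, strands) -> None:
        self.reads[contig] = (
            np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64),
            np.asarray(strands, dtype=np.int8),
        )

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_sam(
        cls,
        path: str | os.PathLike,
        genome: Genome | None = None,
        min_mapq: int = 10,
        keep_clipped: bool = False,
        library_label: str = "",
    ) -> "ReadSet":
        """Load retained alignments from SAM/BAM.

        Unmapped, secondary, supplementary and duplicate records are
        dropped, as are records below the mapping-quality threshold.
        Reads soft-clipped at their 5' end are dropped by default because
        clipping obscures the true fragment end; pass keep_clipped=True
        to retain them (their aligned 5' position is used).
        """
        path = os.fspath(path)
        by_contig: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
        n_filtered = 0
        mode = "rb" if path.endswith(".bam") else "r"
        with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
            for aln in fh:
                if (
                    aln.is_unmapped
                    or aln.is_secondary
                    or aln.is_supplementary
                    or aln.is_duplicate
                    or aln.mapping_quality < min_mapq
                ):
                    n_filtered += 1
                    continue
                contig = aln.reference_name
                if genome is not None and contig not in genome:
                    raise ValueError(
                        f"alignment contig {contig!r} absent from the genome"
                    )
                cig = aln.cigartuples or []
                if not keep_clipped and cig:
                    # 5' end is the first cigar op for '+', last for '-'
                    op = cig[-1][0] if aln.is_reverse else cig[0][0]
                    if op == 4:  # soft clip at the 5' end of interest
                        n_filtered += 1
                        continue
                strand = STRAND_MINUS if aln.is_reverse else STRAND_PLUS
                by_contig[contig].append(
                    (aln.reference_start, aln.reference_end, strand)
                )
        rs = cls(n_filtered=n_filtered, library_label=library_label)
        for contig, rows in by_contig.items():
            arr = np.array(rows, dtype=np.int64)
            rs.add_contig(contig, arr[:, 0], arr[:, 1], arr[:, 2])
        return rs

    @classmethod
    def from_bed(cls, path: str | os.PathLike, library_label: str = "") -> "ReadSet":
        """Load reads from a 6-column interval BED (one read per line)."""
        by_contig: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}:{ln}: expected >=6 BED columns")
                contig, start, end, _name, _score, strand = parts[:6]
                by_contig[contig].append(
                    (int(start), int(end), _STRAND_CODE[strand])
                )
        rs = cls(library_label=library_label)
        for contig, rows in by_contig.items():
            arr = np.array(rows, dtype=np.int64)
            rs.add_contig(contig, arr[:, 0], arr[:, 1], arr[:, 2])
        return rs

    def to_bed(self, path: str | os.PathLike, name: str = "read") -> None:
        with open(path, "w") as fh:
            for contig, (starts, ends, strands) in self.reads.items():
                for a, b, st in zip(starts, ends, strands):
                    fh.write(
                        f"{contig}\t{a}\t{b}\t{name}\t0\t{_STRAND_CHAR[int(st)]}\n"
                    )

    def to_sam(self, path: str | os.PathLike, genome: Genome) -> None:
        """Write a minimal SAM (no sequence/quality, MAPQ 60)."""
        header = {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [
                {"SN": name, "LN": len(seq)}
                for name, seq in genome.sequences.items()
            ],
        }
        with pysam.AlignmentFile(os.fspath(path), "w", header=header) as out:
            i = 0
            for contig, (starts, ends, strands) in self.reads.items():
                tid = out.get_tid(contig)
                for a, b, st in zip(starts, ends, strands):
                    rec = pysam.AlignedSegment(out.header)
                    rec.query_name = f"r{i}"
                    rec.flag = 16 if st == STRAND_MINUS else 0
                    rec.reference_id = tid
                    rec.reference_start = int(a)
                    rec.mapping_quality = 60
                    rec.cigartuples = [(0, int(b - a))]
                    out.write(rec)
                    i += 1


@dataclass
class EndCountTrack:
    """Sparse per-position, per-strand counts of read 5' ends.

    n is the number of retained reads the track was built from; it is the
    binomial n of the caller's null model.
    """

    counts: dict[tuple[str, str], dict[int, int]] = field(default_factory=dict)
    n: int = 0
    n_filtered: int = 0
    library_label: str = ""

    def count_at(self, contig: str, pos: int, strand: str) -> int:
        return self.counts.get((contig, strand), {}).get(pos, 0)

    def add(self, contig: str, pos: int, strand: str, count: int = 1) -> None:
        d = self.counts.setdefault((contig, strand), {})
        d[pos] = d.get(pos, 0) + count
        self.n += count

    def total_ends(self) -> int:
        return sum(sum(d.values()) for d in self.counts.values())

    def to_bedgraph(self, path_prefix: str) -> None:
        """Write one bedGraph per strand: <prefix>.plus.bedgraph etc."""
        for strand, tag in (("+", "plus"), ("-", "minus")):
            with open(f"{path_prefix}.{tag}.bedgraph", "w") as fh:
                for (contig, st), d in sorted(self.counts.items()):
                    if st != strand:
                        continue
                    for pos in sorted(d):
                        fh.write(f"{contig}\t{pos}\t{pos + 1}\t{d[pos]}\n")

    def to_end_bed(self, path: str | os.PathLike) -> None:
        """Write ends as BED6 with the count in the score column."""
        with open(path, "w") as fh:
            for (contig, strand), d in sorted(self.counts.items()):
                for pos in sorted(d):
                    fh.write(f"{contig}\t{pos}\t{pos + 1}\tend\t{d[pos]}\t{strand}\n")

    @classmethod
    def from_end_bed(cls, path: str | os.PathLike, library_label: str = "") -> "EndCountTrack":
        """Read the BED6 end interchange (score column = end count)."""
        track = cls(library_label=library_label)
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}:{ln}: expected >=6 BED columns")
                contig, pos, _end, _name, count, strand = parts[:6]
                track.add(contig, int(pos), strand, int(count))
        return track


@dataclass
class SiteEvidence:
    """Per-site caller input: cut-end count x and spanning-read count.

    n_end_positions is the number of genomic (position, strand) cells
    aggregated into x; the caller multiplies the per-position background
    probability by it.
    """

    site: MotifSite
    x: int
    spanning: int
    n_end_positions: int


def extract_ends(
    reads: ReadSet | str | os.PathLike,
    genome: Genome | None = None,
    min_mapq: int = 10,
    keep_clipped: bool = False,
    library_label: str = "",
) -> EndCountTrack:
    """Tally read 5' ends per (contig, position, strand).

    Accepts a ReadSet or a SAM/BAM path. Every retained read contributes
    exactly one end, so the track's counts sum to n.
    """
    if not isinstance(reads, ReadSet):
        reads = ReadSet.from_sam(
            reads, genome=genome, min_mapq=min_mapq,
            keep_clipped=keep_clipped, library_label=library_label,
        )
    track = EndCountTrack(
        n_filtered=reads.n_filtered,
        library_label=library_label or reads.library_label,
    )
    for contig, (starts, ends, strands) in reads.reads.items():
        if genome is not None and contig not in genome:
            raise ValueError(f"read contig {contig!r} absent from the genome")
        for strand_code, strand_char in _STRAND_CHAR.items():
            mask = strands == strand_code
            if not mask.any():
                continue
            pos5 = starts[mask] if strand_code == STRAND_PLUS else ends[mask] - 1
            uniq, cnt = np.unique(pos5, return_counts=True)
            d = track.counts.setdefault((contig, strand_char), {})
            for p, c in zip(uniq, cnt):
                d[int(p)] = d.get(int(p), 0) + int(c)
            track.n += int(mask.sum())
    return track


def _expected_window(site: MotifSite, jitter: int) -> list[tuple[int, str]]:
    out = []
    for pos, strand in site.expected_end_positions:
        for dp in range(-jitter, jitter + 1):
            out.append((pos + dp, strand))
    return out


def evidence_from_track(
    track: EndCountTrack,
    sites: list[MotifSite],
    jitter: int = 0,
) -> list[SiteEvidence]:
    """Site evidence from an end track alone (spanning counts unavailable).

    Used for the lightweight end-BED path; spanning is reported as 0, so
    methylation levels are not meaningful but significance calls are.
    """
    out = []
    for site in sites:
        window = _expected_window(site, jitter)
        x = sum(track.count_at(site.contig, p, s) for p, s in window)
        out.append(SiteEvidence(site=site, x=x, spanning=0, n_end_positions=len(window)))
    return out


def collect_site_evidence(
    track: EndCountTrack,
    sites: list[MotifSite],
    reads: ReadSet | None = None,
    jitter: int = 0,
) -> list[SiteEvidence]:
    """Per-site cut-end and spanning-read counts.

    x sums end counts over the site's expected end positions, optionally
    widened by +/-jitter bp to absorb end-repair artifacts. A spanning
    read must cover the site's full motif interval and must not have its
    5' end at any expected (jitter-widened) end position. Output order
    follows the input site order.
    """
    if reads is None:
        return evidence_from_track(track, sites, jitter=jitter)

    spanning = _spanning_counts(sites, reads, jitter)
    out = []
    for site, span in zip(sites, spanning):
        window = _expected_window(site, jitter)
        x = sum(track.count_at(site.contig, p, s) for p, s in window)
        out.append(
            SiteEvidence(site=site, x=x, spanning=int(span), n_end_positions=len(window))
        )
    return out


def _spanning_counts(sites: list[MotifSite], reads: ReadSet, jitter: int) -> np.ndarray:
    """Vectorized spanning-read counts, one per input site.

    Reads covering [start, start+L) are counted with a difference-array
    sweep over sites sorted by start (grouped per contig and motif
    length); reads terminating at an expected end position are then
    subtracted. For interior cut registers the subtraction is a no-op
    because a read ending inside the motif cannot cover it.
    """
    counts = np.zeros(len(sites), dtype=np.int64)
    by_group: dict[tuple[str, int], list[int]] = defaultdict(list)
    for i, site in enumerate(sites):
        by_group[(site.contig, site.length)].append(i)

    for (contig, L), idx in by_group.items():
        if contig not in reads.reads:
            continue
        starts, ends, strands = reads.reads[contig]
        order = sorted(idx, key=lambda i: sites[i].start)
        s_starts = np.array([sites[i].start for i in order], dtype=np.int64)
        # read [a,b) covers site [s,s+L) iff s >= a and s <= b-L
        i0 = np.searchsorted(s_starts, starts, side="left")
        i1 = np.searchsorted(s_starts, ends - L, side="right")
        valid = i1 > i0
        diff = np.zeros(len(order) + 1, dtype=np.int64)
        np.add.at(diff, i0[valid], 1)
        np.add.at(diff, i1[valid], -1)
        cover = np.cumsum(diff[:-1])

        # subtract covering reads whose 5' end sits at an expected position
        plus_by_start = None
        minus_by_end = None
        for k, i in enumerate(order):
            site = sites[i]
            correction = 0
            for pos, strand in _expected_window(site, jitter):
                if strand == "+" and pos <= site.start:
                    if plus_by_start is None:
                        plus_by_start = _index_reads(starts, ends, strands, STRAND_PLUS, key="start")
                    for b in plus_by_start.get(pos, ()):
                        if b >= site.end:
                            correction += 1
                elif strand == "-" and pos >= site.end - 1:
                    if minus_by_end is None:
                        minus_by_end = _index_reads(starts, ends, strands, STRAND_MINUS, key="end")
                    for a in minus_by_end.get(pos, ()):
                        if a <= site.start:
                            correction += 1
            counts[i] = cover[k] - correction
    return counts


def _index_reads(starts, ends, strands, strand_code, key):
    d: dict[int, list[int]] = defaultdict(list)
    mask = strands == strand_code
    if key == "start":
        for a, b in zip(starts[mask], ends[mask]):
            d[int(a)].append(int(b))
    else:
        for a, b in zip(starts[mask], ends[mask]):
            d[int(b) - 1].append(int(a))
    return d
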