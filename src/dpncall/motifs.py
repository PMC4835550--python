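"""Recognition-motif scanning and expected cleavage-end geometry.

A methylation-sensitive restriction enzyme (DpnI here) cuts duplex DNA at
short recognition motifs carrying N6-methyladenine. A double-strand blunt
cut at offset ``c`` inside a motif occurrence [s, s+L) leaves a 5' fragment
end at s+c on the plus strand and at s+c-1 on the minus strand; those two
positions are where digestion-derived read 5' ends pile up, and they are the
positions the caller tests.

DpnI's canonical target is the palindrome GATC (cut GA^TC). It additionally
cleaves fully methylated CATC/GATG, which is non-palindromic: a CATC
occurrence on the minus strand appears as GATG in the forward reference.
The default cut register for CATC/GATG mirrors the GATC chemistry (blunt,
between A and T) and is configurable per motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genome import Genome, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MotifSpec:
    """An exact-match recognition motif.

    adenine_offset: 0-based index of the methylatable A within the motif.
    cut_offset: 0-based offset of the blunt double-strand cut, i.e. the 5'
        end of the downstream fragment on the motif-bearing strand.
    """

    name: str
    sequence: str
    adenine_offset: int = 1
    cut_offset: int = 2

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if set(seq) - set("ACGT"):
            raise ValueError(f"motif {self.name!r}: non-ACGT characters in {seq!r}")
        if not 0 <= self.adenine_offset < len(seq):
            raise ValueError(f"motif {self.name!r}: adenine_offset out of range")
        if seq[self.adenine_offset] != "A":
            raise ValueError(
                f"motif {self.name!r}: base at adenine_offset is "
                f"{seq[self.adenine_offset]!r}, expected 'A'"
            )
        if not 0 <= self.cut_offset <= len(seq):
            raise ValueError(f"motif {self.name!r}: cut_offset out of range")

    @property
    def palindromic(self) -> bool:
        return self.sequence == revcomp(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


#: DpnI motif set: GATC (GA^TC) plus the non-palindromic CATC/GATG target.
DPNI_MOTIFS = (
    MotifSpec("GATC", "GATC", adenine_offset=1, cut_offset=2),
    MotifSpec("CATC", "CATC", adenine_offset=1, cut_offset=2),
)

#: DpnII cuts unmethylated GATC. Real DpnII leaves a 5' overhang at ^GATC;
#: end repair during library construction blunts it, so a blunt cut at the
#: motif start is the working approximation for read-end geometry.
DPNII_MOTIFS = (MotifSpec("GATC", "GATC", adenine_offset=1, cut_offset=0),)


@dataclass
class CleavageModel:
    """Per-motif, per-methylation-status cut register and efficiency.

    efficiencies map (motif_name, status) -> probability that one molecule
    carrying that status is cut at the site. Statuses: 'full', 'hemi',
    'unmethylated'.
    """

    cut_offsets: dict[str, int] = field(default_factory=dict)
    efficiencies: dict[tuple[str, str], float] = field(default_factory=dict)

    def cut_offset(self, spec: MotifSpec) -> int:
        return self.cut_offsets.get(spec.name, spec.cut_offset)

    def efficiency(self, motif_name: str, status: str) -> float:
        return self.efficiencies.get((motif_name, status), 0.0)


@dataclass(frozen=True)
class MotifSite:
    """One candidate methylatable locus.

    start is the 0-based forward-reference start of the motif occurrence;
    strand is the strand on which the motif reads 5'->3'. Palindromic
    occurrences are reported once, on '+'. adenine_pos is the forward
    coordinate of the methylatable A on the motif strand.
    expected_end_positions are the (position, strand) pairs where
    enzyme-generated read 5' ends are expected.
    """

    contig: str
    start: int
    strand: str
    motif_name: str
    adenine_pos: int
    length: int
    expected_end_positions: tuple[tuple[int, str], ...]

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.start, self.strand)


def expected_ends(
    spec: MotifSpec,
    start: int,
    strand: str,
    model: CleavageModel | None = None,
) -> tuple[tuple[int, str], ...]:
    """Expected read 5'-end positions for a blunt double-strand cut.

    For a motif occurrence on '+' at [s, s+L) with cut offset c the cut
    falls between s+c-1 and s+c: the downstream fragment starts at s+c
    (plus-strand 5' end) and the upstream fragment's minus-strand read has
    its 5' end at s+c-1. On a '-' occurrence the offsets mirror.
    """
    c = model.cut_offset(spec) if model is not None else spec.cut_offset
    L = len(spec)
    if strand == "+":
        cut = start + c
    elif strand == "-":
        cut = start + L - c
    else:
        raise ValueError(f"invalid strand {strand!r}")
    return ((cut, "+"), (cut - 1, "-"))


def _site(
    spec: MotifSpec,
    contig: str,
    start: int,
    strand: str,
    model: CleavageModel | None,
) -> MotifSite:
    L = len(spec)
    if strand == "+":
        a_pos = start + spec.adenine_offset
    else:
        a_pos = start + L - 1 - spec.adenine_offset
    return MotifSite(
        contig=contig,
        start=start,
        strand=strand,
        motif_name=spec.name,
        adenine_pos=a_pos,
        length=L,
        expected_end_positions=expected_ends(spec, start, strand, model),
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) occurrence starts of needle in haystack."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def scan_motifs(
    genome: Genome,
    specs: list[MotifSpec] | tuple[MotifSpec, ...] = DPNI_MOTIFS,
    model: CleavageModel | None = None,
) -> list[MotifSite]:
    """Enumerate every motif occurrence on both strands of the genome.

    Palindromic motifs are reported once per locus (strand '+', ends on
    both strands). Occurrences overlapping an N are skipped and counted in
    a log summary. Output is sorted by (contig, start, strand, motif).
    """
    if not specs:
        raise ValueError("empty motif spec list")
    sites: list[MotifSite] = []
    n_skipped = 0
    for contig, seq in genome.sequences.items():
        for spec in specs:
            motif = spec.sequence
            for s in _find_all(seq, motif):
                sites.append(_site(spec, contig, s, "+", model))
            if spec.palindromic:
                continue
            rc = revcomp(motif)
            for s in _find_all(seq, rc):
                sites.append(_site(spec, contig, s, "-", model))
        if "N" in seq:
            # exact find() can never match through an N, but count candidate
            # windows lost to Ns for the log
            n_skipped += seq.count("N")
    if n_skipped:
        logger.info("scan_motifs: %d N bases in genome; motifs overlapping N skipped", n_skipped)
    sites.sort(key=lambda s: (s.contig, s.start, s.strand, s.motif_name))
    return sites


def forward_context(genome: Genome, site: MotifSite) -> str:
    """Tetramer (motif-length) context as read on the forward reference."""
    return genome[site.contig][site.start : site.end]


def sites_to_bed(sites: list[MotifSite], path: str) -> None:
    """Write sites as BED6 (0-based, name=motif, score=0)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.motif_name}\t0\t{s.strand}\n")
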