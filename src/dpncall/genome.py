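"""Reference genome container and FASTA I/O.

Sequences are held in memory as plain uppercase strings, which is adequate
for the microbial-scale genomes this tool targets (tens of megabases).
Coordinates everywhere in this package are 0-based, half-open; 1-based
conventions (SAM, GFF3) are converted at the I/O boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(COMPLEMENT)[::-1]


class FastaError(ValueError):
    """Raised when a FASTA record cannot be parsed or validated."""


@dataclass
class Genome:
    """A reference genome: contig name -> uppercase sequence.

    ``gs`` (genome size) is the summed contig length; it is the denominator
    of the per-position background probability used by the caller.
    """

    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def gs(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences

    def __getitem__(self, contig: str) -> str:
        return self.sequences[contig]

    def contigs(self) -> list[str]:
        return list(self.sequences)


def read_genome(fasta_path: str | os.PathLike) -> Genome:
    """Read a (possibly multi-record, line-wrapped) FASTA into a Genome.

    Sequences are uppercased. Records containing characters outside
    A/C/G/T/N, duplicate contig names, or empty files raise FastaError
    naming the offending record.
    """
    fasta_path = os.fspath(fasta_path)
    if not os.path.exists(fasta_path):
        raise FileNotFoundError(fasta_path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(fasta_path, "fasta"):
        name = record.id
        if not name:
            raise FastaError(f"{fasta_path}: record with empty header")
        if name in sequences:
            raise FastaError(f"{fasta_path}: duplicate contig name {name!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise FastaError(
                f"{fasta_path}: record {name!r} contains non-ACGTN "
                f"characters {sorted(bad)!r}"
            )
        sequences[name] = seq
    if not sequences:
        raise FastaError(f"{fasta_path}: no FASTA records found")
    return Genome(sequences)


def write_genome(genome: Genome, fasta_path: str | os.PathLike, width: int = 70) -> None:
    """Write a Genome as wrapped FASTA."""
    with open(fasta_path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
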