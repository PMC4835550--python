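import numpy as np
import pysam
import pytest

from dpncall import Genome, MotifSite
from dpncall.motifs import expected_ends as _expected_ends, MotifSpec


@pytest.fixture
def write_fasta(tmp_path):
    """Write a dict of contig -> sequence as a FASTA file, return the path."""

    def _write(sequences, name="genome.fa", width=60):
        path = tmp_path / name
        with open(path, "w") as fh:
            for contig, seq in sequences.items():
                fh.write(f">{contig}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        return str(path)

    return _write


@pytest.fixture
def write_sam(tmp_path):
    """Write reads [(contig, start, end, strand, mapq, flag_extra, cigar)] as SAM."""

    def _write(reads, contig_lengths, name="reads.sam"):
        path = tmp_path / name
        header = {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": c, "LN": ln} for c, ln in contig_lengths.items()],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for i, read in enumerate(reads):
                contig, start, end, strand = read[:4]
                mapq = read[4] if len(read) > 4 else 60
                flag_extra = read[5] if len(read) > 5 else 0
                cigar = read[6] if len(read) > 6 else [(0, end - start)]
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = f"r{i}"
                rec.flag = (16 if strand == "-" else 0) | flag_extra
                rec.reference_id = out.get_tid(contig)
                rec.reference_start = start
                rec.mapping_quality = mapq
                rec.cigartuples = cigar
                out.write(rec)
        return str(path)

    return _write


def make_site(contig="c1", start=100, strand="+", motif="GATC", cut_offset=2,
              adenine_offset=1):
    """A MotifSite with the default blunt-cut end geometry."""
    spec = MotifSpec(motif, motif, adenine_offset=adenine_offset, cut_offset=cut_offset)
    L = len(motif)
    a_pos = start + adenine_offset if strand == "+" else start + L - 1 - adenine_offset
    return MotifSite(
        contig=contig,
        start=start,
        strand=strand,
        motif_name=motif,
        adenine_pos=a_pos,
        length=L,
        expected_end_positions=_expected_ends(spec, start, strand),
    )


def naive_find(seq: str, motif: str) -> list[int]:
    """Brute-force O(n*m) substring search (overlaps included)."""
    L = len(motif)
    return [i for i in range(len(seq) - L + 1) if seq[i : i + L] == motif]


@pytest.fixture
def rng():
    return np.random.default_rng(20160415)
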