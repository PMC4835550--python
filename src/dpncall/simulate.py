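"""Generative model of the restriction-digestion sequencing assay.

Emulates the wet-lab workflow well enough to exercise every pipeline
stage with known truth: a random genome, a per-site methylation truth
(unmethylated / hemi / full, plus a per-site molecule-level methylation
fraction q for partially methylated regimes), status- and motif-dependent
enzymatic cleavage at the model's cut register, then uniform random
shearing to a configurable mean fragment length (Poisson breakage), with
each fragment emitting one read per strand from its two ends.

Enzymatic cutting is applied before shearing, matching the protocol
order. Reads are exact fragment copies with no sequencing-error model;
alignment is assumed perfect since mapping is upstream of this tool.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .genome import Genome
from .motifs import (
    CleavageModel,
    DPNI_MOTIFS,
    DPNII_MOTIFS,
    MotifSite,
    MotifSpec,
    scan_motifs,
)
from .readends import ReadSet

STATUS_UNMETHYLATED = "unmethylated"
STATUS_HEMI = "hemi"
STATUS_FULL = "full"

#: Overnight (12 h) digestion: full sites cut efficiently in both contexts,
#: hemi GATC partially, hemi CATC/GATG essentially never.
DPNI_EFFICIENCIES_OVERNIGHT = {
    ("GATC", STATUS_FULL): 0.95,
    ("GATC", STATUS_HEMI): 0.3,
    ("CATC", STATUS_FULL): 0.9,
    ("CATC", STATUS_HEMI): 0.0,
}

#: 30-minute digestion: the enzyme is strongly full-methylation-specific
#: in a limited time window; hemi GATC is barely touched and the
#: non-palindromic context needs long incubation. This is the preset the
#: dual-enzyme (full vs hemi) classification relies on.
DPNI_EFFICIENCIES_30MIN = {
    ("GATC", STATUS_FULL): 0.95,
    ("GATC", STATUS_HEMI): 0.05,
    ("CATC", STATUS_FULL): 0.2,
    ("CATC", STATUS_HEMI): 0.0,
}

#: The complementary enzyme cuts only unmethylated GATC.
DPNII_EFFICIENCIES = {("GATC", STATUS_UNMETHYLATED): 0.95}

EFFICIENCY_PRESETS = {
    "overnight": DPNI_EFFICIENCIES_OVERNIGHT,
    "30min": DPNI_EFFICIENCIES_30MIN,
}


@dataclass
class SimParams:
    """Study conditions for one simulated library.

    q is the molecule-level methylation fraction of a methylated site:
    1.0 models clonal (full/hemi on every molecule) methylation; the
    'uniform' mode draws q from q_range, emulating genomes where most
    sites are methylated in only a small fraction of cells.
    """

    genome_length: int = 1_000_000
    gc_content: float = 0.5
    contig_name: str = "sim1"
    methylated_fraction: float = 0.02
    full_fraction: float = 1.0
    efficiencies: dict = field(default_factory=lambda: dict(DPNI_EFFICIENCIES_OVERNIGHT))
    mean_fragment_length: float = 300.0
    coverage: float = 50.0
    read_length: int | None = None  # None: the read is the whole fragment
    q_mode: str = "point"  # 'point' or 'uniform'
    q_value: float = 1.0
    q_range: tuple[float, float] = (0.01, 0.10)
    seed: int = 0

    def __post_init__(self):
        for name in ("gc_content", "methylated_fraction", "full_fraction", "q_value"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0 < self.gc_content < 1:
            raise ValueError(f"gc_content must be in (0,1), got {self.gc_content}")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.mean_fragment_length <= 1:
            raise ValueError("mean_fragment_length must exceed 1 bp")

    def to_json(self, path: str | os.PathLike) -> None:
        d = asdict(self)
        d["efficiencies"] = {f"{m}:{s}": v for (m, s), v in self.efficiencies.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)


@dataclass
class SimTruth:
    """Ground-truth methylation assignment over the scanned motif sites."""

    sites: list[MotifSite]
    status: np.ndarray  # of str
    q: np.ndarray       # molecule-level methylation fraction per site

    def status_by_key(self) -> dict[tuple[str, int, str], str]:
        return {s.key: st for s, st in zip(self.sites, self.status)}

    def methylated_keys(self) -> set[tuple[str, int, str]]:
        return {
            s.key
            for s, st in zip(self.sites, self.status)
            if st != STATUS_UNMETHYLATED
        }

    def to_bed(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for s, st, q in zip(self.sites, self.status, self.q):
                fh.write(
                    f"{s.contig}\t{s.start}\t{s.end}\t{s.motif_name}:{st}:{q:.4f}"
                    f"\t0\t{s.strand}\n"
                )


def make_genome(
    length: int,
    gc_content: float = 0.5,
    seed: int | np.random.Generator = 0,
    contig_name: str = "sim1",
) -> Genome:
    """I.i.d. random genome with the stated GC content (deterministic per seed)."""
    if not 0 < gc_content < 1:
        raise ValueError(f"gc_content must be in (0,1), got {gc_content}")
    if length < 1000:
        raise ValueError("genome length must be >= 1 kb")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    at, gc = (1 - gc_content) / 2, gc_content / 2
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=[at, gc, gc, at])
    return Genome({contig_name: bases.tobytes().decode("ascii")})


def assign_truth(
    sites: list[MotifSite],
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> SimTruth:
    """Bernoulli site selection and full/hemi split per the study conditions."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    n = len(sites)
    status = np.full(n, STATUS_UNMETHYLATED, dtype=object)
    q = np.zeros(n)
    methylated = rng.random(n) < params.methylated_fraction
    full = rng.random(n) < params.full_fraction
    status[methylated & full] = STATUS_FULL
    status[methylated & ~full] = STATUS_HEMI
    if params.q_mode == "point":
        q[methylated] = params.q_value
    elif params.q_mode == "uniform":
        lo, hi = params.q_range
        q[methylated] = rng.uniform(lo, hi, size=int(methylated.sum()))
    else:
        raise ValueError(f"unknown q_mode {params.q_mode!r}")
    return SimTruth(sites=list(sites), status=status, q=q)


def _cleavage_model(params: SimParams, specs) -> CleavageModel:
    return CleavageModel(
        cut_offsets={s.name: s.cut_offset for s in specs},
        efficiencies=dict(params.efficiencies),
    )


def simulate_reads(
    genome: Genome,
    truth: SimTruth,
    params: SimParams,
    rng: np.random.Generator | None = None,
    enzyme: str = "dpnI",
) -> ReadSet:
    """Digest, shear and sequence the genome against the truth.

    Per molecule (one of round(coverage) genome copies): each site is cut
    with probability q_site * efficiency(motif, status) for the
    methylation-directed enzyme, or (1 - q_site) * efficiency(motif,
    'unmethylated') for the methylation-blocked one; random shear break
    points follow a Poisson process at rate 1/mean_fragment_length; the
    resulting fragments each emit a plus-strand and a minus-strand read.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    n_molecules = max(1, int(round(params.coverage)))

    # per-site cut probability and cut coordinate (the blunt break point)
    cut_probs = np.empty(len(truth.sites))
    cut_pos = np.empty(len(truth.sites), dtype=np.int64)
    contigs = np.array([s.contig for s in truth.sites], dtype=object)
    for i, (site, status, q) in enumerate(zip(truth.sites, truth.status, truth.q)):
        cut_pos[i] = site.expected_end_positions[0][0]  # plus-strand 5' end
        if enzyme == "dpnI":
            eff = params.efficiencies.get((site.motif_name, status), 0.0)
            cut_probs[i] = q * eff
        elif enzyme == "dpnII":
            eff = params.efficiencies.get((site.motif_name, STATUS_UNMETHYLATED), 0.0)
            cut_probs[i] = (1.0 - q) * eff
        else:
            raise ValueError(f"unknown enzyme {enzyme!r}")

    out = ReadSet(library_label=f"sim-{enzyme}")
    for contig, seq in genome.sequences.items():
        L = len(seq)
        in_contig = contigs == contig
        c_probs = cut_probs[in_contig]
        c_pos = cut_pos[in_contig]
        starts_all, ends_all = [], []
        for _ in range(n_molecules):
            cuts = c_pos[rng.random(len(c_probs)) < c_probs]
            n_shear = rng.poisson(L / params.mean_fragment_length)
            shears = rng.integers(1, L, size=n_shear)
            breaks = np.unique(np.concatenate([[0, L], cuts, shears]))
            starts_all.append(breaks[:-1])
            ends_all.append(breaks[1:])
        frag_starts = np.concatenate(starts_all)
        frag_ends = np.concatenate(ends_all)
        # both fragment ends are sequenced: one read per strand
        r_starts = np.concatenate([frag_starts, frag_starts])
        r_ends = np.concatenate([frag_ends, frag_ends])
        r_strands = np.concatenate(
            [np.zeros(len(frag_starts), dtype=np.int8), np.ones(len(frag_ends), dtype=np.int8)]
        )
        if params.read_length is not None:
            rl = params.read_length
            plus = r_strands == 0
            r_ends = np.where(plus, np.minimum(r_ends, r_starts + rl), r_ends)
            r_starts = np.where(~plus, np.maximum(r_starts, r_ends - rl), r_starts)
        out.add_contig(contig, r_starts, r_ends, r_strands)
    return out


def uniform_end_track(
    genome: Genome,
    n_ends: int,
    rng: np.random.Generator,
    library_label: str = "sim-null",
):
    """Null library: n read 5' ends placed uniformly over the genome.

    Models random shearing with no enzymatic cutting at all; used for
    false-positive-rate calibration of the caller.
    """
    from .readends import EndCountTrack

    track = EndCountTrack(library_label=library_label)
    contigs = list(genome.sequences)
    lengths = np.array([len(genome.sequences[c]) for c in contigs], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    flat = rng.integers(0, offsets[-1], size=n_ends)
    strands = rng.integers(0, 2, size=n_ends)
    for ci, contig in enumerate(contigs):
        in_c = (flat >= offsets[ci]) & (flat < offsets[ci + 1])
        for strand_code, strand in ((0, "+"), (1, "-")):
            pos = flat[in_c & (strands == strand_code)] - offsets[ci]
            uniq, cnt = np.unique(pos, return_counts=True)
            d = track.counts.setdefault((contig, strand), {})
            for p, c in zip(uniq, cnt):
                d[int(p)] = int(c)
            track.n += int(pos.size)
    return track


def dpnII_mode(
    genome: Genome,
    truth: SimTruth,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> ReadSet:
    """Complementary library: cleave unmethylated GATC, blocked by 6mA.

    Only GATC sites are valid for this enzyme; the truth must come from a
    GATC-only scan. The cut register is the motif start (the enzyme's 5'
    overhang is blunted during end repair).
    """
    for site in truth.sites:
        if site.motif_name != "GATC":
            raise ValueError(
                f"dpnII digestion is GATC-only, got {site.motif_name!r} "
                f"at {site.contig}:{site.start}"
            )
    dpnII_params = SimParams(**{**asdict(params), "efficiencies": dict(DPNII_EFFICIENCIES)})
    # re-register truth sites on the dpnII cut offset
    spec = DPNII_MOTIFS[0]
    model = _cleavage_model(dpnII_params, DPNII_MOTIFS)
    resited = scan_sites_like(truth.sites, spec, model)
    truth_II = SimTruth(sites=resited, status=truth.status, q=truth.q)
    return simulate_reads(genome, truth_II, dpnII_params, rng=rng, enzyme="dpnII")


def scan_sites_like(
    sites: list[MotifSite],
    spec: MotifSpec,
    model: CleavageModel,
) -> list[MotifSite]:
    """Re-derive expected end positions of existing sites under another cut model."""
    from .motifs import _site

    return [_site(spec, s.contig, s.start, s.strand, model) for s in sites]


def simulate_library(
    params: SimParams,
    specs=DPNI_MOTIFS,
    enzyme: str = "dpnI",
) -> tuple[Genome, list[MotifSite], SimTruth, ReadSet]:
    """One-call convenience: genome, motif sites, truth and reads."""
    rng = np.random.default_rng(params.seed)
    genome = make_genome(params.genome_length, params.gc_content, rng, params.contig_name)
    model = _cleavage_model(params, specs)
    sites = scan_motifs(genome, specs, model)
    truth = assign_truth(sites, params, rng)
    if enzyme == "dpnII":
        reads = dpnII_mode(genome, truth, params, rng)
    else:
        reads = simulate_reads(genome, truth, params, rng, enzyme=enzyme)
    return genome, sites, truth, reads
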