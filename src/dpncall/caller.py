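"""Binomial read-end test, multiple-testing control and site classification.

Null model: each of n retained reads is randomly sheared and maps its 5'
end to any single genomic position with probability 1/gs (gs = genome
size). A site aggregating k end positions (two for a blunt double-strand
cut, more with a jitter window) therefore accumulates ends as
X ~ Binomial(n, k/gs), and the evidence against the null at observed count
x is the upper tail P(X >= x). P-values are Bonferroni-corrected across
the m tested sites at alpha = 0.01 by default (a Benjamini-Hochberg mode
is also provided), i.e. the design keeps the expected false-positive rate
among motif sites below 1%.

Methylation level at a site is estimated as x / (x + spanning): the
fraction of site-informative reads that arose from enzymatic cleavage
rather than from random shearing across an uncut molecule. A significant
site with more spanning than cut reads is classified "partial" (only a
minority of molecules carry the mark); otherwise "high".
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .genome import Genome
from .motifs import MotifSite, MotifSpec, expected_ends, forward_context
from .readends import SiteEvidence

STATUS_UNMETHYLATED = "unmethylated"
STATUS_PARTIAL = "partial"
STATUS_HIGH = "high"


@dataclass
class BinomialNull:
    """Null model parameters.

    p is the per-position background probability 1/gs; the caller scales
    it by each site's number of aggregated end positions. m is the test
    family size (number of tested sites) used for correction.
    """

    n: int
    p: float
    m: int
    alpha: float = 0.01

    def __post_init__(self):
        if not 0 < self.p < 1:
            raise ValueError(f"p must be in (0,1), got {self.p}")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n < 0:
            raise ValueError("n must be non-negative")

    @classmethod
    def from_genome(cls, n: int, gs: int, m: int, alpha: float = 0.01) -> "BinomialNull":
        return cls(n=n, p=1.0 / gs, m=m, alpha=alpha)


def binomial_pvalue(x, n: int, p: float):
    """Exact upper-tail P(X >= x) for X ~ Binomial(n, p).

    Accepts scalar or array x. Stable for large n and tiny p via the
    regularized incomplete beta function (scipy's survival function).
    """
    x_arr = np.asarray(x)
    if np.any(x_arr < 0) or np.any(x_arr > n):
        raise ValueError(f"x must satisfy 0 <= x <= n={n}")
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0,1), got {p}")
    # P(X >= x) = sf(x-1); sf(-1) = 1 handles x = 0
    out = binom.sf(x_arr - 1, n, p)
    return float(out) if np.isscalar(x) or x_arr.ndim == 0 else out


def min_end_cutoff(null: BinomialNull, k: int = 2) -> int:
    """Smallest end count x* significant under Bonferroni correction.

    Returns the least integer x* with P(X >= x*) * m < alpha where
    X ~ Binomial(n, k*p); monotone non-decreasing in n and m. Raises if
    no x* <= n reaches significance.
    """
    p_site = k * null.p
    if not 0 < p_site < 1:
        raise ValueError(f"aggregate background probability {p_site} outside (0,1)")
    threshold = null.alpha / null.m

    def sig(x: int) -> bool:
        return binomial_pvalue(x, null.n, p_site) < threshold

    if not sig(null.n):
        raise ValueError(
            "no achievable cutoff: even x = n is not significant "
            f"(n={null.n}, p={p_site}, m={null.m}, alpha={null.alpha})"
        )
    # exponential then binary search on the monotone tail
    lo, hi = 0, 1
    while hi <= null.n and not sig(hi):
        lo, hi = hi, hi * 2
    if hi > null.n:
        hi = null.n  # sig(n) verified above
    while lo + 1 < hi:
        mid = (lo + hi) // 2
        if sig(mid):
            hi = mid
        else:
            lo = mid
    return hi


def estimate_methylation_level(x: int, spanning: int) -> float:
    """x / (x + spanning); NaN when there is no evidence at all."""
    total = x + spanning
    if total == 0:
        return math.nan
    return x / total


def classify_partial(x: int, spanning: int, significant: bool) -> str:
    """Partial iff significant with more spanning than cut reads."""
    if not significant:
        return STATUS_UNMETHYLATED
    return STATUS_PARTIAL if spanning > x else STATUS_HIGH


@dataclass
class MethylationCall:
    """A tested site with its p-value, significance and classification."""

    site: MotifSite
    x: int
    spanning: int
    pvalue: float
    corrected_significant: bool
    methylation_level: float
    status: str
    context: str
    no_data: bool = False

    @property
    def key(self):
        return self.site.key


def call_sites(
    evidence: list[SiteEvidence],
    null: BinomialNull,
    correction: str = "bonferroni",
    genome: Genome | None = None,
) -> list[MethylationCall]:
    """Test every site against the binomial null and classify it.

    correction: 'bonferroni' (default; significant iff pvalue*m < alpha,
    strictly) or 'bh' (Benjamini-Hochberg at q = alpha). The family size
    is null.m, which callers normally set to len(evidence). Sites with
    neither cut nor spanning reads are reported as unmethylated with the
    no_data flag set, so the output is a complete audit of the motif
    universe. Output order follows input order.
    """
    if not evidence:
        return []
    pvals = np.array(
        [
            binomial_pvalue(ev.x, null.n, ev.n_end_positions * null.p)
            for ev in evidence
        ]
    )
    if correction == "bonferroni":
        significant = pvals * null.m < null.alpha
    elif correction == "bh":
        significant = multipletests(pvals, alpha=null.alpha, method="fdr_bh")[0]
    else:
        raise ValueError(f"unknown correction {correction!r}")

    calls = []
    for ev, pval, sig in zip(evidence, pvals, significant):
        context = (
            forward_context(genome, ev.site) if genome is not None else ev.site.motif_name
        )
        calls.append(
            MethylationCall(
                site=ev.site,
                x=ev.x,
                spanning=ev.spanning,
                pvalue=float(pval),
                corrected_significant=bool(sig),
                methylation_level=estimate_methylation_level(ev.x, ev.spanning),
                status=classify_partial(ev.x, ev.spanning, bool(sig)),
                context=context,
                no_data=(ev.x == 0 and ev.spanning == 0),
            )
        )
    return calls


# ------------------------------------------------------- dual-enzyme logic

LABEL_FULL = "full"
LABEL_HEMI = "hemi"
LABEL_UNMETHYLATED = "unmethylated"
LABEL_DISCORDANT = "discordant"


def dpnII_resistant_sites(dpnII_calls: list[MethylationCall]) -> list[MotifSite]:
    """Sites the methylation-blocked enzyme failed to cut.

    In the complementary library the enzyme (DpnII) cleaves only
    unmethylated GATC, so a site *not* called cut there is resistant,
    i.e. hemi- or fully methylated.
    """
    return [c.site for c in dpnII_calls if not c.corrected_significant]


def integrate_dual_enzyme(
    dpnI_calls: list[MethylationCall],
    dpnII_uncut_sites: list[MotifSite],
) -> dict[tuple[str, int, str], str]:
    """Combine the methylation-directed and methylation-blocked libraries.

    DpnI cleaves fully methylated GATC; DpnII is blocked by hemi- or full
    methylation. Per GATC site:

      full         - DpnI-called and DpnII-resistant
      hemi         - DpnII-resistant but not DpnI-called
      unmethylated - DpnII-cut and not DpnI-called
      discordant   - DpnI-called yet DpnII-cut (logged anomaly)

    Sites present only in the resistant set are labelled hemi. Only GATC
    sites are meaningful in this design; any other motif raises.
    """
    for site in dpnII_uncut_sites:
        if site.motif_name != "GATC":
            raise ValueError(
                f"dual-enzyme input must be GATC sites, got {site.motif_name!r} "
                f"at {site.contig}:{site.start}"
            )
    resistant = {s.key for s in dpnII_uncut_sites}
    labels: dict[tuple[str, int, str], str] = {}
    for call in dpnI_calls:
        if call.site.motif_name != "GATC":
            raise ValueError(
                f"dual-enzyme input must be GATC sites, got {call.site.motif_name!r}"
            )
        key = call.key
        if call.corrected_significant:
            labels[key] = LABEL_FULL if key in resistant else LABEL_DISCORDANT
        else:
            labels[key] = LABEL_HEMI if key in resistant else LABEL_UNMETHYLATED
    for key in resistant - set(labels):
        labels[key] = LABEL_HEMI
    return labels


# ------------------------------------------------------------------- I/O

CALL_COLUMNS = [
    "chrom", "start", "end", "context", "x", "spanning",
    "pvalue", "significant", "methylation_level", "status", "strand",
    "motif", "a_pos",
]


def calls_to_dataframe(calls: list[MethylationCall]) -> pd.DataFrame:
    rows = [
        (
            c.site.contig, c.site.start, c.site.end, c.context, c.x, c.spanning,
            c.pvalue, c.corrected_significant, c.methylation_level, c.status,
            c.site.strand, c.site.motif_name, c.site.adenine_pos,
        )
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def write_calls(
    calls: list[MethylationCall],
    path: str | os.PathLike,
    metadata: dict | None = None,
) -> None:
    """Write calls as TSV; optional JSON run-metadata sidecar <path>.json."""
    calls_to_dataframe(calls).to_csv(path, sep="\t", index=False)
    if metadata is not None:
        with open(f"{os.fspath(path)}.json", "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True)


def read_calls(
    path: str | os.PathLike,
    specs: list[MotifSpec] | tuple[MotifSpec, ...] | None = None,
) -> list[MethylationCall]:
    """Read a calls TSV back into MethylationCall objects.

    Expected end positions are reconstructed from the motif specs
    (defaults to the DpnI set) so downstream integration and annotation
    work from files alone.
    """
    from .motifs import DPNI_MOTIFS

    spec_by_name = {s.name: s for s in (specs or DPNI_MOTIFS)}
    df = pd.read_csv(path, sep="\t")
    calls = []
    for row in df.itertuples(index=False):
        spec = spec_by_name.get(row.motif)
        ends = (
            expected_ends(spec, int(row.start), row.strand) if spec is not None else ()
        )
        site = MotifSite(
            contig=row.chrom,
            start=int(row.start),
            strand=row.strand,
            motif_name=row.motif,
            adenine_pos=int(row.a_pos),
            length=int(row.end) - int(row.start),
            expected_end_positions=ends,
        )
        calls.append(
            MethylationCall(
                site=site,
                x=int(row.x),
                spanning=int(row.spanning),
                pvalue=float(row.pvalue),
                corrected_significant=bool(row.significant),
                methylation_level=float(row.methylation_level),
                status=row.status,
                context=row.context,
                no_data=(row.x == 0 and row.spanning == 0),
            )
        )
    return calls
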