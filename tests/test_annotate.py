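"""Region assignment, metagene/periodicity, contexts, composition matrix."""

import math

import numpy as np
import pytest

from dpncall import (
    Gene,
    Genome,
    MethylationCall,
    classify_region,
    composition_matrix,
    context_breakdown,
    estimate_periodicity,
    metagene_profile,
)
from dpncall.annotate import (
    GffError,
    MetageneProfile,
    read_bed_genes,
    read_gff3_genes,
)
from conftest import make_site


def call_at(pos, contig="c1", context="GATC", strand="+", significant=True,
            motif=None):
    site = make_site(contig=contig, start=pos - 1, strand=strand,
                     motif=motif or ("CATC" if context in ("CATC", "GATG") else "GATC"))
    return MethylationCall(
        site=site, x=10, spanning=0, pvalue=1e-9,
        corrected_significant=significant, methylation_level=1.0,
        status="high" if significant else "unmethylated", context=context,
    )


class TestGeneInput:
    def test_gff3_coordinates_and_tss(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(
            "##gff-version 3\n"
            "c1\tsrc\tgene\t1001\t3000\t.\t+\t.\tID=gA\n"
            "c1\tsrc\tgene\t5001\t7000\t.\t-\t.\tID=gB\n"
            "c1\tsrc\texon\t1001\t1200\t.\t+\t.\tParent=gA\n"
        )
        genes = read_gff3_genes(path)
        assert len(genes) == 2
        assert (genes[0].start, genes[0].end, genes[0].tss) == (1000, 3000, 1000)
        assert genes[1].tss == 6999  # '-' gene: TSS at interval end - 1
        assert genes[0].name == "gA"

    def test_gff3_malformed_line_number(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("c1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g\nc1\tgene\toops\n")
        with pytest.raises(GffError, match="line 2"):
            read_gff3_genes(path)

    def test_bed_genes(self, tmp_path):
        path = tmp_path / "genes.bed"
        path.write_text("c1\t1000\t3000\tgA\t0\t+\nc1\t5000\t7000\tgB\t0\t-\n")
        genes = read_bed_genes(path)
        assert genes[0].tss == 1000 and genes[1].tss == 6999


class TestClassifyRegion:
    GENES = [
        Gene("c1", 10_000, 18_000, "+", "gA"),
        Gene("c1", 30_000, 42_000, "-", "gB"),
    ]

    def test_upstream_site_in_promoter(self):
        labels, _ = classify_region([call_at(9_500)], self.GENES)
        assert labels == ["promoter"]

    def test_mid_gene_far_from_tss_is_genic(self):
        labels, _ = classify_region([call_at(15_000)], self.GENES)
        assert labels == ["genic"]

    def test_far_site_intergenic(self):
        labels, _ = classify_region([call_at(60_000)], self.GENES)
        assert labels == ["intergenic"]

    def test_minus_gene_promoter_at_interval_end(self):
        # gB TSS at 41_999; 500 bp downstream in genome coords is upstream of gB
        labels, _ = classify_region([call_at(42_400)], self.GENES)
        assert labels == ["promoter"]

    def test_missing_contig_warns_and_falls_back(self, caplog):
        labels, _ = classify_region([call_at(100, contig="cX")], self.GENES)
        assert labels == ["intergenic"]
        assert any("cX" in rec.message for rec in caplog.records)

    def test_fractions_match_interval_oracle(self, rng):
        calls = [call_at(int(p)) for p in rng.integers(100, 50_000, size=400)]
        labels, fractions = classify_region(calls, self.GENES)
        hw = 1000
        for call, label in zip(calls, labels):
            pos = call.site.adenine_pos
            in_prom = any(abs(pos - g.tss) <= hw for g in self.GENES)
            in_gene = any(g.start <= pos < g.end for g in self.GENES)
            expected = "promoter" if in_prom else ("genic" if in_gene else "intergenic")
            assert label == expected
        assert sum(fractions.values()) == pytest.approx(1.0)


class TestMetagene:
    GENES = [Gene("c1", 10_000 * (i + 1), 10_000 * (i + 1) + 3000, "+", f"g{i}")
             for i in range(10)]

    def test_site_at_tss_lands_in_center_bin(self):
        profile = metagene_profile([call_at(10_000)], self.GENES, W=2000, b=10)
        center = np.flatnonzero(profile.density)
        assert list(center) == [200]  # bin [0, 10)

    def test_total_mass_counts_window_sites(self):
        calls = [call_at(10_000 + d) for d in (-1500, -20, 0, 130, 1990)]
        calls += [call_at(55_000)]  # midway between TSSs, outside every window
        profile = metagene_profile(calls, self.GENES, W=2000, b=10)
        mass = profile.density.sum() * profile.b * profile.n_tss
        assert mass == pytest.approx(5)
        assert profile.n_in_window == 5

    def test_minus_strand_orientation_flipped(self):
        genes = [Gene("c1", 10_000, 13_000, "-", "g")]
        # 500 bp left of the '-' TSS (12_999) is downstream of transcription
        profile = metagene_profile([call_at(12_499)], genes, W=2000, b=10)
        [idx] = np.flatnonzero(profile.density)
        assert profile.bin_edges[idx] == 500

    def test_bin_must_divide_window(self):
        with pytest.raises(ValueError):
            metagene_profile([], self.GENES, W=2000, b=300)

    def test_uniform_sites_roughly_flat(self, rng):
        calls = [call_at(int(p)) for p in rng.integers(5_000, 105_000, size=4000)]
        profile = metagene_profile(calls, self.GENES, W=2000, b=100)
        d = profile.density
        assert d.max() < 4 * d.mean()  # no systematic structure


class TestPeriodicity:
    def _profile(self, values, b=10):
        W = len(values) * b // 2
        return MetageneProfile(
            bin_edges=np.arange(-W, W + 1, b), density=np.asarray(values, float),
            W=W, b=b, n_tss=1, n_in_window=0,
        )

    def test_pure_cosine_recovered(self):
        t = np.arange(400) * 10.0
        profile = self._profile(1 + np.cos(2 * np.pi * t / 130))
        period, strength = estimate_periodicity(profile)
        assert abs(period - 130) <= 10
        assert strength > 0.5

    def test_flat_profile_undefined(self):
        period, strength = estimate_periodicity(self._profile(np.ones(400)))
        assert period is None and math.isnan(strength)

    def test_noisy_cosine_within_one_bin(self, rng):
        t = np.arange(400) * 10.0
        signal = np.cos(2 * np.pi * t / 130)
        noisy = signal + rng.normal(0, 0.5, size=t.size)  # SNR ~ 2
        period, _ = estimate_periodicity(self._profile(1 + noisy))
        assert abs(period - 130) <= 10

    @pytest.mark.parametrize("true_period", [60, 130, 200, 350])
    def test_planted_periods_across_range(self, true_period):
        t = np.arange(600) * 10.0
        profile = self._profile(1 + np.cos(2 * np.pi * t / true_period))
        period, _ = estimate_periodicity(profile)
        assert abs(period - true_period) <= 10


class TestContextBreakdown:
    def test_counting(self):
        calls = [call_at(100 * i, context="GATC") for i in range(1, 4)]
        calls.append(call_at(900, context="CATC"))
        assert context_breakdown(calls) == {"GATC": 0.75, "CATC/GATG": 0.25}

    def test_gatg_pooled_with_catc(self):
        calls = [call_at(100, context="CATC"), call_at(300, context="GATG")]
        assert context_breakdown(calls) == {"CATC/GATG": 1.0}

    def test_only_significant_counted(self):
        calls = [call_at(100), call_at(300, significant=False)]
        assert context_breakdown(calls) == {"GATC": 1.0}

    def test_empty(self):
        assert context_breakdown([]) == {}


class TestCompositionMatrix:
    def _genome_with(self, motif, n=20, flank=12):
        rng = np.random.default_rng(7)
        seq, starts = [], []
        pos = 0
        for _ in range(n):
            pad = "".join(rng.choice(list("ACGT"), size=flank * 2))
            seq.append(pad)
            pos += len(pad)
            starts.append(pos)
            seq.append(motif)
            pos += len(motif)
        return Genome({"c1": "".join(seq)}), starts

    def test_gatc_flanks_forced_by_motif(self):
        genome, starts = self._genome_with("GATC")
        calls = [call_at(s + 1, motif="GATC") for s in starts]  # A at s+1
        mat = composition_matrix(calls, genome, flank=2)
        center = 2
        assert mat.freqs[center].tolist() == [1.0, 0.0, 0.0, 0.0]     # A
        assert mat.freqs[center - 1].tolist() == [0.0, 0.0, 1.0, 0.0]  # G
        assert mat.freqs[center + 1].tolist() == [0.0, 0.0, 0.0, 1.0]  # T

    def test_mixture_fractions_at_minus_one(self):
        g_gatc, s_gatc = self._genome_with("GATC", n=3)
        calls = [call_at(s + 1, motif="GATC") for s in s_gatc]
        g_catc, s_catc = self._genome_with("CATC", n=1)
        offset = len(g_gatc["c1"])
        merged = Genome({"c1": g_gatc["c1"] + g_catc["c1"]})
        calls += [call_at(offset + s + 1, motif="CATC", context="CATC") for s in s_catc]
        mat = composition_matrix(calls, merged, flank=1)
        # offset -1: G for 3 GATC calls, C for 1 CATC call
        assert mat.freqs[0].tolist() == [0.0, 0.25, 0.75, 0.0]

    def test_minus_strand_read_on_motif_strand(self):
        # forward GATG = CATC on '-', so oriented window must read ...CATC...
        genome = Genome({"c1": "TTTTTGATGTTTTT"})
        site = make_site(start=5, strand="-", motif="CATC")  # forward GATG at [5,9)
        assert site.adenine_pos == 7
        site_call = MethylationCall(
            site=site, x=10, spanning=0, pvalue=1e-9, corrected_significant=True,
            methylation_level=1.0, status="high", context="GATG",
        )
        mat = composition_matrix([site_call], genome, flank=2)
        # minus strand around forward pos 7 (base T, pairing A): CATCA -> centre A
        assert mat.freqs[2].tolist() == [1.0, 0.0, 0.0, 0.0]
        assert mat.freqs[1].tolist() == [0.0, 1.0, 0.0, 0.0]  # C before A

    def test_rows_sum_to_one_and_edges_skipped(self, rng):
        genome, starts = self._genome_with("GATC", n=10, flank=5)
        calls = [call_at(s + 1, motif="GATC") for s in starts]
        calls.append(call_at(2))  # too close to the contig edge for flank 10
        mat = composition_matrix(calls, genome, flank=10)
        # the edge call plus the last motif (no trailing pad) are skipped
        assert mat.n_skipped == 2 and mat.n_sites == 9
        assert np.allclose(mat.freqs.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_naive_tally(self, rng):
        genome = Genome({"c1": "".join(rng.choice(list("ACGT"), size=2000))})
        positions = rng.integers(50, 1950, size=30)
        calls = []
        F = 4
        expected = np.zeros((2 * F + 1, 4))
        base_idx = {b: i for i, b in enumerate("ACGT")}
        for p in positions:
            calls.append(call_at(int(p)))
            window = genome["c1"][p - F : p + F + 1]
            for i, base in enumerate(window):
                expected[i, base_idx[base]] += 1
        mat = composition_matrix(calls, genome, flank=F)
        assert np.allclose(mat.freqs, expected / len(positions))
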