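"""Bisulfite-aware alignment, per-read calling, QC filtering, summaries."""

import numpy as np
import pytest

from amplimeth.amplicon import MethylationProfile, bisulfite_convert, reverse_complement
from amplimeth.caller import (
    CallerParams,
    InsufficientCoverageError,
    ReadCall,
    align_read,
    call_read,
    filter_reads,
    quantify,
    summarize,
)
from amplimeth.simulate import ReadSimParams, simulate_reads

NOISELESS = dict(conversion_rate=1.0, inappropriate_conversion=0.0, subst_error=0.0)


def _top_read(amplicon, profile=None):
    return bisulfite_convert(amplicon.sequence, "top", profile, amplicon.cpg_offsets)


def _bottom_read(amplicon, profile=None):
    conv = bisulfite_convert(amplicon.sequence, "bottom", profile, amplicon.cpg_offsets)
    return reverse_complement(conv)  # sequencing orientation


class TestAlignAndCall:
    def test_perfect_top_read(self, dr4_amplicon):
        read = _top_read(dr4_amplicon)
        aln, strand = align_read(read, dr4_amplicon)
        call = call_read(aln, strand, dr4_amplicon)
        assert strand == "top"
        assert call.identity == 1.0
        assert call.conversion_efficiency == 1.0
        assert call.site_states == ("U",) * 6

    def test_perfect_bottom_read(self, dr4_amplicon):
        read = _bottom_read(dr4_amplicon)
        aln, strand = align_read(read, dr4_amplicon)
        call = call_read(aln, strand, dr4_amplicon)
        assert strand == "bottom"
        assert call.identity == 1.0
        assert call.site_states == ("U",) * 6

    def test_fully_methylated_read(self, dr4_amplicon):
        prof = MethylationProfile([1.0] * 6)
        for make in (_top_read, _bottom_read):
            read = make(dr4_amplicon, prof)
            aln, strand = align_read(read, dr4_amplicon)
            call = call_read(aln, strand, dr4_amplicon)
            assert call.site_states == ("M",) * 6
            assert call.conversion_efficiency == 1.0

    def test_single_substitution_identity(self, dr4_amplicon):
        """One non-bisulfite substitution: identity (L-1)/L over scored
        positions (reference non-C columns on the top strand)."""
        read = list(_top_read(dr4_amplicon))
        pos = next(i for i, b in enumerate(dr4_amplicon.sequence) if b == "A")
        read[pos] = "G"
        aln, strand = align_read("".join(read), dr4_amplicon)
        call = call_read(aln, strand, dr4_amplicon)
        scored = sum(1 for b in dr4_amplicon.sequence if b != "C")
        assert strand == "top"
        assert call.identity == pytest.approx((scored - 1) / scored)

    def test_half_unconverted_conversion_efficiency(self, dr4_amplicon):
        """Leaving half of the non-CpG Cs unconverted halves the QC metric."""
        seq = dr4_amplicon.sequence
        cpg_c = set(dr4_amplicon.cpg_offsets)
        qc_pos = [i for i, b in enumerate(seq) if b == "C" and i not in cpg_c]
        keep = set(qc_pos[: len(qc_pos) // 2])
        read = "".join(
            b if (b != "C" or i in keep) else "T" for i, b in enumerate(seq)
        )
        aln, strand = align_read(read, dr4_amplicon)
        call = call_read(aln, strand, dr4_amplicon)
        expected = (len(qc_pos) - len(keep)) / len(qc_pos)
        assert call.conversion_efficiency == pytest.approx(expected)


class TestFilterReads:
    def _call(self, identity=1.0, conversion=1.0, length=136):
        return ReadCall("r", "top", ("U",), conversion, identity, length)

    def test_perfect_reads_all_pass(self):
        passing, report = filter_reads([self._call() for _ in range(10)])
        assert report.n_pass == 10
        assert all(v == 0 for v in report.counts.values())

    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            (dict(identity=0.5), "identity"),
            (dict(conversion=0.5), "conversion"),
            (dict(length=10), "length"),
            (dict(identity=0.5, conversion=0.5), "identity"),  # first rule wins
        ],
    )
    def test_failure_reasons(self, kwargs, reason):
        passing, report = filter_reads([self._call(**kwargs)])
        assert report.n_pass == 0
        assert report.counts[reason] == 1

    def test_pass_fraction_matches_binomial(self, dr4_amplicon):
        """At c=0.995 nearly all reads clear the 0.9 conversion threshold."""
        prof = MethylationProfile([0.0] * 6)
        recs, _ = simulate_reads(
            dr4_amplicon, prof,
            ReadSimParams(n_reads=1000, conversion_rate=0.995,
                          inappropriate_conversion=0.0, subst_error=0.0, seed=9),
        )
        calls = []
        for rid, seq, _ in recs:
            aln, strand = align_read(seq, dr4_amplicon)
            calls.append(call_read(aln, strand, dr4_amplicon, rid))
        _, report = filter_reads(calls)
        # ~24-28 QC positions per strand; P(fail) = P(>10% unconverted) is tiny
        assert report.n_pass >= 990


class TestSummarize:
    def _mk_calls(self, percents, n=10):
        """Calls yielding the given per-site percents at coverage n."""
        n_sites = len(percents)
        calls = []
        for i in range(n):
            states = tuple(
                "M" if i < round(p / 100 * n) else "U" for p in percents
            )
            calls.append(ReadCall(f"r{i}", "top", states, 1.0, 1.0, 100))
        return calls

    def test_fifty_percent_site(self, dr4_amplicon):
        calls = self._mk_calls([50, 50, 50, 50, 50, 50], n=10)
        sites, summary = summarize(calls, dr4_amplicon, min_coverage=10)
        assert sites[0].coverage == 10
        assert sites[0].n_methylated == 5
        assert sites[0].percent_methylation == 50.0

    def test_unweighted_mean(self, dr4_amplicon):
        calls = self._mk_calls([0, 0, 30, 30, 90, 90], n=10)
        _, summary = summarize(calls, dr4_amplicon, min_coverage=10)
        assert summary.mean_percent_methylation == pytest.approx(40.0)

    def test_mean_is_mean_of_reported_site_percents(self, dr4_amplicon):
        calls = self._mk_calls([10, 20, 30, 40, 50, 60], n=10)
        sites, summary = summarize(calls, dr4_amplicon, min_coverage=10)
        assert summary.mean_percent_methylation == pytest.approx(
            np.mean([s.percent_methylation for s in sites])
        )

    def test_insufficient_coverage(self, dr4_amplicon):
        calls = self._mk_calls([50] * 6, n=3)
        with pytest.raises(InsufficientCoverageError):
            summarize(calls, dr4_amplicon, min_coverage=100)

    def test_low_coverage_site_reported_missing(self, dr4_amplicon):
        calls = self._mk_calls([50] * 6, n=10)
        # blank out one site with N calls
        calls = [
            ReadCall(c.read_id, c.strand, ("N",) + c.site_states[1:],
                     c.conversion_efficiency, c.identity, c.read_length)
            for c in calls
        ]
        sites, summary = summarize(calls, dr4_amplicon, min_coverage=5)
        assert sites[0].percent_methylation is None
        assert summary.n_sites_passing == 5


class TestQuantify:
    def test_truth_table_oracle_equivalence(self, dr4_amplicon):
        """Noiseless simulation: per-site (M,U) counts equal the simulator
        truth exactly, both strands mixed."""
        prof = MethylationProfile([0.0, 0.0, 0.3, 0.3, 0.9, 0.94])
        recs, truth = simulate_reads(
            dr4_amplicon, prof, ReadSimParams(n_reads=400, seed=21, **NOISELESS)
        )
        res = quantify(recs, dr4_amplicon, CallerParams(min_coverage=1))
        for j, s in enumerate(res.sites):
            assert s.n_methylated == truth[f"site{j}"].sum()
            assert s.coverage == len(truth)

    def test_strand_symmetry_noiseless(self, dr4_amplicon):
        """All-top and all-bottom runs with the same seed share the same
        truth, hence identical noiseless estimates."""
        prof = MethylationProfile([0.1, 0.2, 0.4, 0.6, 0.8, 0.9])
        results = []
        for frac in (0.0, 1.0):
            recs, _ = simulate_reads(
                dr4_amplicon, prof,
                ReadSimParams(n_reads=300, frac_top_strand=frac, seed=33, **NOISELESS),
            )
            res = quantify(recs, dr4_amplicon, CallerParams(min_coverage=1))
            results.append([s.n_methylated for s in res.sites])
        assert results[0] == results[1]

    def test_parameter_recovery_with_noise(self, dr5_amplicon):
        prof = MethylationProfile([0.05 * j for j in range(13)])
        recs, _ = simulate_reads(dr5_amplicon, prof, ReadSimParams(n_reads=600, seed=17))
        res = quantify(recs, dr5_amplicon, CallerParams(min_coverage=50))
        for s, p in zip(res.sites, prof.values):
            assert s.percent_methylation == pytest.approx(100 * p, abs=5.0)

    def test_empty_fastq_errors(self, dr4_amplicon):
        with pytest.raises(ValueError, match="no reads"):
            quantify([], dr4_amplicon)
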