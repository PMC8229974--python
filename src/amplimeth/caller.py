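"""Bisulfite-aware methylation calling for amplicon reads.

Reads are aligned to the *unconverted* amplicon under two asymmetric
substitution models: on the top strand a reference C is allowed to read as
C or T at no penalty (retained methylated C vs converted unmethylated C);
on the bottom strand — reads emitted in sequencing orientation, i.e. the
reverse complement of the converted bottom strand — a reference G is
allowed to read as G or A.  The higher-scoring model decides the strand.

Per read, each CpG site is called M (methylated, retained C/G), U
(converted, T/A) or N (anything else, including gaps); conversion
efficiency is estimated from non-CpG reference cytosines, which are
assumed unmethylated, and serves as a per-read QC statistic alongside
alignment identity over non-bisulfite-ambiguous positions.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .amplicon import AmpliconSpec

__all__ = [
    "CallerParams",
    "ReadCall",
    "SiteSummary",
    "AmpliconSummary",
    "FilterReport",
    "QuantifyResult",
    "InsufficientCoverageError",
    "align_read",
    "call_read",
    "filter_reads",
    "summarize",
    "quantify",
    "read_fastq",
]


class InsufficientCoverageError(ValueError):
    """No CpG site reaches the minimum coverage."""


@dataclass(frozen=True)
class CallerParams:
    """QC and scoring defaults for the caller.

    Identity and conversion thresholds are applied per read; sites with
    coverage below ``min_coverage`` are reported as missing and excluded
    from the amplicon mean.
    """

    min_identity: float = 0.90
    min_conversion: float = 0.90
    min_length: int = 50
    min_coverage: int = 100
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -2.0


@dataclass
class ReadCall:
    read_id: str
    strand: str  # "top" | "bottom"
    site_states: tuple[str, ...]  # per CpG site: "M" | "U" | "N"
    conversion_efficiency: float
    identity: float
    read_length: int


@dataclass
class SiteSummary:
    site_index: int
    offset: int
    coverage: int  # M + U calls
    n_methylated: int
    percent_methylation: Optional[float]  # None below min_coverage


@dataclass
class AmpliconSummary:
    mean_percent_methylation: Optional[float]
    n_sites: int
    n_sites_passing: int
    n_reads_total: int
    n_reads_pass: int
    filter_counts: dict


@dataclass
class FilterReport:
    n_total: int
    n_pass: int
    counts: dict  # failure reason -> count


@dataclass
class QuantifyResult:
    sites: list
    summary: AmpliconSummary

    def site_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "site_index": s.site_index,
                    "offset": s.offset,
                    "coverage": s.coverage,
                    "n_methylated": s.n_methylated,
                    "percent": s.percent_methylation,
                }
                for s in self.sites
            ]
        )

    def summary_json(self) -> str:
        d = dict(vars(self.summary))
        return json.dumps(d, indent=2)


def _make_aligner(strand: str, params: CallerParams) -> Align.PairwiseAligner:
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            mat[a, b] = params.match_score if a == b else params.mismatch_score
    if strand == "top":
        mat["C", "T"] = params.match_score  # converted unmethylated C
    else:
        mat["G", "A"] = params.match_score  # converted bottom-strand C
    for x in "ACGTN":
        mat["N", x] = mat[x, "N"] = params.mismatch_score
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = mat
    al.open_gap_score = al.extend_gap_score = params.gap_score
    # free end gaps: partial-length reads are not charged for reference overhang
    al.end_deletion_score = 0.0
    al.end_insertion_score = 0.0
    return al


def align_read(
    read: str, amplicon: AmpliconSpec, params: CallerParams = CallerParams()
):
    """Align a read under both strand models; return (alignment, strand).

    The alignment is against the unconverted amplicon sequence; strand is
    the model with the higher score (ties resolved as top).
    """
    read = read.upper()
    best = None
    for strand in ("top", "bottom"):
        aligner = _make_aligner(strand, params)
        aln = aligner.align(amplicon.sequence, read)[0]
        if best is None or aln.score > best[0].score:
            best = (aln, strand)
    return best


def _ref_to_read_map(alignment) -> dict[int, str]:
    """Map reference position -> read base ('-' for a gap in the read)."""
    ref_g, read_g = str(alignment[0]), str(alignment[1])
    mapping: dict[int, str] = {}
    rp = 0
    for a, b in zip(ref_g, read_g):
        if a != "-":
            mapping[rp] = b
            rp += 1
    return mapping


def call_read(
    alignment, strand: str, amplicon: AmpliconSpec, read_id: str = ""
) -> ReadCall:
    """Per-CpG calls plus conversion-efficiency and identity QC statistics.

    Top strand: the read base at the CpG C is C->M, T->U, other/gap->N.
    Bottom strand: the read base at the CpG G (the bottom-strand C seen in
    top coordinates) is G->M, A->U, other/gap->N.  Conversion efficiency
    is the converted fraction of non-CpG reference C (top) / G (bottom)
    positions; identity is the matching fraction of aligned positions
    whose reference base is not bisulfite-ambiguous.
    """
    seq = amplicon.sequence
    mapping = _ref_to_read_map(alignment)
    cpg_c = set(amplicon.cpg_offsets)
    cpg_g = {o + 1 for o in amplicon.cpg_offsets}

    if strand == "top":
        ambiguous_base, meth_base, conv_base = "C", "C", "T"
        cpg_positions = amplicon.cpg_offsets
        qc_positions = [p for p, b in enumerate(seq) if b == "C" and p not in cpg_c]
    else:
        ambiguous_base, meth_base, conv_base = "G", "G", "A"
        cpg_positions = tuple(o + 1 for o in amplicon.cpg_offsets)
        qc_positions = [p for p, b in enumerate(seq) if b == "G" and p not in cpg_g]

    states = []
    for p in cpg_positions:
        b = mapping.get(p, None)
        if b == meth_base:
            states.append("M")
        elif b == conv_base:
            states.append("U")
        else:
            states.append("N")

    conv = unconv = 0
    for p in qc_positions:
        b = mapping.get(p, None)
        if b == conv_base:
            conv += 1
        elif b == meth_base:
            unconv += 1
    efficiency = conv / (conv + unconv) if (conv + unconv) else 1.0

    matches = scored = 0
    for p, ref_base in enumerate(seq):
        if ref_base == ambiguous_base:
            continue
        b = mapping.get(p, None)
        if b is None or b == "-":
            continue
        scored += 1
        if b == ref_base:
            matches += 1
    identity = matches / scored if scored else 1.0

    read_len = sum(1 for b in str(alignment[1]) if b != "-")
    return ReadCall(
        read_id=read_id,
        strand=strand,
        site_states=tuple(states),
        conversion_efficiency=efficiency,
        identity=identity,
        read_length=read_len,
    )


def filter_reads(
    calls: Sequence[ReadCall], params: CallerParams = CallerParams()
) -> tuple[list[ReadCall], FilterReport]:
    """Apply per-read QC; failure reason is the first failing rule in the
    order identity, conversion, length."""
    passing = []
    counts = {"identity": 0, "conversion": 0, "length": 0}
    for c in calls:
        if c.identity < params.min_identity:
            counts["identity"] += 1
        elif c.conversion_efficiency < params.min_conversion:
            counts["conversion"] += 1
        elif c.read_length < params.min_length:
            counts["length"] += 1
        else:
            passing.append(c)
    return passing, FilterReport(n_total=len(calls), n_pass=len(passing), counts=counts)


def summarize(
    calls: Sequence[ReadCall],
    amplicon: AmpliconSpec,
    min_coverage: int = 100,
    filter_report: Optional[FilterReport] = None,
) -> tuple[list[SiteSummary], AmpliconSummary]:
    """Per-site M/U tallies (N ignored per site) and the amplicon mean.

    percent = 100*M/(M+U); the amplicon mean is the unweighted mean over
    sites with coverage >= min_coverage (matching the 'mean percent
    methylation over CG dinucleotides' convention, not coverage-weighted).
    """
    n_sites = amplicon.n_sites
    m = np.zeros(n_sites, int)
    u = np.zeros(n_sites, int)
    for c in calls:
        for j, s in enumerate(c.site_states):
            if s == "M":
                m[j] += 1
            elif s == "U":
                u[j] += 1
    sites = []
    percents = []
    for j in range(n_sites):
        cov = int(m[j] + u[j])
        pct = 100.0 * m[j] / cov if cov >= min_coverage and cov > 0 else None
        if pct is not None:
            percents.append(pct)
        sites.append(
            SiteSummary(
                site_index=j,
                offset=amplicon.cpg_offsets[j],
                coverage=cov,
                n_methylated=int(m[j]),
                percent_methylation=pct,
            )
        )
    if not percents:
        raise InsufficientCoverageError(
            f"insufficient coverage: no site reaches {min_coverage} M+U calls"
        )
    mean_pct = float(np.mean(percents))
    summary = AmpliconSummary(
        mean_percent_methylation=mean_pct,
        n_sites=n_sites,
        n_sites_passing=len(percents),
        n_reads_total=filter_report.n_total if filter_report else len(calls),
        n_reads_pass=filter_report.n_pass if filter_report else len(calls),
        filter_counts=dict(filter_report.counts) if filter_report else {},
    )
    return sites, summary


def read_fastq(path) -> list[tuple[str, str]]:
    """(read_id, sequence) pairs from a FASTQ file (.gz supported)."""
    path = Path(path)
    op = gzip.open if path.suffix == ".gz" else open
    with op(path, "rt") as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fastq")]


def quantify(
    reads,
    amplicon: AmpliconSpec,
    params: CallerParams = CallerParams(),
) -> QuantifyResult:
    """End-to-end: align -> call -> filter -> summarize.

    ``reads`` is a FASTQ path or an iterable of (read_id, sequence)
    pairs (a trailing quality element is ignored).
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    reads = [r[:2] for r in reads]
    if not reads:
        raise ValueError("no reads")
    calls = []
    for rid, seq in reads:
        aln, strand = align_read(seq, amplicon, params)
        calls.append(call_read(aln, strand, amplicon, read_id=rid))
    passing, report = filter_reads(calls, params)
    sites, summary = summarize(passing, amplicon, params.min_coverage, report)
    return QuantifyResult(sites=sites, summary=summary)
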