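"""Amplicon model: CpG site discovery, in-silico bisulfite conversion and PCR.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as T
after PCR) while 5-methylcytosine is protected.  An amplicon is represented
by its *unconverted* genomic top-strand sequence together with the 0-based
offsets of the C of every CG dinucleotide; primers live in bisulfite space
and, for methylation-independent amplification, must not contain CG.

Coordinates are 0-based half-open throughout.  Amplicons are primer
inclusive: the reported length counts both primer footprints, which is the
convention under which a 136-bp / 212-bp product is measured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from Bio.Seq import Seq

__all__ = [
    "AmpliconSpec",
    "MethylationProfile",
    "PrimerNotFoundError",
    "AmbiguousAmplificationError",
    "DR4_PRIMERS",
    "DR5_PRIMERS",
    "find_cpg_sites",
    "bisulfite_convert",
    "validate_primer",
    "in_silico_pcr",
    "reverse_complement",
]

_DNA = set("ACGTN")

#: Bisulfite-space primer pairs for the DR4 (TNFRSF10A) and DR5 (TNFRSF10B)
#: promoter CpG-island amplicons.  Neither primer contains a CG dinucleotide,
#: so amplification is independent of the methylation state of the template.
DR4_PRIMERS = ("GGAAGGAAGTTTAGGGTTAGTTAATAG", "TACCAAATCAATCCAAAAAACAAC")
DR5_PRIMERS = ("AAGTGTTTTTTTTAATTTATTTTTTTTAAG", "CAACTACAAATTCCACCACAAATTA")


class PrimerNotFoundError(ValueError):
    """No binding site for a primer in the converted template."""


class AmbiguousAmplificationError(ValueError):
    """More than one product under the configured size cap."""


def _check_dna(sequence: str, *, what: str = "sequence") -> str:
    seq = sequence.upper()
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters in {what}: {sorted(bad)}")
    return seq


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def find_cpg_sites(sequence: str) -> list[int]:
    """Return the 0-based offsets of the C of every CG dinucleotide.

    N is never part of a CpG site.  CG cannot overlap itself, so a simple
    scan enumerates every site exactly once.
    """
    seq = _check_dna(sequence)
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


@dataclass(frozen=True)
class AmpliconSpec:
    """A bisulfite PCR amplicon on the unconverted genomic top strand.

    Parameters
    ----------
    name:
        Identifier (typically the gene symbol).
    sequence:
        Uppercase unconverted top-strand sequence, primer inclusive.
    fwd_primer, rev_primer:
        Bisulfite-space primer sequences (must not contain CG).
    cpg_offsets:
        0-based offsets of the C of each CG dinucleotide in ``sequence``.
    source_coords:
        Optional ``(assembly, chrom, start, end)`` with 0-based half-open
        coordinates of the amplicon in its source sequence.
    """

    name: str
    sequence: str
    fwd_primer: str
    rev_primer: str
    cpg_offsets: tuple[int, ...]
    source_coords: Optional[tuple[str, str, int, int]] = None

    def __post_init__(self):
        object.__setattr__(self, "sequence", _check_dna(self.sequence))
        object.__setattr__(self, "cpg_offsets", tuple(self.cpg_offsets))
        offs = self.cpg_offsets
        if list(offs) != sorted(set(offs)):
            raise ValueError("cpg_offsets must be strictly increasing")
        for o in offs:
            if self.sequence[o : o + 2] != "CG":
                raise ValueError(f"offset {o} is not a CG dinucleotide")
        for p in (self.fwd_primer, self.rev_primer):
            if not validate_primer(p):
                raise ValueError(f"primer {p} contains a CG dinucleotide")
        if len(self.sequence) < len(self.fwd_primer) + len(self.rev_primer):
            raise ValueError("amplicon shorter than its primers")

    @property
    def n_sites(self) -> int:
        return len(self.cpg_offsets)

    def __len__(self) -> int:
        return len(self.sequence)

    def to_json(self) -> str:
        d = asdict(self)
        d["cpg_offsets"] = list(self.cpg_offsets)
        if self.source_coords is not None:
            d["source_coords"] = list(self.source_coords)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AmpliconSpec":
        d = json.loads(text)
        if d.get("source_coords") is not None:
            d["source_coords"] = tuple(d["source_coords"])
        return cls(**d)


@dataclass(frozen=True)
class MethylationProfile:
    """Per-CpG-site methylation fractions (the simulation ground truth)."""

    values: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if any(not 0.0 <= v <= 1.0 for v in self.values):
            raise ValueError("methylation fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)


def validate_primer(primer: str) -> bool:
    """True iff the primer contains no CG dinucleotide (methylation neutral)."""
    if not primer:
        raise ValueError("empty primer")
    return "CG" not in _check_dna(primer, what="primer")


def bisulfite_convert(
    sequence: str,
    strand: str = "top",
    profile: Optional[MethylationProfile | Sequence[float]] = None,
    cpg_offsets: Optional[Sequence[int]] = None,
) -> str:
    """Deterministic in-silico bisulfite conversion.

    Every cytosine outside a CpG context converts to T.  A CpG cytosine is
    retained iff its profile entry is treated as methylated (entry >= 0.5);
    ``profile=None`` means fully unmethylated.  ``strand="bottom"`` converts
    the reverse complement and reports the result in bottom-strand
    orientation.  Stochastic (partial) conversion is the read simulator's
    job, not this function's.
    """
    seq = _check_dna(sequence)
    if strand not in ("top", "bottom"):
        raise ValueError("strand must be 'top' or 'bottom'")
    vals = None
    if profile is not None:
        vals = list(profile.values if isinstance(profile, MethylationProfile) else profile)
    if strand == "bottom":
        # CG is its own reverse complement: the bottom-strand C of top-site o
        # sits at n - 2 - o in bottom orientation, and site order reverses.
        n = len(seq)
        top_offs = list(cpg_offsets) if cpg_offsets is not None else find_cpg_sites(seq)
        seq = reverse_complement(seq)
        offs = sorted(n - 2 - o for o in top_offs)
        if vals is not None:
            vals = vals[::-1]
        return _convert_top(seq, offs, vals)
    offs = list(cpg_offsets) if cpg_offsets is not None else find_cpg_sites(seq)
    return _convert_top(seq, offs, vals)


def _convert_top(seq: str, cpg_offsets: Sequence[int], values: Optional[Sequence[float]]) -> str:
    if values is not None and len(values) != len(cpg_offsets):
        raise ValueError(
            f"profile length {len(values)} != number of CpG sites {len(cpg_offsets)}"
        )
    methylated = set()
    if values is not None:
        methylated = {o for o, v in zip(cpg_offsets, values) if v >= 0.5}
    out = []
    for i, base in enumerate(seq):
        if base == "C" and i not in methylated:
            out.append("T")
        else:
            out.append(base)
    return "".join(out)


def _find_with_mismatches(hay: str, needle: str, max_mismatches: int, start: int = 0) -> list[int]:
    """All start positions where needle matches hay with <= max_mismatches.

    N in the haystack never matches a primer base.
    """
    hits = []
    n, m = len(hay), len(needle)
    for i in range(start, n - m + 1):
        mm = 0
        for a, b in zip(hay[i : i + m], needle):
            if a != b or a == "N":
                mm += 1
                if mm > max_mismatches:
                    break
        else:
            hits.append(i)
    return hits


def in_silico_pcr(
    genomic_sequence: str,
    fwd_primer: str,
    rev_primer: str,
    max_mismatches: int = 0,
    max_product_size: int = 2000,
    name: str = "amplicon",
    strand: str = "top",
    assembly: Optional[str] = None,
    chrom: Optional[str] = None,
) -> AmpliconSpec:
    """In-silico bisulfite PCR against an unconverted genomic sequence.

    The template strand is fully converted (every C to T — legitimate
    because CG-free primers bind identically regardless of methylation);
    the leftmost forward-primer site is located, then the nearest
    downstream reverse-complemented reverse-primer site.  The returned
    amplicon is primer inclusive and mapped back to the *unconverted*
    sequence, with CpG offsets computed on the unconverted amplicon.

    ``strand="bottom"`` runs the same search on the reverse complement of
    the input and reports coordinates mapped back to the input.
    """
    seq = _check_dna(genomic_sequence)
    if strand == "bottom":
        spec = in_silico_pcr(
            reverse_complement(seq), fwd_primer, rev_primer, max_mismatches,
            max_product_size, name=name, strand="top", assembly=assembly, chrom=chrom,
        )
        if spec.source_coords is not None:
            a, c, s, e = spec.source_coords
            n = len(seq)
            spec = AmpliconSpec(
                name=spec.name, sequence=spec.sequence, fwd_primer=spec.fwd_primer,
                rev_primer=spec.rev_primer, cpg_offsets=spec.cpg_offsets,
                source_coords=(a, c, n - e, n - s),
            )
        return spec

    fwd = _check_dna(fwd_primer, what="primer")
    rev_rc = reverse_complement(_check_dna(rev_primer, what="primer"))
    converted = _convert_top(seq, find_cpg_sites(seq), None).replace("C", "T")

    fwd_hits = _find_with_mismatches(converted, fwd, max_mismatches)
    if not fwd_hits:
        raise PrimerNotFoundError("primer not found: forward primer has no binding site")
    start = fwd_hits[0]
    rev_hits = _find_with_mismatches(converted, rev_rc, max_mismatches, start=start + len(fwd))
    rev_hits = [h for h in rev_hits if h + len(rev_rc) - start <= max_product_size]
    if not rev_hits:
        raise PrimerNotFoundError("primer not found: reverse primer has no downstream site")
    if len(rev_hits) > 1:
        raise AmbiguousAmplificationError(
            f"ambiguous amplification: {len(rev_hits)} products under {max_product_size} bp"
        )
    end = rev_hits[0] + len(rev_rc)

    amp_seq = seq[start:end]
    return AmpliconSpec(
        name=name,
        sequence=amp_seq,
        fwd_primer=fwd_primer,
        rev_primer=rev_primer,
        cpg_offsets=tuple(find_cpg_sites(amp_seq)),
        source_coords=(assembly or "custom", chrom or "seq", start, end),
    )
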