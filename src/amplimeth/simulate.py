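"""Synthetic data: bisulfite reads with known truth, a cell-line panel, and
a 450k-style cohort.

Every generator is deterministic given its seed and writes plain-text
outputs (4-line FASTQ, TSV tables), so the whole pipeline is testable
without any external download.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .amplicon import (
    AmpliconSpec,
    MethylationProfile,
    DR4_PRIMERS,
    DR5_PRIMERS,
    find_cpg_sites,
    reverse_complement,
)

__all__ = [
    "ReadSimParams",
    "PanelGenParams",
    "GroupPrior",
    "CohortGenParams",
    "simulate_reads",
    "simulate_panel",
    "expression_level",
    "trail_inhibition",
    "simulate_array_cohort",
    "synthetic_promoter",
    "synthetic_amplicon",
    "write_fastq",
    "CELL_LINE_PANEL_GROUPS",
    "COHORT_SUBTYPE_COUNTS",
    "DEFAULT_P_HYPER",
]

_BASES = np.array(list("ACGT"))
_Q30 = "?"  # phred+33 quality 30; the caller does not use qualities


# --------------------------------------------------------------------------
# bisulfite amplicon reads
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimParams:
    """Read-simulator settings.

    conversion_rate is the probability that an unmethylated C reads as T;
    inappropriate_conversion the probability that a methylated CpG C reads
    as T; subst_error the per-base substitution rate.  Indels are not
    modelled.
    """

    n_reads: int = 1000
    conversion_rate: float = 0.995
    inappropriate_conversion: float = 0.005
    subst_error: float = 0.005
    frac_top_strand: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("conversion_rate", "inappropriate_conversion", "subst_error", "frac_top_strand"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")


def simulate_reads(
    amplicon: AmpliconSpec,
    profile: MethylationProfile,
    params: ReadSimParams,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate full-length bisulfite amplicon reads with known truth.

    Per read: a strand is drawn (top with probability ``frac_top_strand``),
    each CpG methylation state is Bernoulli(profile_i) independently, then
    conversion and substitution noise are applied.  Bottom-strand reads are
    emitted in sequencing orientation, i.e. the reverse complement of the
    converted bottom strand, which aligns to the top-strand amplicon under
    a G/A-tolerant model.

    Returns ``(records, truth)`` where records are ``(read_id, sequence,
    quality)`` tuples and truth has one row per read with the drawn strand
    and the per-site methylation states (1 = methylated).
    """
    if len(profile) != amplicon.n_sites:
        raise ValueError("profile length does not match amplicon CpG sites")
    rng = np.random.default_rng(params.seed)
    seq = np.frombuffer(amplicon.sequence.encode(), dtype="S1").astype("U1")
    n = len(seq)
    offs = np.array(amplicon.cpg_offsets, dtype=int)
    prof = np.array(profile.values)
    is_cpg_c = np.zeros(n, bool)
    is_cpg_c[offs] = True
    is_c = seq == "C"
    is_g = seq == "G"
    # G of each CpG (the bottom-strand C in top coordinates)
    is_cpg_g = np.zeros(n, bool)
    is_cpg_g[offs + 1] = True

    records: list[tuple[str, str, str]] = []
    truth_rows = []
    for i in range(params.n_reads):
        # fixed draw order keeps the stream aligned across strand choices
        states = (rng.random(len(offs)) < prof).astype(int) if len(offs) else np.zeros(0, int)
        top = rng.random() < params.frac_top_strand
        conv_u = rng.random(n)
        read = seq.copy()
        if top:
            meth_mask = np.zeros(n, bool)
            meth_mask[offs[states == 1]] = True
            convert = (is_c & ~meth_mask & (conv_u < params.conversion_rate)) | (
                is_c & meth_mask & (conv_u < params.inappropriate_conversion)
            )
            read[convert] = "T"
        else:
            # converted bottom strand, reported as its reverse complement:
            # bottom-strand C corresponds to top-strand G; conversion C->T on
            # the bottom shows up as G->A in sequencing orientation.
            meth_mask = np.zeros(n, bool)
            meth_mask[offs[states == 1] + 1] = True
            convert = (is_g & ~meth_mask & (conv_u < params.conversion_rate)) | (
                is_g & meth_mask & (conv_u < params.inappropriate_conversion)
            )
            read[convert] = "A"
        if params.subst_error > 0:
            err_u = rng.random(n)
            err_pos = np.nonzero(err_u < params.subst_error)[0]
            for p in err_pos:
                choices = _BASES[_BASES != read[p]]
                read[p] = choices[rng.integers(len(choices))]
        read_id = f"read{i:06d}"
        records.append((read_id, "".join(read), _Q30 * n))
        truth_rows.append((read_id, "top" if top else "bottom", *states))

    cols = ["read_id", "strand"] + [f"site{j}" for j in range(len(offs))]
    truth = pd.DataFrame(truth_rows, columns=cols)
    return records, truth


def write_fastq(records, path) -> None:
    """Write (id, seq, qual) records as 4-line FASTQ (gz if path ends .gz)."""
    path = Path(path)
    op = gzip.open if path.suffix == ".gz" else open
    with op(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# --------------------------------------------------------------------------
# synthetic promoter stand-ins
# --------------------------------------------------------------------------

# CpG islands are GC-rich; a generous share of non-CpG C/G gives the caller
# enough conversion-QC positions per read on either strand.
_BG_POOL = np.array(list("ACGT"))
_BG_P = np.array([0.25, 0.30, 0.20, 0.25])


def _fill_background(length: int, rng: np.random.Generator, next_char: str = "A") -> list[str]:
    """Random CG-free background (no C immediately before a G)."""
    out: list[str] = []
    for i in range(length):
        while True:
            b = str(rng.choice(_BG_POOL, p=_BG_P))
            prev = out[-1] if out else "A"
            nxt = next_char if i == length - 1 else None
            if prev == "C" and b == "G":
                continue
            if b == "C" and nxt == "G":
                continue
            out.append(b)
            break
    return out


def _insert_with_cpgs(length: int, n_cpg: int, rng: np.random.Generator, next_char: str) -> str:
    """Background sequence of `length` containing exactly `n_cpg` CG sites."""
    starts = np.linspace(2, length - 4, n_cpg).astype(int)
    seq: list[str] = ["?"] * length
    for s in starts:
        seq[s], seq[s + 1] = "C", "G"
    for i in range(length):
        if seq[i] != "?":
            continue
        while True:
            b = str(rng.choice(_BG_POOL, p=_BG_P))
            prev = seq[i - 1] if i > 0 else "A"
            nxt = seq[i + 1] if i + 1 < length else next_char
            if prev == "C" and b == "G":
                continue
            if b == "C" and nxt == "G":
                continue
            seq[i] = b
            break
    return "".join(seq)


def synthetic_promoter(gene: str, flank: int = 60, seed: int = 20210864) -> str:
    """A synthetic stand-in for the DR4/DR5 promoter CpG-island region.

    Builds an unconverted top-strand sequence into which the real
    bisulfite-PCR primer pair binds after full conversion, reproducing the
    assay geometry — a 136-bp product with 6 CpG sites for DR4 and a
    212-bp product with 13 CpG sites for DR5.  The sequence itself is
    synthetic (the flanks and inter-primer backbone are generated), not
    the human genomic sequence.
    """
    gene = gene.upper()
    if gene == "DR4":
        fwd, rev = DR4_PRIMERS
        total, n_cpg = 136, 6
    elif gene == "DR5":
        fwd, rev = DR5_PRIMERS
        total, n_cpg = 212, 13
    else:
        raise ValueError("gene must be 'DR4' or 'DR5'")
    rng = np.random.default_rng(seed + (0 if gene == "DR4" else 1))
    rev_rc = reverse_complement(rev)
    insert_len = total - len(fwd) - len(rev)
    insert = _insert_with_cpgs(insert_len, n_cpg, rng, next_char=rev_rc[0])
    left = "".join(_fill_background(flank, rng, next_char=fwd[0]))
    right = "".join(_fill_background(flank, rng))
    region = left + fwd + insert + rev_rc + right
    assert len(find_cpg_sites(fwd + insert + rev_rc)) == n_cpg
    return region


def synthetic_amplicon(gene: str, **kwargs) -> AmpliconSpec:
    """In-silico PCR of the synthetic promoter stand-in (see above)."""
    from .amplicon import in_silico_pcr

    gene = gene.upper()
    primers = DR4_PRIMERS if gene == "DR4" else DR5_PRIMERS
    return in_silico_pcr(synthetic_promoter(gene, **kwargs), *primers, name=gene)


# --------------------------------------------------------------------------
# cell-line panel
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupPrior:
    """Per-karyotype methylation prior for one receptor gene.

    With probability ``p_high`` the promoter is hypermethylated (beta draw
    around ``high_mean``), else essentially unmethylated (around
    ``low_mean``); fractions on the [0, 1] scale.  The hypermethylated
    mode is high enough that a line methylated on both genes loses most
    receptor availability and lands TRAIL-resistant.
    """

    p_high: float
    high_mean: float = 0.70
    low_mean: float = 0.004

    def draw(self, rng: np.random.Generator, u: Optional[float] = None) -> float:
        """Draw one methylation fraction; ``u`` is the high/low uniform.

        Passing the same ``u`` for both receptors of a line makes their
        hypermethylation indicators nested, reproducing the positive
        DR4/DR5 correlation seen across lines.
        """
        if u is None:
            u = rng.random()
        if u < self.p_high:
            a = self.high_mean * 20
            return float(np.clip(rng.beta(a, 20 - a), 0.02, 0.98))
        a = self.low_mean * 800
        return float(np.clip(rng.beta(a, 800 - a), 0.0, 0.02))


#: 32-line BCP-ALL panel layout: karyotype -> (n lines, DR4 prior, DR5 prior).
#: Hypermethylation is frequent in MLL-rearranged and MEF2D-rearranged lines,
#: absent in TCF3-HLF and ETV6-RUNX1 lines, and mixed elsewhere.
CELL_LINE_PANEL_GROUPS: dict[str, tuple[int, GroupPrior, GroupPrior]] = {
    "MLLr": (9, GroupPrior(1.0), GroupPrior(6 / 9)),
    "BCR-ABL1": (6, GroupPrior(0.3), GroupPrior(0.3)),
    "TCF3-PBX1": (7, GroupPrior(0.4), GroupPrior(0.4)),
    "TCF3-HLF": (4, GroupPrior(0.0), GroupPrior(0.0)),
    "ETV6-RUNX1": (2, GroupPrior(0.0), GroupPrior(0.0)),
    "MEF2Dr": (2, GroupPrior(1.0), GroupPrior(1.0)),
    "DUX4r": (2, GroupPrior(0.5), GroupPrior(0.25)),
}


@dataclass(frozen=True)
class PanelGenParams:
    """Cell-line panel generator settings.

    log10 relative expression = alpha − beta·m + N(0, sigma_e); receptor
    availability s = max_r(1 − m_r); percent inhibition by rhsTRAIL
    (100 ng/mL) = 100·logistic(theta·(s − s0)) + N(0, sigma_t), clipped to
    [−10, 100].
    """

    groups: tuple = tuple(CELL_LINE_PANEL_GROUPS.items())
    alpha: float = 0.0
    beta: float = 2.0
    sigma_e: float = 0.15
    theta: float = 10.0
    s0: float = 0.5
    sigma_t: float = 3.0
    rfi_scale: float = 9.0
    sigma_rfi: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.sigma_e < 0 or self.sigma_t < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @property
    def n_lines(self) -> int:
        return sum(n for _, (n, _, _) in self.groups)


def expression_level(m: float, params: PanelGenParams, noise: float = 0.0) -> float:
    """Relative mRNA expression given methylation fraction m:
    10**(alpha - beta*m + noise)."""
    return float(10.0 ** (params.alpha - params.beta * m + noise))


def trail_inhibition(m4: float, m5: float, params: PanelGenParams, noise: float = 0.0) -> float:
    """Percent inhibition by rhsTRAIL given both methylation fractions.

    Either receptor suffices for killing, so availability is
    s = max(1 - m4, 1 - m5) and inhibition = 100*logistic(theta*(s - s0))
    plus noise, clipped to [-10, 100].
    """
    s = max(1.0 - m4, 1.0 - m5)
    inh = 100.0 * float(expit(params.theta * (s - params.s0)))
    return float(np.clip(inh + noise, -10.0, 100.0))


def simulate_panel(params: PanelGenParams) -> pd.DataFrame:
    """Generate a cell-line panel phenotype + truth-methylation table.

    Columns: sample_id, karyotype, dr4_pct, dr5_pct (truth mean percent
    methylation), expr_dr4, expr_dr5 (relative mRNA expression vs a TRAIL
    sensitive control line), rfi_dr4, rfi_dr5 (cell-surface relative
    fluorescence intensity), inhibition_pct (% inhibition by rhsTRAIL).
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    k = 0
    for group, (n, prior4, prior5) in params.groups:
        for _ in range(n):
            u = rng.random()  # shared high/low indicator -> nested hyper states
            m4 = prior4.draw(rng, u)
            m5 = prior5.draw(rng, u)
            expr = {}
            rfi = {}
            for recep, m in (("dr4", m4), ("dr5", m5)):
                expr[recep] = expression_level(m, params, rng.normal(0, params.sigma_e))
                rfi[recep] = 1.0 + params.rfi_scale * (1.0 - m) * float(
                    np.exp(rng.normal(0, params.sigma_rfi))
                )
            inh = trail_inhibition(m4, m5, params, rng.normal(0, params.sigma_t))
            rows.append(
                {
                    "sample_id": f"line{k:02d}",
                    "karyotype": group,
                    "dr4_pct": 100.0 * m4,
                    "dr5_pct": 100.0 * m5,
                    "expr_dr4": expr["dr4"],
                    "expr_dr5": expr["dr5"],
                    "rfi_dr4": rfi["dr4"],
                    "rfi_dr5": rfi["dr5"],
                    "inhibition_pct": inh,
                }
            )
            k += 1
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# array-style cohort
# --------------------------------------------------------------------------

#: Diagnostic BCP-ALL cross-section, 459 samples by karyotype subtype.
COHORT_SUBTYPE_COUNTS: dict[str, int] = {
    "high-hyperdiploid": 187,
    "ETV6-RUNX1": 164,
    "TCF3-PBX1": 23,
    "iAMP21": 10,
    "dic(9;20)": 20,
    "BCR-ABL1": 19,
    "MLLr": 28,
    "hypodiploid": 5,
    "polyploid": 3,
}

#: Default per-gene hypermethylation probability per subtype — the observed
#: per-subtype frequencies of promoter methylation >= 10% in the 459-sample
#: diagnostic cohort (zero in subtypes where none was seen).
DEFAULT_P_HYPER: dict[str, dict[str, float]] = {
    "DR4": {"TCF3-PBX1": 1 / 23, "dic(9;20)": 1 / 20, "MLLr": 2 / 28, "hypodiploid": 1 / 5},
    "DR5": {"dic(9;20)": 5 / 20, "MLLr": 10 / 28, "hypodiploid": 1 / 5},
}


@dataclass(frozen=True)
class CohortGenParams:
    """Array-cohort generator settings.

    Baseline (unmethylated) gene-level beta values sit around 0.025 —
    the 2–3% seen in remission marrow and normal lymphocytes — and
    hypermethylated ones around 0.30; the two modes are kept separated
    (baseline clipped to <=0.07, hypermethylated to >=0.13) because array
    promoter methylation is strongly bimodal, which also makes the >=10%
    flag coincide with the generator truth label.  By default DR4 and DR5
    hypermethylation indicators are nested (drawn from one shared uniform
    per sample), reproducing the positive inter-gene correlation.
    """

    subtype_counts: tuple = tuple(COHORT_SUBTYPE_COUNTS.items())
    p_hyper: tuple = (
        ("DR4", tuple(DEFAULT_P_HYPER["DR4"].items())),
        ("DR5", tuple(DEFAULT_P_HYPER["DR5"].items())),
    )
    baseline_mean: float = 0.025
    baseline_conc: float = 200.0
    baseline_gene_sd: float = 0.008
    hyper_mean: float = 0.30
    hyper_conc: float = 20.0
    probe_jitter_sd: float = 0.01
    n_pairs: int = 24
    p_relapse_up: float = 0.2
    n_remission: int = 25
    n_normal: int = 10
    n_decoy_probes: int = 20
    shared_hyper: bool = True
    seed: int = 0

    def __post_init__(self):
        for g, items in self.p_hyper:
            if any(not 0 <= p <= 1 for _, p in items):
                raise ValueError("hypermethylation probabilities must lie in [0, 1]")
        if self.p_relapse_up < 0 or self.p_relapse_up > 1:
            raise ValueError("p_relapse_up must lie in [0, 1]")


_GENE_SYMBOL = {"DR4": "TNFRSF10A", "DR5": "TNFRSF10B"}
_N_PROBES = {"DR4": 6, "DR5": 5}


def _make_annotation(params: CohortGenParams, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for gene, n in _N_PROBES.items():
        for i in range(n):
            rows.append(
                {"probe_id": f"cg{gene}_{i:02d}", "gene": _GENE_SYMBOL[gene],
                 "feature_group": "TSS200", "island_relation": "Island"}
            )
    # decoys: same genes in other feature groups / island relations, and
    # unrelated genes, so probe selection has something to reject
    feature_groups = ["TSS1500", "Body", "5'UTR"]
    relations = ["Shore", "Shelf", "OpenSea"]
    for i in range(params.n_decoy_probes):
        if i % 3 == 0:
            gene = _GENE_SYMBOL["DR4" if i % 2 else "DR5"]
            fg = feature_groups[i % len(feature_groups)]
            rel = "Island" if i % 2 else relations[i % len(relations)]
        else:
            gene = f"GENE{i:02d}"
            fg = "TSS200" if i % 2 else feature_groups[i % len(feature_groups)]
            rel = "Island" if i % 4 == 0 else relations[i % len(relations)]
        rows.append({"probe_id": f"cgDECOY_{i:03d}", "gene": gene,
                     "feature_group": fg, "island_relation": rel})
    return pd.DataFrame(rows)


def _draw_sample_baseline(rng, params: CohortGenParams) -> float:
    """Shared per-sample baseline methylation level.

    Both genes' baseline betas deviate around this value, which is what
    couples their ranks across unmethylated samples (cellularity and
    global methylation vary per sample, not per gene).
    """
    a = params.baseline_mean * params.baseline_conc
    b = params.baseline_conc - a
    return float(np.clip(rng.beta(a, b), 0.004, 0.06))


def _draw_gene_beta(rng, params: CohortGenParams, hyper: bool, b_base: float) -> float:
    if hyper:
        a = params.hyper_mean * params.hyper_conc
        b = params.hyper_conc - a
        return float(np.clip(rng.beta(a, b), 0.13, 0.95))
    return float(np.clip(b_base + rng.normal(0, params.baseline_gene_sd), 0.001, 0.07))


def simulate_array_cohort(
    params: CohortGenParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (beta matrix, sample table, probe annotation, truth table).

    The beta matrix has probes as rows and sample_ids as columns.  The
    sample table carries subtype, phase (diagnosis/relapse/remission/
    normal) and pair_id for the paired diagnosis/relapse samples (pairs
    reuse diagnostic samples, so the diagnostic cross-section size is
    exactly the sum of the subtype counts).  The truth table records the
    hypermethylation indicator per sample and gene.
    """
    rng = np.random.default_rng(params.seed)
    annotation = _make_annotation(params, rng)
    p_hyper = {g: dict(items) for g, items in params.p_hyper}

    samples = []
    truth_rows = []
    gene_beta: dict[str, dict[str, float]] = {g: {} for g in _N_PROBES}

    for subtype, n in params.subtype_counts:
        for i in range(n):
            sid = f"{subtype}_{i:03d}".replace(";", "").replace("(", "").replace(")", "")
            samples.append({"sample_id": sid, "subtype": subtype,
                            "phase": "diagnosis", "pair_id": ""})
            u_shared = rng.random()
            b_base = _draw_sample_baseline(rng, params)
            for gene in _N_PROBES:
                p = p_hyper.get(gene, {}).get(subtype, 0.0)
                u = u_shared if params.shared_hyper else rng.random()
                hyper = u < p
                gene_beta[gene][sid] = _draw_gene_beta(rng, params, hyper, b_base)
                truth_rows.append({"sample_id": sid, "gene": gene,
                                   "is_hyper": int(hyper), "relapse_up": 0})

    sample_df = pd.DataFrame(samples)
    diag_ids = sample_df.loc[sample_df.phase == "diagnosis", "sample_id"].tolist()
    n_pairs = min(params.n_pairs, len(diag_ids))
    paired = rng.choice(diag_ids, size=n_pairs, replace=False)
    truth = pd.DataFrame(truth_rows).set_index(["sample_id", "gene"])

    extra = []
    for j, sid in enumerate(paired):
        pair_id = f"pair{j:02d}"
        sample_df.loc[sample_df.sample_id == sid, "pair_id"] = pair_id
        rid = f"{sid}_rel"
        subtype = sample_df.loc[sample_df.sample_id == sid, "subtype"].iloc[0]
        extra.append({"sample_id": rid, "subtype": subtype,
                      "phase": "relapse", "pair_id": pair_id})
        u_shared = rng.random()
        b_base = _draw_sample_baseline(rng, params)
        for gene in _N_PROBES:
            diag_hyper = bool(truth.loc[(sid, gene), "is_hyper"])
            u = u_shared if params.shared_hyper else rng.random()
            up = (not diag_hyper) and (u < params.p_relapse_up)
            hyper = diag_hyper or up
            gene_beta[gene][rid] = _draw_gene_beta(rng, params, hyper, b_base)
            truth.loc[(rid, gene), :] = (int(hyper), int(up))

    for phase, n in (("remission", params.n_remission), ("normal", params.n_normal)):
        for i in range(n):
            sid = f"{phase}_{i:03d}"
            extra.append({"sample_id": sid, "subtype": phase,
                          "phase": phase, "pair_id": ""})
            b_base = _draw_sample_baseline(rng, params)
            for gene in _N_PROBES:
                gene_beta[gene][sid] = _draw_gene_beta(rng, params, False, b_base)
                truth.loc[(sid, gene), :] = (0, 0)

    sample_df = pd.concat([sample_df, pd.DataFrame(extra)], ignore_index=True)

    all_ids = sample_df.sample_id.tolist()
    beta = pd.DataFrame(index=annotation.probe_id, columns=all_ids, dtype=float)
    for gene, n in _N_PROBES.items():
        probes = [f"cg{gene}_{i:02d}" for i in range(n)]
        centers = np.array([gene_beta[gene][s] for s in all_ids])
        jitter = rng.normal(0, params.probe_jitter_sd, size=(n, len(all_ids)))
        beta.loc[probes, :] = np.clip(centers[None, :] + jitter, 0.0, 1.0)
    decoys = annotation.probe_id[annotation.probe_id.str.startswith("cgDECOY")]
    beta.loc[decoys, :] = np.clip(
        rng.beta(0.5, 0.5, size=(len(decoys), len(all_ids))), 0.0, 1.0
    )
    truth = truth.reset_index().astype({"is_hyper": int, "relapse_up": int})
    return beta, sample_df, annotation, truth
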