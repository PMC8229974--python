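"""450k-style cohort aggregation: probe selection, per-sample gene
methylation, subtype summaries, and paired diagnosis/relapse deltas.

Gene-level methylation is the mean beta of the probes annotated as both
TSS200 (0-200 bases upstream of the transcription start site) and CpG
island for the gene, expressed as a percent (100*beta).  Missing betas
are excluded pairwise; a sample is missing only if all its gene probes
are missing.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from . import stats as _stats

__all__ = [
    "NoProbesError",
    "select_probes",
    "gene_methylation",
    "subtype_summary",
    "paired_delta",
    "cohort_correlation",
]

FEATURE_GROUPS = {"TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR"}
ISLAND_RELATIONS = {"Island", "Shore", "Shelf", "OpenSea"}


class NoProbesError(ValueError):
    """No probe matches the selection rule for the gene."""


def select_probes(
    annotation: pd.DataFrame,
    gene: str,
    feature_group: str = "TSS200",
    require_island: bool = True,
) -> list[str]:
    """Probe ids annotated to ``gene`` in ``feature_group`` (and on a CpG
    island when ``require_island``), order-stable by probe_id."""
    if annotation.empty:
        raise ValueError("empty annotation")
    mask = (annotation["gene"] == gene) & (annotation["feature_group"] == feature_group)
    if require_island:
        mask &= annotation["island_relation"] == "Island"
    probes = sorted(annotation.loc[mask, "probe_id"].tolist())
    if not probes:
        raise NoProbesError(f"no probes for gene {gene!r}")
    return probes


def gene_methylation(beta_matrix: pd.DataFrame, probes: list[str]) -> pd.Series:
    """Per-sample percent methylation: 100 x mean beta over the probes.

    NaN betas are excluded per sample; the result is NaN only when every
    probe is missing for that sample.
    """
    if not probes:
        raise ValueError("empty probe list")
    missing = [p for p in probes if p not in beta_matrix.index]
    if missing:
        raise KeyError(f"probes absent from beta matrix: {missing}")
    sub = beta_matrix.loc[probes].astype(float)
    if ((sub < 0) | (sub > 1)).any().any():
        raise ValueError("beta values must lie in [0, 1]")
    return 100.0 * sub.mean(axis=0, skipna=True)


def subtype_summary(
    gene_pct: pd.Series,
    samples: pd.DataFrame,
    threshold: float = 10.0,
) -> pd.DataFrame:
    """Counts of samples at or above ``threshold`` percent per subtype.

    ``gene_pct`` is indexed by sample_id; ``samples`` must provide a
    subtype for every sample in it.  The returned table has one row per
    subtype plus an 'overall' row with the total count and percentage.
    """
    sub = samples.set_index("sample_id")["subtype"]
    missing = gene_pct.index.difference(sub.index)
    if len(missing):
        raise ValueError(f"samples missing subtype: {list(missing)[:5]}")
    df = pd.DataFrame({"pct": gene_pct, "subtype": sub.reindex(gene_pct.index)})
    rows = []
    for subtype, grp in df.groupby("subtype", sort=False):
        n_ge = int((grp.pct >= threshold).sum())
        rows.append({"subtype": subtype, "n": len(grp), "n_ge_threshold": n_ge,
                     "fraction": n_ge / len(grp)})
    total = len(df)
    n_ge = int((df.pct >= threshold).sum())
    rows.append({"subtype": "overall", "n": total, "n_ge_threshold": n_ge,
                 "fraction": n_ge / total if total else np.nan})
    return pd.DataFrame(rows)


def paired_delta(
    gene_pct: pd.Series,
    samples: pd.DataFrame,
    gene: str = "",
    margin: float = 5.0,
) -> pd.DataFrame:
    """Per-pair (diagnosis, relapse, delta) with an upregulated flag.

    Pairs are defined by pair_id: exactly one diagnosis and one relapse
    sample must share each pair_id.  ``upregulated`` means the relapse
    value exceeds the diagnosis value by more than ``margin`` percentage
    points.
    """
    paired = samples[samples["pair_id"].astype(str) != ""]
    rows = []
    for pair_id, grp in paired.groupby("pair_id"):
        diag = grp[grp.phase == "diagnosis"]
        rel = grp[grp.phase == "relapse"]
        if len(diag) != 1 or len(rel) != 1:
            raise ValueError(f"broken pair {pair_id!r}: needs one diagnosis and one relapse sample")
        d = float(gene_pct[diag.sample_id.iloc[0]])
        r = float(gene_pct[rel.sample_id.iloc[0]])
        rows.append({"pair_id": pair_id, "gene": gene,
                     "diagnosis_pct": d, "relapse_pct": r,
                     "delta": r - d, "upregulated": (r - d) > margin})
    return pd.DataFrame(rows).sort_values("pair_id").reset_index(drop=True)


def cohort_correlation(
    dr4_pct: pd.Series,
    dr5_pct: pd.Series,
    floor: float = _stats.DEFAULT_LOG_FLOOR,
) -> _stats.CorrelationResult:
    """Spearman correlation of the two genes' log10-floored percents over
    the samples present in both series."""
    common = dr4_pct.index.intersection(dr5_pct.index)
    x = _stats.log10_percent(dr4_pct.loc[common].to_numpy(), floor)
    y = _stats.log10_percent(dr5_pct.loc[common].to_numpy(), floor)
    return _stats.spearman(x, y)
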