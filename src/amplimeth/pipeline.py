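"""End-to-end reproducible runs: configuration, stage orchestration,
heat-map style matrices, and a run manifest.

All artifacts are plain-text TSV/JSON; a run re-executed from its emitted
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .amplicon import MethylationProfile
from .caller import CallerParams, quantify, SiteSummary
from .cohort import gene_methylation, paired_delta, select_probes, subtype_summary, cohort_correlation
from .phenotype import classify_methylation, classify_trail
from .simulate import (
    CohortGenParams,
    PanelGenParams,
    ReadSimParams,
    simulate_array_cohort,
    simulate_panel,
    simulate_reads,
    synthetic_amplicon,
    write_fastq,
    _GENE_SYMBOL,
    _N_PROBES,
)
from .stats import associate_panel

__all__ = ["RunConfig", "run_pipeline", "heatmap_matrix", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and reason."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full demo run (all stages on synthetic data)."""

    seed: int = 0
    n_samples: int = 4
    n_reads: int = 400
    conversion_rate: float = 0.995
    inappropriate_conversion: float = 0.005
    subst_error: float = 0.005
    min_coverage: int = 50
    cohort: bool = True
    panel: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def heatmap_matrix(site_summaries: dict[str, list[SiteSummary]]) -> pd.DataFrame:
    """Samples x CpG-sites matrix of percent methylation.

    All samples must share the amplicon (same site offsets); sites below
    the coverage threshold appear as NaN (empty cells in TSV).
    """
    offsets = None
    rows = {}
    for sample, sites in site_summaries.items():
        offs = tuple(s.offset for s in sites)
        if offsets is None:
            offsets = offs
        elif offs != offsets:
            raise ValueError("amplicon mismatch: site offsets differ between samples")
        rows[sample] = [
            np.nan if s.percent_methylation is None else s.percent_methylation
            for s in sites
        ]
    cols = [f"site{j}_off{o}" for j, o in enumerate(offsets or ())]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _log(msg: str, t0: float) -> None:
    print(f"[amplimeth +{time.time() - t0:6.1f}s] {msg}", file=sys.stderr)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute simulate -> call -> classify -> associate -> cohort.

    Writes all stage TSV/JSON outputs plus a manifest (package version,
    seed, config hash, stage list) under ``outdir`` and returns the
    manifest dict.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages = []
    rng = np.random.default_rng(config.seed)

    # --- simulate: bisulfite reads with per-sample truth profiles --------
    stage = "simulate"
    try:
        amplicons = {g: synthetic_amplicon(g) for g in ("DR4", "DR5")}
        truth_levels = {}
        fastqs = {}
        for i in range(config.n_samples):
            for gene, amp in amplicons.items():
                level = float(rng.choice([0.004, 0.05, 0.35, 0.9]))
                prof = MethylationProfile([level] * amp.n_sites)
                params = ReadSimParams(
                    n_reads=config.n_reads,
                    conversion_rate=config.conversion_rate,
                    inappropriate_conversion=config.inappropriate_conversion,
                    subst_error=config.subst_error,
                    seed=int(rng.integers(2**31 - 1)),
                )
                recs, _ = simulate_reads(amp, prof, params)
                path = out / f"sample{i:02d}_{gene}.fastq"
                write_fastq(recs, path)
                fastqs[(i, gene)] = path
                truth_levels[(i, gene)] = level
        stages.append(stage)
        _log(f"{stage}: {len(fastqs)} FASTQ files", t0)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage {stage}: {e}") from e

    # --- call: per-sample per-site methylation ---------------------------
    stage = "call"
    try:
        cparams = CallerParams(min_coverage=config.min_coverage)
        means = {}
        site_summaries = {g: {} for g in amplicons}
        for (i, gene), path in fastqs.items():
            res = quantify(path, amplicons[gene], cparams)
            means[(i, gene)] = res.summary.mean_percent_methylation
            site_summaries[gene][f"sample{i:02d}"] = res.sites
            res.site_table().to_csv(out / f"sample{i:02d}_{gene}_sites.tsv",
                                    sep="\t", index=False)
        for gene in amplicons:
            heatmap_matrix(site_summaries[gene]).to_csv(
                out / f"heatmap_{gene}.tsv", sep="\t", float_format="%.3f"
            )
        stages.append(stage)
        _log(f"{stage}: quantified {len(means)} sample/gene pairs", t0)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage {stage}: {e}") from e

    # --- classify: methylation and TRAIL categories on the panel ---------
    stage = "classify"
    try:
        panel = simulate_panel(PanelGenParams(seed=config.seed)) if config.panel else None
        if panel is not None:
            calls = [classify_methylation(r.dr4_pct, r.dr5_pct) for r in panel.itertuples()]
            panel_out = panel.copy()
            panel_out["methylation_category"] = [c.category.value for c in calls]
            panel_out["highly_methylated"] = [c.highly_methylated for c in calls]
            panel_out["trail_category"] = [
                classify_trail(v).value for v in panel.inhibition_pct
            ]
            panel_out.to_csv(out / "panel_classified.tsv", sep="\t",
                             index=False, float_format="%.4f")
        stages.append(stage)
        _log(f"{stage}: panel of {0 if panel is None else len(panel)} lines", t0)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage {stage}: {e}") from e

    # --- associate: panel statistics -------------------------------------
    stage = "associate"
    try:
        if panel is not None:
            report = associate_panel(panel)
            report.to_csv(out / "associations.tsv", sep="\t", index=False,
                          float_format="%.6g")
        stages.append(stage)
        _log(f"{stage}: association report written", t0)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage {stage}: {e}") from e

    # --- cohort: array-style aggregation ----------------------------------
    stage = "cohort"
    try:
        if config.cohort:
            beta, samples, annotation, _truth = simulate_array_cohort(
                CohortGenParams(seed=config.seed)
            )
            diag = samples[samples.phase == "diagnosis"]
            pcts = {}
            for gene, symbol in _GENE_SYMBOL.items():
                probes = select_probes(annotation, symbol)
                pct = gene_methylation(beta, probes)
                pcts[gene] = pct
                subtype_summary(pct.loc[diag.sample_id], samples).to_csv(
                    out / f"cohort_{gene}_subtypes.tsv", sep="\t", index=False,
                    float_format="%.4f"
                )
                paired_delta(pct, samples, gene=gene).to_csv(
                    out / f"cohort_{gene}_pairs.tsv", sep="\t", index=False,
                    float_format="%.4f"
                )
            corr = cohort_correlation(pcts["DR4"].loc[diag.sample_id],
                                      pcts["DR5"].loc[diag.sample_id])
            (out / "cohort_correlation.json").write_text(json.dumps(
                {"rho": corr.rho, "r_squared": corr.r_squared,
                 "p_value": corr.p_value, "n": corr.n}, indent=2))
        stages.append(stage)
        _log(f"{stage}: cohort outputs written", t0)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(f"stage {stage}: {e}") from e

    config_json = config.to_json()
    manifest = {
        "package": "amplimeth",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "stages": stages,
    }
    (out / "config.json").write_text(config_json)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
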