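"""End-to-end pipeline: wire the analysis stages over files on disk.

Each stage reads/writes plain-text tables so any subset can be re-run; a
JSON manifest records seeds, thresholds and per-stage record counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import io as mio
from .diffexpr import NBDiffExpression
from .events import build_events, flag_nmd
from .m6a import assign_peaks, enrichment_test, ptc_association
from .motifs import (
    center_enrichment, density_profile, extract_windows, match_random_regions,
)
from .psi import compute_psi, delta_psi, combine_knockdowns
from .survival import CoxLassoRisk

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    Quantification inputs are given per knockdown: each entry of
    ``quant_samples`` maps a sample name to its quantifier TSV, with
    ``conditions`` naming each sample's condition.  Stages whose inputs are
    absent are skipped.
    """

    annotation_path: str | Path | None = None
    quant_samples: list[dict[str, str]] = field(default_factory=list)
    conditions: dict[str, str] = field(default_factory=dict)
    control_condition: str = "control"
    treatment_condition: str = "knockdown"
    peaks_path: str | Path | None = None
    genome_path: str | Path | None = None
    clinical_path: str | Path | None = None
    motif: str = "DRACH"
    dse_fdr: float = 0.05
    enrichment_alpha: float = 0.01
    km_alpha: float = 0.05
    window_half_width: int = 150
    profile_half_range: int = 80
    risk_quantile: float = 0.75
    seed: int = 0
    outdir: str | Path = "results"

    def __post_init__(self) -> None:
        for t in (self.dse_fdr, self.enrichment_alpha, self.km_alpha):
            if not (0 < t < 1):
                raise ValueError("thresholds must lie in (0, 1)")
        if self.window_half_width <= 0 or self.profile_half_range <= 0:
            raise ValueError("window sizes must be positive")
        if self.genome_path is None and self.peaks_path is not None:
            # motif profiling needs sequence; fail before any computation
            if self.motif:
                raise ValueError(
                    "motif profiling requested (peaks given) but no genome FASTA"
                )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            "dse_fdr": config.dse_fdr,
            "enrichment_alpha": config.enrichment_alpha,
            "km_alpha": config.km_alpha,
        },
        "stages": {},
    }

    annotation = events = None
    if config.annotation_path:
        annotation = mio.read_gtf(config.annotation_path)
        events = build_events(annotation)
        mio.write_events_table(events, out / "events.tsv")
        manifest["stages"]["events"] = {"n_events": len(events)}

    combined = None
    dse_tables = []
    if events and config.quant_samples:
        for k, sample_paths in enumerate(config.quant_samples, 1):
            quant = mio.read_quant(sample_paths, config.conditions)
            psi = compute_psi(events, quant)
            psi.psi.to_csv(out / f"psi_kd{k}.tsv", sep="\t")
            dse = delta_psi(psi, config.control_condition,
                            config.treatment_condition)
            dse.to_csv(out / f"dse_kd{k}.tsv", sep="\t")
            dse_tables.append(dse)
            # differential expression on the same counts
            model = NBDiffExpression(quant.counts, quant.conditions)
            res = model.fit(config.control_condition,
                            config.treatment_condition)
            res.table.to_csv(out / f"deg_kd{k}.tsv", sep="\t")
            manifest["stages"][f"kd{k}"] = {
                "n_events_tested": len(dse),
                "n_dse": int((dse["fdr"] < config.dse_fdr).sum()),
                "n_deg": int((res.table["fdr"] < config.dse_fdr).sum()),
            }
        if len(dse_tables) >= 2:
            combined = combine_knockdowns(dse_tables[0], dse_tables[1],
                                          alpha=config.dse_fdr)
        else:
            combined = dse_tables[0][dse_tables[0]["fdr"] < config.dse_fdr]
        combined.to_csv(out / "dse_combined.tsv", sep="\t")
        manifest["stages"]["combine"] = {"n_combined_dse": len(combined)}

    if events and config.peaks_path and combined is not None:
        peaks = mio.read_bed(config.peaks_path)
        se_events = [e for e in events if e.event_type == "SE"]
        m6a_flags = assign_peaks(
            peaks, se_events,
            valid_contigs=set(annotation.contig_lengths) or None,
        )
        dse_flags = pd.Series(
            {e.event_id: e.event_id in combined.index for e in se_events}
        )
        enr = enrichment_test(dse_flags, m6a_flags)
        pd.DataFrame(
            enr.table, index=["DSE", "non-DSE"], columns=["m6A+", "m6A-"]
        ).to_csv(out / "m6a_contingency.tsv", sep="\t")
        manifest["stages"]["m6a"] = {
            "fisher_p": enr.pvalue,
            "fraction_dse_m6a": enr.fraction_significant_flagged,
            "significant": bool(enr.pvalue < config.enrichment_alpha),
        }
        nmd = flag_nmd(annotation)
        if nmd:
            ptc = ptc_association(se_events, nmd, dse_flags)
            manifest["stages"]["ptc"] = {"fisher_p": ptc.pvalue}

        if config.genome_path:
            genome = mio.read_fasta(config.genome_path)
            wp = extract_windows(peaks, genome, config.window_half_width)
            wr = match_random_regions(peaks, annotation, genome,
                                      seed=config.seed,
                                      half_width=config.window_half_width)
            prof_p = density_profile(wp, config.motif,
                                     config.profile_half_range, "peaks")
            prof_r = density_profile(wr, config.motif,
                                     config.profile_half_range, "random")
            pd.DataFrame({
                "position": prof_p.positions,
                "density_peaks": prof_p.density,
                "density_random": prof_r.density,
            }).to_csv(out / "motif_density.tsv", sep="\t", index=False)
            ce = center_enrichment(wp, wr, config.motif, seed=config.seed)
            manifest["stages"]["motif"] = {
                "center_ratio": ce.ratio, "permutation_p": ce.pvalue,
            }

    if config.clinical_path:
        cohort = mio.read_clinical(config.clinical_path)
        res = CoxLassoRisk(cohort, quantile=config.risk_quantile).fit(
            seed=config.seed
        )
        mio.write_json(
            {"betas": res.betas.to_dict(),
             "penalty": res.risk_model.penalty,
             "cutoff": res.risk_model.cutoff},
            out / "risk_model.json",
        )
        pd.DataFrame({"score": res.scores, "group": res.groups}).to_csv(
            out / "risk_scores.tsv", sep="\t"
        )
        chi2, p = res.logrank()
        manifest["stages"]["survival"] = {
            "n_high": int((res.groups == "high").sum()),
            "n_low": int((res.groups == "low").sum()),
            "logrank_chi2": chi2,
            "logrank_p": p,
            "significant": bool(p < config.km_alpha),
        }

    mio.write_json(manifest, out / "manifest.json")
    return manifest
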