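"""Percent-spliced-in (PSI) computation and differential splicing.

PSI of an event in a sample is the fraction of the event's transcript
abundance (TPM) carried by the inclusion isoforms:

    PSI = sum TPM(inclusion) / sum TPM(inclusion + exclusion)

Differential splicing between two conditions scores the difference of
condition-mean PSI (dPSI) against an empirical null built from
between-replicate PSI fluctuations of events with similar expression,
followed by Benjamini–Hochberg FDR control.  Two independent knockdowns
against the same control are combined by intersection with sign concordance,
the standard guard against shRNA off-target effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .events import ASEvent

logger = logging.getLogger(__name__)


@dataclass
class QuantTable:
    """Transcript quantifications: TPM and read counts per sample."""

    tpm: pd.DataFrame  # transcripts x samples
    counts: pd.DataFrame  # transcripts x samples
    conditions: dict[str, str]  # sample -> condition label
    lengths: pd.Series | None = None
    effective_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.tpm.values < 0).any():
            raise ValueError("negative TPM values")
        if not self.tpm.columns.equals(self.counts.columns):
            raise ValueError("TPM and count tables have different samples")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.tpm.columns if self.conditions.get(s) == condition]


@dataclass
class PSIMatrix:
    """Events x samples PSI values plus total event abundance."""

    psi: pd.DataFrame  # events x samples, NaN = undefined
    total_tpm: pd.DataFrame  # events x samples
    conditions: dict[str, str] = field(default_factory=dict)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.psi.columns if self.conditions.get(s) == condition]


def compute_psi(
    events: list[ASEvent], quant: QuantTable, *, min_total_tpm: float = 0.0
) -> PSIMatrix:
    """Per-sample PSI for each event from transcript TPMs.

    PSI is undefined (NaN) where the event's total TPM does not exceed
    ``min_total_tpm`` (always undefined at exactly zero).  Unknown transcript
    ids raise, naming the offending event.
    """
    tpm = quant.tpm
    known = set(tpm.index)
    inc_rows = np.zeros((len(events), tpm.shape[1]))
    tot_rows = np.zeros_like(inc_rows)
    ids = []
    for k, ev in enumerate(events):
        missing = (ev.inclusion_transcripts | ev.exclusion_transcripts) - known
        if missing:
            raise KeyError(
                f"event {ev.event_id}: transcripts absent from quantification: "
                f"{sorted(missing)}"
            )
        inc = tpm.loc[sorted(ev.inclusion_transcripts)].sum(axis=0)
        exc = tpm.loc[sorted(ev.exclusion_transcripts)].sum(axis=0)
        inc_rows[k] = inc.values
        tot_rows[k] = inc.values + exc.values
        ids.append(ev.event_id)
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = inc_rows / tot_rows
    psi[(tot_rows <= min_total_tpm) | (tot_rows == 0.0)] = np.nan
    return PSIMatrix(
        psi=pd.DataFrame(psi, index=ids, columns=tpm.columns),
        total_tpm=pd.DataFrame(tot_rows, index=ids, columns=tpm.columns),
        conditions=dict(quant.conditions),
    )


def delta_psi(
    psi: PSIMatrix,
    cond_a: str,
    cond_b: str,
    *,
    expression_floor: float = 1.0,
    n_bins: int = 10,
    min_defined_fraction: float = 0.5,
) -> pd.DataFrame:
    """Differential PSI between two conditions with empirical significance.

    dPSI = mean PSI(cond_b) - mean PSI(cond_a).  The null distribution is
    the pool of absolute between-replicate PSI differences within conditions,
    collected from events of similar abundance (``n_bins`` equal-occupancy
    bins of log total event TPM) and rescaled by sqrt((1/nA + 1/nB)/2) so its
    spread matches that of a difference of condition means.  p-values are the
    empirical tail probability (add-one corrected); FDR is Benjamini–Hochberg.

    Events undefined in more than half the samples of either condition, or
    with condition-mean total TPM below ``expression_floor`` in either
    condition, are dropped and counted in the log.
    """
    sa = psi.samples_for(cond_a)
    sb = psi.samples_for(cond_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need >= 2 replicates per condition")
    pa, pb = psi.psi[sa], psi.psi[sb]
    ta, tb = psi.total_tpm[sa], psi.total_tpm[sb]

    defined_ok = (pa.notna().mean(axis=1) >= min_defined_fraction) & (
        pb.notna().mean(axis=1) >= min_defined_fraction
    )
    expressed = (ta.mean(axis=1) >= expression_floor) & (
        tb.mean(axis=1) >= expression_floor
    )
    keep = defined_ok & expressed
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("delta_psi: dropped %d/%d events (undefined or below "
                    "expression floor)", n_dropped, len(keep))
    pa, pb, ta, tb = pa[keep], pb[keep], ta[keep], tb[keep]
    if pa.empty:
        return pd.DataFrame(
            columns=["event_id", "dpsi", "pvalue", "fdr", "sign"]
        ).set_index("event_id")

    dpsi = pb.mean(axis=1, skipna=True) - pa.mean(axis=1, skipna=True)
    scale = np.sqrt((1.0 / len(sa) + 1.0 / len(sb)) / 2.0)

    # per-event pool of within-condition between-replicate |dPSI|
    null_values: list[np.ndarray] = []
    null_owner: list[np.ndarray] = []
    for block in (pa, pb):
        vals = block.values
        for i, j in combinations(range(vals.shape[1]), 2):
            d = np.abs(vals[:, i] - vals[:, j]) * scale
            null_values.append(d)
            null_owner.append(np.arange(len(block)))
    null_all = np.concatenate(null_values)
    owner_all = np.concatenate(null_owner)

    abundance = np.log10(0.5 * (ta.mean(axis=1) + tb.mean(axis=1)).values + 1e-9)
    # keep >= ~30 events per bin so the empirical tail stays resolvable
    n_bins_eff = max(1, min(n_bins, len(abundance) // 30,
                            len(np.unique(abundance))))
    try:
        bins = pd.qcut(abundance, n_bins_eff, labels=False, duplicates="drop")
    except ValueError:
        bins = np.zeros(len(abundance), dtype=int)
    bins = np.asarray(bins, dtype=int)

    pvals = np.ones(len(dpsi))
    obs = np.abs(dpsi.values)
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        pool = null_all[~np.isnan(null_all) & np.isin(owner_all, members)]
        pool = np.sort(pool)
        if pool.size == 0:
            continue
        # count of null >= |obs| via searchsorted on the sorted pool
        ge = pool.size - np.searchsorted(pool, obs[members] - 1e-12, side="left")
        pvals[members] = (1.0 + ge) / (1.0 + pool.size)

    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "dpsi": dpsi.values,
            "pvalue": pvals,
            "fdr": fdr,
            "sign": np.sign(dpsi.values),
        },
        index=pd.Index(dpsi.index, name="event_id"),
    )
    return out


def combine_knockdowns(
    dse1: pd.DataFrame, dse2: pd.DataFrame, *, alpha: float = 0.05
) -> pd.DataFrame:
    """Intersect two knockdown DSE tables (same control) with sign concordance.

    An event is retained iff FDR < ``alpha`` in both inputs and the dPSI signs
    agree; reported dPSI is the mean of the two, reported p (and FDR) the
    maximum — the conservative choice for an intersection rule.
    """
    common = dse1.index.intersection(dse2.index)
    if len(common) == 0:
        logger.warning("combine_knockdowns: disjoint event universes")
        return pd.DataFrame(
            columns=["dpsi", "pvalue", "fdr", "sign"],
            index=pd.Index([], name="event_id"),
        )
    a, b = dse1.loc[common], dse2.loc[common]
    keep = (
        (a["fdr"] < alpha)
        & (b["fdr"] < alpha)
        & (np.sign(a["dpsi"]) == np.sign(b["dpsi"]))
        & (np.sign(a["dpsi"]) != 0)
    )
    out = pd.DataFrame(
        {
            "dpsi": 0.5 * (a["dpsi"] + b["dpsi"]),
            "pvalue": np.maximum(a["pvalue"], b["pvalue"]),
            "fdr": np.maximum(a["fdr"], b["fdr"]),
            "sign": np.sign(a["dpsi"]),
        },
        index=common,
    )[keep.values]
    out.index.name = "event_id"
    return out
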