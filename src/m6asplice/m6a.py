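"""Intronic m6A / differential-splicing association.

Peaks are assigned to skipped-exon events when a peak *summit* falls inside
either flanking intron of the cassette exon; 2x2 enrichment of the m6A flag
(or the PTC flag) in significant vs non-significant events is scored with a
two-sided Fisher exact test computed in exact integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .events import ASEvent, NMDFlag
from .peaks import PeakSet


def assign_peaks(
    peaks: PeakSet,
    events: list[ASEvent],
    *,
    valid_contigs: set[str] | None = None,
    mode: str = "summit",
) -> pd.Series:
    """Flag SE events whose flanking introns carry an m6A peak.

    ``mode="summit"`` (default) requires a peak summit inside a flanking
    intron; ``mode="overlap"`` accepts any overlap of the peak interval.
    Peaks on contigs unknown to the annotation raise, listing the offenders.
    """
    if mode not in ("summit", "overlap"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    se = [e for e in events if e.event_type == "SE"]
    contigs = valid_contigs if valid_contigs is not None else {e.contig for e in se}
    unmatched = sorted(peaks.contigs() - contigs)
    if unmatched:
        raise ValueError(f"peaks on contigs absent from annotation: {unmatched}")

    by_contig: dict[str, list] = {}
    for p in peaks:
        by_contig.setdefault(p.contig, []).append(p)

    flags = {}
    for ev in se:
        hit = False
        for s, e in ev.flanking_introns:
            for p in by_contig.get(ev.contig, ()):
                if mode == "summit":
                    if s <= p.summit < e:
                        hit = True
                        break
                else:
                    if p.start < e and s < p.end:
                        hit = True
                        break
            if hit:
                break
        flags[ev.event_id] = hit
    return pd.Series(flags, dtype=bool, name="m6a")


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, by integer enumeration.

    p is the sum of hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed that of the observed table.
    Hypergeometric weights C(r1,k)*C(r2,c1-k) are integers, so the "no more
    likely than observed" comparison is exact — no floating-point ties.
    A zero row or column margin yields p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    return float(num / sum(weights))


@dataclass
class EnrichmentResult:
    """2x2 association of a binary event attribute with DSE status."""

    table: np.ndarray  # rows: [significant, non-significant]; cols: [flag+, flag-]
    pvalue: float
    fraction_significant_flagged: float

    def summary(self) -> str:
        (a, b), (c, d) = self.table
        return (
            "          flag+  flag-\n"
            f"DSE       {a:5d}  {b:5d}\n"
            f"non-DSE   {c:5d}  {d:5d}\n"
            f"Fisher two-sided p = {self.pvalue:.4g}; "
            f"flagged fraction among DSE = "
            f"{self.fraction_significant_flagged:.3f}"
        )


def enrichment_test(dse_flags: pd.Series, attr_flags: pd.Series) -> EnrichmentResult:
    """Cross-tabulate DSE status against a binary flag and Fisher-test it.

    Also reports the fraction of significant events carrying the flag (the
    "more than half of the flanking introns harbor m6A" style statistic).
    The event universe is the intersection of the two flag maps.
    """
    common = dse_flags.index.intersection(attr_flags.index)
    if len(common) == 0:
        raise ValueError("enrichment_test: flag maps share no events")
    dse = dse_flags.loc[common].astype(bool)
    attr = attr_flags.loc[common].astype(bool)
    a = int((dse & attr).sum())
    b = int((dse & ~attr).sum())
    c = int((~dse & attr).sum())
    d = int((~dse & ~attr).sum())
    table = np.array([[a, b], [c, d]])
    frac = a / (a + b) if (a + b) > 0 else float("nan")
    return EnrichmentResult(table, fisher_exact_2x2(table), frac)


def ptc_flags_for_events(
    events: list[ASEvent], nmd_flags: list[NMDFlag]
) -> pd.Series:
    """Event-level PTC status: any event transcript classified PTC+."""
    ptc_tx = {f.transcript_id for f in nmd_flags if f.is_ptc}
    return pd.Series(
        {
            e.event_id: bool(
                (e.inclusion_transcripts | e.exclusion_transcripts) & ptc_tx
            )
            for e in events
        },
        dtype=bool,
        name="ptc",
    )


def ptc_association(
    events: list[ASEvent],
    nmd_flags: list[NMDFlag],
    dse_flags: pd.Series,
) -> EnrichmentResult:
    """PTC/NMD analogue of the m6A enrichment test (same 2x2 machinery)."""
    return enrichment_test(dse_flags, ptc_flags_for_events(events, nmd_flags))
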