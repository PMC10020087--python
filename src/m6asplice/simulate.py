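"""Synthetic-data generator with known ground truth.

Every input the pipeline consumes can be generated here: a gene annotation
realizing all seven AS event classes (one event per gene, on independent
contigs), replicate transcript quantifications with condition-specific
isoform-usage shifts and NB count noise, m6A-style peak sets enriched in the
flanking introns of planted differential events, genome sequence with a
motif instance planted at each peak summit, and a patient cohort whose
hazard follows a proportional-hazards model on PSI covariates.

All generators are deterministic functions of ``SimConfig.seed``; each stage
draws from its own child stream so stages can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit
import pandas as pd

from .annotation import GeneAnnotation, Interval, Transcript
from .events import EVENT_TYPES, build_events, flag_nmd
from .motifs import IUPAC, reverse_complement
from .peaks import Peak, PeakSet
from .psi import QuantTable
from .survival import SurvivalCohort

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for the synthetic pipeline inputs.

    The defaults emulate a two-condition knockdown experiment with three
    replicates, a moderate isoform-usage shift (dPSI 0.3) planted in 20% of
    genes, bulk-RNA-seq-like NB overdispersion (phi = 0.1), strong intronic
    peak enrichment at planted events over a sparse background, a canonical
    DRACH instance at peak summits, and a 1000-patient cohort with hazard
    coefficients (1.5, -1.5, 0) and 20% independent censoring.
    """

    n_genes: int = 200
    isoforms_per_gene: tuple[int, int] = (2, 2)
    event_mix: dict[str, float] = field(
        default_factory=lambda: {t: 1.0 / 7.0 for t in EVENT_TYPES}
    )
    n_replicates: int = 3
    condition_names: tuple[str, str] = ("control", "knockdown")
    dse_fraction: float = 0.2
    psi_shift: float = 0.3
    psi_noise_sd: float = 0.25  # logit-scale between-replicate usage noise
    expr_noise_sd: float = 0.15  # log-scale multiplicative expression noise
    expr_log_mean: float = 2.5  # ln TPM of gene expression
    expr_log_sd: float = 1.0
    depth_factor: float = 1e-3  # expected counts per (TPM x nt effective length)
    dispersion_fn: Callable | None = None  # mean -> phi; default constant 0.1
    peak_enrichment_fraction: float = 0.8
    background_peak_rate: float = 0.1  # peaks per kb of non-target intron
    peak_width: int = 150
    motif: str = "GGACT"
    n_patients: int = 1000
    true_betas: tuple[float, ...] = (1.5, -1.5, 0.0)
    baseline_hazard: float = 0.1
    censor_rate: float = 0.2
    ptc_fraction: float = 0.0
    exon_length: int = 150
    intron_length: int = 1000
    pad: int = 400  # flanking sequence per contig end
    alt_ext: int = 60  # extension of the alternative 5'/3' splice-site exon
    terminal_gap: int = 300  # spacing between alternative terminal exons
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_replicates <= 0 or self.n_patients <= 0:
            raise ValueError("counts must be positive")
        if self.isoforms_per_gene != (2, 2):
            raise ValueError(
                "each gene realizes its event with the canonical two-isoform "
                "pair; isoforms_per_gene must be (2, 2)"
            )
        unknown = set(self.event_mix) - set(EVENT_TYPES)
        if unknown:
            raise ValueError(f"event_mix covers unknown types: {sorted(unknown)}")
        total = sum(self.event_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("event_mix proportions must sum to 1")
        if not (0.0 < self.psi_shift <= 1.0):
            raise ValueError("psi_shift must lie in (0, 1]")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must lie in [0, 1)")
        if min(self.exon_length, self.intron_length, self.pad) <= 0:
            raise ValueError("impossible geometry: lengths must be positive")
        if self.psi_shift > 0.6:
            # base PSI is drawn in [0.35, 0.65]; larger shifts leave [0, 1]
            raise ValueError("psi_shift > 0.6 cannot be planted within [0, 1]")

    def dispersion(self, mean):
        if self.dispersion_fn is None:
            return np.full_like(np.asarray(mean, dtype=float), 0.1)
        return np.asarray(self.dispersion_fn(mean), dtype=float)


@dataclass
class GroundTruth:
    """What was planted: the key against which recovery is judged."""

    gene_types: dict[str, str] = field(default_factory=dict)
    gene_to_event: dict[str, str] = field(default_factory=dict)
    expression: dict[str, float] = field(default_factory=dict)
    true_psi: dict[str, dict[str, float]] = field(default_factory=dict)
    dse_events: list[str] = field(default_factory=list)
    dse_direction: dict[str, int] = field(default_factory=dict)
    peak_events: list[str] = field(default_factory=list)
    motif_positions: list[tuple[str, int]] = field(default_factory=list)
    true_betas: dict[str, float] = field(default_factory=dict)
    ptc_transcripts: list[str] = field(default_factory=list)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# --- annotation ------------------------------------------------------------

def _gene_structures(
    etype: str, strand: str, config: SimConfig
) -> tuple[tuple[Interval, ...], tuple[Interval, ...]]:
    """Exon structures (inclusion form, exclusion form) in genomic coords.

    Strand-mirrored classes (A5/A3, AF/AL) switch their genomic construction
    with the strand so the emitted event class matches the request.
    """
    E, I, P = config.exon_length, config.intron_length, config.pad
    ext, gap = config.alt_ext, config.terminal_gap

    def chain(start: int, *lengths_gaps) -> list[Interval]:
        exons, pos = [], start
        for length, gap_after in lengths_gaps:
            exons.append((pos, pos + length))
            pos += length + gap_after
        return exons

    if etype == "SE":
        a, b, c = chain(P, (E, I), (E, I), (E, 0))
        return (a, b, c), (a, c)
    if etype == "RI":
        a, b = chain(P, (E, I), (E, 0))
        return ((a[0], b[1]),), (a, b)
    if etype == "MX":
        a = (P, P + E)
        x1 = (a[1] + I, a[1] + I + E)
        x2 = (x1[1] + I, x1[1] + I + E)
        c = (x2[1] + I, x2[1] + I + E)
        return (a, x1, c), (a, x2, c)
    donor_side = (etype == "A5") == (strand == "+")
    if etype in ("A5", "A3"):
        if donor_side:  # alternative donor: exon end differs
            short = (P, P + E)
            long_ = (P, P + E + ext)
            c = (long_[1] + I, long_[1] + I + E)
            return (long_, c), (short, c)
        # alternative acceptor: exon start differs
        a = (P, P + E)
        long_ = (a[1] + I, a[1] + I + E + ext)
        short = (long_[0] + ext, long_[1])
        return (a, long_), (a, short)
    left_side = (etype == "AF") == (strand == "+")
    if etype in ("AF", "AL"):
        if left_side:  # alternative genomic-first exons, shared acceptor
            f1 = (P, P + E)
            f2 = (f1[1] + gap, f1[1] + gap + E)
            c = (f2[1] + I, f2[1] + I + E)
            return (f1, c), (f2, c)
        a = (P, P + E)
        l1 = (a[1] + I, a[1] + I + E)
        l2 = (l1[1] + gap, l1[1] + gap + E)
        return (a, l1), (a, l2)
    raise ValueError(f"unknown event type {etype!r}")


def _mrna_to_genomic(tx_exons: tuple[Interval, ...], strand: str,
                     m_start: int, m_end: int) -> tuple[Interval, ...]:
    """Map an mRNA [m_start, m_end) interval to genomic CDS intervals."""
    exons = tx_exons if strand == "+" else tuple(reversed(tx_exons))
    out, offset = [], 0
    for s, e in exons:
        ln = e - s
        lo, hi = max(m_start - offset, 0), min(m_end - offset, ln)
        if lo < hi:
            if strand == "+":
                out.append((s + lo, s + hi))
            else:
                out.append((e - hi, e - lo))
        offset += ln
    return tuple(sorted(out))


def _make_cds(exons: tuple[Interval, ...], strand: str,
              ptc: bool) -> tuple[Interval, ...]:
    lengths = [e - s for s, e in (exons if strand == "+" else reversed(exons))]
    total = sum(lengths)
    last_junction = total - lengths[-1]
    start = 9
    if ptc and len(exons) > 1:
        stop_end = last_junction - 1 - 100  # 100 nt upstream of last junction
    else:
        stop_end = total - 11  # stop inside the last exon
    stop_end -= (stop_end - start + 1) % 3  # keep the frame
    if stop_end <= start:
        stop_end = start + 3
    return _mrna_to_genomic(exons, strand, start, stop_end + 1)


def make_annotation(config: SimConfig) -> GeneAnnotation:
    """Generate one gene per contig, each realizing its assigned event type."""
    rng = _rng(config, 0)
    types = [t for t in EVENT_TYPES if config.event_mix.get(t, 0) > 0]
    probs = np.array([config.event_mix[t] for t in types])
    assigned = rng.choice(types, size=config.n_genes, p=probs / probs.sum())
    strands = rng.choice(np.array(["+", "-"]), size=config.n_genes)
    ptc_draw = rng.random(config.n_genes)

    ann = GeneAnnotation()
    for i in range(config.n_genes):
        gid = f"G{i + 1:05d}"
        contig = f"ctg{i + 1:05d}"
        etype, strand = str(assigned[i]), str(strands[i])
        inc_exons, exc_exons = _gene_structures(etype, strand, config)
        gene_end = max(e for _, e in inc_exons + exc_exons)
        ann.contig_lengths[contig] = gene_end + config.pad
        plant_ptc = config.ptc_fraction > 0 and ptc_draw[i] < config.ptc_fraction
        for tag, exons, ptc in (("t1", inc_exons, False),
                                ("t2", exc_exons, plant_ptc)):
            tid = f"{gid}.{tag}"
            cds = _make_cds(tuple(exons), strand, ptc)
            ann.add_transcript(Transcript(tid, gid, contig, strand,
                                          tuple(exons), cds))
    return ann


# --- quantifications -------------------------------------------------------

def _plant_truth(annotation: GeneAnnotation, config: SimConfig,
                 gt: GroundTruth) -> None:
    """Draw per-gene expression and PSI truth (stream 1: shared across runs)."""
    rng = _rng(config, 1)
    events = build_events(annotation)
    by_gene: dict[str, list] = {}
    for e in events:
        by_gene.setdefault(e.gene_id, []).append(e)
    gt.gene_types = {
        e.gene_id: e.event_type for e in events
    }
    gt.ptc_transcripts = [
        f.transcript_id for f in flag_nmd(annotation) if f.is_ptc
    ]
    ca, cb = config.condition_names
    for gid in sorted(annotation.genes):
        evs = by_gene.get(gid, [])
        if len(evs) != 1:
            raise AssertionError(
                f"generator invariant broken: gene {gid} yields {len(evs)} events"
            )
        ev = evs[0]
        gt.gene_to_event[gid] = ev.event_id
        expr = float(np.exp(rng.normal(config.expr_log_mean, config.expr_log_sd)))
        gt.expression[gid] = expr
        psi1 = float(rng.uniform(0.35, 0.65))
        is_dse = rng.random() < config.dse_fraction
        direction = int(rng.choice([-1, 1]))
        psi2 = psi1 + direction * config.psi_shift if is_dse else psi1
        gt.true_psi[ev.event_id] = {ca: psi1, cb: psi2}
        if is_dse:
            gt.dse_events.append(ev.event_id)
            gt.dse_direction[ev.event_id] = direction


def simulate_quantifications(
    annotation: GeneAnnotation,
    config: SimConfig,
    *,
    seed_offset: int = 0,
    ground_truth: GroundTruth | None = None,
) -> tuple[QuantTable, GroundTruth]:
    """Replicate transcript TPM/count tables with planted usage shifts.

    TPM = gene expression x isoform usage (logit-normal noise around the
    true PSI), renormalized to 1e6 per sample; counts are NB draws around
    TPM x effective length x depth, with variance mean + phi(mean) mean^2.
    The planted truth depends only on ``config.seed``; ``seed_offset``
    varies the measurement noise (e.g. two independent knockdowns of the
    same biology use offsets 0 and 1).
    """
    gt = ground_truth if ground_truth is not None else GroundTruth()
    if not gt.true_psi:
        _plant_truth(annotation, config, gt)
    rng = _rng(config, 1000 + seed_offset)
    ca, cb = config.condition_names
    samples = [f"{c}_r{r + 1}" for c in (ca, cb)
               for r in range(config.n_replicates)]
    conditions = {s: s.rsplit("_r", 1)[0] for s in samples}

    events = {e.event_id: e for e in build_events(annotation)}
    tids = sorted(annotation.transcripts)
    tx_index = {t: k for k, t in enumerate(tids)}
    tpm = np.zeros((len(tids), len(samples)))
    for gid in sorted(annotation.genes):
        ev = events[gt.gene_to_event[gid]]
        expr = gt.expression[gid]
        for j, s in enumerate(samples):
            cond = conditions[s]
            true_psi = gt.true_psi[ev.event_id][cond]
            if config.expr_noise_sd > 0:
                e_s = expr * float(np.exp(rng.normal(0, config.expr_noise_sd)))
            else:
                e_s = expr
            if config.psi_noise_sd > 0:
                usage = float(expit(logit(true_psi)
                                    + rng.normal(0, config.psi_noise_sd)))
            else:
                usage = true_psi
            inc = sorted(ev.inclusion_transcripts)
            exc = sorted(ev.exclusion_transcripts)
            for t in inc:
                tpm[tx_index[t], j] = e_s * usage / len(inc)
            for t in exc:
                tpm[tx_index[t], j] = e_s * (1 - usage) / len(exc)
    tpm = tpm / tpm.sum(axis=0, keepdims=True) * 1e6

    lengths = pd.Series({t: annotation.transcripts[t].length() for t in tids})
    eff = np.maximum(lengths.values - 200, 25)
    mean_counts = tpm * eff[:, None] * config.depth_factor
    phi = config.dispersion(mean_counts)
    counts = np.zeros_like(mean_counts, dtype=np.int64)
    pos = mean_counts > 0
    lam = np.array(mean_counts)
    over = pos & (phi > 0)
    if over.any():
        shape = 1.0 / phi[over]
        lam[over] = rng.gamma(shape, phi[over] * mean_counts[over])
    counts[pos] = rng.poisson(lam[pos])

    quant = QuantTable(
        tpm=pd.DataFrame(tpm, index=tids, columns=samples),
        counts=pd.DataFrame(counts, index=tids, columns=samples),
        conditions=conditions,
        lengths=lengths,
        effective_lengths=pd.Series(eff, index=tids),
    )
    return quant, gt


# --- peaks -----------------------------------------------------------------

def simulate_peaks(
    annotation: GeneAnnotation,
    ground_truth: GroundTruth,
    config: SimConfig,
    *,
    seed_offset: int = 0,
) -> PeakSet:
    """Peak set enriched in flanking introns of planted differential SE events.

    A fraction ``peak_enrichment_fraction`` of planted-DSE SE events receives
    a peak whose summit lies inside one flanking intron; background peaks
    fall as a Poisson process at ``background_peak_rate`` per kb on all other
    introns.  Flanking introns of planted events are excluded from the
    background so the planted flag probability is exactly the enrichment
    fraction.  ``seed_offset`` draws an independent peak realization over
    the same planted truth.
    """
    rng = _rng(config, 2000 + seed_offset)
    ground_truth.peak_events = []  # record this realization only
    events = build_events(annotation)
    se = {e.event_id: e for e in events if e.event_type == "SE"}
    planted = [eid for eid in ground_truth.dse_events if eid in se]
    target_introns = {
        (se[eid].contig, iv) for eid in planted for iv in se[eid].flanking_introns
    }
    margin = 20
    half = config.peak_width // 2
    peaks: list[Peak] = []

    def add_peak(contig: str, strand: str, s: int, e: int, name: str) -> None:
        if e - s <= 2 * margin:
            return
        summit = int(rng.integers(s + margin, e - margin))
        clen = annotation.contig_lengths.get(contig, e + config.pad)
        start = max(summit - half, 0)
        end = min(summit + half + 1, clen)
        peaks.append(Peak(contig, start, end, summit, name, 1.0, strand))

    for eid in planted:
        ev = se[eid]
        if rng.random() < config.peak_enrichment_fraction:
            iv = ev.flanking_introns[int(rng.integers(len(ev.flanking_introns)))]
            add_peak(ev.contig, ev.strand, iv[0], iv[1], f"peak_{eid}")
            ground_truth.peak_events.append(eid)
    if config.background_peak_rate > 0:
        for gid in sorted(annotation.genes):
            gene = annotation.genes[gid]
            introns = sorted({iv for tx in gene.transcripts.values()
                              for iv in tx.introns()})
            for iv in introns:
                if (gene.contig, iv) in target_introns:
                    continue
                lam = config.background_peak_rate * (iv[1] - iv[0]) / 1000.0
                for k in range(rng.poisson(lam)):
                    add_peak(gene.contig, gene.strand, iv[0], iv[1],
                             f"bg_{gid}_{iv[0]}_{k}")
    return PeakSet(peaks)


# --- sequences -------------------------------------------------------------

def _concrete_motif(motif: str, rng: np.random.Generator) -> str:
    return "".join(
        IUPAC[ch][int(rng.integers(len(IUPAC[ch])))] for ch in motif.upper()
    )


def simulate_sequences(
    annotation: GeneAnnotation,
    peaks: PeakSet,
    config: SimConfig,
    ground_truth: GroundTruth | None = None,
) -> dict[str, str]:
    """Random background genome with a motif instance at each peak summit.

    The instance is written on the peak's strand so that the strand-aware
    summit window reads the motif starting exactly at offset 0.
    """
    rng = _rng(config, 4)
    genome: dict[str, np.ndarray] = {}
    for contig in sorted(annotation.contig_lengths):
        n = annotation.contig_lengths[contig]
        genome[contig] = _BASES[rng.integers(0, 4, size=n)].copy()
    m = len(config.motif)
    for p in sorted(peaks, key=lambda p: (p.contig, p.summit)):
        inst = _concrete_motif(config.motif, rng)
        seq = genome[p.contig]
        if p.strand == "-":
            lo = p.summit - m + 1
            written = reverse_complement(inst)
        else:
            lo = p.summit
            written = inst
        if lo < 0 or lo + m > len(seq):
            continue
        seq[lo:lo + m] = np.frombuffer(written.encode(), dtype="S1")
        if ground_truth is not None:
            ground_truth.motif_positions.append((p.contig, p.summit))
    return {c: b"".join(a).decode() for c, a in genome.items()}


# --- cohort ----------------------------------------------------------------

def simulate_cohort(
    event_ids: list[str],
    config: SimConfig,
    *,
    expression_assoc: float = 0.0,
) -> tuple[SurvivalCohort, GroundTruth]:
    """Patient cohort whose hazard follows exp(sum beta_i PSI_i).

    PSI covariates are uniform on [0, 1]; survival times are exponential
    with rate ``baseline_hazard * exp(X beta)``; censoring is independent
    exponential, its rate solved so the expected censored fraction equals
    ``censor_rate``.  ``expression_assoc`` adds an expression column
    correlated with the first PSI covariate.
    """
    if len(config.true_betas) != len(event_ids):
        raise ValueError("true_betas length must match the number of events")
    rng = _rng(config, 5)
    n, k = config.n_patients, len(event_ids)
    X = rng.uniform(0.0, 1.0, size=(n, k))
    beta = np.asarray(config.true_betas, dtype=float)
    rate = config.baseline_hazard * np.exp(X @ beta)
    T = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        target = config.censor_rate

        def censored_fraction(lam):
            return float(np.mean(1.0 - np.exp(-lam * T))) - target

        lam_c = brentq(censored_fraction, 1e-12, 1e9)
        C = rng.exponential(1.0 / lam_c, size=n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        time, event = T, np.ones(n, dtype=int)

    patients = [f"P{i + 1:05d}" for i in range(n)]
    psi = pd.DataFrame(X, index=patients, columns=event_ids)
    expr = None
    if expression_assoc != 0.0:
        expr = pd.Series(
            expression_assoc * X[:, 0] + rng.normal(0, 1, size=n),
            index=patients, name="expression",
        )
    gt = GroundTruth(true_betas=dict(zip(event_ids, beta.tolist())))
    cohort = SurvivalCohort(
        psi, pd.Series(time, index=patients, name="time"),
        pd.Series(event, index=patients, name="event"), expr,
    )
    return cohort, gt


def simulate_knockdown_pair(
    annotation: GeneAnnotation, config: SimConfig
) -> tuple[QuantTable, QuantTable, GroundTruth]:
    """Two independent knockdown experiments over the same planted biology.

    Both share the planted truth (same events, same shift directions) but
    have independent measurement noise — the sh1/sh2 replication design.
    """
    gt = GroundTruth()
    q1, gt = simulate_quantifications(annotation, config, seed_offset=0,
                                      ground_truth=gt)
    q2, _ = simulate_quantifications(annotation, config, seed_offset=1,
                                     ground_truth=gt)
    return q1, q2, gt
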