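"""Readers and writers for the standard formats.

Coordinate conventions are converted exactly once, here: GTF is 1-based
closed on disk and 0-based half-open in memory; BED is already 0-based
half-open.  All readers fail loudly (with line numbers) on malformed
records rather than silently coercing.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import gffutils
import pandas as pd
from pyfaidx import Fasta

from .annotation import GeneAnnotation, Transcript
from .events import ASEvent
from .peaks import Peak, PeakSet
from .psi import QuantTable
from .survival import SurvivalCohort

logger = logging.getLogger(__name__)

QUANT_COLUMNS = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]


# --- GTF -------------------------------------------------------------------

def read_gtf(path) -> GeneAnnotation:
    """Parse a GTF into a :class:`GeneAnnotation` (0-based half-open).

    Exon and CDS records are grouped by their ``transcript_id``/``gene_id``
    attributes; a feature lacking ``transcript_id`` is a hard error naming
    the line.  ``#!contig <name> <length>`` header comments, as written by
    :func:`write_gtf`, populate contig lengths.
    """
    path = Path(path)
    contig_lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                parts = line.strip().split()
                if len(parts) == 3 and parts[0] == "#!contig":
                    contig_lengths[parts[1]] = int(parts[2])
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: not a 9-column GTF line")
            if fields[2] in ("exon", "CDS") and "transcript_id" not in fields[8]:
                raise ValueError(
                    f"{path}:{lineno}: {fields[2]} record lacks transcript_id"
                )

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    exons: dict[str, dict] = {}
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        rec = exons.setdefault(
            tid,
            {"gene": gid, "contig": feat.seqid, "strand": feat.strand,
             "exons": [], "cds": []},
        )
        # GTF 1-based closed -> 0-based half-open
        interval = (feat.start - 1, feat.end)
        rec["exons" if feat.featuretype == "exon" else "cds"].append(interval)

    ann = GeneAnnotation(contig_lengths=contig_lengths)
    for tid, rec in exons.items():
        ann.add_transcript(Transcript(
            transcript_id=tid,
            gene_id=rec["gene"],
            contig=rec["contig"],
            strand=rec["strand"],
            exons=tuple(rec["exons"]),
            cds=tuple(rec["cds"]) if rec["cds"] else None,
        ))
    return ann


def write_gtf(annotation: GeneAnnotation, path) -> None:
    """Write the annotation as GTF (1-based closed), with contig headers."""
    with open(path, "w") as fh:
        for contig in sorted(annotation.contig_lengths):
            fh.write(f"#!contig {contig} {annotation.contig_lengths[contig]}\n")
        for gid in sorted(annotation.genes):
            gene = annotation.genes[gid]
            for tid in sorted(gene.transcripts):
                tx = gene.transcripts[tid]
                attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                for s, e in tx.exons:
                    fh.write(
                        f"{tx.contig}\tm6asplice\texon\t{s + 1}\t{e}\t.\t"
                        f"{tx.strand}\t.\t{attrs}\n"
                    )
                for s, e in tx.cds or ():
                    fh.write(
                        f"{tx.contig}\tm6asplice\tCDS\t{s + 1}\t{e}\t.\t"
                        f"{tx.strand}\t0\t{attrs}\n"
                    )


# --- BED -------------------------------------------------------------------

def read_bed(path) -> PeakSet:
    """Read peaks from BED (0-based half-open).

    An optional 7th column is the summit offset from the peak start; when
    absent the midpoint is used.  Malformed intervals raise with the line
    number.
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "."
            if len(f) > 6:
                summit = start + int(f[6])
                if not (start <= summit < end):
                    raise ValueError(f"{path}:{lineno}: summit outside peak")
            else:
                summit = (start + end) // 2
            peaks.append(Peak(f[0], start, end, summit, name, score, strand))
    return PeakSet(peaks)


def write_bed(peaks: PeakSet, path) -> None:
    """Write BED6+1 with the summit offset in column 7."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.contig}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t"
                f"{p.strand}\t{p.summit - p.start}\n"
            )


# --- FASTA -----------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Load a genome FASTA into a contig -> sequence dict."""
    fa = Fasta(str(path), as_raw=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# --- quantification tables -------------------------------------------------

def read_quant(
    paths: dict[str, str | Path], conditions: dict[str, str]
) -> QuantTable:
    """Join per-sample quantifier tables on transcript id.

    Each file has the pseudoalignment-quantifier layout
    ``Name\\tLength\\tEffectiveLength\\tTPM\\tNumReads``.  Transcripts absent
    from a sample are zero-filled (counted in the log).
    """
    tpm_cols, count_cols = {}, {}
    lengths = {}
    eff_lengths = {}
    for sample, p in paths.items():
        df = pd.read_csv(p, sep="\t")
        missing_cols = [c for c in QUANT_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"{p}: missing columns {missing_cols}")
        df = df.set_index("Name")
        tpm_cols[sample] = df["TPM"]
        count_cols[sample] = df["NumReads"]
        lengths.update(df["Length"].to_dict())
        eff_lengths.update(df["EffectiveLength"].to_dict())
    tpm = pd.DataFrame(tpm_cols)
    counts = pd.DataFrame(count_cols)
    n_filled = int(tpm.isna().sum().sum())
    if n_filled:
        logger.warning("read_quant: %d transcript/sample entries zero-filled",
                       n_filled)
    return QuantTable(
        tpm=tpm.fillna(0.0),
        counts=counts.fillna(0).round().astype(int),
        conditions=dict(conditions),
        lengths=pd.Series(lengths),
        effective_lengths=pd.Series(eff_lengths),
    )


def write_quant(quant: QuantTable, outdir) -> dict[str, Path]:
    """Write one quantifier-layout TSV per sample; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}
    lengths = quant.lengths if quant.lengths is not None else pd.Series(
        0, index=quant.tpm.index
    )
    eff = (
        quant.effective_lengths
        if quant.effective_lengths is not None
        else lengths
    )
    for sample in quant.tpm.columns:
        df = pd.DataFrame({
            "Name": quant.tpm.index,
            "Length": lengths.reindex(quant.tpm.index).values,
            "EffectiveLength": eff.reindex(quant.tpm.index).values,
            "TPM": quant.tpm[sample].values,
            "NumReads": quant.counts[sample].values,
        })
        path = outdir / f"{sample}.quant.tsv"
        df.to_csv(path, sep="\t", index=False)
        out[sample] = path
    return out


# --- event tables ----------------------------------------------------------

def write_events_table(events: list[ASEvent], path) -> None:
    """ioe-style event TSV, extended with coordinates and flanking introns."""
    rows = []
    for e in events:
        rows.append({
            "event_id": e.event_id,
            "event_type": e.event_type,
            "gene_id": e.gene_id,
            "contig": e.contig,
            "strand": e.strand,
            "inclusion_transcripts": ",".join(sorted(e.inclusion_transcripts)),
            "total_transcripts": ",".join(
                sorted(e.inclusion_transcripts | e.exclusion_transcripts)
            ),
            "coordinates": "-".join(map(str, e.coordinates)),
            "flanking_introns": ";".join(
                f"{s}-{t}" for s, t in e.flanking_introns
            ),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_table(path) -> list[ASEvent]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    events = []
    for _, r in df.iterrows():
        inc = frozenset(r["inclusion_transcripts"].split(","))
        total = frozenset(r["total_transcripts"].split(","))
        flanks = tuple(
            tuple(map(int, pair.split("-")))
            for pair in r["flanking_introns"].split(";")
            if pair
        )
        events.append(ASEvent(
            event_id=r["event_id"],
            event_type=r["event_type"],
            gene_id=r["gene_id"],
            contig=r["contig"],
            strand=r["strand"],
            inclusion_transcripts=inc,
            exclusion_transcripts=total - inc,
            coordinates=tuple(map(int, str(r["coordinates"]).split("-"))),
            flanking_introns=flanks,
        ))
    return events


# --- clinical tables -------------------------------------------------------

def read_clinical(path) -> SurvivalCohort:
    """Clinical TSV: patient_id, time, event, psi_<event>..., [expression]."""
    df = pd.read_csv(path, sep="\t").set_index("patient_id")
    psi_cols = [c for c in df.columns if c.startswith("psi_")]
    psi = df[psi_cols].rename(columns=lambda c: c[4:])
    expr = df["expression"] if "expression" in df.columns else None
    return SurvivalCohort(psi, df["time"], df["event"].astype(int), expr)


def write_clinical(cohort: SurvivalCohort, path) -> None:
    df = cohort.psi.rename(columns=lambda c: f"psi_{c}").copy()
    df.insert(0, "time", cohort.time)
    df.insert(1, "event", cohort.event)
    if cohort.expression is not None:
        df["expression"] = cohort.expression
    df.index.name = "patient_id"
    df.to_csv(path, sep="\t")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
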