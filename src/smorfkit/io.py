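"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA and GTF carry the transcriptome; tab-separated tables carry reads,
P-sites, offsets, ORFs and calls. The GTF dialect is transcript-space
friendly: a reader collapses multi-exon gene structure onto contiguous
transcript coordinates, so genome-side annotations with spliced transcripts
can be ingested, while the writer emits one exon per transcript with the
transcript itself as the sequence region. CDS features include the stop
codon (the model's ``cds`` interval does too).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .transcriptome_model import (
    LNCRNA,
    PROTEIN_CODING,
    CandidateORF,
    Transcript,
    ValidationError,
)

READ_COLUMNS = [
    "read_id",
    "transcript_id",
    "five_prime_pos",
    "length",
    "multimapping",
    "replicate",
    "condition",
    "assay",
]

PSITE_COLUMNS = [
    "transcript_id",
    "pos",
    "length",
    "multimapping",
    "replicate",
    "condition",
]

OFFSET_COLUMNS = ["length", "offset", "in_frame_fraction", "n_reads", "selected"]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{id: sequence}`` (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(transcripts: Iterable[Transcript], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            fh.write(f">{tx.id}\n")
            for i in range(0, len(tx.sequence), width):
                fh.write(tx.sequence[i : i + width] + "\n")


# ------------------------------------------------------------------ GTF

def _gtf_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for field in raw.strip().rstrip(";").split(";"):
        field = field.strip()
        if not field:
            continue
        key, _, value = field.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def write_gtf(transcripts: Iterable[Transcript], path: str | Path) -> None:
    """Write transcript-space GTF: seqname = transcript id, 1-based closed."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = (
                f'transcript_id "{tx.id}"; gene_id "{tx.id}"; '
                f'transcript_biotype "{tx.biotype}";'
            )
            fh.write(
                f"{tx.id}\tsmorfkit\texon\t1\t{len(tx.sequence)}\t.\t+\t.\t{attrs}\n"
            )
            if tx.cds is not None:
                s, e = tx.cds
                fh.write(
                    f"{tx.id}\tsmorfkit\tCDS\t{s + 1}\t{e}\t.\t+\t.\t{attrs}\n"
                )


def read_gtf(path: str | Path, sequences: dict[str, str]) -> list[Transcript]:
    """Build transcripts from a GTF plus their (transcript-space) sequences.

    Exon features are collapsed, in strand order, onto contiguous transcript
    coordinates; CDS features are mapped through the same exon chain. A
    transcript with any CDS feature is treated as protein-coding, otherwise
    its ``transcript_biotype``/``gene_biotype`` attribute decides (default
    lncRNA). If a CDS, as annotated, excludes the stop codon, the three
    following bases are absorbed when they form a stop.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cdss: dict[str, list[tuple[int, int]]] = {}
    strands: dict[str, str] = {}
    biotypes: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValidationError(f"malformed GTF line: {line!r}")
            _, _, feature, start, end, _, strand, _, raw_attrs = parts[:9]
            if feature not in ("exon", "CDS"):
                continue
            attrs = _gtf_attributes(raw_attrs)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ValidationError("GTF feature without transcript_id")
            iv = (int(start) - 1, int(end))  # to 0-based half-open
            (exons if feature == "exon" else cdss).setdefault(tid, []).append(iv)
            strands[tid] = strand
            bt = attrs.get("transcript_biotype") or attrs.get("gene_biotype")
            if bt:
                biotypes[tid] = bt
    out = []
    for tid, ex in exons.items():
        if tid not in sequences:
            continue
        seq = sequences[tid]
        reverse = strands.get(tid) == "-"
        ex_sorted = sorted(ex, reverse=reverse)
        # genomic -> transcript offset per exon, in transcription order
        offsets = []
        pos = 0
        for s, e in ex_sorted:
            offsets.append((s, e, pos))
            pos += e - s
        cds_span = None
        if tid in cdss:
            tx_coords: list[int] = []
            for cs, ce in cdss[tid]:
                for gs, ge, off in offsets:
                    if cs >= gs and ce <= ge:
                        if reverse:
                            tx_coords.extend([off + (ge - ce), off + (ge - cs)])
                        else:
                            tx_coords.extend([off + (cs - gs), off + (ce - gs)])
                        break
                else:
                    raise ValidationError(f"{tid}: CDS segment outside exons")
            lo, hi = min(tx_coords), max(tx_coords)
            from .transcriptome_model import STOP_CODONS

            if seq[hi - 3 : hi] not in STOP_CODONS and seq[hi : hi + 3] in STOP_CODONS:
                hi += 3  # annotation excluded the stop codon
            cds_span = (lo, hi)
        biotype = PROTEIN_CODING if cds_span is not None else biotypes.get(tid, LNCRNA)
        if biotype not in (PROTEIN_CODING, LNCRNA):
            biotype = LNCRNA
        out.append(Transcript(id=tid, sequence=seq, biotype=biotype, cds=cds_span))
    return sorted(out, key=lambda t: t.id)


def read_transcriptome(fasta: str | Path, gtf: str | Path) -> list[Transcript]:
    return read_gtf(gtf, read_fasta(fasta))


# --------------------------------------------------------------- tables

def write_reads_tsv(reads: pd.DataFrame, path: str | Path) -> None:
    reads.to_csv(path, sep="\t", index=False, columns=READ_COLUMNS)


def read_reads_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "read_id": str,
            "transcript_id": str,
            "five_prime_pos": int,
            "length": int,
            "multimapping": bool,
            "replicate": str,
            "condition": str,
            "assay": str,
        },
    )
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing read columns {sorted(missing)}")
    return df[READ_COLUMNS]


def write_psites_tsv(psites: pd.DataFrame, path: str | Path) -> None:
    psites.to_csv(path, sep="\t", index=False, columns=PSITE_COLUMNS)


def read_psites_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        dtype={
            "transcript_id": str,
            "pos": int,
            "length": int,
            "multimapping": bool,
            "replicate": str,
            "condition": str,
        },
    )


def write_offsets_tsv(offsets: pd.DataFrame, path: str | Path) -> None:
    offsets.to_csv(path, sep="\t", index=False, columns=OFFSET_COLUMNS)


def orf_table(orfs: Sequence[CandidateORF]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "orf_id": [o.orf_id for o in orfs],
            "transcript_id": [o.transcript_id for o in orfs],
            "start": [o.start for o in orfs],
            "end": [o.end for o in orfs],
            "frame": [o.frame for o in orfs],
            "category": [o.category for o in orfs],
            "length_codons": [o.length_codons for o in orfs],
            "peptide": [o.peptide for o in orfs],
        }
    )


def write_orf_tsv(orfs: Sequence[CandidateORF], path: str | Path) -> None:
    orf_table(orfs).to_csv(path, sep="\t", index=False)


def read_orf_tsv(path: str | Path) -> list[CandidateORF]:
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "orf_id": str})
    return [
        CandidateORF(
            orf_id=r.orf_id,
            transcript_id=r.transcript_id,
            start=int(r.start),
            end=int(r.end),
            frame=int(r.frame),
            length_codons=int(r.length_codons),
            peptide=r.peptide,
            category=r.category,
        )
        for r in df.itertuples()
    ]


def write_orf_bed(orfs: Sequence[CandidateORF], path: str | Path) -> None:
    """Transcript-space BED6: name = orf_id, score = length in codons."""
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(
                f"{o.transcript_id}\t{o.start}\t{o.end}\t{o.orf_id}\t{o.length_codons}\t+\n"
            )


# ------------------------------------------------------------------ SAM

def read_sam(
    path: str | Path,
    replicate: str,
    condition: str,
    assay: str = "ribo",
) -> pd.DataFrame:
    """Ingest transcript-space alignments (SAM vs the transcript FASTA).

    The reference name is the transcript, the 0-based reference start the
    5' end (unspliced, forward-strand alignments only). Multimapping is
    taken from the NH tag when present (NH > 1), else from MAPQ == 0.
    """
    import pysam  # optional dependency, only needed for SAM input

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for i, aln in enumerate(sam.fetch(until_eof=True)):
            if aln.is_unmapped or aln.is_reverse:
                continue
            try:
                multi = aln.get_tag("NH") > 1
            except KeyError:
                multi = aln.mapping_quality == 0
            rows.append(
                (
                    aln.query_name or f"read{i}",
                    aln.reference_name,
                    aln.reference_start,
                    aln.query_length or aln.infer_read_length() or 0,
                    multi,
                    replicate,
                    condition,
                    assay,
                )
            )
    return pd.DataFrame(rows, columns=READ_COLUMNS)
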