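"""Transcript-space data model and candidate-ORF enumeration.

All coordinates are 0-based, half-open, in transcript space (sense strand).
Multi-exon gene structure is collapsed onto contiguous transcript coordinates
before anything in this package sees it (see :mod:`smorfkit.io`), because every
calling rule downstream — P-site framing, start selection, coverage gates —
is local to the mature transcript.

An ORF here is an ATG followed by the nearest in-frame stop codon; the span
``[start, end)`` includes the stop codon, but ``length_codons`` (and the
peptide) exclude it. Only ATG starts are considered; near-cognate initiation
is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

from Bio.Seq import Seq

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
VALID_BASES = frozenset("ACGTN")

PROTEIN_CODING = "protein_coding"
LNCRNA = "lncRNA"
BIOTYPES = frozenset({PROTEIN_CODING, LNCRNA})

#: ORF categories relative to the transcript annotation.
CANONICAL = "canonical"
UORF = "uORF"
DORF = "dORF"
LNCRNA_SMORF = "lncRNA_smORF"
OTHER = "other"
CATEGORIES = (CANONICAL, UORF, DORF, LNCRNA_SMORF, OTHER)


class ValidationError(ValueError):
    """Raised when a transcript or ORF violates a model invariant."""


@dataclass(frozen=True)
class Transcript:
    """A mature transcript: sense-strand sequence plus minimal annotation.

    Parameters
    ----------
    id : str
        Transcript identifier (e.g. an Ensembl transcript accession).
    sequence : str
        Nucleotide sequence, uppercase ACGT (N tolerated, never part of a
        start or stop codon).
    biotype : str
        ``"protein_coding"`` or ``"lncRNA"``.
    cds : tuple of (int, int), optional
        Annotated CDS as a half-open interval in transcript coordinates,
        stop codon included. Required for protein-coding transcripts and
        forbidden for lncRNAs.
    """

    id: str
    sequence: str
    biotype: str
    cds: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("transcript id must be non-empty")
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValidationError(
                f"{self.id}: non-ACGTN characters in sequence: {sorted(bad)}"
            )
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"{self.id}: unknown biotype {self.biotype!r} "
                f"(expected one of {sorted(BIOTYPES)})"
            )
        if self.biotype == PROTEIN_CODING:
            if self.cds is None:
                raise ValidationError(f"{self.id}: protein_coding requires a CDS span")
            s, e = self.cds
            if not (0 <= s < e <= len(self.sequence)):
                raise ValidationError(f"{self.id}: CDS [{s}, {e}) out of bounds")
            if (e - s) % 3 != 0:
                raise ValidationError(f"{self.id}: CDS length not a multiple of 3")
            if self.sequence[s : s + 3] != START_CODON:
                raise ValidationError(f"{self.id}: CDS does not begin with ATG")
            if self.sequence[e - 3 : e] not in STOP_CODONS:
                raise ValidationError(f"{self.id}: CDS does not end in a stop codon")
        elif self.cds is not None:
            raise ValidationError(f"{self.id}: lncRNA must not carry a CDS span")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CandidateORF:
    """An ATG-to-stop span in one reading frame of a transcript.

    ``length_codons`` and ``peptide`` exclude the stop codon;
    ``frame = start mod 3``.
    """

    orf_id: str
    transcript_id: str
    start: int
    end: int
    frame: int
    length_codons: int
    peptide: str
    category: str = OTHER

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0 or self.end - self.start < 6:
            raise ValidationError(
                f"{self.orf_id}: span must be a multiple of 3 and >= 6 nt"
            )
        if self.length_codons != (self.end - self.start) // 3 - 1:
            raise ValidationError(f"{self.orf_id}: inconsistent length_codons")
        if len(self.peptide) != self.length_codons or (
            self.peptide and self.peptide[0] != "M"
        ):
            raise ValidationError(f"{self.orf_id}: peptide inconsistent with span")
        if self.category not in CATEGORIES:
            raise ValidationError(f"{self.orf_id}: unknown category {self.category!r}")


def orf_id(transcript_id: str, start: int, end: int) -> str:
    """ORF naming convention: ``<transcript>_<start>_<end>``."""
    return f"{transcript_id}_{start}_{end}"


def _translate(seq: str) -> str:
    return str(Seq(seq).translate())


def enumerate_orfs(
    transcript: Transcript,
    min_codons: int = 5,
    max_codons: int = 300,
    classify: bool = True,
) -> list[CandidateORF]:
    """Enumerate every ATG -> nearest-in-frame-stop ORF in all three frames.

    ORFs that run off the transcript end without reaching a stop codon are
    not reported. Several ATGs may share one stop (nested starts); each is
    reported as its own ORF. Results are ordered by ``(start, end)``.

    Parameters
    ----------
    transcript : Transcript
    min_codons, max_codons : int
        Inclusive bounds on ``length_codons`` (stop excluded). The defaults
        target small ORFs: at least 5 codons, at most 300.
    classify : bool
        Attach the annotation-relative category (see :func:`classify_orf`).

    Returns
    -------
    list of CandidateORF
    """
    if not (1 <= min_codons <= max_codons):
        raise ValidationError(
            f"require 1 <= min_codons <= max_codons, got {min_codons}, {max_codons}"
        )
    seq = transcript.sequence
    found: list[tuple[int, int]] = []
    for frame in range(3):
        open_starts: list[int] = []
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon == START_CODON:
                open_starts.append(i)
            elif codon in STOP_CODONS:
                for s in open_starts:
                    n_codons = (i - s) // 3
                    if min_codons <= n_codons <= max_codons:
                        found.append((s, i + 3))
                open_starts.clear()
    found.sort()
    orfs = []
    for s, e in found:
        o = CandidateORF(
            orf_id=orf_id(transcript.id, s, e),
            transcript_id=transcript.id,
            start=s,
            end=e,
            frame=s % 3,
            length_codons=(e - s) // 3 - 1,
            peptide=_translate(seq[s : e - 3]),
        )
        if classify:
            o = replace(o, category=classify_orf(o, transcript))
        orfs.append(o)
    return orfs


def classify_orf(orf: CandidateORF, transcript: Transcript) -> str:
    """Place an ORF relative to the transcript annotation.

    lncRNA host -> ``lncRNA_smORF``. On a protein-coding transcript: an exact
    match of the annotated CDS span -> ``canonical``; strictly upstream of the
    CDS (ending at or before ``cds_start``) -> ``uORF``; strictly downstream
    (starting at or after ``cds_end``) -> ``dORF``; everything else (CDS
    overlap out of frame, alternative in-frame starts, ...) -> ``other``.
    """
    if orf.transcript_id != transcript.id:
        raise ValidationError(
            f"{orf.orf_id}: transcript mismatch ({orf.transcript_id} vs {transcript.id})"
        )
    if not (0 <= orf.start < orf.end <= len(transcript)):
        raise ValidationError(f"{orf.orf_id}: outside transcript bounds")
    if transcript.biotype == LNCRNA:
        return LNCRNA_SMORF
    cds_start, cds_end = transcript.cds  # type: ignore[misc]
    if (orf.start, orf.end) == (cds_start, cds_end):
        return CANONICAL
    if orf.end <= cds_start:
        return UORF
    if orf.start >= cds_end:
        return DORF
    return OTHER


def enumerate_transcriptome(
    transcripts: Iterable[Transcript],
    min_codons: int = 5,
    max_codons: int = 300,
) -> list[CandidateORF]:
    """Enumerate and classify candidate ORFs over a whole transcriptome."""
    out: list[CandidateORF] = []
    for tx in transcripts:
        out.extend(enumerate_orfs(tx, min_codons, max_codons))
    return out
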