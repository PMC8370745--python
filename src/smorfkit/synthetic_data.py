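"""Synthetic transcriptomes and footprint/RNA read tables.

The generator emulates the statistical structure a polysome ribosome-profiling
(Poly-Ribo-Seq) experiment hands to the downstream caller: a mixed
transcriptome of protein-coding mRNAs and lncRNAs, a subset of lncRNAs
carrying a translated small ORF, footprints of 31/33 nt whose 5' ends sit at a
fixed length-specific distance upstream of the ribosomal P-site, strong 3-nt
periodicity inside translated ORFs with an elevated initiation peak at the
start codon, near-uniform background elsewhere, i.i.d. multimapping
contamination, and RNA-seq 5' ends spread uniformly along each expressed
transcript. Three biological replicates per condition, two conditions, by
default.

Counts are Poisson (shot noise); an optional negative-binomial switch adds
overdispersion. Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .transcriptome_model import (
    LNCRNA,
    LNCRNA_SMORF,
    CANONICAL,
    PROTEIN_CODING,
    START_CODON,
    STOP_CODONS,
    Transcript,
    orf_id,
)

_BASES = np.array(list("ACGT"))
_STOPS = sorted(STOP_CODONS)
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

MANIFEST_COLUMNS = [
    "orf_id",
    "transcript_id",
    "start",
    "end",
    "category",
    "conditions",
    "depth",
    "in_frame_prob",
    "rna_depth",
]


class ConfigError(ValueError):
    """Raised for infeasible or inconsistent simulation settings."""


@dataclass
class PlantedTranslation:
    """Per-ORF translation settings.

    depth
        Expected footprint (P-site) count per ORF per replicate.
    in_frame_prob
        Probability a footprint's P-site lands in frame 0 of the ORF;
        the remainder splits evenly between frames 1 and 2.
    rna_depth
        Expected RNA-seq 5'-end count per transcript per replicate.
    """

    depth: float = 50.0
    in_frame_prob: float = 0.85
    rna_depth: float = 100.0


@dataclass
class SimulationConfig:
    seed: int = 0
    n_protein_coding: int = 20
    n_lncRNA: int = 30
    #: number of lncRNAs carrying a planted translated smORF (default: half).
    n_translated_lncRNA: Optional[int] = None
    transcript_length_range: tuple[int, int] = (400, 1200)
    cds_codons_range: tuple[int, int] = (60, 250)
    smorf_codons_range: tuple[int, int] = (30, 90)
    planted: PlantedTranslation = field(default_factory=PlantedTranslation)
    read_length_probs: dict[int, float] = field(
        default_factory=lambda: {31: 0.5, 33: 0.5}
    )
    true_offsets: dict[int, int] = field(default_factory=lambda: {31: 12, 33: 13})
    multimap_rate: float = 0.05
    #: expected off-ORF (background) P-sites per 100 nt per replicate.
    background_rate: float = 1.0
    #: fraction of a translated ORF's footprints whose P-site is the start
    #: codon itself — the initiation pause seen in real metagene profiles.
    start_peak_fraction: float = 0.15
    rna_read_length: int = 36
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("Control", "RA")
    #: negative-binomial dispersion (variance = mu + mu^2/size); None = Poisson.
    nb_size: Optional[float] = None

    def validate(self) -> None:
        if self.n_protein_coding < 0 or self.n_lncRNA < 0:
            raise ConfigError("transcript counts must be non-negative")
        n_tr = self.n_translated_lncRNA
        if n_tr is not None and not (0 <= n_tr <= self.n_lncRNA):
            raise ConfigError("n_translated_lncRNA out of range")
        lo, hi = self.transcript_length_range
        if not (1 <= lo <= hi):
            raise ConfigError("bad transcript_length_range")
        if abs(sum(self.read_length_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("read_length_probs must sum to 1")
        for L, p in self.read_length_probs.items():
            if not 0 <= p <= 1:
                raise ConfigError("read length probabilities must be in [0, 1]")
            off = self.true_offsets.get(L)
            if off is None:
                raise ConfigError(f"no true offset for read length {L}")
            if not 0 <= off < L:
                raise ConfigError(f"offset {off} not in [0, {L}) for length {L}")
        for name, value in [
            ("multimap_rate", self.multimap_rate),
            ("start_peak_fraction", self.start_peak_fraction),
            ("in_frame_prob", self.planted.in_frame_prob),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for name, value in [
            ("depth", self.planted.depth),
            ("rna_depth", self.planted.rna_depth),
            ("background_rate", self.background_rate),
        ]:
            if value < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("need at least one replicate")
        # smallest geometry: 5' UTR (20) + ORF + 3' slack (20)
        min_cds_nt = 3 * (min(self.cds_codons_range) + 1)
        if self.n_protein_coding and lo < min_cds_nt + 40:
            raise ConfigError(
                f"transcripts of {lo} nt cannot hold a "
                f"{min(self.cds_codons_range)}-codon CDS plus UTRs"
            )
        min_smorf_nt = 3 * (min(self.smorf_codons_range) + 1)
        if self.n_lncRNA and (n_tr is None or n_tr > 0) and lo < min_smorf_nt + 40:
            raise ConfigError("transcripts too short for the requested smORFs")


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(_BASES, size=n)


def _plant_orf(
    seq: np.ndarray, start: int, n_codons: int, rng: np.random.Generator
) -> int:
    """Overwrite ``seq`` with ATG + ``n_codons - 1`` sense codons + stop.

    Returns the half-open end (past the stop codon). The span contains no
    internal in-frame stop by construction.
    """
    codons = [START_CODON]
    codons += list(rng.choice(_SENSE_CODONS, size=n_codons - 1))
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    block = "".join(codons)
    end = start + len(block)
    seq[start:end] = list(block)
    return end


def _condition_pattern(i: int, conditions: Sequence[str]) -> tuple[str, ...]:
    """Assign planted smORFs to conditions: A-only, B-only, both, cycling."""
    if len(conditions) == 1:
        return (conditions[0],)
    patterns = [(conditions[0],), (conditions[1],), tuple(conditions[:2])]
    return patterns[i % 3]


def generate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[Transcript], pd.DataFrame]:
    """Generate transcripts plus the ground-truth translated-ORF manifest.

    Protein-coding transcripts carry a valid annotated CDS, translated in
    every condition. A designated subset of lncRNAs carries one planted
    smORF, cycled through condition patterns (first condition only, second
    only, both); the remaining lncRNAs are untranslated controls that only
    ever receive background footprints.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.transcript_length_range
    transcripts: list[Transcript] = []
    rows: list[tuple] = []

    for i in range(config.n_protein_coding):
        tid = f"MRNA{i:04d}"
        L = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, L)
        utr5 = int(rng.integers(20, max(21, min(120, L // 4))))
        max_codons = min(max(config.cds_codons_range), (L - utr5 - 20) // 3 - 1)
        n_codons = int(rng.integers(min(config.cds_codons_range), max_codons + 1))
        end = _plant_orf(seq, utr5, n_codons, rng)
        transcripts.append(
            Transcript(tid, "".join(seq), PROTEIN_CODING, cds=(utr5, end))
        )
        rows.append(
            (
                orf_id(tid, utr5, end),
                tid,
                utr5,
                end,
                CANONICAL,
                ";".join(config.conditions),
                config.planted.depth,
                config.planted.in_frame_prob,
                config.planted.rna_depth,
            )
        )

    n_translated = (
        config.n_lncRNA // 2
        if config.n_translated_lncRNA is None
        else config.n_translated_lncRNA
    )
    for i in range(config.n_lncRNA):
        tid = f"LNC{i:04d}"
        L = int(rng.integers(lo, hi + 1))
        seq = _random_seq(rng, L)
        if i < n_translated:
            start = int(rng.integers(20, max(21, min(120, L // 4))))
            max_codons = min(max(config.smorf_codons_range), (L - start - 20) // 3 - 1)
            n_codons = int(rng.integers(min(config.smorf_codons_range), max_codons + 1))
            end = _plant_orf(seq, start, n_codons, rng)
            rows.append(
                (
                    orf_id(tid, start, end),
                    tid,
                    start,
                    end,
                    LNCRNA_SMORF,
                    ";".join(_condition_pattern(i, config.conditions)),
                    config.planted.depth,
                    config.planted.in_frame_prob,
                    config.planted.rna_depth,
                )
            )
        transcripts.append(Transcript(tid, "".join(seq), LNCRNA))

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return transcripts, manifest


def control_lncRNAs(
    transcripts: Sequence[Transcript], manifest: pd.DataFrame
) -> list[str]:
    """Ids of lncRNAs with no planted smORF (negative controls)."""
    planted = set(manifest["transcript_id"])
    return [t.id for t in transcripts if t.biotype == LNCRNA and t.id not in planted]


def _draw_count(rng: np.random.Generator, mu: float, nb_size: Optional[float]) -> int:
    if mu <= 0:
        return 0
    if nb_size is None:
        return int(rng.poisson(mu))
    p = nb_size / (nb_size + mu)
    return int(rng.negative_binomial(nb_size, p))


def simulate_reads(
    transcripts: Sequence[Transcript],
    manifest: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate footprint and RNA-seq read tables for every replicate.

    Per replicate and condition: each manifest ORF translated in that
    condition receives ~Poisson(depth) footprints. A footprint is an
    initiation-pause read with probability ``start_peak_fraction`` — its
    P-site is the start codon itself, in frame — otherwise its P-site falls
    on a uniformly drawn codon of the ORF (stop codon excluded) and is in
    frame 0 with probability ``in_frame_prob``, else in frame 1 or 2
    equiprobably. The 5' end
    is P-site minus the length-specific true offset. Background footprints
    (uniform position, uniform frame) fall on every transcript at
    ``background_rate`` per 100 nt; RNA-seq 5' ends fall uniformly on every
    transcript at ``rna_depth``. Multimapping flags are i.i.d. Bernoulli on
    footprints. Reads whose 5' end would leave the transcript are dropped.
    """
    config.validate()
    known = {t.id for t in transcripts}
    missing = set(manifest["transcript_id"]) - known
    if missing:
        raise ConfigError(f"manifest refers to unknown transcripts: {sorted(missing)}")
    rng = np.random.default_rng(config.seed + 1)
    lengths = np.array(sorted(config.read_length_probs), dtype=int)
    length_p = np.array([config.read_length_probs[L] for L in lengths])
    offsets = np.array([config.true_offsets[L] for L in lengths])
    tx_by_id = {t.id: t for t in transcripts}
    tx_order = sorted(known)

    rows: list[pd.DataFrame] = []

    def _emit(
        tag: str,
        tids: np.ndarray,
        fps: np.ndarray,
        lens: np.ndarray,
        multi: np.ndarray,
        rep: str,
        cond: str,
        assay: str,
    ) -> None:
        n = len(tids)
        if n == 0:
            return
        rows.append(
            pd.DataFrame(
                {
                    "read_id": [f"{tag}_{i}" for i in range(n)],
                    "transcript_id": tids,
                    "five_prime_pos": fps.astype(int),
                    "length": lens.astype(int),
                    "multimapping": multi.astype(bool),
                    "replicate": rep,
                    "condition": cond,
                    "assay": assay,
                }
            )
        )

    for cond in config.conditions:
        active = manifest[
            manifest["conditions"].str.split(";").apply(lambda cs: cond in cs)
        ]
        for r in range(1, config.n_replicates + 1):
            rep = f"rep{r}"
            # --- planted footprints -------------------------------------
            p_tids, p_pos, p_len = [], [], []
            for row in active.itertuples():
                n = _draw_count(rng, row.depth, config.nb_size)
                if n == 0:
                    continue
                n_codons = (row.end - row.start) // 3 - 1
                codon = rng.integers(0, n_codons, size=n)
                is_peak = rng.random(n) < config.start_peak_fraction
                codon[is_peak] = 0
                frame = np.where(
                    rng.random(n) < row.in_frame_prob,
                    0,
                    rng.integers(1, 3, size=n),
                )
                # initiation-pause footprints sit on the AUG itself: frame 0
                frame[is_peak] = 0
                pos = row.start + 3 * codon + frame
                li = rng.choice(len(lengths), size=n, p=length_p)
                fp = pos - offsets[li]
                L = len(tx_by_id[row.transcript_id])
                ok = (fp >= 0) & (fp + lengths[li] <= L)
                p_tids.extend([row.transcript_id] * int(ok.sum()))
                p_pos.append(fp[ok])
                p_len.append(lengths[li][ok])
            # --- background footprints ----------------------------------
            b_tids, b_pos, b_len = [], [], []
            for tid in tx_order:
                L = len(tx_by_id[tid])
                n = _draw_count(
                    rng, config.background_rate * L / 100.0, config.nb_size
                )
                if n == 0:
                    continue
                li = rng.choice(len(lengths), size=n, p=length_p)
                fp = rng.integers(0, np.maximum(1, L - lengths[li] + 1))
                b_tids.extend([tid] * n)
                b_pos.append(fp)
                b_len.append(lengths[li])
            ribo_tids = np.array(p_tids + b_tids, dtype=object)
            ribo_fp = np.concatenate(p_pos + b_pos) if (p_pos or b_pos) else np.array([], int)
            ribo_len = np.concatenate(p_len + b_len) if (p_len or b_len) else np.array([], int)
            multi = rng.random(len(ribo_tids)) < config.multimap_rate
            _emit(f"ribo_{cond}_{rep}", ribo_tids, ribo_fp, ribo_len, multi, rep, cond, "ribo")
            # --- RNA-seq --------------------------------------------------
            rna_depth = dict(
                zip(manifest["transcript_id"], manifest["rna_depth"])
            )
            r_tids, r_pos = [], []
            for tid in tx_order:
                L = len(tx_by_id[tid])
                mu = rna_depth.get(tid, config.planted.rna_depth)
                n = _draw_count(rng, mu, config.nb_size)
                if n == 0:
                    continue
                hi = max(1, L - config.rna_read_length + 1)
                r_tids.extend([tid] * n)
                r_pos.append(rng.integers(0, hi, size=n))
            rna_tids = np.array(r_tids, dtype=object)
            rna_fp = np.concatenate(r_pos) if r_pos else np.array([], int)
            _emit(
                f"rna_{cond}_{rep}",
                rna_tids,
                rna_fp,
                np.full(len(rna_tids), config.rna_read_length),
                np.zeros(len(rna_tids)),
                rep,
                cond,
                "rna",
            )

    if not rows:
        return pd.DataFrame(columns=_io.READ_COLUMNS)
    return pd.concat(rows, ignore_index=True)[_io.READ_COLUMNS]


def write_dataset(
    outdir: str | Path,
    transcripts: Sequence[Transcript],
    manifest: pd.DataFrame,
    reads: pd.DataFrame,
) -> None:
    """Write FASTA, GTF, per-assay/condition/replicate read TSVs, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _io.write_fasta(transcripts, outdir / "transcripts.fasta")
    _io.write_gtf(transcripts, outdir / "annotation.gtf")
    manifest.to_csv(outdir / "truth_manifest.tsv", sep="\t", index=False)
    for (assay, cond, rep), grp in reads.groupby(
        ["assay", "condition", "replicate"], sort=True
    ):
        _io.write_reads_tsv(grp, outdir / f"reads_{assay}_{cond}_{rep}.tsv")
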