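"""P-site offset calibration from annotated start-codon metagenes.

Ribosome footprints of a given length place the ribosomal P-site a fixed
distance downstream of the read's 5' end. That distance is recovered per
read length from footprints on protein-coding transcripts: 5'-end distances
to annotated start codons are histogrammed, and the offset maximising the
aggregate frame-0 fraction of shifted 5' ends inside the CDS is chosen (ties
broken toward the smaller offset). Read lengths whose best in-frame fraction
clears a threshold are selected; the rest are discarded downstream.

Calibration is per replicate by default (each library has its own digestion
signature); a pooled mode is available.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import OFFSET_COLUMNS, PSITE_COLUMNS
from .transcriptome_model import PROTEIN_CODING, Transcript

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    pass


def metagene_by_length(
    ribo_reads: pd.DataFrame,
    transcripts: Sequence[Transcript],
    window: int = 30,
) -> pd.DataFrame:
    """Histogram 5'-end distances to annotated start codons, per read length.

    Parameters
    ----------
    ribo_reads : DataFrame
        Footprint reads (columns ``transcript_id, five_prime_pos, length``).
    transcripts : sequence of Transcript
        Must contain at least one protein-coding transcript.
    window : int
        Signed distances in ``[-window, +window]`` are kept.

    Returns
    -------
    DataFrame with columns ``length, distance, count``; distances outside the
    window contribute nothing, so the counts sum to the number of reads whose
    5' end falls inside a start-codon window.
    """
    cds_start = {
        t.id: t.cds[0] for t in transcripts if t.biotype == PROTEIN_CODING
    }
    if not cds_start:
        raise CalibrationError("metagene requires >=1 protein-coding transcript")
    df = ribo_reads[ribo_reads["transcript_id"].isin(cds_start)].copy()
    starts = df["transcript_id"].map(cds_start)
    df["distance"] = df["five_prime_pos"] - starts
    df = df[df["distance"].abs() <= window]
    out = (
        df.groupby(["length", "distance"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    return out


def infer_offsets(
    metagene: pd.DataFrame,
    candidate_offsets: Optional[Mapping[int, Iterable[int]]] = None,
    min_in_frame: float = 0.6,
) -> pd.DataFrame:
    """Choose a 5'->P-site offset per read length from start metagenes.

    For each candidate offset the score is the frame-0 fraction (relative to
    the annotated start) of shifted 5' ends that land inside the CDS, i.e. at
    or past the start codon. Offsets in the same mod-3 class shift the same
    reads onto the same frame, so the fraction alone identifies the offset
    only up to its phase; candidates whose fraction lies within counting
    noise (two binomial standard deviations) of the maximum are treated as
    tied, and the tie is resolved by the initiation peak — the candidate
    whose negated value sits on the tallest 5'-end bin upstream of the start
    codon wins, exactly as offsets are read off start-codon metaplots —
    with any remaining tie going to the smaller offset.

    Parameters
    ----------
    metagene : DataFrame
        Output of :func:`metagene_by_length`.
    candidate_offsets : mapping length -> iterable of int, optional
        Default: ``range(3, length - 2)`` per observed length.
    min_in_frame : float
        A read length is ``selected`` iff its best fraction reaches this.

    Returns
    -------
    DataFrame ``length, offset, in_frame_fraction, n_reads, selected``.
    """
    if metagene.empty:
        raise CalibrationError("empty metagene: no reads near annotated starts")
    rows = []
    for length, grp in metagene.groupby("length", sort=True):
        d = grp["distance"].to_numpy()
        c = grp["count"].to_numpy()
        total = int(c.sum())
        cands = (
            list(candidate_offsets[length])
            if candidate_offsets is not None and length in candidate_offsets
            else list(range(3, int(length) - 2))
        )
        hist = dict(zip(d.tolist(), c.tolist()))
        scored: list[tuple[int, float, int]] = []
        for off in cands:
            shifted = d + off
            inside = shifted >= 0
            n_inside = int(c[inside].sum())
            if n_inside == 0:
                continue
            in_frame = inside & (shifted % 3 == 0)
            frac = float(c[in_frame].sum()) / n_inside
            scored.append((off, frac, n_inside))
        if not scored:
            continue
        max_frac, n_at_max = max((f, n) for _, f, n in scored)
        tol = 2.0 * float(np.sqrt(max(max_frac * (1.0 - max_frac), 0.0) / n_at_max))
        tied = [(off, f) for off, f, _ in scored if f >= max_frac - tol - 1e-12]
        # ascending candidate order + strict > : smaller offset wins residual ties
        best_off, best_frac, best_peak = None, -1.0, -1
        for off, f in tied:
            peak = int(hist.get(-off, 0))
            if peak > best_peak:
                best_off, best_frac, best_peak = off, f, peak
        rows.append((int(length), int(best_off), best_frac, total))
    if not rows:
        raise CalibrationError("no candidate offset places any read inside a CDS")
    out = pd.DataFrame(rows, columns=["length", "offset", "in_frame_fraction", "n_reads"])
    out["selected"] = out["in_frame_fraction"] >= min_in_frame
    if not out["selected"].any():
        raise CalibrationError(
            "no read length reached min_in_frame="
            f"{min_in_frame:.2f} (best: {out['in_frame_fraction'].max():.3f}); "
            "review the threshold or the library quality"
        )
    return out[OFFSET_COLUMNS]


def assign_psites(
    ribo_reads: pd.DataFrame,
    offset_table: pd.DataFrame,
    transcripts: Sequence[Transcript],
) -> pd.DataFrame:
    """Convert footprint 5' ends to P-site positions.

    Reads of unselected lengths are dropped; each retained read yields one
    P-site at ``five_prime_pos + offset``. P-sites past the transcript end
    are dropped and counted in the log. Replicate/condition/multimapping
    labels are carried through unchanged.
    """
    selected = offset_table[offset_table["selected"]]
    if selected.empty:
        raise CalibrationError("offset table has no selected read length")
    off = dict(zip(selected["length"], selected["offset"]))
    tx_len = {t.id: len(t) for t in transcripts}
    df = ribo_reads[ribo_reads["length"].isin(off)].copy()
    df["pos"] = df["five_prime_pos"] + df["length"].map(off)
    limit = df["transcript_id"].map(tx_len)
    keep = df["pos"] < limit
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("assign_psites: dropped %d P-sites past transcript ends", n_dropped)
    return df.loc[keep, PSITE_COLUMNS].reset_index(drop=True)


def calibrate(
    ribo_reads: pd.DataFrame,
    transcripts: Sequence[Transcript],
    window: int = 30,
    min_in_frame: float = 0.6,
    per_replicate: bool = True,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Infer offset tables, per (condition, replicate) or pooled.

    Returns a mapping ``(condition, replicate) -> offset table``; in pooled
    mode the single key is ``("pooled", "pooled")``.
    """
    if per_replicate:
        out = {}
        for (cond, rep), grp in ribo_reads.groupby(["condition", "replicate"]):
            mg = metagene_by_length(grp, transcripts, window)
            out[(cond, rep)] = infer_offsets(mg, min_in_frame=min_in_frame)
        return out
    mg = metagene_by_length(ribo_reads, transcripts, window)
    return {("pooled", "pooled"): infer_offsets(mg, min_in_frame=min_in_frame)}


def assign_psites_calibrated(
    ribo_reads: pd.DataFrame,
    offset_tables: Mapping[tuple[str, str], pd.DataFrame],
    transcripts: Sequence[Transcript],
) -> pd.DataFrame:
    """Assign P-sites using per-replicate offset tables (or a pooled one)."""
    if set(offset_tables) == {("pooled", "pooled")}:
        return assign_psites(ribo_reads, offset_tables[("pooled", "pooled")], transcripts)
    parts = []
    for (cond, rep), table in sorted(offset_tables.items()):
        grp = ribo_reads[
            (ribo_reads["condition"] == cond) & (ribo_reads["replicate"] == rep)
        ]
        if not grp.empty:
            parts.append(assign_psites(grp, table, transcripts))
    if not parts:
        return pd.DataFrame(columns=PSITE_COLUMNS)
    return pd.concat(parts, ignore_index=True)
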