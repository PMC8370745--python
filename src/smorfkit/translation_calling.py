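"""Active-translation calling from P-sites, per replicate and per condition.

An ORF chain — the in-frame ATGs sharing one stop codon — is the calling
unit. Per replicate, the start codon is chosen first (the most upstream
in-frame ATG with at least five P-sites before the next in-frame ATG; if
none qualifies, the most downstream), then four gates are applied over
``[selected_start, end)``:

1. count: strictly more than five P-sites;
2. framing: at least 50% of those P-sites in frame 0 of the start;
3. periodicity: one-sided exact binomial test of the in-frame count against
   the uniform-frame null p = 1/3, significant at ``alpha``;
4. multimapping: at most 30% of covered positions supported exclusively by
   multimapping reads (strictly more than 30% discards).

A condition-level call requires the gates to hold in at least two of the
replicates (configurable); the consensus start is the most upstream start
selected in any passing replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .transcriptome_model import CandidateORF, Transcript

CALL_COLUMNS = [
    "orf_id",
    "transcript_id",
    "selected_start",
    "end",
    "frame",
    "condition",
    "category",
    "length_codons",
    "n_replicates_passing",
    "called",
]

REPSTATS_COLUMNS = [
    "orf_id",
    "transcript_id",
    "selected_start",
    "end",
    "replicate",
    "condition",
    "n_psites",
    "in_frame_fraction",
    "covered_positions",
    "multimap_only_positions",
    "periodicity_p",
    "passes",
]


@dataclass(frozen=True)
class CallThresholds:
    """Gate settings; the defaults are the method's stated rules."""

    min_psites: int = 6          # "more than five P-sites" == at least 6
    min_in_frame: float = 0.5
    alpha: float = 0.05
    max_multimap: float = 0.30
    min_replicates: int = 2
    min_start_psites: int = 5    # start selection: >=5 between ATG and next ATG
    select_start_first: bool = True


@dataclass
class ReplicateORFStats:
    orf_id: str
    replicate: str
    condition: str
    n_psites: int
    in_frame_fraction: float     # NaN when n_psites == 0
    covered_positions: int
    multimap_only_positions: int
    n_in_frame: int = 0
    periodicity_p: float = float("nan")
    passes: bool = False


@dataclass
class TranslationCall:
    orf_id: str
    condition: str
    selected_start: int
    n_replicates_passing: int
    called: bool
    category: str


def orf_psite_stats(
    start: int,
    end: int,
    positions: np.ndarray,
    multimapping: Optional[np.ndarray] = None,
    orf_id: str = "",
    replicate: str = "",
    condition: str = "",
) -> ReplicateORFStats:
    """Count P-sites inside ``[start, end)`` and their framing/coverage.

    ``positions`` are transcript-space P-site positions from one replicate
    and condition; frame is taken relative to ``start``. A covered position
    is one with at least one P-site; it is multimap-only when every P-site
    there comes from a multimapping read.
    """
    positions = np.asarray(positions)
    inside = (positions >= start) & (positions < end)
    pos = positions[inside]
    n = int(pos.size)
    if n == 0:
        return ReplicateORFStats(orf_id, replicate, condition, 0, float("nan"), 0, 0)
    in_frame = int(((pos - start) % 3 == 0).sum())
    if multimapping is None:
        multi = np.zeros(n, dtype=bool)
    else:
        multi = np.asarray(multimapping)[inside].astype(bool)
    covered = np.unique(pos)
    unique_support = np.unique(pos[~multi])
    mm_only = int(covered.size - unique_support.size)
    return ReplicateORFStats(
        orf_id,
        replicate,
        condition,
        n,
        in_frame / n,
        int(covered.size),
        mm_only,
        n_in_frame=in_frame,
    )


def periodicity_pvalue(n_in_frame: int, n_total: int) -> float:
    """One-sided exact binomial tail P(X >= k | n, p=1/3)."""
    if n_total == 0:
        return float("nan")
    return binomtest(n_in_frame, n_total, p=1.0 / 3.0, alternative="greater").pvalue


def replicate_pass(stats: ReplicateORFStats, thresholds: CallThresholds = CallThresholds()) -> bool:
    """Count, framing and periodicity gates for one replicate.

    Passes iff ``n_psites > 5`` (``min_psites``), the in-frame fraction is at
    least ``min_in_frame``, and the exact binomial test of the in-frame count
    against p = 1/3 is significant at ``alpha``. The multimapping gate is
    applied separately (:func:`multimap_filter`).
    """
    if stats.n_psites < thresholds.min_psites:
        return False
    if math.isnan(stats.in_frame_fraction) or stats.in_frame_fraction < thresholds.min_in_frame:
        return False
    k = stats.n_in_frame if stats.n_psites else 0
    if k == 0 and stats.in_frame_fraction > 0:
        k = round(stats.in_frame_fraction * stats.n_psites)
    p = periodicity_pvalue(int(k), stats.n_psites)
    stats.periodicity_p = float(p)
    return bool(p <= thresholds.alpha)


def multimap_filter(stats: ReplicateORFStats, max_fraction: float = 0.30) -> bool:
    """Return True to retain: multimap-only coverage must not exceed 30%.

    Discards only when the fraction is strictly greater than ``max_fraction``
    (a fraction of exactly 0.30 is retained).
    """
    if stats.covered_positions == 0:
        return True  # nothing to judge; the count gate already failed
    return stats.multimap_only_positions / stats.covered_positions <= max_fraction


def select_start(
    starts: Sequence[int],
    positions: np.ndarray,
    min_psites: int = 5,
) -> int:
    """Pick the start codon of a chain of in-frame ATGs sharing a stop.

    Returns the most upstream ATG with at least ``min_psites`` P-sites
    between it and the next in-frame ATG; if no ATG qualifies, the most
    downstream one. A single-ATG chain returns its only member.
    """
    if not starts:
        raise ValueError("empty start chain")
    starts = sorted(starts)
    positions = np.sort(np.asarray(positions))
    for s, nxt in zip(starts[:-1], starts[1:]):
        n_between = int(
            np.searchsorted(positions, nxt, "left")
            - np.searchsorted(positions, s, "left")
        )
        if n_between >= min_psites:
            return s
    return starts[-1]


def condition_consensus(
    per_replicate: Sequence[tuple[str, int, bool]],
    min_replicates: int = 2,
    orf_id: str = "",
    condition: str = "",
    category: str = "",
) -> TranslationCall:
    """Combine per-replicate decisions into a condition-level call.

    ``per_replicate`` holds ``(replicate, selected_start, passes)`` triples.
    Called iff at least ``min_replicates`` replicates pass; the consensus
    start is the most upstream start selected in any passing replicate
    (most upstream overall when none passes, for reporting).
    """
    if not per_replicate:
        raise ValueError("need at least one evaluated replicate")
    n_pass = sum(bool(p) for _, _, p in per_replicate)
    passing = [s for _, s, p in per_replicate if p]
    sel = min(passing) if passing else min(s for _, s, _ in per_replicate)
    return TranslationCall(
        orf_id=orf_id,
        condition=condition,
        selected_start=sel,
        n_replicates_passing=n_pass,
        called=n_pass >= min_replicates,
        category=category,
    )


def build_chains(
    orfs: Sequence[CandidateORF],
) -> dict[tuple[str, int, int], list[CandidateORF]]:
    """Group candidate ORFs into chains keyed by (transcript, end, frame)."""
    chains: dict[tuple[str, int, int], list[CandidateORF]] = {}
    for o in orfs:
        chains.setdefault((o.transcript_id, o.end, o.frame), []).append(o)
    for members in chains.values():
        members.sort(key=lambda o: o.start)
    return chains


def call_orfs(
    orfs: Sequence[CandidateORF],
    psites: pd.DataFrame,
    thresholds: CallThresholds = CallThresholds(),
    conditions: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full calling procedure over all ORF chains and conditions.

    Parameters
    ----------
    orfs : candidate ORFs (from :func:`~smorfkit.transcriptome_model.enumerate_orfs`).
    psites : DataFrame
        Columns ``transcript_id, pos, multimapping, replicate, condition``.
    thresholds : CallThresholds
    conditions : optional subset of conditions to evaluate.

    Returns
    -------
    (calls, replicate_stats)
        ``calls`` has one row per chain x condition with the consensus
        decision; ``replicate_stats`` is the per-replicate audit table from
        which every gate can be re-derived.
    """
    chains = build_chains(orfs)
    category_of = {(o.transcript_id, o.start, o.end): o.category for o in orfs}
    if conditions is None:
        conditions = sorted(psites["condition"].unique())
    call_rows: list[tuple] = []
    stat_rows: list[tuple] = []
    for cond in conditions:
        sub = psites[psites["condition"] == cond]
        replicates = sorted(sub["replicate"].unique())
        by_rep_tx = {
            key: (grp["pos"].to_numpy(), grp["multimapping"].to_numpy())
            for key, grp in sub.groupby(["replicate", "transcript_id"])
        }
        for (tid, end, frame), members in sorted(chains.items()):
            starts = [o.start for o in members]
            per_rep: list[tuple[str, int, bool]] = []
            for rep in replicates:
                pos, multi = by_rep_tx.get((rep, tid), (np.array([], int), np.array([], bool)))
                if thresholds.select_start_first:
                    sel = select_start(starts, pos, thresholds.min_start_psites)
                else:
                    sel = starts[0]
                stats = orf_psite_stats(sel, end, pos, multi, "", rep, cond)
                ok = replicate_pass(stats, thresholds) and multimap_filter(
                    stats, thresholds.max_multimap
                )
                stats.passes = ok
                per_rep.append((rep, sel, ok))
                stat_rows.append(
                    (
                        f"{tid}_{sel}_{end}",
                        tid,
                        sel,
                        end,
                        rep,
                        cond,
                        stats.n_psites,
                        stats.in_frame_fraction,
                        stats.covered_positions,
                        stats.multimap_only_positions,
                        stats.periodicity_p,
                        ok,
                    )
                )
            if not per_rep:
                per_rep = [("none", starts[-1], False)]
            consensus = condition_consensus(
                per_rep, thresholds.min_replicates, condition=cond
            )
            sel_start = consensus.selected_start
            category = category_of.get((tid, sel_start, end), members[0].category)
            call_rows.append(
                (
                    f"{tid}_{sel_start}_{end}",
                    tid,
                    sel_start,
                    end,
                    frame,
                    cond,
                    category,
                    (end - sel_start) // 3 - 1,
                    consensus.n_replicates_passing,
                    consensus.called,
                )
            )
    calls = pd.DataFrame(call_rows, columns=CALL_COLUMNS)
    repstats = pd.DataFrame(stat_rows, columns=REPSTATS_COLUMNS)
    return calls, repstats


@dataclass
class ConditionSets:
    """Called-ORF sets per condition plus their union/intersection sizes."""

    sets: dict[str, set]
    union: int = 0
    intersection: int = 0
    category_counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sets.items()}


def condition_sets(calls: pd.DataFrame) -> ConditionSets:
    """Per-condition translated-ORF sets, union/intersection, category tallies.

    Identity is the ORF chain (transcript, stop, frame), so an ORF whose
    consensus start differs between conditions still counts once in the
    union. The union size satisfies |A u B| = |A| + |B| - |A n B| by
    construction; both sides are computed from the sets directly.
    """
    called = calls[calls["called"]]
    conds = sorted(calls["condition"].unique())
    sets = {
        c: set(
            map(
                tuple,
                called.loc[
                    called["condition"] == c, ["transcript_id", "end", "frame"]
                ].itertuples(index=False),
            )
        )
        for c in conds
    }
    union: set = set().union(*sets.values()) if sets else set()
    inter: set = (
        set.intersection(*sets.values()) if sets else set()
    )
    tally = (
        called.groupby(["category", "condition"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=conds, fill_value=0)
    )
    return ConditionSets(
        sets=sets,
        union=len(union),
        intersection=len(inter),
        category_counts=tally,
    )
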