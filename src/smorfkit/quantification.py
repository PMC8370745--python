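"""Translational efficiency and metagene start/stop profiles.

Translational efficiency (TE) for an ORF in a condition is

    TE = mean_r( psites_r / median_orf(psites_r) )
         / mean_r( rna_r / median_orf(rna_r) )

where ``psites_r`` counts P-sites inside the ORF in replicate ``r``,
``rna_r`` counts RNA-seq read 5' ends inside the ORF, and each replicate is
normalized by its median over the ORF set being reported. The per-replicate
median normalization makes TE invariant to library-size rescaling of any
single replicate. TE is undefined (NaN, flagged) when the RNA denominator
is zero.

Metagene profiles average P-site counts positionwise in windows around the
selected start codon and the stop codon, after scaling each transcript's
counts by its total across both windows, so every transcript contributes
unit mass regardless of expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


def count_sites(
    sites: pd.DataFrame,
    orfs: pd.DataFrame,
    pos_column: str = "pos",
) -> pd.DataFrame:
    """Count sites (P-sites or RNA 5' ends) inside each ORF per replicate.

    Parameters
    ----------
    sites : DataFrame with ``transcript_id``, a position column, ``replicate``.
    orfs : DataFrame with ``orf_id, transcript_id, selected_start, end``
        (``start`` accepted in place of ``selected_start``).
    pos_column : name of the position column (``pos`` for P-sites,
        ``five_prime_pos`` for RNA reads).

    Returns
    -------
    DataFrame indexed by orf_id with one column per replicate.
    """
    start_col = "selected_start" if "selected_start" in orfs.columns else "start"
    replicates = sorted(sites["replicate"].unique())
    by_tx = {
        (rep, tid): np.sort(grp[pos_column].to_numpy())
        for (rep, tid), grp in sites.groupby(["replicate", "transcript_id"])
    }
    data = {}
    for rep in replicates:
        col = []
        for row in orfs.itertuples():
            pos = by_tx.get((rep, row.transcript_id))
            if pos is None:
                col.append(0)
            else:
                s = getattr(row, start_col)
                col.append(
                    int(np.searchsorted(pos, row.end, "left") - np.searchsorted(pos, s, "left"))
                )
        data[rep] = col
    return pd.DataFrame(data, index=pd.Index(orfs["orf_id"], name="orf_id"))


def translational_efficiency(
    psite_counts: pd.DataFrame,
    rna_counts: pd.DataFrame,
) -> pd.DataFrame:
    """Apply the TE formula to per-ORF, per-replicate count tables.

    Both tables must be indexed by orf_id with replicate columns; medians are
    taken over the supplied ORF set, per replicate. Replicates whose median
    is zero cannot be normalized and are dropped with a warning.

    Returns a DataFrame indexed by orf_id with columns ``te``,
    ``te_defined``, ``mean_norm_psites``, ``mean_norm_rna`` plus the
    per-replicate normalized components.
    """
    psite_counts, rna_counts = psite_counts.align(rna_counts, join="inner", axis=0)

    def _normalize(counts: pd.DataFrame, label: str) -> pd.DataFrame:
        keep = {}
        for rep in counts.columns:
            med = counts[rep].median()
            if med == 0:
                warnings.warn(
                    f"replicate {rep}: median {label} count is zero; replicate dropped"
                )
                continue
            keep[rep] = counts[rep] / med
        if not keep:
            raise ValueError(f"all replicates have zero median {label} counts")
        return pd.DataFrame(keep)

    norm_p = _normalize(psite_counts, "P-site")
    norm_r = _normalize(rna_counts, "RNA-site")
    mean_p = norm_p.mean(axis=1)
    mean_r = norm_r.mean(axis=1)
    te = mean_p / mean_r.where(mean_r > 0)
    out = pd.DataFrame(
        {
            "te": te,
            "te_defined": mean_r > 0,
            "mean_norm_psites": mean_p,
            "mean_norm_rna": mean_r,
        }
    )
    for rep in norm_p.columns:
        out[f"norm_psites_{rep}"] = norm_p[rep]
    for rep in norm_r.columns:
        out[f"norm_rna_{rep}"] = norm_r[rep]
    return out


def te_group_summary(
    te: pd.DataFrame, categories: pd.Series
) -> pd.DataFrame:
    """Median/quartile TE per ORF category; undefined TEs excluded, counted."""
    df = te.join(categories.rename("category"), how="inner")
    rows = []
    for cat, grp in df.groupby("category"):
        defined = grp.loc[grp["te_defined"], "te"].dropna()
        rows.append(
            {
                "category": cat,
                "n": len(grp),
                "n_undefined": int(len(grp) - len(defined)),
                "median_te": defined.median() if len(defined) else np.nan,
                "q1_te": defined.quantile(0.25) if len(defined) else np.nan,
                "q3_te": defined.quantile(0.75) if len(defined) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("category")


@dataclass
class MetageneProfile:
    """Positionwise mean of per-transcript-normalized P-site counts."""

    half_width: int
    positions: np.ndarray          # -half_width .. +half_width
    start_profile: np.ndarray
    stop_profile: np.ndarray
    n_transcripts: int
    n_excluded: int                # zero-count transcripts left out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "start_mean": self.start_profile,
                "stop_mean": self.stop_profile,
                "n_transcripts": self.n_transcripts,
            }
        )


def metagene_profile(
    psites: pd.DataFrame,
    orfs: pd.DataFrame,
    half_width: int = 75,
) -> MetageneProfile:
    """Average normalized P-site counts around start and stop codons.

    For each ORF, P-sites are counted at every signed position in
    ``[-half_width, +half_width]`` relative to the selected start codon and
    relative to the stop codon (anchor: first nucleotide of the stop), the
    two windows are jointly scaled to unit mass, and the scaled counts are
    averaged positionwise across ORFs. ORFs with no P-site in either window
    are excluded and counted. Window positions beyond the transcript bounds
    simply contribute zeros.
    """
    if orfs.empty:
        raise ValueError("metagene_profile requires a non-empty ORF set")
    start_col = "selected_start" if "selected_start" in orfs.columns else "start"
    width = 2 * half_width + 1
    start_sum = np.zeros(width)
    stop_sum = np.zeros(width)
    n_used = 0
    n_excluded = 0
    by_tx = {
        tid: grp["pos"].to_numpy() for tid, grp in psites.groupby("transcript_id")
    }
    for row in orfs.itertuples():
        pos = by_tx.get(row.transcript_id, np.array([], int))
        s = int(getattr(row, start_col))
        stop = int(row.end) - 3
        rel_start = pos - s
        rel_stop = pos - stop
        w_start = np.bincount(
            rel_start[np.abs(rel_start) <= half_width] + half_width, minlength=width
        ).astype(float)
        w_stop = np.bincount(
            rel_stop[np.abs(rel_stop) <= half_width] + half_width, minlength=width
        ).astype(float)
        total = w_start.sum() + w_stop.sum()
        if total == 0:
            n_excluded += 1
            continue
        start_sum += w_start / total
        stop_sum += w_stop / total
        n_used += 1
    if n_used == 0:
        raise ValueError("no ORF had any P-site in its start/stop windows")
    return MetageneProfile(
        half_width=half_width,
        positions=np.arange(-half_width, half_width + 1),
        start_profile=start_sum / n_used,
        stop_profile=stop_sum / n_used,
        n_transcripts=n_used,
        n_excluded=n_excluded,
    )


def stop_dropoff_ratio(profile: MetageneProfile) -> float:
    """Mean signal downstream of the stop codon over mean in-ORF signal.

    In-ORF signal: start-window positions >= 0 plus stop-window positions
    < 3 (the stop codon belongs to the ORF span); downstream signal:
    stop-window positions >= 3. A small ratio is the footprint drop-off
    expected of genuine termination.
    """
    h = profile.half_width
    in_orf = np.concatenate(
        [profile.start_profile[h:], profile.stop_profile[: h + 3]]
    )
    downstream = profile.stop_profile[h + 3 :]
    denom = in_orf.mean()
    if denom == 0:
        return float("nan")
    return float(downstream.mean() / denom)


def sample_comparison_orfs(
    orf_ids: Sequence[str],
    n: int = 100,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[str]:
    """Uniform sample (without replacement) of ORFs for metagene comparison.

    Used to draw the canonical-ORF comparison set (default 100). If the pool
    is smaller than ``n`` the whole pool is returned with a warning.
    Deterministic given ``seed`` (or a supplied generator).
    """
    if len(orf_ids) == 0:
        raise ValueError("empty ORF pool")
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(orf_ids) <= n:
        if len(orf_ids) < n:
            warnings.warn(
                f"pool of {len(orf_ids)} ORFs smaller than requested {n}; using all"
            )
        return list(orf_ids)
    idx = rng.choice(len(orf_ids), size=n, replace=False)
    return [orf_ids[i] for i in sorted(idx)]


def plot_metagene(profile: MetageneProfile, path: str) -> None:
    """Write a two-panel start/stop metagene figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3), sharey=True)
    for ax, ys, anchor in zip(
        axes, [profile.start_profile, profile.stop_profile], ["start", "stop"]
    ):
        ax.bar(profile.positions, ys, width=1.0)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel(f"nt from {anchor} codon")
    axes[0].set_ylabel("mean normalized P-sites")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
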