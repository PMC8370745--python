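"""Peptide-level summaries and the set/percentage reporting arithmetic.

Covers amino-acid composition of called ORF sets against an
expected-by-chance reference table, length distributions in codons, and the
union/intersection/percentage bookkeeping used when reporting overlaps
between ORF sets (conditions, external evidence, homolog searches).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


def load_expected_frequencies(path: Optional[str | Path] = None) -> pd.Series:
    """Load the expected-by-chance residue frequency table.

    Default: the packaged reference (codon multiplicity over the 61 sense
    codons). Any TSV with ``residue`` and ``expected`` columns may be
    substituted.
    """
    if path is None:
        source = resources.files("smorfkit.data") / "expected_aa_freqs.tsv"
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    s = df.set_index("residue")["expected"].reindex(AMINO_ACIDS)
    if s.isna().any():
        raise ValueError("expected-frequency table missing residues")
    return s


def aa_composition(
    peptides: Sequence[str],
    expected: Optional[pd.Series] = None,
    mode: str = "per_peptide",
) -> pd.DataFrame:
    """Average amino-acid composition of a peptide set vs expectation.

    ``per_peptide`` (default) computes each peptide's own frequency vector
    and averages them unweighted, so short and long peptides count equally;
    ``pooled`` concatenates all residues first. The mode is recorded in the
    result attrs.

    Returns a DataFrame indexed by residue with ``observed``, ``expected``
    and ``difference`` columns. Non-standard residues raise, naming the
    offending peptide.
    """
    if len(peptides) == 0:
        raise ValueError("need at least one peptide")
    if mode not in ("per_peptide", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    counts = np.zeros((len(peptides), 20))
    for i, pep in enumerate(peptides):
        if not pep:
            raise ValueError(f"empty peptide at index {i}")
        for ch in pep:
            j = aa_index.get(ch)
            if j is None:
                raise ValueError(f"non-standard residue {ch!r} in peptide {pep!r}")
            counts[i, j] += 1
    if mode == "per_peptide":
        freqs = counts / counts.sum(axis=1, keepdims=True)
        observed = freqs.mean(axis=0)
    else:
        observed = counts.sum(axis=0) / counts.sum()
    if expected is None:
        expected = load_expected_frequencies()
    out = pd.DataFrame(
        {
            "observed": observed,
            "expected": expected.to_numpy(),
            "difference": observed - expected.to_numpy(),
        },
        index=pd.Index(AMINO_ACIDS, name="residue"),
    )
    out.attrs["mode"] = mode
    out.attrs["n_peptides"] = len(peptides)
    return out


def length_summary(orf_sets: Mapping[str, Sequence[int]]) -> pd.DataFrame:
    """Median and quartiles of ORF lengths (codons) per labelled set.

    The median of an even-sized set is the mean of the central pair.
    """
    rows = []
    for label, lengths in orf_sets.items():
        if len(lengths) == 0:
            raise ValueError(f"empty ORF set {label!r}")
        arr = np.asarray(lengths, dtype=float)
        rows.append(
            {
                "set": label,
                "n": len(arr),
                "median_codons": float(np.median(arr)),
                "q1_codons": float(np.quantile(arr, 0.25)),
                "q3_codons": float(np.quantile(arr, 0.75)),
                "min_codons": float(arr.min()),
                "max_codons": float(arr.max()),
            }
        )
    return pd.DataFrame(rows).set_index("set")


def length_histogram(
    lengths: Sequence[int], bin_width: int = 10
) -> pd.DataFrame:
    """Histogram of ORF lengths in codon bins, for export/plotting."""
    arr = np.asarray(lengths)
    hi = (int(arr.max()) // bin_width + 1) * bin_width
    edges = np.arange(0, hi + bin_width, bin_width)
    counts, _ = np.histogram(arr, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )


def percentage(numerator: int, denominator: int) -> int:
    """Integer percentage, rounding half away from zero (126/178 -> 71)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise ValueError(
            f"numerator {numerator} outside [0, denominator={denominator}]"
        )
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def union_size(n_a: int, n_b: int, n_intersection: int) -> int:
    """|A u B| by inclusion-exclusion, with the containment checks."""
    if min(n_a, n_b, n_intersection) < 0:
        raise ValueError("set sizes must be non-negative")
    if n_intersection > min(n_a, n_b):
        raise ValueError("intersection cannot exceed either set")
    return n_a + n_b - n_intersection


@dataclass
class SetSummary:
    """Labelled counts with derived set sizes and rounded percentages."""

    counts: dict[str, int]
    unions: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, int] = field(default_factory=dict)

    def add_union(self, label: str, a: str, b: str, intersection: str) -> int:
        u = union_size(self.counts[a], self.counts[b], self.counts[intersection])
        self.unions[label] = u
        self.counts[label] = u
        return u

    def add_percentage(self, label: str, numerator: str, denominator: str) -> int:
        p = percentage(self.counts[numerator], self.counts[denominator])
        self.percentages[label] = p
        return p

    def add_difference(self, label: str, a: str, b: str) -> int:
        d = self.counts[a] - self.counts[b]
        if d < 0:
            raise ValueError(f"{a} smaller than {b}")
        self.counts[label] = d
        return d

    def add_total(self, label: str, parts: Sequence[str]) -> int:
        t = sum(self.counts[p] for p in parts)
        self.counts[label] = t
        return t


def overlap_percentages(pairs: Mapping[str, tuple[int, int]]) -> pd.DataFrame:
    """Rounded integer percentages for labelled (numerator, denominator) pairs."""
    rows = []
    for label, (num, den) in pairs.items():
        rows.append(
            {
                "label": label,
                "numerator": num,
                "denominator": den,
                "percent": percentage(num, den),
            }
        )
    return pd.DataFrame(rows).set_index("label")
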