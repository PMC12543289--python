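"""Compartment-wise k-mer counting, frequencies, and enrichment ratios.

The screen tracks all 336 k-mers of length 2, 3 and 4 (16 + 64 + 256) over
the alphabet {A, C, G, T}. Counts are taken on the given strand; a window is
counted only when it lies wholly inside a single interval of the compartment
and contains no N — equivalent to counting on a hard-masked assembly where
the compartment complement is replaced by N.

Frequencies are normalized per compartment. The default scope normalizes
within each k-length (dimer frequencies sum to 1, trimer frequencies sum to
1, tetramer frequencies sum to 1), which makes enrichment ratios invariant
to the mixture of k's; ``all_kmers`` normalizes by the grand total instead.

For each k-mer two enrichment ratios are formed:

* ``E_noncoding = f_noncoding / f_coding`` — non-coding over coding,
* ``E_repeat = f_repeat / f_noncoding`` — repeat over non-coding.

A ratio is undefined whenever its denominator is zero; undefined ratios are
flagged and excluded from every downstream threshold count.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, Iterable, Mapping

import numpy as np
import pandas as pd

from .genome import CompartmentMap, GenomeAssembly
from .intervals import IntervalSet

__all__ = [
    "KMER_SIZES",
    "ALL_KMERS",
    "KmerFrequencies",
    "EnrichmentProfile",
    "count_kmers",
    "compartment_counts",
    "normalize",
    "enrichment_profile",
    "genome_enrichment",
]

KMER_SIZES = (2, 3, 4)

_BASES = "ACGT"

#: the complete 336-k-mer universe of the screen (16 dimers + 64 trimers
#: + 256 tetramers), in lexicographic order within each k
ALL_KMERS = tuple(
    "".join(p) for k in KMER_SIZES for p in product(_BASES, repeat=k)
)

# byte-value -> code lookup; A,C,G,T -> 0..3, everything else -> 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i


def encode(sequence: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3; other -> 4)."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _count_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Count k-mer windows in a code array; windows containing non-ACGT skip."""
    n = codes.size
    if n < k:
        return np.zeros(4**k, dtype=np.int64)
    m = n - k + 1
    idx = np.zeros(m, dtype=np.int64)
    bad = np.zeros(m, dtype=bool)
    for i in range(k):
        c = codes[i : m + i]
        bad |= c >= 4
        idx = idx * 4 + np.where(c < 4, c, 0).astype(np.int64)
    if bad.any():
        idx = idx[~bad]
    return np.bincount(idx, minlength=4**k)


def _kmer_strings(k: int) -> list[str]:
    return ["".join(p) for p in product(_BASES, repeat=k)]


def count_kmers(
    assembly: GenomeAssembly, intervals: IntervalSet, k: int
) -> Dict[str, int]:
    """Count k-mers over an interval set on the given strand.

    Windows never span interval boundaries and windows containing N are
    skipped, matching counting on a hard-masked FASTA.
    """
    if k not in KMER_SIZES:
        raise ValueError(f"k must be one of {KMER_SIZES}, got {k}")
    total = np.zeros(4**k, dtype=np.int64)
    for scaf, seq in assembly.scaffolds.items():
        pairs = intervals.pairs(scaf)
        if not pairs:
            continue
        codes = encode(seq)
        for s, e in pairs:
            total += _count_codes(codes[s:e], k)
    return dict(zip(_kmer_strings(k), total.tolist()))


def compartment_counts(
    assembly: GenomeAssembly, intervals: IntervalSet
) -> pd.Series:
    """Counts for the whole 336 k-mer universe over one compartment."""
    out: Dict[str, int] = {}
    for k in KMER_SIZES:
        out.update(count_kmers(assembly, intervals, k))
    return pd.Series(out, name="count").reindex(list(ALL_KMERS))


@dataclass
class KmerFrequencies:
    """Normalized k-mer frequencies for one compartment.

    ``f`` is indexed by k-mer; entries for a k-length whose total count is
    zero are NaN and flagged undefined.
    """

    f: pd.Series
    defined: pd.Series
    normalization_scope: str = "per_k_length"

    def __getitem__(self, kmer: str) -> float:
        return float(self.f[kmer])


def normalize(
    counts: Mapping[str, int] | pd.Series,
    scope: str = "per_k_length",
    allow_empty: bool = False,
) -> KmerFrequencies:
    """Turn raw counts into frequencies.

    ``per_k_length`` (default): each k-mer is divided by the summed counts
    of its own length, so frequencies sum to 1 within each k. ``all_kmers``:
    divided by the grand total. An entirely empty compartment is an error
    unless ``allow_empty`` is set, in which case every frequency is NaN and
    flagged undefined (downstream ratios then propagate the flag).
    """
    counts = pd.Series(counts, dtype=float)
    if counts.sum() == 0 and not allow_empty:
        raise ValueError("empty compartment: all k-mer counts are zero")
    klen = counts.index.str.len()
    if scope == "per_k_length":
        totals = counts.groupby(klen).transform("sum")
    elif scope == "all_kmers":
        totals = pd.Series(counts.sum(), index=counts.index)
    else:
        raise ValueError(f"unknown normalization scope {scope!r}")
    defined = totals > 0
    f = counts.where(defined) / totals.where(defined)
    return KmerFrequencies(f=f, defined=defined, normalization_scope=scope)


@dataclass
class EnrichmentProfile:
    """Per-k-mer compartment frequencies and the two enrichment ratios.

    ``table`` columns: kmer (index), k, f_coding, f_noncoding, f_repeat,
    E_noncoding, E_repeat, defined_nc, defined_rep. A ratio is defined iff
    its numerator's compartment has counts for that k and the denominator
    frequency is strictly positive.
    """

    table: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=True, index_label="kmer")

    @classmethod
    def from_tsv(cls, path) -> "EnrichmentProfile":
        return cls(pd.read_csv(path, sep="\t", index_col="kmer"))


def enrichment_profile(
    freq_coding: KmerFrequencies,
    freq_noncoding: KmerFrequencies,
    freq_repeat: KmerFrequencies,
) -> EnrichmentProfile:
    """Combine the three compartments' frequencies into enrichment ratios."""
    idx = freq_coding.f.index
    if not (idx.equals(freq_noncoding.f.index) and idx.equals(freq_repeat.f.index)):
        raise ValueError("mismatched k-mer universes between compartments")

    fc, fn, fr = freq_coding.f, freq_noncoding.f, freq_repeat.f
    defined_nc = fn.notna() & fc.notna() & (fc > 0)
    defined_rep = fr.notna() & fn.notna() & (fn > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_nc = (fn / fc).where(defined_nc)
        e_rep = (fr / fn).where(defined_rep)

    table = pd.DataFrame(
        {
            "k": idx.str.len(),
            "f_coding": fc,
            "f_noncoding": fn,
            "f_repeat": fr,
            "E_noncoding": e_nc,
            "E_repeat": e_rep,
            "defined_nc": defined_nc,
            "defined_rep": defined_rep,
        }
    )
    return EnrichmentProfile(table=table)


def genome_enrichment(
    assembly: GenomeAssembly,
    cmap: CompartmentMap,
    scope: str = "per_k_length",
) -> EnrichmentProfile:
    """End-to-end enrichment profile for one assembly and compartment map."""
    fc = normalize(
        compartment_counts(assembly, cmap.coding).fillna(0), scope, allow_empty=True
    )
    fn = normalize(
        compartment_counts(assembly, cmap.noncoding).fillna(0), scope, allow_empty=True
    )
    fr = normalize(
        compartment_counts(assembly, cmap.repeats).fillna(0), scope, allow_empty=True
    )
    return enrichment_profile(fc, fn, fr)
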