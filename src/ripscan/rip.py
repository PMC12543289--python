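"""RIP activity classification and repeat-linker-repeat (RLR) cross analysis.

Repeat-induced point mutation (RIP) converts C to T in a CpA dinucleotide
context (equivalently G to A at TpG on the shown strand) within duplicated
sequences. Active RIP therefore skews k-mer composition of repeats towards
AT-rich words, and — because mutated relics accumulate in intergenic space —
of the non-coding compartment relative to coding sequence.

A genome is summarized by three counts over its enrichment profile at a
fold threshold (default 2):

* ``n_noncoding`` — defined k-mers with non-coding/coding enrichment > fold,
* ``n_repeat``    — defined k-mers with repeat/non-coding enrichment > fold,
* ``n_both``      — k-mers passing both,

and by ``ratio = n_both / n_noncoding``. The categorical call is:

* ``recent``       — ratio > 0.5 and n_both >= 10,
* ``trace``        — 0.3 <= ratio <= 0.5,
* ``none``         — everything else,
* ``undetermined`` — no k-mer is non-coding enriched (n_noncoding = 0).

A genome with ratio > 0.5 but fewer than 10 doubly enriched k-mers is
classified ``none`` and flagged: the 10-k-mer floor exists to suppress
small-count artifacts, and the high ratio is then not trustworthy.

The RLR analysis measures the same signature experimentally: a parent
construct carries two identical repeats (802 bp) flanking a linker
(729 bp); progeny of a cross are compared to the parent via per-region
k-mer frequency ratios, pooling the two repeat copies as the "duplicated"
region and keeping the linker separate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .composition import KMER_SIZES, _count_codes, _kmer_strings, encode
from .composition import EnrichmentProfile

__all__ = [
    "RipParams",
    "RipSummary",
    "RLRLayout",
    "RLRResult",
    "classify_rip",
    "rlr_kmer_ratios",
    "count_mutations",
]


@dataclass(frozen=True)
class RipParams:
    """Thresholds of the categorical RIP call."""

    fold: float = 2.0
    ratio_recent: float = 0.5
    ratio_trace_low: float = 0.3
    min_both: int = 10


@dataclass
class RipSummary:
    """Per-genome enriched-k-mer counts and the categorical RIP status."""

    n_noncoding: int
    n_repeat: int
    n_both: int
    ratio: float
    status: str
    params: RipParams = field(default_factory=RipParams)
    low_count_warning: bool = False

    def as_row(self, assembly: str = "") -> Dict[str, object]:
        return {
            "assembly": assembly,
            "n_noncoding": self.n_noncoding,
            "n_repeat": self.n_repeat,
            "n_both": self.n_both,
            "ratio": self.ratio,
            "status": self.status,
        }


def classify_rip(
    profile: EnrichmentProfile, params: RipParams = RipParams()
) -> RipSummary:
    """Classify a genome's RIP activity from its enrichment profile.

    Undefined enrichment ratios are excluded from every count. The rule
    order is: undetermined (no non-coding-enriched k-mer), then recent,
    then the trace band, then none.
    """
    t = profile.table
    nc_enriched = t["defined_nc"] & (t["E_noncoding"] > params.fold)
    rep_enriched = t["defined_rep"] & (t["E_repeat"] > params.fold)
    both = nc_enriched & rep_enriched

    n_nc = int(nc_enriched.sum())
    n_rep = int(rep_enriched.sum())
    n_both = int(both.sum())

    if n_nc == 0:
        return RipSummary(0, n_rep, 0, float("nan"), "undetermined", params)

    ratio = n_both / n_nc
    warn = False
    if ratio > params.ratio_recent and n_both >= params.min_both:
        status = "recent"
    elif params.ratio_trace_low <= ratio <= params.ratio_recent:
        status = "trace"
    else:
        status = "none"
        if ratio > params.ratio_recent:
            # high ratio carried by fewer than min_both k-mers
            warn = True
    return RipSummary(n_nc, n_rep, n_both, ratio, status, params, warn)


# ---------------------------------------------------------------------------
# RLR cross analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RLRLayout:
    """Coordinates of the repeat-linker-repeat regions on the parent.

    Half-open coordinates on the parent sequence; the two repeats must be
    equal length and the three regions contiguous and non-overlapping.
    """

    repeat1: Tuple[int, int]
    linker: Tuple[int, int]
    repeat2: Tuple[int, int]

    def __post_init__(self) -> None:
        r1, l, r2 = self.repeat1, self.linker, self.repeat2
        if not (r1[0] < r1[1] == l[0] < l[1] == r2[0] < r2[1]):
            raise ValueError("RLR regions must be contiguous and ordered")
        if r1[1] - r1[0] != r2[1] - r2[0]:
            raise ValueError("repeat copies must have equal length")

    @property
    def repeat_length(self) -> int:
        return self.repeat1[1] - self.repeat1[0]

    @property
    def linker_length(self) -> int:
        return self.linker[1] - self.linker[0]

    @classmethod
    def standard(cls, repeat_len: int = 802, linker_len: int = 729) -> "RLRLayout":
        """The published construct geometry: 802 bp repeats, 729 bp linker."""
        return cls(
            repeat1=(0, repeat_len),
            linker=(repeat_len, repeat_len + linker_len),
            repeat2=(repeat_len + linker_len, 2 * repeat_len + linker_len),
        )


@dataclass
class RLRResult:
    """Per-region progeny/parent k-mer frequency ratios for one progeny.

    ``table`` columns: region ('duplicated' or 'linker'), kmer, k,
    f_parent, f_progeny, ratio, defined. Frequencies are normalized per
    k-length within each region independently.
    """

    table: pd.DataFrame
    mutation_count: int

    def region(self, name: str) -> pd.DataFrame:
        return self.table[self.table["region"] == name]


def _region_frequencies(seq: str, windows: Sequence[Tuple[int, int]]) -> pd.DataFrame:
    rows = []
    codes = encode(seq)
    for k in KMER_SIZES:
        counts = np.zeros(4**k, dtype=np.int64)
        for s, e in windows:
            counts += _count_codes(codes[s:e], k)
        total = counts.sum()
        freq = counts / total if total > 0 else np.full(counts.size, np.nan)
        rows.append(
            pd.DataFrame({"kmer": _kmer_strings(k), "k": k, "f": freq})
        )
    return pd.concat(rows, ignore_index=True)


def rlr_kmer_ratios(parent: str, progeny: str, layout: RLRLayout) -> RLRResult:
    """Progeny/parent k-mer frequency ratios per RLR region.

    The two repeat copies are pooled into the "duplicated" region (windows
    are counted per copy, never across the junction); the linker is counted
    separately. Sequences must be equal length (positional comparison) —
    indel-containing progeny should be aligned to the parent first.
    """
    if len(parent) != len(progeny):
        raise ValueError(
            "parent and progeny lengths differ "
            f"({len(parent)} vs {len(progeny)}); align the progeny to the "
            "parent coordinates before computing ratios"
        )
    regions = {
        "duplicated": [layout.repeat1, layout.repeat2],
        "linker": [layout.linker],
    }
    frames = []
    for name, windows in regions.items():
        fp = _region_frequencies(parent, windows).rename(columns={"f": "f_parent"})
        fq = _region_frequencies(progeny, windows).rename(columns={"f": "f_progeny"})
        merged = fp.merge(fq, on=["kmer", "k"])
        merged.insert(0, "region", name)
        frames.append(merged)
    table = pd.concat(frames, ignore_index=True)
    table["defined"] = table["f_parent"].notna() & (table["f_parent"] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        table["ratio"] = (table["f_progeny"] / table["f_parent"]).where(
            table["defined"]
        )
    span = (layout.repeat1[0], layout.repeat2[1])
    muts = count_mutations(parent[span[0]:span[1]], progeny[span[0]:span[1]])
    return RLRResult(table=table, mutation_count=muts)


def count_mutations(parent: str, progeny: str) -> int:
    """Number of positions where two equal-length sequences differ.

    Positions where either sequence has N are excluded from the count.
    """
    if len(parent) != len(progeny):
        raise ValueError(
            f"sequences must be equal length ({len(parent)} vs {len(progeny)})"
        )
    a = np.frombuffer(parent.upper().encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(progeny.upper().encode("ascii"), dtype=np.uint8)
    n = ord("N")
    valid = (a != n) & (b != n)
    return int(((a != b) & valid).sum())
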