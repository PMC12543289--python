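"""Genome assemblies, annotation readers, and compartment construction.

The screen works on three genomic compartments per assembly:

* **coding** — the union of ``gene`` features (introns included),
* **non-coding** — the exact complement of the coding compartment on every
  retained scaffold,
* **repeats** — merged repeat annotations; repeats may overlap both of the
  other compartments, so the three are not mutually exclusive.

Scaffolds shorter than a minimum length (default 50 kb) are dropped before
any compartment is built, which suppresses artefacts from fragmented
assemblies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping

import gffutils
import numpy as np
from Bio import SeqIO

from .intervals import Interval, IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeAssembly",
    "CompartmentMap",
    "read_fasta",
    "read_gene_annotation",
    "read_repeat_annotation",
    "build_compartments",
]

_VALID = set("ACGTN")

# translate table: uppercase, then any letter outside {A,C,G,T,N} -> N
_TO_N = {ord(c): "N" for c in "BDEFHIJKLMOPQRSUVWXYZ"}


def _clean_sequence(seq: str) -> str:
    s = seq.upper().translate(_TO_N)
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


@dataclass
class GenomeAssembly:
    """An in-memory assembly: ordered scaffold id -> sequence over A/C/G/T/N."""

    scaffolds: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.scaffolds.items():
            if not seq:
                raise ValueError(f"empty scaffold {name!r}")

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.scaffolds.items()}

    @property
    def total_bp(self) -> int:
        return sum(len(s) for s in self.scaffolds.values())

    def filtered(self, min_len: int) -> "GenomeAssembly":
        kept = {n: s for n, s in self.scaffolds.items() if len(s) >= min_len}
        if not kept:
            raise ValueError(
                f"no scaffold passes the minimum length filter ({min_len} bp)"
            )
        return GenomeAssembly(kept)

    def extents(self) -> IntervalSet:
        return IntervalSet.from_pairs(
            (n, 0, len(s)) for n, s in self.scaffolds.items()
        )


@dataclass
class CompartmentMap:
    """Coding / non-coding / repeat compartments of a filtered assembly.

    ``coding`` and ``noncoding`` partition every retained scaffold exactly;
    ``repeats`` lies within scaffold extents but may intersect both.
    """

    coding: IntervalSet
    noncoding: IntervalSet
    repeats: IntervalSet
    min_scaffold_len: int

    def validate(self, assembly: GenomeAssembly) -> None:
        lengths = assembly.lengths
        for scaf, n in lengths.items():
            cod = sum(e - s for s, e in self.coding.pairs(scaf))
            non = sum(e - s for s, e in self.noncoding.pairs(scaf))
            if cod + non != n:
                raise AssertionError(
                    f"compartments do not partition {scaf}: {cod}+{non} != {n}"
                )
        if self.coding.intersect(self.noncoding).total_bp != 0:
            raise AssertionError("coding and noncoding overlap")


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a multi-record FASTA into a :class:`GenomeAssembly`.

    Sequences are upper-cased and IUPAC ambiguity codes other than N are
    mapped to N. Duplicate headers and empty records are errors.
    """
    scaffolds: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in scaffolds:
            raise ValueError(f"duplicate FASTA header {rec.id!r} in {path}")
        seq = _clean_sequence(str(rec.seq))
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        scaffolds[rec.id] = seq
    if not scaffolds:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeAssembly(scaffolds)


def read_gene_annotation(
    path: str | Path,
    feature: str = "gene",
    lengths: Mapping[str, int] | None = None,
) -> IntervalSet:
    """Read gene spans from a GFF3 file as a merged :class:`IntervalSet`.

    Only rows of the requested feature type are used; coordinates are
    converted from the file's 1-based inclusive convention to 0-based
    half-open. Rows on scaffolds absent from ``lengths`` (when given) are
    skipped with a warning.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    intervals = []
    for feat in db.features_of_type(feature):
        if feat.start > feat.end:
            raise ValueError(
                f"start > end in GFF3 row {feat.seqid}:{feat.start}-{feat.end}"
            )
        if lengths is not None and feat.seqid not in lengths:
            logger.warning(
                "skipping %s on unknown scaffold %r", feature, feat.seqid
            )
            continue
        intervals.append(Interval(feat.seqid, feat.start - 1, feat.end))
    out = IntervalSet(intervals)
    if lengths is not None:
        out = out.clip_to(lengths)
    return out


def read_repeat_annotation(
    path: str | Path,
    format: str = "gff3",
    lengths: Mapping[str, int] | None = None,
) -> IntervalSet:
    """Read repeat intervals from GFF3 or BED3 and merge overlaps.

    BED is 0-based half-open natively; GFF3 is converted. All feature types
    in a GFF3 repeat file are kept (RepeatMasker-style files use varied type
    strings). Intervals beyond scaffold ends are clipped with a warning.
    """
    intervals = []
    if format == "bed":
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{line_no}: fewer than 3 BED columns")
                scaf, start, end = parts[0], int(parts[1]), int(parts[2])
                intervals.append(Interval(scaf, start, end))
    elif format == "gff3":
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 8:
                    raise ValueError(f"{path}:{line_no}: fewer than 8 GFF3 columns")
                scaf, start, end = parts[0], int(parts[3]), int(parts[4])
                if start > end:
                    raise ValueError(f"{path}:{line_no}: start > end")
                intervals.append(Interval(scaf, start - 1, end))
    else:
        raise ValueError(f"unknown repeat annotation format {format!r}")
    out = IntervalSet(intervals)
    if lengths is not None:
        out = out.clip_to(lengths)
    return out


def build_compartments(
    assembly: GenomeAssembly,
    genes: IntervalSet,
    repeats: IntervalSet,
    min_scaffold_len: int = 50_000,
) -> CompartmentMap:
    """Construct the three compartments on scaffolds >= ``min_scaffold_len``.

    ``noncoding`` is the exact per-scaffold complement of the merged gene
    spans, so coding + noncoding partition each retained scaffold.
    """
    kept = assembly.filtered(min_scaffold_len)
    lengths = kept.lengths
    retained = set(lengths)

    coding = genes.restrict_scaffolds(retained).clip_to(lengths)
    noncoding = coding.complement(lengths)
    reps = repeats.restrict_scaffolds(retained).clip_to(lengths)

    cmap = CompartmentMap(
        coding=coding,
        noncoding=noncoding,
        repeats=reps,
        min_scaffold_len=min_scaffold_len,
    )
    cmap.validate(kept)
    return cmap
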