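"""Homology-based metrics from tabular pairwise alignments and orthogroup
tables.

All operations here consume externally produced tables: 12-column tabular
alignments (the standard ``outfmt 6`` dialect, 1-based inclusive query and
subject coordinates), orthogroup membership tables (species, orthogroup,
gene_id), and per-species gene orders (species, scaffold, rank, gene_id).
They cover:

* repeat self-alignment identity binning — cumulative alignment-length bins
  (>100, >1,000, >5,000, >10,000 bp) crossed with two identity bins
  (80-95% and >95%); the per-genome headline statistic is ``n_1kb``, the
  number of hits longer than 1 kb at >95% identity, a proxy for recent,
  unmutated repeat copies;
* protein self-alignment length bins (<=50, 50-100, 100-500, >500 aa);
* reciprocal best hits between two proteomes;
* pangenome categories from orthogroup presence across species;
* orthogroup microsynteny ratios over 10-gene windows.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ALIGNMENT_COLUMNS",
    "read_alignment_table",
    "dedupe_hits",
    "RepeatIdentityProfile",
    "bin_repeat_hits",
    "bin_protein_hits",
    "reciprocal_best_hits",
    "pangenome_categories",
    "select_focal_orthogroups",
    "synteny_scores",
]

#: the standard 12 tabular alignment columns
ALIGNMENT_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

LENGTH_BINS = (100, 1000, 5000, 10000)
IDENTITY_BINS = ("80-95", ">95")


def read_alignment_table(path) -> pd.DataFrame:
    """Read a 12-column tab-separated alignment table, preserving row order."""
    df = pd.read_csv(
        path, sep="\t", names=list(ALIGNMENT_COLUMNS), comment="#", header=None
    )
    if (df["pident"] < 0).any() or (df["pident"] > 100).any():
        raise ValueError("pident outside [0, 100]")
    if (df["length"] < 1).any():
        raise ValueError("alignment length < 1")
    return df


def dedupe_hits(records: pd.DataFrame) -> pd.DataFrame:
    """Remove self-hits and repeated identically scored hits.

    A self-hit is a query aligned to itself over its own coordinates
    (qseqid == sseqid and qstart == sstart and qend == send). Among records
    sharing (qseqid, sseqid, pident, length, mismatch, gapopen, qstart),
    only the first in input order is retained.
    """
    self_hit = (
        (records["qseqid"] == records["sseqid"])
        & (records["qstart"] == records["sstart"])
        & (records["qend"] == records["send"])
    )
    out = records[~self_hit]
    out = out.drop_duplicates(
        subset=["qseqid", "sseqid", "pident", "length", "mismatch",
                "gapopen", "qstart"],
        keep="first",
    )
    return out.reset_index(drop=True)


@dataclass
class RepeatIdentityProfile:
    """Counts of repeat self-alignment hits per length x identity bin.

    Length bins are cumulative: a hit increments every length bin whose
    threshold it (strictly) exceeds. Identity bins are exclusive:
    80 <= pident <= 95 versus pident > 95. Hits below 80% identity are
    ignored (the upstream search is expected to pre-filter at 80%).
    """

    counts: pd.DataFrame  # index: ">100" ... ">10000"; columns: "80-95", ">95"

    @property
    def n_1kb(self) -> int:
        """Hits > 1 kb at > 95% identity — the recent-duplication statistic."""
        return int(self.counts.loc[">1000", ">95"])

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="length_bin")


def bin_repeat_hits(
    records: pd.DataFrame, cumulative: bool = True
) -> RepeatIdentityProfile:
    """Bin deduped repeat self-hits by alignment length and identity.

    With ``cumulative=False`` each hit lands in only its largest exceeded
    length bin (an exclusive cross-check mode).
    """
    kept = records[records["pident"] >= 80]
    counts = pd.DataFrame(
        0, index=[f">{t}" for t in LENGTH_BINS], columns=list(IDENTITY_BINS)
    )
    ident = np.where(kept["pident"] > 95, ">95", "80-95")
    for t in LENGTH_BINS:
        exceeded = kept["length"] > t
        if not cumulative:
            larger = [u for u in LENGTH_BINS if u > t]
            if larger:
                exceeded &= ~(kept["length"] > min(larger))
        for ib in IDENTITY_BINS:
            counts.loc[f">{t}", ib] = int((exceeded & (ident == ib)).sum())
    return RepeatIdentityProfile(counts=counts)


PROTEIN_BINS = ("<=50", "50-100", "100-500", ">500")


def bin_protein_hits(records: pd.DataFrame) -> pd.DataFrame:
    """Classify protein self-alignment hits by aligned length (aa).

    Bins: <=50, 50 < l <= 100, 100 < l <= 500, > 500. Returns the records
    with a ``length_bin`` column appended; each record is in exactly one
    bin, and per-bin identity distributions can be read off directly.
    """
    out = records.copy()
    out["length_bin"] = pd.cut(
        out["length"],
        bins=[0, 50, 100, 500, np.inf],
        labels=list(PROTEIN_BINS),
        right=True,
    )
    return out


def _best_per_query(records: pd.DataFrame) -> Dict[str, str]:
    """Top subject per query by bitscore; ties by lower evalue, then input order."""
    best: Dict[str, Tuple[Tuple[float, float, int], str]] = {}
    for order, row in enumerate(records.itertuples(index=False)):
        key = (-float(row.bitscore), float(row.evalue), order)
        cur = best.get(row.qseqid)
        if cur is None or key < cur[0]:
            best[row.qseqid] = (key, row.sseqid)
        elif key[:2] == cur[0][:2] and row.sseqid != cur[1]:
            logger.warning(
                "bitscore/evalue tie for query %r: keeping first-seen "
                "subject %r over %r", row.qseqid, cur[1], row.sseqid
            )
    return {q: v[1] for q, v in best.items()}


def reciprocal_best_hits(
    records_ab: pd.DataFrame, records_ba: pd.DataFrame
) -> Set[Tuple[str, str]]:
    """Pairs (a, b) where b is a's best hit in A->B and a is b's best in B->A.

    Best hits are ranked by bitscore, with ties broken by lower evalue and
    then input order (a tie kept this way is logged).
    """
    best_ab = _best_per_query(records_ab)
    best_ba = _best_per_query(records_ba)
    return {
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    }


PANGENOME_CATEGORIES = ("core", "softcore", "shell", "variable", "singleton")


def pangenome_categories(presence: pd.DataFrame) -> pd.Series:
    """Assign each orthogroup a pangenome category from species presence.

    ``presence`` is a species x orthogroup count (or boolean) matrix. With
    f the fraction of species carrying the orthogroup: core f > 0.9;
    softcore 0.8 < f <= 0.9; shell 0.5 < f <= 0.8; variable f <= 0.5;
    singleton when exactly one species carries it. Categories are
    exhaustive and mutually exclusive.
    """
    if presence.size == 0:
        raise ValueError("empty presence matrix")
    carried = presence > 0
    n_species = carried.shape[0]
    n_present = carried.sum(axis=0)
    freq = n_present / n_species

    cats = pd.Series("variable", index=presence.columns, name="category")
    cats[freq > 0.5] = "shell"
    cats[freq > 0.8] = "softcore"
    cats[freq > 0.9] = "core"
    cats[n_present == 1] = "singleton"
    cats[n_present == 0] = "absent"
    if (cats == "absent").any():
        raise ValueError("orthogroup present in zero species")
    return cats


def select_focal_orthogroups(
    membership: pd.DataFrame,
    class_labels: Mapping[str, str],
    n_species: int | None = None,
    min_presence: float = 0.05,
    min_single_copy: float = 0.8,
    min_classes: int = 10,
) -> Set[str]:
    """Focal orthogroups for the synteny analysis.

    ``membership`` has columns species, orthogroup, gene_id. Kept are
    orthogroups present in more than ``min_presence`` of the dataset,
    single-copy in more than ``min_single_copy`` of their carrier genomes,
    and represented in at least ``min_classes`` taxonomic classes.
    """
    if n_species is None:
        n_species = membership["species"].nunique()
    copies = (
        membership.groupby(["orthogroup", "species"])["gene_id"]
        .size()
        .rename("n_copies")
        .reset_index()
    )
    g = copies.groupby("orthogroup")
    carriers = g["species"].nunique()
    single_frac = g["n_copies"].agg(lambda x: (x == 1).mean())
    classes = copies.assign(
        cls=copies["species"].map(class_labels)
    ).groupby("orthogroup")["cls"].nunique()

    keep = (
        (carriers / n_species > min_presence)
        & (single_frac > min_single_copy)
        & (classes >= min_classes)
    )
    return set(keep[keep].index)


def synteny_scores(
    orders: pd.DataFrame,
    focal: Iterable[str],
    window: int = 10,
) -> pd.DataFrame:
    """Mean microsynteny per focal orthogroup over 10+10-gene windows.

    ``orders`` has columns species, scaffold, rank, orthogroup, giving the
    gene order per scaffold (windows never cross scaffolds). For each
    species carrying a focal orthogroup, the window is the union over its
    copies of the <= ``window`` genes on each side. For each neighbor
    orthogroup, ratio = (number of species whose window contains it) /
    (number of species carrying the focal orthogroup); ``mean_synteny`` is
    the mean over all neighbor orthogroups observed in any species' window.
    """
    focal = set(focal)
    # per (species, scaffold): orthogroup sequence sorted by rank
    grouped: Dict[str, List[List[str]]] = {}
    for (species, _scaffold), block in orders.sort_values("rank").groupby(
        ["species", "scaffold"], sort=False
    ):
        grouped.setdefault(species, []).append(block["orthogroup"].tolist())

    rows = []
    for og in sorted(focal):
        windows: Dict[str, Set[str]] = {}
        for species, scaffolds in grouped.items():
            neigh: Set[str] = set()
            present = False
            for seq in scaffolds:
                for i, g in enumerate(seq):
                    if g != og:
                        continue
                    present = True
                    lo = max(0, i - window)
                    neigh.update(seq[lo:i])
                    neigh.update(seq[i + 1 : i + 1 + window])
            if present:
                windows[species] = neigh
        if not windows:
            raise ValueError(f"focal orthogroup {og!r} absent from all species")
        n_carriers = len(windows)
        neighbor_counts: Dict[str, int] = {}
        for neigh in windows.values():
            for g in neigh:
                neighbor_counts[g] = neighbor_counts.get(g, 0) + 1
        if neighbor_counts:
            ratios = np.array(list(neighbor_counts.values())) / n_carriers
            mean_synteny = float(ratios.mean())
            n_neighbors = len(neighbor_counts)
        else:
            mean_synteny = float("nan")
            n_neighbors = 0
        rows.append((og, mean_synteny, n_carriers, n_neighbors))
    return pd.DataFrame(
        rows, columns=["orthogroup", "mean_synteny", "n_species", "n_neighbors"]
    )
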