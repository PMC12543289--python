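"""Synthetic genomes, RIP mutagenesis, RLR crosses, and Brownian traits.

The generator emulates the inputs of the screen without any downloads:

* assemblies with gene-dense and gene-sparse regions,
* coding sequence with elevated GC so coding and non-coding composition
  differ (as codon bias does in real genomes),
* multi-copy repeat families with controlled neutral divergence,
* RIP-style C->T mutations restricted to CpA (and, on the shown strand,
  TpG for the reverse-complement context) within annotated repeats,
* parent/progeny repeat-linker-repeat (RLR) constructs (802 bp repeats,
  729 bp linker),
* correlated Brownian traits on a tree, as an oracle for the contrast
  machinery.

RIP chemistry has a useful closure property: converting C->T at CpA or
G->A at TpG can never create a *new* CpA or TpG context (the created base
contradicts the context requirement), so repeated rounds of RIP commute
into a single pass with a cumulative per-context probability. The genome
simulator exploits this: repeats are treated as relics of
``rip_generations`` sexual cycles, each mutating available contexts with
probability ``rip_rate``, applied as one pass at
``1 - (1 - rip_rate) ** rip_generations``. A single experimental cross
(:func:`simulate_rlr_cross`) applies ``rip_rate`` directly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

from .genome import GenomeAssembly
from .intervals import Interval, IntervalSet
from .rip import RLRLayout

__all__ = [
    "SimConfig",
    "SimulatedGenome",
    "rip_mutator",
    "simulate_genome",
    "simulate_rlr_cross",
    "simulate_brownian_traits",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (int(b) for b in _BASES)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _to_str(codes: np.ndarray) -> str:
    return codes.tobytes().decode("ascii")


def _rip_positions(
    codes: np.ndarray,
    intervals: Sequence[Tuple[int, int]],
    p: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Positions to mutate: C of CpA and G of TpG, inside intervals, w.p. p."""
    n = codes.size
    in_iv = np.zeros(n, dtype=bool)
    for s, e in intervals:
        in_iv[max(0, s) : min(n, e)] = True
    ca = np.zeros(n, dtype=bool)
    ca[:-1] = (codes[:-1] == _C) & (codes[1:] == _A)
    tg = np.zeros(n, dtype=bool)
    tg[1:] = (codes[1:] == _G) & (codes[:-1] == _T)
    ctx = (ca | tg) & in_iv
    pos = np.flatnonzero(ctx)
    if p >= 1.0:
        return pos
    if p <= 0.0 or pos.size == 0:
        return pos[:0]
    return pos[rng.random(pos.size) < p]


def rip_mutator(
    sequence: str,
    intervals: Sequence[Tuple[int, int]],
    p: float,
    rng: np.random.Generator,
) -> Tuple[str, int]:
    """Apply RIP-style mutations within intervals of one sequence.

    Each C immediately followed by A mutates to T with probability ``p``;
    each G immediately preceded by T mutates to A with the same
    probability (the reverse-strand CpA). Contexts are evaluated against
    the pre-mutation sequence in a single pass; only positions inside the
    given half-open intervals change. Returns the mutated sequence and the
    realized mutation count.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"mutation probability must be in [0, 1], got {p}")
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    pos = _rip_positions(codes, intervals, p, rng)
    codes[pos] = np.where(codes[pos] == _C, _T, _A)
    return _to_str(codes), int(pos.size)


@dataclass
class SimConfig:
    """Study conditions for one simulated genome.

    Defaults describe a moderately repetitive, compartmentalized fungal
    genome: 2 Mb over five 400 kb scaffolds, 500 genes (~1.5 kb each,
    coding GC 0.60 against a 0.50 background), five repeat families of
    forty 600 bp copies (~6% repeat content) with 2% neutral per-copy
    divergence, and a fifth of each scaffold kept gene-sparse with ~2% of
    genes placed there in isolation.
    """

    seed: int = 0
    n_scaffolds: int = 5
    scaffold_len: int = 400_000
    gc_content: float = 0.5
    n_genes: int = 500
    gene_len_mean: float = 1500.0
    gene_len_sd: float = 300.0
    coding_gc: float = 0.6
    n_repeat_families: int = 5
    copies_per_family: int = 40
    repeat_len: int = 600
    repeat_divergence: float = 0.02
    rip_rate: float = 0.0
    rip_generations: int = 7
    sparse_region_fraction: float = 0.2
    sparse_gene_fraction: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.rip_rate <= 1.0:
            raise ValueError("rip_rate must be in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")

    @property
    def effective_rip_probability(self) -> float:
        """Cumulative per-context mutation probability over all generations."""
        return 1.0 - (1.0 - self.rip_rate) ** self.rip_generations


@dataclass
class SimulatedGenome:
    """A simulated assembly, its annotations, and the mutation truth."""

    assembly: GenomeAssembly
    genes: IntervalSet
    repeats: IntervalSet
    truth: pd.DataFrame  # scaffold, start, end, family, mutations
    rip_applied: bool
    config: SimConfig

    def write(self, outdir: str | Path) -> None:
        """Emit genome.fa, genes.gff3, repeats.bed and truth.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seed = self.config.seed
        with open(outdir / "genome.fa", "w") as fh:
            for name, seq in self.assembly.scaffolds.items():
                fh.write(f">{name} seed={seed}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(outdir / "genes.gff3", "w") as fh:
            fh.write(f"##gff-version 3\n#seed={seed}\n")
            for i, iv in enumerate(self.genes):
                fh.write(
                    f"{iv.scaffold}\tripscan-sim\tgene\t{iv.start + 1}\t"
                    f"{iv.end}\t.\t+\t.\tID=gene{i:05d}\n"
                )
        with open(outdir / "repeats.bed", "w") as fh:
            for iv in self.repeats:
                fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\n")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _place_genes(
    rng: np.random.Generator, cfg: SimConfig, scaf_genes: int
) -> List[Tuple[int, int]]:
    """Gene spans for one scaffold: packed dense region + isolated sparse genes."""
    L = cfg.scaffold_len
    sparse_len = int(L * cfg.sparse_region_fraction)
    dense_len = L - sparse_len
    n_sparse = int(round(cfg.sparse_gene_fraction * scaf_genes))
    n_dense = scaf_genes - n_sparse

    lengths = rng.normal(cfg.gene_len_mean, cfg.gene_len_sd, size=scaf_genes)
    lengths = np.clip(lengths, 300, None).astype(int)
    dense_lens, sparse_lens = lengths[:n_dense], lengths[n_dense:]

    leftover = dense_len - int(dense_lens.sum())
    if leftover < n_dense + 1:
        raise ValueError(
            "infeasible gene packing: reduce n_genes or gene_len_mean"
        )
    gaps = rng.multinomial(leftover, np.full(n_dense + 1, 1.0 / (n_dense + 1)))
    spans = []
    pos = 0
    for gap, glen in zip(gaps[:-1], dense_lens):
        pos += int(gap)
        spans.append((pos, pos + int(glen)))
        pos += int(glen)

    # sparse genes: evenly spaced through the gene-sparse tail so both
    # flanks exceed the 5 kb sparseness threshold
    if n_sparse:
        step = sparse_len // (n_sparse + 1)
        for i, glen in enumerate(sparse_lens):
            start = dense_len + (i + 1) * step
            spans.append((start, min(start + int(glen), L)))
    return spans


def _place_repeats(
    rng: np.random.Generator,
    cfg: SimConfig,
    gene_spans: Dict[str, List[Tuple[int, int]]],
) -> List[Tuple[str, int, int, int]]:
    """(scaffold, start, end, family) for every repeat copy, outside genes."""
    free: List[Tuple[str, int, int]] = []
    for scaf, spans in gene_spans.items():
        pos = 0
        for s, e in sorted(spans):
            if s - pos >= cfg.repeat_len:
                free.append((scaf, pos, s))
            pos = e
        if cfg.scaffold_len - pos >= cfg.repeat_len:
            free.append((scaf, pos, cfg.scaffold_len))

    placements = []
    n_copies = cfg.n_repeat_families * cfg.copies_per_family
    for copy_idx in range(n_copies):
        family = copy_idx // cfg.copies_per_family
        weights = np.array(
            [e - s - cfg.repeat_len + 1 for _, s, e in free], dtype=float
        )
        if len(free) == 0 or weights.sum() <= 0:
            raise ValueError(
                "infeasible repeat packing: reduce copies or repeat_len"
            )
        seg = int(rng.choice(len(free), p=weights / weights.sum()))
        scaf, s, e = free.pop(seg)
        off = s + int(rng.integers(0, e - s - cfg.repeat_len + 1))
        placements.append((scaf, off, off + cfg.repeat_len, family))
        if off - s >= cfg.repeat_len:
            free.append((scaf, s, off))
        if e - (off + cfg.repeat_len) >= cfg.repeat_len:
            free.append((scaf, off + cfg.repeat_len, e))
    return placements


def simulate_genome(config: SimConfig) -> SimulatedGenome:
    """Simulate an annotated genome under the configured study conditions.

    Background sequence is i.i.d. at ``gc_content``; gene spans are
    rewritten at ``coding_gc``; each repeat copy derives from its family
    consensus by uniform substitution at ``repeat_divergence`` and is then
    RIP-mutated at the cumulative per-context probability. Deterministic
    under a fixed seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # scaffold backgrounds
    names = [f"scaffold_{i + 1}" for i in range(cfg.n_scaffolds)]
    seqs = {
        name: _random_bases(rng, cfg.scaffold_len, cfg.gc_content)
        for name in names
    }

    # genes: split evenly across scaffolds, remainder to the first ones
    base, extra = divmod(cfg.n_genes, cfg.n_scaffolds)
    gene_spans: Dict[str, List[Tuple[int, int]]] = {}
    for i, name in enumerate(names):
        gene_spans[name] = _place_genes(rng, cfg, base + (1 if i < extra else 0))
        for s, e in gene_spans[name]:
            seqs[name][s:e] = _random_bases(rng, e - s, cfg.coding_gc)

    # repeat families
    consensi = [
        _random_bases(rng, cfg.repeat_len, cfg.gc_content)
        for _ in range(cfg.n_repeat_families)
    ]
    placements = _place_repeats(rng, cfg, gene_spans)
    for scaf, s, e, fam in placements:
        copy = consensi[fam].copy()
        div = np.flatnonzero(rng.random(cfg.repeat_len) < cfg.repeat_divergence)
        if div.size:
            # substitute with a uniformly chosen *different* base
            shift = rng.integers(1, 4, size=div.size)
            idx = np.searchsorted(_BASES, copy[div])
            copy[div] = _BASES[(idx + shift) % 4]
        seqs[scaf][s:e] = copy

    # RIP over repeat intervals, per scaffold, truth per copy
    p_eff = cfg.effective_rip_probability
    truth_rows = []
    by_scaf: Dict[str, List[Tuple[int, int, int]]] = {}
    for scaf, s, e, fam in placements:
        by_scaf.setdefault(scaf, []).append((s, e, fam))
    for scaf in names:
        reps = sorted(by_scaf.get(scaf, []))
        if reps and p_eff > 0:
            pos = _rip_positions(
                seqs[scaf], [(s, e) for s, e, _ in reps], p_eff, rng
            )
            seqs[scaf][pos] = np.where(seqs[scaf][pos] == _C, _T, _A)
        else:
            pos = np.empty(0, dtype=int)
        for s, e, fam in reps:
            n_mut = int(((pos >= s) & (pos < e)).sum())
            truth_rows.append((scaf, s, e, fam, n_mut))

    assembly = GenomeAssembly({n: _to_str(seqs[n]) for n in names})
    genes = IntervalSet.from_pairs(
        (scaf, s, e) for scaf, spans in gene_spans.items() for s, e in spans
    )
    repeats = IntervalSet.from_pairs(
        (scaf, s, e) for scaf, s, e, _ in placements
    )
    truth = pd.DataFrame(
        truth_rows, columns=["scaffold", "start", "end", "family", "mutations"]
    ).sort_values(["scaffold", "start"], ignore_index=True)
    return SimulatedGenome(
        assembly=assembly,
        genes=genes,
        repeats=repeats,
        truth=truth,
        rip_applied=p_eff > 0,
        config=cfg,
    )


def simulate_rlr_cross(
    parent_seed: int,
    p: float,
    n_progeny: int,
    repeat_len: int = 802,
    linker_len: int = 729,
    gc_content: float = 0.5,
) -> Tuple[str, List[str], RLRLayout, List[int]]:
    """Simulate an RLR cross: one parent construct and RIP'd progeny.

    The parent carries two identical ``repeat_len`` bp copies flanking a
    ``linker_len`` bp linker. Each progeny is independently RIP-mutated at
    per-context probability ``p`` within the repeat copies only. Returns
    (parent, progeny list, layout, per-progeny mutation counts).
    """
    if n_progeny < 1:
        raise ValueError("need at least one progeny")
    rng = np.random.default_rng(parent_seed)
    repeat = _random_bases(rng, repeat_len, gc_content)
    linker = _random_bases(rng, linker_len, gc_content)
    parent = _to_str(np.concatenate([repeat, linker, repeat]))
    layout = RLRLayout.standard(repeat_len, linker_len)
    progeny, counts = [], []
    for _ in range(n_progeny):
        child, n_mut = rip_mutator(
            parent, [layout.repeat1, layout.repeat2], p, rng
        )
        progeny.append(child)
        counts.append(n_mut)
    return parent, progeny, layout, counts


def simulate_brownian_traits(
    tree: dendropy.Tree | str,
    sigma2: float = 1.0,
    rho: float = 0.0,
    seed: int = 0,
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Two correlated Brownian traits evolved along a tree.

    Increments on a branch of length t are bivariate normal with
    covariance ``sigma2 * t * [[1, rho], [rho, 1]]``. Returns two maps
    tip label -> trait value.
    """
    from .phylo import load_tree

    if isinstance(tree, str):
        tree = load_tree(tree)
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    corr = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.sqrt(sigma2) * np.linalg.cholesky(corr + 1e-15 * np.eye(2))

    values: Dict[int, np.ndarray] = {id(tree.seed_node): np.zeros(2)}
    x: Dict[str, float] = {}
    y: Dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            val = values[id(node)]
        else:
            t = node.edge.length or 0.0
            step = chol @ rng.standard_normal(2) * np.sqrt(t)
            val = values[id(node.parent_node)] + step
            values[id(node)] = val
        if node.is_leaf() and node.taxon is not None:
            x[node.taxon.label] = float(val[0])
            y[node.taxon.label] = float(val[1])
    return x, y
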