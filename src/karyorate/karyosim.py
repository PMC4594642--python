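"""Synthetic karyotype-evolution histories along dated trees.

Real painting datasets of the kind this package analyses live in
supplementary tables that are rarely machine-readable, so testing the
reconstruction/counting pipeline needs a generator with ground truth: this
module evolves a root karyotype down a dated tree under independent Poisson
processes of fusions and fissions and returns, per branch, the ordered event
log alongside every node's karyotype.  Replaying the log from the root
reproduces each leaf exactly, which is the invariant the tests lean on.

Model
-----
* The root karyotype has ``root_chromosomes`` chromosomes, each a single
  outgroup "paint colour" (chromosome label ``"1"``, ``"2"``, ...) divided
  into 1-4 uniquely tagged blocks (segment tags ``a, b, x, y``).  One colour
  per root chromosome is what makes downstream paint emulation meaningful.
* On a branch of length ``t`` myr, fusion and fission counts are drawn as
  Poisson(rate x t) and applied sequentially in shuffled order.
* A fusion joins two uniformly chosen chromosomes at uniformly chosen ends;
  a fission splits a uniformly chosen chromosome at a uniform internal
  junction, falling back to splitting an untagged block into ``a``/``b``
  segments when no junction is available.  An event that cannot be applied
  (e.g. a fission on a genome of single-block chromosomes whose blocks are
  all tagged) is skipped and logged, never an error.
* With ``allow_breakpoint_reuse=False`` the generator refuses fissions at
  fusion-created junctions and fusions that (re)create an ancestral
  adjacency, so every event leaves a permanent, countable trace: the event
  counts recovered by :mod:`karyorate.counting` then equal the simulated
  truth exactly.  With reuse allowed, counted events are a lower bound.

``emulate_painting`` censors a karyotype the way limited paint resolution
does: maximal same-colour runs shorter than a detection threshold are
absorbed into their larger neighbour (their blocks disappear from the map).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import DomainError, InputError
from .homology import (
    ChromosomeModel,
    DatedTree,
    Karyotype,
    SyntenicBlock,
    parse_newick_dated,
)

_SEGMENT_SETS = {1: ("",), 2: ("a", "b"), 3: ("a", "b", "x"), 4: ("a", "b", "x", "y")}

_Genome = list[list[SyntenicBlock]]


@dataclass(frozen=True)
class SimConfig:
    tree: DatedTree
    root_chromosomes: int
    blocks_per_chromosome: int = 1
    fusion_rate: float = 0.0
    fission_rate: float = 0.0
    allow_breakpoint_reuse: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_chromosomes < 2:
            raise DomainError("root karyotype needs at least 2 chromosomes")
        if self.blocks_per_chromosome not in _SEGMENT_SETS:
            raise DomainError(
                f"blocks_per_chromosome must be 1-4 (got {self.blocks_per_chromosome}); "
                "segment tags a/b/x/y bound the per-chromosome block resolution"
            )
        if self.fusion_rate < 0 or self.fission_rate < 0:
            raise DomainError("event rates must be non-negative")


@dataclass(frozen=True)
class KaryoEvent:
    """One replayable rearrangement event.

    ``kind`` is ``fusion``, ``fission`` or ``fission_within``.  Payload block
    tuples are the *pre-event* chromosomes, so a log can be replayed on any
    genome in which they occur (chromosome block tuples are unique because
    block triples are)."""

    kind: str
    chrom_a: tuple[str, ...]
    chrom_b: tuple[str, ...] = ()
    reverse_a: bool = False
    reverse_b: bool = False
    index: int = 0  # fission junction index, or block index for within-block splits
    junction: tuple[str, str] = ("", "")  # block labels meeting at a fusion junction


@dataclass
class SimTruth:
    """Ground truth of one simulated history."""

    config: SimConfig
    root_karyotype: Karyotype
    node_karyotypes: dict[str, Karyotype]
    branch_logs: dict[str, list[KaryoEvent]]  # keyed by child node label
    branch_counts: dict[str, tuple[int, int]]  # (fusions, fissions) applied
    branch_skipped: dict[str, int]


def root_karyotype(n_chromosomes: int, blocks_per_chromosome: int = 1) -> Karyotype:
    """Outgroup-style root: chromosome *i* = colour ``str(i)``, tagged blocks."""
    if blocks_per_chromosome not in _SEGMENT_SETS:
        raise DomainError("blocks_per_chromosome must be 1-4")
    segs = _SEGMENT_SETS[blocks_per_chromosome]
    autosomes = tuple(
        ChromosomeModel(
            chrom_id=str(i),
            blocks=tuple(SyntenicBlock(chrom=str(i), segment=seg) for seg in segs),
            centromere_index=0,
            morphology="A",
        )
        for i in range(1, n_chromosomes + 1)
    )
    return Karyotype(species="root", autosomes=autosomes)


def _genome_of(k: Karyotype) -> _Genome:
    return [list(c.blocks) for c in k.autosomes]


def _karyotype_of(genome: _Genome, species: str) -> Karyotype:
    autosomes = tuple(
        ChromosomeModel(chrom_id=str(i + 1), blocks=tuple(blocks))
        for i, blocks in enumerate(genome)
    )
    return Karyotype(
        species=species, autosomes=autosomes, diploid_number=2 * len(autosomes) + 2
    )


def _base_pair(a: SyntenicBlock, b: SyntenicBlock) -> frozenset[str]:
    return frozenset({a.base, b.base})


def _root_adjacencies(k: Karyotype) -> set[frozenset[str]]:
    out: set[frozenset[str]] = set()
    for chrom in k.autosomes:
        for a, b in zip(chrom.blocks, chrom.blocks[1:]):
            out.add(_base_pair(a, b))
    return out


def apply_event(genome: _Genome, event: KaryoEvent) -> None:
    """Apply one logged event in place (used by the simulator and by replay)."""

    def find(blocks: tuple[str, ...]) -> int:
        for i, chrom in enumerate(genome):
            if tuple(b.label for b in chrom) == blocks:
                return i
        raise InputError(f"replay: no chromosome with blocks {blocks}")

    if event.kind == "fusion":
        ia = find(event.chrom_a)
        ib = find(event.chrom_b)
        left = list(reversed(genome[ia])) if event.reverse_a else list(genome[ia])
        right = list(reversed(genome[ib])) if event.reverse_b else list(genome[ib])
        for i in sorted((ia, ib), reverse=True):
            del genome[i]
        genome.append(left + right)
    elif event.kind == "fission":
        i = find(event.chrom_a)
        chrom = genome.pop(i)
        genome.append(chrom[: event.index])
        genome.append(chrom[event.index :])
    elif event.kind == "fission_within":
        i = find(event.chrom_a)
        chrom = genome.pop(i)
        block = chrom[event.index]
        if block.segment != "":
            raise InputError(f"replay: block {block.label} is already a sub-segment")
        left = SyntenicBlock(block.chrom, block.arm, "a")
        right = SyntenicBlock(block.chrom, block.arm, "b")
        genome.append(chrom[: event.index] + [left])
        genome.append([right] + chrom[event.index + 1 :])
    else:
        raise InputError(f"unknown event kind {event.kind!r}")


def replay_events(karyotype: Karyotype, events: Sequence[KaryoEvent]) -> Karyotype:
    """Replay an event log from a starting karyotype (the replay invariant)."""
    genome = _genome_of(karyotype)
    for ev in events:
        apply_event(genome, ev)
    return _karyotype_of(genome, karyotype.species)


def _attempt_fusion(
    genome: _Genome,
    rng: np.random.Generator,
    root_adj: set[frozenset[str]],
    allow_reuse: bool,
    attempts: int = 100,
) -> Optional[KaryoEvent]:
    if len(genome) < 2:
        return None
    for _ in range(attempts):
        ia, ib = rng.choice(len(genome), size=2, replace=False)
        rev_a = bool(rng.integers(2))  # True: chromosome A contributes its head
        rev_b = bool(rng.integers(2))  # True: chromosome B contributes its tail
        left_end = genome[ia][0] if rev_a else genome[ia][-1]
        right_end = genome[ib][-1] if rev_b else genome[ib][0]
        pair = _base_pair(left_end, right_end)
        if not allow_reuse:
            if pair in root_adj or left_end.base == right_end.base:
                continue  # would recreate an ancestral adjacency or rejoin a split block
        return KaryoEvent(
            kind="fusion",
            chrom_a=tuple(b.label for b in genome[ia]),
            chrom_b=tuple(b.label for b in genome[ib]),
            reverse_a=rev_a,
            reverse_b=rev_b,
            junction=(left_end.label, right_end.label),
        )
    return None


def _attempt_fission(
    genome: _Genome,
    rng: np.random.Generator,
    root_adj: set[frozenset[str]],
    allow_reuse: bool,
) -> Optional[KaryoEvent]:
    eligible: list[tuple[int, int]] = []
    for i, chrom in enumerate(genome):
        for j in range(1, len(chrom)):
            if allow_reuse or _base_pair(chrom[j - 1], chrom[j]) in root_adj:
                eligible.append((i, j))
    if eligible:
        i, j = eligible[rng.integers(len(eligible))]
        return KaryoEvent(
            kind="fission", chrom_a=tuple(b.label for b in genome[i]), index=j
        )
    splittable = [
        (i, j)
        for i, chrom in enumerate(genome)
        for j, b in enumerate(chrom)
        if b.segment == ""
    ]
    if not splittable:
        return None
    i, j = splittable[rng.integers(len(splittable))]
    return KaryoEvent(
        kind="fission_within", chrom_a=tuple(b.label for b in genome[i]), index=j
    )


def evolve_karyotypes(cfg: SimConfig) -> SimTruth:
    """Evolve the root karyotype over the dated tree; reproducible by seed."""
    rng = np.random.default_rng(cfg.seed)
    root = root_karyotype(cfg.root_chromosomes, cfg.blocks_per_chromosome)
    root_adj = _root_adjacencies(root)
    tree = cfg.tree

    node_genomes: dict[str, _Genome] = {tree.root: _genome_of(root)}
    node_karyotypes: dict[str, Karyotype] = {
        tree.root: _karyotype_of(node_genomes[tree.root], tree.root)
    }
    branch_logs: dict[str, list[KaryoEvent]] = {}
    branch_counts: dict[str, tuple[int, int]] = {}
    branch_skipped: dict[str, int] = {}

    for parent, child in tree.preorder_branches():
        genome = [list(chrom) for chrom in node_genomes[parent]]
        t = tree.branch_time(child)
        n_fus = int(rng.poisson(cfg.fusion_rate * t))
        n_fis = int(rng.poisson(cfg.fission_rate * t))
        ops = ["fusion"] * n_fus + ["fission"] * n_fis
        rng.shuffle(ops)
        log: list[KaryoEvent] = []
        applied = {"fusion": 0, "fission": 0}
        skipped = 0
        for op in ops:
            if op == "fusion":
                event = _attempt_fusion(genome, rng, root_adj, cfg.allow_breakpoint_reuse)
            else:
                event = _attempt_fission(genome, rng, root_adj, cfg.allow_breakpoint_reuse)
            if event is None:
                skipped += 1
                continue
            apply_event(genome, event)
            applied[op] += 1
            log.append(event)
        node_genomes[child] = genome
        node_karyotypes[child] = _karyotype_of(genome, child)
        branch_logs[child] = log
        branch_counts[child] = (applied["fusion"], applied["fission"])
        branch_skipped[child] = skipped

    return SimTruth(
        config=cfg,
        root_karyotype=root,
        node_karyotypes=node_karyotypes,
        branch_logs=branch_logs,
        branch_counts=branch_counts,
        branch_skipped=branch_skipped,
    )


def emulate_painting(k: Karyotype, min_detectable_blocks: int) -> Karyotype:
    """Censor a karyotype to mimic paint resolution limits.

    Maximal runs of blocks sharing an outgroup colour are the segments a
    paint experiment can see; any run shorter than ``min_detectable_blocks``
    is absorbed into its larger neighbouring run (its blocks vanish from the
    map).  A chromosome consisting of a single run is returned unchanged --
    there is no neighbour to absorb it.  Painting-derived maps therefore
    under-report rearrangements, never over-report them.
    """
    if min_detectable_blocks < 1:
        raise DomainError("min_detectable_blocks must be >= 1")
    new_autosomes = []
    for chrom in k.autosomes:
        runs: list[list[SyntenicBlock]] = []
        for block in chrom.blocks:
            if runs and runs[-1][0].chrom == block.chrom:
                runs[-1].append(block)
            else:
                runs.append([block])
        while len(runs) > 1 and min(len(r) for r in runs) < min_detectable_blocks:
            sizes = [len(r) for r in runs]
            i = sizes.index(min(sizes))
            del runs[i]
            # coalesce neighbours that now touch with the same colour
            if 0 < i < len(runs) and runs[i - 1][0].chrom == runs[i][0].chrom:
                runs[i - 1].extend(runs.pop(i))
        new_autosomes.append(
            ChromosomeModel(
                chrom_id=chrom.chrom_id,
                blocks=tuple(b for run in runs for b in run),
                morphology=chrom.morphology,
            )
        )
    return Karyotype(
        species=k.species,
        autosomes=tuple(new_autosomes),
        sex_chromosomes=k.sex_chromosomes,
    )


def random_dated_tree(
    n_leaves: int,
    seed_or_rng: Union[int, np.random.Generator],
    *,
    scale: float = 2.0,
    age_se: float = 0.0,
) -> DatedTree:
    """Random rooted binary dated tree (leaves ``L1..Ln``, internals ``N*``).

    Topology by random sequential coalescence; each internal node is older
    than both children by an Exp(1) x ``scale`` increment, so branch times
    are strictly positive.
    """
    if n_leaves < 2:
        raise DomainError("need at least 2 leaves")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    lineages = [(f"L{i + 1}", 0.0) for i in range(n_leaves)]
    newick = {name: name for name, _ in lineages}
    ages: dict[str, tuple[float, float]] = {}
    counter = 0
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (na, aa), (nb, ab) = lineages[i], lineages[j]
        counter += 1
        name = f"N{counter}"
        age = max(aa, ab) + scale * float(rng.exponential())
        ages[name] = (age, age_se)
        newick[name] = f"({newick[na]},{newick[nb]}){name}"
        del lineages[j], lineages[i]
        lineages.append((name, age))
    return parse_newick_dated(newick[lineages[0][0]] + ";", ages)
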