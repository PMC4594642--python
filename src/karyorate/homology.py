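"""Data model and I/O for chromosome-painting homology maps and dated trees.

Cross-species chromosome painting (zoo-FISH) resolves each chromosome of a
studied species into an ordered series of *syntenic blocks*, each named after
the outgroup chromosome whose paint probe hybridises to it.  A karyotype is
therefore an ordered block composition per chromosome; the adjacency of two
blocks on the same chromosome is a *syntenic association*, the binary
character used downstream for ancestral reconstruction.

Conventions
-----------
* Block labels concatenate outgroup chromosome, arm and segment tag, e.g.
  ``"2q"`` (long arm of outgroup chromosome 2) or ``"16a"`` (a fission
  segment of chromosome 16 with uncertain arm origin).
* Positions and indices are 0-based.  A centromere position is a *junction*
  index between blocks (``0`` = before the first block, ``n`` = after the
  last); paint resolution rarely localises a centromere more finely, so a
  centromere inside a block is recorded with a within-block flag instead.
* Sex chromosomes are parsed and carried along but excluded from association
  characters and event counts (no Y paint is available in this kind of data,
  and the X is conserved).
* Associations are unordered, orientation-blind pairs: painting carries no
  reliable orientation information.  Inversion annotations are chromosome
  level notes, not characters.

Homology tables are plain TSV with header columns
``species  chrom_id  position  block  arm  segment  centromere_flag  morphology``;
``#`` lines are comments.  ``centromere_flag`` is ``0`` (none), ``1``
(within this block), ``L`` (junction left of this block) or ``R`` (junction
right of this block).
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

from .errors import (
    ChronologyError,
    FormatError,
    InputError,
    UniquenessError,
)

ARMS = ("", "p", "q")
SEGMENTS = ("", "a", "b", "x", "y")
BIARMED_MORPHOLOGIES = frozenset({"M", "SM", "ST", "B"})
MORPHOLOGIES = frozenset({"A"}) | BIARMED_MORPHOLOGIES

TABLE_COLUMNS = (
    "species",
    "chrom_id",
    "position",
    "block",
    "arm",
    "segment",
    "centromere_flag",
    "morphology",
)

_EMPTY_TOKENS = {"", ".", "-", "none", "None", "NA"}


@dataclass(frozen=True, order=True)
class SyntenicBlock:
    """One painting-detected homologous segment.

    ``chrom`` is the outgroup chromosome label, ``arm`` one of ``p``/``q``/``""``
    and ``segment`` a fission-segment tag (``a``/``b``/``x``/``y``/``""``).
    """

    chrom: str
    arm: str = ""
    segment: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise InputError("syntenic block needs a non-empty outgroup chromosome label")
        if self.arm not in ARMS:
            raise InputError(f"invalid arm {self.arm!r} (expected one of {ARMS})")
        if self.segment not in SEGMENTS:
            raise InputError(f"invalid segment {self.segment!r} (expected one of {SEGMENTS})")

    @property
    def label(self) -> str:
        """Full display label, e.g. ``16a`` or ``2q``."""
        return f"{self.chrom}{self.arm}{self.segment}"

    @property
    def base(self) -> str:
        """Label with the fission-segment tag stripped (``16a`` -> ``16``)."""
        return f"{self.chrom}{self.arm}"

    @classmethod
    def from_label(cls, label: str) -> "SyntenicBlock":
        """Parse a concatenated label (trailing segment tag, then arm)."""
        chrom, arm, segment = label, "", ""
        if chrom and chrom[-1] in ("a", "b", "x", "y"):
            segment, chrom = chrom[-1], chrom[:-1]
        if chrom and chrom[-1] in ("p", "q"):
            arm, chrom = chrom[-1], chrom[:-1]
        return cls(chrom, arm, segment)


@dataclass(frozen=True)
class ChromosomeModel:
    """One chromosome (one representative of the homologous pair)."""

    chrom_id: str
    blocks: tuple[SyntenicBlock, ...]
    centromere_index: Optional[int] = None
    centromere_within_block: bool = False
    morphology: Optional[str] = None
    note: str = ""

    def __post_init__(self) -> None:
        if not self.blocks:
            raise InputError(f"chromosome {self.chrom_id}: empty block list")
        n = len(self.blocks)
        if self.centromere_index is not None:
            hi = n - 1 if self.centromere_within_block else n
            if not 0 <= self.centromere_index <= hi:
                raise InputError(
                    f"chromosome {self.chrom_id}: centromere index "
                    f"{self.centromere_index} outside [0, {hi}]"
                )
        if self.morphology is not None and self.morphology not in MORPHOLOGIES:
            raise InputError(
                f"chromosome {self.chrom_id}: unknown morphology {self.morphology!r}"
            )

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def is_biarmed(self) -> bool:
        return self.morphology in BIARMED_MORPHOLOGIES

    def block_labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.blocks)


@dataclass(frozen=True)
class Karyotype:
    """A species karyotype as painted-block composition.

    ``autosomes`` lists one representative chromosome per homologous pair;
    ``sex_chromosomes`` are kept but ignored by association/event analyses.
    """

    species: str
    autosomes: tuple[ChromosomeModel, ...]
    sex_chromosomes: tuple[ChromosomeModel, ...] = ()
    diploid_number: Optional[int] = None
    fundamental_number: Optional[int] = None

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str, str], str] = {}
        for chrom in self.autosomes:
            for b in chrom.blocks:
                key = (b.chrom, b.arm, b.segment)
                if key in seen:
                    raise UniquenessError(
                        f"species {self.species}: block {b.label!r} appears on "
                        f"chromosomes {seen[key]} and {chrom.chrom_id}"
                    )
                seen[key] = chrom.chrom_id
        if self.diploid_number is not None:
            expected = 2 * len(self.autosomes) + 2
            if self.diploid_number != expected:
                raise InputError(
                    f"species {self.species}: diploid number {self.diploid_number} "
                    f"inconsistent with {len(self.autosomes)} autosome pairs "
                    f"(expected {expected})"
                )

    def block_labels(self) -> tuple[str, ...]:
        """All autosomal block labels, in chromosome-then-position order."""
        return tuple(b.label for chrom in self.autosomes for b in chrom.blocks)


def associations_of(karyotype: Karyotype) -> set[str]:
    """Syntenic associations (adjacent block pairs) on the autosomes.

    A chromosome with *m* blocks contributes *m - 1* associations; pairs are
    rendered canonically as ``"X+Y"`` with the lexicographically smaller
    label first.
    """
    out: set[str] = set()
    for chrom in karyotype.autosomes:
        labels = chrom.block_labels()
        for a, b in zip(labels, labels[1:]):
            out.add(association_label(a, b))
    return out


def association_label(a: str, b: str) -> str:
    """Canonical unordered rendering of an adjacency."""
    if a == b:
        raise InputError(f"association members must be distinct (got {a!r} twice)")
    lo, hi = sorted((a, b))
    return f"{lo}+{hi}"


def compute_fn(karyotype: Karyotype, convention: str = "autosomal_arms") -> int:
    """Fundamental number (chromosome-arm count) of a karyotype.

    Biarmed morphologies (M, SM, ST, B) contribute two arms, acrocentric (A)
    one, doubled over the homologous pair for autosomes.  ``convention``
    selects whether the listed sex chromosomes are included (each listed sex
    chromosome is counted once).
    """
    if convention not in ("autosomal_arms", "all_arms"):
        raise InputError(f"unknown FN convention {convention!r}")

    def arms(chrom: ChromosomeModel) -> int:
        if chrom.morphology is None:
            raise InputError(
                f"species {karyotype.species}: cannot compute FN, chromosome "
                f"{chrom.chrom_id} has unspecified morphology"
            )
        return 2 if chrom.is_biarmed else 1

    total = sum(2 * arms(c) for c in karyotype.autosomes)
    if convention == "all_arms":
        total += sum(arms(c) for c in karyotype.sex_chromosomes)
    return total


# ---------------------------------------------------------------------------
# Homology table I/O
# ---------------------------------------------------------------------------


def _norm_token(value: str) -> str:
    value = value.strip()
    return "" if value in _EMPTY_TOKENS else value


def _is_sex_chromosome(chrom_id: str) -> bool:
    return chrom_id.upper().startswith(("X", "Y"))


def parse_homology_table(text: str) -> list[Karyotype]:
    """Parse a TSV homology table into one :class:`Karyotype` per species.

    Row order within a chromosome defines block order; ``position`` must be
    0-based and consecutive per chromosome.  Species and chromosomes keep
    their order of first appearance.
    """
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    header: Optional[dict[str, int]] = None
    # (species, chrom_id) -> list of (lineno, row fields)
    rows: dict[tuple[str, str], list[tuple[int, dict[str, str]]]] = {}
    species_order: list[str] = []
    chrom_order: dict[str, list[str]] = {}

    for lineno, raw in enumerate(reader, start=1):
        if not raw or not "".join(raw).strip() or raw[0].lstrip().startswith("#"):
            continue
        if header is None:
            cols = [c.strip() for c in raw]
            missing = [c for c in TABLE_COLUMNS if c not in cols]
            if missing:
                raise FormatError(
                    f"line {lineno}: header is missing column(s) {', '.join(missing)}"
                )
            header = {c: cols.index(c) for c in TABLE_COLUMNS}
            continue
        if len(raw) < len(header):
            raise FormatError(f"line {lineno}: expected {len(header)} fields, got {len(raw)}")
        rec = {c: raw[i].strip() for c, i in header.items()}
        key = (rec["species"], rec["chrom_id"])
        if rec["species"] not in species_order:
            species_order.append(rec["species"])
            chrom_order[rec["species"]] = []
        if rec["chrom_id"] not in chrom_order[rec["species"]]:
            chrom_order[rec["species"]].append(rec["chrom_id"])
        rows.setdefault(key, []).append((lineno, rec))
    if header is None:
        raise FormatError("empty table: no header line found")

    karyotypes: list[Karyotype] = []
    for species in species_order:
        autosomes: list[ChromosomeModel] = []
        sex: list[ChromosomeModel] = []
        for chrom_id in chrom_order[species]:
            entries = rows[(species, chrom_id)]
            blocks: list[SyntenicBlock] = []
            cent_index: Optional[int] = None
            cent_within = False
            morphology: Optional[str] = None
            for expected_pos, (lineno, rec) in enumerate(entries):
                try:
                    pos = int(rec["position"])
                except ValueError:
                    raise FormatError(f"line {lineno}: non-integer position {rec['position']!r}")
                if pos != expected_pos:
                    raise FormatError(
                        f"line {lineno}: position {pos} for {species} chromosome "
                        f"{chrom_id}, expected {expected_pos} (0-based, consecutive)"
                    )
                blocks.append(
                    SyntenicBlock(
                        chrom=_norm_token(rec["block"]),
                        arm=_norm_token(rec["arm"]),
                        segment=_norm_token(rec["segment"]),
                    )
                )
                flag = _norm_token(rec["centromere_flag"]) or "0"
                if flag != "0":
                    if cent_index is not None:
                        raise FormatError(
                            f"line {lineno}: second centromere flag on {species} "
                            f"chromosome {chrom_id}"
                        )
                    if flag == "1":
                        cent_index, cent_within = pos, True
                    elif flag == "L":
                        cent_index, cent_within = pos, False
                    elif flag == "R":
                        cent_index, cent_within = pos + 1, False
                    else:
                        raise FormatError(
                            f"line {lineno}: invalid centromere flag {flag!r} "
                            "(expected 0, 1, L or R)"
                        )
                m = _norm_token(rec["morphology"])
                if m:
                    morphology = m
            chrom = ChromosomeModel(
                chrom_id=chrom_id,
                blocks=tuple(blocks),
                centromere_index=cent_index,
                centromere_within_block=cent_within,
                morphology=morphology,
            )
            (sex if _is_sex_chromosome(chrom_id) else autosomes).append(chrom)
        karyotypes.append(
            Karyotype(species=species, autosomes=tuple(autosomes), sex_chromosomes=tuple(sex))
        )
    return karyotypes


def write_homology_table(karyotypes: Iterable[Karyotype]) -> str:
    """Serialise karyotypes to the canonical TSV dialect (round-trip safe)."""
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(TABLE_COLUMNS)
    for k in karyotypes:
        for chrom in list(k.autosomes) + list(k.sex_chromosomes):
            for pos, block in enumerate(chrom.blocks):
                flag = "0"
                cent = chrom.centromere_index
                if cent is not None:
                    if chrom.centromere_within_block:
                        if cent == pos:
                            flag = "1"
                    elif cent < chrom.n_blocks:
                        if cent == pos:
                            flag = "L"
                    elif pos == chrom.n_blocks - 1:
                        flag = "R"
                writer.writerow(
                    [
                        k.species,
                        chrom.chrom_id,
                        pos,
                        block.chrom,
                        block.arm,
                        block.segment,
                        flag,
                        chrom.morphology or "",
                    ]
                )
    return out.getvalue()


# ---------------------------------------------------------------------------
# Dated trees
# ---------------------------------------------------------------------------


class DatedTree:
    """Rooted topology with node ages (myr) and age standard errors.

    Ages are absolute node times before present; the internodal time of a
    branch is ``parent.age - child.age`` and must be strictly positive.
    Newick parsing/writing is delegated to :mod:`dendropy`; ages travel in a
    separate ``label -> (age, age_se)`` table because Newick has no standard
    slot for either.
    """

    def __init__(self, tree: dendropy.Tree, ages: Mapping[str, tuple[float, float]]):
        self._tree = tree
        self._parent: dict[str, Optional[str]] = {}
        self._children: dict[str, tuple[str, ...]] = {}
        self._ages: dict[str, float] = {}
        self._age_se: dict[str, float] = {}
        self._leaves: list[str] = []
        self._preorder: list[str] = []

        def label_of(node: dendropy.Node) -> str:
            lab = node.taxon.label if node.taxon is not None else node.label
            if not lab:
                raise FormatError("unlabeled internal node in Newick input")
            return lab

        for node in tree.preorder_node_iter():
            lab = label_of(node)
            if lab in self._parent:
                raise FormatError(f"duplicate node label {lab!r} in tree")
            self._preorder.append(lab)
            self._parent[lab] = label_of(node.parent_node) if node.parent_node else None
            kids = tuple(label_of(c) for c in node.child_nodes())
            self._children[lab] = kids
            if not kids:
                self._leaves.append(lab)
            if lab in ages:
                age, se = ages[lab]
            elif not kids:
                age, se = 0.0, 0.0
            else:
                raise FormatError(f"internal node {lab!r} has no entry in the ages table")
            if se < 0:
                raise InputError(f"node {lab!r}: negative age SE {se}")
            self._ages[lab] = float(age)
            self._age_se[lab] = float(se)

        for child, parent in self._parent.items():
            if parent is None:
                continue
            if not self._ages[parent] > self._ages[child]:
                raise ChronologyError(
                    f"node {child!r} (age {self._ages[child]}) is not younger than "
                    f"its parent {parent!r} (age {self._ages[parent]})"
                )

    # -- structure ---------------------------------------------------------
    @property
    def root(self) -> str:
        return self._preorder[0]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self._preorder)

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(self._leaves)

    def is_leaf(self, label: str) -> bool:
        return not self._children[self._check(label)]

    def parent(self, label: str) -> Optional[str]:
        return self._parent[self._check(label)]

    def children(self, label: str) -> tuple[str, ...]:
        return self._children[self._check(label)]

    def preorder(self) -> tuple[str, ...]:
        return tuple(self._preorder)

    def postorder(self) -> tuple[str, ...]:
        return tuple(reversed(self._preorder))

    def preorder_branches(self) -> tuple[tuple[str, str], ...]:
        """(parent, child) pairs in preorder of the child."""
        return tuple(
            (self._parent[lab], lab) for lab in self._preorder if self._parent[lab] is not None
        )

    # -- ages --------------------------------------------------------------
    def age(self, label: str) -> float:
        return self._ages[self._check(label)]

    def age_se(self, label: str) -> float:
        return self._age_se[self._check(label)]

    def branch_time(self, child: str) -> float:
        parent = self.parent(child)
        if parent is None:
            raise InputError(f"{child!r} is the root; it has no subtending branch")
        return self._ages[parent] - self._ages[child]

    def branch_se(self, child: str) -> float:
        """SE of the internodal time, node SEs combined in quadrature."""
        parent = self.parent(child)
        if parent is None:
            raise InputError(f"{child!r} is the root; it has no subtending branch")
        return math.hypot(self._age_se[parent], self._age_se[child])

    # -- I/O ---------------------------------------------------------------
    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def ages_table(self) -> dict[str, tuple[float, float]]:
        return {lab: (self._ages[lab], self._age_se[lab]) for lab in self._preorder}

    def _check(self, label: str) -> str:
        if label not in self._parent:
            raise InputError(f"unknown node label {label!r}")
        return label


def parse_newick_dated(
    newick: str, ages: Mapping[str, tuple[float, float]]
) -> DatedTree:
    """Parse a rooted Newick string plus a node-age table into a DatedTree."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise FormatError(f"cannot parse Newick input: {exc}") from exc
    return DatedTree(tree, ages)


def read_ages_table(text: str) -> dict[str, tuple[float, float]]:
    """Read a node-ages TSV (columns ``label``, ``age``, ``age_se``)."""
    ages: dict[str, tuple[float, float]] = {}
    for lineno, raw in enumerate(csv.reader(io.StringIO(text), delimiter="\t"), start=1):
        if not raw or not "".join(raw).strip() or raw[0].lstrip().startswith("#"):
            continue
        if raw[0].strip() == "label":
            continue
        if len(raw) < 3:
            raise FormatError(f"ages table line {lineno}: expected label, age, age_se")
        try:
            ages[raw[0].strip()] = (float(raw[1]), float(raw[2]))
        except ValueError as exc:
            raise FormatError(f"ages table line {lineno}: {exc}") from exc
    return ages


def write_ages_table(ages: Mapping[str, tuple[float, float]]) -> str:
    out = io.StringIO()
    writer = csv.writer(out, delimiter="\t", lineterminator="\n")
    writer.writerow(["label", "age", "age_se"])
    for label, (age, se) in ages.items():
        writer.writerow([label, repr(float(age)), repr(float(se))])
    return out.getvalue()
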