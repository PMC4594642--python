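"""Fitch parsimony over syntenic-association presence/absence characters.

Each syntenic association (block adjacency) observed in any species becomes
one binary character; the state of a taxon is 1 when the association is
present on its karyotype.  Characters are optimised independently on the
rooted topology with the classic two-pass Fitch algorithm (unordered binary
states, gains and losses weighted equally).  Polarity follows the outgroup:
when the top-down pass leaves the root ambiguous, the outgroup's observed
state is chosen, so every ancestral assignment is deterministic.

Branch lengths/ages play no role here; the dated tree contributes topology
only, and its ages are consumed downstream by the rates module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import InputError, MappingError
from .homology import DatedTree, Karyotype, associations_of

logger = logging.getLogger(__name__)


@dataclass
class CharacterMatrix:
    """Binary taxa x associations matrix (1 = association present)."""

    taxa: list[str]
    characters: list[str]
    states: np.ndarray  # shape (len(taxa), len(characters)), dtype int8

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.taxa), len(self.characters)):
            raise InputError(
                f"state matrix shape {self.states.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise InputError("duplicate taxon labels in character matrix")
        keep = self.states.any(axis=0)
        if not keep.all():
            dropped = [c for c, k in zip(self.characters, keep) if not k]
            logger.info("dropping all-zero character column(s): %s", ", ".join(dropped))
            self.characters = [c for c, k in zip(self.characters, keep) if k]
            self.states = self.states[:, keep]

    def state(self, taxon: str, character: str) -> int:
        return int(self.states[self.taxa.index(taxon), self.characters.index(character)])

    def to_tsv(self) -> str:
        lines = ["taxon\t" + "\t".join(self.characters)]
        for i, t in enumerate(self.taxa):
            lines.append(t + "\t" + "\t".join(str(int(v)) for v in self.states[i]))
        return "\n".join(lines) + "\n"

    def to_nexus(self) -> str:
        """Plain NEXUS-like character block for interoperability."""
        rows = "\n".join(
            f"    {t}  {''.join(str(int(v)) for v in self.states[i])}"
            for i, t in enumerate(self.taxa)
        )
        return (
            "#NEXUS\nBEGIN DATA;\n"
            f"  DIMENSIONS NTAX={len(self.taxa)} NCHAR={len(self.characters)};\n"
            '  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n'
            f"  [characters: {' '.join(self.characters)}]\n"
            f"  MATRIX\n{rows}\n  ;\nEND;\n"
        )


def build_character_matrix(karyotypes: Sequence[Karyotype]) -> CharacterMatrix:
    """Union of all associations across species as binary characters."""
    if len(karyotypes) < 2:
        raise InputError("need at least two karyotypes to build a character matrix")
    taxa = [k.species for k in karyotypes]
    if len(set(taxa)) != len(taxa):
        raise InputError("duplicate species labels among karyotypes")
    assoc_sets = [associations_of(k) for k in karyotypes]
    characters = sorted(set().union(*assoc_sets))
    states = np.zeros((len(taxa), len(characters)), dtype=np.int8)
    for i, assoc in enumerate(assoc_sets):
        for j, c in enumerate(characters):
            if c in assoc:
                states[i, j] = 1
    return CharacterMatrix(taxa=taxa, characters=characters, states=states)


@dataclass
class AncestralAssignment:
    """Result of Fitch optimisation over all characters.

    ``node_states`` maps every node label (leaves included) to the set of
    associations assigned present; ``scores`` holds the per-character minimum
    change count and ``homoplasy`` flags characters with score > 1 (a binary
    character arising more than once under Fitch optimisation).
    """

    tree: DatedTree
    outgroup: str
    characters: list[str]
    node_states: dict[str, frozenset[str]]
    scores: dict[str, int]
    homoplasy: dict[str, bool]

    def present_at(self, node: str) -> frozenset[str]:
        if node not in self.node_states:
            raise MappingError(f"unknown node {node!r}")
        return self.node_states[node]


def fitch_parsimony(
    tree: DatedTree, matrix: CharacterMatrix, outgroup: str
) -> AncestralAssignment:
    """Two-pass Fitch optimisation, root/ambiguity resolved to the outgroup state.

    Leaves present in the tree but absent from the matrix are treated as
    missing data (uninformative {0, 1} state sets).
    """
    leaves = set(tree.leaf_labels)
    for t in matrix.taxa:
        if t not in leaves:
            raise MappingError(f"matrix taxon {t!r} is not a leaf of the tree")
    if outgroup not in leaves:
        raise MappingError(f"outgroup {outgroup!r} is not a leaf of the tree")

    taxon_row = {t: i for i, t in enumerate(matrix.taxa)}
    node_chars: dict[str, set[str]] = {lab: set() for lab in tree.labels}
    scores: dict[str, int] = {}
    homoplasy: dict[str, bool] = {}

    postorder = tree.postorder()
    preorder = tree.preorder()

    for j, char in enumerate(matrix.characters):
        if outgroup in taxon_row:
            og_state = int(matrix.states[taxon_row[outgroup], j])
        else:
            og_state = 0  # association never observed in the outgroup
        prelim: dict[str, frozenset[int]] = {}
        score = 0
        for lab in postorder:
            if tree.is_leaf(lab):
                if lab in taxon_row:
                    prelim[lab] = frozenset({int(matrix.states[taxon_row[lab], j])})
                else:
                    prelim[lab] = frozenset({0, 1})
                continue
            sets = [prelim[c] for c in tree.children(lab)]
            inter = frozenset.intersection(*sets)
            if inter:
                prelim[lab] = inter
            else:
                prelim[lab] = frozenset.union(*sets)
                score += 1
        final: dict[str, int] = {}
        for lab in preorder:
            parent = tree.parent(lab)
            options = prelim[lab]
            if parent is None:
                final[lab] = og_state if og_state in options else next(iter(options))
            elif final[parent] in options:
                final[lab] = final[parent]
            else:
                final[lab] = next(iter(options))
        for lab, st in final.items():
            if st:
                node_chars[lab].add(char)
        scores[char] = score
        homoplasy[char] = score > 1

    return AncestralAssignment(
        tree=tree,
        outgroup=outgroup,
        characters=list(matrix.characters),
        node_states={lab: frozenset(chars) for lab, chars in node_chars.items()},
        scores=scores,
        homoplasy=homoplasy,
    )


def synapomorphies_at(assignment: AncestralAssignment, node: str) -> frozenset[str]:
    """Associations gained on the branch into ``node``.

    Present at ``node`` and absent at its parent; for the root, compared
    against the outgroup's observed state (the source of polarity).
    """
    tree = assignment.tree
    if node not in assignment.node_states:
        raise MappingError(f"unknown node {node!r}")
    if tree.is_leaf(node):
        raise InputError(f"{node!r} is a leaf; synapomorphies are defined for internal nodes")
    parent = tree.parent(node)
    reference = assignment.node_states[parent] if parent else assignment.node_states[assignment.outgroup]
    return frozenset(assignment.node_states[node] - reference)


def assignment_to_tsv(assignment: AncestralAssignment) -> str:
    """Node x character presence table plus per-character score/homoplasy."""
    lines = ["node\t" + "\t".join(assignment.characters)]
    for lab in assignment.tree.preorder():
        present = assignment.node_states[lab]
        lines.append(lab + "\t" + "\t".join("1" if c in present else "0" for c in assignment.characters))
    lines.append("score\t" + "\t".join(str(assignment.scores[c]) for c in assignment.characters))
    lines.append(
        "homoplasy\t" + "\t".join("1" if assignment.homoplasy[c] else "0" for c in assignment.characters)
    )
    return "\n".join(lines) + "\n"
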