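"""Fusion/fission counting between an ancestral and a derived karyotype.

The derived karyotype is decomposed into maximal *fragments*: runs of blocks
that are contiguous (adjacent, in either order) on a single ancestral
chromosome.  Painting carries no orientation, so adjacency is orientation
blind; this can under-count inversions, which are deliberately excluded from
rate counting anyway.  Sub-segment labels (``16a``/``16b``) are matched to
the untagged ancestral block (``16``), so splitting one block across two
derived chromosomes counts as a single fission.

From the decomposition:

* fusions  = sum over derived chromosomes of (number of fragments - 1),
* fissions = sum over ancestral chromosomes of (number of fragments it was
  split into - 1), ancestral chromosomes entirely absent from the derived
  karyotype (paint censoring) contribute nothing.

When every ancestral block is represented, the event balance
``n_derived = n_ancestral + fissions - fusions`` is an identity of these
definitions.  Each fusion junction is further classified as Robertsonian
(centric), telomeric/tandem, or unspecified when the centromere annotation
required for the call is missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .errors import HomologyError, InputError
from .homology import (
    BIARMED_MORPHOLOGIES,
    ChromosomeModel,
    Karyotype,
    SyntenicBlock,
)

logger = logging.getLogger(__name__)

TELOMERIC_TANDEM = "telomeric_tandem"
ROBERTSONIAN = "robertsonian"
UNSPECIFIED = "unspecified"


@dataclass
class Fragment:
    """A maximal run of derived blocks contiguous on one ancestral chromosome."""

    anc_chrom: str
    blocks: list[SyntenicBlock]
    positions: list[int]  # ancestral block indices, derived order
    partial: list[bool]  # True where the block is a sub-segment of the ancestral block

    def _completed_inward(self, i: int, inward: int) -> bool:
        j = i + inward
        return 0 <= j < len(self.positions) and self.positions[j] == self.positions[i]

    def end_junctions(self, side: str) -> Optional[frozenset[int]]:
        """Possible ancestral junction indices at the ``left``/``right`` end.

        ``None`` means the end falls within an ancestral block (a sub-segment
        break) and cannot be placed on a junction.
        """
        i, inward = (0, +1) if side == "left" else (len(self.positions) - 1, -1)
        if self.partial[i] and not self._completed_inward(i, inward):
            return None
        uniq = sorted(set(self.positions))
        if len(uniq) == 1:
            p = uniq[0]
            return frozenset({p, p + 1})
        ascending = self.positions[0] <= self.positions[-1]
        if side == "left":
            return frozenset({self.positions[0] if ascending else self.positions[0] + 1})
        return frozenset({self.positions[-1] + 1 if ascending else self.positions[-1]})


@dataclass
class FragmentDecomposition:
    ancestral: Karyotype
    derived: Karyotype
    fragments: list[tuple[ChromosomeModel, list[Fragment]]]
    split_counts: dict[str, int]  # ancestral chrom_id -> number of fragments


@dataclass(frozen=True)
class EventCount:
    fusions: int
    fissions: int
    tandem_fusions: int = 0
    robertsonian_fusions: int = 0
    unspecified_fusions: int = 0

    def __post_init__(self) -> None:
        if min(self.fusions, self.fissions) < 0:
            raise InputError("negative event count")
        if self.tandem_fusions + self.robertsonian_fusions + self.unspecified_fusions != self.fusions:
            raise InputError("fusion classification does not sum to the fusion total")

    @property
    def n_changes(self) -> int:
        return self.fusions + self.fissions


def _position_index(ancestral: Karyotype):
    exact: dict[str, tuple[str, int]] = {}
    by_base: dict[str, list[tuple[str, int, SyntenicBlock]]] = {}
    for chrom in ancestral.autosomes:
        for i, b in enumerate(chrom.blocks):
            exact[b.label] = (chrom.chrom_id, i)
            by_base.setdefault(b.base, []).append((chrom.chrom_id, i, b))
    return exact, by_base


def decompose(ancestral: Karyotype, derived: Karyotype) -> FragmentDecomposition:
    """Greedy maximal-run decomposition of ``derived`` against ``ancestral``."""
    exact, by_base = _position_index(ancestral)

    def locate(block: SyntenicBlock) -> tuple[str, int, bool]:
        if block.label in exact:
            chrom_id, idx = exact[block.label]
            return chrom_id, idx, False
        homes = by_base.get(block.base, [])
        if len(homes) == 1 and homes[0][2].segment == "":
            chrom_id, idx, _ = homes[0]
            return chrom_id, idx, True
        raise HomologyError(
            f"derived block {block.label!r} ({derived.species}) has no home in the "
            f"ancestral karyotype ({ancestral.species})"
        )

    fragments: list[tuple[ChromosomeModel, list[Fragment]]] = []
    split_counts: dict[str, int] = {c.chrom_id: 0 for c in ancestral.autosomes}
    for chrom in derived.autosomes:
        frags: list[Fragment] = []
        cur: Optional[Fragment] = None
        for block in chrom.blocks:
            anc_chrom, idx, partial = locate(block)
            extend = False
            if cur is not None and cur.anc_chrom == anc_chrom:
                prev = cur.positions[-1]
                if abs(idx - prev) == 1 and idx not in cur.positions:
                    extend = True
                elif (
                    idx == prev
                    and partial
                    and cur.partial[-1]
                    and cur.blocks[-1].base == block.base
                    and cur.blocks[-1].segment != block.segment
                ):
                    extend = True  # the two sub-segments of one split block
            if extend:
                cur.blocks.append(block)
                cur.positions.append(idx)
                cur.partial.append(partial)
            else:
                cur = Fragment(anc_chrom, [block], [idx], [partial])
                frags.append(cur)
                split_counts[anc_chrom] += 1
        fragments.append((chrom, frags))
    return FragmentDecomposition(
        ancestral=ancestral, derived=derived, fragments=fragments, split_counts=split_counts
    )


def classify_fusion(
    left: Fragment,
    right: Fragment,
    ancestral: Karyotype,
    derived_chrom: ChromosomeModel,
) -> str:
    """Classify the junction between two adjacent fragments.

    Robertsonian: both joined fragment ends carry their ancestral centromeric
    junctions and the derived chromosome is biarmed.  Telomeric/tandem: both
    ends are ancestral chromosome termini away from the centromere.  Missing
    centromere annotation (or a within-block centromere, which defines no
    clean junction) degrades the call to unspecified.
    """
    anc_by_id = {c.chrom_id: c for c in ancestral.autosomes}

    def chrom_info(frag: Fragment):
        chrom = anc_by_id[frag.anc_chrom]
        cent = None
        if chrom.centromere_index is not None and not chrom.centromere_within_block:
            cent = chrom.centromere_index
        return chrom.n_blocks, cent

    len_l, cent_l = chrom_info(left)
    len_r, cent_r = chrom_info(right)
    if cent_l is None or cent_r is None:
        logger.debug("fusion junction unclassified: missing centromere annotation")
        return UNSPECIFIED
    jl = left.end_junctions("right")
    jr = right.end_junctions("left")
    if jl is None or jr is None:
        return UNSPECIFIED

    def centromeric(junctions: frozenset[int], cent: int) -> bool:
        return cent in junctions

    def telomeric(junctions: frozenset[int], n: int, cent: int) -> bool:
        return any(j in (0, n) and j != cent for j in junctions)

    if centromeric(jl, cent_l) and centromeric(jr, cent_r):
        if derived_chrom.morphology in BIARMED_MORPHOLOGIES:
            return ROBERTSONIAN
        return UNSPECIFIED
    if telomeric(jl, len_l, cent_l) and telomeric(jr, len_r, cent_r):
        return TELOMERIC_TANDEM
    return UNSPECIFIED


def count_events(decomposition: FragmentDecomposition) -> EventCount:
    """Fusion/fission totals (with fusion classification) from a decomposition."""
    fusions = 0
    tandem = rb = unspec = 0
    for derived_chrom, frags in decomposition.fragments:
        fusions += max(len(frags) - 1, 0)
        for a, b in zip(frags, frags[1:]):
            kind = classify_fusion(a, b, decomposition.ancestral, derived_chrom)
            if kind == TELOMERIC_TANDEM:
                tandem += 1
            elif kind == ROBERTSONIAN:
                rb += 1
            else:
                unspec += 1
    fissions = sum(max(c - 1, 0) for c in decomposition.split_counts.values())
    return EventCount(
        fusions=fusions,
        fissions=fissions,
        tandem_fusions=tandem,
        robertsonian_fusions=rb,
        unspecified_fusions=unspec,
    )


def count_between(ancestral: Karyotype, derived: Karyotype) -> EventCount:
    """Convenience: ``count_events(decompose(ancestral, derived))``."""
    return count_events(decompose(ancestral, derived))


def event_counts_to_tsv(counts: Mapping[str, EventCount]) -> str:
    """Serialise per-branch counts (branch, fusions, fissions, classification)."""
    lines = ["branch\tfusions\tfissions\ttandem\trobertsonian\tunspecified"]
    for branch, ec in counts.items():
        lines.append(
            f"{branch}\t{ec.fusions}\t{ec.fissions}\t{ec.tandem_fusions}"
            f"\t{ec.robertsonian_fusions}\t{ec.unspecified_fusions}"
        )
    return "\n".join(lines) + "\n"
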