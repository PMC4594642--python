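"""Per-branch rates of chromosomal evolution with SE-propagated bounds.

The rate on a branch is the number of fixed unique changes (fusions +
fissions) divided by the internodal time in million years.  Uncertainty in
divergence dates is propagated by re-evaluating the rate at time - SE and
time + SE; when the SE exceeds the time itself the t - SE bound is negative
(or infinite) and is reported as-is with a ``nonphysical`` flag rather than
clamped, so published tables of this kind can be reproduced verbatim.

``per_generation_rate`` converts changes/myr into fixations per species per
generation (rate x 1e-6 x generation length in years), the quantity consumed
by the underdominant-fixation model in :mod:`karyorate.lande`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional, Sequence, Union

from .counting import EventCount
from .errors import DomainError, MappingError
from .homology import DatedTree

#: display rounding used by the TSV writer (round-half-even)
DISPLAY_DECIMALS = 4

#: default annotation thresholds; narrative labels, not analysis
STASIS_MAX_CHANGES = 1
EVOLUTION_RATE_THRESHOLD = 2.0


class BranchRate(NamedTuple):
    central: float
    at_t_minus_se: float
    at_t_plus_se: float
    nonphysical: bool


def branch_rate(n_changes: int, time: float, time_se: float) -> BranchRate:
    """Rate triple (n/t, n/(t-se), n/(t+se)) in changes per myr.

    ``nonphysical`` is set when ``time_se >= time`` makes the t - SE bound
    negative or singular.
    """
    if time <= 0:
        raise DomainError(f"branch time must be positive (got {time})")
    if n_changes < 0 or time_se < 0:
        raise DomainError("n_changes and time_se must be non-negative")
    central = n_changes / time
    lo_t = time - time_se
    if lo_t == 0:
        minus = math.inf if n_changes else 0.0
    else:
        minus = n_changes / lo_t
    plus = n_changes / (time + time_se)
    return BranchRate(central, minus, plus, nonphysical=time_se >= time and n_changes > 0)


def per_generation_rate(rate_per_myr: float, generation_length: float) -> float:
    """Changes/myr -> fixations per species per generation.

    ``generation_length`` is in years; one myr contains 1e6/g generations.
    """
    if rate_per_myr < 0 or generation_length < 0:
        raise DomainError("rate and generation length must be non-negative")
    return rate_per_myr * 1e-6 * generation_length


@dataclass(frozen=True)
class BranchChangeRecord:
    branch: str  # "parent->child"
    parent: str
    child: str
    n_changes: int
    time: float
    time_se: float
    rate_central: float
    rate_at_t_minus_se: float
    rate_at_t_plus_se: float
    nonphysical: bool
    annotation: str


def _annotate(n_changes: int, rate_central: float, stasis_max: int, evo_threshold: float) -> str:
    if rate_central > evo_threshold:
        return "Evolution"
    if n_changes <= stasis_max:
        return "Stasis"
    return "variable"


CountLike = Union[EventCount, tuple, int]


def _n_changes(value: CountLike) -> int:
    if isinstance(value, EventCount):
        return value.n_changes
    if isinstance(value, tuple):
        return int(sum(value))
    return int(value)


def rates_table(
    tree: DatedTree,
    counts: Mapping[str, CountLike],
    *,
    stasis_max_changes: int = STASIS_MAX_CHANGES,
    evolution_rate_threshold: float = EVOLUTION_RATE_THRESHOLD,
) -> list[BranchChangeRecord]:
    """One record per counted branch, in tree pre-order.

    ``counts`` maps the child label of each branch to an
    :class:`~karyorate.counting.EventCount`, a (fusions, fissions) tuple, or
    a plain change count.  Branch times and SEs come from the dated tree
    (node age SEs combined in quadrature).
    """
    known_children = {child for _, child in tree.preorder_branches()}
    missing = sorted(set(counts) - known_children)
    if missing:
        raise MappingError(f"counted branch(es) not in the tree: {', '.join(missing)}")
    records = []
    for parent, child in tree.preorder_branches():
        if child not in counts:
            continue
        n = _n_changes(counts[child])
        t = tree.branch_time(child)
        se = tree.branch_se(child)
        rate = branch_rate(n, t, se)
        records.append(
            BranchChangeRecord(
                branch=f"{parent}->{child}",
                parent=parent,
                child=child,
                n_changes=n,
                time=t,
                time_se=se,
                rate_central=rate.central,
                rate_at_t_minus_se=rate.at_t_minus_se,
                rate_at_t_plus_se=rate.at_t_plus_se,
                nonphysical=rate.nonphysical,
                annotation=_annotate(n, rate.central, stasis_max_changes, evolution_rate_threshold),
            )
        )
    return records


def records_from_rows(
    rows: Sequence[tuple[str, int, float, float]],
    *,
    stasis_max_changes: int = STASIS_MAX_CHANGES,
    evolution_rate_threshold: float = EVOLUTION_RATE_THRESHOLD,
) -> list[BranchChangeRecord]:
    """Build records directly from (branch, n_changes, time, time_se) rows.

    This is the path used when per-branch times and SEs are given explicitly
    (e.g. re-using a published table) instead of being derived from a tree.
    """
    records = []
    for branch, n, t, se in rows:
        parent, _, child = branch.partition("->")
        rate = branch_rate(n, t, se)
        records.append(
            BranchChangeRecord(
                branch=branch,
                parent=parent if child else "",
                child=child or branch,
                n_changes=n,
                time=t,
                time_se=se,
                rate_central=rate.central,
                rate_at_t_minus_se=rate.at_t_minus_se,
                rate_at_t_plus_se=rate.at_t_plus_se,
                nonphysical=rate.nonphysical,
                annotation=_annotate(n, rate.central, stasis_max_changes, evolution_rate_threshold),
            )
        )
    return records


def _fmt(x: float) -> str:
    if math.isinf(x):
        return "inf" if x > 0 else "-inf"
    return format(round(x, DISPLAY_DECIMALS), f".{DISPLAY_DECIMALS}f")


def rates_to_tsv(records: Sequence[BranchChangeRecord]) -> str:
    """TSV mirroring the usual lineage-rate table layout."""
    lines = [
        "lineage\ttime_myr\ttime_se\tn_changes\trate_at_t_minus_se\trate_central"
        "\trate_at_t_plus_se\tnonphysical\tcomments"
    ]
    for r in records:
        lines.append(
            f"{r.branch}\t{_fmt(r.time)}\t{_fmt(r.time_se)}\t{r.n_changes}\t"
            f"{_fmt(r.rate_at_t_minus_se)}\t{_fmt(r.rate_central)}\t"
            f"{_fmt(r.rate_at_t_plus_se)}\t{int(r.nonphysical)}\t{r.annotation}"
        )
    return "\n".join(lines) + "\n"
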