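"""Shared fixtures-by-function and independent oracles for the test suite.

The oracles here are deliberately naive and independent of the package
internals: exhaustive enumeration over internal labelings for parsimony
scores, and a dense absorbing-chain linear solve for exact Wright-Fisher
fixation probabilities.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import binom

from karyorate.homology import ChromosomeModel, DatedTree, Karyotype, SyntenicBlock


def chrom(labels, chrom_id="c", centromere_index=None, morphology=None, within=False):
    return ChromosomeModel(
        chrom_id=chrom_id,
        blocks=tuple(SyntenicBlock.from_label(lab) for lab in labels),
        centromere_index=centromere_index,
        centromere_within_block=within,
        morphology=morphology,
    )


def karyotype(species, chromosomes, sex=()):
    """Build a Karyotype from lists of block labels (or ChromosomeModels)."""
    autosomes = tuple(
        c if isinstance(c, ChromosomeModel) else chrom(c, chrom_id=str(i))
        for i, c in enumerate(chromosomes, start=1)
    )
    return Karyotype(species=species, autosomes=autosomes, sex_chromosomes=tuple(sex))


#: published lineage-rate table: branch, time (myr), SE, n_changes,
#: (rate at t-SE, central, rate at t+SE) as printed, nonphysical t-SE flag
TABLE1 = [
    ("PGA->PA", 1.7006, 3.4345, 1, (-0.5756, 0.5880, 0.1947), True),
    ("PA->PiA", 3.9046, 3.1613, 0, (0.0, 0.0, 0.0), False),
    ("PiA->L/M", 0.6135, 2.9292, 0, (0.0, 0.0, 0.0), False),
    ("L/M->M", 3.0248, 2.8037, 1, (4.5228, 0.3306, 0.1715), False),
    ("L/M->L", 10.1032, 1.2038, 0, (0.0, 0.0, 0.0), False),
    ("PiA->T", 6.2324, 2.7562, 39, (11.22, 6.26, 4.34), False),
    ("T->TSA/TBI", 12.6332, 1.7908, 1, (0.0922, 0.0791, 0.0693), False),
    ("PGA->GA", 7.786, 3.3742, 2, (0.4533, 0.2568, 0.1792), False),
    ("GA->A", 4.6205, 3.2150, 14, (9.9609, 3.03, 1.7867), False),
    ("A->ACA/AGE", 6.7802, 2.0390, 0, (0.0, 0.0, 0.0), False),
]

#: rate bounds (changes/myr) of the two fast branches, central with SE bounds
TSA_RATES = (4.34, 6.26, 11.22)
ACU_RATES = (1.7867, 3.03, 9.9609)


def printed_tolerance(printed: float) -> float:
    """Agreement to the precision a value was printed with (floor 0.001).

    Published tables mix rounding and truncation, so values printed to two
    decimals can only be matched to half an ulp of that precision; values
    printed to four decimals are matched to +-0.001.
    """
    text = repr(printed)
    decimals = len(text.split(".")[1]) if "." in text else 0
    return max(0.001, 0.5 * 10.0 ** (-decimals))


def exhaustive_min_changes(tree: DatedTree, leaf_states: dict[str, int]) -> int:
    """Minimum state changes over all internal 0/1 labelings (brute force)."""
    internals = [lab for lab in tree.preorder() if not tree.is_leaf(lab)]
    branches = tree.preorder_branches()
    best = None
    for combo in itertools.product((0, 1), repeat=len(internals)):
        states = dict(leaf_states)
        states.update(zip(internals, combo))
        changes = sum(states[p] != states[c] for p, c in branches)
        if best is None or changes < best:
            best = changes
    return best


def exact_wf_fixation(n_diploid: int, s: float, copies: int = 1) -> float:
    """Exact fixation probability of the finite Wright-Fisher chain.

    Dense transition matrix over allele counts 0..2N with deterministic
    viability selection on Hardy-Weinberg genotypes, solved as an absorbing
    Markov chain.  Independent of the simulator's code path.
    """
    two_n = 2 * n_diploid
    counts = np.arange(two_n + 1)
    p = counts / two_n
    pq = p * (1 - p)
    p_sel = (p * p + pq * (1 - s)) / (1 - 2 * s * pq)
    transition = np.vstack([binom.pmf(counts, two_n, ps) for ps in p_sel])
    interior = slice(1, two_n)
    lhs = np.eye(two_n - 1) - transition[interior, interior]
    rhs = transition[interior, two_n]
    h = np.linalg.solve(lhs, rhs)
    return float(h[copies - 1])


def true_path_counts(truth, tree, leaf: str) -> tuple[int, int]:
    """Ground-truth cumulative (fusions, fissions) from the root to a leaf."""
    fus = fis = 0
    label = leaf
    while tree.parent(label) is not None:
        f, g = truth.branch_counts[label]
        fus, fis = fus + f, fis + g
        label = tree.parent(label)
    return fus, fis
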