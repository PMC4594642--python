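"""Forward Wright-Fisher Monte Carlo for underdominant rearrangements.

This is the stochastic oracle against which the diffusion formula in
:mod:`karyorate.lande` is validated: a diploid population of constant size
``N`` with symmetric underdominance (genotype fitnesses 1 : 1-s : 1), random
mating, and multinomial (here: binomial on the allele count) resampling of
``2N`` gametes each generation.  Replicates are run to loss or fixation and
the fixation fraction estimated with a Clopper-Pearson 95% interval.

``deme_fixation_experiment`` is a deliberately minimal explicit-individual
model of rearrangement fixation in very small demes (monogamous pairs,
Poisson offspring, viability selection against heterozygotes, hard cap at
the founding size).  It is exploratory -- a direction check for predictions
about small-deme fixation/extinction trade-offs, not a reproduction of any
published simulation.

Note on interpretation: ``s`` is strictly the heterozygote fitness
reduction.  Statements about "production of unviable gametes" in the
empirical literature conflate gamete inviability with heterozygote fitness;
here selection acts once, on the heterozygous genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import DomainError, NumericalError


@dataclass(frozen=True)
class WFConfig:
    """Parameters of one fixation experiment."""

    N: int
    s: float
    initial_copies: int = 1
    reps: int = 10_000
    seed: int = 0
    max_generations: int = 10_000_000

    def __post_init__(self) -> None:
        if self.N < 2:
            raise DomainError(f"population size must be >= 2 (got {self.N})")
        if not 0 <= self.s <= 1:
            raise DomainError(f"s must lie in [0, 1] (got {self.s})")
        if not 1 <= self.initial_copies <= 2 * self.N:
            raise DomainError("initial_copies must lie in [1, 2N]")
        if self.reps < 1:
            raise DomainError("reps must be >= 1")


@dataclass(frozen=True)
class FixationEstimate:
    p_hat: float
    ci95: tuple[float, float]
    mean_sojourn: float
    n_fixed: int
    reps: int


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def simulate_fixation(cfg: WFConfig) -> FixationEstimate:
    """Run ``cfg.reps`` replicates to absorption; fully seed-reproducible.

    One generation: deterministic selection on Hardy-Weinberg genotype
    frequencies (post-selection allele frequency
    ``p' = (p^2 + p q (1-s)) / (1 - 2 s p q)``), then binomial sampling of
    the ``2N`` allele copies of the next generation.  All replicates advance
    in lockstep on a single seeded generator, which keeps results bit
    reproducible for a given seed.
    """
    rng = np.random.default_rng(cfg.seed)
    two_n = 2 * cfg.N
    count = np.full(cfg.reps, cfg.initial_copies, dtype=np.int64)
    absorbed_at = np.zeros(cfg.reps, dtype=np.int64)
    active = np.flatnonzero((count > 0) & (count < two_n))
    gen = 0
    while active.size:
        gen += 1
        if gen > cfg.max_generations:
            raise NumericalError(
                f"{active.size} replicate(s) unabsorbed after {cfg.max_generations} generations"
            )
        p = count[active] / two_n
        pq = p * (1.0 - p)
        p_sel = (p * p + pq * (1.0 - cfg.s)) / (1.0 - 2.0 * cfg.s * pq)
        count[active] = rng.binomial(two_n, p_sel)
        done = (count[active] == 0) | (count[active] == two_n)
        absorbed_at[active[done]] = gen
        active = active[~done]
    n_fixed = int(np.count_nonzero(count == two_n))
    return FixationEstimate(
        p_hat=n_fixed / cfg.reps,
        ci95=_clopper_pearson(n_fixed, cfg.reps),
        mean_sojourn=float(absorbed_at.mean()),
        n_fixed=n_fixed,
        reps=cfg.reps,
    )


def deme_fixation_experiment(
    founders: int,
    s: float,
    offspring_per_mating: float,
    reps: int,
    seed: int,
    *,
    initial_copies: int = 1,
    max_generations: int = 5_000,
) -> tuple[float, float]:
    """Fixation and extinction fractions in a small closed deme (exploratory).

    Model: ``founders`` adults, ``initial_copies`` of them heterozygous for
    the rearrangement; each generation the adults are paired monogamously at
    random (an odd adult stays unmated), each pair produces
    Poisson(``offspring_per_mating``) offspring with Mendelian gametes,
    heterozygous offspring survive with probability 1 - s, and survivors are
    culled at random down to the founding size.  A deme with fewer than two
    adults is extinct.  A replicate ends at fixation, at extinction, or --
    once the rearrangement is lost under supercritical demography
    (``offspring_per_mating >= 2``) -- as a surviving wild-type deme; demes
    that lose the allele under subcritical demography are followed until
    their (near-certain) demographic extinction.  Returns ``(fixation
    fraction, extinction fraction)`` over the replicates; runs not absorbed
    within ``max_generations`` count toward neither fraction.
    """
    if founders < 2:
        raise DomainError("founders must be >= 2")
    if offspring_per_mating < 1:
        raise DomainError("offspring_per_mating must be >= 1")
    if not 0 <= s <= 1:
        raise DomainError(f"s must lie in [0, 1] (got {s})")
    if not 1 <= initial_copies <= founders:
        raise DomainError("initial_copies must lie in [1, founders]")
    rng = np.random.default_rng(seed)
    n_fixed = 0
    n_extinct = 0
    for _ in range(reps):
        # genotypes as derived-allele counts per individual (0, 1, 2)
        adults = np.zeros(founders, dtype=np.int8)
        adults[:initial_copies] = 1
        lost = False
        for _gen in range(max_generations):
            total = int(adults.sum())
            if not lost and total == 0:
                lost = True  # rearrangement gone; deme demography still at risk
            if not lost and total == 2 * adults.size:
                n_fixed += 1
                break
            if lost and offspring_per_mating >= 2:
                # supercritical demography: a lost-allele deme persists
                break
            order = rng.permutation(adults.size)
            n_pairs = adults.size // 2
            mothers = adults[order[:n_pairs]]
            fathers = adults[order[n_pairs : 2 * n_pairs]]
            brood = rng.poisson(offspring_per_mating, size=n_pairs)
            if brood.sum() == 0:
                n_extinct += 1
                break
            gm = np.repeat(mothers, brood)
            gf = np.repeat(fathers, brood)
            m = gm.size
            offspring = (rng.random(m) < gm / 2.0).astype(np.int8) + (
                rng.random(m) < gf / 2.0
            ).astype(np.int8)
            survives = (offspring != 1) | (rng.random(m) < 1.0 - s)
            offspring = offspring[survives]
            if offspring.size < 2:
                n_extinct += 1
                break
            if offspring.size > founders:
                offspring = offspring[
                    rng.choice(offspring.size, size=founders, replace=False)
                ]
            adults = offspring
        else:
            continue  # unresolved run: neither fixed nor extinct
    return n_fixed / reps, n_extinct / reps
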