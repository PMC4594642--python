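"""Long-term effective population size under underdominant fixation.

A chromosomal rearrangement that lowers heterozygote fitness by ``s``
(genotype fitnesses 1 : 1-s : 1) fixes against selection only by drift.  In
the diffusion approximation its fixation probability from initial frequency
``p0`` in a population of effective size ``Ne`` is

    P(Ne, s, p0) = int_0^p0 exp(4 Ne s x (1 - x)) dx
                   / int_0^1  exp(4 Ne s x (1 - x)) dx,

which reduces to ``p0`` when ``s = 0`` (the neutral limit).  With a
spontaneous chromosomal mutation rate ``u`` per gamete per generation, the
long-run fixation rate per generation is

    R(Ne) = 2 N u * P(Ne, s, 1/(2N)),

with census size ``N`` taken equal to ``Ne`` by default (an Ne/N ratio can
be supplied).  For ``s > 0`` this rate is strictly decreasing in ``Ne``, so
an observed fixation rate can be inverted for the long-term ``Ne`` by
bracketed root finding on log Ne.

Numerics: both integrals are evaluated after factoring out the integrand's
maximum ``exp(Ne s)``, i.e. on ``exp(-4 Ne s (x - 1/2)^2)``, which keeps the
quadrature overflow-free at any ``Ne s``; a Laplace/erf closed form valid
for large ``Ne s`` is retained as an independent cross-check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import integrate, optimize, special

from .errors import DomainError, NumericalError
from .rates import per_generation_rate

#: search bracket for Ne inversion
NE_MIN = 2.0
NE_MAX = 1e7

STATUS_SOLVED = "solved"
STATUS_SUPRA_NEUTRAL = "supra_neutral_no_solution"
STATUS_BELOW_MINIMUM = "below_minimum"


def fixation_prob_underdominant(ne: float, s: float, p0: float) -> float:
    """Diffusion fixation probability of an underdominant rearrangement.

    Adaptive quadrature (relative tolerance 1e-10) on the shifted integrand;
    exactly ``p0`` at ``s = 0``.  At extreme ``Ne s`` (> ~700) the ratio
    underflows to 0.0, which is the correct double-precision limit.
    """
    if ne < 2:
        raise DomainError(f"effective size must be >= 2 (got {ne})")
    if not 0 <= s <= 1:
        raise DomainError(f"selection coefficient must lie in [0, 1] (got {s})")
    if not 0 < p0 < 1:
        raise DomainError(f"initial frequency must lie in (0, 1) (got {p0})")
    if s == 0:
        return p0
    a = 4.0 * ne * s

    def g(x: float) -> float:
        return math.exp(-a * (x - 0.5) ** 2)

    def _quad(lo: float, hi: float) -> float:
        val, err = integrate.quad(g, lo, hi, epsabs=0.0, epsrel=1e-10, limit=200)
        if val > 0 and err > 1e-8 * val:
            raise NumericalError(
                f"quadrature did not converge (ne={ne}, s={s}, p0={p0}, "
                f"interval [{lo}, {hi}], estimate {val}, error {err})"
            )
        return val

    denominator = 2.0 * _quad(0.5, 1.0)  # integrand symmetric about 1/2
    if p0 <= 0.5:
        numerator = _quad(0.0, p0)
    else:
        numerator = denominator - _quad(p0, 1.0)
    if denominator == 0.0:
        raise NumericalError(f"degenerate denominator at ne={ne}, s={s}")
    return min(numerator / denominator, 1.0)


def lande_rate(ne: float, u: float, s: float, ne_n_ratio: float = 1.0) -> float:
    """Fixation rate of underdominant rearrangements per generation.

    ``2 N u`` new rearrangements enter the population per generation, each a
    single heterozygote (``p0 = 1/(2N)``); a fraction ``P`` of them fixes.
    Exactly ``u`` when ``s = 0`` (the neutral substitution-rate identity).
    """
    if not 0 < u <= 1:
        raise DomainError(f"mutation rate must lie in (0, 1] (got {u})")
    if ne_n_ratio <= 0:
        raise DomainError("Ne/N ratio must be positive")
    n_census = ne / ne_n_ratio
    return 2.0 * n_census * u * fixation_prob_underdominant(ne, s, 1.0 / (2.0 * n_census))


def lande_rate_closed_form(ne: float, u: float, s: float) -> float:
    """Laplace/erf approximation 2u sqrt(Ne s / pi) e^(-Ne s) / erf(sqrt(Ne s)).

    Valid in the joint limit ``s -> 0`` with ``Ne s`` large: besides the
    Laplace treatment of the denominator it linearises the numerator in the
    initial frequency, dropping a factor ``(e^(2s) - 1) / (2s) = 1 + O(s)``.
    Kept as an independent cross-check of the quadrature in its regime of
    validity, never as the primary computation.
    """
    if s <= 0:
        raise DomainError("closed form requires s > 0")
    nes = ne * s
    return 2.0 * u * math.sqrt(nes / math.pi) * math.exp(-nes) / special.erf(math.sqrt(nes))


@dataclass(frozen=True)
class NeSolution:
    """Result of inverting the fixation-rate equation for Ne."""

    ne: Optional[float]
    status: str
    residual: float
    r_gen: float
    u: float
    s: float


def solve_ne(
    r_gen: float,
    u: float,
    s: float,
    *,
    ne_n_ratio: float = 1.0,
    ne_min: float = NE_MIN,
    ne_max: float = NE_MAX,
    rtol: float = 1e-6,
    max_iter: int = 200,
) -> NeSolution:
    """Solve ``lande_rate(Ne, u, s) = r_gen`` for Ne on [ne_min, ne_max].

    The rate is strictly decreasing in Ne for ``s > 0`` (checked on the
    bracket ends), so the root is isolated; Brent's bracketed method runs on
    log Ne.  ``supra_neutral_no_solution``: the target rate meets or exceeds
    the rate at the minimum population size (underdominance cannot reach the
    neutral rate).  ``below_minimum``: the target rate lies below anything
    attainable within the bracket (Ne would exceed ``ne_max``).
    """
    if r_gen <= 0:
        raise DomainError(f"target fixation rate must be positive (got {r_gen})")
    if s <= 0:
        raise DomainError(
            "neutral-degenerate: s must be positive, at s = 0 the rate equals u "
            "for every Ne and carries no population-size information"
        )
    rate_at_min = lande_rate(ne_min, u, s, ne_n_ratio)
    if r_gen >= rate_at_min:
        return NeSolution(None, STATUS_SUPRA_NEUTRAL, math.inf, r_gen, u, s)
    rate_at_max = lande_rate(ne_max, u, s, ne_n_ratio)
    if r_gen <= rate_at_max:
        return NeSolution(None, STATUS_BELOW_MINIMUM, math.inf, r_gen, u, s)
    if not rate_at_max < rate_at_min:
        raise NumericalError(f"rate not decreasing over bracket (u={u}, s={s})")

    def f(log_ne: float) -> float:
        return lande_rate(math.exp(log_ne), u, s, ne_n_ratio) - r_gen

    log_root = optimize.brentq(
        f, math.log(ne_min), math.log(ne_max), xtol=1e-13, rtol=1e-15, maxiter=max_iter
    )
    ne = math.exp(log_root)
    residual = abs(lande_rate(ne, u, s, ne_n_ratio) - r_gen)
    if residual > rtol * r_gen:
        raise NumericalError(
            f"root residual {residual:.3e} exceeds {rtol:.0e} x target "
            f"(r_gen={r_gen}, u={u}, s={s})"
        )
    return NeSolution(ne, STATUS_SOLVED, residual, r_gen, u, s)


def ne_grid(
    rates_myr: Sequence[float],
    generation_years: Sequence[float],
    u_values: Sequence[float],
    s_values: Sequence[float],
    *,
    ne_n_ratio: float = 1.0,
) -> pd.DataFrame:
    """Cartesian sensitivity grid of Ne solutions.

    For each (rate in changes/myr, generation length, u, s) cell the rate is
    converted to fixations per generation and inverted for Ne.  Columns:
    ``R_myr, g_years, u, s, R_gen, ne, status``; rows sorted on the
    parameter columns for reproducibility.
    """
    for name, grid in (
        ("rates_myr", rates_myr),
        ("generation_years", generation_years),
        ("u_values", u_values),
        ("s_values", s_values),
    ):
        if len(grid) == 0:
            raise DomainError(f"empty grid: {name}")
    rows = []
    for r_myr, g, u, s in itertools.product(rates_myr, generation_years, u_values, s_values):
        r_gen = per_generation_rate(r_myr, g)
        sol = solve_ne(r_gen, u, s, ne_n_ratio=ne_n_ratio)
        rows.append(
            {
                "R_myr": r_myr,
                "g_years": g,
                "u": u,
                "s": s,
                "R_gen": r_gen,
                "ne": sol.ne if sol.ne is not None else float("nan"),
                "status": sol.status,
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values(["R_myr", "g_years", "u", "s"], kind="mergesort").reset_index(
        drop=True
    )
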