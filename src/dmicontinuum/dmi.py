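"""Closed-form probabilities of Dobzhansky-Muller incompatibility (DMI) formation.

Two allopatric haploid populations adapt under strong selection and weak
mutation (SSWM): each population fixes whichever beneficial mutation arises
and establishes first.  A DMI forms when the populations fix derived alleles
at *different* loci, so that the two derived alleles meet for the first time
in a hybrid, where their epistatic interaction is deleterious.

Models
------
``p_dmi_uo``
    Classic Unckless-Orr two-locus probability under identical environments,
    ``2 s_A s_B / (s_A + s_B)**2``.  Maximised (0.5) when ``s_A == s_B``,
    i.e. when the order of fixation is maximally stochastic.
``p_dmi_env``
    Single-pair extension for environments related by a symmetry parameter
    ``phi = s_foreign / s_home`` in [0, 1]:
    ``s_A s_B (1 + phi**2) / ((s_A + phi s_B)(phi s_A + s_B))``.
    ``phi = 1`` recovers the Unckless-Orr value; ``phi = 0`` (complete
    asymmetry) makes DMI formation certain.
``p_dmi_poly``
    Polygenic extension for ``n`` interacting loci,
    ``1 - phi**(sigma1 sigma2 / sum_i s_i**2)``, where ``sigma1``/``sigma2``
    are the sums of the selection coefficients experienced by each population.
``p_dmi_poly_equal_s``
    Equal-coefficient simplification ``1 - phi**n``.

Selection coefficients are dimensionless (fitness ``1 + s``); probabilities
are clamped to [0, 1] with a 1e-12 floating-point tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DomainError",
    "DegenerateInputError",
    "LocusSet",
    "PopulationSums",
    "p_dmi_uo",
    "p_dmi_env",
    "population_sums",
    "p_dmi_poly",
    "p_dmi_poly_equal_s",
]

_CLAMP_TOL = 1e-12


class DomainError(ValueError):
    """A parameter lies outside the model's domain (e.g. phi not in [0, 1])."""


class DegenerateInputError(DomainError):
    """Inputs describe a degenerate scenario the model leaves undefined
    (e.g. no beneficial allele anywhere, or a 0/0 boundary form)."""


def _check_phi(phi: float) -> float:
    phi = float(phi)
    if not (0.0 <= phi <= 1.0) or np.isnan(phi):
        raise DomainError(f"environmental symmetry phi must lie in [0, 1], got {phi}")
    return phi


def _check_pair(s_a: float, s_b: float) -> tuple[float, float]:
    s_a, s_b = float(s_a), float(s_b)
    if s_a < 0 or s_b < 0 or np.isnan(s_a) or np.isnan(s_b):
        raise DomainError(f"selection coefficients must be >= 0, got ({s_a}, {s_b})")
    if s_a == 0.0 and s_b == 0.0:
        raise DegenerateInputError(
            "s_A = s_B = 0: no adaptation occurs, DMI probability is undefined"
        )
    return s_a, s_b


def _clamp(p: float) -> float:
    if p < -_CLAMP_TOL or p > 1.0 + _CLAMP_TOL:
        raise AssertionError(f"probability {p} outside [0, 1] beyond tolerance")
    return min(1.0, max(0.0, p))


@dataclass(frozen=True)
class LocusSet:
    """A set of loci under positive selection, each with a home environment.

    Parameters
    ----------
    s
        Home-environment selection coefficients, one per locus; all > 0.
    home_env
        Home environment of each locus, coded 1 or 2 (population k lives in
        environment k).  A locus is under full selection ``s_i`` in its home
        environment and reduced selection ``phi * s_i`` in the other.
    """

    s: np.ndarray
    home_env: np.ndarray

    def __init__(self, s, home_env=None):
        s = np.asarray(s, dtype=float)
        if s.ndim != 1 or s.size < 1:
            raise DomainError("LocusSet needs a 1-D, non-empty coefficient vector")
        if np.any(~np.isfinite(s)) or np.any(s <= 0):
            raise DomainError("all home-environment selection coefficients must be > 0")
        if home_env is None:
            home_env = np.ones(s.size, dtype=int)
        home_env = np.asarray(home_env, dtype=int)
        if home_env.shape != s.shape:
            raise DomainError("s and home_env must have the same length")
        if np.any((home_env != 1) & (home_env != 2)):
            raise DomainError("home_env labels must be 1 or 2")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "home_env", home_env)

    @property
    def n(self) -> int:
        return int(self.s.size)

    def local_coefficients(self, population: int, phi: float) -> np.ndarray:
        """Coefficients experienced by ``population`` (1 or 2) at symmetry phi."""
        phi = _check_phi(phi)
        if population not in (1, 2):
            raise DomainError("population must be 1 or 2")
        return np.where(self.home_env == population, self.s, phi * self.s)


@dataclass(frozen=True)
class PopulationSums:
    """Summed selection pressure per population and the squared-coefficient sum.

    ``sigma1``/``sigma2`` are the sums of coefficients experienced by
    populations 1 and 2 under the phi transfer convention; ``sum_sq`` is
    ``sum_i s_i**2`` over home-environment coefficients.
    """

    sigma1: float
    sigma2: float
    sum_sq: float

    def __post_init__(self):
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise DomainError("population coefficient sums must be >= 0")
        if self.sum_sq <= 0:
            raise DomainError("sum of squared coefficients must be > 0")


def p_dmi_uo(s_a: float, s_b: float) -> float:
    """Unckless-Orr probability that two populations in identical environments
    fix different alleles first: ``2 s_A s_B / (s_A + s_B)**2``.

    Symmetric in its arguments, maximised at 0.5 when ``s_A == s_B``.
    Raises :class:`DegenerateInputError` if both coefficients are zero.
    """
    s_a, s_b = _check_pair(s_a, s_b)
    return _clamp(2.0 * s_a * s_b / (s_a + s_b) ** 2)


def p_dmi_env(s_a: float, s_b: float, phi: float) -> float:
    """DMI probability for one locus pair under environmental symmetry phi.

    ``s_A s_B (1 + phi**2) / ((s_A + phi s_B)(phi s_A + s_B))``.

    ``phi = 1`` reproduces :func:`p_dmi_uo` exactly; ``phi = 0`` returns 1
    whenever both populations hold a locally beneficial allele.  The 0/0 form
    reached when exactly one coefficient is zero at ``phi = 0`` is undefined
    and raises :class:`DegenerateInputError`.
    """
    s_a, s_b = _check_pair(s_a, s_b)
    phi = _check_phi(phi)
    if phi == 0.0:
        if s_a > 0.0 and s_b > 0.0:
            return 1.0
        raise DegenerateInputError(
            "phi = 0 with a single beneficial allele is a 0/0 boundary form; "
            "the model leaves it undefined"
        )
    return _clamp(s_a * s_b * (1.0 + phi * phi) / ((s_a + phi * s_b) * (phi * s_a + s_b)))


def population_sums(loci: LocusSet, phi: float) -> PopulationSums:
    """Sum the selection coefficients each population experiences.

    Population k receives ``s_i`` at loci whose home environment is k and
    ``phi * s_i`` elsewhere; ``sum_sq`` is over home coefficients.
    """
    phi = _check_phi(phi)
    sigma1 = float(np.sum(loci.local_coefficients(1, phi)))
    sigma2 = float(np.sum(loci.local_coefficients(2, phi)))
    return PopulationSums(sigma1=sigma1, sigma2=sigma2, sum_sq=float(np.sum(loci.s**2)))


def p_dmi_poly(loci: LocusSet, phi: float, sums: PopulationSums | None = None) -> float:
    """Probability that at least one DMI forms among ``n`` interacting loci.

    Evaluates ``1 - phi**(sigma1 sigma2 / sum_i s_i**2)``.  By default the
    population sums follow the phi transfer convention via
    :func:`population_sums`; pass precomputed ``sums`` to use a different
    convention (the equal-s simplification ``1 - phi**n`` corresponds to
    ``sigma1 = sigma2 = n * s``).

    ``phi = 0`` returns 1 provided both populations retain positive summed
    selection (complete asymmetry guarantees DMI formation); otherwise the
    exponent is a degenerate 0**0 form and an error is raised.
    """
    phi = _check_phi(phi)
    if sums is None:
        sums = population_sums(loci, phi)
    if phi == 0.0:
        if sums.sigma1 > 0.0 and sums.sigma2 > 0.0:
            return 1.0
        raise DegenerateInputError(
            "phi = 0 with a population under no positive selection is undefined"
        )
    if phi == 1.0:
        return 0.0
    exponent = sums.sigma1 * sums.sigma2 / sums.sum_sq
    return _clamp(1.0 - phi**exponent)


def p_dmi_poly_equal_s(n: int, phi: float) -> float:
    """Equal-coefficient polygenic DMI probability, ``1 - phi**n``.

    Simplification of :func:`p_dmi_poly` when all ``n`` loci share one
    selection coefficient and both populations experience the full sum
    (exponent ``(n s)(n s) / (n s**2) = n``).  Non-decreasing in ``n``,
    non-increasing in phi.
    """
    if not float(n).is_integer() or n < 1:
        raise DomainError(f"number of interacting loci must be an integer >= 1, got {n}")
    phi = _check_phi(phi)
    return _clamp(1.0 - phi ** int(n))
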