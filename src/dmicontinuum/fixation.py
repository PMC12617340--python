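"""Monte-Carlo origination-fixation ("fixation race") simulator.

Two allopatric populations adapt in the strong-selection weak-mutation regime:
each population's next substitution is a race among its available beneficial
mutations.  Locus ``i`` wins the race in population ``k`` with probability
proportional to its local selection coefficient (``s_i`` at home, ``phi*s_i``
abroad), and the waiting time to that substitution is exponential with rate
equal to the summed local coefficients (the common factor ``2 N mu . 2`` is
absorbed into the time unit, so absolute times are arbitrary; ratios are not).

A Dobzhansky-Muller incompatibility (DMI) forms when population 1 fixes locus
``i`` and population 2 fixes locus ``j`` for an interacting ordered pair
``(i, j)`` with ``i != j``.  The simulator is the mechanistic oracle for the
closed forms in :mod:`dmicontinuum.dmi` and also measures the foreign/home
substitution-rate ratio, whose expectation is phi.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dmi import DomainError, LocusSet, _check_phi

__all__ = [
    "NO_SUBSTITUTION",
    "SimConfig",
    "SimResult",
    "race_once",
    "estimate_pairwise",
    "estimate_polygenic",
    "substitution_rate_ratio",
]

#: Sentinel locus index for a population with no positively selected locus
#: (it never substitutes).
NO_SUBSTITUTION = -1


def _default_interaction_map(n: int) -> dict[tuple[int, int], float]:
    """All ordered hetero-locus pairs, full severity t = 1."""
    return {(i, j): 1.0 for i in range(n) for j in range(n) if i != j}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation run.

    Parameters
    ----------
    loci
        The loci under selection, with home-environment labels.
    phi
        Environmental symmetry in [0, 1].
    n_reps
        Number of independent replicate races.
    horizon
        Substitutions per population before stopping (sequential races
        without replacement of already-fixed loci).
    seed
        RNG seed; the result is a pure function of the whole config.
    interaction_map
        Mapping ``(i, j) -> severity t`` declaring that locus ``i`` fixed in
        population 1 and locus ``j`` fixed in population 2 form a DMI of
        severity ``t`` in hybrids.  Defaults to every ordered pair ``i != j``
        at ``t = 1``.  Severity does not affect whether a DMI forms, only the
        hybrid-fitness bookkeeping; it drives within-population purging for
        horizons > 1 (a locus incompatible with an allele already fixed
        locally is removed from that population's race when ``t > 0``).
    """

    loci: LocusSet
    phi: float
    n_reps: int = 10_000
    horizon: int = 1
    seed: int = 0
    interaction_map: dict[tuple[int, int], float] | None = None

    def __post_init__(self):
        _check_phi(self.phi)
        if self.n_reps < 1:
            raise DomainError("n_reps must be >= 1")
        if self.horizon < 1:
            raise DomainError("horizon must be >= 1")
        n = self.loci.n
        if self.interaction_map is not None:
            for (i, j), t in self.interaction_map.items():
                if not (0 <= i < n and 0 <= j < n):
                    raise DomainError(f"interaction pair ({i}, {j}) references a missing locus")
                if i == j:
                    raise DomainError("an interaction pair must involve two distinct loci")
                if not (0.0 <= t <= 1.0):
                    raise DomainError(f"severity t must lie in [0, 1], got {t}")

    def interactions(self) -> dict[tuple[int, int], float]:
        if self.interaction_map is None:
            return _default_interaction_map(self.loci.n)
        return dict(self.interaction_map)


@dataclass(frozen=True)
class SimResult:
    """Monte-Carlo estimates with binomial standard errors.

    ``p_dmi_hat`` is the fraction of replicates in which at least one DMI
    formed; ``rate_ratio_hat`` the estimated population-2 / population-1
    substitution-rate ratio (NaN when not computed, 0 when population 2 never
    substitutes); ``n_one_sided`` counts replicates where exactly one
    population substituted.
    """

    p_dmi_hat: float
    se: float
    rate_ratio_hat: float
    n_reps: int
    seed: int
    rate_ratio_se: float = float("nan")
    n_one_sided: int = 0

    def __post_init__(self):
        if not math.isnan(self.p_dmi_hat) and not (0.0 <= self.p_dmi_hat <= 1.0):
            raise DomainError("p_dmi_hat must lie in [0, 1]")


def race_once(loci: LocusSet, phi: float, rng: np.random.Generator):
    """Run one first-substitution race in each population.

    Returns ``(first_fixed_pop1, first_fixed_pop2, (time1, time2))``.  The
    winning locus in population k is categorical with probabilities
    proportional to the local coefficients; the waiting time is exponential
    with rate equal to their sum.  A population with zero total local
    selection returns ``NO_SUBSTITUTION`` and an infinite waiting time.
    """
    out_idx, out_t = [], []
    for pop in (1, 2):
        w = loci.local_coefficients(pop, phi)
        total = w.sum()
        if total <= 0.0:
            out_idx.append(NO_SUBSTITUTION)
            out_t.append(math.inf)
        else:
            out_idx.append(int(rng.choice(loci.n, p=w / total)))
            out_t.append(float(rng.exponential(1.0 / total)))
    return out_idx[0], out_idx[1], (out_t[0], out_t[1])


def _first_fixed_batch(w: np.ndarray, n_reps: int, rng: np.random.Generator):
    """Vectorised first-substitution draws for one population.

    Returns (indices, waiting_times); all-sentinel when no locus is under
    positive local selection.
    """
    total = w.sum()
    if total <= 0.0:
        return (
            np.full(n_reps, NO_SUBSTITUTION, dtype=np.int64),
            np.full(n_reps, np.inf),
        )
    cum = np.cumsum(w) / total
    idx = np.searchsorted(cum, rng.random(n_reps), side="right")
    idx = np.minimum(idx, w.size - 1)  # guard against u == 1.0 rounding
    times = rng.exponential(1.0 / total, size=n_reps)
    return idx.astype(np.int64), times


def _interaction_matrix(cfg: SimConfig) -> np.ndarray:
    n = cfg.loci.n
    m = np.zeros((n, n), dtype=bool)
    for (i, j) in cfg.interactions():
        m[i, j] = True
    return m


def _capable_masks(mat: np.ndarray):
    """Per-locus flags: can this locus, fixed alone, enter any DMI pair?"""
    return mat.any(axis=1), mat.any(axis=0)  # as pop-1 allele, as pop-2 allele


def _one_sided_events(idx1, idx2, cap1, cap2):
    """Classify replicates where exactly one population substituted.

    Such a replicate counts as a DMI event iff the lone fixed allele is
    incompatible-capable (appears in some interaction pair for its side).
    """
    only1 = (idx1 != NO_SUBSTITUTION) & (idx2 == NO_SUBSTITUTION)
    only2 = (idx2 != NO_SUBSTITUTION) & (idx1 == NO_SUBSTITUTION)
    ev = np.zeros(idx1.shape, dtype=bool)
    ev[only1] = cap1[idx1[only1]]
    ev[only2] = cap2[idx2[only2]]
    return ev, only1 | only2


def _ratio_of_rates(t1: np.ndarray, t2: np.ndarray):
    """Pop-2/pop-1 substitution-rate ratio from waiting times, with a
    delta-method standard error; 0 when population 2 never substitutes."""
    if np.isinf(t2).all():
        return 0.0, 0.0
    if np.isinf(t1).all():
        return math.inf, math.nan
    m1, m2 = t1.mean(), t2.mean()
    ratio = m1 / m2
    n = t1.size
    cv1 = t1.std(ddof=1) / m1
    cv2 = t2.std(ddof=1) / m2
    se = ratio * math.sqrt((cv1**2 + cv2**2) / n)
    return float(ratio), float(se)


def estimate_pairwise(cfg: SimConfig) -> SimResult:
    """Estimate P(the two populations' first substitutions form a DMI).

    Requires exactly two loci and horizon 1.  For ``phi = 1`` the estimate
    converges to the Unckless-Orr probability; for general phi it converges
    to the environmental-extension closed form — this convergence is the
    mechanistic justification of that formula's parsing.
    """
    if cfg.loci.n != 2:
        raise DomainError("estimate_pairwise requires exactly 2 loci")
    if cfg.horizon != 1:
        raise DomainError("estimate_pairwise is a horizon-1 race")
    return estimate_polygenic(cfg)


def estimate_polygenic(cfg: SimConfig) -> SimResult:
    """Estimate P(at least one DMI) within ``horizon`` substitutions per population.

    Horizon-1 races are fully vectorised; longer horizons run sequential
    races without replacement, purging from a population's race any locus
    that would be incompatible (severity > 0) with an allele already fixed
    in that same population.
    """
    rng = np.random.default_rng(cfg.seed)
    mat = _interaction_matrix(cfg)
    cap1, cap2 = _capable_masks(mat)

    if cfg.horizon == 1:
        w1 = cfg.loci.local_coefficients(1, cfg.phi)
        w2 = cfg.loci.local_coefficients(2, cfg.phi)
        idx1, t1 = _first_fixed_batch(w1, cfg.n_reps, rng)
        idx2, t2 = _first_fixed_batch(w2, cfg.n_reps, rng)
        both = (idx1 != NO_SUBSTITUTION) & (idx2 != NO_SUBSTITUTION)
        events = np.zeros(cfg.n_reps, dtype=bool)
        events[both] = mat[idx1[both], idx2[both]]
        one_sided_ev, one_sided = _one_sided_events(idx1, idx2, cap1, cap2)
        events |= one_sided_ev
        ratio, ratio_se = _ratio_of_rates(t1, t2)
        p_hat = float(events.mean())
        return SimResult(
            p_dmi_hat=p_hat,
            se=math.sqrt(p_hat * (1.0 - p_hat) / cfg.n_reps),
            rate_ratio_hat=ratio,
            rate_ratio_se=ratio_se,
            n_reps=cfg.n_reps,
            seed=cfg.seed,
            n_one_sided=int(one_sided.sum()),
        )

    severities = cfg.interactions()
    n = cfg.loci.n
    events = np.zeros(cfg.n_reps, dtype=bool)
    one_sided = 0
    tot_time = np.zeros(2)
    tot_subs = np.zeros(2)
    for rep in range(cfg.n_reps):
        fixed: list[list[int]] = [[], []]
        for pop in (1, 2):
            avail = np.ones(n, dtype=bool)
            w_full = cfg.loci.local_coefficients(pop, cfg.phi)
            for _step in range(cfg.horizon):
                w = np.where(avail, w_full, 0.0)
                total = w.sum()
                if total <= 0.0:
                    break
                u = rng.random()
                locus = int(np.searchsorted(np.cumsum(w) / total, u, side="right"))
                locus = min(locus, n - 1)
                tot_time[pop - 1] += rng.exponential(1.0 / total)
                tot_subs[pop - 1] += 1
                fixed[pop - 1].append(locus)
                avail[locus] = False
                # purge loci incompatible with the allele just fixed locally
                for other in range(n):
                    if avail[other] and (
                        severities.get((locus, other), 0.0) > 0.0
                        or severities.get((other, locus), 0.0) > 0.0
                    ):
                        avail[other] = False
        f1, f2 = fixed
        if f1 and f2:
            events_here = any(
                (i, j) in severities and i != j for i in f1 for j in f2
            )
        elif f1 or f2:
            one_sided += 1
            lone, cap = (f1, cap1) if f1 else (f2, cap2)
            events_here = bool(any(cap[i] for i in lone))
        else:
            events_here = False
        events[rep] = events_here
    p_hat = float(events.mean())
    if tot_subs[1] == 0:
        ratio = 0.0
    elif tot_subs[0] == 0:
        ratio = math.inf
    else:
        ratio = float((tot_subs[1] / tot_time[1]) / (tot_subs[0] / tot_time[0]))
    return SimResult(
        p_dmi_hat=p_hat,
        se=math.sqrt(p_hat * (1.0 - p_hat) / cfg.n_reps),
        rate_ratio_hat=ratio,
        n_reps=cfg.n_reps,
        seed=cfg.seed,
        n_one_sided=one_sided,
    )


def substitution_rate_ratio(cfg: SimConfig) -> SimResult:
    """Estimate the foreign/home substitution-rate ratio.

    All loci must be home in environment 1, so population 2 adapts entirely
    under phi-scaled coefficients.  The ratio of mean first-substitution
    rates (inverse mean waiting times) has expectation phi.  ``phi = 0``
    returns 0 with a warning, since the foreign population never adapts.
    """
    if np.any(cfg.loci.home_env != 1):
        raise DomainError(
            "substitution_rate_ratio requires every locus home in environment 1"
        )
    if cfg.phi == 0.0:
        warnings.warn(
            "phi = 0: the foreign population never substitutes; rate ratio is 0",
            stacklevel=2,
        )
        return SimResult(
            p_dmi_hat=float("nan"),
            se=float("nan"),
            rate_ratio_hat=0.0,
            rate_ratio_se=0.0,
            n_reps=cfg.n_reps,
            seed=cfg.seed,
        )
    rng = np.random.default_rng(cfg.seed)
    rate1 = cfg.loci.local_coefficients(1, cfg.phi).sum()
    rate2 = cfg.loci.local_coefficients(2, cfg.phi).sum()
    t1 = rng.exponential(1.0 / rate1, size=cfg.n_reps)
    t2 = rng.exponential(1.0 / rate2, size=cfg.n_reps)
    ratio, se = _ratio_of_rates(t1, t2)
    return SimResult(
        p_dmi_hat=float("nan"),
        se=float("nan"),
        rate_ratio_hat=ratio,
        rate_ratio_se=se,
        n_reps=cfg.n_reps,
        seed=cfg.seed,
    )
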