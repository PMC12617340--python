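"""Seeded generators for every input the pipeline consumes.

The crossing-design generator emulates the structure of a paired coastal
ecotype study: eight populations (two dune-headland pairs in each of two
phylogenetic clades), intra-population control crosses, and all ordered
inter-population crosses, 260 crosses in total by default.  Outcomes are
binomial at two stages (seed set out of a per-head seed count; germination
out of five tested seeds) with class-dependent success probabilities, chosen
so that design cells carry planted reproductive-isolation values — including
hybrid vigour (negative RI) for dune x dune crosses, moderate isolation for
between-clade headland x headland seed set, and near-complete isolation for
between-clade dune x headland crosses.  These defaults are illustrative of
the qualitative pattern, not estimates of any real study's cell means.

Also provided: low-rank-plus-noise trait/soil matrices with a recoverable
latent dimension, random bifurcating trees (optionally with a two-clade
constraint), and selection-coefficient sets (fixed or exponential).

All generators are pure functions of their spec, seed included.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dmi import DomainError, LocusSet
from .ri import ri_linear

__all__ = [
    "CrossDesignSpec",
    "TraitSpec",
    "SelectionSpec",
    "implied_hybrid_prob",
    "make_populations",
    "make_crosses",
    "make_traits",
    "make_tree",
    "make_selection",
]

STAGES = ("seed_set", "viability")

#: Planted RI per (cross_class, clade_scope, stage).  Same-ecotype crosses
#: within clades show mild hybrid vigour; between-clade HxH seed set carries
#: the mutation-order signal; between-clade DxH/HxD are close to complete
#: isolation.
DEFAULT_CELL_RI = {
    ("DxD", "within", "seed_set"): -0.05,
    ("DxD", "between", "seed_set"): -0.05,
    ("HxH", "within", "seed_set"): -0.05,
    ("HxH", "between", "seed_set"): 0.40,
    ("DxH", "within", "seed_set"): 0.35,
    ("DxH", "between", "seed_set"): 0.90,
    ("HxD", "within", "seed_set"): 0.35,
    ("HxD", "between", "seed_set"): 0.90,
    ("DxD", "within", "viability"): -0.05,
    ("DxD", "between", "viability"): -0.05,
    ("HxH", "within", "viability"): -0.02,
    ("HxH", "between", "viability"): 0.10,
    ("DxH", "within", "viability"): 0.25,
    ("DxH", "between", "viability"): 0.80,
    ("HxD", "within", "viability"): 0.25,
    ("HxD", "between", "viability"): 0.80,
}

DEFAULT_CONTROL_PROBS = {"seed_set": 0.8, "viability": 0.85}


def implied_hybrid_prob(control_prob: float, ri: float) -> float:
    """Invert the linear RI index: the hybrid success probability H such that
    ri_linear(H, control_prob) == ri, i.e. ``H = C (1 - r) / (1 + r)``."""
    if not (-1.0 < ri <= 1.0):
        raise DomainError(f"planted RI must lie in (-1, 1], got {ri}")
    h = control_prob * (1.0 - ri) / (1.0 + ri)
    if not (0.0 <= h <= 1.0):
        raise DomainError(
            f"planted RI {ri} with control probability {control_prob} implies "
            f"hybrid probability {h} outside [0, 1]"
        )
    return h


@dataclass(frozen=True)
class CrossDesignSpec:
    """Crossing-design generator settings.

    ``cell_ri`` maps (cross_class, clade_scope, stage) to the planted RI of
    that design cell; hybrid success probabilities are derived from it and
    the stage control probabilities.  ``total_crosses`` pads the design with
    extra control crosses (round-robin over populations) so the table reaches
    the stated size; set to None to skip padding.
    """

    n_pairs_per_clade: int = 2
    cell_ri: dict = field(default_factory=lambda: dict(DEFAULT_CELL_RI))
    control_probs: dict = field(default_factory=lambda: dict(DEFAULT_CONTROL_PROBS))
    crosses_per_pair: int = 4
    controls_per_pop: int = 4
    total_crosses: int | None = 260
    seeds_per_head_offset: int = 10
    seeds_per_head_nb_n: float = 5.0
    seeds_per_head_nb_p: float = 0.5
    seeds_tested_per_cross: int = 5
    seed: int = 0

    def hybrid_prob(self, cross_class: str, clade_scope: str, stage: str) -> float:
        key = (cross_class, clade_scope, stage)
        if key not in self.cell_ri:
            raise DomainError(f"no planted RI for design cell {key}")
        return implied_hybrid_prob(self.control_probs[stage], self.cell_ri[key])


@dataclass(frozen=True)
class TraitSpec:
    """Low-rank-plus-noise trait matrix settings (populations x variables)."""

    n_pops: int = 8
    n_vars: int = 38
    latent_dims: int = 5
    loading_scale: float = 3.0
    noise_sd: float = 0.1
    kind: str = "soil"
    seed: int = 0

    def __post_init__(self):
        if not (self.n_vars >= self.latent_dims >= 1):
            raise DomainError("need n_vars >= latent_dims >= 1")


@dataclass(frozen=True)
class SelectionSpec:
    """Selection-coefficient generator settings.

    ``distribution`` is "fixed" (all coefficients equal ``s``) or
    "exponential" (mean ``s``, the standard assumption for beneficial-effect
    sizes); ``home_rule`` assigns home environments: "all_1" (every locus
    home in environment 1) or "split" (alternating 1, 2, 1, 2, ...).
    """

    n_loci: int = 2
    distribution: str = "fixed"
    s: float = 0.01
    home_rule: str = "split"
    seed: int = 0

    def __post_init__(self):
        if self.n_loci < 1:
            raise DomainError("n_loci must be >= 1")
        if self.distribution not in ("fixed", "exponential"):
            raise DomainError(f"unknown distribution {self.distribution!r}")
        if self.home_rule not in ("all_1", "split"):
            raise DomainError(f"unknown home_rule {self.home_rule!r}")
        if self.s <= 0:
            raise DomainError("s must be > 0")


def make_populations(n_pairs_per_clade: int = 2) -> pd.DataFrame:
    """Population metadata frame: id, ecotype (D/H), clade."""
    rows = []
    for clade, prefix in (("eastern", "E"), ("southeastern", "S")):
        for i in range(1, n_pairs_per_clade + 1):
            for eco in ("D", "H"):
                rows.append({"pop": f"{prefix}{i}{eco}", "ecotype": eco, "clade": clade})
    return pd.DataFrame(rows)


def _design_rows(spec: CrossDesignSpec) -> pd.DataFrame:
    pops = make_populations(spec.n_pairs_per_clade)
    meta = pops.set_index("pop")
    rows = []
    for mother in pops["pop"]:
        for father in pops["pop"]:
            if mother == father:
                continue
            for _ in range(spec.crosses_per_pair):
                rows.append((mother, father))
    n_controls = {p: spec.controls_per_pop for p in pops["pop"]}
    if spec.total_crosses is not None:
        base = len(rows) + sum(n_controls.values())
        extra = spec.total_crosses - base
        if extra < 0:
            raise DomainError(
                f"total_crosses={spec.total_crosses} is smaller than the base design ({base})"
            )
        for k, p in zip(range(extra), list(pops["pop"]) * (extra // len(pops) + 1)):
            n_controls[p] += 1
    for p, k in n_controls.items():
        rows.extend([(p, p)] * k)

    out = pd.DataFrame(rows, columns=["mother_pop", "father_pop"])
    for side in ("mother", "father"):
        out[f"{side}_ecotype"] = meta.loc[out[f"{side}_pop"], "ecotype"].to_numpy()
        out[f"{side}_clade"] = meta.loc[out[f"{side}_pop"], "clade"].to_numpy()
    return out


def _success_probs(design: pd.DataFrame, spec: CrossDesignSpec) -> pd.DataFrame:
    probs = {stage: np.empty(len(design)) for stage in STAGES}
    for k, row in enumerate(design.itertuples()):
        control = row.mother_pop == row.father_pop
        scope = "within" if row.mother_clade == row.father_clade else "between"
        cls = f"{row.mother_ecotype}x{row.father_ecotype}"
        for stage in STAGES:
            if control:
                probs[stage][k] = spec.control_probs[stage]
            else:
                probs[stage][k] = spec.hybrid_prob(cls, scope, stage)
    return design.assign(**{f"_p_{s}": probs[s] for s in STAGES})


def make_crosses(spec: CrossDesignSpec | None = None) -> pd.DataFrame:
    """Generate a crossing table with binomial outcomes at both stages.

    Deterministic given the spec (seed included).  Seed counts per flower
    head are ``offset + NegativeBinomial(n, p)``; five seeds per cross are
    germination-tested by default.
    """
    spec = spec or CrossDesignSpec()
    design = _success_probs(_design_rows(spec), spec)
    rng = np.random.default_rng(spec.seed)
    m = len(design)
    seeds_total = spec.seeds_per_head_offset + rng.negative_binomial(
        spec.seeds_per_head_nb_n, spec.seeds_per_head_nb_p, size=m
    )
    seeds_fert = rng.binomial(seeds_total, design["_p_seed_set"].to_numpy())
    seeds_tested = np.full(m, spec.seeds_tested_per_cross)
    seeds_germ = rng.binomial(seeds_tested, design["_p_viability"].to_numpy())
    out = design.drop(columns=[f"_p_{s}" for s in STAGES]).assign(
        seeds_fertilised=seeds_fert,
        seeds_total=seeds_total,
        seeds_germinated=seeds_germ,
        seeds_tested=seeds_tested,
    )
    return out


def make_traits(spec: TraitSpec | None = None, populations=None) -> pd.DataFrame:
    """Low-rank-plus-noise trait matrix with a recoverable latent dimension.

    ``X = U diag(scales) V' + E``: U holds orthonormal mean-zero population
    scores, V orthonormal variable loadings, and the per-axis scales decline
    linearly from ``loading_scale`` to 60% of it, so the signal spectrum is
    exactly controlled (each latent axis carries a non-negligible variance
    share) and E is iid Gaussian noise.  With noise_sd = 0 the matrix has
    exactly ``latent_dims`` nonzero principal axes.
    """
    spec = spec or TraitSpec()
    rng = np.random.default_rng(spec.seed)
    if populations is None:
        populations = [f"P{i+1}" for i in range(spec.n_pops)]
    if len(populations) != spec.n_pops:
        raise DomainError("populations list must match spec.n_pops")
    if spec.latent_dims >= spec.n_pops:
        raise DomainError("latent_dims must be smaller than n_pops (centering costs one rank)")
    scales = spec.loading_scale * np.linspace(1.0, 0.6, spec.latent_dims)
    g = rng.standard_normal((spec.n_pops, spec.latent_dims))
    g -= g.mean(axis=0)
    u, _ = np.linalg.qr(g)
    v, _ = np.linalg.qr(rng.standard_normal((spec.n_vars, spec.latent_dims)))
    x = (u * scales) @ v.T
    if spec.noise_sd > 0:
        x = x + rng.standard_normal(x.shape) * spec.noise_sd
    cols = [f"{spec.kind}_var{j+1}" for j in range(spec.n_vars)]
    out = pd.DataFrame(x, index=list(populations), columns=cols)
    out.index.name = "pop"
    return out


def _join_newick(a: str, la: float, b: str, lb: float) -> str:
    return f"({a}:{la:.6f},{b}:{lb:.6f})"


def _random_subtree(labels, depth_scale: float, rng: np.random.Generator) -> str:
    frags = list(labels)
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        b = frags.pop(j)
        a = frags.pop(i)
        la, lb = rng.uniform(0.05, 0.15, size=2) * depth_scale
        frags.append(_join_newick(a, la, b, lb))
    return frags[0]


def make_tree(
    n_tips: int,
    depth: float = 1.0,
    seed: int = 0,
    two_clades: bool = False,
    tip_labels=None,
) -> str:
    """Random rooted bifurcating tree with positive branch lengths, as newick.

    With ``two_clades=True`` the first half of the tips forms one clade and
    the rest the other, joined by long stems (length ``depth`` each) so every
    between-clade patristic distance exceeds every within-clade distance.
    Deterministic given the seed.
    """
    if n_tips < 2:
        raise DomainError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    if tip_labels is None:
        tip_labels = [f"T{i+1}" for i in range(n_tips)]
    if len(tip_labels) != n_tips:
        raise DomainError("tip_labels length must equal n_tips")
    if two_clades and n_tips >= 4:
        half = n_tips // 2
        left = _random_subtree(tip_labels[:half], depth, rng)
        right = _random_subtree(tip_labels[half:], depth, rng)
        newick = _join_newick(left, depth, right, depth)
    else:
        newick = _random_subtree(tip_labels, depth, rng)
    return newick + ";"


def make_selection(spec: SelectionSpec | None = None) -> LocusSet:
    """Draw a selection-coefficient set per the spec; deterministic given seed."""
    spec = spec or SelectionSpec()
    rng = np.random.default_rng(spec.seed)
    if spec.distribution == "fixed":
        s = np.full(spec.n_loci, spec.s)
    else:
        # rejection-free: exponential draws are > 0 almost surely; guard exact 0
        s = rng.exponential(spec.s, size=spec.n_loci)
        s = np.maximum(s, np.finfo(float).tiny)
    if spec.home_rule == "all_1":
        home = np.ones(spec.n_loci, dtype=int)
    else:
        home = np.where(np.arange(spec.n_loci) % 2 == 0, 1, 2)
    return LocusSet(s=s, home_env=home)
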