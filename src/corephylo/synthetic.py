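"""Synthetic species: trees and parameters emulating real core-genome panels.

A synthetic species is a pure-birth (Yule) tree with 13-55 taxa, rescaled
so the mean root-to-tip depth matches a target divergence drawn
log-uniformly from 0.005-0.05 substitutions/site (a realistic
intra-species core-genome range), plus simulation parameters in the
ranges seen across bacterial core genomes: GC content 0.25-0.70,
transition/transversion rate ratio 1-4, codon-position rates with the
third position fastest, and a genome length defaulting to 100 kb (the
scale used for simulation genomes; real concatenates reach megabases and
are scaled down here).  dN/dS is attached as a covariate label only — the
simulated process is neutral, so selection-related correlations are
exercised on constructed monotone fixtures, not mechanistically.

:func:`fixture_panel` draws a panel covering these ranges with a Latin
hypercube so even small panels span the parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import dendropy
import numpy as np
from scipy.stats import qmc

from .alignment import SpeciesParams
from .trees import read_newick

__all__ = [
    "SyntheticSpecies",
    "random_species",
    "yule_tree",
    "rescale_depth",
    "mean_root_to_tip",
    "unresolved_variant",
    "fixture_panel",
]

N_RANGE = (13, 55)
GC_RANGE = (0.25, 0.70)
KAPPA_RANGE = (1.0, 4.0)
DIVERGENCE_RANGE = (0.005, 0.05)  # mean root-to-tip depth, subs/site (log-uniform)
DNDS_RANGE = (0.04, 0.4)  # log-uniform covariate label


@dataclass(frozen=True)
class SyntheticSpecies:
    """One generated species: tree, simulation parameters, covariates."""

    species_id: str
    tree: dendropy.Tree
    params: SpeciesParams
    divergence: float
    dnds: float
    seed: int

    @property
    def n(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())


def yule_tree(n: int, rng: np.random.Generator, birth_rate: float = 1.0) -> dendropy.Tree:
    """Ultrametric pure-birth tree on ``n`` tips via exponential waiting
    times; all branch lengths strictly positive."""
    if n < 3:
        raise ValueError("need at least 3 tips")
    # lineage bookkeeping: each active lineage records its birth time
    next_label = [0]

    class _N:
        __slots__ = ("label", "children", "length", "birth")

        def __init__(self, birth):
            self.label = None
            self.children = []
            self.length = 0.0
            self.birth = birth

    t = 0.0
    root = _N(0.0)
    active = [_N(0.0), _N(0.0)]
    root.children = active[:]
    while len(active) < n:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        parent = active[k]
        parent.length = t - parent.birth
        kids = [_N(t), _N(t)]
        parent.children = kids
        active[k] = kids[0]
        active.append(kids[1])
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for i, leaf in enumerate(active):
        leaf.length = t - leaf.birth
        leaf.label = f"t{i + 1}"

    def to_newick(node):
        if not node.children:
            return f"{node.label}:{node.length:.17g}"
        inner = ",".join(to_newick(c) for c in node.children)
        return f"({inner}):{node.length:.17g}"

    return read_newick("(" + ",".join(to_newick(c) for c in root.children) + ");")


def mean_root_to_tip(tree: dendropy.Tree) -> float:
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    return float(np.mean(depths))


def rescale_depth(tree: dendropy.Tree, target: float) -> dendropy.Tree:
    """Scale every branch so the mean root-to-tip depth equals ``target``
    exactly (in-place; returns the tree)."""
    cur = mean_root_to_tip(tree)
    if cur <= 0:
        raise ValueError("tree has zero depth")
    f = target / cur
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= f
    return tree


def random_species(
    seed: int,
    n: Optional[int] = None,
    gc: Optional[float] = None,
    kappa: Optional[float] = None,
    codon_rates: Optional[tuple] = None,
    divergence: Optional[float] = None,
    dnds: Optional[float] = None,
    length: int = 100_000,
    min_internal_branch: Optional[float] = None,
    species_id: Optional[str] = None,
) -> SyntheticSpecies:
    """Draw one synthetic species; any field can be overridden.

    ``min_internal_branch`` raises short internal branches to a floor after
    depth rescaling — handy to guarantee a resolvable topology.  Overrides
    violating the declared ranges (n outside 13-55, nonpositive divergence)
    raise.
    """
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(N_RANGE[0], N_RANGE[1] + 1))
    if not N_RANGE[0] <= n <= N_RANGE[1]:
        raise ValueError(f"n must lie in {N_RANGE}")
    if gc is None:
        gc = float(rng.uniform(*GC_RANGE))
    if kappa is None:
        kappa = float(rng.uniform(*KAPPA_RANGE))
    if divergence is None:
        divergence = float(np.exp(rng.uniform(*np.log(DIVERGENCE_RANGE))))
    if divergence <= 0:
        raise ValueError("divergence must be positive")
    if dnds is None:
        dnds = float(np.exp(rng.uniform(*np.log(DNDS_RANGE))))
    if codon_rates is None:
        # third position fastest, first >= second (typical coding pattern)
        r2 = float(rng.uniform(0.35, 0.6))
        r1 = r2 * float(rng.uniform(1.0, 1.4))
        r3 = 3.0 - r1 - r2
        codon_rates = (r1, r2, r3)
    tree = rescale_depth(yule_tree(n, rng), divergence)
    if min_internal_branch is not None:
        for node in tree.preorder_node_iter():
            if node is tree.seed_node or node.is_leaf():
                continue
            if node.edge.length < min_internal_branch:
                node.edge.length = min_internal_branch
    params = SpeciesParams(gc=gc, kappa=kappa, codon_rates=codon_rates, length=length)
    return SyntheticSpecies(
        species_id=species_id or f"synth{seed}",
        tree=tree,
        params=params,
        divergence=divergence,
        dnds=dnds,
        seed=seed,
    )


def unresolved_variant(
    species: SyntheticSpecies, epsilon: float, fraction: float = 0.5
) -> SyntheticSpecies:
    """Copy of a species with a fraction of its internal branches shrunk to
    ``epsilon``, emulating poorly resolved trees.

    The shrunk branches are the shortest internal ones (deterministic);
    ``epsilon`` at or above a branch's length leaves it unchanged.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    tree = species.tree.clone(depth=1)
    internal = [
        node for node in tree.preorder_node_iter()
        if node is not tree.seed_node and not node.is_leaf()
    ]
    internal.sort(key=lambda nd: nd.edge.length)
    k = int(round(fraction * len(internal)))
    for node in internal[:k]:
        node.edge.length = min(node.edge.length, epsilon)
    return replace(species, tree=tree)


def fixture_panel(n_species: int, seed: int) -> list[SyntheticSpecies]:
    """Deterministic panel spanning the parameter ranges by Latin hypercube
    over (gc, kappa, log divergence, n, log dN/dS)."""
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    sampler = qmc.LatinHypercube(d=4, seed=seed)
    u = sampler.random(n_species)
    # taxon counts on an even grid across the declared range (distinct for
    # panels up to the range width), continuous parameters Latin-hypercubed
    n_values = np.unique(np.round(np.linspace(*N_RANGE, n_species)).astype(int)) \
        if n_species > 1 else np.array([N_RANGE[0]])
    if n_values.size < n_species:  # panels wider than the range: allow repeats
        n_values = np.round(np.linspace(*N_RANGE, n_species)).astype(int)
    panel = []
    for i in range(n_species):
        gc = GC_RANGE[0] + u[i, 0] * (GC_RANGE[1] - GC_RANGE[0])
        kappa = KAPPA_RANGE[0] + u[i, 1] * (KAPPA_RANGE[1] - KAPPA_RANGE[0])
        divergence = float(
            np.exp(np.log(DIVERGENCE_RANGE[0])
                   + u[i, 2] * np.log(DIVERGENCE_RANGE[1] / DIVERGENCE_RANGE[0]))
        )
        n = int(n_values[i])
        dnds = float(
            np.exp(np.log(DNDS_RANGE[0])
                   + u[i, 3] * np.log(DNDS_RANGE[1] / DNDS_RANGE[0]))
        )
        sub_seed = int(np.random.default_rng([seed, i]).integers(0, 2**31 - 1))
        panel.append(
            random_species(
                seed=sub_seed, n=min(n, N_RANGE[1]), gc=gc, kappa=kappa,
                divergence=divergence, dnds=dnds, species_id=f"panel{seed}_{i}",
            )
        )
    return panel
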