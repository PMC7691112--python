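"""Forward-in-time core-genome evolution with homologous recombination.

The model evolves a 100 kb-scale nucleotide alignment along a given
phylogeny.  A random root genome is drawn at the requested GC content;
branch lengths (expected substitutions per site) define both the
mutational input and the time axis.  The tree is cut at every node depth
into intervals of contemporaneous branch segments; within each interval
the lineages alive evolve *simultaneously*: every lineage's substitution
and recombination events are pooled into one globally shuffled queue and
applied sequentially, so a recipient can receive alleles a donor itself
just acquired.

Per lineage segment of duration ``l`` (subs/site) on a genome of ``L``
sites:

* substitutions ~ Poisson(l * L); each picks a site with probability
  proportional to its codon-position rate, then replaces the current base
  by a transition with probability kappa/(kappa+2) and by each
  transversion with probability 1/(kappa+2) (K80 convention);
* recombination events ~ Poisson(rho * l * L), rho being events per
  substitution; each picks a uniform tract start, a tract length from a
  geometric law with mean delta (support >= 1, truncated at the sequence
  end, realized length recorded), a donor uniformly among the *other*
  lineages alive, counts the donor/recipient differences inside the tract
  and then overwrites the recipient's tract with the donor's.  Events with
  no eligible donor are discarded and not counted.

Accounting yields the effective recombination rate r/m = rho * delta * nu
with nu the per-site polymorphism density inside realized tracts; the
identity r/m = (events/substitutions) x (mean realized tract) x nu holds
exactly by construction (see :func:`measure_rm`).

The substitution process is base-symmetric: GC content enters through the
root genome only and erodes toward 0.5 over long trees — a deliberate
model limitation, acceptable at intra-species divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

from .alignment import Alignment, SpeciesParams
from .trees import leaf_labels

__all__ = [
    "SimConfig",
    "RecombinationEvent",
    "SimResult",
    "root_sequence",
    "time_segments",
    "evolve",
    "measure_rm",
]

_DEPTH_DECIMALS = 12  # depths are sums of branch lengths; round to dedupe


@dataclass(frozen=True)
class SimConfig:
    """Inputs of one simulation run.

    rho: recombination events per substitution; delta: mean tract length
    (bp, geometric); rng_seed is mandatory — every run is reproducible.
    """

    tree: dendropy.Tree
    params: SpeciesParams
    rho: float = 0.0
    delta: float = 100.0
    rng_seed: Optional[int] = None

    def __post_init__(self):
        if self.rng_seed is None:
            raise ValueError("rng_seed is required: simulations must be reproducible")
        if not np.isfinite(self.rho) or self.rho < 0:
            raise ValueError("rho must be finite and non-negative")
        if self.delta < 1:
            raise ValueError("delta must be >= 1 bp")


@dataclass(frozen=True)
class RecombinationEvent:
    """One homologous-recombination (gene-conversion) event.

    ``depth`` is the start of the time interval (subs/site from the root)
    in which the event occurred; ``alleles_transferred`` counts sites where
    donor and recipient differed inside the tract before copying."""

    depth: float
    donor: str
    recipient: str
    start: int
    tract_length: int
    alleles_transferred: int


@dataclass(frozen=True)
class SimResult:
    """Simulated leaf alignment plus full event accounting."""

    alignment: Alignment
    events: tuple[RecombinationEvent, ...]
    m_realized: int
    n_events: int
    r_total: int
    tract_bp_total: int
    ti_realized: int = 0  # transitions among the applied substitutions
    root_seq: np.ndarray = field(repr=False, default=None)
    rng_seed: Optional[int] = None

    @property
    def nu(self) -> float:
        """Per-site polymorphism density within realized tracts."""
        return self.r_total / self.tract_bp_total if self.tract_bp_total else 0.0

    @property
    def rm(self) -> float:
        """Effective recombination rate r/m."""
        return self.r_total / self.m_realized if self.m_realized else 0.0

    @property
    def rho_m(self) -> float:
        """Realized events-per-substitution rate."""
        return self.n_events / self.m_realized if self.m_realized else 0.0

    @property
    def delta_realized(self) -> float:
        """Mean realized (truncation-aware) tract length."""
        return self.tract_bp_total / self.n_events if self.n_events else 0.0


def root_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. root genome: P(G) = P(C) = gc/2, P(A) = P(T) = (1-gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _node_ids(tree: dendropy.Tree) -> dict:
    ids = {}
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            ids[node] = node.taxon.label
        else:
            ids[node] = f"node{k}"
            k += 1
    return ids


def _depths(tree: dendropy.Tree) -> dict:
    depths = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        depths[node] = round(depths[node.parent_node] + bl, _DEPTH_DECIMALS)
    return depths


def time_segments(tree: dendropy.Tree):
    """Cut the tree into intervals of contemporaneous branch segments.

    Depth = cumulative branch length from the root.  Breakpoints sit at
    every distinct node depth; within an interval ``[d0, d1)`` the set of
    lineages alive (edges, named by their child node) is constant: an edge
    is alive on [depth(parent), depth(child)).  Returns an ordered list of
    ``(d0, d1, frozenset of lineage ids)`` partitioning [0, max depth).
    """
    ids = _node_ids(tree)
    depths = _depths(tree)
    points = sorted(set(depths.values()))
    segments = []
    for d0, d1 in zip(points[:-1], points[1:]):
        alive = frozenset(
            ids[node]
            for node in tree.preorder_node_iter()
            if node is not tree.seed_node
            and depths[node.parent_node] <= d0
            and depths[node] >= d1
        )
        segments.append((d0, d1, alive))
    return segments


_TV_CHOICE = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)
# transversion targets per current base (A->C/T, C->A/G, G->C/T, T->A/G)


def evolve(config: SimConfig) -> SimResult:
    """Run one forward simulation; see the module docstring for the model."""
    tree = config.tree
    params = config.params
    if sum(1 for _ in tree.leaf_node_iter()) < 3:
        raise ValueError("tree must have at least 3 leaves")
    L = params.length
    kappa = params.kappa
    p_ti = kappa / (kappa + 2.0)
    rng = np.random.default_rng(config.rng_seed)

    ids = _node_ids(tree)
    depths = _depths(tree)
    root = tree.seed_node
    root_seq = root_sequence(L, params.gc, rng)

    # per-site weights for substitution placement (codon-position rates)
    w = np.asarray(params.codon_rates, dtype=float)[np.arange(L) % 3]
    cumw = np.cumsum(w)
    W = cumw[-1]

    # children of each node, looked up by depth where they spawn
    spawn_at: dict[float, list] = {}
    for node in tree.preorder_node_iter():
        spawn_at.setdefault(depths[node], []).append(node)

    current: dict[str, np.ndarray] = {}  # lineage id -> evolving sequence
    parent_of: dict[str, str] = {}
    finished: dict[str, np.ndarray] = {}

    def spawn(node, seq):
        for child in node.child_nodes():
            current[ids[child]] = seq.copy()
            parent_of[ids[child]] = ids[node]

    spawn(root, root_seq)

    events: list[RecombinationEvent] = []
    m_realized = 0
    ti_realized = 0
    n_events = 0
    r_total = 0
    tract_bp_total = 0

    for d0, d1, alive in time_segments(tree):
        # close lineages ending at d0 and spawn their children
        for node in spawn_at.get(d0, []):
            if node is root:
                continue
            nid = ids[node]
            if nid in current:
                seq = current.pop(nid)
                finished[nid] = seq
                spawn(node, seq)
        lineages = sorted(alive)
        ell = d1 - d0
        n_alive = len(lineages)
        mean_sub = ell * L
        n_sub = rng.poisson(mean_sub, size=n_alive)
        n_rec = (
            rng.poisson(config.rho * mean_sub, size=n_alive)
            if config.rho > 0
            else np.zeros(n_alive, dtype=np.int64)
        )
        total_sub = int(n_sub.sum())
        total_rec = int(n_rec.sum())
        if total_sub + total_rec == 0:
            continue
        # one pooled, globally shuffled event queue for the interval
        owner = np.concatenate(
            [np.repeat(np.arange(n_alive), n_sub), np.repeat(np.arange(n_alive), n_rec)]
        )
        is_rec = np.concatenate(
            [np.zeros(total_sub, dtype=bool), np.ones(total_rec, dtype=bool)]
        )
        order = rng.permutation(total_sub + total_rec)
        owner = owner[order]
        is_rec = is_rec[order]

        # bulk random draws, consumed in queue order
        u_site = rng.random(total_sub) * W
        u_type = rng.random(total_sub)
        u_tv = rng.integers(0, 2, size=total_sub)
        if total_rec:
            u_start = rng.integers(0, L, size=total_rec)
            u_len = rng.geometric(1.0 / config.delta, size=total_rec)
            u_donor = rng.integers(0, max(n_alive - 1, 1), size=total_rec)
        seqs = [current[lin] for lin in lineages]
        ks = kr = 0
        for idx in range(owner.size):
            li = owner[idx]
            if not is_rec[idx]:
                site = int(np.searchsorted(cumw, u_site[ks], side="right"))
                if site >= L:  # guard against float edge at cumw[-1]
                    site = L - 1
                seq = seqs[li]
                base = seq[site]
                if u_type[ks] < p_ti:
                    seq[site] = base ^ 2  # A<->G, C<->T
                    ti_realized += 1
                else:
                    seq[site] = _TV_CHOICE[base, u_tv[ks]]
                m_realized += 1
                ks += 1
            else:
                if n_alive < 2:
                    kr += 1  # no eligible donor: discard, not counted
                    continue
                di = int(u_donor[kr])
                if di >= li:
                    di += 1
                start = int(u_start[kr])
                end = min(start + int(u_len[kr]), L)
                rec_seq = seqs[li]
                don_seq = seqs[di]
                diffs = int(np.count_nonzero(don_seq[start:end] != rec_seq[start:end]))
                rec_seq[start:end] = don_seq[start:end]
                realized = end - start
                n_events += 1
                r_total += diffs
                tract_bp_total += realized
                events.append(
                    RecombinationEvent(
                        depth=d0,
                        donor=lineages[di],
                        recipient=lineages[li],
                        start=start,
                        tract_length=realized,
                        alleles_transferred=diffs,
                    )
                )
                kr += 1

    # close lineages ending at the final breakpoint (the deepest leaves)
    for nid, seq in current.items():
        finished[nid] = seq
    labels = tuple(sorted(leaf_labels(tree)))
    data = np.vstack([finished[lab] for lab in labels])
    return SimResult(
        alignment=Alignment(labels, data),
        events=tuple(events),
        m_realized=m_realized,
        n_events=n_events,
        r_total=r_total,
        tract_bp_total=tract_bp_total,
        ti_realized=ti_realized,
        root_seq=root_seq,
        rng_seed=config.rng_seed,
    )


def measure_rm(result: SimResult) -> tuple[float, float, float]:
    """(r/m, nu, rho_m) from a simulation's event accounting.

    r/m = r_total / m_realized; nu = r_total / total realized tract bp;
    rho_m = n_events / m_realized.  The bookkeeping identity
    r/m = rho_m x delta_realized x nu holds exactly.
    """
    if result.m_realized == 0:
        raise ValueError("no substitutions realized; r/m undefined")
    return result.rm, result.nu, result.rho_m
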