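"""Tree inference from alignments: distances, BIONJ, bootstrap, ML adapter.

Distance trees are built by BIONJ (Gascuel 1997): neighbor-joining
agglomeration in which the distance update for a merged pair is
variance-weighted, ``d(u,k) = lam*d(i,k) + (1-lam)*d(j,k) - lam*b_i -
(1-lam)*b_j`` with ``lam`` chosen to minimise the variance of the new
distances.  Pairwise distances default to the JC69 correction
``-(3/4) ln(1 - 4p/3)`` of the p-distance; saturated pairs (p >= 0.74)
are capped at the p = 0.74 value with a logged warning so the builder
stays runnable on pathological replicates.

Bootstrap supports follow the classical recipe: resample alignment
columns with replacement to the original length, rebuild, and score each
nontrivial bipartition of the point tree by the percentage of replicates
containing it.  Replicate RNG streams are indexed by replicate number, so
supports do not depend on taxon order.

Maximum-likelihood inference is delegated to an external program through
:func:`external_ml_adapter` (GTR + Gamma; FastTree by default).  No ML
math is re-implemented; every pipeline stage accepts either builder.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import dendropy
import numpy as np

from .alignment import Alignment, write_fasta
from .trees import MISSING, bipartitions, leaf_labels, read_newick

__all__ = [
    "DistanceMatrix",
    "SupportedTree",
    "MLBackendUnavailableError",
    "MLOutputError",
    "distance_matrix",
    "bionj_tree",
    "bionj_from_alignment",
    "bootstrap_supports",
    "external_ml_adapter",
    "to_phylip",
]

logger = logging.getLogger(__name__)

_P_CAP = 0.74
_JC_CAP = -0.75 * np.log(1.0 - 4.0 * _P_CAP / 3.0)


class MLBackendUnavailableError(RuntimeError):
    """The external ML program is not on the execution path."""


class MLOutputError(RuntimeError):
    """The external ML program produced unparseable output."""


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal, subs/site

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.isfinite(v).all():
            raise ValueError("distances must be finite")
        if (np.abs(np.diag(v)) > 1e-12).any():
            raise ValueError("diagonal must be zero")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")


def distance_matrix(alignment: Alignment, correction: str = "JC69") -> DistanceMatrix:
    """Pairwise evolutionary distances over unambiguous shared sites.

    ``correction='raw'`` gives the p-distance; ``'JC69'`` applies the
    Jukes-Cantor multiple-hit correction, capped at p = 0.74.
    """
    if correction not in ("raw", "JC69"):
        raise ValueError("correction must be 'raw' or 'JC69'")
    if alignment.n_sequences < 3:
        raise ValueError("need at least 3 sequences")
    data = alignment.data
    n = alignment.n_sequences
    valid = data < MISSING
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = valid[i] & valid[j]
            total = int(comparable.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable sites between {alignment.labels[i]!r} "
                    f"and {alignment.labels[j]!r}"
                )
            p = int((comparable & (data[i] != data[j])).sum()) / total
            if correction == "raw":
                dist = p
            else:
                if p >= _P_CAP:
                    logger.warning(
                        "saturated distance (p=%.3f) between %s and %s capped at p=%.2f",
                        p, alignment.labels[i], alignment.labels[j], _P_CAP,
                    )
                    dist = _JC_CAP
                else:
                    dist = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(alignment.labels, d)


def _newick_of(children, lengths, node, parent=None) -> str:
    kids = [c for c in children.get(node, []) if c != parent]
    if not kids:
        return f"{node}:{lengths[node]:.17g}"
    inner = ",".join(_newick_of(children, lengths, c, node) for c in kids)
    return f"({inner}):{lengths.get(node, 0.0):.17g}"


def bionj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """BIONJ agglomeration of a distance matrix into an unrooted tree.

    Ties in the Q criterion are broken by the lowest (row, column) label
    pair, making the builder deterministic; negative branch-length
    estimates are clamped to 0.  Consistent on additive matrices (exact
    topology and branch lengths).
    """
    n0 = len(matrix.labels)
    if n0 < 3:
        raise ValueError("need at least 3 taxa")
    D = matrix.values.copy()
    V = D.copy()  # BIONJ variance estimates, initialised to the distances
    names: list = list(matrix.labels)
    children: dict = {}
    lengths: dict = {}
    next_id = 0

    while len(names) > 3:
        n = len(names)
        S = D.sum(axis=1)
        Q = (n - 2) * D - S[:, None] - S[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (row, col) pair on ties
        i, j = divmod(int(np.argmin(Q)), n)
        if i > j:
            i, j = j, i
        d_ij = D[i, j]
        b_i = 0.5 * d_ij + (S[i] - S[j]) / (2.0 * (n - 2))
        b_j = d_ij - b_i
        b_i, b_j = max(b_i, 0.0), max(b_j, 0.0)
        mask = np.ones(n, dtype=bool)
        mask[[i, j]] = False
        if V[i, j] > 1e-12:
            lam = 0.5 + (V[j, mask] - V[i, mask]).sum() / (2.0 * (n - 2) * V[i, j])
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        new_d = lam * D[i, mask] + (1 - lam) * D[j, mask] - lam * b_i - (1 - lam) * b_j
        new_d = np.maximum(new_d, 0.0)
        new_v = lam * V[i, mask] + (1 - lam) * V[j, mask] - lam * (1 - lam) * V[i, j]
        new_v = np.maximum(new_v, 0.0)

        node = f"__u{next_id}"
        next_id += 1
        children[node] = [names[i], names[j]]
        lengths[names[i]] = b_i
        lengths[names[j]] = b_j

        keep = [k for k in range(n) if k not in (i, j)]
        D = D[np.ix_(keep, keep)]
        V = V[np.ix_(keep, keep)]
        D = np.pad(D, ((0, 1), (0, 1)))
        V = np.pad(V, ((0, 1), (0, 1)))
        D[-1, :-1] = D[:-1, -1] = new_d
        V[-1, :-1] = V[:-1, -1] = new_v
        names = [names[k] for k in keep] + [node]

    # join the last three nodes at a central (unrooted) vertex
    a, b, c = names
    root = f"__u{next_id}"
    children[root] = [a, b, c]
    lengths[a] = max(0.5 * (D[0, 1] + D[0, 2] - D[1, 2]), 0.0)
    lengths[b] = max(0.5 * (D[0, 1] + D[1, 2] - D[0, 2]), 0.0)
    lengths[c] = max(0.5 * (D[0, 2] + D[1, 2] - D[0, 1]), 0.0)
    newick = "(" + ",".join(_newick_of(children, lengths, x, root) for x in (a, b, c)) + ");"
    return read_newick(newick)


def bionj_from_alignment(alignment: Alignment, correction: str = "JC69") -> dendropy.Tree:
    """Convenience builder: JC69 distances then BIONJ."""
    return bionj_tree(distance_matrix(alignment, correction=correction))


@dataclass(frozen=True)
class SupportedTree:
    """A point tree with bootstrap support (percent of replicates) for each
    of its nontrivial bipartitions."""

    tree: dendropy.Tree
    supports: dict  # frozenset bipartition -> percent in [0, 100]
    n_replicates: int

    @property
    def mean_support(self) -> float:
        """Unweighted mean support over the point tree's nontrivial
        bipartitions (the 'average bootstrap support' of a tree)."""
        if not self.supports:
            raise ValueError("tree has no nontrivial bipartitions")
        return float(np.mean(list(self.supports.values())))

    def newick_with_supports(self) -> str:
        """Newick string with supports as internal-node labels."""
        tree = self.tree.clone(depth=1)
        full = frozenset(leaf_labels(tree))
        anchor = min(full)
        sets = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                sets[node] = frozenset((node.taxon.label,))
            else:
                acc = frozenset()
                for ch in node.child_nodes():
                    acc |= sets[ch]
                sets[node] = acc
                side = acc if anchor not in acc else full - acc
                if side in self.supports:
                    node.label = f"{self.supports[side]:g}"
        return tree.as_string(schema="newick", suppress_rooting=True).strip()


def bootstrap_supports(
    alignment: Alignment,
    builder: Optional[Callable[[Alignment], dendropy.Tree]] = None,
    replicates: int = 100,
    rng_seed: int = 0,
) -> SupportedTree:
    """Column-resampling bootstrap supports for the point tree.

    Each replicate resamples columns with replacement to the original
    length (RNG stream indexed by replicate number) and rebuilds with
    ``builder`` (default: JC69 + BIONJ).  A builder failure aborts with
    the replicate index and seed.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if builder is None:
        builder = bionj_from_alignment
    point = builder(alignment)
    point_bips = bipartitions(point)
    counts = {bip: 0 for bip in point_bips}
    L = alignment.length
    for rep in range(replicates):
        rng = np.random.default_rng([rng_seed, rep])
        cols = rng.integers(0, L, size=L)
        try:
            rep_tree = builder(alignment.take_sites(cols))
        except Exception as exc:
            raise RuntimeError(
                f"builder failed on bootstrap replicate {rep} (seed {rng_seed})"
            ) from exc
        rep_bips = bipartitions(rep_tree)
        for bip in counts:
            if bip in rep_bips:
                counts[bip] += 1
    supports = {bip: 100.0 * c / replicates for bip, c in counts.items()}
    return SupportedTree(tree=point, supports=supports, n_replicates=replicates)


def external_ml_adapter(
    alignment: Alignment,
    workdir=None,
    program: str = "fasttree",
    extra_args: tuple = (),
) -> dendropy.Tree:
    """Maximum-likelihood tree via an external program (GTR + Gamma).

    Writes the alignment to FASTA, invokes the program (FastTree by
    default: ``-nt -gtr -gamma``), and parses the Newick it emits.  Raises
    :class:`MLBackendUnavailableError` when the program is absent — an
    error distinct from inference failure — and :class:`MLOutputError`
    with the captured output when its result cannot be parsed.
    """
    exe = shutil.which(program)
    if exe is None:
        raise MLBackendUnavailableError(
            f"ML backend unavailable: {program!r} not found on PATH"
        )
    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    wd = Path(ctx.name if ctx else workdir)
    try:
        fasta = wd / "aln.fasta"
        write_fasta(alignment, fasta)
        args = [exe, "-nt", "-gtr", "-gamma", "-quiet", "-nosupport", "-seed", "1"]
        args += list(extra_args) + [str(fasta)]
        proc = subprocess.run(args, capture_output=True, text=True)
        if proc.returncode != 0:
            raise MLOutputError(
                f"{program} exited with status {proc.returncode}:\n{proc.stderr}"
            )
        try:
            return read_newick(proc.stdout)
        except Exception as exc:
            raise MLOutputError(
                f"could not parse {program} output as Newick:\n{proc.stdout[:500]}"
            ) from exc
    finally:
        if ctx:
            ctx.cleanup()


def to_phylip(matrix: DistanceMatrix) -> str:
    """PHYLIP-format serialisation of a distance matrix."""
    lines = [f"{len(matrix.labels)}"]
    for label, row in zip(matrix.labels, matrix.values):
        lines.append(label + "  " + "  ".join(f"{x:.8f}" for x in row))
    return "\n".join(lines) + "\n"
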