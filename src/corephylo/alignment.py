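"""Core-genome alignments and estimation of simulation parameters.

A core-genome concatenate is held as an :class:`Alignment`: ordered labels
plus an ``(n_sequences, length)`` array of nucleotide codes (A=0, C=1,
G=2, T=3; anything else, e.g. N or a gap, is the missing code 4).  The
codon frame starts at alignment position 1 (gene concatenates in frame).

From a real concatenate the simulator needs four quantities, bundled as
:class:`SpeciesParams`:

* GC content of the unambiguous bases,
* transition/transversion ratio ``kappa``,
* relative substitution rates of the three codon positions, estimated
  from the fraction of polymorphic columns at each position and
  normalised to mean 1,
* alignment length.

``kappa`` conventions: :func:`estimate_kappa` counts pairwise transition
and transversion differences.  Their raw ratio (the default) is the
observed ti/tv count ratio; with ``rate_ratio=True`` it is doubled,
giving the K80-style rate ratio (transition rate over each single
transversion rate) that the simulator consumes — at low divergence a
process with rate ratio kappa produces ti/tv difference counts of
kappa/2, since there are two transversion targets per site.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import MISSING, NUCLEOTIDES

__all__ = [
    "Alignment",
    "SpeciesParams",
    "RaggedAlignmentError",
    "ZeroTransversionsError",
    "read_fasta",
    "write_fasta",
    "estimate_gc",
    "estimate_kappa",
    "estimate_codon_rates",
    "estimate_species_params",
    "branch_sub_mean",
]

_ENCODE = np.full(256, MISSING, dtype=np.uint8)
for _i, _c in enumerate(NUCLEOTIDES):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


class RaggedAlignmentError(ValueError):
    """Sequences of unequal length in one alignment."""


class ZeroTransversionsError(ValueError):
    """No transversion differences observed; kappa undefined.  Re-run with
    ``pseudocount=True`` to add one pseudo-transversion."""


def encode_sequence(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class Alignment:
    """Label-ordered, equal-length nucleotide alignment (codes, see module
    docstring)."""

    labels: tuple[str, ...]
    data: np.ndarray  # (n, L) uint8

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.uint8)
        object.__setattr__(self, "data", data)
        if data.ndim != 2 or data.shape[0] != len(self.labels):
            raise ValueError("data must be (n_labels, length)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")

    @classmethod
    def from_strings(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        labels, rows = [], []
        length = None
        for label, seq in records:
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise RaggedAlignmentError(
                    f"record {label!r} has length {len(seq)}, expected {length}"
                )
            labels.append(label)
            rows.append(encode_sequence(seq))
        if not labels:
            raise ValueError("empty alignment")
        return cls(tuple(labels), np.vstack(rows))

    @property
    def n_sequences(self) -> int:
        return self.data.shape[0]

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def sequence(self, label: str) -> str:
        return decode_sequence(self.data[self.labels.index(label)])

    def take_sites(self, indices) -> "Alignment":
        return Alignment(self.labels, self.data[:, indices])


def read_fasta(path) -> Alignment:
    """Read a multi-FASTA alignment; order-preserving."""
    return Alignment.from_strings(
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    )


def write_fasta(alignment: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(decode_sequence(row)), id=label, description="")
        for label, row in zip(alignment.labels, alignment.data)
    ]
    SeqIO.write(records, str(path), "fasta")


def estimate_gc(alignment: Alignment) -> float:
    """(G + C) / (A + C + G + T), missing symbols excluded."""
    data = alignment.data
    unambig = int((data < MISSING).sum())
    if unambig == 0:
        raise ValueError("alignment contains no unambiguous bases")
    gc = int(((data == 1) | (data == 2)).sum())
    return gc / unambig


def _pairwise_titv(alignment: Alignment) -> tuple[int, int]:
    data = alignment.data
    ti = tv = 0
    for i, j in combinations(range(alignment.n_sequences), 2):
        a, b = data[i], data[j]
        diff = (a != b) & (a < MISSING) & (b < MISSING)
        # purines (A=0, G=2) are even codes, pyrimidines (C=1, T=3) odd:
        # a difference within one parity class is a transition
        same_parity = (a & 1) == (b & 1)
        t = int((diff & same_parity).sum())
        ti += t
        tv += int(diff.sum()) - t
    return ti, tv


def estimate_kappa(
    alignment: Alignment, pseudocount: bool = False, rate_ratio: bool = False
) -> float:
    """Transition/transversion ratio from pairwise difference counts.

    Default: raw ti/tv count ratio over all sequence pairs and sites (no
    multiple-hit correction; appropriate at intra-species divergence).
    ``rate_ratio=True`` returns twice that, the K80 rate ratio.  With no
    transversions observed, raises unless ``pseudocount=True`` (adds 1).
    """
    if alignment.n_sequences < 2:
        raise ValueError("need at least two sequences")
    ti, tv = _pairwise_titv(alignment)
    if tv == 0:
        if not pseudocount:
            raise ZeroTransversionsError(
                "no transversion differences observed; pass pseudocount=True "
                "to add a single pseudo-transversion"
            )
        tv = 1
    ratio = ti / tv
    return 2.0 * ratio if rate_ratio else ratio


def estimate_codon_rates(alignment: Alignment) -> tuple[float, float, float]:
    """Relative substitution rates of codon positions 1..3.

    p_i = fraction of polymorphic columns (>= 2 distinct unambiguous
    bases, singletons included) among scorable columns at codon position
    i; rates are 3 p_i / (p1 + p2 + p3).  All-monomorphic input returns
    (1, 1, 1).  A trailing partial codon is ignored.
    """
    if alignment.length < 3:
        raise ValueError("alignment shorter than one codon")
    L = alignment.length - alignment.length % 3
    data = alignment.data[:, :L]
    p = []
    for pos in range(3):
        cols = data[:, pos::3]
        present = np.zeros((4, cols.shape[1]), dtype=bool)
        for b in range(4):
            present[b] = (cols == b).any(axis=0)
        n_states = present.sum(axis=0)
        scorable = n_states >= 1
        if not scorable.any():
            p.append(np.nan)
            continue
        p.append(float((n_states >= 2).sum() / scorable.sum()))
    p = np.array(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("a codon position has no scorable columns")
    total = p.sum()
    if total == 0:
        return (1.0, 1.0, 1.0)
    r = 3.0 * p / total
    return (float(r[0]), float(r[1]), float(r[2]))


@dataclass(frozen=True)
class SpeciesParams:
    """Simulation inputs estimated from one species' core genome.

    ``kappa`` is the K80 rate ratio consumed by the simulator;
    ``codon_rates`` are normalised so their mean is 1.
    """

    gc: float
    kappa: float
    codon_rates: tuple[float, float, float] = (1.0, 1.0, 1.0)
    length: int = 100_000

    def __post_init__(self):
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must lie in [0, 1]")
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")
        if self.length < 1:
            raise ValueError("length must be a positive integer")
        r = np.asarray(self.codon_rates, dtype=float)
        if r.shape != (3,) or (r < 0).any():
            raise ValueError("codon_rates must be three non-negative numbers")
        if r.sum() == 0:
            raise ValueError("codon_rates cannot all be zero")
        r = 3.0 * r / r.sum()
        object.__setattr__(self, "codon_rates", (float(r[0]), float(r[1]), float(r[2])))


def estimate_species_params(alignment: Alignment, pseudocount: bool = True) -> SpeciesParams:
    """Bundle all simulation parameters estimated from one alignment."""
    return SpeciesParams(
        gc=estimate_gc(alignment),
        kappa=estimate_kappa(alignment, pseudocount=pseudocount, rate_ratio=True),
        codon_rates=estimate_codon_rates(alignment),
        length=alignment.length,
    )


def branch_sub_mean(tree: dendropy.Tree, length: int) -> dict:
    """Expected substitution count per branch: m = branch length (subs/site)
    x alignment length, as a real-valued Poisson mean.  Keyed by the edge's
    head (child) node."""
    if length < 0:
        raise ValueError("alignment length must be non-negative")
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length
        if bl is None:
            bl = 0.0
        if bl < 0:
            raise ValueError("negative branch length")
        out[node] = bl * length
    return out
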