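"""Robustness sweep over recombination rates and cross-species statistics.

:func:`run_grid` runs one simulate -> infer -> score cycle per requested
recombination rate rho (the study default grid is rho = 0..10 in steps of
0.1) and records both the configured rho and the realized effective rate
r/m, so degradation curves can be drawn on either axis.  Statistical
helpers provide Spearman rank correlation (exact permutation p-value for
n <= 9, t-approximation beyond) and the Wilcoxon signed-rank test (exact
tie-aware distribution for up to 25 non-zero pairs, normal approximation
with continuity and tie correction beyond).  :func:`correlate_robustness`
assembles the cross-species table: mean topology score against bootstrap
support of the true tree, mean branch length, dN/dS, GC content and taxon
count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Callable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .alignment import SpeciesParams
from .inference import bionj_from_alignment, bootstrap_supports
from .simulate import SimConfig, evolve
from .trees import tts

__all__ = [
    "GridRow",
    "SpeciesRecord",
    "run_grid",
    "spearman",
    "wilcoxon_signed_rank",
    "correlate_robustness",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridRow:
    """One cell of the rho grid: configured rate, realized rates, topology
    score and (optionally) mean bootstrap support.  A failed cell keeps its
    rho and seed and carries the error message instead of values."""

    rho: float
    rm: Optional[float]
    rho_m: Optional[float]
    tts: Optional[float]
    mean_bootstrap: Optional[float]
    builder: str
    seed: int
    error: Optional[str] = None


@dataclass(frozen=True)
class SpeciesRecord:
    """Per-species analysis row feeding the correlation analyses."""

    species: str
    n: int
    gc: float
    mean_branch_length: float
    mean_tts: float
    dnds: Optional[float] = None
    mean_bootstrap_real: Optional[float] = None

    def __post_init__(self):
        if self.n < 4:
            raise ValueError("need at least 4 taxa")
        if self.dnds is not None and not self.dnds > 0:
            raise ValueError("dnds must be positive when present")


def run_grid(
    tree: dendropy.Tree,
    params: SpeciesParams,
    rho_values: Sequence[float],
    seed: int,
    builder: Optional[Callable] = None,
    builder_name: str = "bionj",
    delta: float = 100.0,
    bootstrap_replicates: int = 0,
) -> list[GridRow]:
    """One simulate -> infer -> score cycle per rho value.

    Each cell derives its own RNG stream from (seed, cell index), so
    duplicate rho values with distinct indices give distinct rows.  A
    failing cell is recorded as missing (with its error), never fatal.
    """
    if len(rho_values) == 0:
        raise ValueError("rho_values must be non-empty")
    if any(r < 0 for r in rho_values):
        raise ValueError("rho values must be non-negative")
    if builder is None:
        builder = bionj_from_alignment
    rows = []
    for idx, rho in enumerate(rho_values):
        cell_seed = int(np.random.default_rng([seed, idx]).integers(0, 2**31 - 1))
        try:
            result = evolve(
                SimConfig(tree=tree, params=params, rho=float(rho), delta=delta,
                          rng_seed=cell_seed)
            )
            inferred = builder(result.alignment)
            score = tts(tree, inferred).score
            mean_bs = None
            if bootstrap_replicates:
                mean_bs = bootstrap_supports(
                    result.alignment, builder=builder,
                    replicates=bootstrap_replicates, rng_seed=cell_seed,
                ).mean_support
            rows.append(GridRow(rho=float(rho), rm=result.rm, rho_m=result.rho_m,
                                tts=score, mean_bootstrap=mean_bs,
                                builder=builder_name, seed=cell_seed))
        except Exception as exc:  # record, do not abort the sweep
            logger.warning("grid cell rho=%s failed: %s", rho, exc)
            rows.append(GridRow(rho=float(rho), rm=None, rho_m=None, tts=None,
                                mean_bootstrap=None, builder=builder_name,
                                seed=cell_seed, error=str(exc)))
    return rows


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks on ties.

    p-value: exact permutation distribution for n <= 9, two-sided
    t-approximation beyond.  Constant input raises (correlation
    undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= 9:
        perms = np.array(list(permutations(range(n))))
        ry_perm = ry[perms]  # (n!, n)
        rxc = rx - rx.mean()
        ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        rhos = (ryc @ rxc) / np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def _wilcoxon_exact_two_sided(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided p for W+ given doubled (integer) signed ranks, by
    dynamic-programming convolution over the 2^n sign assignments."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(w2))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(paired_a: Sequence[float], paired_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; tie-aware exact distribution for up to
    25 non-zero pairs, else normal approximation with continuity and tie
    corrections.  All-zero differences give p = 1 with a warning.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need two equal-length vectors")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        logger.warning("all paired differences are zero; returning p = 1")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        return _wilcoxon_exact_two_sided(np.round(2 * ranks), 2 * w_plus)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / math.sqrt(sigma2)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


#: covariates tested against mean topology score, in output order
_COVARIATES = ("mean_bootstrap_real", "mean_branch_length", "dnds", "gc", "n")


def correlate_robustness(records: Sequence[SpeciesRecord]) -> pd.DataFrame:
    """Spearman correlations of per-species mean topology score against
    each covariate; covariates absent (or constant) across records are
    skipped with a log notice.  Missing values are excluded pairwise."""
    if len(records) < 5:
        raise ValueError("need at least 5 species records")
    df = pd.DataFrame([vars(r) for r in records])
    rows = []
    for cov in _COVARIATES:
        sub = df[["mean_tts", cov]].dropna()
        if len(sub) < 5:
            logger.info("covariate %s absent for too many records; skipped", cov)
            continue
        try:
            rho, p = spearman(sub[cov].to_numpy(float), sub["mean_tts"].to_numpy())
        except ValueError as exc:
            logger.info("covariate %s skipped: %s", cov, exc)
            continue
        rows.append({"covariate": cov, "spearman_rho": rho, "p_value": p, "n": len(sub)})
    return pd.DataFrame(rows, columns=["covariate", "spearman_rho", "p_value", "n"])
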