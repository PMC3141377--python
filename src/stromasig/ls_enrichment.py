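"""The LS gene-set statistic and its random-gene-set resampling null.

For a set of N genes with univariate differential-expression p-values
p_1..p_N, the LS statistic is mean(-ln p_i); the summary statistic is
its negation, mean(ln p_i).  Significance is assessed competitively:
R random sets of N genes are drawn uniformly without replacement from
the full universe of analyzed genes, and the LS P value is the fraction
of random sets whose summary statistic is less than or equal to the
observed one (smaller summary = more enriched; ties count as extreme,
which makes the test conservative and pins the degenerate whole-universe
case at P = 1).  An LS P of 0 is displayed as "< 1/R".

An exhaustive enumerator over all C(U, N) subsets is provided for small
universes; it is the exact reference the Monte-Carlo path is validated
against.
"""
from __future__ import annotations

import itertools
import math
import warnings
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .diffexp import P_FLOOR, univariate_de
from .errors import AnalysisError
from .io_formats import ExpressionMatrix, GeneSet

SIGNIFICANCE_LEVEL = 0.01


@dataclass(frozen=True)
class LSResult:
    """Outcome of one gene-set comparison."""

    set_name: str
    n: int                    # set size after intersection with the universe
    ls_statistic: float       # mean -ln(p) over members
    summary_statistic: float  # mean ln(p) (= -ls_statistic)
    r: int                    # number of random sets sampled
    ls_p: float
    seed: int
    n_unmapped: int = 0       # members that fell outside the universe

    @property
    def significant(self) -> bool:
        return self.ls_p < SIGNIFICANCE_LEVEL

    @property
    def display_p(self) -> str:
        if self.ls_p == 0.0:
            return f"< {1.0 / self.r:g}"
        return f"{self.ls_p:g}"


def floor_pvalues(p) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), P_FLOOR, 1.0)


def ls_statistic(p_values) -> float:
    """Mean negative natural log of the member p-values."""
    arr = np.asarray(list(p_values) if not isinstance(p_values, np.ndarray)
                     else p_values, dtype=float)
    if arr.size == 0:
        raise AnalysisError("ls_statistic needs at least one p-value")
    if (arr <= 0.0).any() or (arr > 1.0).any():
        raise AnalysisError("p-values must lie in (0, 1]; floor them upstream")
    return float(-np.log(arr).mean())


def summary_statistic(p_values) -> float:
    """Mean natural log of the member p-values (negated LS statistic)."""
    return -ls_statistic(p_values)


def _as_series(universe_p) -> pd.Series:
    if isinstance(universe_p, pd.Series):
        ser = universe_p.astype(float)
    else:
        ser = pd.Series(dict(universe_p), dtype=float)
    if ser.empty:
        raise AnalysisError("empty gene universe")
    if ser.index.duplicated().any():
        raise AnalysisError("duplicate gene ids in universe")
    if (ser <= 0.0).any() or (ser > 1.0).any():
        raise AnalysisError("universe p-values must lie in (0, 1]")
    return ser


def _random_set_summaries(lnp: np.ndarray, n: int, r: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Summary statistics of r uniform random n-subsets of the universe."""
    universe = lnp.size
    out = np.empty(r)
    # random keys + argpartition gives uniform subsets without replacement;
    # chunked to bound memory at ~few tens of MB
    chunk = max(1, 4_000_000 // universe)
    done = 0
    while done < r:
        k = min(chunk, r - done)
        keys = rng.random((k, universe))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        # ascending index order fixes the summation order, so a random
        # draw of the observed set ties it exactly in floating point
        idx = np.sort(idx, axis=1)
        out[done:done + k] = lnp[idx].mean(axis=1)
        done += k
    return out


def ls_pvalue(members, universe_p, R: int = 100_000, seed: int = 0,
              set_name: Optional[str] = None) -> LSResult:
    """Monte-Carlo LS P value of a gene set against a p-value universe.

    ``members`` is a GeneSet or iterable of gene ids; ``universe_p`` maps
    every analyzed gene to its (pre-floored) univariate p-value.  Members
    outside the universe are counted in ``n_unmapped`` and excluded from
    N.  Identical seed implies identical ls_p.
    """
    if isinstance(members, GeneSet):
        name = set_name if set_name is not None else members.name
        member_ids = set(members.members)
    else:
        name = set_name if set_name is not None else "<unnamed>"
        member_ids = set(members)
    if R < 1:
        raise AnalysisError("R must be >= 1")
    ser = _as_series(universe_p)
    inter = member_ids & set(ser.index)
    n_unmapped = len(member_ids) - len(inter)
    if not inter:
        raise AnalysisError(
            f"gene set {name!r} has no overlap with the analyzed universe")
    lnp = np.log(ser.to_numpy())
    positions = np.sort(ser.index.get_indexer(sorted(inter)))
    obs = lnp[positions].mean()
    n = len(inter)
    if n == ser.size:
        warnings.warn(
            f"gene set {name!r} equals the whole universe; LS P is 1 by "
            f"construction", stacklevel=2)
        p = 1.0
    else:
        rng = np.random.default_rng(seed)
        rand = _random_set_summaries(lnp, n, R, rng)
        p = float(np.count_nonzero(rand <= obs) / R)
    return LSResult(set_name=name, n=n, ls_statistic=float(-obs),
                    summary_statistic=float(obs), r=R, ls_p=p,
                    seed=int(seed), n_unmapped=n_unmapped)


def ls_pvalue_exact(members, universe_p,
                    set_name: Optional[str] = None,
                    max_subsets: int = 2_000_000) -> LSResult:
    """Exact LS P by exhaustive enumeration of all C(U, N) subsets.

    Only feasible for small universes; raises when the subset count
    exceeds ``max_subsets``.
    """
    if isinstance(members, GeneSet):
        name = set_name if set_name is not None else members.name
        member_ids = set(members.members)
    else:
        name = set_name if set_name is not None else "<unnamed>"
        member_ids = set(members)
    ser = _as_series(universe_p)
    inter = member_ids & set(ser.index)
    if not inter:
        raise AnalysisError(
            f"gene set {name!r} has no overlap with the analyzed universe")
    lnp = np.log(ser.to_numpy())
    n = len(inter)
    total = math.comb(ser.size, n)
    if total > max_subsets:
        raise AnalysisError(
            f"C({ser.size},{n}) = {total} subsets exceed max_subsets")
    positions = np.sort(ser.index.get_indexer(sorted(inter)))
    obs = lnp[positions].mean()
    hits = sum(1 for combo in itertools.combinations(range(ser.size), n)
               if lnp[list(combo)].mean() <= obs)
    return LSResult(set_name=name, n=n, ls_statistic=float(-obs),
                    summary_statistic=float(obs), r=total,
                    ls_p=hits / total, seed=-1,
                    n_unmapped=len(member_ids) - n)


def child_seed(master_seed: int, *parts: str) -> int:
    """Deterministic per-cell seed: master XOR a CRC of the cell labels.

    Keeps every derived seed below 2^31 and makes each (method, set)
    cell's resampling stream independent of which other sets are run.
    """
    crc = zlib.crc32("\x1f".join(parts).encode("utf-8"))
    return (int(master_seed) ^ crc) & 0x7FFFFFFF


def geneset_comparison(matrix: ExpressionMatrix, sets: Iterable[GeneSet],
                       R: int = 100_000, seed: int = 0,
                       test: str = "welch") -> list:
    """Run univariate DE once, then the LS test for every gene set.

    The universe is the full set of genes on the matrix.  Each set gets
    its own deterministic child seed, so results do not depend on which
    other sets are evaluated in the same call.
    """
    sets = list(sets)
    if not sets:
        raise AnalysisError("no gene sets supplied")
    de = univariate_de(matrix, test=test)
    universe = de["p_value"]
    return [
        ls_pvalue(gs, universe, R=R, seed=child_seed(seed, gs.name))
        for gs in sets
    ]


def member_report(gene_set: GeneSet, de_macro: pd.DataFrame,
                  de_micro: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Partition set members by which dissection method detects them.

    A member is ``both`` / ``micro_only`` / ``macro_only`` / ``neither``
    according to whether its univariate p falls below ``alpha`` in each
    method's DE table; members missing from either table are reported as
    ``unmapped`` rather than dropped.  Directions come from the
    fold-change sign.
    """
    if not 0.0 < alpha < 1.0:
        raise AnalysisError("alpha must lie in (0, 1)")
    rows = []
    for gene in sorted(gene_set.members):
        in_macro = gene in de_macro.index
        in_micro = gene in de_micro.index
        if not (in_macro and in_micro):
            rows.append({"gene": gene, "category": "unmapped",
                         "macro_p": np.nan, "micro_p": np.nan,
                         "macro_direction": "", "micro_direction": ""})
            continue
        mp = float(de_macro.at[gene, "p_value"])
        up = float(de_micro.at[gene, "p_value"])
        hit_macro, hit_micro = mp < alpha, up < alpha
        if hit_macro and hit_micro:
            cat = "both"
        elif hit_micro:
            cat = "micro_only"
        elif hit_macro:
            cat = "macro_only"
        else:
            cat = "neither"
        rows.append({"gene": gene, "category": cat,
                     "macro_p": mp, "micro_p": up,
                     "macro_direction": de_macro.at[gene, "direction"],
                     "micro_direction": de_micro.at[gene, "direction"]})
    return pd.DataFrame(rows).set_index("gene")
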