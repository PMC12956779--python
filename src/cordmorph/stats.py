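"""Nonparametric statistics for repeated segmental measurements.

Friedman's rank test (tie-corrected, with an optional exact/permutation p),
Dunn-type pairwise post-hoc comparisons with Bonferroni correction, and
mean ± SD summaries.  Blocks are subjects; treatments are spinal segments
or anatomical sides.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata

#: permutation budget switch: full enumeration when (k!)^n is at most this
EXACT_ENUMERATION_LIMIT = 1_000_000
#: Monte-Carlo permutations when enumeration is infeasible
N_MONTE_CARLO = 100_000
#: fixed seed for the Monte-Carlo permutation stream (reproducibility)
MC_SEED = 20240915


@dataclass
class RepeatedMeasures:
    """n_blocks × k_treatments matrix of paired measurements."""

    values: np.ndarray
    block_ids: list[str] = field(default_factory=list)
    treatment_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D (blocks × treatments) matrix")
        n, k = self.values.shape
        if k < 2:
            raise ValueError("k<2: at least two treatments required")
        if n < 2:
            raise ValueError("at least two blocks required")
        if np.isnan(self.values).any():
            raise ValueError("missing cells: apply listwise deletion upstream")
        if not self.block_ids:
            self.block_ids = [f"block{i}" for i in range(n)]
        if not self.treatment_ids:
            self.treatment_ids = [f"t{j}" for j in range(k)]
        if len(self.block_ids) != n or len(self.treatment_ids) != k:
            raise ValueError("id lists must match the matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p_value: float
    rank_sums: np.ndarray
    p_exact: float | None = None
    exact_method: str | None = None  # 'enumeration' | 'monte-carlo'


@dataclass
class PairwiseResult:
    pairs: list[tuple[str, str]]
    z_statistics: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray


def _ranks(values: np.ndarray) -> np.ndarray:
    """Within-block mid-ranks."""
    return rankdata(values, axis=1)


def _chi2_from_rank_sums(rank_sums: np.ndarray, n: int, k: int,
                         denom: float) -> np.ndarray:
    """Tie-corrected Friedman statistic from treatment rank sums.

    chi2 = (k−1) · Σ_j (R_j − n(k+1)/2)² / (Σ_ij r_ij² − n·k(k+1)²/4);
    the denominator is permutation-invariant and passed in precomputed.
    """
    dev = rank_sums - n * (k + 1) / 2.0
    num = (k - 1) * np.sum(np.square(dev), axis=-1)
    return num / denom


def friedman_test(data: RepeatedMeasures, exact: bool = False) -> FriedmanResult:
    """Friedman's test with mid-rank ties and the tie-corrected statistic.

    With ``exact=True`` a permutation p-value is added: all (k!)^n
    within-block orderings when that count is at most 10^6, otherwise 10^5
    Monte-Carlo permutations with a fixed seed.
    """
    n, k = data.n, data.k
    r = _ranks(data.values)
    rank_sums = r.sum(axis=0)
    denom = float(np.sum(np.square(r)) - n * k * (k + 1) ** 2 / 4.0)
    if denom <= 1e-12:
        # every block fully tied: no evidence either way
        return FriedmanResult(chi2=0.0, df=k - 1, p_value=1.0,
                              rank_sums=rank_sums,
                              p_exact=1.0 if exact else None,
                              exact_method="degenerate" if exact else None)
    chi2_obs = float(_chi2_from_rank_sums(rank_sums, n, k, denom))
    p_asym = float(chi2_dist.sf(chi2_obs, k - 1))
    result = FriedmanResult(chi2=chi2_obs, df=k - 1, p_value=p_asym,
                            rank_sums=rank_sums)
    if not exact:
        return result

    n_orderings = math.factorial(k) ** n
    if n_orderings <= EXACT_ENUMERATION_LIMIT:
        perms = np.array(list(itertools.permutations(range(k))))
        sums = r[0][perms]                      # (k!, k)
        for b in range(1, n):
            nxt = r[b][perms]                   # (k!, k)
            sums = (sums[:, None, :] + nxt[None, :, :]).reshape(-1, k)
        stats = _chi2_from_rank_sums(sums, n, k, denom)
        result.p_exact = float(np.mean(stats >= chi2_obs - 1e-12))
        result.exact_method = "enumeration"
    else:
        rng = np.random.default_rng(MC_SEED)
        arr = np.tile(r, (N_MONTE_CARLO, 1, 1))
        rng.permuted(arr, axis=2, out=arr)
        sums = arr.sum(axis=1)
        stats = _chi2_from_rank_sums(sums, n, k, denom)
        hits = int(np.sum(stats >= chi2_obs - 1e-12))
        result.p_exact = (hits + 1) / (N_MONTE_CARLO + 1)
        result.exact_method = "monte-carlo"
    return result


def pairwise_posthoc(data: RepeatedMeasures) -> PairwiseResult:
    """Dunn-type pairwise z-tests on Friedman rank sums, Bonferroni-adjusted.

    z = (R_a − R_b) / sqrt(n·k(k+1)/6); two-sided normal p; the Bonferroni
    factor is m = k(k−1)/2 and adjusted p is capped at 1.
    """
    n, k = data.n, data.k
    if k < 3:
        raise ValueError("k >= 3 required: with k=2 the omnibus test is the "
                         "pairwise test")
    rank_sums = _ranks(data.values).sum(axis=0)
    se = math.sqrt(n * k * (k + 1) / 6.0)
    pairs: list[tuple[str, str]] = []
    zs: list[float] = []
    for a, b in itertools.combinations(range(k), 2):
        pairs.append((data.treatment_ids[a], data.treatment_ids[b]))
        zs.append((rank_sums[a] - rank_sums[b]) / se)
    z_arr = np.asarray(zs)
    p_raw = 2.0 * norm.sf(np.abs(z_arr))
    m = k * (k - 1) // 2
    p_adj = np.minimum(1.0, p_raw * m)
    return PairwiseResult(pairs=pairs, z_statistics=z_arr, p_raw=p_raw,
                          p_adjusted=p_adj)


def segment_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD and n per (segment, quantity, side_or_view).

    Intended for stacked morphometry tables from repeated runs/subjects;
    SD uses the n−1 denominator and is missing when n = 1.
    """
    df = table.dropna(subset=["value"])
    grouped = df.groupby(["segment", "quantity", "side_or_view"], sort=False)
    out = grouped["value"].agg(mean="mean", sd=lambda v: v.std(ddof=1),
                               n="count").reset_index()
    out.loc[out["n"] < 2, "sd"] = float("nan")
    return out
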