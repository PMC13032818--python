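"""Uncertainty quantification: linear-fit CI, auxiliary-population
bootstrap, and the SNP-block dependence analysis.

Two distinct 95% error bars accompany the admixture proportion:

* ``delta1`` — from the dispersion of the regression points around the
  through-origin fit (a t-interval on the slope);
* ``delta2`` — from a bootstrap over the *auxiliary populations*: the m
  labels are resampled with replacement, the pair set re-enumerated from
  the resampled multiset (self-pairs and degenerate pairs skipped), and
  the statistic recomputed per replicate.  The interval is the percentile
  interval of the replicate distribution.

The post-JL angle gets the same bootstrap error bar; the pre-JL angle does
not depend on the auxiliaries and carries no error estimate.

The block analysis probes how the estimates depend on the dimension of the
frequency space: for each block size L it evaluates alpha and both angles
on random-origin blocks of L adjacent retained SNPs and reports mean and
one standard deviation per size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .genotype_io import FrequencyTable
from .geometry import (
    AdmixtureModel,
    F4PrimePoints,
    MIN_AUX_BOOTSTRAP,
    alpha_jl,
    angle_post_jl,
    angle_pre_jl,
    regression_points,
)

__all__ = [
    "BootstrapSpec",
    "BlockAnalysisResult",
    "fit_ci",
    "bootstrap_aux",
    "block_analysis",
]

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class BootstrapSpec:
    """Auxiliary-population bootstrap settings (>= 100 replicates; the
    model must provide at least 8 auxiliaries)."""

    n_replicates: int = 1000
    seed: int = 0
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_replicates < 100:
            raise ValueError("bootstrap needs at least 100 replicates")
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must be in (0, 1)")


def fit_ci(points: F4PrimePoints, level: float = 0.95) -> float:
    """95% (by default) half-width for the through-origin slope from the
    dispersion of the regression points.

    SE^2 = sum (y - alpha x)^2 / ((n - 1) sum x^2) with n points; the
    half-width is t_{n-1, 1-(1-level)/2} * SE.
    """
    n = points.n
    if n < 3:
        raise ValueError(f"need at least 3 regression points, got {n}")
    a = alpha_jl(points)
    resid = points.y_coords - a * points.x_coords
    sxx = float(points.x_coords @ points.x_coords)
    se = np.sqrt(float(resid @ resid) / ((n - 1) * sxx))
    t = stats.t.ppf(1.0 - (1.0 - level) / 2.0, df=n - 1)
    return float(t * se)


# ---------------------------------------------------------------------------
# Auxiliary-population bootstrap
# ---------------------------------------------------------------------------

class _PairCache:
    """Per-label-pair f2 and f4 values over the auxiliary set, precomputed
    so each bootstrap replicate costs O(m^2) instead of O(s m^2)."""

    def __init__(self, ft: FrequencyTable, model: AdmixtureModel):
        self.s = ft.s
        aux = list(model.aux)
        self.m = len(aux)
        P = np.column_stack([np.asarray(ft.column(p)) for p in aux])
        gram = P.T @ P
        sq = np.diag(gram)
        # f2[i, j] = mean over SNPs of (p_i - p_j)^2
        self.f2 = (sq[:, None] + sq[None, :] - 2.0 * gram) / self.s

        def projections(u: str, v: str) -> np.ndarray:
            d = np.asarray(ft.column(u)) - np.asarray(ft.column(v))
            return (d @ P) / self.s

        # f4(u,v;i,j) = c[i] - c[j] for the relevant top pairs
        self.c_ab = projections(model.a, model.b)
        self.c_xb = projections(model.x, model.b)
        self.c_xa = projections(model.x, model.a)

    def _pair_indices(self, labels_idx: np.ndarray) -> list[tuple[int, int]]:
        """Valid (i, j) auxiliary index pairs from a resampled label multiset:
        positions k < l, skipping identical labels and degenerate pairs."""
        out = []
        for k, l in combinations(range(len(labels_idx)), 2):
            i, j = int(labels_idx[k]), int(labels_idx[l])
            if i == j or self.f2[i, j] <= 0.0:
                continue
            out.append((i, j))
        return out

    def statistic(self, pairs: list[tuple[int, int]], which: str) -> float | None:
        """alpha or varphi on an explicit pair set; None when undefined."""
        if not pairs:
            return None
        ii = np.fromiter((p[0] for p in pairs), dtype=int)
        jj = np.fromiter((p[1] for p in pairs), dtype=int)
        w = self.s / self.f2[ii, jj]  # f4' = s * f4 / f2 per pair
        if which == "alpha":
            x = (self.c_ab[ii] - self.c_ab[jj]) * w
            y = (self.c_xb[ii] - self.c_xb[jj]) * w
            denom = float(x @ x)
            if denom == 0.0:
                return None
            return float(x @ y) / denom
        if which == "varphi":
            u = (self.c_xa[ii] - self.c_xa[jj]) * w
            v = (self.c_xb[ii] - self.c_xb[jj]) * w
            uu, vv = float(u @ u), float(v @ v)
            if uu == 0.0 or vv == 0.0:
                return None
            c = float(u @ v) / np.sqrt(uu * vv)
            return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
        raise ValueError(f"unknown statistic {which!r}")


def bootstrap_aux(
    ft: FrequencyTable,
    model: AdmixtureModel,
    spec: BootstrapSpec,
    statistic: str = "alpha",
) -> tuple[float, float]:
    """Bootstrap over auxiliary populations.

    Returns ``(point, delta2)``: the full-data statistic and the half-width
    of the percentile interval at ``spec.level`` over ``spec.n_replicates``
    label resamples.  A replicate whose resampled multiset yields fewer
    than 2 distinct usable auxiliaries (or an undefined statistic) is
    redrawn, up to a bounded number of retries.
    """
    if model.m < MIN_AUX_BOOTSTRAP:
        raise ValueError(
            f"bootstrap requires at least {MIN_AUX_BOOTSTRAP} auxiliary "
            f"populations, got {model.m}"
        )
    if statistic not in ("alpha", "varphi"):
        raise ValueError("statistic must be 'alpha' or 'varphi'")

    cache = _PairCache(ft, model)
    full_pairs = cache._pair_indices(np.arange(cache.m))
    point = cache.statistic(full_pairs, statistic)
    if point is None:
        raise ValueError("statistic undefined on the full auxiliary set")

    rng = np.random.default_rng(spec.seed)
    values = np.empty(spec.n_replicates)
    for r in range(spec.n_replicates):
        val = None
        for _ in range(_MAX_REDRAWS):
            idx = rng.integers(0, cache.m, size=cache.m)
            if len(set(idx.tolist())) < 2:
                continue
            val = cache.statistic(cache._pair_indices(idx), statistic)
            if val is not None:
                break
        if val is None:
            raise RuntimeError(
                "could not draw a usable bootstrap replicate after "
                f"{_MAX_REDRAWS} attempts"
            )
        values[r] = val

    tail = 100.0 * (1.0 - spec.level) / 2.0
    lo, hi = np.percentile(values, [tail, 100.0 - tail])
    return point, float((hi - lo) / 2.0)


# ---------------------------------------------------------------------------
# SNP-block analysis
# ---------------------------------------------------------------------------

@dataclass
class BlockAnalysisResult:
    """Mean and one SD of alpha, phi and varphi over random-origin blocks
    of adjacent SNPs, per block size."""

    block_sizes: list[int]
    n_blocks: int
    seed: int
    means: dict[str, list[float]] = field(default_factory=dict)
    sds: dict[str, list[float]] = field(default_factory=dict)

    STATS = ("alpha", "phi", "varphi")

    def to_tsv(self) -> str:
        """Tab-separated export: size, statistic, mean, sd."""
        lines = ["size\tstat\tmean\tsd"]
        for k, size in enumerate(self.block_sizes):
            for stat in self.STATS:
                lines.append(
                    f"{size}\t{stat}\t{self.means[stat][k]:.6g}"
                    f"\t{self.sds[stat][k]:.6g}"
                )
        return "\n".join(lines) + "\n"


def block_analysis(
    ft: FrequencyTable,
    model: AdmixtureModel,
    block_sizes: list[int],
    n_blocks: int = 20,
    seed: int = 0,
) -> BlockAnalysisResult:
    """Evaluate alpha, phi and varphi on random-origin blocks of adjacent
    retained SNPs, for each requested block size.

    Origins are uniform on [0, s - L] and drawn with replacement; blocks do
    not wrap around the SNP sequence.  SDs use the population convention,
    so a size equal to ``s`` (a single possible block) reports SD 0 and
    means equal to the full-data values.
    """
    s = ft.s
    for size in block_sizes:
        if not 0 < size <= s:
            raise ValueError(f"block size {size} outside (0, {s}]")
    rng = np.random.default_rng(seed)
    res = BlockAnalysisResult(list(block_sizes), n_blocks, seed)
    for stat in BlockAnalysisResult.STATS:
        res.means[stat], res.sds[stat] = [], []
    for size in block_sizes:
        vals = {stat: np.empty(n_blocks) for stat in BlockAnalysisResult.STATS}
        origins = rng.integers(0, s - size + 1, size=n_blocks)
        for b, origin in enumerate(origins):
            sub = ft.subset_snps(slice(int(origin), int(origin) + size))
            pts = regression_points(sub, model)
            vals["alpha"][b] = alpha_jl(pts)
            vals["phi"][b] = angle_pre_jl(sub, model)
            vals["varphi"][b] = angle_post_jl(sub, model)
        for stat in BlockAnalysisResult.STATS:
            res.means[stat].append(float(vals[stat].mean()))
            res.sds[stat].append(float(vals[stat].std(ddof=0)))
    return res
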