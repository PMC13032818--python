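"""Two-way admixture estimation in allele-frequency space.

An admixed population ``x`` is modelled as a point on the segment between
two sources, ``p_x = alpha * p_a + (1 - alpha) * p_b``.  Sampled proxies
have drifted away from that alignment, so the overdetermined linear system
is first projected onto the subspace spanned by difference vectors of
pairs of m auxiliary populations — a Johnson-Lindenstrauss (JL) style
dimensional reduction that attenuates the population-private drift — and
then solved by least squares.  Concretely, alpha is the through-origin
slope of the regression of f4'(x, b; i, j) on f4'(a, b; i, j) over the
m(m-1)/2 auxiliary pairs:

    alpha = sum_{i<j} f4'(x,b;i,j) f4'(a,b;i,j) / sum_{i<j} f4'(a,b;i,j)^2

Model quality is read off two angles at the admixed vertex:

* phi (pre-JL): the angle between (a - x) and (b - x) computed directly
  from proxy frequencies, cos phi = f3(a,b;x) / sqrt(f2(a,x) f2(b,x)).
  180 deg marks the start of the mixing process; phi > 90 deg is the
  classical admixture condition (equivalent to f3 < 0).
* varphi (post-JL): the same angle after JL projection,
  cos varphi = sum f4'(x,a)f4'(x,b) / sqrt(sum f4'(x,a)^2 sum f4'(x,b)^2).
  varphi > phi means the projection removed drift; varphi < phi rules the
  model out.

Angles are reported in degrees; cosines are clamped to [-1, 1] (rounding
can push them past the boundary by ~1e-16, never more).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fstats import AuxPair, DegeneratePairError, aux_pairs, f2, f3, f4
from .genotype_io import FrequencyTable

__all__ = [
    "AdmixtureModel",
    "F4PrimePoints",
    "F4Ratio",
    "AdmixtureResult",
    "regression_points",
    "alpha_jl",
    "angle_pre_jl",
    "angle_post_jl",
    "f4_ratio_distribution",
    "in_range_mean",
    "alpha_pre_jl",
    "f3_admixture_test",
    "rank_outlier_pairs",
    "analyze",
    "result_log",
]

MIN_AUX = 4
MIN_AUX_BOOTSTRAP = 8


@dataclass(frozen=True)
class AdmixtureModel:
    """A two-way admixture model: target ``x``, sources ``a`` and ``b``,
    plus the ordered list of m >= 4 auxiliary (outgroup) populations."""

    x: str
    a: str
    b: str
    aux: tuple[str, ...]

    def __init__(self, x: str, a: str, b: str, aux):
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "aux", tuple(aux))
        labels = [x, a, b, *self.aux]
        if len(set(labels)) != len(labels):
            raise ValueError("model populations must be distinct")
        if len(self.aux) < MIN_AUX:
            raise ValueError(
                f"need at least {MIN_AUX} auxiliary populations, "
                f"got {len(self.aux)}"
            )

    @property
    def m(self) -> int:
        return len(self.aux)

    def swapped(self) -> "AdmixtureModel":
        """The same model with the two source roles exchanged."""
        return AdmixtureModel(self.x, self.b, self.a, self.aux)


@dataclass
class F4PrimePoints:
    """The regression point cloud: one (f4'(a,b;i,j), f4'(x,b;i,j)) point
    per auxiliary pair i < j."""

    pairs: list[AuxPair]
    x_coords: np.ndarray
    y_coords: np.ndarray

    def __post_init__(self) -> None:
        self.x_coords = np.asarray(self.x_coords, dtype=float)
        self.y_coords = np.asarray(self.y_coords, dtype=float)
        if not (len(self.pairs) == self.x_coords.size == self.y_coords.size):
            raise ValueError("pairs and coordinate arrays must have equal length")
        if not (np.isfinite(self.x_coords).all() and np.isfinite(self.y_coords).all()):
            raise ValueError("non-finite regression point")

    @property
    def n(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class F4Ratio:
    """A single-pair admixture estimate f4(x,b;i,j) / f4(a,b;i,j).

    ``defined`` is False when the denominator vanishes; ``in_range`` when
    the ratio lies in the closed interval [0, 1] where an admixture
    proportion is meaningful.
    """

    pair: AuxPair
    ratio: float
    defined: bool

    @property
    def in_range(self) -> bool:
        return self.defined and 0.0 <= self.ratio <= 1.0


@dataclass
class AdmixtureResult:
    """Full numerical outcome of a two-way admixture analysis."""

    alpha: float
    delta1: float  # 95% half-width from the linear fit
    delta2: float | None  # 95% half-width, auxiliary bootstrap (None if off)
    phi_deg: float
    varphi_deg: float
    varphi_delta2: float | None
    f3_value: float
    alpha_pre: float
    f4ratio_mean_in_range: float
    s: int
    model: AdmixtureModel
    f4_ratios: list[F4Ratio] = field(default_factory=list, repr=False)
    points: F4PrimePoints | None = field(default=None, repr=False)

    @property
    def is_valid(self) -> bool:
        """Model passes both acceptance rules: alpha in [0, 1] and
        varphi > phi (drift reduced rather than amplified).

        The angle comparison uses a 1e-6 degree tolerance so the exactly
        collinear case (phi = varphi = 180 to rounding) counts as valid.
        """
        return (
            0.0 <= self.alpha <= 1.0
            and self.varphi_deg > self.phi_deg - 1e-6
        )


# ---------------------------------------------------------------------------
# Regression in the JL subspace
# ---------------------------------------------------------------------------

def _pair_f4prime(
    ft: FrequencyTable, top: tuple[str, str], pairs: list[AuxPair]
) -> np.ndarray:
    """Vector of f4'(top; i, j) over pairs, computed in one pass.

    f4(u,v;i,j) factorises as c_i - c_j with c_k = <p_u - p_v, p_k> / s,
    so the whole vector costs O(s * m) instead of O(s * m^2).
    """
    u, v = top
    d = ft.column(u) - ft.column(v)
    s = ft.s
    labels = sorted({lab for p in pairs for lab in p})
    proj = {lab: float(d @ ft.column(lab)) / s for lab in labels}
    sq = {lab: float(ft.column(lab) @ ft.column(lab)) for lab in labels}
    cross = {}
    out = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        if (i, j) not in cross:
            cross[(i, j)] = float(ft.column(i) @ ft.column(j))
        f2_ij = (sq[i] + sq[j] - 2.0 * cross[(i, j)]) / s
        if i == j or f2_ij <= 0.0:
            raise DegeneratePairError(i, j)
        out[k] = s * (proj[i] - proj[j]) / f2_ij
    return out


def regression_points(ft: FrequencyTable, model: AdmixtureModel) -> F4PrimePoints:
    """Build the per-pair point cloud {(f4'(a,b;i,j), f4'(x,b;i,j))}."""
    pairs = aux_pairs(list(model.aux))
    xs = _pair_f4prime(ft, (model.a, model.b), pairs)
    ys = _pair_f4prime(ft, (model.x, model.b), pairs)
    return F4PrimePoints(pairs, xs, ys)


def alpha_jl(points: F4PrimePoints) -> float:
    """The JL-projected admixture proportion: through-origin least-squares
    slope of the regression cloud."""
    denom = float(points.x_coords @ points.x_coords)
    if denom == 0.0:
        raise ValueError(
            "undefined slope: all f4'(a,b;i,j) vanish — the auxiliary set "
            "cannot distinguish the two sources"
        )
    return float(points.x_coords @ points.y_coords) / denom


# ---------------------------------------------------------------------------
# Angles at the admixed vertex
# ---------------------------------------------------------------------------

def _clamped_arccos_deg(c: float) -> float:
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def angle_pre_jl(ft: FrequencyTable, model: AdmixtureModel) -> float:
    """Pre-JL angle phi (degrees) at the admixed vertex, from raw proxies."""
    f2ax = f2(ft, model.a, model.x)
    f2bx = f2(ft, model.b, model.x)
    for (u, v), val in (((model.a, model.x), f2ax), ((model.b, model.x), f2bx)):
        if val <= 0.0:
            raise ValueError(
                f"cannot form the vertex angle: populations {u!r} and {v!r} "
                "coincide in frequency space (f2 = 0)"
            )
    c = f3(ft, model.a, model.b, model.x) / math.sqrt(f2ax * f2bx)
    return _clamped_arccos_deg(c)


def angle_post_jl(ft: FrequencyTable, model: AdmixtureModel) -> float:
    """Post-JL angle varphi (degrees): the vertex angle between the
    coordinate vectors f4'(x,a;.) and f4'(x,b;.) over auxiliary pairs."""
    pairs = aux_pairs(list(model.aux))
    u = _pair_f4prime(ft, (model.x, model.a), pairs)
    v = _pair_f4prime(ft, (model.x, model.b), pairs)
    uu, vv = float(u @ u), float(v @ v)
    if uu == 0.0 or vv == 0.0:
        blind = model.a if uu == 0.0 else model.b
        raise ValueError(
            f"auxiliary set is blind to the direction x - {blind}: "
            "all projected coordinates vanish"
        )
    return _clamped_arccos_deg(float(u @ v) / math.sqrt(uu * vv))


# ---------------------------------------------------------------------------
# Single-pair ratios, pre-JL proportion, f3 test, outliers
# ---------------------------------------------------------------------------

def f4_ratio_distribution(
    ft: FrequencyTable, model: AdmixtureModel
) -> list[F4Ratio]:
    """Per-pair f4-ratios f4(x,b;i,j)/f4(a,b;i,j) — the m = 2 special case
    of the slope formula, one estimate per auxiliary pair.

    Pairs with a vanishing denominator are reported with ``defined=False``,
    never silently dropped.
    """
    out = []
    for i, j in aux_pairs(list(model.aux)):
        den = f4(ft, model.a, model.b, i, j)
        num = f4(ft, model.x, model.b, i, j)
        if den == 0.0:
            out.append(F4Ratio((i, j), math.nan, False))
        else:
            out.append(F4Ratio((i, j), num / den, True))
    return out


def in_range_mean(ratios: list[F4Ratio]) -> float:
    """Unweighted mean of the defined ratios lying in [0, 1]; NaN if none."""
    vals = [r.ratio for r in ratios if r.in_range]
    return float(np.mean(vals)) if vals else math.nan


def alpha_pre_jl(ft: FrequencyTable, model: AdmixtureModel) -> float:
    """Admixture proportion without JL projection: the through-origin
    projection of (x - b) on (a - b) in raw frequency space.

    Drift on the target inflates |x - b| in directions only partially
    aligned with a - b, so this estimate is typically attenuated relative
    to the JL value on drifted data.
    """
    da = ft.column(model.a) - ft.column(model.b)
    dx = ft.column(model.x) - ft.column(model.b)
    denom = float(da @ da)
    if denom == 0.0:
        raise ValueError(
            f"sources {model.a!r} and {model.b!r} coincide in frequency space"
        )
    return float(dx @ da) / denom


def f3_admixture_test(
    ft: FrequencyTable, model: AdmixtureModel
) -> tuple[float, bool]:
    """The conventional admixture test: f3(a, b; x) and whether it is
    negative (the classical signal that x lies between a and b)."""
    val = f3(ft, model.a, model.b, model.x)
    return val, val < 0.0


def rank_outlier_pairs(
    points: F4PrimePoints, alpha: float, k: int
) -> list[tuple[AuxPair, float]]:
    """Top-k auxiliary pairs by absolute residual from the fitted line.

    Removing the auxiliary populations behind the worst residuals is the
    interactive refinement heuristic; this is its batch equivalent.
    Returns (pair, signed residual), largest |residual| first.
    """
    if k > points.n:
        raise ValueError(f"k={k} exceeds the number of pairs ({points.n})")
    resid = points.y_coords - alpha * points.x_coords
    order = np.argsort(-np.abs(resid), kind="stable")[:k]
    return [(points.pairs[int(t)], float(resid[int(t)])) for t in order]


# ---------------------------------------------------------------------------
# Orchestration and result log
# ---------------------------------------------------------------------------

def analyze(
    ft: FrequencyTable,
    model: AdmixtureModel,
    bootstrap=None,
) -> AdmixtureResult:
    """Run the full analysis: alpha with both error bars, both angles,
    f4-ratio summary, pre-JL proportion and the f3 test.

    ``bootstrap`` is a :class:`~admixgeo.uncertainty.BootstrapSpec` or None;
    with bootstrap enabled the model needs m >= 8 auxiliaries.
    """
    from .uncertainty import bootstrap_aux, fit_ci  # local: avoid cycle

    points = regression_points(ft, model)
    alpha = alpha_jl(points)
    delta1 = fit_ci(points)
    phi = angle_pre_jl(ft, model)
    varphi = angle_post_jl(ft, model)
    ratios = f4_ratio_distribution(ft, model)
    delta2 = varphi_d2 = None
    if bootstrap is not None:
        _, delta2 = bootstrap_aux(ft, model, bootstrap, "alpha")
        _, varphi_d2 = bootstrap_aux(ft, model, bootstrap, "varphi")
    return AdmixtureResult(
        alpha=alpha,
        delta1=delta1,
        delta2=delta2,
        phi_deg=phi,
        varphi_deg=varphi,
        varphi_delta2=varphi_d2,
        f3_value=f3(ft, model.a, model.b, model.x),
        alpha_pre=alpha_pre_jl(ft, model),
        f4ratio_mean_in_range=in_range_mean(ratios),
        s=ft.s,
        model=model,
        f4_ratios=ratios,
        points=points,
    )


def result_log(res: AdmixtureResult) -> str:
    """Plain-text results log: model, SNP count, estimates with error bars,
    angles, tidbits, and the verdict line."""
    m = res.model
    d2 = f" +- {res.delta2:.4f}" if res.delta2 is not None else ""
    vd2 = f" +- {res.varphi_delta2:.1f}" if res.varphi_delta2 is not None else ""
    lines = [
        f"model: {m.x} = alpha * {m.a} + (1 - alpha) * {m.b}",
        f"SNPs (effective): {res.s}",
        f"auxiliary populations ({m.m}): {' '.join(m.aux)}",
        f"alpha = {res.alpha:.4f} +- {res.delta1:.4f}{d2}",
        f"phi (pre-JL)  = {res.phi_deg:.1f} deg",
        f"varphi (post-JL) = {res.varphi_deg:.1f} deg{vd2}",
        "tidbits:",
        f"  pre-JL admixture proportion = {res.alpha_pre:.4f}",
        f"  mean of in-range f4-ratios  = {res.f4ratio_mean_in_range:.4f}",
        f"  f3 admixture test: f3(a,b;x) = {res.f3_value:.6g} "
        f"({'negative: admixture signal' if res.f3_value < 0 else 'non-negative'})",
    ]
    checks = [
        f"alpha in [0,1]: {'yes' if 0.0 <= res.alpha <= 1.0 else 'NO'}",
        f"varphi > phi: {'yes' if res.varphi_deg > res.phi_deg - 1e-6 else 'NO'}",
        f"f3 < 0: {'yes' if res.f3_value < 0 else 'no'}",
    ]
    if res.is_valid:
        verdict = "verdict: valid admixture model (" + "; ".join(checks) + ")"
    else:
        reasons = []
        if not 0.0 <= res.alpha <= 1.0:
            reasons.append("alpha outside [0,1]")
        if res.varphi_deg <= res.phi_deg - 1e-6:
            reasons.append("varphi < phi (projection did not reduce drift)")
        verdict = "verdict: REJECTED — " + "; ".join(reasons) + " (" + "; ".join(checks) + ")"
    lines.append(verdict)
    return "\n".join(lines) + "\n"
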