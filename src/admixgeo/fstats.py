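"""f-statistics on allele-frequency tables.

Populations are points in allele-frequency space (one axis per SNP).  The
statistics below are, up to the per-SNP mean, inner products of difference
vectors in that space:

* ``f2(a, b)``  — mean of ``(p_a - p_b)^2``: squared Euclidean distance.
* ``f3(a, b; x)`` — mean of ``(p_a - p_x)(p_b - p_x)``: the inner product
  of the two difference vectors meeting at vertex ``x``; a negative value
  is the conventional admixture signal.
* ``f4(a, b; i, j)`` — mean of ``(p_a - p_b)(p_i - p_j)``: the inner
  product of two difference directions.
* ``f4'(a, b; i, j) = s * f4(a, b; i, j) / f2(i, j)`` — f4 renormalised so
  each auxiliary-pair axis has unit squared length; ``s`` is the effective
  SNP count of the table.

All four use the per-SNP *mean* convention (division by ``s``); every
downstream ratio (the admixture slope, both angle cosines) is invariant to
that choice.  No finite-sample bias correction is applied: the geometric
formulation works with plain frequency vectors, a deliberate divergence
from f-statistics packages that subtract a p(1-p)/(n-1) term.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .genotype_io import FrequencyTable

__all__ = [
    "AuxPair",
    "FStatValue",
    "DegeneratePairError",
    "f2",
    "f3",
    "f4",
    "f4_prime",
    "aux_pairs",
    "fstat",
]

AuxPair = tuple[str, str]


class DegeneratePairError(ValueError):
    """An auxiliary pair with f2(i, j) = 0 cannot define a projection axis."""

    def __init__(self, i: str, j: str):
        super().__init__(
            f"degenerate auxiliary pair ({i}, {j}): f2 is zero "
            "(identical frequency columns)"
        )
        self.pair = (i, j)


@dataclass(frozen=True)
class FStatValue:
    """One computed f-statistic with its arguments and SNP count."""

    kind: str  # f2 | f3 | f4 | f4prime
    args: tuple[str, ...]
    value: float
    s: int

    def __str__(self) -> str:
        inner = ";".join(
            [",".join(self.args[:-2]), ",".join(self.args[-2:])]
        ) if self.kind in ("f3", "f4", "f4prime") else ",".join(self.args)
        return f"{self.kind}({inner}) = {self.value:.6g}  [s={self.s}]"


def f2(ft: FrequencyTable, a: str, b: str) -> float:
    """Mean squared frequency difference between populations ``a`` and ``b``."""
    d = ft.column(a) - ft.column(b)
    return float(np.mean(d * d))


def f3(ft: FrequencyTable, a: str, b: str, x: str) -> float:
    """Inner product of the difference vectors (a - x) and (b - x) at vertex x."""
    px = ft.column(x)
    return float(np.mean((ft.column(a) - px) * (ft.column(b) - px)))


def f4(ft: FrequencyTable, a: str, b: str, i: str, j: str) -> float:
    """Inner product of the difference directions (a - b) and (i - j)."""
    return float(
        np.mean((ft.column(a) - ft.column(b)) * (ft.column(i) - ft.column(j)))
    )


def f4_prime(ft: FrequencyTable, a: str, b: str, i: str, j: str) -> float:
    """Renormalised f4: ``s * f4(a, b; i, j) / f2(i, j)``.

    Raises
    ------
    DegeneratePairError
        If ``i == j`` or the two auxiliary columns are identical, so that
        f2(i, j) = 0 and the pair defines no direction.
    """
    if i == j:
        raise DegeneratePairError(i, j)
    denom = f2(ft, i, j)
    if denom <= 0.0:
        raise DegeneratePairError(i, j)
    return ft.s * f4(ft, a, b, i, j) / denom


def aux_pairs(aux: list[str]) -> list[AuxPair]:
    """All m(m-1)/2 unordered pairs (i, j), i before j, of the auxiliary list."""
    return list(combinations(aux, 2))


def fstat(ft: FrequencyTable, kind: str, *labels: str) -> FStatValue:
    """Dispatch by name; used by the command-line f-statistics subcommand."""
    arity = {"f2": 2, "f3": 3, "f4": 4, "f4prime": 4}
    if kind not in arity:
        raise ValueError(f"unknown statistic {kind!r}; choose from {sorted(arity)}")
    if len(labels) != arity[kind]:
        raise ValueError(f"{kind} takes {arity[kind]} population labels")
    func = {"f2": f2, "f3": f3, "f4": f4, "f4prime": f4_prime}[kind]
    return FStatValue(kind, tuple(labels), func(ft, *labels), ft.s)
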