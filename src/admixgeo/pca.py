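"""Population-level PCA in allele-frequency space.

Observations are populations (rows of the transposed frequency table), not
individuals; an admixture triplet tends to appear aligned in the first
components, which makes the projection a quick visual collinearity check
and a way to spot auxiliary populations behind regression outliers.  SNPs
are centred across the selected populations but not variance-scaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotype_io import FrequencyTable

__all__ = ["PCAResult", "pca_project"]


@dataclass
class PCAResult:
    """Population coordinates on the top principal components."""

    coordinates: np.ndarray  # (n_pops, n_components)
    explained_variance_fraction: np.ndarray
    populations: list[str]

    def to_tsv(self) -> str:
        """Tab-separated export: population then one column per component."""
        k = self.coordinates.shape[1]
        lines = ["population\t" + "\t".join(f"PC{c + 1}" for c in range(k))]
        for p, row in zip(self.populations, self.coordinates):
            lines.append(p + "\t" + "\t".join(f"{v:.6g}" for v in row))
        return "\n".join(lines) + "\n"


def pca_project(
    ft: FrequencyTable,
    selected: list[str] | None = None,
    n_components: int = 2,
) -> PCAResult:
    """Project selected populations onto principal axes of frequency space.

    Each SNP is centred across the selected populations; the centred
    population x SNP matrix is decomposed by SVD and coordinates are the
    projections onto the top components.  Sign convention: the loading
    entry of largest magnitude on each component is made positive, so
    repeated runs give identical coordinates.

    At most ``min(n_pops - 1, s)`` components are nontrivial; asking for
    more truncates with a warning.
    """
    if selected is None:
        selected = list(ft.populations)
    if len(selected) < 3:
        raise ValueError("PCA projection needs at least 3 populations")
    X = np.column_stack([np.asarray(ft.column(p)) for p in selected]).T
    Xc = X - X.mean(axis=0)

    rank_cap = min(len(selected) - 1, ft.s)
    if n_components > rank_cap:
        warnings.warn(
            f"n_components={n_components} exceeds the rank bound {rank_cap}; "
            "truncating",
            stacklevel=2,
        )
        n_components = rank_cap

    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((S**2).sum())
    frac = (S**2) / total if total > 0 else np.zeros_like(S)
    # deterministic sign: largest-|loading| entry positive per component
    for c in range(n_components):
        lead = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, lead] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    coords = U[:, :n_components] * S[:n_components]
    return PCAResult(coords, frac[:n_components], list(selected))
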