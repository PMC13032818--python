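"""Synthetic admixture-triplet datasets.

The generator emulates the geometric picture the estimator is built on:
per SNP, an ancestral frequency is drawn, the two sources drift away from
it, the target is formed as an exact alpha/(1-alpha) blend of the sources,
and then target and sources each perform a further independent Brownian
step in frequency space.  Each auxiliary population branches off one of
the two source lineages at a uniform random time (its branch point drawn
from the Brownian bridge between the ancestor and that source) and then
drifts privately.  Diploid genotypes are binomially sampled from the
latent frequencies and optionally masked at a missing rate, giving a
complete no-download test bed in EIGENSTRAT form.

The lineage structure of the auxiliaries is essential, not decorative:
an outgroup pair (i, j) only informs the regression if its difference
direction shares drift with the source split, i.e. E[f4(a, b; i, j)] is
nonzero.  Auxiliaries drifting independently from the common ancestor
(a star phylogeny) would make every f4 a pure noise product and leave the
projected system with no signal about alpha, however many SNPs are used.

Drift is modelled as clipped Gaussian increments of the frequency vector
rather than Wright-Fisher binomial resampling: it is simpler, its variance
is directly controlled by ``drift_sd``, and it reproduces the crinkly
straight-line-to-triangle geometry the estimator must undo.  Clipping at
[0.01, 0.99] keeps frequencies away from fixation, which would create
zero-length difference vectors in the angle cosines.

Default scale mirrors the simulated study setting the estimator is
benchmarked on: tens of thousands of SNPs, populations of 10 diploid
individuals, a nominal mixing proportion of 0.2 and a per-step drift SD
of 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, FrequencyTable, GenotypeDataset
from .geometry import AdmixtureModel

__all__ = [
    "SimSpec",
    "TruthRecord",
    "simulate_triplet",
    "make_wrong_model",
    "exact_mixture_table",
    "write_truth",
]

_CLIP_LO, _CLIP_HI = 0.01, 0.99

TARGET, SOURCE_A, SOURCE_B = "Target", "SourceA", "SourceB"


def _aux_label(k: int) -> str:
    return f"Aux{k + 1:02d}"


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one simulated dataset.

    ``drift_sd`` is the standard deviation, in frequency units, of the
    Brownian drift step each population takes *after* the admixture event
    (the noise the estimator must undo).  ``divergence_sd`` is the SD of
    each source's divergence from the common ancestor *before* admixture
    (the signal defining the triplet geometry); it also sets the scale of
    the auxiliary branch points.  With ``drift_sd = 0`` the dataset is an
    exactly collinear triplet up to genotype sampling noise.
    """

    s: int = 50_000
    alpha_true: float = 0.2
    drift_sd: float = 0.02
    n_aux: int = 10
    n_individuals: int = 10
    ancestral_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    seed: int = 0
    divergence_sd: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_true < 1.0:
            raise ValueError("alpha_true must lie strictly inside (0, 1)")
        if self.drift_sd < 0 or self.divergence_sd <= 0:
            raise ValueError(
                "drift_sd must be non-negative and divergence_sd positive"
            )
        if self.s < 1 or self.n_aux < 1 or self.n_individuals < 1:
            raise ValueError("s, n_aux and n_individuals must be positive")
        lo, hi = self.ancestral_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("ancestral_range must satisfy 0 <= lo < hi <= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class TruthRecord:
    """Latent state of a simulation: the nominal mixing proportion and the
    drift-free frequency vector of every population."""

    alpha_true: float
    latent_freqs: dict[str, np.ndarray] = field(repr=False)
    spec: SimSpec = None

    def model(self) -> AdmixtureModel:
        """The true admixture model for the generated dataset."""
        aux = [_aux_label(k) for k in range(self.spec.n_aux)]
        return AdmixtureModel(TARGET, SOURCE_A, SOURCE_B, aux)


def _drift(p: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    return np.clip(p + rng.normal(0.0, sd, size=p.shape), _CLIP_LO, _CLIP_HI)


def simulate_triplet(spec: SimSpec) -> tuple[GenotypeDataset, TruthRecord]:
    """Generate one admixture-triplet dataset plus its truth record.

    Per SNP: ancestral frequency ~ Uniform(ancestral_range); the sources
    drift from it independently; the target is the exact mixture
    ``alpha_true * a + (1 - alpha_true) * b`` at admixture time; then the
    target and both sources take one further independent drift step.  Each
    auxiliary branches off the lineage of one source (chosen at random) at
    a uniform random time t, its branch point drawn from the Brownian
    bridge between the ancestor and that source, and takes one private
    drift step of its own.  Genotypes are Binomial(2, p) per individual,
    masked at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ancestral_range
    p0 = rng.uniform(lo, hi, size=spec.s)

    a_mix = _drift(p0, spec.divergence_sd, rng)
    b_mix = _drift(p0, spec.divergence_sd, rng)
    x_mix = spec.alpha_true * a_mix + (1.0 - spec.alpha_true) * b_mix

    latent: dict[str, np.ndarray] = {
        TARGET: _drift(x_mix, spec.drift_sd, rng),
        SOURCE_A: _drift(a_mix, spec.drift_sd, rng),
        SOURCE_B: _drift(b_mix, spec.drift_sd, rng),
    }
    for k in range(spec.n_aux):
        t = rng.uniform()
        tip = a_mix if rng.uniform() < 0.5 else b_mix
        # Brownian bridge between the ancestor and the chosen source tip
        bridge_sd = spec.divergence_sd * np.sqrt(t * (1.0 - t))
        branch = p0 + t * (tip - p0) + rng.normal(0.0, bridge_sd, size=spec.s)
        branch = np.clip(branch, _CLIP_LO, _CLIP_HI)
        latent[_aux_label(k)] = _drift(branch, spec.drift_sd, rng)

    pops = list(latent)
    n = spec.n_individuals
    blocks = []
    for pop in pops:
        g = rng.binomial(2, latent[pop][:, None], size=(spec.s, n)).astype(np.int8)
        blocks.append(g)
    genotypes = np.concatenate(blocks, axis=1)
    if spec.missing_rate > 0:
        mask = rng.random(genotypes.shape) < spec.missing_rate
        genotypes[mask] = MISSING

    individual_ids = [f"{pop}_{i}" for pop in pops for i in range(n)]
    population_of = {f"{pop}_{i}": pop for pop in pops for i in range(n)}
    snps = pd.DataFrame(
        {
            "id": [f"rs{k + 1}" for k in range(spec.s)],
            "chrom": ["1"] * spec.s,
            "gpos": ["0.0"] * spec.s,
            "pos": [str(1000 * (k + 1)) for k in range(spec.s)],
            "ref": ["A"] * spec.s,
            "alt": ["G"] * spec.s,
        }
    )
    ds = GenotypeDataset(genotypes, snps, individual_ids, population_of)
    return ds, TruthRecord(spec.alpha_true, latent, spec)


def make_wrong_model(truth: TruthRecord, ft: FrequencyTable) -> AdmixtureModel:
    """A deliberately mis-specified model: both true sources replaced by
    the two auxiliary populations most distant from either parental, with
    the remaining auxiliaries as the reference set.

    Distance is ``min(f2(aux, a), f2(aux, b))`` on the given frequency
    table, so the fake sources are drifted non-parental populations — the
    analogue of proposing two unrelated proxies for a known mixture.  On
    drifted data such a model is rejected by the angle test (post-JL angle
    below the pre-JL one) and often yields a proportion outside [0, 1].
    """
    from .fstats import f2 as _f2

    aux = [_aux_label(k) for k in range(truth.spec.n_aux)]
    if len(aux) < 6:
        raise ValueError(
            "need at least 6 auxiliaries to spare two as fake sources while "
            "keeping a 4-population reference set"
        )
    dist = {
        p: min(_f2(ft, p, SOURCE_A), _f2(ft, p, SOURCE_B)) for p in aux
    }
    ranked = sorted(aux, key=lambda p: dist[p], reverse=True)
    fake_a, fake_b = ranked[0], ranked[1]
    rest = [p for p in aux if p not in (fake_a, fake_b)]
    return AdmixtureModel(TARGET, fake_a, fake_b, rest)


def exact_mixture_table(
    n_snps: int,
    alpha: float,
    n_aux: int,
    seed: int = 0,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> tuple[FrequencyTable, AdmixtureModel]:
    """A drift-free frequency table in which the target is the exact
    per-SNP mixture of the two sources — the collinear limiting case where
    the slope equals ``alpha`` and both vertex angles are 180 degrees.
    """
    rng = np.random.default_rng(seed)
    lo, hi = freq_range
    a = rng.uniform(lo, hi, size=n_snps)
    b = rng.uniform(lo, hi, size=n_snps)
    x = alpha * a + (1.0 - alpha) * b
    cols = [x, a, b] + [rng.uniform(lo, hi, size=n_snps) for _ in range(n_aux)]
    pops = [TARGET, SOURCE_A, SOURCE_B] + [_aux_label(k) for k in range(n_aux)]
    ft = FrequencyTable(np.column_stack(cols), pops)
    return ft, AdmixtureModel(TARGET, SOURCE_A, SOURCE_B, pops[3:])


def write_truth(truth: TruthRecord, path) -> None:
    """Plain-text key/value record of the simulation truth (latent
    frequencies elided to summary statistics to keep the file small)."""
    spec = truth.spec
    with open(path, "w") as fh:
        fh.write(f"alpha_true {truth.alpha_true}\n")
        fh.write(f"s {spec.s}\n")
        fh.write(f"drift_sd {spec.drift_sd}\n")
        fh.write(f"divergence_sd {spec.divergence_sd}\n")
        fh.write(f"n_aux {spec.n_aux}\n")
        fh.write(f"n_individuals {spec.n_individuals}\n")
        fh.write(f"missing_rate {spec.missing_rate}\n")
        fh.write(f"seed {spec.seed}\n")
        for pop, p in truth.latent_freqs.items():
            fh.write(f"latent_mean_{pop} {float(np.mean(p)):.6f}\n")
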