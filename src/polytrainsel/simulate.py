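"""Synthetic autotetraploid diversity panels and quantitative traits.

The generator emulates a potato-style diversity panel: ~190 tetraploid
individuals in a few weakly differentiated subpopulations, a few thousand
biallelic SNPs with integer allele dosages, and traits with high broad-sense
heritability under configurable architectures (few large vs many small QTL,
optional pairwise epistasis).

Population structure follows the Balding-Nichols model: each marker has an
ancestral alternate-allele frequency p_j ~ Uniform(0.05, 0.95); each
subpopulation k draws its own frequency p_jk from a Beta distribution with
mean p_j and variance F * p_j * (1 - p_j), where F is the differentiation
parameter (``fst_target``); individual dosages are then Binomial(q, p_jk).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .panel import DosagePanel, PanelValidationError, TraitSet

__all__ = ["SimConfig", "TraitSpec", "simulate_panel", "simulate_trait"]

N_CHROMOSOMES = 12  # potato karyotype; positions feed QC/IO only


@dataclasses.dataclass
class TraitSpec:
    """Architecture of one simulated trait."""

    name: str = "trait"
    n_qtl: int = 100
    h2: float = 0.85
    effect_distribution: str = "gaussian"  # gaussian | laplace | fixed
    epistasis_pairs: int = 0
    epistasis_effect: float = 0.0


@dataclasses.dataclass
class SimConfig:
    """Panel-level simulation settings.

    Defaults reproduce the study conditions: 190 individuals in 3 weakly
    separated subpopulations, 3,262 biallelic dosage SNPs, differentiation
    F = 0.012 (pairwise Fst of order 0.01-0.02).
    """

    n_individuals: int = 190
    n_markers: int = 3262
    ploidy: int = 4
    n_strata: int = 3
    stratum_proportions: Sequence[float] | None = None
    fst_target: float = 0.012
    missing_rate: float = 0.0
    traits: Sequence[TraitSpec] = dataclasses.field(
        default_factory=lambda: [
            TraitSpec("tuber_length", n_qtl=20, h2=0.91),
            TraitSpec("fructose", n_qtl=20, h2=0.85),
            TraitSpec("sucrose", n_qtl=20, h2=0.67),
        ]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stratum_proportions is None:
            # uneven groups, largest ~half the panel, as in a market-class merge
            base = {1: [1.0], 2: [0.6, 0.4], 3: [0.5, 0.3, 0.2]}.get(self.n_strata)
            if base is None:
                base = [1.0 / self.n_strata] * self.n_strata
            self.stratum_proportions = base
        props = np.asarray(self.stratum_proportions, dtype=float)
        if len(props) != self.n_strata or not np.isclose(props.sum(), 1.0):
            raise PanelValidationError("stratum proportions must sum to 1")
        if not 0 <= self.fst_target < 1:
            raise PanelValidationError("fst_target must lie in [0, 1)")
        if self.n_strata > self.n_individuals:
            raise PanelValidationError("more strata than individuals")


def _stratum_sizes(config: SimConfig) -> np.ndarray:
    """Largest-remainder allocation of individuals to strata."""
    props = np.asarray(config.stratum_proportions, dtype=float)
    quota = props * config.n_individuals
    sizes = np.floor(quota).astype(int)
    rem = config.n_individuals - sizes.sum()
    order = np.argsort(-(quota - sizes))
    sizes[order[:rem]] += 1
    return sizes


def simulate_panel(config: SimConfig) -> DosagePanel:
    """Draw a dosage panel under the Balding-Nichols model.

    Deterministic given ``config.seed``: the same config yields a
    byte-identical panel.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    n, m, q, F = config.n_individuals, config.n_markers, config.ploidy, config.fst_target
    sizes = _stratum_sizes(config)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    dosages = np.empty((n, m), dtype=np.int16)
    strata = np.empty(n, dtype=object)
    row = 0
    for k, size in enumerate(sizes):
        if F > 0:
            # Beta with mean p and variance F*p*(1-p)
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            p_k = rng.beta(a, b)
        else:
            p_k = p_anc
        dosages[row : row + size] = rng.binomial(q, p_k, size=(size, m))
        strata[row : row + size] = f"pop{k + 1}"
        row += size
    missing = np.zeros((n, m), dtype=bool)
    if config.missing_rate > 0:
        missing = rng.random((n, m)) < config.missing_rate
    chrom_ids = np.repeat(
        [str(c + 1) for c in range(N_CHROMOSOMES)],
        int(np.ceil(m / N_CHROMOSOMES)),
    )[:m]
    pos = np.concatenate(
        [
            np.sort(rng.integers(1, 100_000_000, size=(chrom_ids == c).sum()))
            for c in [str(c + 1) for c in range(N_CHROMOSOMES)]
        ]
    )
    return DosagePanel(
        genotype_ids=[f"G{i + 1:03d}" for i in range(n)],
        dosages=dosages,
        ploidy=q,
        marker_ids=[f"snp{j + 1:05d}" for j in range(m)],
        chrom=chrom_ids,
        pos=pos,
        strata=strata.astype(str),
        missing=missing,
    )


def simulate_trait(
    panel: DosagePanel,
    n_qtl: int,
    h2: float,
    effect_distribution: str = "gaussian",
    epistasis: Sequence[tuple[int, int, float]] | None = None,
    seed: int = 0,
    name: str = "trait",
) -> TraitSet:
    """Simulate a quantitative trait on a panel.

    Genetic values are additive over ``n_qtl`` markers chosen uniformly at
    random, g_i = sum_j beta_j * d_ij, with optional pairwise multiplicative
    epistasis terms beta_jk * d_ij * d_ik.  Residuals are drawn Gaussian,
    then orthogonalised against g and rescaled so that the realized sample
    variance ratio var(g)/var(y) equals ``h2`` exactly in every replicate
    (which makes parameter-recovery checks sharp).  Truth (genetic values,
    QTL positions and effects) is stored on the returned :class:`TraitSet`.
    """
    if not 0 < h2 <= 1:
        raise PanelValidationError("h2 must lie in (0, 1]")
    if n_qtl > panel.n_markers:
        raise PanelValidationError("n_qtl exceeds number of markers")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 202]))
    qtl = np.sort(rng.choice(panel.n_markers, size=n_qtl, replace=False))
    if effect_distribution == "gaussian":
        beta = rng.normal(0.0, 1.0, size=n_qtl)
    elif effect_distribution == "laplace":
        beta = rng.laplace(0.0, 1.0, size=n_qtl)
    elif effect_distribution == "fixed":
        beta = np.ones(n_qtl)
    else:
        raise ValueError(f"unknown effect distribution {effect_distribution!r}")
    d = panel.dosage_float()
    # missing QTL dosages contribute their marker mean (truth must be defined)
    col_means = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_means[None, :], d)
    g = d[:, qtl] @ beta
    if epistasis:
        for j, k, eff in epistasis:
            g = g + eff * d[:, j] * d[:, k]
    var_g = np.var(g, ddof=1)
    if var_g == 0:
        raise PanelValidationError("degenerate trait: genetic values are constant")
    if h2 == 1:
        y = g.copy()
    else:
        e = rng.normal(size=panel.n_individuals)
        gc = g - g.mean()
        e = e - e.mean()
        e = e - (e @ gc) / (gc @ gc) * gc  # sample-orthogonal to g
        e *= np.sqrt(var_g * (1 - h2) / h2 / np.var(e, ddof=1))
        y = g + e
    return TraitSet(
        genotype_ids=list(panel.genotype_ids),
        values=y,
        trait_name=name,
        heritability=h2,
        genetic_values=g,
        qtl_indices=qtl,
        qtl_effects=beta,
    )
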