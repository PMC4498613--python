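"""Genome-wide LOD significance thresholds.

The empirical formula treats a one-dimensional scan as M_eff independent
tests, with M_eff proportional to genome length (0.072 tests per cM at
genome-wide alpha 0.05 and 0.084 at 0.01, for a 10 cM marker density).  The
per-test error is Bonferroni alpha_p = alpha_g / M_eff and the threshold is
the upper chi-square quantile at alpha_p, divided by 2 ln 10, with degrees of
freedom equal to the number of genetic parameters tested: e per scan for the
overall QEI statistic in two-class populations (2e for F2), 1 for the
average-effect statistic and e-1 for the interaction statistic.  RIL genomes
enter with length multiplied by 1.9 to account for accumulated recombination.
A permutation alternative reruns the full pipeline on row-shuffled phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .linkage import DH, GeneticMap, PopulationType

__all__ = ["ThresholdSpec", "effective_tests", "lod_threshold",
           "threshold_df", "permutation_threshold", "MEFF_COEFFICIENTS"]

#: tests per cM at 10 cM marker density, keyed by genome-wide alpha
MEFF_COEFFICIENTS = {0.05: 0.072, 0.01: 0.084}

_SCOPES = ("overall", "average_effect", "interaction")


def threshold_df(population_kind: str, n_env: int, scope: str = "overall") -> int:
    """Chi-square degrees of freedom for the three LOD statistics.

    Two-class populations (DH, BC1, RIL) estimate one mean difference per
    environment; F2 doubles every count (accepted here for threshold
    calculation only).
    """
    if scope not in _SCOPES:
        raise ValueError(f"scope must be one of {_SCOPES}")
    mult = 2 if population_kind.upper() == "F2" else 1
    if scope == "overall":
        return mult * n_env
    if scope == "average_effect":
        return mult * 1
    return mult * (n_env - 1)


@dataclass
class ThresholdSpec:
    genome_length: float
    n_env: int = 2
    alpha_g: float = 0.05
    population: PopulationType = DH
    scope: str = "overall"
    meff_coefficient: float | None = None  # tests/cM; default from alpha lookup
    df: int | None = None                  # explicit override of the df rule

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome length must be positive")
        if not (0.0 < self.alpha_g < 1.0):
            raise ValueError("genome-wide alpha must lie in (0, 1)")
        if self.meff_coefficient is None:
            try:
                self.meff_coefficient = MEFF_COEFFICIENTS[self.alpha_g]
            except KeyError:
                raise ValueError(
                    f"no built-in M_eff coefficient for alpha_g={self.alpha_g}; "
                    "supply meff_coefficient explicitly"
                ) from None


def effective_tests(spec: ThresholdSpec) -> float:
    """Effective number of independent tests; kept un-rounded."""
    return spec.meff_coefficient * spec.genome_length * spec.population.genome_expansion


def lod_threshold(spec: ThresholdSpec) -> float:
    """Empirical genome-wide LOD threshold: chi2_inv(alpha_g/M_eff, df) / (2 ln 10)."""
    meff = effective_tests(spec)
    alpha_p = spec.alpha_g / meff
    df = spec.df if spec.df is not None else threshold_df(
        spec.population.kind, spec.n_env, spec.scope)
    return float(stats.chi2.isf(alpha_p, df) / (2.0 * np.log(10.0)))


def permutation_threshold(gmap: GeneticMap, genotypes, phenotypes,
                          population: PopulationType = DH, n_perm: int = 1000,
                          alpha_g: float = 0.05, seed: int = 0,
                          p_in: float = 0.001, p_out: float = 0.002,
                          step: float = 1.0) -> float:
    """(1-alpha_g) percentile of genome-wide max LOD over phenotype permutations.

    Whole phenotype rows are permuted so an individual's environment vector
    stays together; stepwise selection and the scan are rerun per permutation.
    """
    from .cofactors import stepwise_cofactors
    from .scan import scan
    from .simulate import PhenotypeMatrix

    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if n_perm * alpha_g < 10:
        import warnings

        warnings.warn(
            f"{n_perm} permutations give a noisy {1 - alpha_g:.0%} percentile",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    max_lod = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(phenotypes.n_individuals)
        ph = PhenotypeMatrix(phenotypes.values[perm], phenotypes.env_names)
        cof = stepwise_cofactors(genotypes, ph, gmap, population, p_in, p_out)
        profile = scan(gmap, genotypes, ph, cof, population, step=step,
                       fit_interaction=False)
        max_lod[b] = profile["LOD"].max()
    return float(np.quantile(max_lod, 1.0 - alpha_g))
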