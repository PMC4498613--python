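"""Simulation of biparental populations and multi-environment phenotypes.

The generator emulates the benchmark trial design used throughout this
package's validation: a genome of 6 chromosomes x 150 cM with 16 evenly
spaced markers (10 cM density), DH populations of n = 200 individuals
phenotyped in 2 environments, and QTL architectures specified as
per-environment additive effects.  Broad-sense heritability is enforced per
environment through the closed-form genetic variance, so the percentage of
phenotypic variance explained by each simulated QTL is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkage import DH, GeneticMap, PopulationType, haldane_r

__all__ = [
    "QTLArchitecture",
    "TrialDesign",
    "MarkerGenotypes",
    "PhenotypeMatrix",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_population",
    "simulate_null",
    "genetic_variance",
    "expected_pve",
    "standard_map",
    "unlinked_architecture",
    "linked_architecture",
    "LINKED_MODELS",
]


class QTLArchitecture:
    """True QTL positions and per-environment additive effects.

    ``effects`` has shape (n_qtl, n_env); the average effect of QTL j is
    mean_h(a_jh) and its interaction effect in environment h is
    ae_jh = a_jh - abar_j, which sums to zero over environments by
    construction.
    """

    def __init__(self, chromosomes, positions, effects):
        self.chromosomes = [str(c) for c in chromosomes]
        self.positions = np.asarray(positions, dtype=float)
        self.effects = np.atleast_2d(np.asarray(effects, dtype=float))
        if len(self.chromosomes) != len(self.positions) or (
            self.effects.shape[0] != len(self.positions)
        ):
            raise ValueError("chromosomes, positions and effects rows must align")

    @property
    def n_qtl(self) -> int:
        return len(self.positions)

    @property
    def n_env(self) -> int:
        return self.effects.shape[1]

    @property
    def avg_effects(self) -> np.ndarray:
        return self.effects.mean(axis=1)

    @property
    def interaction_effects(self) -> np.ndarray:
        return self.effects - self.avg_effects[:, None]

    @classmethod
    def empty(cls, n_env: int) -> "QTLArchitecture":
        return cls([], np.empty(0), np.empty((0, n_env)))

    def validate_on(self, gmap: GeneticMap) -> None:
        for chrom, pos in zip(self.chromosomes, self.positions):
            if not gmap.contains(chrom, pos):
                raise ValueError(f"QTL at {chrom}:{pos} cM lies outside the map span")

    def to_frame(self) -> pd.DataFrame:
        cols = {f"effect_E{h + 1}": self.effects[:, h] for h in range(self.n_env)}
        return pd.DataFrame(
            {"chromosome": self.chromosomes, "position_cM": self.positions, **cols}
        )


@dataclass
class TrialDesign:
    """Population type, size, environment count, heritability and seed."""

    population: PopulationType = DH
    n: int = 200
    n_env: int = 2
    h2: float = 0.5
    mu: np.ndarray | None = None  # per-environment intercepts, default 0
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("population size must be positive")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("broad-sense heritability must lie in (0, 1]")
        if self.mu is None:
            self.mu = np.zeros(self.n_env)
        else:
            self.mu = np.asarray(self.mu, dtype=float)
            if self.mu.shape != (self.n_env,):
                raise ValueError("mu must have one intercept per environment")


class MarkerGenotypes:
    """Individuals x markers matrix coded +1 (P1 class), -1 (P2 class), NaN missing.

    Simulator output additionally carries the hidden true QTL genotype columns
    in ``qtl_genotypes`` (individuals x n_qtl), which downstream phenotype
    simulation and power evaluation use as ground truth.
    """

    def __init__(self, values, marker_names, qtl_genotypes=None):
        values = np.asarray(values, dtype=float)
        legal = np.isnan(values) | (values == 1.0) | (values == -1.0)
        if not legal.all():
            bad = values[~legal].flat[0]
            raise ValueError(f"illegal genotype code {bad!r}; expected +1, -1 or missing")
        self.values = values
        self.marker_names = list(marker_names)
        if values.shape[1] != len(self.marker_names):
            raise ValueError("marker_names must match genotype columns")
        self.qtl_genotypes = None if qtl_genotypes is None else np.asarray(qtl_genotypes, float)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.values).mean(axis=0)


class PhenotypeMatrix:
    """Individuals x environments trait values; NaN marks missing cells."""

    def __init__(self, values, env_names=None):
        self.values = np.atleast_2d(np.asarray(values, dtype=float))
        e = self.values.shape[1]
        self.env_names = list(env_names) if env_names is not None else [
            f"E{h + 1}" for h in range(e)
        ]
        if len(self.env_names) != e:
            raise ValueError("env_names must match phenotype columns")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_env(self) -> int:
        return self.values.shape[1]

    @property
    def n_observed(self) -> np.ndarray:
        """Per-environment count of non-missing cells."""
        return (~np.isnan(self.values)).sum(axis=0)

    @property
    def variances(self) -> np.ndarray:
        """Per-environment phenotypic variance (1/n denominator, missing skipped)."""
        return np.nanvar(self.values, axis=0)


# ---------------------------------------------------------------------------
# genotype simulation


def _simulate_chromosome(n: int, positions: np.ndarray, population: PopulationType,
                         rng: np.random.Generator) -> np.ndarray:
    """First-order Markov chain of +/-1 genotypes along one chromosome."""
    L = len(positions)
    r = population.effective_fraction(haldane_r(np.diff(positions)))
    flips = rng.random((n, L - 1)) < r if L > 1 else np.empty((n, 0), bool)
    first = rng.integers(0, 2, size=n) * 2 - 1
    steps = np.hstack([first[:, None], 1 - 2 * flips.astype(int)])
    return np.cumprod(steps, axis=1).astype(float)


def simulate_genotypes(gmap: GeneticMap, arch: QTLArchitecture, design: TrialDesign,
                       rng: np.random.Generator | None = None,
                       missing_rate: float = 0.0) -> MarkerGenotypes:
    """Simulate marker genotypes plus hidden QTL genotypes under the map.

    Each chromosome is simulated as a Markov chain over the merged
    (marker + QTL) loci; the transition probability between adjacent loci is
    the Haldane recombination fraction of their distance (mapped through the
    accumulated-recombination transform for RIL).  One gamete per DH/RIL
    individual; the BC1 chain is identical at the two-class coding level.
    """
    arch.validate_on(gmap)
    if rng is None:
        rng = np.random.default_rng(design.seed)
    marker_cols = []
    qtl_cols = {}
    for chrom in gmap.chromosomes:
        mpos = gmap.positions(chrom)
        qidx = [j for j, c in enumerate(arch.chromosomes) if c == chrom]
        qpos = arch.positions[qidx]
        merged = np.concatenate([mpos, qpos])
        order = np.argsort(merged, kind="stable")
        geno = np.empty((design.n, len(merged)))
        geno[:, order] = _simulate_chromosome(
            design.n, merged[order], design.population, rng
        )
        marker_cols.append(geno[:, : len(mpos)])
        for k, j in enumerate(qidx):
            qtl_cols[j] = geno[:, len(mpos) + k]
    markers = np.hstack(marker_cols) if marker_cols else np.empty((design.n, 0))
    qtl = (
        np.column_stack([qtl_cols[j] for j in range(arch.n_qtl)])
        if arch.n_qtl
        else np.empty((design.n, 0))
    )
    if missing_rate > 0:
        mask = rng.random(markers.shape) < missing_rate
        markers[mask] = np.nan
    return MarkerGenotypes(markers, gmap.marker_names, qtl_genotypes=qtl)


# ---------------------------------------------------------------------------
# variance oracle


def genetic_variance(arch: QTLArchitecture, gmap: GeneticMap,
                     population: PopulationType = DH) -> np.ndarray:
    """Per-environment genetic variance of the architecture's genotypic values.

    With two-class loci at frequency 1/2, V_G,h = sum_j a_jh^2
    + 2 sum_{j<j'} a_jh a_j'h D_jj', where D = 1 - 2r for linked pairs
    (r through the accumulated transform for RIL) and 0 across chromosomes.
    """
    e = arch.n_env
    vg = np.zeros(e)
    for h in range(e):
        a = arch.effects[:, h]
        vg[h] = np.sum(a**2)
        for j in range(arch.n_qtl):
            for k in range(j + 1, arch.n_qtl):
                if arch.chromosomes[j] != arch.chromosomes[k]:
                    continue
                r = population.effective_fraction(
                    haldane_r(abs(arch.positions[j] - arch.positions[k]))
                )
                vg[h] += 2.0 * a[j] * a[k] * (1.0 - 2.0 * r)
    return vg


def expected_pve(arch: QTLArchitecture, gmap: GeneticMap,
                 population: PopulationType = DH, h2: float = 0.5) -> pd.DataFrame:
    """Closed-form per-QTL PVE (%), split into average and interaction components.

    V_P = mean_h(V_G,h)/H2; per-QTL variance = mean_h(a_jh^2), which splits as
    abar_j^2 + mean_h(ae_jh^2).
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError("broad-sense heritability must lie in (0, 1]")
    vg = genetic_variance(arch, gmap, population)
    vp = vg.mean() / h2
    abar = arch.avg_effects
    ae = arch.interaction_effects
    if vp == 0.0:  # no genetic variance anywhere: every effect is zero
        pve_a = np.zeros(arch.n_qtl)
        pve_ae = np.zeros(arch.n_qtl)
    else:
        pve_a = 100.0 * abar**2 / vp
        pve_ae = 100.0 * (ae**2).mean(axis=1) / vp
    out = arch.to_frame()
    out["PVE_A"] = pve_a
    out["PVE_AE"] = pve_ae
    out["PVE"] = pve_a + pve_ae
    return out


# ---------------------------------------------------------------------------
# phenotype simulation


def _error_variances(arch: QTLArchitecture, gmap: GeneticMap, design: TrialDesign,
                     floor_sigma2: float | None = None) -> np.ndarray:
    vg = genetic_variance(arch, gmap, design.population)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = vg * (1.0 - design.h2) / design.h2
    zero = vg == 0
    if zero.any() and design.h2 < 1.0:
        if zero.all():
            if floor_sigma2 is None:
                raise ValueError(
                    "architecture has zero genetic variance in every environment; "
                    "supply floor_sigma2 (or use simulate_null)"
                )
            s2[:] = floor_sigma2
        else:
            # environment-specific architectures: give quiet environments the
            # average noise of the informative ones so every trait has error
            s2[zero] = s2[~zero].mean()
    return s2


def simulate_phenotypes(genotypes: MarkerGenotypes, arch: QTLArchitecture,
                        design: TrialDesign, rng: np.random.Generator | None = None,
                        floor_sigma2: float | None = None) -> PhenotypeMatrix:
    """Phenotypes y_ih = mu_h + sum_j a_jh g_ij + eps_ih with per-environment noise.

    eps_ih ~ Normal(0, sigma2_h) with sigma2_h = V_G,h (1-H2)/H2, so realized
    broad-sense heritability matches the design per environment.
    """
    if genotypes.qtl_genotypes is None:
        raise ValueError("genotypes must carry the hidden QTL columns")
    if rng is None:
        rng = np.random.default_rng(design.seed + 1)
    g = genotypes.qtl_genotypes
    values = design.mu[None, :] + g @ arch.effects
    if design.h2 < 1.0:
        s2 = _error_variances(arch, None, design, floor_sigma2)
        values = values + rng.standard_normal((g.shape[0], design.n_env)) * np.sqrt(s2)
    return PhenotypeMatrix(values)


def simulate_population(gmap: GeneticMap, arch: QTLArchitecture, design: TrialDesign,
                        missing_rate: float = 0.0):
    """Convenience: one seeded draw of (genotypes, phenotypes) for a trial."""
    rng = np.random.default_rng(design.seed)
    geno = simulate_genotypes(gmap, arch, design, rng=rng, missing_rate=missing_rate)
    phen = simulate_phenotypes(geno, arch, design, rng=rng)
    return geno, phen


def simulate_null(gmap: GeneticMap, population: PopulationType, n: int, n_env: int,
                  sigma2: float = 1.0, seed: int = 0):
    """No-QTL population: genotypes under the map, phenotypes pure noise.

    Used to calibrate genome-wide LOD thresholds empirically.
    """
    if n <= 0:
        raise ValueError("population size must be positive")
    rng = np.random.default_rng(seed)
    arch = QTLArchitecture.empty(n_env)
    design = TrialDesign(population=population, n=n, n_env=n_env, h2=1.0, seed=seed)
    geno = simulate_genotypes(gmap, arch, design, rng=rng)
    phen = PhenotypeMatrix(rng.standard_normal((n, n_env)) * np.sqrt(sigma2))
    return geno, phen


# ---------------------------------------------------------------------------
# benchmark presets


def standard_map(n_chromosomes: int = 6, length_cM: float = 150.0,
                 n_markers: int = 16) -> GeneticMap:
    """Evenly spaced benchmark map: 6 chromosomes x 150 cM with 16 markers each."""
    rows = []
    for c in range(1, n_chromosomes + 1):
        pos = np.linspace(0.0, length_cM, n_markers)
        for j, p in enumerate(pos, start=1):
            rows.append((f"M{c}_{j}", str(c), p))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM"]))


def unlinked_architecture() -> QTLArchitecture:
    """Five unlinked QTL on chromosomes 1-5 spanning three interaction levels.

    Q1/Q5: average effect only; Q2: pure crossover interaction; Q3/Q4:
    environment-specific effects.  Per-environment effects a_h = A + AE_h.
    """
    return QTLArchitecture(
        chromosomes=["1", "2", "3", "4", "5"],
        positions=[16.0, 3.0, 33.0, 26.0, 35.0],
        effects=[
            [0.5, 0.5],
            [0.5, -0.5],
            [0.0, 0.5],
            [0.5, 0.0],
            [0.5, 0.5],
        ],
    )


#: effects (E1, E2) of the two linked QTL at 25 and 55 cM on chromosome 1
LINKED_MODELS = {
    "L1": [[0.5, -0.5], [0.5, 0.0]],
    "L2": [[0.5, -0.5], [0.5, 0.5]],
    "L3": [[0.5, -0.5], [0.5, -0.5]],
    "L4": [[0.5, 0.0], [0.5, 0.5]],
    "L5": [[0.5, 0.0], [0.5, 0.0]],
    "L6": [[0.5, 0.5], [0.5, 0.5]],
    "L7": [[0.5, -0.5], [-0.5, 0.5]],
    "L8": [[0.5, -0.5], [0.0, 0.5]],
}


def linked_architecture(model: str) -> QTLArchitecture:
    """Two linked QTL at 25 and 55 cM on chromosome 1 under effect scenario L1-L8."""
    if model not in LINKED_MODELS:
        raise ValueError(f"unknown linked model {model!r}; expected one of {sorted(LINKED_MODELS)}")
    return QTLArchitecture(
        chromosomes=["1", "1"], positions=[25.0, 55.0], effects=LINKED_MODELS[model]
    )
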