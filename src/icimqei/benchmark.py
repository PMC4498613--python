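"""Replicated simulation studies on the benchmark genome.

These drive the package's own validation: detection power, FDR and estimate
bias for the 5-QTL unlinked design, and genome-wide null calibration of the
empirical LOD threshold.  Both run the complete pipeline per replicate —
simulation, stepwise cofactor selection, 1 cM QEI scan, peak calling.
"""

from __future__ import annotations

import numpy as np

from .cofactors import stepwise_cofactors
from .evaluation import PowerReport, call_peaks, power_fdr
from .linkage import DH, PopulationType
from .scan import scan
from .simulate import (QTLArchitecture, TrialDesign, simulate_null,
                       simulate_population, standard_map, unlinked_architecture)
from .thresholds import ThresholdSpec, lod_threshold

__all__ = ["unlinked_power_study", "null_max_lods"]


def unlinked_power_study(n_replicates: int = 200, seed: int = 1,
                         n: int = 200, h2: float = 0.5,
                         threshold: float | None = None,
                         arch: QTLArchitecture | None = None,
                         support_halfwidth: float = 5.0,
                         progress: bool = False) -> PowerReport:
    """Power/FDR/bias of the QEI scan on replicated unlinked-design trials.

    Each replicate simulates a DH population of size ``n`` at heritability
    ``h2`` on the benchmark 6 x 150 cM genome, runs stepwise selection
    (p_in = 0.001, p_out = 0.002) and the 1 cM scan, and calls peaks at the
    empirical threshold (3.11 for this genome at genome-wide alpha 0.05
    unless overridden).
    """
    gmap = standard_map()
    if arch is None:
        arch = unlinked_architecture()
    if threshold is None:
        threshold = round(lod_threshold(
            ThresholdSpec(gmap.total_length, arch.n_env)), 2)
    calls = []
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_replicates) % (2**31 - 1)
    for b in range(n_replicates):
        design = TrialDesign(n=n, n_env=arch.n_env, h2=h2, seed=int(rep_seeds[b]))
        geno, phen = simulate_population(gmap, arch, design)
        cof = stepwise_cofactors(geno, phen, gmap)
        profile = scan(gmap, geno, phen, cof)
        calls.append(call_peaks(profile, threshold))
        if progress and (b + 1) % 25 == 0:  # pragma: no cover
            print(f"  replicate {b + 1}/{n_replicates}")
    return power_fdr(calls, arch, support_halfwidth=support_halfwidth)


def null_max_lods(n_replicates: int = 500, seed: int = 2, n: int = 200,
                  n_env: int = 2, population: PopulationType = DH,
                  sigma2: float = 1.0, progress: bool = False) -> np.ndarray:
    """Genome-wide maximum LOD per replicate under the no-QTL model.

    Runs the full pipeline (stepwise + scan) on pure-noise phenotypes over
    the benchmark genome; the empirical distribution of the maxima calibrates
    the LOD threshold (its 95th percentile should sit at the formula value).
    """
    gmap = standard_map()
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_replicates) % (2**31 - 1)
    out = np.empty(n_replicates)
    for b in range(n_replicates):
        geno, phen = simulate_null(gmap, population, n, n_env, sigma2,
                                   seed=int(rep_seeds[b]))
        cof = stepwise_cofactors(geno, phen, gmap, population)
        profile = scan(gmap, geno, phen, cof, population, fit_interaction=False)
        out[b] = profile["LOD"].max()
        if progress and (b + 1) % 50 == 0:  # pragma: no cover
            print(f"  null replicate {b + 1}/{n_replicates}")
    return out
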