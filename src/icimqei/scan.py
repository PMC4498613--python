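"""One-dimensional QEI genome scan: mixture fits, LOD decomposition, effects, PVE.

At every testing position the adjusted phenotypes follow, per environment, a
two-component normal mixture whose mixing proportions are the conditional
QTL-genotype probabilities given the flanking-marker group.  Three nested
hypotheses are fit:

* H0 - no QTL: a single normal per environment (closed form);
* H1 - a QTL with any effects: unconstrained ECM;
* H2 - interaction only: ECM with the average effect constrained to zero
  through a Lagrange multiplier in the conditional M-step.

LOD_A = (l1 - l2)/ln10 tests the average effect, LOD_AE = (l2 - l0)/ln10 the
interaction effects, and their sum LOD = (l1 - l0)/ln10 tests any effect.
The default likelihood couples environments through a shared QTL genotype
(product of per-environment densities inside the mixture); the alternative
``printed-sum`` variant replaces that product by a sum of densities in the
E-step, for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cofactors import CofactorModel, adjust_phenotypes
from .linkage import (DH, GeneticMap, PopulationType, group_index, haldane_r,
                      interval_probabilities)
from .simulate import MarkerGenotypes, PhenotypeMatrix

__all__ = ["MixtureFit", "fit_H0", "fit_H1", "fit_H2", "lod_scores",
           "estimate_effects", "pve_decomposition", "scan"]

LN10 = np.log(10.0)
_TOL = 1e-6
_MAX_ITER = 200


@dataclass
class MixtureFit:
    """Fitted mixture parameters at one testing position.

    ``mu`` has shape (2, e) — component means for the QQ and qq genotypes per
    environment; ``sigma2`` the per-environment residual variances;
    ``weights`` the posterior genotype probabilities w_ik (n, 2).  For
    constrained fits ``lagrange`` carries the final multiplier and
    ``constraint_residual`` the residual of sum_h(mu_1h - mu_2h).
    """

    mu: np.ndarray
    sigma2: np.ndarray
    loglik: float
    n_iter: int = 0
    converged: bool = True
    weights: np.ndarray | None = None
    lagrange: float | None = None
    constraint_residual: float | None = None


# ---------------------------------------------------------------------------
# H0 (closed form)


def fit_H0(dy: np.ndarray) -> MixtureFit:
    """Single-normal MLE per environment on the adjusted phenotypes."""
    dy = np.atleast_2d(np.asarray(dy, float))
    obs = ~np.isnan(dy)
    n_h = obs.sum(axis=0)
    if np.any(n_h < 2):
        raise ValueError("need at least 2 observed values per environment")
    mu = np.nanmean(dy, axis=0)
    s2 = np.nanvar(dy, axis=0)  # 1/n (biased) MLE
    if np.any(s2 <= 0):
        raise ValueError("zero phenotypic variance in at least one environment")
    ll = float(np.sum(-0.5 * n_h * (np.log(2 * np.pi * s2) + 1.0)))
    return MixtureFit(mu=np.vstack([mu, mu]), sigma2=s2, loglik=ll)


# ---------------------------------------------------------------------------
# batched ECM over scan positions


def _initial_values(dy: np.ndarray, groups: np.ndarray):
    """Start the ECM from the two double-non-recombinant marker groups.

    mu_1h from group (+,+), mu_2h from group (-,-), pooled variance from the
    two; if either group is empty, fall back to overall mean +/- half the
    pooled SD.
    """
    g1 = groups == 0
    g4 = groups == 3
    if g1.any() and g4.any():
        mu1 = np.nanmean(dy[g1], axis=0)
        mu2 = np.nanmean(dy[g4], axis=0)
        both = dy[g1 | g4]
        centers = np.where(g1[g1 | g4, None], mu1[None, :], mu2[None, :])
        dev = both - centers
        n_obs = (~np.isnan(dev)).sum(axis=0)
        s2 = np.nansum(dev**2, axis=0) / np.maximum(n_obs, 1)
    else:
        m = np.nanmean(dy, axis=0)
        sd = np.sqrt(np.nanvar(dy, axis=0))
        mu1 = m + 0.5 * sd
        mu2 = m - 0.5 * sd
        s2 = np.nanvar(dy, axis=0)
    s2 = np.maximum(s2, 1e-12)
    return mu1, mu2, s2


def _ecm_batch(dy: np.ndarray, prior: np.ndarray, groups: np.ndarray,
               constrained: bool, likelihood: str = "product",
               tol: float = _TOL, max_iter: int = _MAX_ITER,
               iteration_hook=None):
    """Run the ECM jointly at P testing positions sharing the same Delta_y.

    ``prior`` is (P, n, 2): per-position, per-individual QTL-genotype priors
    pi_lk.  Returns dict of arrays over positions.
    """
    dy = np.atleast_2d(dy)
    n, e = dy.shape
    P = prior.shape[0]
    obs = ~np.isnan(dy)
    Y = np.where(obs, dy, 0.0)
    n_h = obs.sum(axis=0)

    mu1, mu2, s2 = _initial_values(dy, groups)
    mu = np.broadcast_to(np.stack([mu1, mu2]), (P, 2, e)).copy()
    sigma2 = np.broadcast_to(s2, (P, e)).copy()

    log_prior = np.log(np.maximum(prior, 1e-300))
    ll_prev = np.full(P, -np.inf)
    lagrange = np.zeros(P)
    converged = np.zeros(P, bool)
    w = None
    for it in range(1, max_iter + 1):
        # E-step: per-position, per-individual, per-component log density
        diff = Y[None, :, None, :] - mu[:, None, :, :]          # (P, n, 2, e)
        logf_env = -0.5 * (np.log(2 * np.pi * sigma2)[:, None, None, :]
                           + diff**2 / sigma2[:, None, None, :])
        logf_env = np.where(obs[None, :, None, :], logf_env, 0.0)
        if likelihood == "product":
            logf = logf_env.sum(axis=3)                         # (P, n, 2)
        elif likelihood == "printed-sum":
            # sum of per-environment densities inside the mixture
            mx = logf_env.max(axis=3, keepdims=True)
            logf = np.squeeze(mx, 3) + np.log(
                np.exp(logf_env - mx).sum(axis=3))
        else:
            raise ValueError(f"unknown likelihood variant {likelihood!r}")
        a = log_prior + logf
        amax = a.max(axis=2, keepdims=True)
        lse = np.squeeze(amax, 2) + np.log(np.exp(a - amax).sum(axis=2))
        ll = lse.sum(axis=1)                                    # (P,)
        w = np.exp(a - lse[:, :, None])                         # (P, n, 2)

        # CM-step
        W = np.einsum("pnk,nh->pkh", w, obs.astype(float))      # (P, 2, e)
        W = np.maximum(W, 1e-12)
        S = np.einsum("pnk,nh->pkh", w, Y)
        m_kh = S / W
        if constrained:
            delta = m_kh[:, 0, :] - m_kh[:, 1, :]               # (P, e)
            denom = (sigma2 * (1.0 / W[:, 0, :] + 1.0 / W[:, 1, :])).sum(axis=1)
            lagrange = 2.0 * e * delta.sum(axis=1) / np.maximum(denom, 1e-300)
            shift = sigma2 * lagrange[:, None] / (2.0 * e)
            mu = np.stack([(S[:, 0, :] - shift) / W[:, 0, :],
                           (S[:, 1, :] + shift) / W[:, 1, :]], axis=1)
        else:
            mu = m_kh
        # pin empty components to the overall environment mean
        empty = W < 1e-8
        if empty.any():
            overall = Y.sum(axis=0) / np.maximum(n_h, 1)
            mu = np.where(empty, overall[None, None, :], mu)
        diff = Y[None, :, None, :] - mu[:, None, :, :]
        sq = np.where(obs[None, :, None, :], diff**2, 0.0)
        sigma2 = np.einsum("pnk,pnkh->ph", w, sq) / n_h
        sigma2 = np.maximum(sigma2, 1e-12)

        if iteration_hook is not None:
            iteration_hook(it, ll, ll_prev)
        done = np.abs(ll - ll_prev) < tol
        converged = done
        ll_prev = ll
        if done.all():
            break

    # final likelihood at the converged parameters
    diff = Y[None, :, None, :] - mu[:, None, :, :]
    logf_env = -0.5 * (np.log(2 * np.pi * sigma2)[:, None, None, :]
                       + diff**2 / sigma2[:, None, None, :])
    logf_env = np.where(obs[None, :, None, :], logf_env, 0.0)
    if likelihood == "product":
        logf = logf_env.sum(axis=3)
    else:
        mx = logf_env.max(axis=3, keepdims=True)
        logf = np.squeeze(mx, 3) + np.log(np.exp(logf_env - mx).sum(axis=3))
    a = log_prior + logf
    amax = a.max(axis=2, keepdims=True)
    lse = np.squeeze(amax, 2) + np.log(np.exp(a - amax).sum(axis=2))
    ll = lse.sum(axis=1)
    w = np.exp(a - lse[:, :, None])
    residual = (mu[:, 0, :] - mu[:, 1, :]).sum(axis=1) if constrained else None
    return {"mu": mu, "sigma2": sigma2, "loglik": ll, "weights": w,
            "n_iter": it, "converged": converged, "lagrange": lagrange,
            "constraint_residual": residual}


def _single_fit(dy, prior, groups, constrained, likelihood="product", **kw) -> MixtureFit:
    dy = np.atleast_2d(np.asarray(dy, float))
    prior = np.asarray(prior, float)[None, :, :]
    out = _ecm_batch(dy, prior, np.asarray(groups), constrained, likelihood, **kw)
    return MixtureFit(
        mu=out["mu"][0], sigma2=out["sigma2"][0], loglik=float(out["loglik"][0]),
        n_iter=out["n_iter"], converged=bool(out["converged"][0]),
        weights=out["weights"][0],
        lagrange=float(out["lagrange"][0]) if constrained else None,
        constraint_residual=(float(out["constraint_residual"][0])
                             if constrained else None),
    )


def fit_H1(dy, groups, pi, likelihood: str = "product", **kw) -> MixtureFit:
    """Unconstrained mixture fit: QTL with arbitrary per-environment effects.

    ``groups`` are flanking-marker group labels (0..3) and ``pi`` either the
    4x2 group probability table or per-individual (n, 2) priors.
    """
    prior = _per_individual_prior(pi, groups)
    return _single_fit(dy, prior, groups, constrained=False,
                       likelihood=likelihood, **kw)


def fit_H2(dy, groups, pi, likelihood: str = "product", **kw) -> MixtureFit:
    """Mixture fit with the average effect constrained to zero (interaction only)."""
    prior = _per_individual_prior(pi, groups)
    return _single_fit(dy, prior, groups, constrained=True,
                       likelihood=likelihood, **kw)


def _per_individual_prior(pi, groups) -> np.ndarray:
    pi = np.asarray(pi, float)
    groups = np.asarray(groups)
    if pi.shape == (4, 2):
        return pi[groups]
    if pi.shape == (len(groups), 2):
        return pi
    raise ValueError("pi must be a 4x2 group table or per-individual (n, 2) priors")


# ---------------------------------------------------------------------------
# derived statistics


def lod_scores(fit0: MixtureFit, fit1: MixtureFit, fit2: MixtureFit):
    """(LOD, LOD_A, LOD_AE) from the three nested fits; LOD = LOD_A + LOD_AE."""
    lod_a = (fit1.loglik - fit2.loglik) / LN10
    lod_ae = (fit2.loglik - fit0.loglik) / LN10
    lod = lod_a + lod_ae
    for name, v in (("LOD", lod), ("LOD_A", lod_a), ("LOD_AE", lod_ae)):
        if v < -1e-6:
            raise ValueError(f"negative {name} = {v:.3g}: ECM convergence failure")
    return lod, lod_a, lod_ae


def estimate_effects(fit1: MixtureFit):
    """Per-environment additive effects a_h = (mu_1h - mu_2h)/2, their mean and deviations."""
    a_h = 0.5 * (fit1.mu[0] - fit1.mu[1])
    abar = float(a_h.mean())
    return a_h, abar, a_h - abar


def pve_decomposition(fit1: MixtureFit, phenotypes: PhenotypeMatrix | np.ndarray,
                      freqs: np.ndarray | None = None) -> dict:
    """Variance components of the fitted 2 x e genotype-mean table.

    The two-way (genotype x environment) decomposition is orthogonal:
    V_A = sum_k f_k (mu_k. - mu_..)^2 = 4 f_1 f_2 abar^2 and
    V_AE = sum_kh f_kh QEI_kh^2 = (4/e) f_1 f_2 sum_h (a_h - abar)^2 with
    QEI_kh = mu_kh - mu_k. - mu_.h + mu_.. .  PVEs are percentages of the
    average raw per-environment phenotypic variance.
    """
    mu = fit1.mu
    e = mu.shape[1]
    if freqs is None:
        if fit1.weights is None:
            raise ValueError("fit carries no posterior weights; pass freqs explicitly")
        freqs = fit1.weights.mean(axis=0)
    f = np.asarray(freqs, float)
    if isinstance(phenotypes, PhenotypeMatrix):
        vph = phenotypes.variances
    else:
        vph = np.asarray(phenotypes, float)
    vp = float(vph.mean())
    if vp <= 0:
        raise ValueError("zero phenotypic variance")
    f_kh = f[:, None] / e * np.ones((2, e))
    grand = float((f_kh * mu).sum())
    row = mu.mean(axis=1)                      # mu_k.
    col = (f[:, None] * mu).sum(axis=0)        # mu_.h
    v_a = float(np.sum(f * (row - grand) ** 2))
    qei = mu - row[:, None] - col[None, :] + grand
    v_ae = float((f_kh * qei**2).sum())
    pve_a = 100.0 * v_a / vp
    pve_ae = 100.0 * v_ae / vp
    return {"V_A": v_a, "V_AE": v_ae, "V_P": vp, "PVE_A": pve_a,
            "PVE_AE": pve_ae, "PVE": pve_a + pve_ae, "QEI": qei}


# ---------------------------------------------------------------------------
# genome scan


def _interval_grid(length: float, step: float) -> np.ndarray:
    """Closed grid over one interval: both endpoints included."""
    k = int(np.floor(length / step + 1e-9))
    offs = np.arange(k + 1) * step
    if length - offs[-1] > 1e-9:
        offs = np.append(offs, length)
    return offs


def _interval_priors(offsets: np.ndarray, length: float, groups: np.ndarray,
                     population: PopulationType) -> np.ndarray:
    """(P, n, 2) priors for complete flanking genotypes."""
    P = len(offsets)
    prior = np.empty((P, len(groups), 2))
    for p, off in enumerate(offsets):
        ip = interval_probabilities(off, length - off, population)
        prior[p] = ip.pi[groups]
    return prior


def _informative_flanks(row: np.ndarray, jl: int, jr: int, n_mark: int):
    left = next((k for k in range(jl, -1, -1) if not np.isnan(row[k])), None)
    right = next((k for k in range(jr, n_mark) if not np.isnan(row[k])), None)
    return left, right


def scan(gmap: GeneticMap, genotypes: MarkerGenotypes, phenotypes: PhenotypeMatrix,
         cofactors: CofactorModel | None = None, population: PopulationType = DH,
         step: float = 1.0, fit_interaction: bool = True,
         likelihood: str = "product") -> pd.DataFrame:
    """Full one-dimensional QEI scan over every marker interval.

    The adjusted phenotype (and hence the H0 fit) is computed once per
    interval; H1 and the constrained H2 are fit jointly at every grid position
    of the interval (step in cM, both endpoints included; a marker position
    shared by two intervals is reported once, from its left interval).  With
    ``fit_interaction=False`` the H2 fit is skipped and only LOD is reported
    (enough for genome-wide maxima, e.g. permutation thresholds).

    Returns a DataFrame with one row per scan position carrying the LOD
    decomposition, effect estimates and PVE components.
    """
    e = phenotypes.n_env
    if genotypes.n_individuals != phenotypes.n_individuals:
        raise ValueError("genotype and phenotype individual counts differ")
    rows = []
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        off0 = gmap.offset(chrom)
        for k in range(len(pos) - 1):
            jl, jr = off0 + k, off0 + k + 1
            length = pos[k + 1] - pos[k]
            if cofactors is not None:
                dy = adjust_phenotypes(phenotypes, cofactors, (jl, jr))
            else:
                dy = phenotypes.values
            offsets = _interval_grid(length, step)
            if k > 0:
                offsets = offsets[1:]  # shared marker reported from the left interval
            xl = genotypes.values[:, jl]
            xr = genotypes.values[:, jr]
            missing = np.isnan(xl) | np.isnan(xr)
            groups = group_index(np.where(np.isnan(xl), 1, xl),
                                 np.where(np.isnan(xr), 1, xr))
            prior = _interval_priors(offsets, length, groups, population)
            include = np.ones(len(xl), bool)
            if missing.any():
                include = _patch_missing_priors(
                    prior, offsets, pos, k, genotypes.values[:, off0:off0 + len(pos)],
                    missing, population)
            dy_used = dy[include]
            fit0 = fit_H0(dy_used)
            prior_used = prior[:, include, :]
            groups_used = groups[include]
            out1 = _ecm_batch(dy_used, prior_used, groups_used, False, likelihood)
            if fit_interaction:
                out2 = _ecm_batch(dy_used, prior_used, groups_used, True, likelihood)
                ll2 = out2["loglik"]
            else:
                ll2 = None
            mu = out1["mu"]
            a_h = 0.5 * (mu[:, 0, :] - mu[:, 1, :])
            abar = a_h.mean(axis=1)
            ae = a_h - abar[:, None]
            f1 = out1["weights"][:, :, 0].mean(axis=1)
            f2 = 1.0 - f1
            vp = float(phenotypes.variances.mean())
            v_a = 4.0 * f1 * f2 * abar**2
            v_ae = (4.0 / e) * f1 * f2 * (ae**2).sum(axis=1)
            lod = (out1["loglik"] - fit0.loglik) / LN10
            if ll2 is not None:
                lod_a = (out1["loglik"] - ll2) / LN10
                lod_ae = (ll2 - fit0.loglik) / LN10
            else:
                lod_a = np.full_like(lod, np.nan)
                lod_ae = np.full_like(lod, np.nan)
            for p in range(len(offsets)):
                rows.append((
                    chrom, pos[k] + offsets[p], lod[p], lod_a[p], lod_ae[p],
                    100.0 * (v_a[p] + v_ae[p]) / vp, 100.0 * v_a[p] / vp,
                    100.0 * v_ae[p] / vp, abar[p], *ae[p], *a_h[p],
                ))
    cols = (["chromosome", "position_cM", "LOD", "LOD_A", "LOD_AE",
             "PVE", "PVE_A", "PVE_AE", "avg_effect"]
            + [f"ae_{h + 1}" for h in range(e)] + [f"a_{h + 1}" for h in range(e)])
    return pd.DataFrame(rows, columns=cols)


def _patch_missing_priors(prior: np.ndarray, offsets: np.ndarray, pos: np.ndarray,
                          k: int, chrom_geno: np.ndarray, missing: np.ndarray,
                          population: PopulationType) -> np.ndarray:
    """Per-individual priors from the nearest informative markers.

    For individuals missing a flanking genotype, the conditional QTL
    probabilities are rebuilt from the nearest non-missing markers on each
    side; individuals with no informative marker on the chromosome are
    excluded from this interval's likelihood.  Returns the inclusion mask.
    """
    include = np.ones(len(missing), bool)
    n_mark = chrom_geno.shape[1]
    for i in np.nonzero(missing)[0]:
        row = chrom_geno[i]
        left, right = _informative_flanks(row, k, k + 1, n_mark)
        if left is None and right is None:
            include[i] = False
            continue
        for p, off in enumerate(offsets):
            qpos = pos[k] + off
            if left is not None and right is not None:
                ip = interval_probabilities(qpos - pos[left], pos[right] - qpos,
                                            population)
                pr = ip.pi[int((row[left] < 0) * 2 + (row[right] < 0))]
            else:
                j = left if left is not None else right
                r = population.effective_fraction(haldane_r(abs(qpos - pos[j])))
                p_same = 1.0 - r
                pr = (p_same, 1 - p_same) if row[j] > 0 else (1 - p_same, p_same)
            prior[p, i] = pr
    return include
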