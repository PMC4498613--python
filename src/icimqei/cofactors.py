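"""Stepwise cofactor selection and background-adjusted phenotypes.

The inclusive linear model regresses each environment's phenotype on all
marker indicator variables; forward-entry/backward-removal stepwise
regression picks the markers carrying QTL signal.  During the genome scan the
phenotype is adjusted by the fitted contributions of every selected marker
except the two flanking the current interval, which removes background
genetic variation while leaving the local QTL information intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .linkage import GeneticMap, PopulationType, DH, haldane_r, interval_probabilities
from .simulate import MarkerGenotypes, PhenotypeMatrix

__all__ = ["CofactorModel", "stepwise_select", "stepwise_cofactors",
           "adjust_phenotypes", "impute_markers"]


@dataclass
class CofactorModel:
    """Selected markers and jointly refit coefficients, one set per environment."""

    selected: list[np.ndarray]          # marker indices per environment
    coefficients: list[np.ndarray]      # matching b_jh per environment
    intercepts: np.ndarray              # b_0h
    p_in: float
    p_out: float
    marker_matrix: np.ndarray = field(repr=False)  # imputed n x m design used for fitting

    @property
    def n_env(self) -> int:
        return len(self.selected)


def impute_markers(genotypes: MarkerGenotypes, gmap: GeneticMap,
                   population: PopulationType = DH) -> np.ndarray:
    """Fill missing marker codes with their conditional expectation (regression use only).

    A missing genotype is replaced by lam*x_left + rho*x_right from the nearest
    non-missing flanking markers on the same chromosome; if only one side is
    informative the single-marker expectation (1-2r)*x_near is used, and 0 (the
    population mean) when the whole chromosome is missing for that individual.
    """
    X = genotypes.values.copy()
    if not np.isnan(X).any():
        return X
    for chrom in gmap.chromosomes:
        off = gmap.offset(chrom)
        pos = gmap.positions(chrom)
        cols = slice(off, off + len(pos))
        block = X[:, cols]
        miss_i, miss_j = np.nonzero(np.isnan(block))
        for i, j in zip(miss_i, miss_j):
            row = block[i]
            left = next((k for k in range(j - 1, -1, -1) if not np.isnan(row[k])), None)
            right = next((k for k in range(j + 1, len(pos)) if not np.isnan(row[k])), None)
            if left is not None and right is not None:
                ip = interval_probabilities(pos[j] - pos[left], pos[right] - pos[j],
                                            population)
                X[i, off + j] = ip.lam * row[left] + ip.rho * row[right]
            elif left is not None or right is not None:
                k = left if left is not None else right
                r = population.effective_fraction(haldane_r(abs(pos[j] - pos[k])))
                X[i, off + j] = (1.0 - 2.0 * r) * row[k]
            else:
                X[i, off + j] = 0.0
    return X


def _partial_f_pvalues_entry(Q: np.ndarray, resid: np.ndarray, rss: float,
                             cand: np.ndarray, df_resid: int) -> np.ndarray:
    """Entry p-value for each candidate column, given QR basis Q of the current model."""
    Z = cand - Q @ (Q.T @ cand)          # candidates orthogonalized to current design
    zz = np.einsum("ij,ij->j", Z, Z)
    zr = Z.T @ resid
    with np.errstate(divide="ignore", invalid="ignore"):
        drop = np.where(zz > 1e-12, zr**2 / zz, 0.0)
        rss_new = np.maximum(rss - drop, 0.0)
        F = drop / (rss_new / df_resid)
    p = np.where(zz > 1e-12, stats.f.sf(F, 1, df_resid), 1.0)
    return p


def stepwise_select(X: np.ndarray, y: np.ndarray, p_in: float = 0.001,
                    p_out: float = 0.002) -> tuple[np.ndarray, np.ndarray, float]:
    """Forward-entry / backward-removal stepwise regression on marker columns.

    Entry: the not-yet-selected marker with the smallest partial-F p-value
    enters if p <= p_in.  After every entry, any selected marker whose
    partial-F p-value (in the joint model) exceeds p_out is removed; this
    alternation repeats to a fixed point.  Ties break to the lower marker
    index.  Returns (selected indices, jointly refit coefficients, intercept).
    """
    if not p_in < p_out:
        raise ValueError("entry threshold p_in must be stricter than removal p_out")
    obs = ~np.isnan(y)
    y = y[obs]
    X = X[obs]
    n, m = X.shape
    selected: list[int] = []
    while True:
        k = len(selected)
        df_resid = n - k - 2  # after adding one more column
        if df_resid < 2:
            break
        design = np.column_stack([np.ones(n), X[:, selected]]) if k else np.ones((n, 1))
        Q, _ = np.linalg.qr(design)
        resid = y - Q @ (Q.T @ y)
        rss = float(resid @ resid)
        if rss <= 1e-12:
            break
        remaining = np.setdiff1d(np.arange(m), selected)
        if remaining.size == 0:
            break
        pvals = _partial_f_pvalues_entry(Q, resid, rss, X[:, remaining], df_resid)
        best = int(np.argmin(pvals))  # argmin takes the first minimum: lower index wins
        if pvals[best] > p_in:
            break
        selected.append(int(remaining[best]))
        # backward removal sweep
        while len(selected) > 1:
            p_sel = _selected_pvalues(X, y, selected)
            worst = int(np.argmax(p_sel))
            if p_sel[worst] <= p_out:
                break
            del selected[worst]
    sel = np.array(sorted(selected), dtype=int)
    if sel.size:
        design = np.column_stack([np.ones(n), X[:, sel]])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        return sel, beta[1:], float(beta[0])
    return sel, np.empty(0), float(y.mean()) if n else 0.0


def _selected_pvalues(X: np.ndarray, y: np.ndarray, selected: list[int]) -> np.ndarray:
    """Partial (type-III) F p-values of each selected marker in the joint model."""
    n = len(y)
    design = np.column_stack([np.ones(n), X[:, selected]])
    df_resid = n - design.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    XtX_inv = np.linalg.pinv(design.T @ design)
    s2 = rss / max(df_resid, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = beta[1:] ** 2 / (s2 * np.diag(XtX_inv)[1:])
    return stats.f.sf(t2, 1, max(df_resid, 1))


def stepwise_cofactors(genotypes: MarkerGenotypes, phenotypes: PhenotypeMatrix,
                       gmap: GeneticMap, population: PopulationType = DH,
                       p_in: float = 0.001, p_out: float = 0.002) -> CofactorModel:
    """Run stepwise selection independently in every environment."""
    X = impute_markers(genotypes, gmap, population)
    zero_var = X.std(axis=0) == 0.0
    selected, coefs, intercepts = [], [], []
    for h in range(phenotypes.n_env):
        Xh = X.copy()
        if zero_var.any():
            Xh[:, zero_var] = 0.0  # monomorphic markers can never enter
        sel, b, b0 = stepwise_select(Xh, phenotypes.values[:, h], p_in, p_out)
        selected.append(sel)
        coefs.append(b)
        intercepts.append(b0)
    return CofactorModel(selected=selected, coefficients=coefs,
                         intercepts=np.asarray(intercepts), p_in=p_in, p_out=p_out,
                         marker_matrix=X)


def adjust_phenotypes(phenotypes: PhenotypeMatrix, model: CofactorModel,
                      flanking: tuple[int, int]) -> np.ndarray:
    """Background-adjusted phenotypes for the interval flanked by the two markers.

    Delta_y_ih = y_ih - sum_{j selected, j not flanking} b_jh x_ij.  The
    intercept is not subtracted; the result is constant for every testing
    position inside the interval.
    """
    dy = phenotypes.values.copy()
    X = model.marker_matrix
    for h in range(model.n_env):
        keep = ~np.isin(model.selected[h], flanking)
        if keep.any():
            dy[:, h] -= X[:, model.selected[h][keep]] @ model.coefficients[h][keep]
    return dy
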