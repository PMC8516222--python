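"""Per-SNP generalized-least-squares scan for main and interaction effects.

For each marker the fixed-effect design is augmented with a centered dose
column x_snp = m - 2p and an interaction column x_inter (x_snp on HS-exposed
animals, 0 elsewhere); b1 = (X1' V^-1 X1)^-1 X1' V^-1 y with V assembled once
per (trait, week) from the pre-estimated variance components. Wald chi-square
statistics (1 df), the genomic inflation factor (median chi-square over
0.4549...), LD-based independent-SNP counting, and Bonferroni/suggestive
thresholds complete the scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import stats

from .errors import DegenerateInputError, DomainError
from .geno_qc import GenotypeMatrix
from .varcomp import MixedModelSpec, VarianceComponents

#: median of the chi-squared distribution with 1 df (lambda reference)
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))

_LN10 = log(10.0)
_SCAN_CHUNK = 512  # markers whitened per block (bounds peak memory)


def snp_columns(doses: np.ndarray, p_hat: float, exposed_mask: np.ndarray):
    """(x_snp, x_inter): all-animal centered doses and their exposed-only copy.

    Centering uses the overall allele frequency for both columns; unexposed
    entries of x_inter are 0, so b_inter is the exposed-vs-unexposed deviation
    of the allele-substitution effect.
    """
    doses = np.asarray(doses, dtype=float)
    if np.isnan(doses).any():
        raise DomainError("snp_columns requires imputed (complete) doses")
    x_snp = doses - 2.0 * float(p_hat)
    x_inter = np.where(np.asarray(exposed_mask, bool), x_snp, 0.0)
    return x_snp, x_inter


def assemble_v(spec: MixedModelSpec, vc: VarianceComponents) -> np.ndarray:
    """V = G*s2g (+ W G_hs W' * s2ghs) + I*s2e from REML estimates."""
    v = vc.sigma2_g * spec.grm.values + vc.sigma2_e * np.eye(spec.n)
    if vc.sigma2_ghs is not None and vc.sigma2_ghs > 0.0 and spec.exposed_mask.any():
        v += vc.sigma2_ghs * spec.interaction_cov()
    return v


@dataclass
class ThresholdSet:
    n_snps: int
    n_independent: int
    p_bonf: float
    p_sugg: float
    neglog_bonf: float
    neglog_sugg: float


def thresholds(n_snps: int, n_independent: int, alpha: float = 0.05) -> ThresholdSet:
    """Bonferroni (alpha/n_snps) and suggestive (alpha/n_independent) cutoffs."""
    if n_snps <= 0 or n_independent <= 0:
        raise DomainError("SNP counts must be positive")
    p_bonf = alpha / n_snps
    p_sugg = alpha / n_independent
    return ThresholdSet(
        n_snps=n_snps, n_independent=n_independent,
        p_bonf=p_bonf, p_sugg=p_sugg,
        neglog_bonf=-np.log10(p_bonf), neglog_sugg=-np.log10(p_sugg),
    )


def inflation_factor(chi2_values) -> float:
    """lambda = median(chi2) / median of chi-squared(1)."""
    arr = np.asarray(chi2_values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise DomainError("inflation factor undefined for an empty chi-square vector")
    if np.any(arr < 0):
        raise DomainError("chi-square statistics must be non-negative")
    return float(np.median(arr) / CHI2_1DF_MEDIAN)


class GlsScanner:
    """Caches one Cholesky factorization of V and the base-design cross
    products; each marker costs two triangular solves plus a rank-2 Schur
    update of X'V^-1X."""

    def __init__(self, spec: MixedModelSpec, vc: VarianceComponents):
        self.spec = spec
        self.vc = vc
        v = assemble_v(spec, vc)
        self._chol = sla.cholesky(v, lower=True)
        self._xw = sla.solve_triangular(self._chol, spec.X, lower=True)
        self._yw = sla.solve_triangular(self._chol, spec.y, lower=True)
        self._xtx = self._xw.T @ self._xw
        self._xtx_inv = np.linalg.inv(self._xtx)
        self._xty = self._xw.T @ self._yw
        self._beta0 = self._xtx_inv @ self._xty
        self._yty = float(self._yw @ self._yw)

    def whiten(self, columns: np.ndarray) -> np.ndarray:
        """L^-1 @ columns for raw (unwhitened) design columns."""
        return sla.solve_triangular(self._chol, columns, lower=True)

    def fit_whitened(self, u1: np.ndarray, u2: Optional[np.ndarray]) -> dict:
        """GLS for the augmented design, given whitened snp columns.

        Returns beta/se/chi2/p for the main (and, when estimable, the
        interaction) coordinate via the Schur complement of the cached
        normal-equation block.
        """
        cols = [u1] if u2 is None else [u1, u2]
        U = np.column_stack(cols)
        B = self._xw.T @ U                      # p x k
        C = U.T @ U                             # k x k
        r = U.T @ self._yw
        S = C - B.T @ (self._xtx_inv @ B)
        rhs = r - B.T @ self._beta0

        k = S.shape[0]
        if k == 2:
            # estimability check for the interaction coordinate
            s_cond = S[1, 1] - S[0, 1] ** 2 / S[0, 0] if S[0, 0] > 0 else 0.0
            scale = max(abs(S[0, 0]), abs(S[1, 1]), 1e-300)
            if not np.isfinite(s_cond) or s_cond <= 1e-10 * scale:
                out = self.fit_whitened(u1, None)
                out["status"] = "interaction-dropped"
                return out
        if S[0, 0] <= 0 or not np.isfinite(S).all():
            return _skipped_fit()
        try:
            s_inv = np.linalg.inv(S)
        except np.linalg.LinAlgError:
            return _skipped_fit()
        beta = s_inv @ rhs
        var = np.diag(s_inv)
        if np.any(var <= 0):
            return _skipped_fit()
        chi2 = beta**2 / var
        logp = stats.chi2.logsf(chi2, df=1)
        out = {
            "beta_main": float(beta[0]), "se_main": float(np.sqrt(var[0])),
            "chi2_main": float(chi2[0]), "p_main": float(np.exp(logp[0])),
            "neglog10_p_main": float(-logp[0] / _LN10),
            "beta_inter": np.nan, "se_inter": np.nan,
            "chi2_inter": np.nan, "p_inter": np.nan,
            "neglog10_p_inter": np.nan, "cov_main_inter": np.nan,
            "status": "ok" if k == 2 else "interaction-dropped",
        }
        if k == 2:
            out.update({
                "beta_inter": float(beta[1]), "se_inter": float(np.sqrt(var[1])),
                "chi2_inter": float(chi2[1]), "p_inter": float(np.exp(logp[1])),
                "neglog10_p_inter": float(-logp[1] / _LN10),
                "cov_main_inter": float(s_inv[0, 1]),
            })
        return out


def _skipped_fit() -> dict:
    return {
        "beta_main": np.nan, "se_main": np.nan, "chi2_main": np.nan,
        "p_main": np.nan, "neglog10_p_main": np.nan,
        "beta_inter": np.nan, "se_inter": np.nan, "chi2_inter": np.nan,
        "p_inter": np.nan, "neglog10_p_inter": np.nan,
        "cov_main_inter": np.nan, "status": "skipped",
    }


def gls_augmented(spec: MixedModelSpec, vc: VarianceComponents,
                  x_snp: np.ndarray, x_inter: Optional[np.ndarray]) -> dict:
    """One-marker GLS fit (convenience wrapper around :class:`GlsScanner`)."""
    scanner = GlsScanner(spec, vc)
    if np.ptp(x_snp) == 0.0:
        return _skipped_fit()
    u1 = scanner.whiten(x_snp)
    u2 = None
    if x_inter is not None and np.any(x_inter != 0.0):
        u2 = scanner.whiten(x_inter)
    return scanner.fit_whitened(u1, u2)


@dataclass
class ScanResult:
    trait: str
    week: int
    model: str
    fits: pd.DataFrame
    lambda_main: float
    lambda_inter: float
    thresholds: ThresholdSet
    vc: Optional[VarianceComponents] = None


def gls_scan(
    spec: MixedModelSpec,
    vc: VarianceComponents,
    genotypes: GenotypeMatrix,
    exposed_mask: Optional[np.ndarray] = None,
    trait: str = "y",
    week: int = 0,
    model: str = "GWA_wHS",
    r2_cutoff: float = 0.15,
    ld_window: int = 500,
) -> ScanResult:
    """Scan every marker; never aborts on a single bad marker.

    ``genotypes`` must be complete (post-imputation). The V factorization is
    computed once; markers are whitened in blocks.
    """
    if exposed_mask is None:
        exposed_mask = spec.exposed_mask
    exposed_mask = np.asarray(exposed_mask, bool)
    scanner = GlsScanner(spec, vc)
    doses = genotypes.doses
    if np.isnan(doses).any():
        raise DomainError("gls_scan requires imputed (complete) doses")
    n, m = doses.shape
    p_hat = doses.sum(axis=0) / (2.0 * n)

    rows = []
    any_exposed = bool(exposed_mask.any())
    for start in range(0, m, _SCAN_CHUNK):
        stop = min(start + _SCAN_CHUNK, m)
        x_main = doses[:, start:stop] - 2.0 * p_hat[start:stop]
        u_main = scanner.whiten(x_main)
        if any_exposed:
            u_inter = scanner.whiten(x_main * exposed_mask[:, None])
        for j in range(stop - start):
            if np.ptp(doses[:, start + j]) == 0.0:
                rows.append(_skipped_fit())
                continue
            u2 = u_inter[:, j] if any_exposed else None
            rows.append(scanner.fit_whitened(u_main[:, j], u2))

    fits = pd.DataFrame(rows)
    fits.insert(0, "snp_id", genotypes.markers["snp_id"].to_numpy())
    fits.insert(1, "chrom", genotypes.markers["chrom"].to_numpy())
    fits.insert(2, "pos", genotypes.markers["pos"].to_numpy())
    fits.insert(3, "maf", np.minimum(p_hat, 1.0 - p_hat))

    lam_main = inflation_factor(fits["chi2_main"]) if fits["chi2_main"].notna().any() else np.nan
    lam_inter = (inflation_factor(fits["chi2_inter"])
                 if fits["chi2_inter"].notna().any() else np.nan)
    n_indep = count_independent(genotypes, r2_cutoff=r2_cutoff, window=ld_window)
    ts = thresholds(m, n_indep)
    return ScanResult(trait=trait, week=week, model=model, fits=fits,
                      lambda_main=lam_main, lambda_inter=lam_inter,
                      thresholds=ts, vc=vc)


def count_independent(genotypes: GenotypeMatrix, r2_cutoff: float = 0.15,
                      window: int = 500) -> int:
    """Number of LD-independent markers.

    Markers are split per chromosome into consecutive non-overlapping
    ``window``-marker blocks in map order; within each block a marker is
    retained only if its squared Pearson correlation with every
    already-retained marker of the block is <= ``r2_cutoff``.
    """
    if genotypes.n_markers == 0:
        raise DomainError("no markers to count")
    doses = genotypes.doses
    filled = doses.copy()
    if np.isnan(filled).any():
        col_mean = np.nanmean(filled, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(filled))
        filled[nan_r, nan_c] = col_mean[nan_c]
    chrom = genotypes.markers["chrom"].to_numpy()
    pos = genotypes.markers["pos"].to_numpy()
    total = 0
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        for w0 in range(0, idx.size, window):
            block = idx[w0:w0 + window]
            x = filled[:, block]
            x = x - x.mean(axis=0)
            norms = np.sqrt(np.sum(x**2, axis=0))
            kept: list[int] = []
            for j in range(block.size):
                if norms[j] == 0.0:
                    continue  # monomorphic: carries no LD information
                ok = True
                for k in kept:
                    denom = norms[j] * norms[k]
                    r2 = (float(x[:, j] @ x[:, k]) / denom) ** 2
                    if r2 > r2_cutoff:
                        ok = False
                        break
                if ok:
                    kept.append(j)
            total += len(kept)
    return total


def classify_hits(scan: ScanResult) -> pd.DataFrame:
    """Label each fit none/suggestive/significant for main and interaction
    p-values (comparison is <=, so a p exactly at a threshold counts)."""
    ts = scan.thresholds
    fits = scan.fits.copy()

    def label(p):
        if pd.isna(p):
            return "none"
        if p <= ts.p_bonf:
            return "significant"
        if p <= ts.p_sugg:
            return "suggestive"
        return "none"

    fits["label_main"] = fits["p_main"].map(label)
    fits["label_inter"] = fits["p_inter"].map(label)
    return fits
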