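"""AI-REML variance components for the no-interaction and genotype-by-HS models.

Model without interaction:      y = Xb + Zg + e,        V = G*s2g + I*s2e
Model with interaction:         y = Xb + Zg + W g_hs + e,
                                V = G*s2g + W G_hs W' * s2ghs + I*s2e

Z is the identity (every phenotyped animal is genotyped); W allocates records
to exposed-animal interaction effects, so W G_hs W' is G's exposed principal
submatrix embedded at the exposed rows/columns. The restricted log-likelihood
-0.5 [log|V| + log|X'V^-1 X| + y'Py] is maximized with average-information
updates; an expectation-maximization step (guaranteed ascent) is used for the
first iterations and whenever an AI step would leave the feasible region or
decrease the likelihood. Components are floored at 1e-6 times the sample
phenotypic variance so boundary estimates (interaction ratio 0) remain
representable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .climate import ExposureTable
from .errors import DegenerateInputError, DesignError, DomainError
from .geno_qc import Grm, subset_grm

FLOOR_FRACTION = 1e-6
MAX_ITER = 200
TOL_LOGLIK = 1e-8
TOL_PARAM = 1e-6
_N_EM_WARMUP = 2  # EM iterations before AI steps are attempted


# --- fixed-effect class binning ------------------------------------------

def afc_class(months: float) -> int:
    """Age-at-first-calving class 1..6 (<=22, 23-24, 25-26, 27-28, 29-30, >=31)."""
    m = float(months)
    if m <= 22:
        return 1
    if m >= 31:
        return 6
    return int((m - 23) // 2) + 2


def dam_age_class(lactation: int, months: float) -> int:
    """Combined dam lactation x calving-age class 1..21."""
    lact = int(lactation)
    m = float(months)
    if lact < 1:
        raise DomainError("lactation number must be >= 1")
    if lact == 1:
        return afc_class(m)
    if lact == 2:
        if m <= 35:
            return 7
        if m <= 37:
            return 8
        if m <= 39:
            return 9
        if m <= 42:
            return 10
        return 11
    if lact == 3:
        if m <= 48:
            return 12
        if m <= 51:
            return 13
        if m <= 54:
            return 14
        return 15
    if lact == 4:
        if m <= 61:
            return 16
        if m <= 66:
            return 17
        return 18
    if lact == 5:
        return 19 if m <= 77 else 20
    return 21  # lactation 6 and beyond


def dim_class(days: float) -> int:
    """Days-in-milk class 1..6 (<=10, 11-15, 16-20, 21-25, 26-30, >=31)."""
    d = float(days)
    if d <= 10:
        return 1
    if d >= 31:
        return 6
    return int((d - 11) // 5) + 2


def lactation_length_class(days: float) -> int:
    """16 equal intervals over 275..305 days: min(16, floor((len-275)*16/31)+1)."""
    d = float(days)
    if d < 275 or d > 305:
        raise DomainError("lactation length must lie in 275..305 days")
    return min(16, int((d - 275) * 16 // 31) + 1)


# --- model specification --------------------------------------------------

@dataclass
class MixedModelSpec:
    """Design pieces for one (trait, week) mixed-model fit."""

    y: np.ndarray
    X: np.ndarray
    grm: Grm
    exposed_mask: np.ndarray
    ghs_grm: Optional[Grm] = None
    column_names: list = field(default_factory=list)
    dropped_columns: list = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        self.exposed_mask = np.asarray(self.exposed_mask, dtype=bool)
        n = self.y.size
        if self.X.shape[0] != n or self.exposed_mask.size != n or self.grm.n != n:
            raise DesignError("row counts of y, X, exposure mask and G disagree")

    @property
    def n(self) -> int:
        return self.y.size

    def interaction_cov(self) -> Optional[np.ndarray]:
        """W G_hs W' as a dense n x n matrix (None when nobody is exposed)."""
        if not self.exposed_mask.any():
            return None
        ghs = self.ghs_grm
        if ghs is None:
            ghs = subset_grm(self.grm, self.grm.animal_ids[self.exposed_mask])
        a = np.zeros((self.n, self.n))
        idx = np.flatnonzero(self.exposed_mask)
        a[np.ix_(idx, idx)] = ghs.values
        return a


def _drop_aliased(X: np.ndarray, names: Sequence[str], tol: float = 1e-9):
    """Keep a maximal linearly independent column subset (QR with pivoting)."""
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > tol * (diag[0] if diag.size else 1.0)))
    keep = np.sort(piv[:rank])
    dropped = [names[i] for i in sorted(set(range(X.shape[1])) - set(keep))]
    return X[:, keep], [names[i] for i in keep], dropped


def build_design(
    phenotypes: pd.DataFrame,
    trait: str,
    week: int,
    exposure: ExposureTable,
    grm: Grm,
    factors: Optional[Sequence[str]] = None,
) -> MixedModelSpec:
    """Assemble y, X (intercept + factor dummies + the week's HS dummy) and
    the exposure structures for one trait/week.

    ``factors`` defaults to every column of ``phenotypes`` named like a
    categorical fixed effect (herd, calving_year, calving_month, *_class,
    factor*). Single-level factors are skipped; aliased dummy columns are
    dropped via pivoted QR and recorded in ``dropped_columns``.
    """
    ids = grm.animal_ids
    df = phenotypes.set_index(phenotypes["animal_id"].astype(str)).loc[ids]
    if trait not in df.columns:
        raise DesignError(f"trait column {trait!r} not in phenotype table")
    y = df[trait].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise DesignError(f"trait {trait!r} has missing values")

    if factors is None:
        known = ("herd_id", "herd", "calving_year", "calving_month")
        factors = [c for c in df.columns
                   if c in known or c.endswith("_class") or c.startswith("factor")]

    cols = [np.ones(len(ids))]
    names = ["intercept"]
    for f in factors:
        levels = pd.unique(df[f])
        if len(levels) < 2:
            continue  # constant factor: absorbed by the intercept
        for lev in sorted(levels, key=str)[1:]:  # first level = reference
            cols.append((df[f] == lev).to_numpy(dtype=float))
            names.append(f"{f}={lev}")

    exposed = exposure.exposed_mask(ids, week)
    if exposed.any() and not exposed.all():
        cols.append(exposed.astype(float))
        names.append(f"hs_week{week}")

    X = np.column_stack(cols)
    X, kept, dropped = _drop_aliased(X, names)
    ghs = subset_grm(grm, ids[exposed]) if exposed.any() else None
    return MixedModelSpec(y=y, X=X, grm=grm, exposed_mask=exposed,
                          ghs_grm=ghs, column_names=kept, dropped_columns=dropped)


# --- variance components --------------------------------------------------

@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    sigma2_ghs: Optional[float] = None
    loglik: float = float("nan")
    n_iter: int = 0
    converged: bool = False
    se: Optional[dict] = None
    loglik_history: list = field(default_factory=list)
    model: str = ""

    @property
    def total_variance(self) -> float:
        return self.sigma2_g + (self.sigma2_ghs or 0.0) + self.sigma2_e


def ratios(vc: VarianceComponents):
    """h2_g for the plain model; (h2_c, r_hs) for the interaction model."""
    total = vc.total_variance
    if total <= 0.0:
        raise DegenerateInputError("zero total variance: ratios undefined")
    if vc.sigma2_ghs is None:
        return vc.sigma2_g / total
    return vc.sigma2_g / total, vc.sigma2_ghs / total


@dataclass
class _State:
    ll: float
    yp_a_py: np.ndarray   # y'P A_i P y per component
    tr_pa: np.ndarray     # tr(P A_i) per component
    ai: np.ndarray        # average-information matrix


def _dense_evaluator(y, X, comps):
    """Evaluator over dense covariance structures. ``comps`` is a list of
    n x n matrices (identity included explicitly)."""
    n = y.size

    def evaluate(theta: np.ndarray) -> _State:
        V = np.zeros((n, n))
        for t, A in zip(theta, comps):
            V += t * A
        c, low = sla.cho_factor(V, lower=True)
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        vinv = sla.cho_solve((c, low), np.eye(n))
        vinv_x = sla.cho_solve((c, low), X)
        xtvx = X.T @ vinv_x
        cx = sla.cho_factor(xtvx, lower=True)
        logdet_x = 2.0 * np.sum(np.log(np.diag(cx[0])))
        P = vinv - vinv_x @ sla.cho_solve(cx, vinv_x.T)
        py = P @ y
        ll = -0.5 * (logdet_v + logdet_x + float(y @ py))
        k = len(comps)
        w = [A @ py for A in comps]
        yp_a_py = np.array([float(py @ wi) for wi in w])
        tr_pa = np.array([float(np.sum(P * A)) for A in comps])  # all A symmetric
        pw = [P @ wi for wi in w]
        ai = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                ai[i, j] = ai[j, i] = 0.5 * float(w[i] @ pw[j])
        return _State(ll, yp_a_py, tr_pa, ai)

    return evaluate


def _rotated_evaluator(y, X, grm_values):
    """Two-component fast path: rotate by the eigenvectors of G so V is
    diagonal and every per-iteration quantity is O(n p^2)."""
    d, u = np.linalg.eigh(grm_values)
    d = np.clip(d, 0.0, None)
    ys = u.T @ y
    xs = u.T @ X

    def evaluate(theta: np.ndarray) -> _State:
        s2g, s2e = theta
        v = s2g * d + s2e
        logdet_v = float(np.sum(np.log(v)))
        vinv_x = xs / v[:, None]
        xtvx = xs.T @ vinv_x
        cx = sla.cho_factor(xtvx, lower=True)
        logdet_x = 2.0 * np.sum(np.log(np.diag(cx[0])))
        vinv_y = ys / v
        alpha = sla.cho_solve(cx, xs.T @ vinv_y)
        py = vinv_y - vinv_x @ alpha
        ll = -0.5 * (logdet_v + logdet_x + float(ys @ py))

        def p_mult(w):
            vw = w / v
            return vw - vinv_x @ sla.cho_solve(cx, xs.T @ vw)

        t = sla.cho_solve(cx, vinv_x.T)  # p x n
        diag_p = 1.0 / v - np.einsum("ij,ji->i", vinv_x, t)
        w_g = d * py
        w_e = py
        pw_g = p_mult(w_g)
        pw_e = p_mult(w_e)
        yp_a_py = np.array([float(py @ w_g), float(py @ w_e)])
        tr_pa = np.array([float(np.sum(d * diag_p)), float(np.sum(diag_p))])
        ai = 0.5 * np.array([
            [float(w_g @ pw_g), float(w_g @ pw_e)],
            [float(w_g @ pw_e), float(w_e @ pw_e)],
        ])
        return _State(ll, yp_a_py, tr_pa, ai)

    return evaluate


def reml_loglik(spec: MixedModelSpec, sigma2_g: float, sigma2_e: float,
                sigma2_ghs: Optional[float] = None) -> float:
    """Restricted log-likelihood at given components (dense evaluation)."""
    comps = [spec.grm.values, np.eye(spec.n)]
    theta = [sigma2_g, sigma2_e]
    if sigma2_ghs is not None:
        a_hs = spec.interaction_cov()
        if a_hs is None:
            raise DegenerateInputError("no exposed animals: interaction term undefined")
        comps.insert(1, a_hs)
        theta = [sigma2_g, sigma2_ghs, sigma2_e]
    ev = _dense_evaluator(spec.y, spec.X, comps)
    return ev(np.asarray(theta, float)).ll


def _maximize(evaluate: Callable[[np.ndarray], _State], theta0, q, floor):
    """Shared ascent loop: AI step with EM warm-up/fallback and flooring."""
    theta = np.asarray(theta0, dtype=float)
    q = np.asarray(q, dtype=float)
    st = evaluate(theta)
    history = [st.ll]
    converged = False
    n_iter = 0
    for it in range(1, MAX_ITER + 1):
        n_iter = it
        score = 0.5 * (st.yp_a_py - st.tr_pa)
        em = theta + theta**2 * (st.yp_a_py - st.tr_pa) / q
        em = np.maximum(em, floor)
        candidates = []
        if it > _N_EM_WARMUP:
            try:
                delta = np.linalg.solve(st.ai, score)
                ai_theta = theta + delta
                if np.all(ai_theta >= floor):
                    candidates.append(ai_theta)
                else:
                    # AI step leaves the feasible region: offer the step with
                    # offending components pinned at the floor (boundary
                    # estimates), still subject to the ascent check below
                    candidates.append(np.maximum(ai_theta, floor))
            except np.linalg.LinAlgError:
                pass
        candidates.append(em)

        accepted = None
        for cand in candidates:
            try:
                st_new = evaluate(cand)
            except (np.linalg.LinAlgError, sla.LinAlgError):
                continue
            if st_new.ll >= st.ll - 1e-10:
                accepted = (cand, st_new)
                break
        if accepted is None:  # numerical corner: keep the EM iterate regardless
            cand = candidates[-1]
            accepted = (cand, evaluate(cand))
        theta_new, st_new = accepted
        dll = st_new.ll - st.ll
        rel = np.max(np.abs(theta_new - theta) / np.maximum(np.abs(theta), floor))
        theta, st = theta_new, st_new
        history.append(st.ll)
        if abs(dll) < TOL_LOGLIK or rel < TOL_PARAM:
            converged = True
            break
    se = None
    try:
        se = np.sqrt(np.diag(np.linalg.inv(st.ai)))
    except np.linalg.LinAlgError:
        pass
    return theta, st.ll, n_iter, converged, se, history


def reml_fit(spec: MixedModelSpec, model: str = "whs") -> VarianceComponents:
    """Estimate variance components by AI-REML.

    ``model='nhs'`` fits (s2g, s2e); ``model='whs'`` adds s2ghs with the
    exposed-subset relationship structure. A 'whs' request with zero exposed
    animals degrades to the 'nhs' fit (the interaction term is undefined).
    """
    if model not in ("nhs", "whs"):
        raise DomainError(f"model must be 'nhs' or 'whs', got {model!r}")
    y = spec.y
    vary = float(np.var(y))
    if vary <= 0.0:
        raise DegenerateInputError("phenotype has zero variance")
    floor = FLOOR_FRACTION * vary

    with_inter = model == "whs" and spec.exposed_mask.any()
    if with_inter:
        a_hs = spec.interaction_cov()
        comps = [spec.grm.values, a_hs, np.eye(spec.n)]
        theta0 = np.array([0.5 * vary, 0.1 * vary, 0.5 * vary])
        q = np.array([spec.n, int(spec.exposed_mask.sum()), spec.n], dtype=float)
        evaluate = _dense_evaluator(y, spec.X, comps)
    else:
        theta0 = np.array([0.5 * vary, 0.5 * vary])
        q = np.array([spec.n, spec.n], dtype=float)
        evaluate = _rotated_evaluator(y, spec.X, spec.grm.values)

    theta, ll, n_iter, converged, se, history = _maximize(evaluate, theta0, q, floor)

    if with_inter:
        se_map = None
        if se is not None:
            se_map = {"sigma2_g": se[0], "sigma2_ghs": se[1], "sigma2_e": se[2]}
        return VarianceComponents(
            sigma2_g=float(theta[0]), sigma2_ghs=float(theta[1]),
            sigma2_e=float(theta[2]), loglik=ll, n_iter=n_iter,
            converged=converged, se=se_map, loglik_history=history, model="whs")
    se_map = {"sigma2_g": se[0], "sigma2_e": se[1]} if se is not None else None
    return VarianceComponents(
        sigma2_g=float(theta[0]), sigma2_ghs=(0.0 if model == "whs" else None),
        sigma2_e=float(theta[1]), loglik=ll, n_iter=n_iter,
        converged=converged, se=se_map, loglik_history=history, model=model)
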