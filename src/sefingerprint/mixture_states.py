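"""Per-CE two-component Gaussian mixture modeling of log2 activities.

Each constituent enhancer's log2 activity across the cell panel is modeled
as a mixture of an inactive and an active normal component.  Global priors —
component means and SDs fit per cell line over genome-wide CEs and averaged
— initialize the per-CE EM fits and provide a fallback state rule when a
CE's own fit degenerates (uniformly active or inactive CEs, where a
two-component fit cannot separate anything).  A cell line is called active
for a CE when its posterior probability of the active component exceeds 0.5
(strictly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .activity_matrix import ActivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GlobalPriors",
    "MixtureFit",
    "fit_global_priors",
    "em_fit",
    "assign_states",
    "classify_ce",
    "fit_states",
]

VARIANCE_FLOOR = 1e-3  # log2 units squared; crossing it triggers fallback


@dataclass
class GlobalPriors:
    """Panel-wide consensus of active/inactive component parameters.

    Per-cell-line two-component fits over genome-wide CEs, averaged
    (unweighted) across cell lines.  ``per_cell_line`` retains the
    individual fits for audit.
    """

    mu_active: float
    mu_inactive: float
    sd_active: float
    sd_inactive: float
    per_cell_line: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.mu_active > self.mu_inactive:
            raise ValueError("mu_active must exceed mu_inactive")
        if self.sd_active <= 0 or self.sd_inactive <= 0:
            raise ValueError("component SDs must be positive")


@dataclass
class MixtureFit:
    """A fitted two-component mixture for one CE.

    Component order is (inactive, active): ``mu[1] >= mu[0]`` after
    relabeling.  ``posterior_active`` aligns with the input values.
    ``fit_class`` is ``mixed`` for a clean two-component fit or
    ``degenerate_fallback`` when the fit collapsed (variance floor, merged
    means, or a near-empty component) and state calls must come from the
    global priors instead.
    """

    ce_id: str
    mu: tuple[float, float]
    sigma: tuple[float, float]
    pi: tuple[float, float]
    posterior_active: np.ndarray
    loglik_trace: np.ndarray
    n_iter: int
    fit_class: str
    converged: bool = True

    @property
    def boundary(self) -> float | None:
        """Activity value where the active posterior crosses 0.5 (the
        model-derived activity cutoff); None for degenerate fits."""
        if self.fit_class != "mixed":
            return None
        lo, hi = self.mu
        from scipy.optimize import brentq

        def f(x: float) -> float:
            return self._posterior_at(x) - 0.5

        try:
            return float(brentq(f, lo, hi))
        except ValueError:
            return None

    def _posterior_at(self, x: float) -> float:
        la = np.log(self.pi[1]) + norm.logpdf(x, self.mu[1], self.sigma[1])
        li = np.log(self.pi[0]) + norm.logpdf(x, self.mu[0], self.sigma[0])
        return float(np.exp(la - np.logaddexp(la, li)))


def _em_core(values: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
             pi: np.ndarray, tol: float, max_iter: int,
             prior_mu: np.ndarray | None = None,
             prior_var: np.ndarray | None = None,
             kappa: float = 0.0, nu: float = 0.0
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                        list[float], bool, bool]:
    """EM for a 1-D two-component Gaussian mixture, optionally MAP-penalized.

    With ``kappa``/``nu`` > 0 the component means and variances carry
    conjugate priors centered on ``prior_mu``/``prior_var`` (normal with
    pseudo-count ``kappa``; scaled inverse-chi-square with ``nu`` pseudo
    observations), and the trace records the penalized objective that EM
    then maximizes.  Returns (mu, sigma, pi, responsibilities, trace,
    converged, floor_hit).
    """
    n = len(values)
    penalized = kappa > 0 or nu > 0
    if penalized and (prior_mu is None or prior_var is None):
        raise ValueError("MAP penalty requires prior means and variances")
    trace: list[float] = []
    resp = np.full((n, 2), 0.5)
    converged = False
    floor_hit = False

    def objective(ll: float, mu: np.ndarray, var: np.ndarray) -> float:
        if not penalized:
            return ll
        pen = float(
            (-0.5 * kappa * (mu - prior_mu) ** 2 / var
             - 0.5 * (nu + 3) * np.log(var)
             - 0.5 * nu * prior_var / var).sum())
        return ll + pen

    for _ in range(max_iter):
        # E step
        log_comp = (np.log(pi)[None, :]
                    + norm.logpdf(values[:, None], mu[None, :], sigma[None, :]))
        log_norm = logsumexp(log_comp, axis=1)
        resp = np.exp(log_comp - log_norm[:, None])
        trace.append(objective(float(log_norm.sum()), mu, sigma ** 2))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol:
            converged = True
            break
        # M step
        nk = resp.sum(axis=0)
        if (nk <= 0).any():
            floor_hit = True
            break
        pi = nk / n
        xbar = (resp * values[:, None]).sum(axis=0) / nk
        if penalized:
            mu = (nk * xbar + kappa * prior_mu) / (nk + kappa)
            ss = (resp * (values[:, None] - mu[None, :]) ** 2).sum(axis=0)
            var = (ss + kappa * (mu - prior_mu) ** 2 + nu * prior_var) \
                / (nk + nu + 3)
        else:
            mu = xbar
            var = (resp * (values[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        if (var < VARIANCE_FLOOR).any():
            floor_hit = True
            break
        sigma = np.sqrt(var)
    return mu, sigma, pi, resp, trace, converged, floor_hit


def em_fit(
    values: np.ndarray,
    init: GlobalPriors,
    tol: float = 1e-8,
    max_iter: int = 1000,
    ce_id: str = "",
    prior_mode: str = "map",
    prior_kappa: float = 1.0,
    prior_nu: float = 2.0,
) -> MixtureFit:
    """Fit one CE's two-component mixture by EM.

    The global priors seed the component means and SDs (weights start
    0.5/0.5) and, in the default ``prior_mode='map'``, additionally anchor
    the per-CE fit through conjugate penalties (``prior_kappa`` pseudo
    observations on each mean, ``prior_nu`` on each variance) — a weak pull
    that prevents a component from collapsing onto a few-point subcluster
    far from the panel-wide consensus.  ``prior_mode='init'`` uses the
    priors for initialization only (plain maximum-likelihood EM).
    Convergence when the EM objective changes by at most ``tol``.
    Degeneracy — the variance floor being hit, the fitted means closer than
    half the pooled SD, or a component claiming less than one expected
    observation — yields ``fit_class='degenerate_fallback'``.
    """
    if prior_mode not in ("map", "init"):
        raise ValueError(f"unknown prior_mode {prior_mode!r}")
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2 or np.allclose(values, values[0]):
        return MixtureFit(ce_id, (float(values.min()), float(values.max())),
                          (np.sqrt(VARIANCE_FLOOR),) * 2, (0.5, 0.5),
                          posterior_active=np.full(n, np.nan),
                          loglik_trace=np.array([]), n_iter=0,
                          fit_class="degenerate_fallback")
    mu = np.array([init.mu_inactive, init.mu_active], dtype=float)
    sigma = np.array([init.sd_inactive, init.sd_active], dtype=float)
    pi = np.array([0.5, 0.5])
    if prior_mode == "map":
        mu, sigma, pi, resp, trace, converged, floor_hit = _em_core(
            values, mu, sigma, pi, tol, max_iter,
            prior_mu=mu.copy(), prior_var=sigma.copy() ** 2,
            kappa=prior_kappa, nu=prior_nu)
    else:
        mu, sigma, pi, resp, trace, converged, floor_hit = _em_core(
            values, mu, sigma, pi, tol, max_iter)
    if not converged and not floor_hit:
        logger.warning("EM for %s hit max_iter=%d without converging",
                       ce_id or "<ce>", max_iter)

    # relabel so component 1 is the active (larger-mean) one
    order = np.argsort(mu)
    mu, sigma, pi = mu[order], sigma[order], pi[:][order]
    resp = resp[:, order]

    pooled_sd = float(np.sqrt(0.5 * (sigma[0] ** 2 + sigma[1] ** 2)))
    degenerate = (
        floor_hit
        or (mu[1] - mu[0]) < 0.5 * pooled_sd
        or min(pi) * n < 1.0
    )
    return MixtureFit(
        ce_id=ce_id,
        mu=(float(mu[0]), float(mu[1])),
        sigma=(float(sigma[0]), float(sigma[1])),
        pi=(float(pi[0]), float(pi[1])),
        posterior_active=resp[:, 1],
        loglik_trace=np.asarray(trace),
        n_iter=len(trace),
        fit_class="degenerate_fallback" if degenerate else "mixed",
        converged=converged,
    )


def fit_global_priors(
    m: ActivityMatrix,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> GlobalPriors:
    """Fit per-cell-line global mixtures over genome-wide CEs and average.

    ``m`` is the log2 matrix; occurrences that were zero before imputation
    (``zero_mask``) are excluded from each cell line's fit.  Cell lines
    whose fit degenerates are dropped from the average with a warning; if
    every cell line degenerates the input is rejected.
    """
    if m.stage != "log2":
        raise ValueError(f"expected log2 matrix, got {m.stage}")
    rows = []
    for col in m.columns:
        vec = m.values[col]
        if m.zero_mask is not None:
            vec = vec[~m.zero_mask[col]]
        values = vec.to_numpy(dtype=float)
        if len(values) < 4:
            logger.warning("cell line %s has <4 usable CEs; skipped", col)
            continue
        # moment-based initialization: quartiles for means, overall SD
        q25, q75 = np.quantile(values, [0.25, 0.75])
        if q75 <= q25:
            q75 = q25 + 1.0
        sd0 = max(float(values.std(ddof=0)) / 2, np.sqrt(VARIANCE_FLOOR) * 2)
        seed_prior = GlobalPriors(mu_active=float(q75), mu_inactive=float(q25),
                                  sd_active=sd0, sd_inactive=sd0)
        fit = em_fit(values, seed_prior, tol=tol, max_iter=max_iter,
                     ce_id=f"global:{col}")
        if fit.fit_class != "mixed":
            logger.warning("global fit for cell line %s collapsed; excluded",
                           col)
            continue
        rows.append({"cell_line": col,
                     "mu_inactive": fit.mu[0], "mu_active": fit.mu[1],
                     "sd_inactive": fit.sigma[0], "sd_active": fit.sigma[1],
                     "pi_active": fit.pi[1]})
    if not rows:
        raise ValueError("all per-cell-line global fits collapsed")
    table = pd.DataFrame(rows).set_index("cell_line")
    return GlobalPriors(
        mu_active=float(table["mu_active"].mean()),
        mu_inactive=float(table["mu_inactive"].mean()),
        sd_active=float(table["sd_active"].mean()),
        sd_inactive=float(table["sd_inactive"].mean()),
        per_cell_line=table,
    )


def assign_states(
    fit: MixtureFit, priors: GlobalPriors, values: np.ndarray | None = None
) -> np.ndarray:
    """Boolean active calls for one CE across cell lines.

    Mixed fits: active iff the active-component posterior is strictly
    greater than 0.5 (a posterior of exactly 0.5 is inactive).  Degenerate
    fits: each value is assigned to whichever global prior mean is closer,
    which is how uniformly active / uniformly inactive CEs are recognized.
    """
    if fit.fit_class == "mixed":
        return fit.posterior_active > 0.5
    if values is None:
        raise ValueError("degenerate fit requires the raw values")
    values = np.asarray(values, dtype=float)
    return (np.abs(values - priors.mu_active)
            < np.abs(values - priors.mu_inactive))


def classify_ce(states: np.ndarray) -> str:
    """Three-way CE class: all_active / all_inactive / mixed."""
    states = np.asarray(states, dtype=bool)
    if states.all():
        return "all_active"
    if not states.any():
        return "all_inactive"
    return "mixed"


def fit_states(
    m: ActivityMatrix,
    priors: GlobalPriors,
    ce_ids: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    prior_mode: str = "map",
) -> tuple[pd.DataFrame, dict[str, MixtureFit], pd.DataFrame]:
    """Fit every CE and emit the binary state matrix.

    Returns ``(states, fits, fit_table)``: a complete boolean CE x cell-line
    frame, the per-CE :class:`MixtureFit` objects, and a summary table with
    one row per CE (component parameters, fit class, three-way CE class and
    state provenance).
    """
    if m.stage != "log2":
        raise ValueError(f"expected log2 matrix, got {m.stage}")
    ce_ids = list(ce_ids) if ce_ids is not None else list(m.regions)
    states = {}
    fits: dict[str, MixtureFit] = {}
    rows = []
    for ce in ce_ids:
        values = m.values.loc[ce].to_numpy(dtype=float)
        # occurrences with zero coverage before imputation are inactive by
        # definition and their imputed placeholder values would otherwise
        # form an artificial low spike in the likelihood; fit on the
        # observed occurrences only, call the zeros inactive directly
        observed = np.ones(len(values), dtype=bool)
        if m.zero_mask is not None:
            observed = ~m.zero_mask.loc[ce].to_numpy(dtype=bool)
        fit = em_fit(values[observed], priors, tol=tol, max_iter=max_iter,
                     ce_id=ce, prior_mode=prior_mode)
        calls = np.zeros(len(values), dtype=bool)
        calls[observed] = assign_states(fit, priors, values[observed])
        states[ce] = calls
        fits[ce] = fit
        rows.append({
            "ce_id": ce,
            "mu_inactive": fit.mu[0], "mu_active": fit.mu[1],
            "sd_inactive": fit.sigma[0], "sd_active": fit.sigma[1],
            "pi_active": fit.pi[1],
            "n_iter": fit.n_iter,
            "fit_class": fit.fit_class,
            "ce_class": classify_ce(calls),
            "provenance": "model" if fit.fit_class == "mixed" else "fallback",
        })
    state_df = pd.DataFrame.from_dict(states, orient="index",
                                      columns=list(m.columns)).loc[ce_ids]
    return state_df, fits, pd.DataFrame(rows).set_index("ce_id")
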