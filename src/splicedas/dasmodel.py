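"""Beta-binomial differential splicing test.

Isoform-support counts for a two-isoform event are modelled per sample as
beta-binomial: n_inc ~ BetaBin(n_inc + n_exc, alpha = p * theta,
beta = (1 - p) * theta), the two-category specialisation of the
Dirichlet-Multinomial. The null model shares a single inclusion proportion p
across groups; the alternative gives each group its own p_g; the precision
theta (= alpha + beta) is shared across samples and estimated freely under
both models. Group differences are assessed by a likelihood-ratio test with
chi-squared reference distribution on (#groups - 1) degrees of freedom.

PSI (percent spliced in) is the pooled inclusion fraction
sum(n_inc) / sum(n_inc + n_exc) within a group; a differential (DAS) call
requires |delta PSI| > 0.05 and BH-adjusted q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, expit, gammaln, logit
from scipy.stats import chi2

LOGIT_BOUND = 12.0
LOG_THETA_BOUNDS = (-5.0, 10.0)


@dataclass
class BetaBinFit:
    p: np.ndarray  # per-group inclusion proportions (length 1 under the null)
    theta: float
    loglik: float
    converged: bool


def betabin_loglik(k: np.ndarray, n: np.ndarray, p: float, theta: float) -> float:
    """Log-likelihood of counts k of n under BetaBin(p*theta, (1-p)*theta)."""
    a = p * theta
    b = (1.0 - p) * theta
    ll = (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + betaln(k + a, n - k + b)
        - betaln(a, b)
    )
    return float(np.sum(ll))


def _nll(params: np.ndarray, k: np.ndarray, n: np.ndarray, gidx: np.ndarray) -> float:
    G = len(params) - 1
    p = expit(params[:G])
    theta = np.exp(params[G])
    a = p[gidx] * theta
    b = (1.0 - p[gidx]) * theta
    ll = betaln(k + a, n - k + b) - betaln(a, b)
    return -float(np.sum(ll))  # binomial coefficient is parameter-free


def fit_beta_binomial(
    n_inc: np.ndarray,
    n_exc: np.ndarray,
    groups: np.ndarray | None = None,
    theta: float | None = None,
    extra_starts: list[np.ndarray] | None = None,
) -> BetaBinFit:
    """Maximum-likelihood beta-binomial fit.

    ``groups`` is an integer group index per sample (None => single shared
    proportion, the null model). With ``theta`` given, the precision is held
    fixed and only the proportions are profiled. Optimisation is over
    (logit p_g[, log theta]) with bounds keeping parameters finite and the
    likelihood smooth.
    """
    k = np.asarray(n_inc, dtype=float)
    n = k + np.asarray(n_exc, dtype=float)
    if np.any(n < 0) or np.any(k < 0) or np.any(k > n):
        raise ValueError("counts must be non-negative with n_inc <= total")
    gidx = np.zeros(len(k), dtype=int) if groups is None else np.asarray(groups)
    G = int(gidx.max()) + 1

    # moment-style starts: per-group pooled proportion; several thetas
    p0 = np.empty(G)
    for g in range(G):
        tot = n[gidx == g].sum()
        p0[g] = (k[gidx == g].sum() + 0.5) / (tot + 1.0) if tot > 0 else 0.5
    lp0 = np.clip(logit(p0), -LOGIT_BOUND, LOGIT_BOUND)

    if theta is not None:
        log_th = np.log(theta)
        starts = [np.concatenate([lp0, [log_th]])]
        theta_bounds = (log_th, log_th)
    else:
        starts = [np.concatenate([lp0, [np.log(t)]]) for t in (5.0, 50.0, 1000.0)]
        theta_bounds = LOG_THETA_BOUNDS
    if extra_starts:
        starts.extend(extra_starts)

    bounds = [(-LOGIT_BOUND, LOGIT_BOUND)] * G + [theta_bounds]
    best = None
    ok = False
    for x0 in starts:
        res = minimize(
            _nll, x0, args=(k, n, gidx), method="L-BFGS-B", bounds=bounds
        )
        if best is None or res.fun < best.fun:
            best = res
            ok = res.success
    assert best is not None
    p_hat = expit(best.x[:G])
    theta_hat = float(np.exp(best.x[G]))
    ll = -best.fun + float(
        np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))
    )
    return BetaBinFit(p=p_hat, theta=theta_hat, loglik=ll, converged=bool(ok))


def pooled_dispersion(
    n_inc: np.ndarray, n_exc: np.ndarray, groups: np.ndarray
) -> float:
    """Common beta-binomial precision theta estimated across events.

    Williams-type moment estimator on within-group residuals: with
    v_i = 1 + (n_i - 1) * rho and the group proportion fitted by pooling,
    E[X^2] = sum_i v_i * (1 - n_i / N) per event and group, where
    X^2 = sum_i (k_i - n_i p_g)^2 / (n_i p_g (1 - p_g)). Group mean shifts
    never enter, so the estimate is unbiased under differential splicing;
    pooling the moment equation across events makes it precise even with
    very few samples per group. rho = 1/(theta + 1).

    ``n_inc``/``n_exc`` are events x samples arrays; ``groups`` is the
    integer group index per sample column.
    """
    k = np.atleast_2d(np.asarray(n_inc, dtype=float))
    n = k + np.atleast_2d(np.asarray(n_exc, dtype=float))
    gidx = np.asarray(groups)
    x2 = 0.0
    a = 0.0
    b = 0.0
    for g in np.unique(gidx):
        kk = k[:, gidx == g]
        nn = n[:, gidx == g]
        ok = nn > 0
        ng = np.where(ok, nn, np.nan)
        N = np.nansum(ng, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pg = np.clip(np.nansum(kk, axis=1, keepdims=True) / N, 1e-6, 1 - 1e-6)
            resid = (kk - ng * pg) ** 2 / (ng * pg * (1 - pg))
            w = 1.0 - ng / N
        x2 += np.nansum(resid)
        a += np.nansum(w)
        b += np.nansum((ng - 1) * w)
    if b <= 0:
        return float(np.exp(LOG_THETA_BOUNDS[1]))
    rho = (x2 - a) / b
    rho = min(max(rho, 1e-6), 0.99)
    theta = 1.0 / rho - 1.0
    return float(np.clip(theta, np.exp(LOG_THETA_BOUNDS[0]), np.exp(LOG_THETA_BOUNDS[1])))


def lrt_event(
    n_inc: np.ndarray,
    n_exc: np.ndarray,
    groups: np.ndarray,
    theta: float | None = None,
) -> tuple[float, float, BetaBinFit, BetaBinFit]:
    """Likelihood-ratio test of group-specific vs shared inclusion proportion.

    With ``theta`` given (normally the pooled across-events estimate from
    :func:`pooled_dispersion`), the precision is held fixed under both models
    and only the proportions are profiled; with ``theta=None`` the precision
    is re-estimated freely under each model (the textbook per-event LRT,
    which is badly anticonservative at a few samples per group — see docs).
    Returns (statistic, p, null fit, alternative fit); the statistic is
    clipped at zero, p is the chi-squared upper tail with df = G - 1.
    """
    gidx = np.asarray(groups)
    G = int(gidx.max()) + 1
    null = fit_beta_binomial(n_inc, n_exc, groups=None, theta=theta)
    # seed the alternative from the null optimum: the null is nested, so the
    # alternative log-likelihood can never fall below it
    null_start = np.concatenate(
        [
            np.clip(logit(np.repeat(null.p, G)), -LOGIT_BOUND, LOGIT_BOUND),
            [np.log(null.theta)],
        ]
    )
    alt = fit_beta_binomial(
        n_inc, n_exc, groups=gidx, theta=theta, extra_starts=[null_start]
    )
    stat = max(0.0, 2.0 * (alt.loglik - null.loglik))
    p = float(chi2.sf(stat, df=G - 1)) if G > 1 else 1.0
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return stat, p, null, alt


def estimate_psi(n_inc: np.ndarray, n_exc: np.ndarray) -> float:
    """Pooled PSI: sum of inclusion counts over sum of totals for one group."""
    k = float(np.sum(n_inc))
    tot = k + float(np.sum(n_exc))
    if tot <= 0:
        raise ValueError("PSI undefined: all totals are zero")
    return k / tot


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _pooled_theta_from_tidy(
    sub: pd.DataFrame, case: str, min_group_coverage: int
) -> float:
    """Pooled dispersion across the events that pass the coverage filter."""
    inc = sub.pivot_table(
        index="event_id", columns="sample_id", values="n_inc", fill_value=0
    )
    exc = sub.pivot_table(
        index="event_id", columns="sample_id", values="n_exc", fill_value=0
    )
    exc = exc.reindex(index=inc.index, columns=inc.columns, fill_value=0)
    group_of = dict(zip(sub["sample_id"], sub["group"]))
    gidx = np.array([0 if group_of[s] == case else 1 for s in inc.columns])
    tot = inc.to_numpy(float) + exc.to_numpy(float)
    cov_ok = np.ones(len(inc), dtype=bool)
    for g in (0, 1):
        cov_ok &= tot[:, gidx == g].sum(axis=1) >= min_group_coverage
    if not cov_ok.any():
        cov_ok[:] = True
    return pooled_dispersion(
        inc.to_numpy(float)[cov_ok], exc.to_numpy(float)[cov_ok], gidx
    )


def run_das(
    counts: pd.DataFrame,
    case: str,
    control: str,
    min_group_coverage: int = 10,
) -> pd.DataFrame:
    """Fit and test every event in a tidy counts table (columns event_id,
    sample_id, group, n_inc, n_exc) for a case-vs-control contrast.

    Events where either group has total coverage below ``min_group_coverage``
    are reported with NA statistics and excluded from the BH adjustment.
    The beta-binomial precision is estimated once across all tested events
    (:func:`pooled_dispersion`) and shared by every per-event test.
    Returns a frame with psi_case, psi_control, delta_psi, lrt, p, q.
    """
    sub = counts[counts["group"].isin([case, control])]
    theta = _pooled_theta_from_tidy(sub, case, min_group_coverage)
    rows = []
    for event_id, df in sub.groupby("event_id", sort=True):
        is_case = (df["group"] == case).to_numpy()
        k = df["n_inc"].to_numpy(float)
        n = k + df["n_exc"].to_numpy(float)
        cov_case = n[is_case].sum()
        cov_ctrl = n[~is_case].sum()
        tested = cov_case >= min_group_coverage and cov_ctrl >= min_group_coverage
        rec: dict = {"event_id": event_id}
        if tested:
            gidx = np.where(is_case, 0, 1)
            stat, p, _, _ = lrt_event(
                df["n_inc"].to_numpy(), df["n_exc"].to_numpy(), gidx, theta=theta
            )
            rec.update(
                psi_case=estimate_psi(k[is_case], n[is_case] - k[is_case]),
                psi_control=estimate_psi(k[~is_case], n[~is_case] - k[~is_case]),
                lrt=stat,
                p=p,
            )
        else:
            rec.update(psi_case=np.nan, psi_control=np.nan, lrt=np.nan, p=np.nan)
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["delta_psi"] = out["psi_case"] - out["psi_control"]
    out["q"] = np.nan
    tested_mask = out["p"].notna()
    if tested_mask.any():
        out.loc[tested_mask, "q"] = bh_adjust(out.loc[tested_mask, "p"].to_numpy())
    return out


def call_das(
    records: pd.DataFrame,
    dpsi_threshold: float = 0.05,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Flag significant events: |delta PSI| strictly above dpsi_threshold AND
    q strictly below q_threshold."""
    out = records.copy()
    out["significant"] = (
        (out["delta_psi"].abs() > dpsi_threshold) & (out["q"] < q_threshold)
    ).fillna(False)
    return out


def das_type_summary(records: pd.DataFrame, events_by_id: dict) -> pd.DataFrame:
    """Tally significant events per splicing type."""
    sig = records[records["significant"]]
    types = [events_by_id[e].event_type for e in sig["event_id"] if e in events_by_id]
    counts = pd.Series(types).value_counts() if types else pd.Series(dtype=int)
    return pd.DataFrame(
        {
            "type": list(counts.index),
            "n_significant": list(counts.values),
        }
    )
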