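"""Bulk signature scoring and survival analysis.

The signature score of a bulk sample is the mean over signature genes of the
per-gene z-scored log1p expression — a standard composite proxy for the
abundance of the cell population the signature marks. Survival read-outs are
the log-rank test between score groups and a multivariate Cox
proportional-hazards model (Newton-Raphson on the Efron partial likelihood)
adjusted for stage (binned low/high), age and sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from caflineage.errors import DataError
from caflineage.simulate import BulkCohort

log = logging.getLogger(__name__)

_LOW_STAGES = {"Stage 1", "Stage 2", "LOW"}
_HIGH_STAGES = {"Stage 3", "Stage 4", "HIGH"}


def signature_score(cohort: BulkCohort, signature_genes: list[str]) -> pd.Series:
    """Mean of per-gene z-scored log1p expression over the signature genes."""
    present = [g for g in signature_genes if g in cohort.expression.columns]
    if len(present) < 0.5 * len(signature_genes):
        missing = sorted(set(signature_genes) - set(present))
        raise DataError(f"fewer than half the signature genes present; missing {missing[:10]}")
    X = np.log1p(cohort.expression[present].to_numpy(dtype=float))
    sd = X.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        log.info("signature_score: dropping %d constant genes", int(const.sum()))
    X = X[:, ~const]
    if X.shape[1] == 0:
        raise DataError("all signature genes constant across samples")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    return pd.Series(Z.mean(axis=1), index=cohort.expression.index, name="signature_score")


def caf_abundance(cohort: BulkCohort, panel: list[str]) -> pd.Series:
    """MCPcounter-style population score: mean log2(1+expression) of a
    marker panel (panel supplied by the caller)."""
    if not panel:
        raise DataError("empty marker panel")
    missing = [g for g in panel if g not in cohort.expression.columns]
    if missing:
        raise DataError(f"panel genes missing from cohort: {missing[:10]}")
    X = np.log2(1.0 + cohort.expression[panel].to_numpy(dtype=float))
    return pd.Series(X.mean(axis=1), index=cohort.expression.index, name="caf_abundance")


def bin_stage(stage: str) -> str:
    """Collapse stage labels to low/high: Stage 1/2/LOW vs Stage 3/4/HIGH."""
    if stage in _LOW_STAGES:
        return "low"
    if stage in _HIGH_STAGES:
        return "high"
    accepted = sorted(_LOW_STAGES | _HIGH_STAGES)
    raise DataError(f"unrecognized stage label {stage!r}; accepted: {accepted}")


def subtype_proportion_by_stage(
    cell_table: pd.DataFrame, lineage_subtype: str
) -> pd.DataFrame:
    """Proportion of lineage-subtype CAFs among all CAFs per stage bin."""
    cafs = cell_table[cell_table["fib_class"] == "CAF"].copy()
    if cafs.empty:
        raise DataError("no CAF cells with stage metadata")
    cafs["stage_bin"] = cafs["stage"].map(bin_stage)
    rows = []
    for b in ("low", "high"):
        sub = cafs[cafs["stage_bin"] == b]
        n = len(sub)
        k = int((sub["subtype"] == lineage_subtype).sum())
        rows.append(
            {
                "stage_bin": b,
                "n_caf": n,
                "n_lineage": k,
                "proportion": k / n if n else np.nan,
                "defined": n > 0,
            }
        )
    return pd.DataFrame(rows).set_index("stage_bin")


def logrank_test(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test; chi-square statistic with 1 df and its p.

    Tied event times are handled by summing observed minus expected over the
    distinct event times (hypergeometric variance).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise DataError("logrank_test requires exactly two groups")
    if (groups == labels[0]).sum() == 0 or (groups == labels[1]).sum() == 0:
        raise DataError("one group is empty")
    if events.sum() == 0:
        raise DataError("need at least one event")
    g1 = groups == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & g1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    stat = o_minus_e**2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


def _efron_derivatives(
    beta: np.ndarray, times: np.ndarray, events: np.ndarray, X: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Efron partial log-likelihood, gradient and negative Hessian."""
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # stabilize; partial likelihood is shift-invariant
    w = np.exp(eta)
    ll = 0.0
    U = np.zeros(p)
    info = np.zeros((p, p))
    for t in np.unique(times[events == 1]):
        risk = times >= t
        dead = (times == t) & (events == 1)
        D = int(dead.sum())
        s0 = w[risk].sum()
        s1 = X[risk].T @ w[risk]
        s2 = (X[risk].T * w[risk]) @ X[risk]
        d0 = w[dead].sum()
        d1 = X[dead].T @ w[dead]
        d2 = (X[dead].T * w[dead]) @ X[dead]
        ll += eta[dead].sum()
        for l in range(D):
            f = l / D
            a0 = s0 - f * d0
            a1 = s1 - f * d1
            a2 = s2 - f * d2
            ll -= np.log(a0)
            U_term = a1 / a0
            U -= U_term
            info += a2 / a0 - np.outer(U_term, U_term)
        U += X[dead].sum(axis=0)
    return float(ll), U, info


def cox_score_test(
    times: np.ndarray, events: np.ndarray, X: np.ndarray
) -> tuple[float, float]:
    """Score (Rao) test of beta = 0; equals the log-rank test for a single
    binary covariate without tied event times."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    _, U, info = _efron_derivatives(
        np.zeros(X.shape[1]), np.asarray(times, float), np.asarray(events, int), X
    )
    stat = float(U @ np.linalg.solve(info, U))
    return stat, float(stats.chi2.sf(stat, df=X.shape[1]))


@dataclass
class CoxResult:
    table: pd.DataFrame  # per covariate: beta, se, hr, p
    loglik: float
    n: int
    n_events: int
    iterations: int


def cox_ph(
    times: np.ndarray,
    events: np.ndarray,
    covariates: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxResult:
    """Multivariate Cox proportional hazards by Newton-Raphson (Efron ties).

    Wald p-values per covariate; convergence when the Newton step's max
    absolute component drops below ``tol``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = covariates.to_numpy(dtype=float)
    n, p = X.shape
    if events.sum() < p + 5:
        raise DataError("too few events for the number of covariates")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = list(covariates.columns[sd == 0])
        raise DataError(f"constant covariate(s): {bad}")
    center = X.mean(axis=0)
    scale = sd
    Xs = (X - center) / scale

    beta = np.zeros(p)
    for it in range(1, max_iter + 1):
        ll, U, info = _efron_derivatives(beta, times, events, Xs)
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError as exc:
            raise DataError(f"singular information matrix at iteration {it}") from exc
        new_beta = beta + step
        for _ in range(10):  # step halving if the likelihood decreases
            if _efron_derivatives(new_beta, times, events, Xs)[0] >= ll - 1e-10:
                break
            step = step / 2
            new_beta = beta + step
        beta = new_beta
        if np.abs(beta).max() > 50:
            raise DataError("divergent coefficients: possible separation")
        if np.abs(step).max() < tol:
            break
    else:
        raise DataError(f"Cox model did not converge in {max_iter} iterations")

    ll, U, info = _efron_derivatives(beta, times, events, Xs)
    cov = np.linalg.inv(info)
    beta_nat = beta / scale
    se_nat = np.sqrt(np.diag(cov)) / scale
    z = beta_nat / se_nat
    table = pd.DataFrame(
        {
            "beta": beta_nat,
            "se": se_nat,
            "hr": np.exp(beta_nat),
            "p": 2 * stats.norm.sf(np.abs(z)),
        },
        index=covariates.columns,
    )
    return CoxResult(table=table, loglik=ll, n=n, n_events=int(events.sum()),
                     iterations=it)


def median_split(score: pd.Series) -> pd.Series:
    """High/low dichotomy at the median (strictly above = high)."""
    return pd.Series(
        np.where(score > score.median(), "high", "low"), index=score.index
    )


def survival_by_signature(
    cohort: BulkCohort,
    score: pd.Series,
    split_rule: str = "median",
    adjusters: tuple[str, ...] = ("stage", "age", "sex"),
) -> dict:
    """KM grouping + log-rank on the score dichotomy and adjusted Cox models.

    Cox is run on the continuous score and on the dichotomy, each adjusted
    for the requested clinical covariates (stage entering as the low/high
    bin).
    """
    clin = cohort.clinical
    missing_frac = clin.reindex(columns=list(adjusters)).isna().mean()
    if (missing_frac > 0.2).any():
        raise DataError(
            f"adjusters missing for >20% of samples: {list(missing_frac[missing_frac > 0.2].index)}"
        )
    score = score.loc[clin.index]
    if split_rule == "median":
        group = median_split(score)
    elif split_rule == "tertile-extremes":
        lo, hi = score.quantile([1 / 3, 2 / 3])
        group = pd.Series(
            np.where(score >= hi, "high", np.where(score <= lo, "low", "mid")),
            index=score.index,
        )
        keep = group != "mid"
        clin, score, group = clin[keep], score[keep], group[keep]
    elif split_rule == "continuous":
        group = None
    else:
        raise DataError("split rule must be median, tertile-extremes or continuous")

    out: dict = {"split_rule": split_rule}
    if group is not None:
        stat, p = logrank_test(
            clin["time"].to_numpy(), clin["event"].to_numpy(), group.to_numpy()
        )
        out["logrank_stat"], out["logrank_p"] = stat, p
        out["groups"] = group

    cov = pd.DataFrame(index=clin.index)
    for adj in adjusters:
        if adj == "stage":
            cov["stage_high"] = (clin["stage"].map(bin_stage) == "high").astype(float)
        elif adj == "sex":
            cov["sex_male"] = (clin["sex"] == "M").astype(float)
        else:
            cov[adj] = clin[adj].astype(float)

    cont = cov.copy()
    cont.insert(0, "score", score.to_numpy())
    out["cox_continuous"] = cox_ph(
        clin["time"].to_numpy(), clin["event"].to_numpy(), cont
    )
    if group is not None:
        dich = cov.copy()
        dich.insert(0, "score_high", (group == "high").astype(float).to_numpy())
        out["cox_dichotomous"] = cox_ph(
            clin["time"].to_numpy(), clin["event"].to_numpy(), dich
        )
    return out


def group_compare(
    values_a: np.ndarray, values_b: np.ndarray, method: str = "mann-whitney"
) -> tuple[float, float]:
    """Two-sided two-group comparison (Mann-Whitney U or Welch t).

    Mann-Whitney is exact for combined n <= 20 without ties, otherwise the
    tie-corrected normal approximation.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("both groups need at least 2 values")
    if method == "mann-whitney":
        n = a.size + b.size
        ties = len(np.unique(np.concatenate([a, b]))) < n
        if np.all(np.concatenate([a, b]) == a[0]):
            return float(a.size * b.size / 2), 1.0
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided",
            method="exact" if (n <= 20 and not ties) else "asymptotic",
        )
        return float(res.statistic), float(res.pvalue)
    if method == "t":
        if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
            raise DataError("zero variance in both groups: t-test undefined")
        res = stats.ttest_ind(a, b)
        return float(res.statistic), float(res.pvalue)
    raise DataError("method must be 'mann-whitney' or 't'")
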