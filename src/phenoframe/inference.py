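"""Pooled inference across multiply imputed datasets.

Every quantity is estimated on each completed dataset separately and
combined by Rubin's rules (total variance = within + (1 + 1/m) * between)
with the Barnard-Rubin small-sample degrees of freedom. Correlations are
pooled on the Fisher z scale (variance 1/(n-3)); adjusted R-squared is
pooled on the Fisher z scale of its square root and reported in percent.
No p-values are reported anywhere: estimates travel with their 95% CIs,
and candidate screening/stepwise elimination run on CI-excludes-zero at
full precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from phenoframe.features.pipeline import FEATURES

SENSING_CLUSTERS = ("app", "call", "location", "screen")
CLUSTERS = ("ema",) + SENSING_CLUSTERS


@dataclass
class PooledEstimate:
    """A Rubin-pooled point estimate with its variance decomposition and CI."""

    estimate: float
    within: float
    between: float
    total: float
    df: float
    ci: tuple[float, float]
    degenerate: bool = False

    def excludes_zero(self) -> bool:
        return self.ci[0] > 0.0 or self.ci[1] < 0.0

    @property
    def width(self) -> float:
        return self.ci[1] - self.ci[0]

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci95": list(self.ci),
            "within_var": self.within,
            "between_var": self.between,
            "total_var": self.total,
            "df": self.df,
            "degenerate": self.degenerate,
        }


@dataclass
class ModelReport:
    """A fitted (possibly empty) standardized regression model, pooled."""

    label: str
    predictors: dict[str, PooledEstimate]
    adj_r2: PooledEstimate  # percent scale
    aic: float
    bic: float
    n: int
    trace: list[tuple[str, float]] = field(default_factory=list)
    covariates: dict[str, PooledEstimate] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.predictors

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "predictors": {k: v.to_dict() for k, v in self.predictors.items()},
            "covariates": {k: v.to_dict() for k, v in self.covariates.items()},
            "adj_r2_percent": self.adj_r2.to_dict(),
            "aic": self.aic,
            "bic": self.bic,
            "n": self.n,
            "elimination_trace": [[p, r] for p, r in self.trace],
        }


def rubin_pool(estimates, variances, nu_com: float) -> PooledEstimate:
    """Rubin's rules with Barnard-Rubin degrees of freedom.

    ``estimates`` and ``variances`` are the per-dataset point estimates and
    their squared standard errors; ``nu_com`` is the complete-data df. With
    m = 1 the single estimate passes through with df = nu_com.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1 or len(q) == 0:
        raise ValueError("estimates and variances must be equal-length 1-d vectors")
    if np.any(u < 0):
        raise ValueError("negative within-imputation variance")
    m = len(q)
    qbar = float(q.mean())
    w = float(u.mean())
    if m == 1:
        b = 0.0
    else:
        b = float(q.var(ddof=1))
    t_var = w + (1.0 + 1.0 / m) * b
    if t_var <= 0:
        return PooledEstimate(qbar, w, b, t_var, float(nu_com), (qbar, qbar))
    lam = (1.0 + 1.0 / m) * b / t_var
    nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
    if m > 1 and lam > 0:
        nu_old = (m - 1.0) / lam**2
        df = nu_old * nu_obs / (nu_old + nu_obs)
    elif m == 1:
        df = float(nu_com)
    else:
        df = nu_obs
    half = stats.t.ppf(0.975, df) * np.sqrt(t_var)
    return PooledEstimate(qbar, w, b, t_var, float(df), (qbar - half, qbar + half))


def pooled_correlation(tables: list[pd.DataFrame], x: str, y: str) -> PooledEstimate:
    """Pearson correlation pooled across imputations on the Fisher z scale."""
    zs, ns, rs = [], [], []
    for t in tables:
        xv = t[x].to_numpy(float)
        yv = t[y].to_numpy(float)
        n = len(xv)
        if n < 4:
            raise ValueError("need at least 4 observations per dataset")
        if xv.std() == 0 or yv.std() == 0:
            raise ValueError(f"correlation undefined: zero variance in {x!r} or {y!r}")
        r = float(np.corrcoef(xv, yv)[0, 1])
        rs.append(r)
        ns.append(n)
        if abs(r) < 1.0 - 1e-12:
            zs.append(np.arctanh(r))
    n = ns[0]
    if len(zs) < len(rs):  # perfect correlation in some dataset
        est = float(np.mean(rs))
        return PooledEstimate(est, 0.0, 0.0, 0.0, float(n - 3), (est, est), degenerate=True)
    pooled = rubin_pool(zs, [1.0 / (n - 3)] * len(zs), nu_com=n - 3)
    return PooledEstimate(
        float(np.tanh(pooled.estimate)),
        pooled.within,
        pooled.between,
        pooled.total,
        pooled.df,
        (float(np.tanh(pooled.ci[0])), float(np.tanh(pooled.ci[1]))),
    )


def episode_feature_cluster(name: str) -> str | None:
    """Cluster of an episode-level column (feature aggregates end _mean/_sd)."""
    for cand in (name, name.removesuffix("_mean"), name.removesuffix("_sd")):
        if cand in FEATURES:
            return FEATURES[cand][0]
    return None


def correlation_screen(tables: list[pd.DataFrame], outcome: str = "phq8_sum") -> dict[str, PooledEstimate]:
    """Pooled correlation of every episode-level feature with the outcome.

    Columns with zero variance in any dataset (undefined correlation) are
    skipped; everything else is returned keyed by column name.
    """
    out: dict[str, PooledEstimate] = {}
    for col in tables[0].columns:
        if col in (outcome, "participant_id"):
            continue
        if episode_feature_cluster(col) is None:
            continue
        try:
            out[col] = pooled_correlation(tables, col, outcome)
        except ValueError:
            continue
    return out


def screen_candidates(correlations: dict[str, PooledEstimate]) -> dict[str, list[str]]:
    """Features whose pooled-correlation 95% CI excludes zero, by cluster.

    Exclusion is evaluated on unrounded CI bounds: a bound that would print
    as -0.00 but is strictly negative still qualifies.
    """
    cands: dict[str, list[str]] = {c: [] for c in CLUSTERS}
    for name, est in correlations.items():
        if est.degenerate or not est.excludes_zero():
            continue
        cluster = episode_feature_cluster(name)
        if cluster is not None:
            cands[cluster].append(name)
    return {c: sorted(v) for c, v in cands.items()}


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (v - v.mean()) / sd


def fit_standardized_model(
    tables: list[pd.DataFrame],
    outcome: str,
    predictors: list[str],
    covariates: tuple[str, ...] = (),
    label: str = "",
) -> ModelReport:
    """Fully standardized OLS fitted per dataset and pooled by Rubin's rules.

    Outcome, predictors and covariates are z-scored within each dataset;
    betas pool with nu_com = n - p - 1, adjusted R-squared pools on the
    Fisher z of its square root and is reported in percent. AIC/BIC are
    arithmetic means across datasets (used for model ordering only).
    """
    cols = list(predictors) + list(covariates)
    n = len(tables[0])
    p = len(cols)
    if p and n <= p + 2:
        raise ValueError(f"n={n} too small for {p} predictors")
    betas = {c: ([], []) for c in cols}
    adj_q, aics, bics = [], [], []
    degenerate = False
    for t in tables:
        yv = _zscore(t[outcome].to_numpy(float))
        if p:
            xmat = np.column_stack([_zscore(t[c].to_numpy(float)) for c in cols])
            if p > 1:
                cc = np.corrcoef(xmat, rowvar=False)
                hi = np.argwhere(np.triu(np.abs(cc), 1) > 1.0 - 1e-10)
                if len(hi):
                    i, j = hi[0]
                    raise ValueError(f"collinear predictors: {cols[i]!r} and {cols[j]!r}")
            design = sm.add_constant(xmat)
        else:
            design = np.ones((n, 1))
        res = sm.OLS(yv, design).fit()
        for k, c in enumerate(cols):
            betas[c][0].append(float(res.params[k + 1]))
            betas[c][1].append(float(res.bse[k + 1] ** 2))
        r2 = float(res.rsquared) if p else 0.0
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
        if adj > 1.0 - 1e-12:
            degenerate = True
        adj_q.append(np.arctanh(np.sqrt(np.clip(adj, 0.0, 1.0 - 1e-12))))
        aics.append(float(res.aic))
        bics.append(float(res.bic))

    nu_com = n - p - 1
    pooled_betas = {c: rubin_pool(q, u, nu_com) for c, (q, u) in betas.items()}
    pz = rubin_pool(adj_q, [1.0 / (n - 3)] * len(adj_q), nu_com=n - 3)
    adj_est = float(np.tanh(pz.estimate) ** 2 * 100.0)
    lo = float(np.tanh(max(pz.ci[0], 0.0)) ** 2 * 100.0)
    hi = float(np.tanh(pz.ci[1]) ** 2 * 100.0)
    adj_pool = PooledEstimate(adj_est, pz.within, pz.between, pz.total, pz.df, (lo, hi), degenerate=degenerate)
    return ModelReport(
        label=label,
        predictors={c: pooled_betas[c] for c in predictors},
        covariates={c: pooled_betas[c] for c in covariates},
        adj_r2=adj_pool,
        aic=float(np.mean(aics)),
        bic=float(np.mean(bics)),
        n=n,
    )


def stepwise_backward(
    tables: list[pd.DataFrame],
    outcome: str,
    candidates: list[str],
    covariates: tuple[str, ...] = (),
    label: str = "",
) -> ModelReport:
    """Backward elimination of predictors with zero-including pooled CIs.

    At each step the zero-including predictor with the smallest |pooled
    beta| is removed (ties: wider CI, then name); the model is refitted and
    the adjusted R-squared after the removal is recorded in the trace. The
    procedure stops when every remaining predictor's CI excludes zero; an
    empty final model is a legal outcome.
    """
    current = sorted(candidates)
    trace: list[tuple[str, float]] = []
    report = fit_standardized_model(tables, outcome, current, covariates, label)
    while current:
        removable = [c for c in current if not report.predictors[c].excludes_zero()]
        if not removable:
            break
        victim = min(removable, key=lambda c: (abs(report.predictors[c].estimate), -report.predictors[c].width, c))
        current.remove(victim)
        report = fit_standardized_model(tables, outcome, current, covariates, label)
        trace.append((victim, report.adj_r2.estimate))
    report.trace = trace
    return report


def run_model_suite(
    tables: list[pd.DataFrame],
    outcome: str = "phq8_sum",
    demographics: pd.DataFrame | None = None,
    sensing_pool: str = "survivors",
) -> dict:
    """Correlation screening plus the full battery of stepwise models.

    Fits the five cluster-wise models, a sensing-combined model (candidate
    pool: final survivors of the sensing clusters, or all screened sensing
    candidates with ``sensing_pool='all'``), and the EMA+sensing combined
    model; computes adjusted R-squared differences; and, when demographics
    are supplied, refits the three headline models with age and gender.
    """
    correlations = correlation_screen(tables, outcome)
    candidates = screen_candidates(correlations)

    def _prune_duplicates(names: list[str]) -> tuple[list[str], list[str]]:
        """Drop candidates perfectly collinear with an earlier one (e.g.
        structural twins like max stay duration vs time at the top place)."""
        kept: list[str] = []
        dropped: list[str] = []
        for name in names:
            dup = False
            for other in kept:
                rr = [abs(np.corrcoef(t[name], t[other])[0, 1]) for t in tables]
                if min(rr) > 1.0 - 1e-10:
                    dup = True
                    break
            (dropped if dup else kept).append(name)
        return kept, dropped

    pruned: dict[str, list[str]] = {}
    for cluster in CLUSTERS:
        candidates[cluster], pruned[cluster] = _prune_duplicates(candidates.get(cluster, []))

    models: dict[str, ModelReport] = {}
    for cluster in CLUSTERS:
        models[cluster] = stepwise_backward(tables, outcome, candidates.get(cluster, []), label=cluster)

    if sensing_pool == "survivors":
        pool = sorted(set().union(*(models[c].predictors.keys() for c in SENSING_CLUSTERS)))
    elif sensing_pool == "all":
        pool = sorted(set().union(*(candidates.get(c, []) for c in SENSING_CLUSTERS)))
    else:
        raise ValueError("sensing_pool must be 'survivors' or 'all'")
    models["sensing"] = stepwise_backward(tables, outcome, pool, label="sensing")
    combined_pool = sorted(set(models["ema"].predictors) | set(models["sensing"].predictors))
    models["combined"] = stepwise_backward(tables, outcome, combined_pool, label="combined")

    def _delta(a: str, b: str) -> float | None:
        if models[a].empty or models[b].empty:
            return None
        return models[a].adj_r2.estimate - models[b].adj_r2.estimate

    deltas = {
        "sensing_vs_ema": _delta("sensing", "ema"),
        "combined_vs_ema": _delta("combined", "ema"),
        "combined_vs_sensing": _delta("combined", "sensing"),
    }

    sensitivity: dict[str, ModelReport] = {}
    if demographics is not None:
        demo = demographics.copy()
        if demo["gender"].dtype == object:
            demo["gender"] = (demo["gender"] == "female").astype(float)
        merged = [t.merge(demo[["participant_id", "age", "gender"]], on="participant_id", how="left") for t in tables]
        for name in ("ema", "sensing", "combined"):
            if not models[name].empty:
                sensitivity[name] = fit_standardized_model(
                    merged, outcome, sorted(models[name].predictors), covariates=("age", "gender"), label=f"{name}+demographics"
                )

    return {
        "correlations": correlations,
        "candidates": candidates,
        "pruned": pruned,
        "models": models,
        "deltas": deltas,
        "sensitivity": sensitivity,
    }
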