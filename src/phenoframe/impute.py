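"""Multiple imputation by chained equations with participant random intercepts.

Missing day-level cells are imputed by two-level predictive mean matching:
per variable and cycle, a linear model with a participant random intercept
is fit on the observed rows (random-intercept variance by a between/within
moment decomposition, intercepts shrunk by the intraclass-correlation
factor), fixed effects are perturbed by a draw from their sampling
distribution, and each missing cell copies the observed value of a donor
whose predicted value is among the ``donors`` nearest. The m completed day
tables are then aggregated to the episode level (mean and SD over the 14
days per feature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from phenoframe.features.pipeline import WINDOW_FEATURES

_META_COLS = ("participant_id", "date")


class ImputationSpec(BaseModel):
    """Imputation run parameters (m completed datasets, chained-cycle count)."""

    model_config = ConfigDict(frozen=True)

    m: int = Field(default=20, ge=2)
    iterations: int = Field(default=10, ge=1)
    donors: int = Field(default=5, ge=1)
    seed: int = 0


@dataclass
class ImputedStack:
    """m completed datasets: day level, episode level, and chain diagnostics."""

    tables: list[pd.DataFrame]  # episode-level, one row per participant
    day_tables: list[pd.DataFrame]
    traces: dict  # var -> array (m, iterations, 2): mean, sd of imputed cells
    spec: ImputationSpec

    @property
    def m(self) -> int:
        return len(self.tables)


def _sym_sqrt(cov: np.ndarray) -> np.ndarray:
    """Matrix square root of a (possibly semi-definite) covariance."""
    w, v = np.linalg.eigh((cov + cov.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def _random_intercepts(resid: np.ndarray, groups: np.ndarray) -> dict:
    """Moment-based between/within decomposition and shrunk group intercepts."""
    uniq, inv, counts = np.unique(groups, return_inverse=True, return_counts=True)
    n, j = len(resid), len(uniq)
    means = np.bincount(inv, weights=resid) / counts
    within_ss = float(((resid - means[inv]) ** 2).sum())
    sigma2 = within_ss / max(n - j, 1)
    if j > 1:
        grand = resid.mean()
        msb = float((counts * (means - grand) ** 2).sum()) / (j - 1)
        n0 = (n - (counts**2).sum() / n) / (j - 1)
        tau2 = max(0.0, (msb - sigma2) / n0) if n0 > 0 else 0.0
    else:
        tau2 = 0.0
    shrink = tau2 / (tau2 + sigma2 / np.maximum(counts, 1)) if (tau2 + sigma2) > 0 else np.zeros(j)
    return {pid: float(s * m_) for pid, s, m_ in zip(uniq, np.atleast_1d(shrink), means)}


def two_level_pmm(
    day_table: pd.DataFrame,
    spec: ImputationSpec,
    id_col: str = "participant_id",
) -> tuple[list[pd.DataFrame], dict]:
    """m completed copies of the day-level table (observed cells untouched).

    Requires every incomplete variable to have at least ``spec.donors``
    observed values. Deterministic given ``spec.seed``.
    """
    value_cols = [c for c in day_table.columns if c not in _META_COLS]
    data0 = day_table[value_cols].to_numpy(float)
    groups = day_table[id_col].to_numpy()
    obs_mask = ~np.isnan(data0)

    incomplete = [c for i, c in enumerate(value_cols) if not obs_mask[:, i].all()]
    for c in incomplete:
        n_obs = int(obs_mask[:, value_cols.index(c)].sum())
        if n_obs < spec.donors:
            raise ValueError(f"variable {c!r} has only {n_obs} observed values (< {spec.donors} donors)")

    if not incomplete:
        return [day_table.copy() for _ in range(spec.m)], {}

    # visit sequence: ascending missingness (ties by name, deterministic)
    order = sorted(incomplete, key=lambda c: (-obs_mask[:, value_cols.index(c)].sum(), c))
    ss = np.random.SeedSequence(spec.seed)
    chain_seeds = ss.spawn(spec.m)

    completed: list[pd.DataFrame] = []
    traces: dict[str, np.ndarray] = {c: np.full((spec.m, spec.iterations, 2), np.nan) for c in incomplete}

    for chain in range(spec.m):
        rng = np.random.default_rng(chain_seeds[chain])
        data = data0.copy()
        for c in incomplete:  # initialize from the observed margin
            i = value_cols.index(c)
            mis = ~obs_mask[:, i]
            data[mis, i] = rng.choice(data0[obs_mask[:, i], i], size=int(mis.sum()), replace=True)

        for it in range(spec.iterations):
            for c in order:
                i = value_cols.index(c)
                o = obs_mask[:, i]
                mis = ~o
                y = data0[:, i]
                x_idx = [k for k in range(len(value_cols)) if k != i]
                x = data[:, x_idx]
                # standardize predictors on observed rows; prune degenerate ones
                mu = x[o].mean(axis=0)
                sd = x[o].std(axis=0)
                keep = sd > 1e-10
                xs = (x[:, keep] - mu[keep]) / sd[keep]
                a = np.column_stack([np.ones(len(xs)), xs])
                a_obs, y_obs = a[o], y[o]
                beta, *_ = np.linalg.lstsq(a_obs, y_obs, rcond=None)
                resid = y_obs - a_obs @ beta
                dof = max(len(y_obs) - a.shape[1], 1)
                sigma2 = float(resid @ resid) / dof
                cov = sigma2 * np.linalg.pinv(a_obs.T @ a_obs, hermitian=True)
                beta_t = beta + _sym_sqrt(cov) @ rng.standard_normal(len(beta))
                b_map = _random_intercepts(resid, groups[o])
                b = np.array([b_map.get(g, 0.0) for g in groups])
                pred = a @ beta_t + b
                # predictive mean matching among the observed rows
                d = np.abs(pred[o][None, :] - pred[mis][:, None])
                k = min(spec.donors, d.shape[1])
                nearest = np.argpartition(d, k - 1, axis=1)[:, :k]
                pick = nearest[np.arange(len(nearest)), rng.integers(0, k, size=len(nearest))]
                data[mis, i] = y_obs[pick]
                traces[c][chain, it] = (data[mis, i].mean(), data[mis, i].std())

        out = day_table.copy()
        out[value_cols] = data
        completed.append(out)
    return completed, traces


def aggregate_to_episode(
    day_table: pd.DataFrame,
    id_col: str = "participant_id",
    window_features: frozenset = WINDOW_FEATURES,
) -> pd.DataFrame:
    """Episode-level mean and SD (n-1) of each feature over the 14 days.

    ``phq8_sum`` is episode-constant and carried through unchanged. Features
    computed once per observation window keep their mean but no SD column
    (their within-episode SD is zero by construction).
    """
    counts = day_table.groupby(id_col, observed=True).size()
    if (counts != 14).any():
        bad = counts[counts != 14]
        raise ValueError(f"expected exactly 14 day rows per participant, got {bad.to_dict()}")
    feats = [c for c in day_table.columns if c not in _META_COLS and c != "phq8_sum"]
    g = day_table.groupby(id_col, observed=True)
    out = pd.DataFrame(index=counts.index)
    if "phq8_sum" in day_table.columns:
        out["phq8_sum"] = g["phq8_sum"].first()
    for c in feats:
        out[f"{c}_mean"] = g[c].mean()
        if c not in window_features:
            out[f"{c}_sd"] = g[c].std(ddof=1)
    return out.reset_index()


def impute_episodes(day_table: pd.DataFrame, spec: ImputationSpec) -> ImputedStack:
    """Impute the day table and aggregate each completed copy to episodes."""
    day_tables, traces = two_level_pmm(day_table, spec)
    tables = [aggregate_to_episode(t) for t in day_tables]
    return ImputedStack(tables=tables, day_tables=day_tables, traces=traces, spec=spec)


def convergence_report(stack: ImputedStack) -> dict:
    """Chain-mixing diagnostics from the imputed-cell mean traces.

    Per variable: between-chain spread of final-iteration imputed means, and
    a flag when the trend over the last three iterations (averaged across
    chains) exceeds that spread.
    """
    report: dict = {"variables": {}, "notes": []}
    if not stack.traces:
        report["notes"].append("no missing data: nothing was imputed")
        return report
    iters = stack.spec.iterations
    if iters < 3:
        report["notes"].append("too few iterations to assess convergence trends")
    for var, tr in stack.traces.items():
        final_means = tr[:, -1, 0]
        between_sd = float(final_means.std(ddof=1)) if len(final_means) > 1 else 0.0
        entry = {"final_mean": float(final_means.mean()), "between_chain_sd": between_sd, "flag": False}
        if iters >= 3:
            trend = float(np.mean(tr[:, -1, 0] - tr[:, -3, 0]))
            entry["last3_trend"] = trend
            entry["flag"] = bool(between_sd > 0 and abs(trend) > between_sd)
        report["variables"][var] = entry
    return report
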