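"""Approximate Bayesian computation over the coalescent scenarios.

The workflow mirrors standard summary-statistic ABC for microsatellite
demography: a reference table of (scenario, parameters, statistics) records
simulated from the priors; a prior/scenario adequacy check (per-statistic
rank test plus a PCA projection); scenario choice by rejection proportions
and by a distance-weighted multinomial logistic regression on linear
discriminant axes; error calibration from pseudo-observed datasets (pods);
local-linear (logit-transformed) posterior adjustment for the parameters of
the winning scenario; the theta-ratio (current vs ancestral scaled
diversity) statistic; posterior-predictive checking on held-out statistics;
and generation-to-calendar-year conversion.

``ABCModel`` / ``ABCResults`` provide a statsmodels-style entry point over
these pieces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .coalescent import (DemographicScenario, LociConfig, PriorSpec,
                         StatsCatalog, sample_priors, simulate_dataset,
                         summary_stats)


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Simulated (scenario, parameter vector, summary statistics) records."""

    data: pd.DataFrame
    stat_columns: list[str]
    param_columns: list[str]
    seed: int | None = None
    scaling: pd.DataFrame | None = None  # mean/sd per statistic column

    def __post_init__(self):
        if self.scaling is None:
            stats = self.data[self.stat_columns]
            sd = stats.std(ddof=0).replace(0.0, 1.0)
            self.scaling = pd.DataFrame({"mean": stats.mean(), "sd": sd})

    def scenario_counts(self) -> pd.Series:
        return self.data["scenario"].value_counts()

    def standardized_stats(self, frame: pd.DataFrame | pd.Series | None = None) -> np.ndarray:
        if frame is None:
            frame = self.data[self.stat_columns]
        if isinstance(frame, pd.Series):
            frame = frame.to_frame().T
        X = frame[self.stat_columns].to_numpy(dtype=float)
        mu = self.scaling["mean"].to_numpy()
        sd = self.scaling["sd"].to_numpy()
        return (X - mu) / sd

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# ssrphylo reference table; seed={self.seed}\n")
            self.data.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceTable":
        with open(path) as fh:
            header = fh.readline()
            seed = None
            if header.startswith("#") and "seed=" in header:
                tok = header.split("seed=")[1].strip()
                seed = None if tok == "None" else int(tok)
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        stat_cols = [c for c in df.columns if c.startswith(("nu_", "cp_"))]
        param_cols = [c for c in df.columns if c not in stat_cols and c != "scenario"]
        return cls(df, stat_cols, param_cols, seed=seed)


def build_reference_table(spec: PriorSpec,
                          scenarios: list[str] | list[DemographicScenario],
                          n_per_scenario: int,
                          sample_sizes: dict[str, int],
                          loci_config: LociConfig = LociConfig(),
                          catalog: StatsCatalog = StatsCatalog(),
                          seed: int | None = None,
                          which: str = "fit") -> ReferenceTable:
    """Simulate the ABC reference table (deterministic under ``seed``)."""
    scens = [DemographicScenario(s) if isinstance(s, str) else s for s in scenarios]
    rng = np.random.default_rng(seed)
    rows = []
    stat_cols: list[str] | None = None
    for scen in scens:
        draws = sample_priors(spec, scen, n_per_scenario, rng)
        for p in draws:
            ds = simulate_dataset(scen, p, sample_sizes, loci_config, rng=rng)
            s = summary_stats(ds, catalog, which=which)
            if stat_cols is None:
                stat_cols = list(s.index)
            row = {"scenario": scen.scenario_id}
            row.update(p)
            row.update(s.to_dict())
            rows.append(row)
    df = pd.DataFrame(rows)
    param_cols = [c for c in df.columns if c != "scenario" and c not in (stat_cols or [])]
    return ReferenceTable(df, stat_cols or [], param_cols, seed=seed)


# ---------------------------------------------------------------------------
# Prior/scenario adequacy check
# ---------------------------------------------------------------------------

@dataclass
class PriorCheckResult:
    rank_p: pd.Series           # two-sided rank probability per statistic
    flagged: list[str]          # statistics with rank_p < threshold
    pca_sim: np.ndarray         # simulated stats on the first two PCs
    pca_observed: np.ndarray    # observed point on the same axes


def prior_scenario_check(table: ReferenceTable, observed: pd.Series,
                         threshold: float = 0.01) -> PriorCheckResult:
    """Rank each observed statistic within its simulated distribution.

    Two-sided rank probability; statistics falling in an extreme tail
    (p < threshold) are flagged as poorly reproduced by the scenario-prior
    combination.  Constant simulated columns are skipped.
    """
    if len(table.data) == 0:
        raise ValueError("empty reference table")
    ps = {}
    for c in table.stat_columns:
        sim = table.data[c].to_numpy(dtype=float)
        if np.ptp(sim) == 0:
            continue
        r_le = (1 + np.sum(sim <= observed[c])) / (len(sim) + 1)
        r_ge = (1 + np.sum(sim >= observed[c])) / (len(sim) + 1)
        ps[c] = min(2 * min(r_le, r_ge), 1.0)
    rank_p = pd.Series(ps)
    flagged = list(rank_p.index[rank_p < threshold])
    X = table.standardized_stats()
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    axes = vt[:2].T
    obs = table.standardized_stats(observed) - X.mean(axis=0)
    return PriorCheckResult(rank_p, flagged, Xc @ axes, (obs @ axes)[0])


# ---------------------------------------------------------------------------
# Retention and weights
# ---------------------------------------------------------------------------

def _retain(table: ReferenceTable, observed: pd.Series, tolerance_fraction: float,
            exclude_index: int | None = None):
    """Indices, distances and Epanechnikov weights of the retained rows."""
    X = table.standardized_stats()
    x0 = table.standardized_stats(observed)[0]
    d = np.sqrt(((X - x0) ** 2).sum(axis=1))
    if exclude_index is not None:
        d[exclude_index] = np.inf
    n_keep = max(int(round(tolerance_fraction * len(d))), 10)
    n_keep = min(n_keep, np.isfinite(d).sum())
    idx = np.argpartition(d, n_keep - 1)[:n_keep]
    dmax = d[idx].max()
    if dmax == 0:
        w = np.ones(len(idx))
    else:
        w = 1.0 - (d[idx] / dmax) ** 2
        w[w <= 0] = 1e-12
    return idx, d[idx], w


# ---------------------------------------------------------------------------
# Scenario choice
# ---------------------------------------------------------------------------

def _weighted_multinomial_logit(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                                x0: np.ndarray, n_classes: int,
                                ridge: float = 1e-6, max_iter: int = 100):
    """Weighted multinomial logistic regression fitted by Newton-Raphson.

    Returns class probabilities at ``x0`` and their delta-method standard
    errors from the observed information matrix.
    """
    n, d = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    k = n_classes - 1
    beta = np.zeros((k, d + 1))

    def probs(B, Xmat):
        eta = Xmat @ B.T
        eta = np.hstack([np.zeros((len(Xmat), 1)), eta])
        eta -= eta.max(axis=1, keepdims=True)
        e = np.exp(eta)
        return e / e.sum(axis=1, keepdims=True)

    Y = np.zeros((n, n_classes))
    Y[np.arange(n), y] = 1.0
    for _ in range(max_iter):
        P = probs(beta, Xd)
        grad = np.empty(k * (d + 1))
        H = np.zeros((k * (d + 1), k * (d + 1)))
        for c in range(1, n_classes):
            gc = (w * (Y[:, c] - P[:, c])) @ Xd
            grad[(c - 1) * (d + 1):c * (d + 1)] = gc
        for c in range(1, n_classes):
            for c2 in range(1, n_classes):
                wcc = w * P[:, c] * ((c == c2) - P[:, c2])
                blk = (Xd * wcc[:, None]).T @ Xd
                H[(c - 1) * (d + 1):c * (d + 1), (c2 - 1) * (d + 1):c2 * (d + 1)] = blk
        H += ridge * np.eye(len(H))
        step = np.linalg.solve(H, grad)
        beta_new = beta + step.reshape(k, d + 1)
        if np.max(np.abs(step)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    cov = np.linalg.inv(H)
    x0d = np.concatenate([[1.0], x0])
    p0 = probs(beta, x0d[None, :])[0]
    se = np.zeros(n_classes)
    for c in range(n_classes):
        g = np.zeros(k * (d + 1))
        for c2 in range(1, n_classes):
            coef = p0[c] * ((c == c2) - p0[c2])
            g[(c2 - 1) * (d + 1):c2 * (d + 1)] = coef * x0d
        se[c] = float(np.sqrt(max(g @ cov @ g, 0.0)))
    return p0, se


@dataclass
class ModelChoiceResult:
    direct: pd.Series
    logistic: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    selected: str
    recovered: bool
    n_retained: int


def abc_model_choice(table: ReferenceTable, observed: pd.Series,
                     tolerance_fraction: float = 0.01,
                     use_lda: bool = True) -> ModelChoiceResult:
    """Scenario posterior probabilities at the observed statistics.

    Direct estimate: scenario proportions among the retained nearest
    simulations.  Logistic estimate: multinomial logistic regression of the
    scenario label on linear-discriminant axes of the statistics, weighted by
    an Epanechnikov kernel on distance, evaluated at the observed point.  The
    winner counts as successfully recovered when its point probability
    exceeds every other scenario's 95% CI upper bound.
    """
    scens = sorted(table.data["scenario"].unique())
    if len(scens) < 2:
        raise ValueError("need at least two scenarios")
    idx, dist, w = _retain(table, observed, tolerance_fraction)
    sub = table.data.iloc[idx]
    direct = sub["scenario"].value_counts(normalize=True).reindex(scens).fillna(0.0)

    X = table.standardized_stats(sub)
    y = np.array([scens.index(s) for s in sub["scenario"]])
    x0 = table.standardized_stats(observed)[0]
    present = np.unique(y)
    if len(present) < 2:
        # degenerate: only one scenario among retained rows
        logistic = direct.copy()
        lo = hi = direct.copy()
        sel = direct.idxmax()
        return ModelChoiceResult(direct, logistic, lo, hi, sel, True, len(idx))
    if use_lda:
        lda = LinearDiscriminantAnalysis()
        Xl = lda.fit(X, y).transform(X)
        x0l = lda.transform(x0[None, :])[0]
    else:
        Xl, x0l = X, x0
    # map to compact class labels (scenarios absent among retained get p=0)
    remap = {c: i for i, c in enumerate(present)}
    yc = np.array([remap[v] for v in y])
    p0c, sec = _weighted_multinomial_logit(Xl, yc, w, x0l, len(present))
    p0 = np.zeros(len(scens))
    se = np.zeros(len(scens))
    p0[present] = p0c
    se[present] = sec
    logistic = pd.Series(p0, index=scens)
    lo = pd.Series(np.clip(p0 - 1.96 * se, 0, 1), index=scens)
    hi = pd.Series(np.clip(p0 + 1.96 * se, 0, 1), index=scens)
    sel = logistic.idxmax()
    others = [s for s in scens if s != sel]
    recovered = all(logistic[sel] > hi[o] for o in others)
    return ModelChoiceResult(direct, logistic, lo, hi, sel, bool(recovered), len(idx))


# ---------------------------------------------------------------------------
# Confusion / error calibration from pods
# ---------------------------------------------------------------------------

@dataclass
class ConfusionResult:
    confusion: pd.DataFrame     # true scenario x assigned scenario proportions
    type_i: pd.Series
    type_ii: pd.Series
    posterior_error_rate: float
    n_pods_per_scenario: int
    resampled: bool = False


def confusion_errors(table: ReferenceTable, observed: pd.Series,
                     n_pods: int = 1000, tolerance_fraction: float = 0.01,
                     seed: int | None = None) -> ConfusionResult:
    """Scenario-choice error rates from pseudo-observed datasets.

    Pods are drawn, for each scenario, from that scenario's reference rows
    lying within the closest ``tolerance_fraction`` of simulations to the
    observed statistics; each pod is re-classified against the table with its
    own row excluded (direct rejection estimate, for tractability over
    thousands of pods).  Type I(s): fraction of s-pods not assigned s.
    Type II(s): fraction of other-scenario pods assigned s.  The posterior
    error rate averages 1 - P(true scenario) over pods.
    """
    rng = np.random.default_rng(seed)
    scens = sorted(table.data["scenario"].unique())
    X = table.standardized_stats()
    x0 = table.standardized_stats(observed)[0]
    d = np.sqrt(((X - x0) ** 2).sum(axis=1))
    scen_arr = table.data["scenario"].to_numpy()
    n_keep = max(int(round(tolerance_fraction * len(d))), len(scens) * 2)

    pod_rows = []
    resampled = False
    for s in scens:
        mask = scen_arr == s
        ds_ = d.copy()
        ds_[~mask] = np.inf
        k = min(n_keep, mask.sum())
        cand = np.argpartition(ds_, k - 1)[:k]
        if len(cand) < n_pods:
            resampled = True
        pick = rng.choice(cand, size=n_pods, replace=True)
        pod_rows += [(s, int(i)) for i in pick]

    n_retain = max(int(round(tolerance_fraction * len(table.data))), 10)
    counts = pd.DataFrame(0.0, index=scens, columns=scens)
    per_true = {s: [] for s in scens}
    for true_s, i in pod_rows:
        xi = X[i]
        di = np.sqrt(((X - xi) ** 2).sum(axis=1))
        di[i] = np.inf
        idx = np.argpartition(di, n_retain - 1)[:n_retain]
        probs = pd.Series(scen_arr[idx]).value_counts(normalize=True).reindex(scens).fillna(0.0)
        assigned = probs.idxmax()
        counts.loc[true_s, assigned] += 1
        per_true[true_s].append(1.0 - probs[true_s])
    confusion = counts.div(counts.sum(axis=1), axis=0)
    type_i = 1.0 - pd.Series(np.diag(confusion), index=scens)
    type_ii = pd.Series({
        s: counts.loc[[t for t in scens if t != s], s].sum()
           / max(counts.loc[[t for t in scens if t != s]].to_numpy().sum(), 1)
        for s in scens
    })
    per = float(np.mean([v for vals in per_true.values() for v in vals]))
    return ConfusionResult(confusion, type_i, type_ii, per, n_pods, resampled)


# ---------------------------------------------------------------------------
# Parameter posterior (local-linear, logit transformed)
# ---------------------------------------------------------------------------

@dataclass
class ParameterPosterior:
    draws: pd.DataFrame
    weights: np.ndarray
    summaries: pd.DataFrame
    bounds: pd.DataFrame
    rejection_only: bool = False
    # retained rows before adjustment and their (reduced) regression design,
    # kept so derived quantities (e.g. the theta ratio) can be regression-
    # adjusted directly rather than assembled from per-parameter adjustments
    raw_draws: pd.DataFrame | None = None
    design: np.ndarray | None = None


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q) -> np.ndarray:
    order = np.argsort(x)
    xs, ws = x[order], w[order]
    cum = np.cumsum(ws) - 0.5 * ws
    cum /= ws.sum()
    return np.interp(np.atleast_1d(q), cum, xs)


def weighted_mode(x: np.ndarray, w: np.ndarray) -> float:
    """Argmax of a Gaussian KDE (Silverman bandwidth) on weighted draws."""
    if np.ptp(x) == 0:
        return float(x[0])
    kde = sps.gaussian_kde(x, weights=w, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def abc_parameter_posterior(table: ReferenceTable, observed: pd.Series,
                            scenario: str | None = None,
                            tolerance_fraction: float = 0.01,
                            params: list[str] | None = None) -> ParameterPosterior:
    """Local-linear ABC posterior with logit-transformed parameters.

    Retains the closest simulations of the chosen scenario, regresses each
    logit-mapped parameter on the standardized statistics with Epanechnikov
    weights, and residual-adjusts to the observed point (Beaumont-style).
    Parameter bounds for the logit map come from the scenario's prior draws
    in the table, slightly expanded.  A singular design falls back to the
    rejection-only posterior.
    """
    if scenario is not None:
        sub_tab = ReferenceTable(
            table.data[table.data["scenario"] == scenario].reset_index(drop=True),
            table.stat_columns, table.param_columns, table.seed, table.scaling)
    else:
        sub_tab = table
    if params is None:
        params = [c for c in sub_tab.param_columns
                  if sub_tab.data[c].notna().all() and np.ptp(sub_tab.data[c]) > 0]
    idx, dist, w = _retain(sub_tab, observed, tolerance_fraction)
    sub = sub_tab.data.iloc[idx]
    X = sub_tab.standardized_stats(sub)
    x0 = sub_tab.standardized_stats(observed)[0]

    bounds = pd.DataFrame({
        "lo": sub_tab.data[params].min() - 0.05 * np.abs(sub_tab.data[params].min()) - 1e-9,
        "hi": sub_tab.data[params].max() + 0.05 * np.abs(sub_tab.data[params].max()) + 1e-9,
    })
    draws = {}
    rejection_only = False
    # guard against overfitting when few rows are retained: regress on the
    # leading principal components of the retained statistics, keeping at
    # least ~5 rows per coefficient (the regression is local, so the leading
    # components carry whatever signal the neighbourhood has)
    n_ret = len(X)
    max_dim = max(1, n_ret // 5 - 1)
    Z = X - x0
    if Z.shape[1] > max_dim:
        Zc = Z - Z.mean(axis=0)
        _, _, vt = np.linalg.svd(Zc, full_matrices=False)
        proj = vt[:max_dim].T
        Z = Z @ proj
    Xd = np.hstack([np.ones((n_ret, 1)), Z])
    W = np.sqrt(w)
    ridge = 1e-8 * np.eye(Xd.shape[1])
    A = (Xd * w[:, None]).T @ Xd + ridge
    for prm in params:
        vals = sub[prm].to_numpy(dtype=float)
        blo, bhi = bounds.loc[prm, "lo"], bounds.loc[prm, "hi"]
        vals = np.clip(vals, blo + 1e-12, bhi - 1e-12)
        y = np.log((vals - blo) / (bhi - vals))
        try:
            coef = np.linalg.solve(A, (Xd * w[:, None]).T @ y)
            resid = y - Xd @ coef
            y_adj = coef[0] + resid
        except np.linalg.LinAlgError:
            y_adj = y
            rejection_only = True
        adj = (blo + bhi * np.exp(y_adj)) / (1.0 + np.exp(y_adj))
        big = y_adj > 500
        adj[big] = bhi
        draws[prm] = adj
    ddf = pd.DataFrame(draws)
    rows = []
    for prm in params:
        x = ddf[prm].to_numpy()
        q = _weighted_quantile(x, w, [0.025, 0.25, 0.5, 0.75, 0.975])
        rows.append({"parameter": prm, "median": q[2],
                     "mode": weighted_mode(x, w),
                     "q025": q[0], "q25": q[1], "q75": q[3], "q975": q[4]})
    summaries = pd.DataFrame(rows).set_index("parameter")
    return ParameterPosterior(ddf, w, summaries, bounds, rejection_only,
                              raw_draws=sub[params].reset_index(drop=True),
                              design=Xd)


# ---------------------------------------------------------------------------
# Estimator quality over pods
# ---------------------------------------------------------------------------

def estimator_quality(pod_table: pd.DataFrame) -> dict[str, float]:
    """MRB, relative RMSE, 50%/95% coverage and Factor 2 over pods.

    ``pod_table`` columns: true, est, q25, q75, q025, q975 (one row per pod).
    Pods with true = 0 are excluded.
    """
    if len(pod_table) < 1:
        raise ValueError("no pods")
    t = pod_table["true"].to_numpy(dtype=float)
    ok = t != 0
    t = t[ok]
    sub = pod_table.loc[ok]
    e = sub["est"].to_numpy(dtype=float)
    rel = (e - t) / t
    out = {
        "mrb": float(np.mean(rel)),
        "rrmse": float(np.sqrt(np.mean(rel ** 2))),
        "factor2": float(np.mean((e / t >= 0.5) & (e / t <= 2.0))),
    }
    if {"q25", "q75"} <= set(sub.columns):
        out["coverage50"] = float(np.mean((sub["q25"] <= t) & (t <= sub["q75"])))
    if {"q025", "q975"} <= set(sub.columns):
        out["coverage95"] = float(np.mean((sub["q025"] <= t) & (t <= sub["q975"])))
    return out


# ---------------------------------------------------------------------------
# Theta ratio
# ---------------------------------------------------------------------------

@dataclass
class ThetaRatioResult:
    draws: np.ndarray
    weights: np.ndarray
    mode: float
    p_gt_1: float
    p_lt_1: float
    q025: float
    q975: float


def theta_ratio_posterior(posterior: ParameterPosterior, deme: str) -> ThetaRatioResult:
    """Posterior of theta0/theta1 = (N0*mu)/(N1*mu) = N_current/N_ancestral.

    The mutation rate cancels under the constant-rate assumption, so the
    ratio measures expansion (>1) or contraction (<1) directly.  The ratio is
    treated as a derived parameter: its log is regression-adjusted against
    the retained statistics directly (rather than dividing two separately
    adjusted size posteriors), which preserves the within-draw correlation
    of the two sizes.
    """
    cur, anc = f"N_{deme}", f"N_{deme}_anc"
    if cur not in posterior.draws or anc not in posterior.draws:
        raise KeyError(f"posterior lacks size draws for deme {deme!r}")
    w = posterior.weights
    if posterior.raw_draws is not None and posterior.design is not None:
        y = np.log(posterior.raw_draws[cur].to_numpy()
                   / posterior.raw_draws[anc].to_numpy())
        Xd = posterior.design
        A = (Xd * w[:, None]).T @ Xd + 1e-8 * np.eye(Xd.shape[1])
        try:
            coef = np.linalg.solve(A, (Xd * w[:, None]).T @ y)
            ratio = np.exp(coef[0] + (y - Xd @ coef))
        except np.linalg.LinAlgError:
            ratio = np.exp(y)
    else:
        ratio = posterior.draws[cur].to_numpy() / posterior.draws[anc].to_numpy()
    logr = np.log(ratio)
    mode = float(np.exp(weighted_mode(logr, w)))
    wsum = w.sum()
    q = _weighted_quantile(ratio, w, [0.025, 0.975])
    return ThetaRatioResult(
        draws=ratio, weights=w, mode=mode,
        p_gt_1=float(np.sum(w[ratio > 1]) / wsum),
        p_lt_1=float(np.sum(w[ratio < 1]) / wsum),
        q025=float(q[0]), q975=float(q[1]),
    )


# ---------------------------------------------------------------------------
# Posterior-predictive model checking
# ---------------------------------------------------------------------------

def model_check_ppc(scenario: str, posterior: ParameterPosterior,
                    observed_check: pd.Series,
                    sample_sizes: dict[str, int],
                    loci_config: LociConfig = LociConfig(),
                    catalog: StatsCatalog = StatsCatalog(),
                    n_rep: int = 1000,
                    seed: int | None = None) -> pd.DataFrame:
    """Posterior-predictive p-values for the held-out statistics.

    Parameter vectors are resampled from the weighted posterior (ordering
    constraints re-imposed); each simulates a replicate dataset whose
    held-out statistics are ranked against the observed ones (two-sided).
    """
    fit_names = set()
    for cls in ("nu", "cp"):
        for s in catalog.fit_single + catalog.fit_pair:
            fit_names.add(f"{cls}_{s}_")
    for name in observed_check.index:
        for pre in fit_names:
            if name.startswith(pre):
                raise ValueError(f"statistic {name} overlaps the fitting set")
    rng = np.random.default_rng(seed)
    scen = DemographicScenario(scenario)
    w = posterior.weights / posterior.weights.sum()
    reps = []
    tries = 0
    while len(reps) < n_rep and tries < 50 * n_rep:
        tries += 1
        i = rng.choice(len(posterior.draws), p=w)
        p = posterior.draws.iloc[i].to_dict()
        if not scen.satisfies_ordering(p):
            continue
        ds = simulate_dataset(scen, p, sample_sizes, loci_config, rng=rng)
        reps.append(summary_stats(ds, catalog, which="check"))
    rep_df = pd.DataFrame(reps)
    rows = []
    for c in observed_check.index:
        sim = rep_df[c].to_numpy(dtype=float)
        r_le = (1 + np.sum(sim <= observed_check[c])) / (len(sim) + 1)
        r_ge = (1 + np.sum(sim >= observed_check[c])) / (len(sim) + 1)
        p2 = min(2 * min(r_le, r_ge), 1.0)
        rows.append({"statistic": c, "p_value": p2, "flagged": p2 < 0.05})
    return pd.DataFrame(rows).set_index("statistic")


# ---------------------------------------------------------------------------
# Calendar-time conversion
# ---------------------------------------------------------------------------

def generations_to_years(t_generations: float,
                         generation_time_years: tuple[float, float] = (30.0, 40.0)
                         ) -> tuple[float, float]:
    """Convert generations to a calendar-year interval.

    Scales by the bounds of the generation-time interval (silver fir reaches
    sexual maturity at roughly 30-40 years).
    """
    g_lo, g_hi = generation_time_years
    if t_generations < 0:
        raise ValueError("t_generations must be >= 0")
    if not (0 < g_lo <= g_hi):
        raise ValueError("generation time bounds must satisfy 0 < lo <= hi")
    return (t_generations * g_lo, t_generations * g_hi)


# ---------------------------------------------------------------------------
# Model/Results facade
# ---------------------------------------------------------------------------

class ABCModel:
    """ABC inference bound to observed statistics and a reference table.

    ``fit`` performs scenario choice and the parameter posterior for the
    winning scenario; diagnostics (prior check, error calibration,
    posterior-predictive check) hang off the model and results.
    """

    def __init__(self, observed: pd.Series, table: ReferenceTable,
                 tolerance_fraction: float = 0.01):
        self.observed = observed
        self.table = table
        self.tolerance_fraction = tolerance_fraction

    def prior_check(self, threshold: float = 0.01) -> PriorCheckResult:
        return prior_scenario_check(self.table, self.observed, threshold)

    def confusion(self, n_pods: int = 1000, seed: int | None = None) -> ConfusionResult:
        return confusion_errors(self.table, self.observed, n_pods,
                                self.tolerance_fraction, seed)

    def fit(self, use_lda: bool = True, scenario: str | None = None) -> "ABCResults":
        choice = abc_model_choice(self.table, self.observed,
                                  self.tolerance_fraction, use_lda)
        best = scenario or choice.selected
        post = abc_parameter_posterior(self.table, self.observed, best,
                                       self.tolerance_fraction)
        return ABCResults(self, choice, best, post)


@dataclass
class ABCResults:
    model: ABCModel
    model_choice: ModelChoiceResult
    scenario: str
    posterior: ParameterPosterior
    confusion: ConfusionResult | None = None

    def theta_ratio(self, deme: str) -> ThetaRatioResult:
        return theta_ratio_posterior(self.posterior, deme)

    def posterior_predictive_check(self, observed_check: pd.Series,
                                   sample_sizes: dict[str, int],
                                   loci_config: LociConfig = LociConfig(),
                                   catalog: StatsCatalog = StatsCatalog(),
                                   n_rep: int = 1000,
                                   seed: int | None = None) -> pd.DataFrame:
        return model_check_ppc(self.scenario, self.posterior, observed_check,
                               sample_sizes, loci_config, catalog, n_rep, seed)

    def summary(self) -> str:
        lines = ["ABC scenario choice", "=" * 55]
        for s in self.model_choice.logistic.index:
            lines.append(
                f"  {s}: direct={self.model_choice.direct[s]:.3f}  "
                f"logistic={self.model_choice.logistic[s]:.3f} "
                f"[{self.model_choice.ci_lower[s]:.3f}, {self.model_choice.ci_upper[s]:.3f}]")
        lines.append(f"selected: {self.scenario} "
                     f"(recovered: {self.model_choice.recovered})")
        lines.append("")
        lines.append(f"Parameter posterior ({self.scenario})")
        lines.append("=" * 55)
        lines.append(f"{'parameter':<14}{'median':>12}{'mode':>12}{'2.5%':>12}{'97.5%':>12}")
        for prm, row in self.posterior.summaries.iterrows():
            lines.append(f"{prm:<14}{row['median']:>12.4g}{row['mode']:>12.4g}"
                         f"{row['q025']:>12.4g}{row['q975']:>12.4g}")
        return "\n".join(lines)
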