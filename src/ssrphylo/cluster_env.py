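"""Cluster-number selection, representative-population picking, and the
environment-genetic diversity association stage.

The association stage screens Pearson correlations between per-population
genetic variables and environmental candidates through an empirical-Bayes
local false discovery rate on Fisher-transformed z-values, diagnoses
multicollinearity with variance inflation factors, selects parsimonious
linear models by forward stepwise BIC, and tests category counts with
Pearson's chi-squared.  ``AssociationModel`` / ``AssociationResults`` wrap
the full stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.isotonic import IsotonicRegression


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

def evanno_delta_k(runs: pd.DataFrame) -> pd.DataFrame:
    """Evanno's delta-K from replicate clustering log-probabilities.

    ``runs`` columns: K, replicate, L.  delta-K(K) = |mean second difference
    of L at K| / sd of L(K) across replicates; requires both neighbours of K
    and >= 2 replicates per K.  Returns a table indexed by K with mean_L,
    sd_L, delta_k (NaN where undefined, flagged when sd = 0).
    """
    g = runs.groupby("K")["L"]
    mean_l = g.mean()
    sd_l = g.std(ddof=1)
    ks = sorted(mean_l.index)
    rows = []
    for k in ks:
        row = {"K": k, "mean_L": mean_l[k], "sd_L": sd_l[k], "delta_k": np.nan,
               "sd_zero": False}
        if (k - 1) in mean_l.index and (k + 1) in mean_l.index:
            second = mean_l[k + 1] - 2 * mean_l[k] + mean_l[k - 1]
            if sd_l[k] == 0 or not np.isfinite(sd_l[k]):
                row["sd_zero"] = True
            else:
                row["delta_k"] = abs(second) / sd_l[k]
        rows.append(row)
    out = pd.DataFrame(rows).set_index("K")
    return out


def best_k(runs: pd.DataFrame) -> int:
    """K with the highest delta-K peak."""
    tab = evanno_delta_k(runs)
    if tab["delta_k"].notna().sum() == 0:
        raise ValueError("delta-K undefined for every K")
    return int(tab["delta_k"].idxmax())


# ---------------------------------------------------------------------------
# Representative populations from a Q matrix
# ---------------------------------------------------------------------------

def select_representative_populations(q: pd.DataFrame,
                                      admixture_target: float = 0.5,
                                      exclude: list[str] | None = None
                                      ) -> dict[str, str]:
    """One population per cluster (highest Q) plus one admixed population.

    ``q`` is populations x clusters with rows summing to 1.  The admixed
    representative is the population whose maximum cluster membership is
    closest to ``admixture_target``.  ``exclude`` removes populations before
    selection (used for replicate analyses); ties break to the
    alphabetically first pop_id.
    """
    q = q.drop(index=exclude or [], errors="ignore")
    if q.empty:
        raise ValueError("no populations left after exclusion")
    picks: dict[str, str] = {}
    used: set[str] = set()
    for cl in q.columns:
        sub = q.drop(index=list(used), errors="ignore")
        if sub.empty:
            raise ValueError(f"no candidate population for cluster {cl}")
        col = sub[cl]
        best = col[col == col.max()].index.min()  # deterministic tie-break
        picks[str(cl)] = str(best)
        used.add(best)
    rem = q.drop(index=list(used), errors="ignore")
    if rem.empty:
        raise ValueError("no candidate left for the admixed representative")
    gap = (rem.max(axis=1) - admixture_target).abs()
    picks["admixed"] = str(gap[gap == gap.min()].index.min())
    return picks


# ---------------------------------------------------------------------------
# Correlation screen and local FDR
# ---------------------------------------------------------------------------

def pearson_screen(genetic: pd.DataFrame, env: pd.DataFrame,
                   min_n: int = 5) -> pd.DataFrame:
    """Pearson r and Fisher z for every genetic x environment pair.

    Pairwise-complete observations; z = atanh(r) * sqrt(n - 3) is standard
    normal under the null and feeds the lfdr step.  Zero-variance pairs are
    skipped with a flag.
    """
    rows = []
    for gv in genetic.columns:
        for ev in env.columns:
            x = genetic[gv]
            y = env.reindex(genetic.index)[ev]
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            if n < min_n:
                continue
            xs, ys = x[ok].to_numpy(float), y[ok].to_numpy(float)
            if np.std(xs) == 0 or np.std(ys) == 0:
                rows.append({"genetic": gv, "env": ev, "n": n, "r": np.nan,
                             "z": np.nan, "skipped": True})
                continue
            r = float(np.corrcoef(xs, ys)[0, 1])
            z = float(np.arctanh(np.clip(r, -0.999999, 0.999999)) * np.sqrt(n - 3))
            rows.append({"genetic": gv, "env": ev, "n": n, "r": r, "z": z,
                         "skipped": False})
    return pd.DataFrame(rows)


def local_fdr(z: np.ndarray, isotonic: bool = False,
              null_quantile: float = 0.5) -> tuple[np.ndarray, str]:
    """Empirical-Bayes local false discovery rate with a theoretical null.

    lfdr(z) = pi0 * f0(z) / f(z) with f0 standard normal, pi0 estimated from
    the central proportion of z-values, and f a Gaussian kernel density.
    With fewer than 50 tests falls back to Benjamini-Hochberg adjusted
    p-values (flagged in the returned method string).  ``isotonic``
    optionally enforces monotone non-increase in |z|.
    """
    z = np.asarray(z, dtype=float)
    ok = np.isfinite(z)
    out = np.full(len(z), np.nan)
    zz = z[ok]
    if len(zz) < 50:
        p = 2 * sps.norm.sf(np.abs(zz))
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        bh = np.empty_like(p)
        bh[order] = np.clip(ranked, 0, 1)
        out[ok] = bh
        return out, "bh_fallback"
    z0 = np.quantile(np.abs(zz), null_quantile)
    central = np.mean(np.abs(zz) <= z0)
    expected = 2 * sps.norm.cdf(z0) - 1
    pi0 = min(central / max(expected, 1e-12), 1.0)
    kde = sps.gaussian_kde(zz, bw_method="silverman")
    f = np.maximum(kde(zz), 1e-12)
    lfdr = np.clip(pi0 * sps.norm.pdf(zz) / f, 0, 1)
    if isotonic:
        a = np.abs(zz)
        iso = IsotonicRegression(increasing=False)
        lfdr = np.clip(iso.fit_transform(a, lfdr), 0, 1)
    out[ok] = lfdr
    return out, "lfdr"


# ---------------------------------------------------------------------------
# VIF and forward stepwise BIC
# ---------------------------------------------------------------------------

def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1/(1 - R^2_j) regressing each
    variable on the others (intercept included).  Exact collinearity gives
    inf."""
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need n > p for VIF")
    out = {}
    Xn = X.to_numpy(dtype=float)
    for j, col in enumerate(X.columns):
        y = Xn[:, j]
        others = np.delete(Xn, j, axis=1)
        A = np.hstack([np.ones((len(y), 1)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            raise ValueError(f"constant column {col}")
        r2 = 1 - np.sum(resid ** 2) / ss_tot
        out[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def _bic(y: np.ndarray, X: np.ndarray) -> float:
    n = len(y)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ coef) ** 2))
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + X.shape[1] * np.log(n)


@dataclass
class StepwiseResult:
    selected: list[str]
    path: pd.DataFrame          # step, added, bic
    model: object | None        # statsmodels results for the final fit
    coefficients: pd.Series = field(default_factory=pd.Series)
    p_values: pd.Series = field(default_factory=pd.Series)
    adj_r2: float = float("nan")


def forward_stepwise_bic(y: pd.Series, X: pd.DataFrame) -> StepwiseResult:
    """Forward stepwise selection minimising BIC = n ln(RSS/n) + k ln(n).

    Starts from the intercept-only model and adds, at each step, the
    candidate that lowers BIC the most; stops when no addition lowers it.
    Ties break to the earlier column.  The final model is refit with OLS for
    coefficients, p-values and adjusted R^2.
    """
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    selected: list[str] = []
    path = [{"step": 0, "added": "(intercept)",
             "bic": _bic(yv, np.ones((n, 1)))}]
    current = path[0]["bic"]
    candidates = list(X.columns)
    while True:
        best_bic, best_var = current, None
        for v in candidates:
            if v in selected:
                continue
            cols = selected + [v]
            A = np.hstack([np.ones((n, 1)), X[cols].to_numpy(dtype=float)])
            if A.shape[1] >= n:
                continue
            b = _bic(yv, A)
            if b < best_bic - 1e-12:
                best_bic, best_var = b, v
        if best_var is None:
            break
        selected.append(best_var)
        path.append({"step": len(selected), "added": best_var, "bic": best_bic})
        current = best_bic
    path_df = pd.DataFrame(path)
    if selected:
        design = sm.add_constant(X[selected].astype(float))
        fit = sm.OLS(yv, design).fit()
        return StepwiseResult(selected, path_df, fit,
                              fit.params.drop("const", errors="ignore"),
                              fit.pvalues.drop("const", errors="ignore"),
                              float(fit.rsquared_adj))
    return StepwiseResult(selected, path_df, None)


def category_count_test(counts) -> tuple[float, float]:
    """Pearson chi-squared on category counts against equal expectation."""
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts,
                   dtype=float)
    if len(c) < 2:
        raise ValueError("need >= 2 categories")
    if c.sum() == 0:
        raise ValueError("all-zero counts")
    chi2, p = sps.chisquare(c)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# Association Model/Results
# ---------------------------------------------------------------------------

class AssociationModel:
    """Environment-genetics association stage bound to per-population tables.

    ``genetic`` holds one genetic response per column (diversity statistics,
    cluster membership Q values); ``env`` the candidate environmental
    variables.  ``fit`` runs the lfdr-thresholded correlation screen and a
    forward-stepwise-BIC linear model per genetic response.
    """

    def __init__(self, genetic: pd.DataFrame, env: pd.DataFrame,
                 lfdr_threshold: float = 0.05):
        common = genetic.index.intersection(env.index)
        self.genetic = genetic.loc[common]
        self.env = env.loc[common]
        self.lfdr_threshold = lfdr_threshold

    def fit(self) -> "AssociationResults":
        screen = pearson_screen(self.genetic, self.env)
        lf, method = local_fdr(screen["z"].to_numpy())
        screen = screen.assign(lfdr=lf, significant=lf <= self.lfdr_threshold)
        models: dict[str, StepwiseResult] = {}
        vifs: dict[str, pd.Series] = {}
        for gv in self.genetic.columns:
            sig = screen[(screen["genetic"] == gv) & screen["significant"]]
            cand = list(sig["env"])
            if not cand:
                continue
            Xc = self.env[cand]
            std = Xc.std(ddof=0)
            Xs = (Xc - Xc.mean()) / std.replace(0.0, 1.0)
            if Xs.shape[0] > Xs.shape[1]:
                try:
                    vifs[gv] = vif(Xs)
                except ValueError:
                    pass
            models[gv] = forward_stepwise_bic(self.genetic[gv], Xs)
        return AssociationResults(screen, method, models, vifs,
                                  self.lfdr_threshold)


@dataclass
class AssociationResults:
    screen: pd.DataFrame
    lfdr_method: str
    models: dict[str, StepwiseResult]
    vifs: dict[str, pd.Series]
    lfdr_threshold: float

    def significant_pairs(self) -> pd.DataFrame:
        return self.screen[self.screen["significant"]]

    def summary(self) -> str:
        lines = [f"Correlation screen: {int(self.screen['significant'].sum())} "
                 f"of {len(self.screen)} pairs at lfdr <= {self.lfdr_threshold} "
                 f"({self.lfdr_method})", ""]
        for gv, res in self.models.items():
            lines.append(f"{gv}: selected {res.selected or 'none'} "
                         f"(adj R^2 = {res.adj_r2:.3f})"
                         if res.selected else f"{gv}: intercept-only")
            for v in res.selected:
                lines.append(f"    {v}: coef={res.coefficients[v]:+.3f} "
                             f"p={res.p_values[v]:.3g}")
        return "\n".join(lines)
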