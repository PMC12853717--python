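"""Performance metrics for the method comparison: bias, coverage, MSE.

Bias is ``mean(estimate) - truth`` of the tracked coefficient; coverage is
the fraction of replicates whose 95% confidence interval contains the truth;
the population MSE is the mean squared prediction error of a fitted model on
a 100,000-row reference population whose BLOQ covariate is censored at the
scenario threshold and completed with the rule the method learned at training
time. Every summary carries a Monte-Carlo standard error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .censoring import apply_lloq
from .methods import FitResult, MethodError
from .simulation import PopulationSet

__all__ = [
    "bias",
    "coverage",
    "mse_population",
    "summarize",
    "failure_ledger",
    "plot_metric_curves",
]

_CELL_COLS = ["model", "setting", "n", "lloq_proportion", "target_r2", "method"]


def bias(estimates, truth: float) -> float:
    """Mean estimation error of a coefficient across replicates."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0 or not np.all(np.isfinite(estimates)):
        raise MethodError("no successful fits: bias is undefined")
    return float(estimates.mean() - truth)


def coverage(ci_lower, ci_upper, truth: float) -> float:
    """Fraction of intervals containing the truth."""
    lo = np.asarray(ci_lower, dtype=float)
    hi = np.asarray(ci_upper, dtype=float)
    if lo.size == 0:
        raise MethodError("no successful fits: coverage is undefined")
    if lo.shape != hi.shape or np.any(lo > hi):
        raise MethodError("invalid intervals: lower must not exceed upper")
    return float(np.mean((lo <= truth) & (truth <= hi)))


def _completed_bloq_column(
    fit: FitResult, values: np.ndarray, censored: np.ndarray, lloq: float
) -> dict[str, np.ndarray]:
    """Apply the training-time completion rule to the (censored) population."""
    rule = (fit.completion or {}).get("rule")
    if rule == "constant":
        out = values.copy()
        out[censored] = fit.completion["value"]
        return {"crp": out}
    if rule == "discard":
        # discard fits no completion rule; predictions read the sentinel LLOQ
        out = values.copy()
        out[censored] = lloq
        return {"crp": out}
    if rule == "knn":
        comp = fit.completion
        out = values.copy()
        if censored.any():
            # population covariates standardised with the training moments
            Z = (comp["pop_covariates"] - comp["means"]) / comp["stds"]
            nn = NearestNeighbors(
                n_neighbors=min(comp["k"], len(comp["donor_values"]))
            ).fit(comp["donor_Z"])
            _, idx = nn.kneighbors(Z[censored])
            imput = comp["donor_values"][idx].mean(axis=1)
            if comp.get("truncate", False):
                imput = np.minimum(imput, lloq)
            out[censored] = imput
        return {"crp": out}
    if rule == "two_compartment":
        fill = fit.completion["fill"]
        cols = {"crp_cont": np.where(censored, fill, values)}
        if not fit.completion.get("bin_dropped", False):
            cols["crp_bin"] = censored.astype(float)
        return cols
    raise MethodError(f"no population completion rule for {fit.method!r}")


def mse_population(
    fit: FitResult,
    pop: PopulationSet,
    lloq: float,
    *,
    censor_population: bool = True,
) -> float:
    """Mean squared prediction error of a fit on the reference population.

    The population's BLOQ covariate is censored at the scenario threshold and
    completed the same way the method completed its training data (constants,
    the training kNN donor pool, the training KDE value, the two-compartment
    fill); set ``censor_population=False`` to predict from the clean
    covariate instead. Defined for Model 1 only.
    """
    if pop.model_id != 1:
        raise MethodError("MSE not defined for Model 2 (dependent BLOQ variable)")
    df = pop.df
    x = df["crp"].to_numpy(dtype=float)
    if censor_population:
        cv = apply_lloq(x, lloq)
        values, censored = cv.values, cv.censored
    else:
        values, censored = x, np.zeros(len(x), dtype=bool)
    if (fit.completion or {}).get("rule") == "knn":
        fit.completion["pop_covariates"] = df[fit.completion["columns"]].to_numpy(
            dtype=float
        )
    cols = {
        "age": df["age"].to_numpy(dtype=float),
        "sexmale": df["sexmale"].to_numpy(dtype=float),
    }
    cols.update(_completed_bloq_column(fit, values, censored, lloq))
    yhat = np.full(len(df), fit.coef["Intercept"])
    for name in fit.coef.index:
        if name == "Intercept":
            continue
        if name not in cols:
            raise MethodError(f"population design lacks column {name!r}")
        yhat = yhat + fit.coef[name] * cols[name]
    resid = yhat - df["y"].to_numpy(dtype=float)
    return float(np.mean(resid**2))


def summarize(raw: pd.DataFrame, truths: dict[tuple[int, str], float]) -> pd.DataFrame:
    """Long-format metrics table from raw scenario results.

    ``truths`` maps ``(model_id, setting)`` to the generating (or pseudo-true)
    coefficient. Non-converged or failed replicates are excluded from the
    metric and counted via ``reps_effective``.
    """
    focus = raw[raw["focus"]]
    rows = []
    for cell, grp in focus.groupby(_CELL_COLS, sort=False):
        ok = grp[grp["error"].isna() & grp["converged"]]
        r = len(ok)
        meta = dict(zip(_CELL_COLS, cell))
        truth = truths[(meta["model"], meta["setting"])]
        if r == 0:
            continue
        est = ok["estimate"].to_numpy()
        rows.append(
            meta | {
                "metric": "bias",
                "value": bias(est, truth),
                "mc_se": float(est.std(ddof=1) / np.sqrt(r)) if r > 1 else np.nan,
                "reps_effective": r,
            }
        )
        p = coverage(ok["ci_lower"], ok["ci_upper"], truth)
        rows.append(
            meta | {
                "metric": "coverage",
                "value": p,
                "mc_se": float(np.sqrt(p * (1 - p) / r)),
                "reps_effective": r,
            }
        )
        mse = ok["mse"].dropna()
        if len(mse):
            rows.append(
                meta | {
                    "metric": "mse",
                    "value": float(mse.mean()),
                    "mc_se": float(mse.std(ddof=1) / np.sqrt(len(mse)))
                    if len(mse) > 1 else np.nan,
                    "reps_effective": int(len(mse)),
                }
            )
    return pd.DataFrame(rows)


def failure_ledger(raw: pd.DataFrame) -> pd.DataFrame:
    """Per-cell failure counts; successful + failed replicates = configured reps."""
    focus = raw[raw["focus"]]
    rows = []
    for cell, grp in focus.groupby(_CELL_COLS, sort=False):
        failed = int((grp["error"].notna() | ~grp["converged"]).sum())
        rows.append(
            dict(zip(_CELL_COLS, cell))
            | {"reps": len(grp), "failed": failed, "succeeded": len(grp) - failed}
        )
    return pd.DataFrame(rows)


def plot_metric_curves(
    metrics: pd.DataFrame,
    metric: str,
    out_dir,
    *,
    fmt: str = "png",
) -> list:
    """Metric-vs-censoring-proportion curves, one line per method.

    Facets are setting (rows) by sample size (columns); one figure per model,
    written as ``model<id>_<metric>.<fmt>``. Purely presentational.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    if metrics.empty:
        raise ValueError("metrics table is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sub = metrics[metrics["metric"] == metric]
    paths = []
    for model_id, dfm in sub.groupby("model"):
        settings = sorted(dfm["setting"].unique())
        ns = sorted(dfm["n"].unique())
        fig, axes = plt.subplots(
            len(settings), len(ns),
            figsize=(3.2 * len(ns), 2.6 * len(settings)),
            squeeze=False, sharex=True, sharey=True,
        )
        for i, setting in enumerate(settings):
            for j, n in enumerate(ns):
                ax = axes[i][j]
                cell = dfm[(dfm["setting"] == setting) & (dfm["n"] == n)]
                if cell.empty:
                    ax.text(0.5, 0.5, "no data", ha="center", va="center",
                            transform=ax.transAxes)
                else:
                    for method, dm in cell.groupby("method"):
                        dm = dm.sort_values("lloq_proportion")
                        ax.plot(dm["lloq_proportion"], dm["value"],
                                marker=".", label=method)
                if metric == "coverage":
                    ax.set_ylim(0, 1)
                    ax.axhline(0.95, color="grey", lw=0.8, ls="--")
                if i == 0:
                    ax.set_title(f"n = {n}", fontsize=9)
                if j == 0:
                    ax.set_ylabel(f"{setting}\n{metric}", fontsize=9)
                if i == len(settings) - 1:
                    ax.set_xlabel("proportion below LLOQ", fontsize=9)
        handles, labels = axes[0][0].get_legend_handles_labels()
        if handles:
            fig.legend(handles, labels, loc="lower center",
                       ncol=min(5, len(labels)), fontsize=8)
        fig.tight_layout(rect=(0, 0.06, 1, 1))
        path = out_dir / f"model{model_id}_{metric}.{fmt}"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
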