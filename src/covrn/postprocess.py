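"""Posterior products: correlation reaction-norm curves, posterior
predictive checks, and parameter-recovery reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

_log = logging.getLogger("covrn.postprocess")

from .compiled import CompiledModel
from .inference import PosteriorResult

__all__ = [
    "CorrelationCurve",
    "PPCReport",
    "predict_correlation",
    "sweep_correlation",
    "posterior_predictive",
    "recovery_report",
]


class SchemaError(ValueError):
    pass


@dataclass
class CorrelationCurve:
    """Posterior of the context correlation over a covariate grid.

    For non-repeated and hybrid variants the curve is the
    observation-level correlation r_o; it equals the among-individual
    correlation only up to repeatability weighting, and its sign can
    disagree with the among-individual sign when among- and
    within-individual correlations have opposite signs.
    """

    grid: pd.DataFrame  # raw-scale covariate values, one row per grid point
    r_draws: np.ndarray  # (n_draws, n_points)
    level_label: str  # "observation" or "among-individual"

    def frame(self) -> pd.DataFrame:
        out = self.grid.copy()
        out["r_mean"] = self.r_draws.mean(axis=0)
        out["r_median"] = np.median(self.r_draws, axis=0)
        for lev in (0.50, 0.89):
            lo, hi = np.quantile(self.r_draws, [(1 - lev) / 2, 1 - (1 - lev) / 2], axis=0)
            pct = int(round(lev * 100))
            out[f"r_lo{pct}"] = lo
            out[f"r_hi{pct}"] = hi
        return out

    def to_csv(self, path) -> None:
        self.frame().to_csv(Path(path), index=False)


def _br_draw_matrix(result: PosteriorResult, model: CompiledModel) -> np.ndarray:
    cols = [f"br_{c}" for c in model.x3_names]
    missing = [c for c in cols if c not in result.draws]
    if missing:
        raise SchemaError(f"posterior lacks correlation coefficients {missing}")
    return np.column_stack([np.ravel(result.draws[c]) for c in cols])


def predict_correlation(
    result: PosteriorResult, model: CompiledModel, X3_new: pd.DataFrame
) -> CorrelationCurve:
    """Posterior correlation draws at new context-covariate values.

    ``X3_new`` columns are on the raw data scale and must cover exactly
    the covariates used in the fitted correlation design; they are
    standardized with the statistics stored at build time.
    """
    needed = [c for c in model.x3_names if c != "intercept"]
    missing = [c for c in needed if c not in X3_new.columns]
    extra = [c for c in X3_new.columns if c not in needed]
    if missing or extra:
        raise SchemaError(
            f"X3_new columns do not match the fitted correlation design: "
            f"missing {missing}, unexpected {extra}"
        )
    n = len(X3_new)
    cols = [np.ones(n)]
    for c in needed:
        st = model.standardization[f"contexts.{c}"]
        cols.append((X3_new[c].to_numpy(dtype=float) - st["mean"]) / st["sd"])
    X = np.column_stack(cols)
    br = _br_draw_matrix(result, model)
    r_draws = np.tanh(br @ X.T)
    label = "among-individual" if model.variant == "full" else "observation"
    if label == "observation":
        _log.info(
            "curve is the observation-level correlation: it blends among- and "
            "within-individual correlations weighted by repeatability (hybrid: "
            "r_obs = r_alpha * sqrt(R2)); its sign can differ from the "
            "among-individual correlation when the two oppose each other"
        )
    return CorrelationCurve(grid=X3_new.reset_index(drop=True), r_draws=r_draws, level_label=label)


def sweep_correlation(
    result: PosteriorResult,
    model: CompiledModel,
    covariate: str,
    n_points: int = 50,
    span: tuple[float, float] | None = None,
    held_at: dict[str, float] | None = None,
) -> CorrelationCurve:
    """Sweep one correlation covariate over a grid, others held at their
    fitted-data means (overridable, e.g. at +/- 1 SD)."""
    needed = [c for c in model.x3_names if c != "intercept"]
    if covariate not in needed:
        raise SchemaError(f"{covariate!r} is not a correlation covariate ({needed})")
    st = model.standardization[f"contexts.{covariate}"]
    if span is None:
        span = (st["mean"] - 2 * st["sd"], st["mean"] + 2 * st["sd"])
    grid = {covariate: np.linspace(span[0], span[1], n_points)}
    for c in needed:
        if c == covariate:
            continue
        stc = model.standardization[f"contexts.{c}"]
        value = (held_at or {}).get(c, stc["mean"])
        grid[c] = np.full(n_points, value)
    return predict_correlation(result, model, pd.DataFrame(grid))


# ------------------------------------------------------------------------- PPC

_DEFAULT_STATS = {
    "mean": lambda y: float(np.mean(y)),
    "sd": lambda y: float(np.std(y, ddof=1)),
}


@dataclass
class PPCReport:
    """Observed vs. replicated summary statistics, one replicate per used
    posterior draw, with upper-tail probabilities Pr(rep >= observed)."""

    observed: dict[str, dict[str, float]]  # trait -> stat -> value
    replicated: dict[str, dict[str, np.ndarray]]  # trait -> stat -> (n_reps,)
    histograms: dict[str, pd.DataFrame]

    def tail_probability(self, trait: str, stat: str) -> float:
        rep = self.replicated[trait][stat]
        obs = self.observed[trait][stat]
        return float(np.mean(rep >= obs))

    def frame(self) -> pd.DataFrame:
        rows = []
        for trait, stats in self.observed.items():
            for stat, obs in stats.items():
                rep = self.replicated[trait][stat]
                rows.append(
                    {
                        "trait": trait,
                        "statistic": stat,
                        "observed": obs,
                        "rep_mean": float(rep.mean()),
                        "rep_lo89": float(np.quantile(rep, 0.055)),
                        "rep_hi89": float(np.quantile(rep, 0.945)),
                        "p_upper": self.tail_probability(trait, stat),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.frame().to_csv(Path(path), index=False)


def posterior_predictive(
    result: PosteriorResult,
    model: CompiledModel,
    n_reps: int | None = None,
    seed: int = 0,
    statistics: dict | None = None,
) -> PPCReport:
    """Replicate data under the fitted model and compare summaries.

    Each replicate redraws every latent effect (year effects and
    subject/observation pairs) from its prior at one retained posterior
    draw of the top-level parameters.
    """
    stats = dict(_DEFAULT_STATS, **(statistics or {}))
    raw = result.raw_top
    n_avail = raw.shape[0] * raw.shape[1]
    if n_reps is None:
        n_reps = min(n_avail, 500)
    if n_reps > n_avail:
        raise ValueError(
            f"n_reps={n_reps} exceeds the {n_avail} retained draws; "
            "subsample (n_reps <= available draws) instead"
        )
    flat = raw.reshape(n_avail, -1)
    idx = (
        np.arange(n_avail)
        if n_reps == n_avail
        else np.linspace(0, n_avail - 1, n_reps).astype(int)
    )
    rng = np.random.default_rng(seed)

    names = model.trait_names
    observed = {
        names[0]: {k: f(model.t1.y) for k, f in stats.items()},
        names[1]: {k: f(model.t2.y) for k, f in stats.items()},
    }
    reps: dict[str, dict[str, list]] = {n: {k: [] for k in stats} for n in names}
    hist_counts, hist_nbins = {}, {}
    for j, t in ((0, model.t1), (1, model.t2)):
        if t.family in ("poisson_log", "ordinal_logit"):
            hist_counts[names[j]] = []
            # overflow beyond the observed maximum pools into the top bin
            hist_nbins[names[j]] = int(t.y.max()) + 2

    theta_full = np.zeros(model.n_params)
    for i in idx:
        theta_full[: flat.shape[1]] = flat[i]
        y1, y2 = model.simulate_replicate(rng, theta_full)
        for name, y in ((names[0], y1), (names[1], y2)):
            for k, f in stats.items():
                reps[name][k].append(f(y))
        for j, y in ((0, y1), (1, y2)):
            if names[j] in hist_counts:
                nb = hist_nbins[names[j]]
                clipped = np.minimum(y.astype(int), nb - 1)
                hist_counts[names[j]].append(np.bincount(clipped, minlength=nb))

    replicated = {n: {k: np.asarray(v) for k, v in d.items()} for n, d in reps.items()}
    histograms = {}
    for j, t in ((0, model.t1), (1, model.t2)):
        name = names[j]
        if name in hist_counts:
            nb = hist_nbins[name]
            obs_counts = np.bincount(np.minimum(t.y.astype(int), nb - 1), minlength=nb)
            rep_counts = np.stack(hist_counts[name])
            histograms[name] = pd.DataFrame(
                {
                    "count_value": np.arange(nb),
                    "observed": obs_counts,
                    "rep_mean": rep_counts.mean(axis=0),
                    "rep_lo89": np.quantile(rep_counts, 0.055, axis=0),
                    "rep_hi89": np.quantile(rep_counts, 0.945, axis=0),
                }
            )
    return PPCReport(observed=observed, replicated=replicated, histograms=histograms)


# -------------------------------------------------------------------- recovery

def recovery_report(ground_truth, result: PosteriorResult) -> pd.DataFrame:
    """One row per generating parameter: truth, posterior mean, 50% and
    89% intervals (raw covariate scale), and coverage flags."""
    rows = []
    unmapped = [k for k in ground_truth.param_truth if k not in result.draws_raw]
    if unmapped:
        raise KeyError(
            f"ground-truth parameters {unmapped} have no posterior counterpart; "
            f"available: {sorted(result.draws_raw)}"
        )
    for name, truth in ground_truth.param_truth.items():
        d = np.ravel(result.draws_raw[name])
        lo50, hi50 = np.quantile(d, [0.25, 0.75])
        lo89, hi89 = np.quantile(d, [0.055, 0.945])
        rows.append(
            {
                "parameter": name,
                "truth": float(truth),
                "posterior_mean": float(d.mean()),
                "lo50": float(lo50),
                "hi50": float(hi50),
                "lo89": float(lo89),
                "hi89": float(hi89),
                "covered50": bool(lo50 <= truth <= hi50),
                "covered89": bool(lo89 <= truth <= hi89),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
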