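"""MCMC fitting, convergence diagnostics and posterior summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._nuts import NutsSampler
from .compiled import CompiledModel

__all__ = [
    "MCMCConfig",
    "PosteriorResult",
    "InitializationError",
    "ConvergenceWarning",
    "fit",
    "rhat",
    "summarize",
    "TEST_PROFILE",
    "PAPER_PROFILE",
]

RHAT_WARN_THRESHOLD = 1.01


class InitializationError(RuntimeError):
    """The sampler could not be started (non-finite density, degenerate data)."""


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration. Defaults: 3 chains, 1000 warmup iterations,
    3000 retained samples per chain, no thinning."""

    n_chains: int = 3
    n_warmup: int = 1000
    n_samples: int = 3000
    seed: int = 0
    thinning: int = 1
    target_accept: float = 0.80
    max_treedepth: int = 10

    def __post_init__(self) -> None:
        for name in ("n_chains", "n_warmup", "n_samples", "thinning"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not (0.0 < self.target_accept < 1.0):
            raise ValueError("target_accept must lie strictly in (0, 1)")


# paper-profile matches the published sampler settings; test-profile is the
# scaled-down configuration used in CI and recovery experiments
PAPER_PROFILE = MCMCConfig(n_chains=3, n_warmup=1000, n_samples=3000)
TEST_PROFILE = MCMCConfig(n_chains=2, n_warmup=500, n_samples=500, max_treedepth=7)


def rhat(draws: np.ndarray) -> float:
    """Split-chain Gelman-Rubin statistic.

    ``draws`` has shape (chains, iterations); each chain is split in half
    before computing the classic between/within variance ratio.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2:
        raise ValueError("draws must be a (chains, iterations) array")
    if draws.shape[0] < 2:
        raise ValueError("rhat requires at least 2 chains; run more chains")
    n = draws.shape[1] // 2
    if n < 2:
        raise ValueError("too few iterations per chain for a split-chain rhat")
    halves = np.concatenate([draws[:, :n], draws[:, n : 2 * n]], axis=0)
    m = halves.shape[0]
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def summarize(
    draws: dict[str, np.ndarray], levels: tuple[float, ...] = (0.50, 0.89)
) -> pd.DataFrame:
    """Posterior mean, median and equal-tailed intervals per parameter."""
    rows = {}
    for name, d in draws.items():
        flat = np.ravel(d)
        row = {"mean": float(flat.mean()), "median": float(np.median(flat))}
        for lev in levels:
            lo, hi = np.quantile(flat, [(1 - lev) / 2, 1 - (1 - lev) / 2])
            pct = int(round(lev * 100))
            row[f"lo{pct}"] = float(lo)
            row[f"hi{pct}"] = float(hi)
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class PosteriorResult:
    """Named posterior draws plus diagnostics.

    ``draws`` holds coefficients on the internal standardized-covariate
    scale; ``draws_raw`` holds the same coefficients mapped back to the
    data's original covariate units.
    """

    draws: dict[str, np.ndarray]  # name -> (chains, iterations)
    draws_raw: dict[str, np.ndarray]
    rhat: dict[str, float]
    diagnostics: dict
    config: MCMCConfig
    raw_top: np.ndarray = None  # (chains, iterations, k) untransformed top-level params
    warnings_: list[str] = field(default_factory=list)

    def summary(self, levels=(0.50, 0.89), scale: str = "standardized") -> pd.DataFrame:
        draws = self.draws if scale == "standardized" else self.draws_raw
        table = summarize(draws, levels)
        table["rhat"] = [self.rhat[n] for n in table.index]
        return table

    def interval(self, name: str, level: float = 0.89, scale: str = "standardized"):
        d = (self.draws if scale == "standardized" else self.draws_raw)[name]
        lo, hi = np.quantile(np.ravel(d), [(1 - level) / 2, 1 - (1 - level) / 2])
        return float(lo), float(hi)

    @property
    def n_divergences(self) -> int:
        return int(sum(self.diagnostics["divergences"]))

    def to_draws_frame(self, scale: str = "standardized") -> pd.DataFrame:
        draws = self.draws if scale == "standardized" else self.draws_raw
        n_chains, n_iter = next(iter(draws.values())).shape
        cols = {
            "chain": np.repeat(np.arange(n_chains), n_iter),
            "iteration": np.tile(np.arange(n_iter), n_chains),
        }
        for name, d in draws.items():
            cols[name] = np.ravel(d)
        return pd.DataFrame(cols)

    def to_draws_csv(self, path, scale: str = "standardized") -> None:
        self.to_draws_frame(scale).to_csv(Path(path), index=False)

    def to_summary_csv(self, path, scale: str = "standardized") -> None:
        self.summary(scale=scale).to_csv(Path(path), index_label="parameter")


def _destandardize(draws: dict[str, np.ndarray], model: CompiledModel) -> dict[str, np.ndarray]:
    """Map coefficients on standardized covariates back to raw units."""
    out = {k: v.copy() for k, v in draws.items()}
    blocks = [("b1", model.t1.col_names, "trait1"), ("b2", model.t2.col_names, "trait2"),
              ("br", model.x3_names, "contexts")]
    if model.variant == "full":
        blocks.append(("bre", model.x3_names, "contexts"))
    for prefix, cols, tag in blocks:
        shift = 0.0
        for c in cols:
            if c == "intercept":
                continue
            st = model.standardization[f"{tag}.{c}"]
            name = f"{prefix}_{c}"
            shift = shift + draws[name] * st["mean"] / st["sd"]
            out[name] = draws[name] / st["sd"]
        if "intercept" in cols:
            out[f"{prefix}_intercept"] = draws[f"{prefix}_intercept"] - shift
        elif prefix in ("b1", "b2"):
            # ordinal trait: the mean shift is absorbed by the thresholds
            t = model.t1 if prefix == "b1" else model.t2
            if t.family == "ordinal_logit":
                for k in range(t.n_categories - 1):
                    out[f"theta{k + 1}"] = draws[f"theta{k + 1}"] + shift
    return out


def fit(
    model: CompiledModel,
    config: MCMCConfig = TEST_PROFILE,
    prior_only: bool = False,
    n_init_tries: int = 5,
) -> PosteriorResult:
    """Sample the model posterior (or prior, with ``prior_only=True``).

    Chains run sequentially with independent substreams derived from
    ``config.seed``; results are deterministic given seed and data. A
    split-chain Gelman-Rubin statistic above 1.01 on any reported
    parameter raises a :class:`ConvergenceWarning` (never silent).
    """
    if not prior_only:
        for t, tname in ((model.t1, "trait1"), (model.t2, "trait2")):
            if t.y.size and float(np.std(t.y)) == 0.0:
                raise InitializationError(
                    f"{tname} values are all identical ({t.y[0]!r}); a "
                    "zero-variance trait cannot be fitted"
                )

    f = (lambda th: model.logp_grad(th, prior_only=True)) if prior_only else model.logp_grad
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    k_top = _top_block_end(model)

    chain_raw, chain_diag = [], []
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        sampler = NutsSampler(
            f, rng, target_accept=config.target_accept, max_treedepth=config.max_treedepth
        )
        res = None
        for attempt in range(n_init_tries):
            theta0 = model.initial_point(rng)
            lp0, _ = f(theta0)
            if np.isfinite(lp0):
                res = sampler.run(theta0, config.n_warmup, config.n_samples)
                break
        if res is None:
            raise InitializationError(
                f"chain {c}: no finite log density found in {n_init_tries} "
                f"initialization attempts (last logp={lp0!r})"
            )
        chain_raw.append(res["draws"][:: config.thinning])
        chain_diag.append(res)

    raw = np.stack(chain_raw)  # (chains, iters, dim)
    n_chains, n_iter, _ = raw.shape
    flat = raw.reshape(n_chains * n_iter, -1)
    named = model.report_draws(flat)
    draws = {k: v.reshape(n_chains, n_iter) for k, v in named.items()}
    draws_raw = _destandardize(draws, model)

    rh = {k: (rhat(v) if n_chains >= 2 else float("nan")) for k, v in draws.items()}
    diagnostics = {
        "divergences": [int(d["divergent"].sum()) for d in chain_diag],
        "step_size": [float(d["step_size"]) for d in chain_diag],
        "treedepth_hits": [int((d["treedepth"] >= config.max_treedepth).sum()) for d in chain_diag],
        "n_grad_evals": [int(d["n_grad_evals"]) for d in chain_diag],
        "logp_mean": [float(d["logp"].mean()) for d in chain_diag],
    }

    warns = []
    bad = {k: v for k, v in rh.items() if np.isfinite(v) and v > RHAT_WARN_THRESHOLD}
    if bad:
        msg = "split R-hat above %.2f for: %s" % (
            RHAT_WARN_THRESHOLD,
            ", ".join(f"{k}={v:.3f}" for k, v in sorted(bad.items())),
        )
        warns.append(msg)
        warnings.warn(msg, ConvergenceWarning)

    return PosteriorResult(
        draws=draws,
        draws_raw=draws_raw,
        rhat=rh,
        diagnostics=diagnostics,
        config=config,
        raw_top=raw[:, :, :k_top].copy(),
        warnings_=warns,
    )


def _top_block_end(model: CompiledModel) -> int:
    """Index where latent blocks (v1, v2, u1, u2) begin in the layout."""
    latent_starts = [
        model.sl[b].start for b in ("v1", "v2", "u1", "u2") if b in model.sl
    ]
    return min(latent_starts) if latent_starts else model.n_params
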