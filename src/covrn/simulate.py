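"""Individual-based simulators for context-dependent trait correlations.

Each simulator runs the same open-population demographic engine: a fixed
number of recruits enters the population every year, individuals survive
year to year with constant probability, and every alive individual
expresses two traits whose latent effects are drawn from a bivariate
normal distribution whose correlation is ``tanh`` of a linear function of
that year's environmental covariate(s).

Four dataset layouts are produced:

``simulate_intergenerational``
    Quantity-quality design: repeated offspring-mass measurements per
    mother-year (trait 1) against a single litter-size count (trait 2) —
    a hybrid dataset.
``simulate_intraindividual``
    Growth-fecundity design: one Gaussian growth measurement and one
    Poisson fecundity count per individual-year — a non-repeated dataset.
``simulate_marmot_like`` / ``simulate_sheep_like``
    Schema lookalikes with two context covariates, individual-level
    covariates, year random effects and (for the sheep variant) ordinal
    fecundity in {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .data import TraitDataset

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_intergenerational",
    "simulate_intraindividual",
    "simulate_marmot_like",
    "simulate_sheep_like",
]


@dataclass
class SimConfig:
    """Knobs of the demographic engine and the trait model.

    Defaults follow the validation setup: 30 years, 25 recruits/year,
    mean litter size 2.5, annual survival 0.6, a single standard-normal
    climate covariate per year influencing both trait means and, through
    ``beta_r`` on the atanh scale, the among-individual correlation.
    """

    n_years: int = 30
    recruits_per_year: int = 25
    mean_fecundity: float = 2.5
    annual_survival: float = 0.6
    mean_trait1: float = 0.0
    beta_mu1: float = 0.3
    beta_mu2: float = 0.2
    beta_r: tuple[float, ...] = (-0.2, 0.5)
    sd_o1: float = 0.5
    sd_o2: float = 0.6
    sd_within: float = 0.4
    climate_dist: str | list[float] = "normal"
    thresholds: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 1 or self.recruits_per_year < 1:
            raise ValueError("n_years and recruits_per_year must be positive")
        if not (0.0 <= self.annual_survival <= 1.0):
            raise ValueError(f"annual_survival={self.annual_survival} not in [0, 1]")
        if self.mean_fecundity <= 0:
            raise ValueError("mean_fecundity must be positive")
        for name in ("sd_o1", "sd_o2", "sd_within"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if isinstance(self.climate_dist, (list, tuple)) and len(self.climate_dist) != self.n_years:
            raise ValueError(
                f"fixed climate sequence has length {len(self.climate_dist)}, "
                f"need n_years={self.n_years}"
            )

    @property
    def total_recruits(self) -> int:
        return self.n_years * self.recruits_per_year

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta_r"] = list(self.beta_r)
        d["thresholds"] = list(self.thresholds)
        if isinstance(d["climate_dist"], tuple):
            d["climate_dist"] = list(d["climate_dist"])
        return d


@dataclass
class GroundTruth:
    """Generating parameters and realized latent state, for recovery checks."""

    config: SimConfig
    climate: pd.DataFrame  # context, covariate columns
    r_context: pd.DataFrame  # context, r
    latents: pd.DataFrame  # individual, context, o1, o2
    param_truth: dict = field(default_factory=dict)

    def write(self, path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "param_truth": {k: float(v) for k, v in self.param_truth.items()},
            "r_context": {
                str(c): float(r)
                for c, r in zip(self.r_context["context"], self.r_context["r"])
            },
        }
        with open(Path(path), "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _year_rngs(seed: int, n_years: int) -> list[np.random.Generator]:
    # Fixed per-year substreams: edits affecting later years leave earlier
    # years' draws untouched.
    return [
        np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(y,)))
        for y in range(n_years)
    ]


def _draw_climate(cfg: SimConfig, rngs) -> np.ndarray:
    if isinstance(cfg.climate_dist, (list, tuple)):
        return np.asarray(cfg.climate_dist, dtype=float)
    if cfg.climate_dist != "normal":
        raise ValueError(f"unknown climate_dist {cfg.climate_dist!r}")
    return np.array([rngs[y].standard_normal() for y in range(cfg.n_years)])


def _correlated_pair(rng, n, r, sd1, sd2):
    """Exact non-centered construction of n latent pairs at correlation r."""
    u1 = rng.standard_normal(n)
    u2 = rng.standard_normal(n)
    o1 = sd1 * u1
    o2 = sd2 * (r * u1 + np.sqrt(1.0 - r * r) * u2)
    return o1, o2


def _zero_truncated_poisson(rng, lam):
    """Inverse-CDF draw of Poisson conditioned on being >= 1."""
    lam = np.asarray(lam, dtype=float)
    p0 = np.exp(-lam)
    u = p0 + (1.0 - p0) * rng.random(lam.shape)
    # guard against u == 1 rounding to the far tail
    u = np.minimum(u, 1.0 - 1e-12)
    return stats.poisson.ppf(u, lam).astype(int)


def ztp_baseline_log_rate(mean_fecundity: float, sd_o2: float) -> float:
    """Baseline log-rate ``a`` such that a zero-truncated Poisson litter
    with rate ``exp(a + o2)``, o2 ~ N(0, sd_o2^2), has expected size
    ``mean_fecundity`` at baseline covariates.

    The truncation at 1 and the lognormal latent both inflate the
    realized mean above the rate parameter, so the rate intercept must
    sit below ``log(mean_fecundity)`` for the configured mean to be the
    realized one.
    """
    if mean_fecundity <= 1.0:
        raise ValueError(
            f"mean_fecundity={mean_fecundity} impossible for litters truncated at >= 1"
        )
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    weights = weights / weights.sum()

    def realized_mean(a: float) -> float:
        lam = np.exp(a + sd_o2 * nodes)
        return float(np.sum(weights * lam / -np.expm1(-lam)))

    from scipy.optimize import brentq

    hi = np.log(mean_fecundity)
    return float(brentq(lambda a: realized_mean(a) - mean_fecundity, hi - 12.0, hi, xtol=1e-12))


class _Population:
    """Tracks which individuals are alive in which year."""

    def __init__(self, cfg: SimConfig, rngs):
        self.alive_by_year: list[list[int]] = []
        next_id = 0
        alive: list[int] = []
        for y in range(cfg.n_years):
            recruits = list(range(next_id, next_id + cfg.recruits_per_year))
            next_id += cfg.recruits_per_year
            alive = alive + recruits
            self.alive_by_year.append(list(alive))
            survive = rngs[y].random(len(alive)) < cfg.annual_survival
            alive = [i for i, s in zip(alive, survive) if s]
        self.n_individuals = next_id


def _ind_label(i: int) -> str:
    return f"ind_{i:04d}"


def _context_label(y: int) -> str:
    return f"year_{y + 1:02d}"


def simulate_intergenerational(cfg: SimConfig) -> tuple[TraitDataset, GroundTruth]:
    """Quantity-quality hybrid dataset.

    Every alive mother-year draws a latent pair (mass effect, fecundity
    effect) at the year's correlation, produces a zero-truncated-Poisson
    litter, and each offspring contributes one mass measurement. Trait 1
    is offspring mass (repeated within mother-year), trait 2 litter size
    (single count per mother-year).
    """
    rngs = _year_rngs(cfg.seed, cfg.n_years)
    climate = _draw_climate(cfg, rngs)
    pop = _Population(cfg, rngs)
    br = np.asarray(cfg.beta_r, dtype=float)
    r_years = np.tanh(br[0] + br[1] * climate)
    labels = np.array([_ind_label(i) for i in range(pop.n_individuals)])
    # rate intercept calibrated so the realized mean litter size at
    # baseline climate equals mean_fecundity despite truncation at 1
    b2_0 = ztp_baseline_log_rate(cfg.mean_fecundity, cfg.sd_o2)

    parts1, parts2, lat_parts = [], [], []
    for y in range(cfg.n_years):
        rng = rngs[y]
        mothers = np.asarray(pop.alive_by_year[y], dtype=np.intp)
        n = len(mothers)
        o1, o2 = _correlated_pair(rng, n, r_years[y], cfg.sd_o1, cfg.sd_o2)
        lam = np.exp(b2_0 + cfg.beta_mu2 * climate[y] + o2)
        litters = _zero_truncated_poisson(rng, lam)
        mu_mass = cfg.mean_trait1 + cfg.beta_mu1 * climate[y] + o1
        masses = np.repeat(mu_mass, litters) + cfg.sd_within * rng.standard_normal(litters.sum())
        ctx = _context_label(y)
        parts1.append(
            pd.DataFrame(
                {
                    "individual": labels[np.repeat(mothers, litters)],
                    "context": ctx,
                    "value": masses,
                    "climate": climate[y],
                }
            )
        )
        parts2.append(
            pd.DataFrame(
                {
                    "individual": labels[mothers],
                    "context": ctx,
                    "value": litters,
                    "climate": climate[y],
                }
            )
        )
        lat_parts.append(
            pd.DataFrame(
                {"individual": labels[mothers], "context": ctx, "o1": o1, "o2": o2}
            )
        )

    trait1 = pd.concat(parts1, ignore_index=True)
    trait2 = pd.concat(parts2, ignore_index=True)
    contexts = pd.DataFrame(
        {"context": [_context_label(y) for y in range(cfg.n_years)], "climate": climate}
    )
    ds = TraitDataset(
        trait1,
        trait2,
        contexts,
        design="hybrid",
        families=("gaussian", "poisson_log"),
        trait_names=("offspring_mass", "litter_size"),
        zero_truncated=(False, True),
        meta={"seed": cfg.seed, "kind": "intergenerational"},
    )
    gt = GroundTruth(
        config=cfg,
        climate=contexts.copy(),
        r_context=pd.DataFrame({"context": contexts["context"], "r": r_years}),
        latents=pd.concat(lat_parts, ignore_index=True),
        param_truth={
            "b1_intercept": cfg.mean_trait1,
            "b1_climate": cfg.beta_mu1,
            "b2_intercept": b2_0,
            "b2_climate": cfg.beta_mu2,
            "br_intercept": br[0],
            "br_climate": br[1],
            "sd_alpha1": cfg.sd_o1,
            "sd_eps1": cfg.sd_within,
            "sd_o2": cfg.sd_o2,
        },
    )
    return ds, gt


def simulate_intraindividual(cfg: SimConfig) -> tuple[TraitDataset, GroundTruth]:
    """Growth-fecundity non-repeated dataset.

    One Gaussian growth value and one Poisson fecundity count per
    individual-year; the correlation between the two observation-level
    effects follows the climate-driven reaction norm.
    """
    rngs = _year_rngs(cfg.seed, cfg.n_years)
    climate = _draw_climate(cfg, rngs)
    pop = _Population(cfg, rngs)
    br = np.asarray(cfg.beta_r, dtype=float)
    r_years = np.tanh(br[0] + br[1] * climate)
    labels = np.array([_ind_label(i) for i in range(pop.n_individuals)])
    # lognormal mean correction: realized mean fecundity at baseline
    # climate equals mean_fecundity
    b2_0 = float(np.log(cfg.mean_fecundity) - 0.5 * cfg.sd_o2**2)

    parts1, parts2, lat_parts = [], [], []
    for y in range(cfg.n_years):
        rng = rngs[y]
        inds = np.asarray(pop.alive_by_year[y], dtype=np.intp)
        n = len(inds)
        o1, o2 = _correlated_pair(rng, n, r_years[y], cfg.sd_o1, cfg.sd_o2)
        growth = cfg.mean_trait1 + cfg.beta_mu1 * climate[y] + o1
        lam = np.exp(b2_0 + cfg.beta_mu2 * climate[y] + o2)
        fec = rng.poisson(lam)
        ctx = _context_label(y)
        names = labels[inds]
        parts1.append(
            pd.DataFrame(
                {"individual": names, "context": ctx, "value": growth, "climate": climate[y]}
            )
        )
        parts2.append(
            pd.DataFrame(
                {"individual": names, "context": ctx, "value": fec, "climate": climate[y]}
            )
        )
        lat_parts.append(
            pd.DataFrame({"individual": names, "context": ctx, "o1": o1, "o2": o2})
        )

    trait1 = pd.concat(parts1, ignore_index=True)
    trait2 = pd.concat(parts2, ignore_index=True)
    contexts = pd.DataFrame(
        {"context": [_context_label(y) for y in range(cfg.n_years)], "climate": climate}
    )
    ds = TraitDataset(
        trait1,
        trait2,
        contexts,
        design="non_repeated",
        families=("gaussian", "poisson_log"),
        trait_names=("growth", "fecundity"),
        meta={"seed": cfg.seed, "kind": "intraindividual"},
    )
    gt = GroundTruth(
        config=cfg,
        climate=contexts.copy(),
        r_context=pd.DataFrame({"context": contexts["context"], "r": r_years}),
        latents=pd.concat(lat_parts, ignore_index=True),
        param_truth={
            "b1_intercept": cfg.mean_trait1,
            "b1_climate": cfg.beta_mu1,
            "b2_intercept": b2_0,
            "b2_climate": cfg.beta_mu2,
            "br_intercept": br[0],
            "br_climate": br[1],
            "sd_o1": cfg.sd_o1,
            "sd_o2": cfg.sd_o2,
        },
    )
    return ds, gt


_MARMOT_EFFECTS = {
    "beta1": {"snow": 0.2, "june_temp": -0.15, "age": 0.1, "age_sq": -0.05, "mother_mass": 0.3},
    "beta2": {"snow": 0.1, "age": 0.15, "age_sq": -0.08, "mother_mass": 0.2},
    "beta_r": (-0.2, 0.4, -0.3),  # intercept, snow, june_temp
    "sd_year1": 0.2,
    "sd_year2": 0.15,
}

_SHEEP_EFFECTS = {
    "beta1": {"log_prior_mass": 0.5, "age": 0.2, "age_sq": -0.1, "density": -0.2},
    "beta2": {"log_prior_mass": 0.5, "age": 0.15, "age_sq": -0.08, "density": -0.15, "nao": -0.1},
    "beta_r": (-0.3, 0.3, 0.25),  # intercept, nao, density
    "sd_year1": 0.2,
    "sd_year2": 0.15,
}


def simulate_marmot_like(cfg: SimConfig, effects: dict | None = None) -> tuple[TraitDataset, GroundTruth]:
    """Hybrid dataset shaped like the marmot quantity-quality analysis.

    Two context covariates (winter snow and June temperature), mother
    age / age^2 / mass covariates, year random effects on both traits.
    """
    eff = dict(_MARMOT_EFFECTS, **(effects or {}))
    rngs = _year_rngs(cfg.seed, cfg.n_years)
    pop = _Population(cfg, rngs)
    env_rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(10_000,)))
    snow = env_rng.standard_normal(cfg.n_years)
    june = env_rng.standard_normal(cfg.n_years)
    dy1 = eff["sd_year1"] * env_rng.standard_normal(cfg.n_years)
    dy2 = eff["sd_year2"] * env_rng.standard_normal(cfg.n_years)
    br = np.asarray(eff["beta_r"], dtype=float)
    r_years = np.tanh(br[0] + br[1] * snow + br[2] * june)

    entry = {}
    for y in range(cfg.n_years):
        for i in pop.alive_by_year[y]:
            entry.setdefault(i, y)
    b2_0 = ztp_baseline_log_rate(cfg.mean_fecundity, cfg.sd_o2)

    rows1, rows2, lat_rows = [], [], []
    for y in range(cfg.n_years):
        rng = rngs[y]
        mothers = pop.alive_by_year[y]
        n = len(mothers)
        o1, o2 = _correlated_pair(rng, n, r_years[y], cfg.sd_o1, cfg.sd_o2)
        ages = np.array([1.0 + (y - entry[i]) for i in mothers])
        mass_mom = rng.standard_normal(n)
        b1, b2 = eff["beta1"], eff["beta2"]
        eta1 = (
            cfg.mean_trait1
            + b1["snow"] * snow[y] + b1["june_temp"] * june[y]
            + b1["age"] * ages + b1["age_sq"] * ages**2
            + b1["mother_mass"] * mass_mom + dy1[y] + o1
        )
        eta2 = (
            b2_0
            + b2["snow"] * snow[y]
            + b2["age"] * ages + b2["age_sq"] * ages**2
            + b2["mother_mass"] * mass_mom + dy2[y] + o2
        )
        litters = _zero_truncated_poisson(rng, np.exp(eta2))
        ctx = _context_label(y)
        for k, mother in enumerate(mothers):
            ind = _ind_label(mother)
            cov = (snow[y], june[y], ages[k], ages[k] ** 2, mass_mom[k])
            masses = eta1[k] + cfg.sd_within * rng.standard_normal(litters[k])
            for m in masses:
                rows1.append((ind, ctx, float(m)) + cov)
            rows2.append((ind, ctx, int(litters[k])) + cov)
            lat_rows.append((ind, ctx, float(o1[k]), float(o2[k])))

    cols = ["individual", "context", "value", "snow", "june_temp", "age", "age_sq", "mother_mass"]
    trait1 = pd.DataFrame(rows1, columns=cols)
    trait2 = pd.DataFrame(rows2, columns=cols)
    contexts = pd.DataFrame(
        {"context": [_context_label(y) for y in range(cfg.n_years)], "snow": snow, "june_temp": june}
    )
    ds = TraitDataset(
        trait1,
        trait2,
        contexts,
        design="hybrid",
        families=("gaussian", "poisson_log"),
        trait_names=("offspring_mass", "litter_size"),
        zero_truncated=(False, True),
        meta={"seed": cfg.seed, "kind": "marmot_like"},
    )
    gt = GroundTruth(
        config=cfg,
        climate=contexts.copy(),
        r_context=pd.DataFrame({"context": contexts["context"], "r": r_years}),
        latents=pd.DataFrame(lat_rows, columns=["individual", "context", "o1", "o2"]),
        param_truth={
            "br_intercept": br[0], "br_snow": br[1], "br_june_temp": br[2],
            "sd_alpha1": cfg.sd_o1, "sd_eps1": cfg.sd_within, "sd_o2": cfg.sd_o2,
        },
    )
    return ds, gt


def simulate_sheep_like(cfg: SimConfig, effects: dict | None = None) -> tuple[TraitDataset, GroundTruth]:
    """Non-repeated dataset shaped like the sheep growth-fecundity analysis.

    Ordinal fecundity in {0, 1, 2} via a cumulative-logit latent, Gaussian
    log mass, two context covariates (winter NAO and density), year random
    effects on both traits.
    """
    theta1, theta2 = cfg.thresholds
    if not theta1 < theta2:
        raise ValueError(f"thresholds must be strictly increasing, got {cfg.thresholds}")
    eff = dict(_SHEEP_EFFECTS, **(effects or {}))
    rngs = _year_rngs(cfg.seed, cfg.n_years)
    pop = _Population(cfg, rngs)
    env_rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(10_000,)))
    nao = env_rng.standard_normal(cfg.n_years)
    density = env_rng.standard_normal(cfg.n_years)
    dy1 = eff["sd_year1"] * env_rng.standard_normal(cfg.n_years)
    dy2 = eff["sd_year2"] * env_rng.standard_normal(cfg.n_years)
    br = np.asarray(eff["beta_r"], dtype=float)
    r_years = np.tanh(br[0] + br[1] * nao + br[2] * density)

    entry = {}
    for y in range(cfg.n_years):
        for i in pop.alive_by_year[y]:
            entry.setdefault(i, y)

    rows1, rows2, lat_rows = [], [], []
    for y in range(cfg.n_years):
        rng = rngs[y]
        inds = pop.alive_by_year[y]
        n = len(inds)
        o1, o2 = _correlated_pair(rng, n, r_years[y], cfg.sd_o1, cfg.sd_o2)
        ages = np.array([1.0 + (y - entry[i]) for i in inds])
        prior_mass = rng.standard_normal(n)
        b1, b2 = eff["beta1"], eff["beta2"]
        eta1 = (
            b1["log_prior_mass"] * prior_mass + b1["age"] * ages
            + b1["age_sq"] * ages**2 + b1["density"] * density[y] + dy1[y] + o1
        )
        # cumulative logit: P(y <= i) = logistic(theta_i - eta)
        p_le0 = 1.0 / (1.0 + np.exp(-(theta1 - eta1)))
        p_le1 = 1.0 / (1.0 + np.exp(-(theta2 - eta1)))
        u = rng.random(n)
        fec = np.where(u < p_le0, 0, np.where(u < p_le1, 1, 2))
        eta2 = (
            cfg.mean_trait1
            + b2["log_prior_mass"] * prior_mass + b2["age"] * ages
            + b2["age_sq"] * ages**2 + b2["density"] * density[y]
            + b2["nao"] * nao[y] + dy2[y] + o2
        )
        ctx = _context_label(y)
        for k, i in enumerate(inds):
            ind = _ind_label(i)
            cov = (nao[y], density[y], ages[k], ages[k] ** 2, prior_mass[k])
            rows1.append((ind, ctx, int(fec[k])) + cov)
            rows2.append((ind, ctx, float(eta2[k])) + cov)
            lat_rows.append((ind, ctx, float(o1[k]), float(o2[k])))

    cols = ["individual", "context", "value", "nao", "density", "age", "age_sq", "log_prior_mass"]
    trait1 = pd.DataFrame(rows1, columns=cols)
    trait2 = pd.DataFrame(rows2, columns=cols)
    contexts = pd.DataFrame(
        {"context": [_context_label(y) for y in range(cfg.n_years)], "nao": nao, "density": density}
    )
    ds = TraitDataset(
        trait1,
        trait2,
        contexts,
        design="non_repeated",
        families=("ordinal_logit", "gaussian"),
        trait_names=("fecundity", "log_mass"),
        meta={"seed": cfg.seed, "kind": "sheep_like", "n_categories": 3},
    )
    gt = GroundTruth(
        config=cfg,
        climate=contexts.copy(),
        r_context=pd.DataFrame({"context": contexts["context"], "r": r_years}),
        latents=pd.DataFrame(lat_rows, columns=["individual", "context", "o1", "o2"]),
        param_truth={
            "br_intercept": br[0], "br_nao": br[1], "br_density": br[2],
            "sd_o1": cfg.sd_o1, "sd_o2": cfg.sd_o2,
            "theta1": theta1, "theta2": theta2,
        },
    )
    return ds, gt
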