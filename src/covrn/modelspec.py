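"""Declarative model specifications and compilation to fit-ready models.

Three variants are supported:

``full``
    Both traits Gaussian with repeated, paired measurements per
    (subject, context); separate among-subject and within-subject
    correlation reaction norms.
``non_repeated``
    One measurement of each trait per (subject, context); a single
    observation-level latent pair per measurement pair.
``hybrid``
    Trait 1 repeated within (subject, context) (e.g. offspring masses in
    a litter), trait 2 measured once (e.g. litter size); the correlation
    links trait 1's subject-context effect to trait 2's
    observation-level effect.

Continuous covariates are standardized internally (sample mean/SD of the
supplied data); the standardization is stored on the compiled model so
that predictions can be made on either scale. Latent SDs are constant
across contexts (intercept-only variance model): context covariates act
on the correlation, not on the scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compiled import CompiledModel, _TraitBlock
from .data import TraitDataset

__all__ = [
    "FamilySpec",
    "PriorSpec",
    "CRNModelSpec",
    "build_model",
    "marmot_preset",
    "sheep_preset",
]


class ModelSpecError(ValueError):
    """Specification/data mismatch or invalid specification."""


@dataclass(frozen=True)
class FamilySpec:
    family: str  # gaussian | poisson_log | ordinal_logit
    n_categories: int = 0
    zero_truncated: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "poisson_log", "ordinal_logit"):
            raise ModelSpecError(f"unknown family {self.family!r}")
        if self.family == "ordinal_logit" and self.n_categories < 2:
            raise ModelSpecError(
                f"ordinal family needs n_categories >= 2, got {self.n_categories}"
            )
        if self.zero_truncated and self.family != "poisson_log":
            raise ModelSpecError("zero_truncated applies to poisson_log only")


@dataclass(frozen=True)
class PriorSpec:
    """Regularizing priors: Normal(loc, scale) on coefficients,
    Exponential(rate) on SD parameters, Normal on ordinal thresholds."""

    coef_loc: float = 0.0
    coef_scale: float = 1.0
    sd_rate: float = 2.0
    threshold_loc: float = 0.0
    threshold_scale: float = 2.0

    def __post_init__(self) -> None:
        for name in ("coef_scale", "sd_rate", "threshold_scale"):
            if getattr(self, name) <= 0:
                raise ModelSpecError(f"{name} must be strictly positive")


@dataclass
class CRNModelSpec:
    variant: str
    family1: FamilySpec
    family2: FamilySpec
    covariates1: list[str] = field(default_factory=list)
    covariates2: list[str] = field(default_factory=list)
    corr_covariates: list[str] = field(default_factory=list)
    include_year_effects: tuple[bool, bool] = (False, False)
    variance_model: str = "intercept_only"
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self) -> None:
        if self.variant not in ("full", "non_repeated", "hybrid"):
            raise ModelSpecError(f"unknown variant {self.variant!r}")
        if self.variance_model not in ("intercept_only", "with_covariates"):
            raise ModelSpecError(f"unknown variance_model {self.variance_model!r}")
        if self.variant in ("hybrid", "full") and self.family1.family != "gaussian":
            raise ModelSpecError(
                f"{self.variant} variant requires a Gaussian trait 1 "
                f"(repeated measures), got {self.family1.family!r}"
            )
        if self.variant == "full" and self.family2.family != "gaussian":
            raise ModelSpecError("full variant requires Gaussian families for both traits")

    # ------------------------------------------------------------------- YAML
    def to_yaml(self, path=None) -> str:
        payload = {
            "variant": self.variant,
            "family1": asdict(self.family1),
            "family2": asdict(self.family2),
            "covariates1": list(self.covariates1),
            "covariates2": list(self.covariates2),
            "corr_covariates": list(self.corr_covariates),
            "include_year_effects": list(self.include_year_effects),
            "variance_model": self.variance_model,
            "priors": asdict(self.priors),
        }
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "CRNModelSpec":
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            payload = yaml.safe_load(Path(source).read_text())
        else:
            payload = yaml.safe_load(source)
        return cls(
            variant=payload["variant"],
            family1=FamilySpec(**payload["family1"]),
            family2=FamilySpec(**payload["family2"]),
            covariates1=list(payload.get("covariates1", [])),
            covariates2=list(payload.get("covariates2", [])),
            corr_covariates=list(payload.get("corr_covariates", [])),
            include_year_effects=tuple(payload.get("include_year_effects", [False, False])),
            variance_model=payload.get("variance_model", "intercept_only"),
            priors=PriorSpec(**payload.get("priors", {})),
        )


def spec_for_dataset(data: TraitDataset) -> CRNModelSpec:
    """Default spec matching a simulator dataset's metadata."""
    fams = []
    for j, fam in enumerate(data.families):
        n_cat = data.meta.get("n_categories", 0) if fam == "ordinal_logit" else 0
        fams.append(
            FamilySpec(fam, n_categories=n_cat, zero_truncated=data.zero_truncated[j])
        )
    return CRNModelSpec(
        variant=data.design,
        family1=fams[0],
        family2=fams[1],
        covariates1=data.covariate_columns("trait1"),
        covariates2=data.covariate_columns("trait2"),
        corr_covariates=data.covariate_columns("contexts"),
    )


def _standardize(values: np.ndarray, name: str, stats: dict) -> np.ndarray:
    mean = float(np.mean(values))
    sd = float(np.std(values))
    if sd == 0.0:
        raise ModelSpecError(f"covariate {name!r} is constant; cannot standardize")
    stats[name] = {"mean": mean, "sd": sd}
    return (values - mean) / sd


def _design_matrix(table: pd.DataFrame, covariates, intercept: bool, tag: str, stats: dict):
    cols, names = [], []
    if intercept:
        cols.append(np.ones(len(table)))
        names.append("intercept")
    for c in covariates:
        if c not in table.columns:
            raise ModelSpecError(f"covariate column {c!r} absent from {tag} table")
        cols.append(_standardize(table[c].to_numpy(dtype=float), f"{tag}.{c}", stats))
        names.append(c)
    X = np.column_stack(cols) if cols else np.empty((len(table), 0))
    if X.shape[1]:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, R = np.linalg.qr(X)
            bad = [names[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8]
            raise ModelSpecError(f"design matrix for {tag} is rank deficient; collinear columns: {bad}")
    return X, names


def build_model(spec: CRNModelSpec, data: TraitDataset) -> CompiledModel:
    """Compile a model spec against a dataset into a fit-ready model."""
    if spec.variance_model == "with_covariates":
        raise NotImplementedError(
            "context-covariate variance models are not implemented; latent SDs "
            "are constant across contexts (variance_model='intercept_only')"
        )
    t1, t2 = data.trait1, data.trait2

    # context indexing follows the contexts table order
    ctx_ids = data.contexts["context"].astype(str).tolist()
    ctx_index = {c: i for i, c in enumerate(ctx_ids)}
    c1 = t1["context"].astype(str).map(ctx_index).to_numpy(dtype=np.intp)
    c2 = t2["context"].astype(str).map(ctx_index).to_numpy(dtype=np.intp)

    # latent units: distinct (individual, context) pairs across both traits
    keys1 = list(zip(t1["individual"].astype(str), t1["context"].astype(str)))
    keys2 = list(zip(t2["individual"].astype(str), t2["context"].astype(str)))
    units = sorted(set(keys1) | set(keys2))
    unit_index = {k: i for i, k in enumerate(units)}
    m1 = np.array([unit_index[k] for k in keys1], dtype=np.intp)
    m2 = np.array([unit_index[k] for k in keys2], dtype=np.intp)
    unit_ctx = np.array([ctx_index[k[1]] for k in units], dtype=np.intp)

    # repeated-measure structure checks per variant
    counts1 = np.bincount(m1, minlength=len(units))
    counts2 = np.bincount(m2, minlength=len(units))
    roles = _assign_roles(spec)
    for j, (role, counts, tname) in enumerate(
        ((roles[0], counts1, "trait1"), (roles[1], counts2, "trait2"))
    ):
        if role in ("residual", "direct"):
            if counts.max(initial=0) > 1:
                raise ModelSpecError(
                    f"{spec.variant} variant requires at most one {tname} measurement "
                    f"per (individual, context); found repeats"
                )
            if counts.min(initial=1) < 1:
                raise ModelSpecError(
                    f"{spec.variant} variant requires a {tname} measurement for every "
                    f"(individual, context) pair present in the data"
                )
    if spec.variant == "hybrid" and counts1.max(initial=0) <= 1:
        raise ModelSpecError(
            "hybrid variant requires repeated trait1 measurements within "
            "(individual, context); none found"
        )
    if spec.variant == "full":
        if len(t1) != len(t2) or keys1 != keys2:
            raise ModelSpecError(
                "full variant requires paired trait1/trait2 measurements in "
                "matching row order (same individual and context per row)"
            )

    stats: dict = {}
    X1, names1 = _design_matrix(
        t1, spec.covariates1, spec.family1.family != "ordinal_logit", "trait1", stats
    )
    X2, names2 = _design_matrix(
        t2, spec.covariates2, spec.family2.family != "ordinal_logit", "trait2", stats
    )
    X3, names3 = _design_matrix(data.contexts, spec.corr_covariates, True, "contexts", stats)

    def block(t, X, ctx, unit, fam: FamilySpec, role, names):
        dtype = float
        return _TraitBlock(
            y=t["value"].to_numpy(dtype=dtype),
            X=X,
            ctx=ctx,
            unit=unit,
            family=fam.family,
            role=role,
            zero_truncated=fam.zero_truncated,
            n_categories=fam.n_categories,
            col_names=names,
        )

    for fam, tname, t in ((spec.family1, "trait1", t1), (spec.family2, "trait2", t2)):
        if fam.family == "poisson_log":
            vals = t["value"].to_numpy(dtype=float)
            if np.any(vals < 0) or np.any(vals != np.round(vals)):
                raise ModelSpecError(f"poisson_log {tname} values must be nonnegative integers")
        if fam.family == "ordinal_logit":
            vals = t["value"].to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > fam.n_categories - 1) | (vals != np.round(vals))):
                raise ModelSpecError(
                    f"ordinal {tname} values must be integers in [0, {fam.n_categories - 1}]"
                )

    model = CompiledModel(
        variant=spec.variant,
        t1=block(t1, X1, c1, m1, spec.family1, roles[0], names1),
        t2=block(t2, X2, c2, m2, spec.family2, roles[1], names2),
        X3=X3,
        x3_names=names3,
        unit_ctx=unit_ctx,
        n_contexts=len(ctx_ids),
        include_year=spec.include_year_effects,
        priors=spec.priors,
        standardization=stats,
        trait_names=data.trait_names,
    )
    model.context_ids = ctx_ids
    model.spec = spec
    return model


def _assign_roles(spec: CRNModelSpec) -> tuple[str, str]:
    if spec.variant == "full":
        return ("paired", "paired")
    if spec.variant == "hybrid":
        role2 = "residual" if spec.family2.family == "gaussian" else "direct"
        return ("repeated", role2)
    role1 = "residual" if spec.family1.family == "gaussian" else "direct"
    role2 = "residual" if spec.family2.family == "gaussian" else "direct"
    return (role1, role2)


# ---------------------------------------------------------------------- presets

_MARMOT_X1 = ["snow", "june_temp", "age", "age_sq", "mother_mass"]
_MARMOT_X2 = ["snow", "age", "age_sq", "mother_mass"]  # June temperature excluded:
# fecundity is determined before summer temperatures act
_MARMOT_X3 = ["snow", "june_temp"]

_SHEEP_X1 = ["log_prior_mass", "age", "age_sq", "density"]
_SHEEP_X2 = ["log_prior_mass", "age", "age_sq", "density", "nao"]
_SHEEP_X3 = ["nao", "density"]


def _require_columns(data: TraitDataset, table: str, cols: list[str]) -> None:
    have = set(getattr(data, table).columns)
    missing = [c for c in cols if c not in have]
    if missing:
        raise ModelSpecError(f"{table} table lacks required columns {missing}")


def marmot_preset(data: TraitDataset) -> CRNModelSpec:
    """Hybrid quantity-quality model: Gaussian offspring mass against
    (zero-truncated) Poisson litter size, snow and June temperature on the
    correlation, year random effects on both traits."""
    _require_columns(data, "trait1", _MARMOT_X1)
    _require_columns(data, "trait2", _MARMOT_X2)
    _require_columns(data, "contexts", _MARMOT_X3)
    return CRNModelSpec(
        variant="hybrid",
        family1=FamilySpec("gaussian"),
        family2=FamilySpec("poisson_log", zero_truncated=data.zero_truncated[1]),
        covariates1=list(_MARMOT_X1),
        covariates2=list(_MARMOT_X2),
        corr_covariates=list(_MARMOT_X3),
        include_year_effects=(True, True),
    )


def sheep_preset(data: TraitDataset) -> CRNModelSpec:
    """Non-repeated growth-fecundity model: ordinal fecundity in {0, 1, 2}
    against Gaussian log mass, NAO and density on the correlation, year
    random effects on both traits."""
    _require_columns(data, "trait1", _SHEEP_X1)
    _require_columns(data, "trait2", _SHEEP_X2)
    _require_columns(data, "contexts", _SHEEP_X3)
    return CRNModelSpec(
        variant="non_repeated",
        family1=FamilySpec("ordinal_logit", n_categories=int(data.meta.get("n_categories", 3))),
        family2=FamilySpec("gaussian"),
        covariates1=list(_SHEEP_X1),
        covariates2=list(_SHEEP_X2),
        corr_covariates=list(_SHEEP_X3),
        include_year_effects=(True, True),
    )
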