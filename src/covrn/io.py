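"""Reading, validating and writing long-format trait tables.

Fixed CSV dialect: UTF-8, comma separators, header row, '.' decimal.
Context and individual IDs are opaque strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .data import DatasetError, TraitDataset
from .modelspec import CRNModelSpec

__all__ = ["read_trait_tables", "validate_design", "RunConfig"]

_FILES = ("trait1.csv", "trait2.csv", "contexts.csv")


def read_trait_tables(directory, design: str | None = None) -> TraitDataset:
    """Load trait1.csv, trait2.csv and contexts.csv (plus metadata.yaml if
    present) from ``directory`` into a validated :class:`TraitDataset`."""
    directory = Path(directory)
    missing = [f for f in _FILES if not (directory / f).exists()]
    if missing:
        raise DatasetError(f"missing required files in {directory}: {missing}")
    trait1 = pd.read_csv(directory / "trait1.csv")
    trait2 = pd.read_csv(directory / "trait2.csv")
    contexts = pd.read_csv(directory / "contexts.csv")
    meta_path = directory / "metadata.yaml"
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    if design is None:
        design = meta.get("design")
    if design is None:
        raise DatasetError(
            "dataset design unknown: no metadata.yaml and no explicit design given"
        )
    known = {"design", "families", "trait_names", "zero_truncated"}
    return TraitDataset(
        trait1,
        trait2,
        contexts,
        design=design,
        families=tuple(meta.get("families", ("gaussian", "gaussian"))),
        trait_names=tuple(meta.get("trait_names", ("trait1", "trait2"))),
        zero_truncated=tuple(meta.get("zero_truncated", (False, False))),
        meta={k: v for k, v in meta.items() if k not in known},
    )


def validate_design(dataset: TraitDataset, spec: CRNModelSpec) -> dict:
    """Check a dataset against a model spec's structural requirements.

    Returns a report dict with per-check pass/fail entries and advisory
    warnings; never raises for a failed check.
    """
    checks: dict[str, bool] = {}
    warnings_: list[str] = []

    dup1 = dataset.trait1.duplicated(subset=["individual", "context"]).any()
    dup2 = dataset.trait2.duplicated(subset=["individual", "context"]).any()
    if spec.variant == "non_repeated":
        checks["trait1_single_measurement_per_individual_context"] = not dup1
        checks["trait2_single_measurement_per_individual_context"] = not dup2
        warnings_.append(
            "non-repeated design: the estimated correlation is observation-level; "
            "it understates (and with opposed among-/within-individual correlations "
            "can flip the sign of) the among-individual correlation unless both "
            "traits' repeatabilities are medium to high"
        )
    elif spec.variant == "hybrid":
        checks["trait1_has_repeated_measurements"] = bool(dup1)
        checks["trait2_single_measurement_per_individual_context"] = not dup2
        warnings_.append(
            "hybrid design: the estimated correlation is the among-individual "
            "correlation shrunk by sqrt(repeatability of trait 2)"
        )
    else:  # full
        checks["paired_measurements"] = len(dataset.trait1) == len(dataset.trait2)

    for j, fam in enumerate((spec.family1, spec.family2), start=1):
        table = dataset.trait1 if j == 1 else dataset.trait2
        vals = table["value"]
        if fam.family == "poisson_log":
            checks[f"trait{j}_counts_nonnegative_integers"] = bool(
                ((vals >= 0) & (vals == vals.round())).all()
            )
        if fam.family == "ordinal_logit":
            checks[f"trait{j}_ordinal_in_range"] = bool(
                vals.isin(range(fam.n_categories)).all()
            )

    missing1 = [c for c in spec.covariates1 if c not in dataset.trait1.columns]
    missing2 = [c for c in spec.covariates2 if c not in dataset.trait2.columns]
    missing3 = [c for c in spec.corr_covariates if c not in dataset.contexts.columns]
    checks["covariate_columns_present"] = not (missing1 or missing2 or missing3)

    return {
        "variant": spec.variant,
        "passed": all(checks.values()),
        "checks": checks,
        "warnings": warnings_,
    }


@dataclass
class RunConfig:
    """End-to-end run configuration resolvable from YAML + seed alone."""

    data_dir: str
    out_dir: str
    model_spec: str  # path to a model-spec YAML
    seed: int = 0
    n_chains: int = 2
    n_warmup: int = 500
    n_samples: int = 500
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in payload.items() if k in known}
        kwargs["extra"] = {k: v for k, v in payload.items() if k not in known}
        return cls(**kwargs)

    def validate(self) -> None:
        if not Path(self.data_dir).exists():
            raise FileNotFoundError(f"data_dir {self.data_dir!r} does not exist")
        if not Path(self.model_spec).exists():
            raise FileNotFoundError(f"model_spec {self.model_spec!r} does not exist")
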