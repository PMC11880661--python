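"""Long-format bivariate trait dataset container and validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

REQUIRED_TRAIT_COLUMNS = ("individual", "context", "value")

VALID_DESIGNS = ("full", "non_repeated", "hybrid")
VALID_FAMILIES = ("gaussian", "poisson_log", "ordinal_logit")


class DatasetError(ValueError):
    """A structural problem with a trait dataset."""


@dataclass
class TraitDataset:
    """Two long-format trait tables plus a context-level covariate table.

    Each trait table has one row per measurement with columns
    ``individual``, ``context``, ``value`` and any number of
    measurement-level covariate columns. ``contexts`` has exactly one
    row per context ID and carries the covariates that drive the
    correlation reaction norm.
    """

    trait1: pd.DataFrame
    trait2: pd.DataFrame
    contexts: pd.DataFrame
    design: str
    families: tuple[str, str] = ("gaussian", "gaussian")
    trait_names: tuple[str, str] = ("trait1", "trait2")
    zero_truncated: tuple[bool, bool] = (False, False)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.design not in VALID_DESIGNS:
            raise DatasetError(
                f"design {self.design!r} not one of {VALID_DESIGNS}"
            )
        for fam in self.families:
            if fam not in VALID_FAMILIES:
                raise DatasetError(f"family {fam!r} not one of {VALID_FAMILIES}")
        if "context" not in self.contexts.columns:
            raise DatasetError("contexts table lacks a 'context' column")
        if self.contexts["context"].duplicated().any():
            dupes = self.contexts.loc[
                self.contexts["context"].duplicated(), "context"
            ].tolist()
            raise DatasetError(f"duplicate context rows in contexts table: {dupes}")
        known = set(self.contexts["context"].astype(str))
        for name, table in (("trait1", self.trait1), ("trait2", self.trait2)):
            missing_cols = [c for c in REQUIRED_TRAIT_COLUMNS if c not in table.columns]
            if missing_cols:
                raise DatasetError(f"{name} table missing columns {missing_cols}")
            if table[list(REQUIRED_TRAIT_COLUMNS)].isna().any().any():
                raise DatasetError(f"{name} table has missing values in required columns")
            orphans = set(table["context"].astype(str)) - known
            if orphans:
                raise DatasetError(
                    f"context IDs {sorted(orphans)} in {name} table absent from contexts table"
                )
        # repeated-measures structure per design
        dup1 = self.trait1.duplicated(subset=["individual", "context"]).any()
        dup2 = self.trait2.duplicated(subset=["individual", "context"]).any()
        if self.design == "non_repeated" and (dup1 or dup2):
            which = [n for n, d in (("trait1", dup1), ("trait2", dup2)) if d]
            raise DatasetError(
                f"non_repeated design forbids repeated (individual, context) "
                f"measurements; found in {which}"
            )
        if self.design == "hybrid" and dup2:
            raise DatasetError(
                "hybrid design requires at most one trait2 measurement per "
                "(individual, context); found duplicates"
            )

    @property
    def context_ids(self) -> list[str]:
        return self.contexts["context"].astype(str).tolist()

    def covariate_columns(self, which: str) -> list[str]:
        table = {"trait1": self.trait1, "trait2": self.trait2, "contexts": self.contexts}[which]
        skip = set(REQUIRED_TRAIT_COLUMNS) | {"context"}
        return [c for c in table.columns if c not in skip]

    def write(self, outdir) -> None:
        """Write trait1.csv, trait2.csv, contexts.csv and metadata.yaml."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.trait1.to_csv(outdir / "trait1.csv", index=False)
        self.trait2.to_csv(outdir / "trait2.csv", index=False)
        self.contexts.to_csv(outdir / "contexts.csv", index=False)
        meta = {
            "design": self.design,
            "families": list(self.families),
            "trait_names": list(self.trait_names),
            "zero_truncated": list(self.zero_truncated),
            **self.meta,
        }
        with open(outdir / "metadata.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)
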