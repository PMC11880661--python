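"""Correlation link function and repeatability-weighted correlation algebra.

A correlation measured on single observations per individual mixes the
among-individual correlation and the within-individual correlation,
weighted by the geometric mean of the two traits' repeatabilities:

    r_obs = r_alpha * sqrt(R1 * R2) + r_eps * sqrt((1 - R1) * (1 - R2))

This module provides that decomposition, its hybrid-design special case
``r_alpha * sqrt(R2)``, the atanh link used to regress correlations on
covariates, and a grid sweep that classifies the parameter regions where
the observation-level correlation has the opposite sign to the
among-individual one (sign bias).

Repeatabilities are taken as supplied; they are assumed to refer to
phenotypic variances already adjusted for mean (fixed-effect) structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BiasPoint",
    "BiasGrid",
    "corr_link",
    "corr_unlink",
    "observation_level_correlation",
    "hybrid_correlation",
    "bias_grid",
]

_PARAM_DOMAINS = {
    "r_alpha": (-1.0, 1.0),
    "r_eps": (-1.0, 1.0),
    "R1": (0.0, 1.0),
    "R2": (0.0, 1.0),
}


def _check_domain(name: str, value: float) -> float:
    lo, hi = _PARAM_DOMAINS[name]
    value = float(value)
    if not math.isfinite(value) or not (lo <= value <= hi):
        raise ValueError(f"{name}={value!r} outside its domain [{lo}, {hi}]")
    return value


@dataclass(frozen=True)
class BiasPoint:
    """One point of the correlation-bias surface.

    ``bias`` is ``r_obs - r_alpha``; ``sign_flipped`` is True only when
    ``r_obs`` and ``r_alpha`` are both nonzero with strictly opposite
    signs (a zero on either side is classified as not flipped).
    """

    r_alpha: float
    r_eps: float
    R1: float
    R2: float
    r_obs: float = field(init=False)
    bias: float = field(init=False)
    sign_flipped: bool = field(init=False)

    def __post_init__(self) -> None:
        for name in ("r_alpha", "r_eps", "R1", "R2"):
            _check_domain(name, getattr(self, name))
        r_obs = self.r_alpha * math.sqrt(self.R1 * self.R2) + self.r_eps * math.sqrt(
            (1.0 - self.R1) * (1.0 - self.R2)
        )
        object.__setattr__(self, "r_obs", r_obs)
        object.__setattr__(self, "bias", r_obs - self.r_alpha)
        flipped = (
            self.r_alpha != 0.0 and r_obs != 0.0 and (self.r_alpha > 0) != (r_obs > 0)
        )
        object.__setattr__(self, "sign_flipped", flipped)


def corr_link(r):
    """Map a correlation in (-1, 1) to the real line via atanh.

    Identical to ``logit((r + 1) / 2) / 2``. Inputs with ``|r| >= 1`` are
    rejected rather than clamped; callers holding boundary values must
    shrink them first.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(np.abs(arr) >= 1.0):
        bad = arr[~(np.isfinite(arr) & (np.abs(arr) < 1.0))]
        raise ValueError(f"correlation(s) {bad!r} not strictly inside (-1, 1)")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


_ONE_BELOW = np.nextafter(1.0, 0.0)


def corr_unlink(eta):
    """Inverse of :func:`corr_link`: tanh, mapping reals into (-1, 1).

    Saturating inputs (|eta| > ~19) are clamped to the nearest float64
    strictly inside the open interval, preserving the range contract.
    """
    arr = np.asarray(eta, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"link-scale value(s) {arr[~np.isfinite(arr)]!r} not finite")
    out = np.clip(np.tanh(arr), -_ONE_BELOW, _ONE_BELOW)
    return float(out) if np.isscalar(eta) or arr.ndim == 0 else out


def observation_level_correlation(
    r_alpha: float, r_eps: float, R1: float, R2: float
) -> BiasPoint:
    """Blend among- and within-individual correlations into the
    correlation expected between single observations per individual."""
    return BiasPoint(r_alpha=r_alpha, r_eps=r_eps, R1=R1, R2=R2)


def hybrid_correlation(r_alpha: float, R2: float) -> float:
    """Observation-level correlation when trait 1 enters as an
    individual-level effect and trait 2 as single measurements.

    Equals ``r_alpha * sqrt(R2)`` — the ``R1 = 1`` limit of
    :func:`observation_level_correlation`, with the within-individual
    correlation irrelevant.
    """
    _check_domain("r_alpha", r_alpha)
    _check_domain("R2", R2)
    return float(r_alpha) * math.sqrt(float(R2))


@dataclass(frozen=True)
class GridAxis:
    """Inclusive sweep of one parameter; ``n`` is the cell count."""

    name: str
    start: float
    stop: float
    n: int

    def __post_init__(self) -> None:
        if self.name not in _PARAM_DOMAINS:
            raise ValueError(f"unknown parameter {self.name!r}")
        if self.n < 1:
            raise ValueError(f"axis {self.name!r} has {self.n} cells; need >= 1")
        _check_domain(self.name, self.start)
        _check_domain(self.name, self.stop)

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n)


@dataclass
class BiasGrid:
    axes: tuple[GridAxis, GridAxis]
    fixed: dict[str, float]
    points: list[list[BiasPoint]]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.axes[0].n, self.axes[1].n)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-cell table suitable for surface plotting."""
        rows = []
        for i, vi in enumerate(self.axes[0].values):
            for j, vj in enumerate(self.axes[1].values):
                p = self.points[i][j]
                rows.append(
                    {
                        self.axes[0].name: vi,
                        self.axes[1].name: vj,
                        "r_alpha": p.r_alpha,
                        "r_eps": p.r_eps,
                        "R1": p.R1,
                        "R2": p.R2,
                        "r_obs": p.r_obs,
                        "bias": p.bias,
                        "sign_flipped": p.sign_flipped,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def bias_grid(
    fixed: dict[str, float],
    axes: Sequence[GridAxis | tuple[str, float, float, int]],
) -> BiasGrid:
    """Evaluate the bias surface over two swept parameters.

    ``fixed`` supplies the parameters not swept; ``axes`` gives exactly
    two distinct swept parameters (as :class:`GridAxis` or
    ``(name, start, stop, n)`` tuples). Endpoints are inclusive.
    """
    ax = tuple(a if isinstance(a, GridAxis) else GridAxis(*a) for a in axes)
    if len(ax) != 2:
        raise ValueError(f"exactly two axes required, got {len(ax)}")
    if ax[0].name == ax[1].name:
        raise ValueError(f"swept parameters must be distinct, both {ax[0].name!r}")
    swept = {a.name for a in ax}
    names = set(_PARAM_DOMAINS)
    missing = names - swept - set(fixed)
    if missing:
        raise ValueError(f"parameters {sorted(missing)} neither fixed nor swept")
    points: list[list[BiasPoint]] = []
    for vi in ax[0].values:
        row = []
        for vj in ax[1].values:
            kw = dict(fixed)
            kw[ax[0].name] = vi
            kw[ax[1].name] = vj
            row.append(BiasPoint(**{k: kw[k] for k in _PARAM_DOMAINS}))
        points.append(row)
    return BiasGrid(axes=ax, fixed=dict(fixed), points=points)
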