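"""Composition-evolution accounting through synthesis, purification and
depolymerization.

All compositions are mole fractions of polymerized units; differences are
reported in percentage points.  The accounting is exact against the
simulator's integer monomer pools: converting a simulated ensemble's
per-monomer conversions back to a composition reproduces the direct
sequence-count composition to machine precision, purification is an exact
partition, and living/dead subpopulation compositions recombine exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chemistry import MonomerRegistry, chain_hlb, chain_molar_mass
from .simulate import Ensemble, FeedState

__all__ = [
    "ConversionRecord",
    "IntegralTable",
    "loss_correct",
    "composition_from_conversions",
    "conversions_from_integrals",
    "compare_compositions",
    "purification_filter",
    "split_living_dead",
    "depolymerization_readout",
]


@dataclass(frozen=True)
class ConversionRecord:
    """Per-monomer conversions x_i plus the feed they refer to."""

    x: np.ndarray
    feed0: FeedState

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
            raise ValueError("conversions must lie in [0, 1]")
        object.__setattr__(self, "x", np.clip(x, 0.0, 1.0))

    @property
    def global_conversion(self) -> float:
        f = self.feed0.fractions
        return float(f @ self.x)

    @classmethod
    def from_ensemble(cls, ensemble: Ensemble) -> "ConversionRecord":
        return cls(x=ensemble.conversion_per_monomer, feed0=ensemble.feed0)


@dataclass(frozen=True)
class IntegralTable:
    """Pre- and post-polymerization per-monomer signal integrals.

    ``loss_fractions`` holds per-monomer fractions lost between the pre- and
    post-polymerization measurements for reasons other than polymerization
    (e.g. evaporation of a volatile monomer during degassing).
    """

    pre: np.ndarray
    post: np.ndarray
    codes: tuple[str, ...]
    loss_fractions: np.ndarray | None = None

    def __post_init__(self) -> None:
        pre = np.asarray(self.pre, dtype=float)
        post = np.asarray(self.post, dtype=float)
        if pre.shape != post.shape or pre.ndim != 1:
            raise ValueError("pre and post integrals must be equal-length vectors")
        if np.any(pre <= 0):
            raise ValueError("pre-polymerization integrals must be positive")
        if np.any(post < 0):
            raise ValueError("integrals must be non-negative")
        loss = self.loss_fractions
        loss = np.zeros_like(pre) if loss is None else np.asarray(loss, dtype=float)
        if np.any(loss < 0) or np.any(loss >= 1):
            raise ValueError("loss fractions must lie in [0, 1)")
        object.__setattr__(self, "pre", pre)
        object.__setattr__(self, "post", post)
        object.__setattr__(self, "loss_fractions", loss)


def loss_correct(feed0: FeedState, loss_fractions) -> FeedState:
    """Correct a feed for pre-polymerization monomer losses.

    f_i' = f_i (1 - loss_i) / sum_k f_k (1 - loss_k).
    """
    loss = np.asarray(loss_fractions, dtype=float)
    if np.any(loss < 0) or np.any(loss >= 1):
        raise ValueError("loss fractions must lie in [0, 1)")
    f = feed0.fractions * (1.0 - loss)
    return FeedState(fractions=f / f.sum())


def composition_from_conversions(feed: FeedState, conv: ConversionRecord) -> np.ndarray:
    """Composition of polymerized units: F_i = f_i x_i / sum_k f_k x_k."""
    w = feed.fractions * conv.x
    total = w.sum()
    if total <= 0:
        raise ValueError("all conversions are zero; composition undefined")
    return w / total


def conversions_from_integrals(table: IntegralTable, clip_warn: float = 0.01) -> ConversionRecord:
    """Per-monomer conversions from pre/post integrals with loss correction.

    x_i = 1 - post_i / (pre_i (1 - loss_i)); values are clipped to [0, 1]
    with a warning when clipping exceeds ``clip_warn``.
    """
    eff_pre = table.pre * (1.0 - table.loss_fractions)
    x = 1.0 - table.post / eff_pre
    if np.any(x < -clip_warn - 1e-12):
        raise ValueError(
            "post-polymerization integral exceeds the loss-corrected pre "
            f"integral beyond tolerance (min x = {x.min():.4f})")
    if np.any((x < 0) | (x > 1)):
        if np.any(x > 1 + clip_warn):
            warnings.warn(f"conversions clipped by more than {clip_warn:.0%}", stacklevel=2)
        x = np.clip(x, 0.0, 1.0)
    feed = FeedState(fractions=table.pre / table.pre.sum())
    return ConversionRecord(x=x, feed0=feed)


def compare_compositions(a, b, codes_a=None, codes_b=None) -> pd.Series:
    """Per-monomer absolute composition difference in percentage points.

    The returned series carries one entry per monomer plus ``max``.  When
    monomer codes are supplied for both sides they must align.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("composition vectors have different lengths")
    if codes_a is not None and codes_b is not None and tuple(codes_a) != tuple(codes_b):
        raise ValueError("monomer codes do not align between the two compositions")
    delta = np.abs(a - b) * 100.0
    index = list(codes_a) if codes_a is not None else [f"m{i}" for i in range(len(a))]
    out = pd.Series(delta, index=index, name="abs_diff_pct_points")
    out.loc["max"] = delta.max()
    return out


def purification_filter(
    ensemble: Ensemble,
    registry: MonomerRegistry | None = None,
    mwco: float | None = None,
    hlb_window: tuple[float, float] | None = None,
) -> tuple[Ensemble, Ensemble, pd.Series]:
    """Partition an ensemble into retained and removed chains.

    A chain is removed when its molar mass is below ``mwco`` (dialysis
    membrane cutoff) or its chain HLB falls outside ``hlb_window``
    (antisolvent-precipitation proxy; the direction of the window is user
    configuration, not hard-coded).  Returns (retained, removed,
    composition shift of retained vs. input in percentage points).
    """
    if mwco is None and hlb_window is None:
        raise ValueError("give at least one filter criterion (mwco or hlb_window)")
    registry = registry or ensemble.registry
    retained_chains, removed_chains = [], []
    for ch in ensemble.chains:
        remove = False
        if len(ch.sequence) == 0:
            remove = mwco is not None and mwco > 0
        else:
            if mwco is not None and chain_molar_mass(ch.sequence, registry) < mwco:
                remove = True
            if not remove and hlb_window is not None:
                h = chain_hlb(ch.sequence, registry)
                if not hlb_window[0] <= h <= hlb_window[1]:
                    remove = True
        (removed_chains if remove else retained_chains).append(ch)
    if not retained_chains or all(len(c.sequence) == 0 for c in retained_chains):
        raise ValueError("filter removed every chain; over-aggressive criteria")
    retained = replace(ensemble, chains=retained_chains, trace=None)
    removed = replace(ensemble, chains=removed_chains, trace=None)
    shift = compare_compositions(
        ensemble.composition(), retained.composition(),
        codes_a=registry.codes, codes_b=registry.codes)
    return retained, removed, shift


def split_living_dead(ensemble: Ensemble) -> tuple[np.ndarray, np.ndarray, pd.Series]:
    """Compositions of the living and dead subpopulations and their difference.

    Raises when either subpopulation is empty (the difference is undefined).
    Difference is living minus dead, in percentage points (signed).
    """
    living = ensemble.monomer_counts("living")
    dead = ensemble.monomer_counts("dead")
    if living.sum() == 0:
        raise ValueError("no living chains with monomers; composition undefined")
    if dead.sum() == 0:
        raise ValueError("no dead chains with monomers; composition undefined")
    f_living = living / living.sum()
    f_dead = dead / dead.sum()
    diff = pd.Series((f_living - f_dead) * 100.0, index=ensemble.registry.codes,
                     name="living_minus_dead_pct_points")
    return f_living, f_dead, diff


def depolymerization_readout(ensemble: Ensemble) -> np.ndarray:
    """Regenerated-monomer composition from ideal chain-end unzipping.

    Only living chains (those retaining the chain-transfer end group) unzip;
    full depolymerization regenerates exactly their monomer content, so the
    readout equals the living-chain mole-fraction composition.
    """
    counts = ensemble.monomer_counts("living")
    if counts.sum() == 0:
        raise ValueError("no living chains to depolymerize")
    return counts / counts.sum()
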