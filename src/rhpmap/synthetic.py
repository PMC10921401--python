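"""Synthetic inputs for every pipeline stage.

Three generators: excess-monomer kinetics tables (for the reactivity-ratio
estimator), pre/post NMR-style integral tables with volatile-monomer loss
(for the composition tracker), and the four named RHP feed designs (for the
simulator and conformation stages).  Measurement noise is multiplicative
lognormal — signal integrals are positive quantities and their repeatability
error is proportional, mirroring quantitative NMR practice; the default 2%
relative sd is a typical integration repeatability, a stand-in rather than a
measured value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import MonomerRegistry, ReactivityMatrix, build_monomer_registry
from .composition import ConversionRecord, IntegralTable
from .jaacks import KineticsDataset
from .simulate import DeadChainSpec, FeedState, SimulationConfig, simulate_batch

__all__ = ["NoiseSpec", "gen_kinetics", "gen_integral_table", "rhp_design_fixtures"]


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative lognormal measurement noise: relative sd and seed."""

    multiplicative_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplicative_sd < 0:
            raise ValueError("noise sd must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.multiplicative_sd == 0:
            return np.asarray(values, dtype=float)
        return values * np.exp(self.multiplicative_sd * rng.standard_normal(np.shape(values)))


def gen_kinetics(
    ratios: ReactivityMatrix,
    feed: FeedState,
    n_timepoints: int,
    stop_conversion: float,
    noise: NoiseSpec,
    excess_index: int | None = None,
    n_chains: int = 20_000,
    mean_dp_target: float = 50.0,
    registry: MonomerRegistry | None = None,
) -> KineticsDataset:
    """Simulate one excess-monomer kinetics experiment.

    Runs the Monte Carlo simulator with checkpoints at ``n_timepoints``
    equally spaced global conversions up to ``stop_conversion`` and records
    residual monomer fractions, then applies multiplicative noise.  The t=0
    row is exactly 1.  With ``noise.multiplicative_sd == 0`` the table
    reproduces the simulator trace exactly.
    """
    if n_timepoints < 2:
        raise ValueError("need at least 2 timepoints")
    if not 0.0 < stop_conversion <= 1.0:
        raise ValueError("stop_conversion must lie in (0, 1]")
    if excess_index is None:
        excess_index = int(np.argmax(feed.fractions))
    checkpoints = np.linspace(stop_conversion / n_timepoints, stop_conversion, n_timepoints)
    config = SimulationConfig(
        n_chains=n_chains, target_conversion=stop_conversion,
        mean_dp_target=mean_dp_target, seed=noise.seed,
    )
    ens = simulate_batch(feed, ratios, config, registry=registry,
                         checkpoints=checkpoints, trace=True)
    residual = ens.trace.attrs["residual"].drop(columns="global_conversion").to_numpy()
    rng = np.random.default_rng(noise.seed + 1)
    residual = np.clip(noise.apply(residual, rng), 1e-12, 1.0)
    table = np.vstack([np.ones(residual.shape[1]), residual])
    return KineticsDataset(
        residuals=table,
        codes=tuple(ens.registry.codes),
        excess_index=excess_index,
        feed0=ens.feed0,
        time=np.arange(table.shape[0], dtype=float),
    )


def gen_integral_table(
    feed: FeedState,
    conversions: ConversionRecord,
    loss_fractions,
    noise: NoiseSpec,
    codes: tuple[str, ...] | None = None,
    scale: float = 100.0,
) -> IntegralTable:
    """Synthetic pre/post signal-integral table.

    pre_i is proportional to the feed fraction; post_i to
    ``f_i (1 - loss_i)(1 - x_i)`` (what remains unreacted after volatile loss
    and polymerization).  Noise applies to both measurements; with zero noise
    :func:`rhpmap.composition.conversions_from_integrals` inverts this table
    exactly back to the input conversions.
    """
    loss = np.asarray(loss_fractions, dtype=float)
    if np.any(loss < 0) or np.any(loss >= 1):
        raise ValueError("loss fractions must lie in [0, 1)")
    pre = scale * feed.fractions
    post = pre * (1.0 - loss) * (1.0 - conversions.x)
    rng = np.random.default_rng(noise.seed)
    pre_meas = noise.apply(pre, rng)
    post_meas = noise.apply(post, rng)
    if codes is None:
        codes = tuple(f"m{i}" for i in range(len(pre)))
    return IntegralTable(pre=pre_meas, post=post_meas, codes=tuple(codes),
                         loss_fractions=loss)


#: Named feed designs (mole fractions in registry order M, E, O, N) and the
#: per-design target global conversion.  RHP1 follows the published design
#: (MMA 10%, EHMA 20%, OEGMA 45%, NHSMA 25% by difference).  RHP2-4 are
#: synthetic stand-ins, NOT the published compositions: they are constrained
#: only to raise the hydrophobic (MMA+EHMA) fraction monotonically, keep
#: OEGMA at 10% or more, and keep EHMA and NHSMA each below 50%.
_DESIGNS = {
    "RHP1": ((0.10, 0.20, 0.45, 0.25), 0.60),
    "RHP2": ((0.20, 0.25, 0.35, 0.20), 0.70),
    "RHP3": ((0.30, 0.30, 0.25, 0.15), 0.80),
    "RHP4": ((0.40, 0.35, 0.15, 0.10), 0.90),
}


def rhp_design_fixtures(
    registry: MonomerRegistry | None = None,
    n_chains: int = 2000,
    mean_dp_target: float = 57.0,
    seed: int = 0,
    dead_fraction: float = 0.0,
) -> dict[str, tuple[FeedState, SimulationConfig]]:
    """The four named RHP feed designs with ready-to-run simulation configs.

    Mean feed HLB decreases strictly from RHP1 to RHP4 (increasing
    hydrophobicity).  ``mean_dp_target`` defaults to the 57-unit average
    chain length of the reference ensembles; ``n_chains`` defaults to a
    desk-scale 2000 (the reference ensembles used 100,000 — pass that for a
    full-scale run).
    """
    if registry is None:
        registry = build_monomer_registry()
    if len(registry) != len(next(iter(_DESIGNS.values()))[0]):
        raise ValueError("designs are defined for the default quaternary registry")
    out = {}
    for k, (name, (fracs, conv)) in enumerate(_DESIGNS.items()):
        feed = FeedState(fractions=np.array(fracs))
        config = SimulationConfig(
            n_chains=n_chains, target_conversion=conv,
            mean_dp_target=mean_dp_target, seed=seed + k,
            dead_chain=DeadChainSpec(fraction=dead_fraction),
        )
        out[name] = (feed, config)
    return out
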