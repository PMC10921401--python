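"""Single-chain self-consistent field theory in implicit selective solvent.

A coarse-grained chain of N statistical segments (length ``b``) with
per-monomer Flory-type solvent interaction parameters chi_i is solved on a
spherically symmetric radial grid.  Chain statistics follow the modified
diffusion equation dq/ds = (b^2/6) Lap q - w_{m(s)} q along the contour s,
with the field acting at contour position s chosen by the monomer identity
there.  The substitution u = r q turns the spherical Laplacian into a plain
1D second derivative with Dirichlet ends, which a type-I discrete sine
transform diagonalizes exactly; contour stepping is Strang splitting
(half-step field, exact spectral diffusion, half-step field), so the
ideal-chain (w = 0) limit is reproduced to spectral accuracy.

Solvent is implicit: space not occupied by monomer is filled by solvent whose
translational entropy supplies the excluded-volume repulsion.  From the
Flory-Huggins free energy density f = (1-phi_p) ln(1-phi_p) +
sum_i chi_i phi_i (1-phi_p) (per reference volume ``v``), the monomer fields
referenced to zero in pure solvent are

    w_i(r) = -ln(1 - phi_p(r)) - chi_i phi_p(r) - sum_j chi_j phi_j(r),

with phi_i = v * rho_i the monomer volume fractions.  The dilute expansion
w = (1 - 2 chi) phi_p for a homopolymer places the theta point at chi = 1/2;
larger chi collapses the chain into a globule whose interior density
saturates where the osmotic pressure vanishes.  Setting
``excluded_volume=False`` removes the solvent-entropy term (with chi = 0
that is the exactly ideal chain).

Translational symmetry is broken by pinning one monomer at the grid origin
(the self-consistent cycle pins the contour midpoint; the two half-chains
propagate outward from a narrow Gaussian launch).  The radius of gyration is
computed from the exact pair identity Rg^2 = (1/2N^2) sum_{s,s'}
<(r_s - r_s')^2>: after convergence the field is frozen and the second moment
of the density is evaluated for several pin positions along the contour;
Rg^2 = (1/2) * <second moment> averaged over pins.  This estimator is exact
for an ideal chain and unbiased in orderings/scaling for collapsed chains
(the frozen mean-field frame compresses deep-globule values by a bounded
constant factor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.fft import dst

from .chemistry import MonomerRegistry, build_monomer_registry
from .simulate import Ensemble

__all__ = [
    "SCFTParams",
    "SCFTSolution",
    "SingleChainSCFT",
    "chi_from_hlb",
    "solve_single_chain",
    "rg_from_solution",
    "rg_of_profile",
    "ensemble_rg",
    "scaling_fit",
    "ScalingFit",
    "composition_projection",
]

#: Default HLB -> chi affine maps per solvent.  Water quality improves
#: (chi falls) with HLB; pentane is the reverse.  These are calibration
#: parameters of the coarse-grained model, chosen so that chains of about
#: 57 units land in the ~1-3 nm Rg range; they are inputs, not predictions.
CHI_MAPS = {
    "water": {"intercept": 2.6, "slope": -0.2},
    "pentane": {"intercept": -0.5, "slope": 0.15},
}


def chi_from_hlb(registry: MonomerRegistry, solvent: str,
                 map_params: dict | None = None) -> np.ndarray:
    """Per-monomer chi from HLB values via an affine solvent map.

    ``solvent`` is ``"water"``, ``"pentane"`` or ``"custom"`` (the latter
    requires explicit ``map_params`` with ``intercept`` and ``slope``).
    """
    if map_params is None:
        if solvent not in CHI_MAPS:
            raise ValueError(f"unknown solvent {solvent!r} without custom chi map")
        map_params = CHI_MAPS[solvent]
    return map_params["intercept"] + map_params["slope"] * registry.hlb


@dataclass(frozen=True)
class SCFTParams:
    """Model and solver parameters for one single-chain solve.

    ``chi`` is one interaction parameter per registry monomer (dimensionless).
    ``b`` is the statistical segment length in nm and ``v`` the monomer volume
    in nm^3 (defaults to b^3).  ``grid_extent`` of None auto-sizes the radial
    box to 3.2 b sqrt(N/2), comfortably beyond the ideal-chain extent.
    ``excluded_volume`` toggles the solvent-entropy repulsion; turning it off
    together with chi = 0 gives the exactly ideal chain.
    """

    chi: np.ndarray
    b: float = 0.7
    v: float | None = None
    excluded_volume: bool = True
    grid_extent: float | None = None
    n_grid: int = 255
    ds: float = 0.25
    mixing: float = 0.1
    anderson: bool = True
    tol: float = 1e-5
    max_iter: int = 2000
    n_pins: int = 8
    solvent: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "chi", np.asarray(self.chi, dtype=float))
        if self.b <= 0 or self.ds <= 0 or self.tol <= 0:
            raise ValueError("b, ds and tol must be positive")
        if abs(round(1.0 / self.ds) - 1.0 / self.ds) > 1e-12:
            raise ValueError("ds must divide one monomer unit evenly")
        if self.v is None:
            object.__setattr__(self, "v", self.b ** 3)

    @classmethod
    def for_solvent(cls, solvent: str, registry: MonomerRegistry | None = None,
                    **kwargs) -> "SCFTParams":
        registry = registry or build_monomer_registry()
        return cls(chi=chi_from_hlb(registry, solvent), solvent=solvent, **kwargs)


@dataclass
class SCFTSolution:
    """Converged (or diagnosed) single-chain solution.

    ``density`` is the total monomer number density (nm^-3) on the radial
    grid in the midpoint-pinned frame; ``density_per_type`` splits it by
    monomer.  ``rg`` is the pair-identity radius of gyration in nm;
    ``pin_second_moments`` holds the per-pin second moments it averages.
    ``norm_drift`` is the maximum relative drift of the single-chain
    partition value along the contour (a discretization diagnostic; the
    density normalization ∫rho dV = N holds to the same relative level).
    """

    r: np.ndarray
    density: np.ndarray
    density_per_type: dict[int, np.ndarray]
    fields: dict[int, np.ndarray]
    partition: float
    iterations: int
    residual: float
    converged: bool
    norm_drift: float
    n_monomers: int
    rg: float | None
    pin_second_moments: np.ndarray | None
    params: SCFTParams


class _Anderson:
    """Field mixer: simple mixing warm-up, then Anderson acceleration.

    Anderson extrapolation is unreliable far from the fixed point (the
    clamped repulsion branch makes the residual map only piecewise smooth), so
    the first ``warmup`` steps use plain simple mixing.  If the accelerated
    residual blows up relative to the best seen, the history is dropped and
    mixing restarts simply.
    """

    def __init__(self, mixing: float, depth: int = 5, warmup: int = 25):
        self.mixing = mixing
        self.depth = depth
        self.warmup = warmup
        self.count = 0
        self.xs: list[np.ndarray] = []
        self.fs: list[np.ndarray] = []
        self.best = np.inf

    def update(self, x: np.ndarray, f: np.ndarray) -> np.ndarray:
        self.count += 1
        res = float(np.sqrt(np.mean(f * f)))
        if res > 5.0 * self.best and self.xs:
            self.xs.clear()
            self.fs.clear()
            self.count = 0  # re-enter warm-up after a blow-up
        self.best = min(self.best, res)
        if self.count <= self.warmup:
            return x + self.mixing * f
        self.xs.append(x.copy())
        self.fs.append(f.copy())
        if len(self.xs) > self.depth:
            self.xs.pop(0)
            self.fs.pop(0)
        k = len(self.xs)
        if k < 2:
            return x + self.mixing * f
        F = np.stack([fi - self.fs[-1] for fi in self.fs[:-1]], axis=0)
        rhs = -self.fs[-1]
        A = F @ F.T + 1e-12 * np.eye(k - 1)
        try:
            gamma = np.linalg.solve(A, F @ rhs)
        except np.linalg.LinAlgError:
            return x + self.mixing * f
        xbar = self.xs[-1] + sum(g * (self.xs[i] - self.xs[-1]) for i, g in enumerate(gamma))
        fbar = self.fs[-1] + sum(g * (self.fs[i] - self.fs[-1]) for i, g in enumerate(gamma))
        return xbar + self.mixing * fbar


class SingleChainSCFT:
    """Model object: one sequence plus parameters; ``solve()`` returns the
    :class:`SCFTSolution`."""

    def __init__(self, sequence, params: SCFTParams,
                 registry: MonomerRegistry | None = None):
        seq = np.asarray(sequence, dtype=int)
        if seq.ndim != 1 or len(seq) < 2:
            raise ValueError("sequence must be 1-D with length >= 2")
        self.sequence = seq
        self.params = params
        self.registry = registry
        self.N = len(seq)
        if seq.max() >= len(params.chi):
            raise ValueError("sequence indices exceed the chi vector length")
        p = params
        self.R = p.grid_extent if p.grid_extent is not None else 3.2 * p.b * math.sqrt(self.N / 2.0)
        self.n = p.n_grid
        self.h = self.R / (self.n + 1)
        self.r = self.h * np.arange(1, self.n + 1)
        k = np.arange(1, self.n + 1)
        self._diff = np.exp(-(p.b ** 2 / 6.0) * (np.pi * k / self.R) ** 2 * p.ds)
        sub = int(round(1.0 / p.ds))
        self._sub = sub
        self.types_sub = np.repeat(seq, sub)          # monomer type per contour substep
        self.types_present = np.unique(seq)
        # pinned-monomer launch built in mode space: a point source at the
        # origin has sine coefficients proportional to k; pre-diffusing it by
        # half a contour substep keeps it smooth on the grid with no
        # real-space sampling error (residual smear adds b^2 ds/6 to second
        # moments -- negligible against N b^2 and N-independent)
        u = dst(k * np.exp(-(p.b ** 2 / 6.0) * (np.pi * k / self.R) ** 2 * (p.ds / 2.0)),
                type=1, norm="ortho")
        self._u_pin = u / (4.0 * np.pi * self.h * (u @ self.r))   # ∫ q dV = 1
        self._u_free = self.r.copy()                              # q = 1

    # -- propagator machinery ------------------------------------------------

    def _step(self, u: np.ndarray, ehalf: np.ndarray) -> np.ndarray:
        u = u * ehalf
        u = dst(u, type=1, norm="ortho")
        u *= self._diff
        u = dst(u, type=1, norm="ortho")
        return u * ehalf

    def _arm(self, arm_types: np.ndarray, E: dict[int, np.ndarray], acc: np.ndarray):
        """Propagate one arm outward from the pin; accumulate per-type
        contour-density contributions into ``acc`` (types x grid).  Returns
        (partition value Q in sum units, max relative Q drift)."""
        nsub = len(arm_types)
        if nsub == 0:
            return None, 0.0
        UF = np.empty((nsub + 1, self.n))
        UF[0] = self._u_pin
        for i in range(nsub):
            UF[i + 1] = self._step(UF[i], E[arm_types[i]])
        ub = self._u_free.copy()
        prod_prev = UF[nsub] * ub
        Qs = np.empty(nsub + 1)
        Qs[nsub] = prod_prev.sum()
        for i in range(nsub - 1, -1, -1):
            ub = self._step(ub, E[arm_types[i]])
            prod = UF[i] * ub
            Qs[i] = prod.sum()
            acc[arm_types[i]] += 0.5 * (prod + prod_prev)
            prod_prev = prod
        Qbar = float(Qs.mean())
        drift = float(np.max(np.abs(Qs / Qbar - 1.0)))
        return Qbar, drift

    def _density(self, w: dict[int, np.ndarray], s_pin: int):
        """Per-type number density (nm^-3) with the contour point at substep
        ``s_pin`` pinned at the origin, in the field ``w``."""
        p = self.params
        # a global constant shift of the field rescales all propagators by
        # exp(-c s) and cancels in normalized densities; shifting by the field
        # minimum keeps every propagator non-growing (no overflow in deep wells)
        shift = min(0.0, min(float(w[t].min()) for t in self.types_present))
        E = {t: np.exp(-(w[t] - shift) * p.ds / 2.0) for t in self.types_present}
        m_max = int(self.types_present.max()) + 1
        acc = np.zeros((m_max, self.n))
        Qs, drifts = [], []
        for arm_types in (self.types_sub[:s_pin][::-1], self.types_sub[s_pin:]):
            acc_arm = np.zeros_like(acc)
            Q, drift = self._arm(arm_types, E, acc_arm)
            if Q is None:
                continue
            acc += acc_arm / Q
            Qs.append(Q)
            drifts.append(drift)
        dens = acc * (p.ds / (4.0 * np.pi * self.h)) / self.r ** 2
        return dens, float(np.mean(Qs)), float(max(drifts))

    # -- fields --------------------------------------------------------------

    def _field_map(self, dens: np.ndarray) -> dict[int, np.ndarray]:
        p = self.params
        phi = p.v * dens
        phi_p = phi.sum(axis=0)
        chi_phi = np.einsum("t,tr->r", p.chi[: phi.shape[0]], phi)
        if p.excluded_volume:
            # -ln(1-phi) with a C1 linear continuation above phi0: the contact
            # density of a continuous chain diverges at the pinned monomer, so
            # a few cells near the origin legitimately exceed phi = 1 and the
            # repulsion must keep dominating the chi attraction there
            phi0 = 0.95
            rep = np.where(
                phi_p < phi0,
                -np.log1p(-np.minimum(phi_p, phi0)),
                -math.log(1.0 - phi0) + (phi_p - phi0) / (1.0 - phi0),
            )
        else:
            rep = 0.0
        return {t: rep - p.chi[t] * phi_p - chi_phi for t in self.types_present}

    def _init_fields(self) -> dict[int, np.ndarray]:
        p = self.params
        counts = np.bincount(self.sequence, minlength=int(self.types_present.max()) + 1)
        radius = (3.0 * self.N * p.v / (4.0 * np.pi)) ** (1.0 / 3.0)
        blob = 0.8 * np.exp(-self.r ** 2 / (2.0 * radius ** 2))
        dens = np.stack([counts[t] / self.N * blob / p.v for t in range(len(counts))])
        return self._field_map(dens)

    # -- driver --------------------------------------------------------------

    def solve(self) -> SCFTSolution:
        p = self.params
        n_sub = len(self.types_sub)
        pin_mid = n_sub // 2      # exact contour midpoint (mirror-symmetric)
        w = self._init_fields()
        order = list(self.types_present)
        mixer = _Anderson(p.mixing) if p.anderson else None
        converged = False
        res = np.inf
        it = 0
        for it in range(1, p.max_iter + 1):
            dens, Q, drift = self._density(w, pin_mid)
            w_new = self._field_map(dens)
            fvec = np.concatenate([w_new[t] - w[t] for t in order])
            res = float(np.sqrt(np.mean(fvec ** 2)))
            if res < p.tol:
                converged = True
                break
            if mixer is not None:
                xvec = np.concatenate([w[t] for t in order])
                xnext = mixer.update(xvec, fvec)
                w = {t: xnext[i * self.n:(i + 1) * self.n] for i, t in enumerate(order)}
            else:
                w = {t: w[t] + p.mixing * (w_new[t] - w[t]) for t in order}

        dens, Q, drift = self._density(w, pin_mid)
        rho_total = dens.sum(axis=0)

        rg = None
        pin_m2 = None
        if converged:
            # pin set is mirror-symmetric under contour reversal, so reversing
            # a sequence reproduces the same Rg exactly
            half = [int(round((kk + 0.5) * n_sub / p.n_pins))
                    for kk in range(p.n_pins // 2)]
            pins = sorted(set(half) | {n_sub - s for s in half})
            if p.n_pins % 2:
                pins = sorted(set(pins) | {pin_mid})
            m2 = []
            shell = 4.0 * np.pi * self.h * self.r ** 2
            for pin in pins:
                dpin, _, _ = self._density(w, int(pin))
                rho = dpin.sum(axis=0)
                m2.append(float((rho * self.r ** 2) @ shell) / self.N)
            pin_m2 = np.array(m2)
            rg = math.sqrt(0.5 * pin_m2.mean())

        return SCFTSolution(
            r=self.r,
            density=rho_total,
            density_per_type={int(t): dens[t] for t in self.types_present},
            fields={int(t): w[t] for t in self.types_present},
            partition=Q,
            iterations=it,
            residual=res,
            converged=converged,
            norm_drift=drift,
            n_monomers=self.N,
            rg=rg,
            pin_second_moments=pin_m2,
            params=p,
        )


def solve_single_chain(sequence, model: SCFTParams,
                       registry: MonomerRegistry | None = None) -> SCFTSolution:
    """Functional wrapper around :class:`SingleChainSCFT`."""
    return SingleChainSCFT(sequence, model, registry=registry).solve()


def rg_from_solution(solution: SCFTSolution) -> float:
    """Radius of gyration (nm) of a converged solution.

    Computed at solve time from the pair identity
    Rg^2 = (1/2) * mean over pins of the pinned-frame second moment; see the
    module docstring.  Raises on a non-converged solution.
    """
    if not solution.converged:
        raise ValueError("solution did not converge; Rg undefined")
    return float(solution.rg)


def rg_of_profile(r: np.ndarray, density: np.ndarray) -> float:
    """Plain second-moment radius of gyration of a centered density profile.

    Rg^2 = ∫ rho r^2 dV / ∫ rho dV on the radial grid (e.g. a uniform ball of
    radius R gives R sqrt(3/5)).  This is a geometry utility for centered
    profiles, distinct from the chain estimator in :func:`rg_from_solution`.
    """
    r = np.asarray(r, dtype=float)
    density = np.asarray(density, dtype=float)
    w = density * r ** 2
    total = np.trapezoid(w, r)
    if total <= 0:
        return 0.0
    return math.sqrt(np.trapezoid(w * r ** 2, r) / total)


def ensemble_rg(
    ensemble: Ensemble,
    params_by_solvent: dict[str, SCFTParams],
    sample_size: int,
    seed: int,
    min_length: int = 2,
    max_nonconverged: float = 0.05,
) -> pd.DataFrame:
    """Per-chain Rg over a seeded random sample of an ensemble.

    ``params_by_solvent`` maps a solvent label to the :class:`SCFTParams` to
    use (e.g. from :meth:`SCFTParams.for_solvent`).  Chains shorter than
    ``min_length`` are never sampled.  Non-converged chains are kept in the
    table flagged ``converged=False`` (exclude them from summaries); if more
    than ``max_nonconverged`` of the solves fail the run errors out.
    """
    registry = ensemble.registry
    eligible = [i for i, ch in enumerate(ensemble.chains) if len(ch.sequence) >= min_length]
    if sample_size > len(eligible):
        raise ValueError(f"sample_size {sample_size} exceeds eligible pool {len(eligible)}")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(eligible), size=sample_size, replace=False)
    rows = []
    n_fail = 0
    for k in sorted(picked):
        idx = eligible[k]
        seq = ensemble.chains[idx].sequence
        counts = np.bincount(seq, minlength=len(registry))
        fracs = counts / counts.sum()
        for solvent, params in params_by_solvent.items():
            sol = SingleChainSCFT(seq, params, registry=registry).solve()
            if not sol.converged:
                n_fail += 1
            row = {"chain_id": idx, "N": len(seq), "solvent": solvent,
                   "Rg_nm": sol.rg if sol.converged else np.nan,
                   "converged": sol.converged}
            row.update({f"frac_{c}": fracs[i] for i, c in enumerate(registry.codes)})
            rows.append(row)
    table = pd.DataFrame(rows)
    n_total = len(table)
    if n_total and n_fail / n_total > max_nonconverged:
        raise RuntimeError(
            f"{n_fail}/{n_total} SCFT solves failed to converge "
            f"(> {max_nonconverged:.0%} allowed)")
    table.attrs["n_nonconverged"] = n_fail
    return table


@dataclass
class ScalingFit:
    """Result of a log-log Rg ~ N power-law fit."""

    nu: float
    prefactor: float
    conf_int: tuple[float, float]
    nobs: int
    ols_results: object = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": [self.nu, self.prefactor],
            "ci95_low": [self.conf_int[0], np.nan],
            "ci95_high": [self.conf_int[1], np.nan],
        }, index=["nu", "prefactor"])


def scaling_fit(table: pd.DataFrame) -> ScalingFit:
    """Least-squares exponent of Rg ~ prefactor * N^nu from an Rg table.

    Uses converged rows only; requires at least 3 distinct chain lengths.
    """
    data = table[table.get("converged", True) & table["Rg_nm"].notna()]
    if data["N"].nunique() < 3:
        raise ValueError("need at least 3 distinct chain lengths for a scaling fit")
    x = np.log(data["N"].to_numpy(dtype=float))
    y = np.log(data["Rg_nm"].to_numpy(dtype=float))
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return ScalingFit(
        nu=float(fit.params[1]),
        prefactor=float(np.exp(fit.params[0])),
        conf_int=(float(ci[1][0]), float(ci[1][1])),
        nobs=int(fit.nobs),
        ols_results=fit,
    )


def composition_projection(
    table: pd.DataFrame,
    monomer_pair: tuple[str, str],
    n_bins: int = 8,
    fixed_N: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project Rg onto the composition plane of two monomers.

    Returns (per-chain scatter rows, mean Rg per composition bin of the first
    monomer).  ``fixed_N`` restricts to chains of one exact length, removing
    length dispersity from the projection.
    """
    a, b = monomer_pair
    if a == b:
        raise ValueError("monomer pair must be two distinct monomers")
    cols = [f"frac_{a}", f"frac_{b}"]
    for c in cols:
        if c not in table.columns:
            raise KeyError(f"column {c} missing from the Rg table")
    data = table[table.get("converged", True) & table["Rg_nm"].notna()].copy()
    if fixed_N is not None:
        data = data[data["N"] == fixed_N]
    if data.empty:
        raise ValueError("no converged rows to project")
    scatter = data[["chain_id", "N", "solvent", *cols, "Rg_nm"]].reset_index(drop=True)
    edges = np.linspace(0.0, float(data[cols[0]].max()) + 1e-12, n_bins + 1)
    binned = (
        scatter.assign(bin=pd.cut(scatter[cols[0]], edges, include_lowest=True))
        .groupby("bin", observed=True)
        .agg(mean_rg=("Rg_nm", "mean"), n=("Rg_nm", "size"),
             mean_frac=(cols[0], "mean"))
        .reset_index()
    )
    return scatter, binned
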