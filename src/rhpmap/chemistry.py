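"""Monomer registry, reactivity-ratio matrix, and per-chain scalar descriptors.

The default system is the four-methacrylate set used throughout the package:
methyl methacrylate (MMA, code ``M``), 2-ethylhexyl methacrylate (EHMA, ``E``),
oligo(ethylene glycol) methyl ether methacrylate (OEGMA, ``O``, number-average
side-chain mass ~500 Da) and methacrylic acid N-hydroxysuccinimide ester
(NHSMA, ``N``).  Hydrophobicity is carried per monomer as a Griffin-type
hydrophilic-lipophilic balance (HLB) value on the 0-20 scale; lower values are
more hydrophobic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Monomer",
    "MonomerRegistry",
    "ReactivityMatrix",
    "build_monomer_registry",
    "default_reactivity_matrix",
    "validate_reactivity_matrix",
    "chain_hlb",
    "chain_molar_mass",
]

#: Default monomer records: (name, code, molar mass / Da, HLB, hydrophobic?).
#: Literature HLB values for the four methacrylates; OEGMA mass is the
#: number-average mass of the commercial macromonomer.
_DEFAULT_MONOMERS = (
    ("MMA", "M", 100.12, 8.45, True),
    ("EHMA", "E", 198.30, 5.125, True),
    ("OEGMA", "O", 500.0, 11.42, False),
    ("NHSMA", "N", 183.16, 12.775, False),
)


@dataclass(frozen=True)
class Monomer:
    """One monomer species.

    Parameters
    ----------
    name : str
        Full name, e.g. ``"MMA"``.
    code : str
        Single-letter symbol used in sequence strings.
    molar_mass : float
        Residue molar mass in Da; must be positive.
    hlb : float
        Hydrophilic-lipophilic balance on the 0-20 Griffin scale.
    hydrophobic : bool
        Convention flag used when binarizing sequences.
    """

    name: str
    code: str
    molar_mass: float
    hlb: float
    hydrophobic: bool = False

    def __post_init__(self) -> None:
        if len(self.code) != 1:
            raise ValueError(f"monomer code must be a single letter, got {self.code!r}")
        if not self.molar_mass > 0:
            raise ValueError(f"molar mass of {self.name} must be positive, got {self.molar_mass}")
        if not 0.0 <= self.hlb <= 20.0:
            raise ValueError(f"HLB of {self.name} must lie in [0, 20], got {self.hlb}")


@dataclass(frozen=True)
class MonomerRegistry:
    """Ordered collection of monomers with lookup by code or index."""

    monomers: tuple[Monomer, ...]
    _by_code: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        codes = [m.code for m in self.monomers]
        if len(set(codes)) != len(codes):
            dupes = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate monomer codes in registry: {dupes}")
        object.__setattr__(self, "_by_code", {m.code: i for i, m in enumerate(self.monomers)})

    def __len__(self) -> int:
        return len(self.monomers)

    def __iter__(self):
        return iter(self.monomers)

    def __getitem__(self, key):
        if isinstance(key, str):
            return self.monomers[self._by_code[key]]
        return self.monomers[key]

    def index(self, code: str) -> int:
        return self._by_code[code]

    @property
    def codes(self) -> list[str]:
        return [m.code for m in self.monomers]

    @property
    def hlb(self) -> np.ndarray:
        return np.array([m.hlb for m in self.monomers])

    @property
    def molar_mass(self) -> np.ndarray:
        return np.array([m.molar_mass for m in self.monomers])

    @property
    def hydrophobic_indices(self) -> list[int]:
        return [i for i, m in enumerate(self.monomers) if m.hydrophobic]

    def encode(self, letters: str) -> np.ndarray:
        """Convert a sequence string like ``"MEON"`` to monomer indices."""
        try:
            return np.array([self._by_code[c] for c in letters], dtype=np.int8)
        except KeyError as exc:
            raise KeyError(f"unknown monomer code {exc.args[0]!r}") from None

    def decode(self, indices) -> str:
        codes = self.codes
        return "".join(codes[int(i)] for i in indices)

    def to_dict(self) -> list[dict]:
        return [
            {
                "name": m.name,
                "code": m.code,
                "molar_mass": m.molar_mass,
                "hlb": m.hlb,
                "hydrophobic": m.hydrophobic,
            }
            for m in self.monomers
        ]


def build_monomer_registry(config: list[dict] | None = None) -> MonomerRegistry:
    """Build the monomer registry; default is the 4-monomer MMA/EHMA/OEGMA/NHSMA set.

    Parameters
    ----------
    config : list of dict, optional
        Complete monomer records (keys matching :class:`Monomer` fields).
        When omitted the default quaternary registry is returned.
    """
    if config is None:
        records = [Monomer(*row) for row in _DEFAULT_MONOMERS]
    else:
        records = [Monomer(**row) for row in config]
    return MonomerRegistry(tuple(records))


@dataclass(frozen=True)
class ReactivityMatrix:
    """Validated m x m matrix of reactivity ratios r_ij = k_ii / k_ij.

    Row index is the terminal (last-added) monomer of the growing chain,
    column index the candidate next monomer.  The diagonal is identically 1
    by definition.  Use :func:`validate_reactivity_matrix` to construct.
    """

    values: np.ndarray
    codes: tuple[str, ...]

    def __getitem__(self, key):
        i, j = key
        if isinstance(i, str):
            i = self.codes.index(i)
        if isinstance(j, str):
            j = self.codes.index(j)
        return float(self.values[i, j])

    @property
    def m(self) -> int:
        return len(self.codes)


def validate_reactivity_matrix(raw, registry: MonomerRegistry) -> ReactivityMatrix:
    """Validate a raw ratio grid against a registry and freeze it.

    The diagonal must equal 1 (self-propagation relative to itself); values
    within 1e-9 of 1 are forced to 1 with a warning, anything further is an
    error.  All entries must be strictly positive.
    """
    values = np.array(raw, dtype=float)
    m = len(registry)
    if values.shape != (m, m):
        raise ValueError(f"reactivity matrix shape {values.shape} does not match registry size {m}")
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValueError("reactivity ratios must be finite and strictly positive")
    diag = np.diag(values)
    off = np.abs(diag - 1.0)
    if np.any(off > 1e-9):
        raise ValueError(f"diagonal reactivity ratios must be 1 exactly, got {diag}")
    if np.any(off > 0):
        warnings.warn("diagonal entries within 1e-9 of 1 were forced to 1", stacklevel=2)
    np.fill_diagonal(values, 1.0)
    values.setflags(write=False)
    return ReactivityMatrix(values=values, codes=tuple(registry.codes))


def default_reactivity_matrix(registry: MonomerRegistry | None = None) -> ReactivityMatrix:
    """Default quaternary reactivity-ratio matrix (order M, E, O, N).

    The NHSMA-terminal cross ratios toward EHMA (2.0) and MMA (0.7) are the
    experimentally measured values for this monomer set.  The remaining ten
    entries are synthetic stand-ins chosen to respect the measured trends:
    every ratio lies in the measured 0.4-2.0 span, cross-propagation toward
    MMA is favoured (r_*/MMA < 1), and self-propagation beats
    cross-propagation toward bulky OEGMA (r_EHMA/OEGMA, r_NHSMA/OEGMA > 1).
    """
    if registry is None:
        registry = build_monomer_registry()
    raw = [
        # added:  M     E     O     N        terminal:
        [1.0, 1.2, 1.5, 0.8],  # MMA
        [0.6, 1.0, 1.5, 0.9],  # EHMA
        [0.5, 0.8, 1.0, 0.7],  # OEGMA
        [0.7, 2.0, 1.5, 1.0],  # NHSMA
    ]
    return validate_reactivity_matrix(raw, registry)


def _as_index_array(sequence, registry: MonomerRegistry) -> np.ndarray:
    seq = np.asarray(sequence)
    if seq.size == 0:
        raise ValueError("sequence must be non-empty")
    if seq.dtype.kind in "US":
        if seq.ndim == 0:
            return registry.encode(str(seq))
        return registry.encode("".join(seq.tolist()))
    seq = seq.astype(np.int64)
    if seq.min() < 0 or seq.max() >= len(registry):
        raise IndexError("sequence contains indices outside the registry")
    return seq


def chain_hlb(sequence, registry: MonomerRegistry) -> float:
    """Mole-fraction-weighted mean HLB of a chain.

    Weighting by mole fraction (not mass) makes any homopolymer's chain HLB
    equal to its monomer HLB regardless of length, which is the convention
    under which the poly(MMA)=8.45 and poly(OEGMA)=11.42 benchmarks hold.
    """
    seq = _as_index_array(sequence, registry)
    counts = np.bincount(seq, minlength=len(registry))
    return float(counts @ registry.hlb / counts.sum())


def chain_molar_mass(sequence, registry: MonomerRegistry, end_group_mass: float = 0.0) -> float:
    """Chain molar mass in Da: sum of residue masses.

    End groups (CTA and initiator fragments) are excluded by default; pass
    ``end_group_mass`` to add a constant offset.
    """
    seq = _as_index_array(sequence, registry)
    counts = np.bincount(seq, minlength=len(registry))
    return float(counts @ registry.molar_mass) + end_group_mass
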