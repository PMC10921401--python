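"""Text-based serialization: FASTA-like ensembles, CSV tables, YAML configs.

Ensembles are stored in a FASTA dialect over the monomer alphabet: ``;``
lines carry file-level metadata (key=value), each ``>`` header carries the
chain id plus living flag and birth/termination conversions, and sequence
lines use the registry's single-letter codes.  Kinetics and reactivity-ratio
tables are plain CSV with ``#`` metadata/comment lines so they stay
pandas-readable.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chemistry import MonomerRegistry, ReactivityMatrix, build_monomer_registry, \
    validate_reactivity_matrix
from .jaacks import KineticsDataset
from .simulate import Chain, Ensemble, FeedState

__all__ = [
    "write_ensemble_fasta", "read_ensemble_fasta",
    "write_matrix_csv", "read_matrix_csv",
    "write_kinetics_csv", "read_kinetics_csv",
    "write_registry_yaml", "read_registry_yaml",
    "config_hash", "stamped_csv",
]


def config_hash(obj) -> str:
    """Short deterministic hash of any YAML-serializable configuration."""
    canon = yaml.safe_dump(obj, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def stamped_csv(df: pd.DataFrame, path, *, seed: int | None = None,
                cfg_hash: str | None = None, index: bool = False) -> None:
    """Write a CSV with a provenance comment line (config hash + seed)."""
    path = Path(path)
    stamp = "# rhpmap"
    if cfg_hash is not None:
        stamp += f" config_hash={cfg_hash}"
    if seed is not None:
        stamp += f" seed={seed}"
    with open(path, "w") as fh:
        fh.write(stamp + "\n")
        df.to_csv(fh, index=index)


def write_ensemble_fasta(ensemble: Ensemble, path) -> None:
    path = Path(path)
    codes = ensemble.registry.codes
    lut = np.array(list("".join(codes)))
    with open(path, "w") as fh:
        fh.write(f"; alphabet={''.join(codes)}\n")
        fh.write(f"; seed={ensemble.seed}\n")
        fh.write(f"; pool0={','.join(str(int(p)) for p in ensemble.pool0)}\n")
        fh.write(f"; consumed={','.join(str(int(c)) for c in ensemble.consumed)}\n")
        fh.write(f"; exhausted={int(ensemble.exhausted)}\n")
        for i, ch in enumerate(ensemble.chains):
            term = "" if ch.termination_conversion is None else f"{ch.termination_conversion:.6g}"
            fh.write(f">chain_{i} living={int(ch.living)} birth={ch.birth_conversion:.6g} term={term}\n")
            seq = "".join(lut[ch.sequence]) if len(ch.sequence) else ""
            for k in range(0, max(len(seq), 1), 80):
                fh.write(seq[k:k + 80] + "\n")


def read_ensemble_fasta(path, registry: MonomerRegistry | None = None) -> Ensemble:
    path = Path(path)
    meta: dict[str, str] = {}
    chains: list[Chain] = []
    header: dict | None = None
    seq_parts: list[str] = []

    def flush():
        if header is None:
            return
        seq = registry.encode("".join(seq_parts)) if seq_parts and "".join(seq_parts) \
            else np.array([], dtype=np.int8)
        chains.append(Chain(
            sequence=seq,
            living=bool(int(header["living"])),
            birth_conversion=float(header["birth"]),
            termination_conversion=float(header["term"]) if header["term"] else None,
        ))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(";"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif line.startswith(">"):
                flush()
                fields = line[1:].split()
                header = dict(f.split("=", 1) for f in fields[1:])
                seq_parts = []
            else:
                seq_parts.append(line.strip())
    if registry is None:
        registry = build_monomer_registry()
    if "alphabet" in meta and meta["alphabet"] != "".join(registry.codes):
        raise ValueError(f"file alphabet {meta['alphabet']} does not match registry")
    flush()
    pool0 = np.array([int(x) for x in meta["pool0"].split(",")], dtype=np.int64)
    consumed = np.array([int(x) for x in meta["consumed"].split(",")], dtype=np.int64)
    return Ensemble(
        chains=chains,
        feed0=FeedState(fractions=pool0 / pool0.sum()),
        pool0=pool0,
        consumed=consumed,
        registry=registry,
        seed=int(meta.get("seed", 0)),
        trace=None,
        exhausted=bool(int(meta.get("exhausted", 0))),
    )


def write_matrix_csv(matrix: ReactivityMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=list(matrix.codes), columns=list(matrix.codes))
    df.index.name = "terminal"
    df.to_csv(path)


def read_matrix_csv(path, registry: MonomerRegistry | None = None) -> ReactivityMatrix:
    if registry is None:
        registry = build_monomer_registry()
    df = pd.read_csv(path, index_col=0, comment="#")
    if list(df.columns) != registry.codes or list(df.index) != registry.codes:
        raise ValueError("matrix CSV codes do not match the registry order")
    return validate_reactivity_matrix(df.to_numpy(), registry)


def write_kinetics_csv(dataset: KineticsDataset, path) -> None:
    path = Path(path)
    feed = ",".join(f"{f:.12g}" for f in dataset.feed0.fractions)
    with open(path, "w") as fh:
        fh.write(f"# excess={dataset.excess_code}\n")
        fh.write(f"# feed={feed}\n")
        dataset.to_frame().to_csv(fh, index=False)


def read_kinetics_csv(path, registry: MonomerRegistry | None = None) -> KineticsDataset:
    if registry is None:
        registry = build_monomer_registry()
    path = Path(path)
    meta: dict[str, str] = {}
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            else:
                body.append(line)
    df = pd.read_csv(_io.StringIO("".join(body)))
    codes = [c for c in df.columns if c != "time"]
    if codes != registry.codes:
        raise ValueError("kinetics CSV monomer columns do not match the registry")
    feed = FeedState(fractions=np.array([float(x) for x in meta["feed"].split(",")]))
    return KineticsDataset(
        residuals=df[codes].to_numpy(),
        codes=tuple(codes),
        excess_index=registry.index(meta["excess"]),
        feed0=feed,
        time=df["time"].to_numpy(dtype=float),
    )


def write_registry_yaml(registry: MonomerRegistry, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"monomers": registry.to_dict()}, fh, sort_keys=False)


def read_registry_yaml(path) -> MonomerRegistry:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return build_monomer_registry(data["monomers"])


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
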