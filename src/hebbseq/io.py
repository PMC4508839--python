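"""Configuration and file I/O: transition-matrix CSV/JSON, learning-record
CSV with JSON sidecars, and validated run configurations.

Matrices travel as plain square CSV tables (no header, row = source state,
0-based states) or as JSON objects ``{"n_states", "kind", "P"}``.  Every
record written to disk carries a JSON sidecar echoing the configuration
and seed that produced it, so any output is regenerable bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hcp import HCPConfig, HCPLearningRecord
from .markov import (
    TransitionMatrix,
    make_birdsong_like_tm,
    make_gaussian_tm,
    make_mixed_tm,
    solve_sigma_for_entropy,
)
from .stdp import STDPParams

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_record",
    "RunConfig",
    "load_config",
    "save_config",
    "parse_matrix_source",
]


def write_matrix(tm: TransitionMatrix, path: str | Path) -> None:
    """Write a transition matrix as CSV (or JSON if the suffix is .json)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(
            json.dumps(
                {"n_states": tm.n_states, "kind": tm.kind, "P": tm.P.tolist()},
                indent=1,
            )
        )
    else:
        np.savetxt(path, tm.P, delimiter=",", fmt="%.17g")


def read_matrix(path: str | Path, kind: str = "forward") -> TransitionMatrix:
    """Read a transition matrix from CSV (square, no header) or JSON."""
    path = Path(path)
    if path.suffix == ".json":
        obj = json.loads(path.read_text())
        P = np.asarray(obj["P"], dtype=float)
        return TransitionMatrix(P=P, kind=obj.get("kind", kind))
    try:
        P = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed CSV in {path}: {exc}") from exc
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError(f"{path}: expected a square table, got shape {P.shape}")
    return TransitionMatrix(P=P, kind=kind)


def write_record(record: HCPLearningRecord, out_prefix: str | Path) -> None:
    """Write a learning record: trajectory CSV, final-matrix CSV, JSON sidecar.

    Produces ``<prefix>.csv`` with columns (song, error, entropy),
    ``<prefix>_M.csv`` with the final (run-averaged) weight matrix, and
    ``<prefix>.json`` echoing the configuration.
    """
    out_prefix = Path(out_prefix)
    df = pd.DataFrame(
        {
            "song": np.arange(len(record.error_t)),
            "error": record.error_t,
            "entropy": record.entropy_t,
        }
    )
    df.to_csv(out_prefix.with_suffix(".csv"), index=False)
    np.savetxt(str(out_prefix) + "_M.csv", record.M_final, delimiter=",", fmt="%.17g")
    sidecar = dataclasses.asdict(record.config)
    sidecar["final_error"] = record.final_error
    sidecar["final_entropy"] = record.final_entropy
    out_prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def parse_matrix_source(spec: str, seed: int = 0) -> TransitionMatrix:
    """Build or load a transition matrix from a source specifier.

    Accepted forms: a CSV/JSON path, ``gaussian:<sigma>``,
    ``gaussian-entropy:<bits>``, ``mixed:<bits>`` (alternating
    deterministic / entropic rows), ``birdsong:<n>,<bits>``.
    """
    if ":" in spec and not Path(spec).exists():
        tag, _, arg = spec.partition(":")
        if tag == "gaussian":
            return make_gaussian_tm(sigma=float(arg))
        if tag == "gaussian-entropy":
            return make_gaussian_tm(sigma=solve_sigma_for_entropy(float(arg)))
        if tag == "mixed":
            return make_mixed_tm(sigma_high=solve_sigma_for_entropy(float(arg)))
        if tag == "birdsong":
            n, _, bits = arg.partition(",")
            return make_birdsong_like_tm(int(n), float(bits), seed)
        raise ValueError(f"unknown matrix source {spec!r}")
    return read_matrix(spec)


@dataclass(frozen=True)
class RunConfig:
    """A validated experiment configuration (JSON/YAML round-trippable)."""

    experiment: str
    matrix: str
    out_dir: str = "."
    seed: int = 0
    verbosity: str = "info"
    hcp: dict = field(default_factory=dict)
    stdp: dict = field(default_factory=dict)

    _EXPERIMENTS = ("train-hcp", "train-binary", "stdp", "grid", "sweep-entropy", "sweep-snr")

    def __post_init__(self) -> None:
        if self.experiment not in self._EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; expected one of {self._EXPERIMENTS}"
            )
        if not self.matrix:
            raise ValueError("missing matrix source (field 'matrix')")
        # constructing the payload dataclasses performs the range checks
        self.hcp_config()
        self.stdp_params()

    def hcp_config(self) -> HCPConfig:
        known = {f.name for f in dataclasses.fields(HCPConfig)}
        unknown = set(self.hcp) - known
        if unknown:
            raise ValueError(f"unknown hcp keys: {sorted(unknown)}")
        return HCPConfig(seed=self.seed, **{k: v for k, v in self.hcp.items() if k != "seed"})

    def stdp_params(self) -> STDPParams:
        known = {f.name for f in dataclasses.fields(STDPParams)}
        unknown = set(self.stdp) - known
        if unknown:
            raise ValueError(f"unknown stdp keys: {sorted(unknown)}")
        return STDPParams(**self.stdp)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    payload = dataclasses.asdict(cfg)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=1))


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    missing = {"experiment", "matrix"} - set(payload)
    if missing:
        raise ValueError(f"missing required config fields: {sorted(missing)}")
    return RunConfig(**payload)
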