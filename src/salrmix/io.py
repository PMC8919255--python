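"""File plumbing: extended-XYZ snapshots and YAML run configurations.

Snapshots use the extended-XYZ dialect: the comment line carries a cubic
``Lattice`` plus free ``key=value`` metadata (cycle index, energy), and the
species column holds ``HSTY`` / ``HS``.  Round trips are lossless to full
float precision (positions are written with 17 significant digits).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .mc import Configuration, MoveSchedule, SystemSpec
from .model import PotentialParams

__all__ = ["read_xyz", "write_xyz", "RunConfig", "load_run_config",
           "save_run_config"]

_SPECIES_NAME = {1: "HSTY", 2: "HS"}
_SPECIES_CODE = {"HSTY": 1, "HS": 2}


class XYZParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def write_xyz(path, configs, metadata: dict | None = None) -> None:
    """Write one Configuration or a sequence of them as extended XYZ frames."""
    if isinstance(configs, Configuration):
        configs = [configs]
    meta = metadata or {}
    with open(path, "w") as fh:
        for idx, cfg in enumerate(configs):
            L = cfg.L
            lattice = f'"{L:.17g} 0 0 0 {L:.17g} 0 0 0 {L:.17g}"'
            extras = " ".join(f"{k}={v}" for k, v in meta.items())
            fh.write(f"{len(cfg.positions)}\n")
            fh.write(f"Lattice={lattice} "
                     f"Properties=species:S:1:pos:R:3 frame={idx}"
                     f"{' ' + extras if extras else ''}\n")
            for s, (x, y, z) in zip(cfg.species, cfg.positions):
                fh.write(f"{_SPECIES_NAME[int(s)]} {x:.17g} {y:.17g} {z:.17g}\n")


def read_xyz(path, validate: bool = True) -> list[Configuration]:
    """Read all extended-XYZ frames; warns (not errors) on overlapping frames."""
    configs = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise XYZParseError("expected particle count", i + 1)
        if i + 1 >= len(lines):
            raise XYZParseError("missing comment line", i + 2)
        comment = lines[i + 1]
        L = _parse_lattice(comment, i + 2)
        rows = lines[i + 2: i + 2 + n]
        if len(rows) < n:
            raise XYZParseError(f"expected {n} particle rows, found {len(rows)}",
                                i + 2 + len(rows))
        species = np.empty(n, dtype=np.int8)
        pos = np.empty((n, 3))
        for j, row in enumerate(rows):
            parts = row.split()
            if len(parts) < 4:
                raise XYZParseError("expected 'species x y z'", i + 3 + j)
            if parts[0] not in _SPECIES_CODE:
                raise XYZParseError(f"unknown species {parts[0]!r}", i + 3 + j)
            species[j] = _SPECIES_CODE[parts[0]]
            try:
                pos[j] = [float(v) for v in parts[1:4]]
            except ValueError:
                raise XYZParseError("malformed coordinate", i + 3 + j)
        cfg = Configuration(pos, species, L)
        if validate and cfg.has_overlap():
            warnings.warn(f"frame {len(configs)} contains hard-core overlaps")
        configs.append(cfg)
        i += 2 + n
    return configs


def _parse_lattice(comment: str, lineno: int) -> float:
    key = "Lattice="
    start = comment.find(key)
    if start < 0:
        raise XYZParseError("missing Lattice", lineno)
    rest = comment[start + len(key):]
    if rest.startswith('"'):
        end = rest.find('"', 1)
        if end < 0:
            raise XYZParseError("unterminated Lattice", lineno)
        vals = rest[1:end].split()
    else:
        vals = rest.split()[:9]
    if len(vals) != 9:
        raise XYZParseError("Lattice must have 9 components", lineno)
    m = np.array([float(v) for v in vals]).reshape(3, 3)
    if not np.allclose(m, np.diag(np.diag(m))) or len(set(np.diag(m))) != 1:
        raise XYZParseError("only cubic boxes are supported", lineno)
    return float(m[0, 0])


@dataclass
class RunConfig:
    """Complete, serialisable description of one simulation run."""

    schema_version: int = 1
    spec: SystemSpec = field(default_factory=lambda: SystemSpec(250, 250, 0.05, 0.25))
    params: PotentialParams = field(default_factory=PotentialParams)
    schedule: MoveSchedule = field(default_factory=MoveSchedule)
    n_equil_cycles: int = 5_000
    n_prod_cycles: int = 20_000
    snapshot_stride: int | None = None
    initial: str = "random"
    output_dir: str = "results"


def save_run_config(path, cfg: RunConfig) -> None:
    d = asdict(cfg)
    d["params"].pop("r0", None)  # derived, recomputed on load
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if d.get("schema_version", 1) != 1:
        raise ValueError("unsupported config schema version")
    d.get("params", {}).pop("r0", None)
    return RunConfig(
        schema_version=d.get("schema_version", 1),
        spec=SystemSpec(**d["spec"]),
        params=PotentialParams(**d.get("params", {})),
        schedule=MoveSchedule(**d.get("schedule", {})),
        n_equil_cycles=d.get("n_equil_cycles", 5_000),
        n_prod_cycles=d.get("n_prod_cycles", 20_000),
        snapshot_stride=d.get("snapshot_stride"),
        initial=d.get("initial", "random"),
        output_dir=d.get("output_dir", "results"),
    )
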