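"""Structure and configuration I/O plus reproducibility plumbing.

Structures are read and written as (multi-frame) XYZ / extended-XYZ text;
base-pair annotations (pivot indices, hydrogen-bond specifications, the
equilibrium reference frame) travel in a JSON sidecar ``<file>.json`` so
the coordinate files stay plain XYZ that any structure viewer can open.

Run configurations are strict YAML/JSON: unknown keys are errors, which
prevents silently mis-calibrated runs.  Every pipeline run writes a
manifest (configuration hash, base seed, package and library versions)
from which the outputs can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .duplex import DuplexModelParams
from .errors import ConfigError, ParseError
from .geometry import HBondSpec, MolecularFrame
from .surface import SurfaceParams

__all__ = [
    "read_structures",
    "write_structures",
    "RunConfig",
    "load_config",
    "save_config",
    "make_manifest",
]


# ---------------------------------------------------------------------------
# XYZ / extended-XYZ structures with JSON sidecar annotations
# ---------------------------------------------------------------------------

def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_structures(frames, path) -> None:
    """Write frames as multi-frame XYZ plus a JSON annotation sidecar."""
    path = Path(path)
    frames = list(frames)
    lines = []
    for frame in frames:
        lines.append(str(frame.n_sites))
        lines.append(frame.comment.replace("\n", " "))
        for el, (x, y, z) in zip(frame.elements, frame.coords):
            lines.append(f"{el} {x:.10f} {y:.10f} {z:.10f}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))

    side = []
    for frame in frames:
        entry = {
            "labels": list(frame.labels),
            "pivot_indices": list(frame.pivot_indices),
            "hbonds": [
                {"donor": hb.donor, "hydrogen": hb.hydrogen,
                 "acceptor": hb.acceptor, "label": hb.label,
                 "eq_length": hb.eq_length}
                for hb in frame.hbonds
            ],
        }
        if frame.equilibrium_reference is not None:
            entry["equilibrium_reference"] = frame.equilibrium_reference.tolist()
        side.append(entry)
    _sidecar_path(path).write_text(json.dumps(side, indent=1))


def read_structures(path) -> list[MolecularFrame]:
    """Read multi-frame XYZ (annotations from the sidecar when present)."""
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    side = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        side = json.loads(sidecar.read_text())

    frames = []
    i = 0
    while i < len(lines):
        if lines[i].strip() == "" and all(l.strip() == "" for l in lines[i:]):
            break
        try:
            natoms = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise ParseError(f"expected an atom count, got {lines[i]!r}", line=i + 1)
        if i + 1 + natoms >= len(lines) + 1 and natoms > 0:
            raise ParseError("truncated frame: file ends before the declared "
                             f"atom count {natoms}", line=i + 1)
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        elements, coords = [], []
        for k in range(natoms):
            ln = i + 2 + k
            if ln >= len(lines):
                raise ParseError("truncated frame: file ends before the declared "
                                 f"atom count {natoms}", line=len(lines))
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"malformed coordinate record {lines[ln]!r}",
                                 line=ln + 1)
            elements.append(parts[0])
            try:
                coords.append([float(p) for p in parts[1:4]])
            except ValueError:
                raise ParseError(f"non-numeric coordinate in {lines[ln]!r}",
                                 line=ln + 1)
        meta = side[len(frames)] if side and len(frames) < len(side) else None
        if meta is not None:
            frame = MolecularFrame(
                labels=meta["labels"],
                elements=elements,
                coords=np.array(coords),
                pivot_indices=tuple(meta["pivot_indices"]),
                hbonds=[HBondSpec(**hb) for hb in meta["hbonds"]],
                equilibrium_reference=(np.array(meta["equilibrium_reference"])
                                       if "equilibrium_reference" in meta else None),
                comment=comment,
            )
        else:
            # bare XYZ: no annotations; use placeholder pivots (first/last atom)
            frame = MolecularFrame(
                labels=[f"X{k}" for k in range(natoms)],
                elements=elements,
                coords=np.array(coords),
                pivot_indices=(0, max(1, natoms - 1)),
                hbonds=[],
                comment=comment,
            )
        frames.append(frame)
        i += 2 + natoms
    return frames


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SCAN_KEYS = {"increment_spacing", "n_increments", "ts_scan_limit",
              "force_tolerance", "max_steps"}
_MEP_KEYS = {"n_images", "force_tolerance", "uncertainty_tolerance",
             "max_true_evaluations", "seed", "climbing_image",
             "spring_constant", "length_scale", "refit_every"}
_STEER_KEYS = {"force", "target_pair", "equilibration_ps", "production_ps",
               "n_replicas", "seed", "sampling_ps"}


@dataclass
class RunConfig:
    """Validated top-level configuration of a pipeline run."""

    preset: str = "AT"
    surface: dict = field(default_factory=dict)
    duplex: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    mep: dict = field(default_factory=dict)
    steering: dict = field(default_factory=dict)
    output_dir: str = "tautopath-out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.preset not in ("AT", "GC"):
            raise ConfigError(f"preset must be 'AT' or 'GC', got {self.preset!r}")
        for name, block, allowed in (
            ("scan", self.scan, _SCAN_KEYS),
            ("mep", self.mep, _MEP_KEYS),
            ("steering", self.steering, _STEER_KEYS),
        ):
            unknown = set(block) - allowed
            if unknown:
                raise ConfigError(f"unknown key(s) in '{name}' block: {sorted(unknown)}")
        # surface/duplex blocks are validated by their owning dataclasses
        self.surface_params()
        self.duplex_params()

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "preset": self.preset, "surface": dict(self.surface),
            "duplex": dict(self.duplex), "scan": dict(self.scan),
            "mep": dict(self.mep), "steering": dict(self.steering),
            "output_dir": self.output_dir, "seed": self.seed,
            "log_level": self.log_level,
        }

    def _preset_block(self, block: str) -> dict:
        text = resources.files("tautopath.data").joinpath(
            f"{self.preset.lower()}.yaml").read_text()
        return yaml.safe_load(text)[block]

    def surface_params(self) -> SurfaceParams:
        base = self._preset_block("surface")
        base.update(self.surface)
        try:
            return SurfaceParams.from_dict(base)
        except Exception as exc:
            raise ConfigError(f"invalid surface block: {exc}") from exc

    def duplex_params(self) -> DuplexModelParams:
        base = self._preset_block("duplex")
        base.update(self.duplex)
        try:
            return DuplexModelParams.from_dict(base)
        except Exception as exc:
            raise ConfigError(f"invalid duplex block: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration (strict: unknown keys error)."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"cannot parse configuration {path}: {exc}")
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(data)}")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def make_manifest(config: RunConfig, command: str) -> dict:
    """Reproducibility manifest: config hash, seed and version pins."""
    import scipy
    import sklearn

    from . import __version__

    # hash only the scientific configuration: where the outputs land and
    # how chattily they are produced must not change their content
    hashed = {k: v for k, v in config.to_dict().items()
              if k not in ("output_dir", "log_level")}
    blob = json.dumps(hashed, sort_keys=True).encode()
    return {
        "command": command,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "versions": {
            "tautopath": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
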