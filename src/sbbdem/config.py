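"""Run configuration: one document holding every tunable default.

The config round-trips losslessly through dict/JSON and can be loaded from
a TOML file; unknown keys are rejected so typos fail loudly instead of
silently falling back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    # cohort simulation
    n_phantoms: int = 8
    density_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    phantom_size: int = 128
    n_masses: int = 1
    mass_radius: int = 10
    mass_contrast: float = 0.12
    noise_sigma: float = 0.02
    # enhancement
    grid_lo: float = 1.0
    grid_hi: float = 1.9
    grid_step: float = 0.1
    scorer: str = "naturalness-fallback"
    # texture
    glcm_levels: int = 8
    glcm_offset: tuple[int, int] = (0, 1)
    # evaluation
    iou_min: float = 0.5
    cs_min: float = 0.5
    # classification
    knn_k: int = 10
    cv_folds: int = 5
    chi2_min: float = 1.0
    feature_select: str = "none"  # none | chi2 | pca
    pca_components: int = 3
    # split
    train_fraction: float = 0.8
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["density_mix"] = list(self.density_mix)
        d["glcm_offset"] = list(self.glcm_offset)
        return d

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        doc = dict(doc)
        if "density_mix" in doc:
            doc["density_mix"] = tuple(doc["density_mix"])
        if "glcm_offset" in doc:
            doc["glcm_offset"] = tuple(doc["glcm_offset"])
        return cls(**doc)

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a config from .toml or .json."""
    path = Path(path)
    if path.suffix == ".toml":
        doc = tomllib.loads(path.read_text())
    elif path.suffix == ".json":
        doc = json.loads(path.read_text())
    else:
        raise ValueError(f"unsupported config format: {path.suffix}")
    return RunConfig.from_dict(doc)
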