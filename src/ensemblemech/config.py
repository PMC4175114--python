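"""TOML run configuration with the pipeline's standard defaults.

The default selection schemes are the three analysis regions of the
LSD1/CoREST study system — the whole complex, the truncated amine-oxidase
(AO) domain (residues 171–427 and 517–836), and the H3-histone binding site
(residues 353–363, 370–391, 529–564) — with the Tower domain (428–516) as
the rigid superposition anchor for the whole-complex scheme.  Shells run
1–30 Å in 1 Å steps with the 30 Å shell as KS reference; clustering sweeps
2–5 Å thresholds.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, asdict

from .report import VerdictThresholds

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config", "DEFAULT_SELECTIONS"]


class ConfigError(ValueError):
    """Invalid run configuration."""


DEFAULT_SELECTIONS: dict[str, dict] = {
    "whole": {"residues": "1-99999", "atom_class": "calpha"},
    "ao_domain": {"residues": "171-427,517-836", "atom_class": "calpha"},
    "binding_site": {"residues": "353-363,370-391,529-564", "atom_class": "calpha"},
    "tower_fit": {"residues": "428-516", "atom_class": "calpha"},
}


@dataclass
class PCAConfig:
    k_pairs: int = 3            # PCs used for nearest-pair matching
    k_overlap: int = 2          # PCs used for grid-cell overlap
    bin_fraction: float = 0.05  # overlap cell edge as fraction of PC1 range
    pair_cutoff: float = 50.0   # PC-space distance cutoff for matched pairs


@dataclass
class ClusteringConfig:
    thresholds: list[float] = field(default_factory=lambda: [2.0, 3.0, 4.0, 5.0])
    stride: int = 1
    max_frames: int = 2000      # subsample cap for the distance matrix


@dataclass
class KSConfig:
    radius_start: float = 1.0
    radius_stop: float = 30.0
    radius_step: float = 1.0
    reference_radius: float = 30.0
    alpha: float = 0.05
    method: str = "auto"

    def radii(self) -> list[float]:
        out = []
        r = self.radius_start
        while r <= self.radius_stop + 1e-9:
            out.append(round(r, 6))
            r += self.radius_step
        return out


@dataclass
class RunConfig:
    unbound: str = ""
    bound: str = ""
    reference: str = ""
    selections: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SELECTIONS.items()})
    pca: PCAConfig = field(default_factory=PCAConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    ks: KSConfig = field(default_factory=KSConfig)
    verdict: VerdictThresholds = field(default_factory=VerdictThresholds)
    seed: int = 0
    discard_first_frames: int = 0


_SECTION_TYPES = {
    "pca": PCAConfig,
    "clustering": ClusteringConfig,
    "ks": KSConfig,
    "verdict": VerdictThresholds,
}
_TOP_KEYS = {"unbound", "bound", "reference", "seed", "discard_first_frames", "selections"}


def _build_section(cls, data: dict, section: str):
    obj = cls()
    valid = set(asdict(obj))
    for key, value in data.items():
        if key not in valid:
            raise ConfigError(f"unknown key [{section}].{key}")
        expected = type(getattr(obj, key))
        if expected in (float, int) and isinstance(value, (int, float)) and not isinstance(value, bool):
            value = expected(value)
        elif not isinstance(value, expected):
            raise ConfigError(
                f"[{section}].{key}: expected {expected.__name__}, got {type(value).__name__}"
            )
        setattr(obj, key, value)
    return obj


def _validate(cfg: RunConfig) -> RunConfig:
    if not 0 < cfg.ks.alpha < 1:
        raise ConfigError(f"[ks].alpha must lie in (0, 1), got {cfg.ks.alpha}")
    if cfg.ks.radius_step <= 0:
        raise ConfigError("[ks].radius_step must be positive")
    ref = cfg.ks.reference_radius
    if not any(abs(ref - r) < 1e-9 for r in cfg.ks.radii()):
        raise ConfigError(f"[ks].reference_radius {ref} is not on the radius grid")
    if any(t <= 0 for t in cfg.clustering.thresholds):
        raise ConfigError("[clustering].thresholds must be positive")
    cfg.clustering.thresholds = [float(t) for t in cfg.clustering.thresholds]
    if cfg.pca.pair_cutoff <= 0:
        raise ConfigError("[pca].pair_cutoff must be positive")
    if cfg.discard_first_frames < 0:
        raise ConfigError("discard_first_frames must be >= 0")
    for name, sel in cfg.selections.items():
        extra = set(sel) - {"residues", "atom_class"}
        if extra:
            raise ConfigError(f"unknown key [selections.{name}].{extra.pop()}")
        if "residues" not in sel:
            raise ConfigError(f"[selections.{name}] needs a 'residues' string")
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration (defaults filled in)."""
    with open(path, "rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(data)


def config_from_dict(data: dict) -> RunConfig:
    cfg = RunConfig()
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"[{key}] must be a table")
            setattr(cfg, key, _build_section(_SECTION_TYPES[key], value, key))
        elif key == "selections":
            if not isinstance(value, dict):
                raise ConfigError("[selections] must be a table of tables")
            merged = {k: dict(v) for k, v in DEFAULT_SELECTIONS.items()}
            merged.update({k: dict(v) for k, v in value.items()})
            cfg.selections = merged
        elif key in _TOP_KEYS:
            current = getattr(cfg, key)
            if type(value) is not type(current) and not (
                isinstance(value, int) and isinstance(current, int)
            ):
                raise ConfigError(
                    f"{key}: expected {type(current).__name__}, got {type(value).__name__}"
                )
            setattr(cfg, key, value)
        else:
            raise ConfigError(f"unknown top-level key {key!r}")
    return _validate(cfg)


def dump_config(cfg: RunConfig) -> dict:
    """Normalized dict form of a config (round-trips through load)."""
    out = asdict(cfg)
    return out
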