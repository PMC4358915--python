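"""Plain-text key-value configuration for simulations.

The format is intentionally minimal: one ``key = value`` pair per line,
``#`` comments, dotted section prefixes (``particle.charge = -4``).
Defaults are the reference model's values throughout; a config file
only needs the keys it overrides.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

from .integrator import IntegratorParams, SimulationProtocol
from .model_core import ParticleSpec, SystemGeometry

__all__ = ["parse_config", "load_config", "build_objects"]


def parse_config(text: str) -> dict[str, str]:
    """Parse ``key = value`` lines into a flat dict of strings."""
    out: dict[str, str] = {}
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {ln}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if not key:
            raise ValueError(f"line {ln}: empty key")
        out[key] = value
    return out


def load_config(path: str | Path) -> dict[str, str]:
    return parse_config(Path(path).read_text())


def _build(cls, cfg: dict[str, str], prefix: str):
    kwargs = {}
    for f in fields(cls):
        key = f"{prefix}.{f.name}"
        if key in cfg:
            raw = cfg[key]
            kwargs[f.name] = int(raw) if f.type == "int" else float(raw)
    return cls(**kwargs)


def build_objects(cfg: dict[str, str]) -> dict:
    """Instantiate model objects from a parsed config.

    Recognised prefixes: ``particle.``, ``geometry.``, ``integrator.``,
    ``protocol.``.  Unknown keys are returned untouched under "extra".
    """
    known = {"particle", "geometry", "integrator", "protocol"}
    extra = {
        k: v for k, v in cfg.items() if k.split(".", 1)[0] not in known
    }
    return {
        "particle": _build(ParticleSpec, cfg, "particle"),
        "geometry": _build(SystemGeometry, cfg, "geometry"),
        "integrator": _build(IntegratorParams, cfg, "integrator"),
        "protocol": _build(SimulationProtocol, cfg, "protocol"),
        "extra": extra,
    }
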