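"""Flat key–value configuration files.

The run configuration mirrors :class:`nmmdfit.dynamics.SimulationParams`
plus the refinement settings, one ``key = value`` per line, ``#``
comments allowed.  Two named presets are shipped: ``mdspace``
(single-particle images: 20,000 steps, dt 0.002 ps, NM mass 5, force
constant 3000) and ``mdtomo`` (subtomograms: 50,000 steps, NM mass 10,
force constant 1000).
"""

from __future__ import annotations

from pathlib import Path

from .dynamics import SimulationParams, mdspace_preset, mdtomo_preset
from .fitting_pipeline import RefinementConfig

__all__ = ["parse_value", "read_config", "write_config", "load_params",
           "PRESETS"]

PRESETS = {"mdspace": mdspace_preset, "mdtomo": mdtomo_preset}

_SIM_KEYS = {
    "sim_type": str, "dt": float, "n_steps": int, "temperature": float,
    "friction": float, "nm_dt": float, "nm_mass": float, "seed": int,
    "k_bias": float, "sigma_gauss": float, "report_interval": int,
}


def parse_value(text: str):
    """Best-effort scalar coercion: int, float, bool, else string."""
    t = text.strip()
    for caster in (int, float):
        try:
            return caster(t)
        except ValueError:
            pass
    if t.lower() in ("true", "false"):
        return t.lower() == "true"
    return t


def read_config(path: str | Path) -> dict:
    """Read a flat ``key = value`` file into a dict."""
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            out[key.strip()] = parse_value(value)
    return out


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, value in cfg.items():
            if isinstance(value, (list, tuple)):
                value = ",".join(str(v) for v in value)
            fh.write(f"{key} = {value}\n")


def load_params(
    preset: str = "mdspace", config_path: str | Path | None = None, **overrides
) -> tuple[SimulationParams, RefinementConfig]:
    """Simulation + refinement parameters from a preset and optional file."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from "
                         f"{sorted(PRESETS)}")
    cfg: dict = {}
    if config_path is not None:
        cfg.update(read_config(config_path))
    cfg.update(overrides)

    refine = RefinementConfig(
        n_iterations=int(cfg.pop("n_iterations", 1)),
        n_pcs=int(cfg.pop("n_pcs", 3)),
    )
    if "mode_indices" in cfg:
        raw = cfg.pop("mode_indices")
        if isinstance(raw, str):
            raw = [int(tok) for tok in raw.replace(",", " ").split()]
        else:
            raw = [int(raw)]
        cfg["mode_indices"] = tuple(raw)
    sim_kwargs = {}
    for key, value in cfg.items():
        if key == "mode_indices":
            sim_kwargs[key] = value
        elif key in _SIM_KEYS:
            sim_kwargs[key] = _SIM_KEYS[key](value)
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    return PRESETS[preset](**sim_kwargs), refine
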