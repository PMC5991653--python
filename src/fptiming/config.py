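"""Structured-text (INI) configuration for all subcommands.

Sections and keys (all rates in reciprocal units of t_star's time unit):

    [regulator]   k, mu, n0, n0_poisson
    [regulation]  sign, alpha (number or "auto" to calibrate), K, H ("inf" ok)
    [system]      x_star, t_star
    [burst]       b                      (optional section)
    [division]    t_d_mean, t_d_sd, volume_factor   (optional section)
"""

from __future__ import annotations

import configparser
import json
import math
from dataclasses import dataclass
from typing import Dict, Optional

from . import __version__
from .errors import ConfigurationError
from .model import BurstSpec, DivisionSpec, RegulationSpec, RegulatorSpec, SystemSpec

__all__ = ["ConfigBundle", "load_config", "provenance_lines"]


@dataclass(frozen=True)
class ConfigBundle:
    system: SystemSpec
    burst: Optional[BurstSpec]
    division: Optional[DivisionSpec]
    alpha_auto: bool
    raw: Dict

    def describe(self) -> Dict:
        return self.raw


def _parse_h(text: str) -> float:
    t = text.strip().lower()
    if t in ("inf", "infinite", "infinity", "step"):
        return math.inf
    return float(t)


def load_config(path) -> ConfigBundle:
    """Read an INI config into model objects, with field-path error messages."""
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise ConfigurationError(f"config file not found or empty: {path}")

    def need(section: str, key: str) -> str:
        if not parser.has_option(section, key):
            raise ConfigurationError(f"missing config field [{section}] {key}")
        return parser.get(section, key)

    def opt(section: str, key: str, default: str) -> str:
        return parser.get(section, key, fallback=default)

    try:
        regulator = RegulatorSpec(
            k=float(opt("regulator", "k", "0")),
            mu=float(opt("regulator", "mu", "0")),
            n0=int(opt("regulator", "n0", "0")),
            n0_poisson=parser.getboolean("regulator", "n0_poisson", fallback=False),
        )
    except ValueError as exc:
        raise ConfigurationError(f"[regulator]: {exc}") from exc

    alpha_text = opt("regulation", "alpha", "auto").strip().lower()
    alpha_auto = alpha_text == "auto"
    try:
        regulation = RegulationSpec(
            sign=need("regulation", "sign").strip().lower(),
            alpha=0.0 if alpha_auto else float(alpha_text),
            K=float(need("regulation", "K")),
            H=_parse_h(opt("regulation", "H", "1")),
        )
    except ValueError as exc:
        raise ConfigurationError(f"[regulation]: {exc}") from exc

    try:
        system = SystemSpec(
            regulator=regulator,
            regulation=regulation,
            x_star=int(need("system", "x_star")),
            t_star=float(need("system", "t_star")),
        )
    except ValueError as exc:
        raise ConfigurationError(f"[system]: {exc}") from exc

    burst = None
    if parser.has_section("burst"):
        burst = BurstSpec(b=float(need("burst", "b")))
    division = None
    if parser.has_section("division"):
        division = DivisionSpec(
            t_d_mean=float(need("division", "t_d_mean")),
            t_d_sd=float(opt("division", "t_d_sd", "0")),
            volume_factor=float(opt("division", "volume_factor", "0.5")),
        )

    raw = {s: dict(parser.items(s)) for s in parser.sections()}
    return ConfigBundle(
        system=system, burst=burst, division=division, alpha_auto=alpha_auto, raw=raw
    )


def provenance_lines(bundle_raw: Dict, seed: Optional[int] = None, **extra) -> list:
    """Comment lines recording the resolved configuration, package version
    and seed, written at the top of every result file."""
    payload = {"fptiming_version": __version__, "config": bundle_raw}
    if seed is not None:
        payload["seed"] = seed
    payload.update(extra)
    return ["# provenance: " + json.dumps(payload, sort_keys=True, default=str)]
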