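"""Plain-text model configuration.

A model file is INI-style with one section per component::

    [genotype]
    variant = two_point        ; gaussian | dirac | two_point |
    sigma_a = 2                ;  double_gaussian | mixture | stable | uniform

    [environment]
    variant = gaussian
    sd = 3

    [selection]
    variant = gaussian         ; gaussian | truncation
    mu = 1
    sigma_w = 1

    [simulate]                 ; optional
    n_parents = 200000
    seed = 1

Unknown keys are hard errors: a silently ignored typo would corrupt the
science downstream.
"""

from __future__ import annotations

import configparser
import math
from typing import Mapping

from .distributions import (
    Dirac,
    Gaussian,
    GaussianMixture,
    GaussianW,
    SelectionFunction,
    SymmetricStable,
    TruncationW,
    TwoPoint,
    Uniform,
    UnivariateLaw,
)
from .simulator import SimulationConfig

__all__ = ["ConfigError", "parse_law", "parse_selection", "load_model"]


class ConfigError(ValueError):
    """A malformed model configuration."""


def _take(section: Mapping[str, str], name: str, allowed: set[str], required: set[str]):
    keys = set(section)
    unknown = keys - allowed - {"variant"}
    if unknown:
        raise ConfigError(f"[{name}] has unknown keys: {sorted(unknown)}")
    missing = required - keys
    if missing:
        raise ConfigError(f"[{name}] is missing keys: {sorted(missing)}")


def _floats(raw: str) -> list[float]:
    return [float(tok) for tok in raw.replace(",", " ").split()]


def parse_law(section: Mapping[str, str], name: str) -> UnivariateLaw:
    """Build a probability law from one config section."""
    try:
        variant = section["variant"].strip().lower()
    except KeyError:
        raise ConfigError(f"[{name}] needs a 'variant' key") from None
    try:
        if variant == "gaussian":
            _take(section, name, {"mean", "sd"}, {"sd"})
            return Gaussian(float(section.get("mean", 0.0)), float(section["sd"]))
        if variant == "dirac":
            _take(section, name, {"point"}, set())
            return Dirac(float(section.get("point", 0.0)))
        if variant == "two_point":
            _take(section, name, {"sigma_a", "mean"}, {"sigma_a"})
            return TwoPoint(float(section["sigma_a"]), float(section.get("mean", 0.0)))
        if variant == "double_gaussian":
            _take(section, name, {"m", "s"}, {"m", "s"})
            return GaussianMixture.double(float(section["m"]), float(section["s"]))
        if variant == "mixture":
            _take(section, name, {"weights", "means", "sds"}, {"weights", "means", "sds"})
            sds = _floats(section["sds"])
            return GaussianMixture(
                _floats(section["weights"]),
                _floats(section["means"]),
                sds[0] if len(sds) == 1 else sds,
            )
        if variant == "stable":
            _take(section, name, {"alpha", "scale", "mean"}, {"alpha", "scale"})
            return SymmetricStable(
                float(section["alpha"]),
                float(section["scale"]),
                float(section.get("mean", 0.0)),
            )
        if variant == "uniform":
            _take(section, name, {"mean", "half_width"}, {"half_width"})
            return Uniform(float(section.get("mean", 0.0)), float(section["half_width"]))
    except ConfigError:
        raise
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"[{name}]: {exc}") from exc
    raise ConfigError(f"[{name}] has unknown variant {variant!r}")


def parse_selection(section: Mapping[str, str]) -> SelectionFunction:
    """Build a selection function from the [selection] section."""
    try:
        variant = section["variant"].strip().lower()
    except KeyError:
        raise ConfigError("[selection] needs a 'variant' key") from None
    try:
        if variant == "gaussian":
            _take(section, "selection", {"mu", "sigma_w"}, {"mu", "sigma_w"})
            return GaussianW(float(section["mu"]), float(section["sigma_w"]))
        if variant == "truncation":
            _take(section, "selection", {"z0"}, {"z0"})
            return TruncationW(float(section["z0"]))
    except ConfigError:
        raise
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"[selection]: {exc}") from exc
    raise ConfigError(f"[selection] has unknown variant {variant!r}")


_SIM_KEYS = {"n_parents", "n_offspring", "seed", "segregation", "segregation_scale"}


def load_model(path) -> dict:
    """Read a model config file.

    Returns a dict with keys ``genotype``, ``environment``, ``selection``
    and, when a [simulate] section is present, ``simulation`` (a
    :class:`~selresp.simulator.SimulationConfig`).
    """
    cp = configparser.ConfigParser(inline_comment_prefixes=(";", "#"))
    read = cp.read(path)
    if not read:
        raise ConfigError(f"cannot read config file {path}")
    for required in ("genotype", "environment", "selection"):
        if required not in cp:
            raise ConfigError(f"config is missing the [{required}] section")
    known_sections = {"genotype", "environment", "selection", "simulate"}
    extra = set(cp.sections()) - known_sections
    if extra:
        raise ConfigError(f"unknown config sections: {sorted(extra)}")

    model = {
        "genotype": parse_law(cp["genotype"], "genotype"),
        "environment": parse_law(cp["environment"], "environment"),
        "selection": parse_selection(cp["selection"]),
    }
    if "simulate" in cp:
        sec = cp["simulate"]
        unknown = set(sec) - _SIM_KEYS
        if unknown:
            raise ConfigError(f"[simulate] has unknown keys: {sorted(unknown)}")
        segregation = None
        kind = sec.get("segregation", "").strip().lower()
        if kind:
            scale = float(sec.get("segregation_scale", "nan"))
            if not math.isfinite(scale):
                raise ConfigError("[simulate] segregation needs segregation_scale")
            if kind == "gaussian":
                segregation = Gaussian(0.0, scale)
            elif kind == "uniform":
                segregation = Uniform(0.0, scale)
            else:
                raise ConfigError(f"unknown segregation kind {kind!r}")
        model["simulation"] = SimulationConfig(
            n_parents=int(sec.get("n_parents", 200_000)),
            genotype=model["genotype"],
            environment=model["environment"],
            selection=model["selection"],
            segregation=segregation,
            n_offspring=int(sec["n_offspring"]) if "n_offspring" in sec else None,
            seed=int(sec.get("seed", 0)),
        )
    return model
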