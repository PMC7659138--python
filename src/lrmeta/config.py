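"""Run configuration helpers: depth algebra, seeding, parameter envelope.

The three depths of a linked-read library obey ``C = C_R * C_F`` (total read
depth = read depth per fragment x physical fragment depth), so any two of
them determine the third; :func:`resolve_depths` performs that algebra and is
what the CLI uses to echo implied values.

A single integer seed drives every stochastic stage.  Each stage draws from
a named substream (:func:`make_rng`), so e.g. the partition assignment is
reproducible independently of how many reads were generated before it.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .errors import ConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "DepthTriple",
    "resolve_depths",
    "round_half_up",
    "format_depth",
    "make_rng",
    "load_config_file",
    "envelope_warnings",
    "PARAMETER_ENVELOPE",
]

#: parameter ranges explored by published linked-read titration studies;
#: values outside them draw a warning, not an error.
PARAMETER_ENVELOPE: dict[str, tuple[float, float]] = {
    "c_f": (28.0, 333.0),
    "c_r": (0.064, 0.77),
    "mu_fl": (5_000.0, 100_000.0),
    "n_fp": (10.0, 160.0),
}


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), as printed summary tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_depth(value: float) -> str:
    """Format a depth for display, two decimals, half-up."""
    return f"{round_half_up(value, 2):.2f}"


@dataclass(frozen=True)
class DepthTriple:
    """A consistent (C, C_R, C_F) triple."""

    c: float
    c_r: float
    c_f: float

    def describe(self) -> str:
        return (
            f"C = {format_depth(self.c)}X, C_R = {format_depth(self.c_r)}X, "
            f"C_F = {format_depth(self.c_f)}X"
        )


def resolve_depths(
    c: float | None = None,
    c_r: float | None = None,
    c_f: float | None = None,
    rel_tol: float = 1e-6,
) -> DepthTriple:
    """Complete a depth triple from any two of ``C``, ``C_R``, ``C_F``.

    If all three are given they must satisfy ``C = C_R * C_F`` within
    ``rel_tol``.  Fewer than two values is an error.
    """
    given = {k: v for k, v in {"c": c, "c_r": c_r, "c_f": c_f}.items() if v is not None}
    for name, value in given.items():
        if value < 0:
            raise ConfigError(f"{name} must be non-negative, got {value}")
    if len(given) < 2:
        raise ConfigError("need at least two of C, C_R, C_F")
    if c is None:
        c = c_r * c_f  # type: ignore[operator]
    elif c_r is None:
        if c_f == 0:
            raise ConfigError("cannot derive C_R with C_F = 0")
        c_r = c / c_f
    elif c_f is None:
        if c_r == 0:
            raise ConfigError("cannot derive C_F with C_R = 0")
        c_f = c / c_r
    else:
        if abs(c - c_r * c_f) > rel_tol * max(1.0, abs(c)):
            raise ConfigError(
                f"inconsistent depths: C={c} but C_R*C_F={c_r * c_f:.6g}"
            )
    return DepthTriple(c=float(c), c_r=float(c_r), c_f=float(c_f))


def make_rng(seed: int, stream: str) -> np.random.Generator:
    """Named, independent random substream derived from one global seed."""
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def load_config_file(path: str | Path) -> dict[str, Any]:
    """Load a YAML or JSON config file mirroring CLI flag names."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: config file must hold a mapping")
    return dict(data)


def envelope_warnings(params: Mapping[str, float]) -> list[str]:
    """Warnings for parameters outside the studied envelope (never errors)."""
    msgs = []
    for name, value in params.items():
        bounds = PARAMETER_ENVELOPE.get(name)
        if bounds is None or value is None:
            continue
        lo, hi = bounds
        if not (lo <= value <= hi):
            msgs.append(
                f"{name}={value:g} is outside the studied envelope "
                f"[{lo:g}, {hi:g}]; results are extrapolation"
            )
    return msgs
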