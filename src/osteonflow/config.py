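"""Configuration parsing and unit-safe validation.

The configuration is a flat TOML document with sections ``[material]``,
``[geometry]``, ``[loading]`` and ``[layers]``.  Keys carry explicit unit
suffixes (``E_r_GPa``, ``a_um``, ``k_m2``, ``frequency_hz`` /
``omega_rad_s``); everything is converted to strict SI (m, Pa, s) on
ingest, so no unit ever travels past this module.
"""

from __future__ import annotations

import math
import tomllib
from pathlib import Path
from typing import Any

import numpy as np

from .model import LayerStack, Loading, MaterialConstants, ValidationError

__all__ = ["load_config", "validate_config"]


def _section(raw: dict, name: str) -> dict:
    try:
        sec = raw[name]
    except KeyError:
        raise ValidationError(f"missing config section [{name}]") from None
    if not isinstance(sec, dict):
        raise ValidationError(f"config section [{name}] must be a table")
    return sec


def _pick(sec: dict, section: str, variants: dict[str, float]) -> float:
    """Fetch exactly one of the unit-suffixed key variants, converted to SI."""
    present = [k for k in variants if k in sec]
    if not present:
        opts = " or ".join(variants)
        raise ValidationError(f"[{section}] requires one of: {opts}")
    if len(present) > 1:
        raise ValidationError(
            f"[{section}] keys {present} are mutually exclusive; give exactly one"
        )
    key = present[0]
    value = sec[key]
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ValidationError(f"[{section}] {key} must be a number, got {value!r}")
    return float(value) * variants[key]


def validate_config(raw: dict[str, Any]) -> tuple[MaterialConstants, LayerStack, Loading]:
    """Validate a parsed key-value tree into SI domain objects.

    Every invariant violation raises :class:`ValidationError` naming the
    offending key.  Geometry accepts either ``n_layers`` (equal-width
    lamellae between ``a`` and ``b``) or an explicit ``radii_um``/``radii_m``
    list; loading accepts ``frequency_hz`` (converted via omega = 2 pi f) or
    ``omega_rad_s`` directly.
    """
    msec = _section(raw, "material")
    mat = MaterialConstants(
        E_r=_pick(msec, "material", {"E_r_GPa": 1e9, "E_r_Pa": 1.0}),
        E_z=_pick(msec, "material", {"E_z_GPa": 1e9, "E_z_Pa": 1.0}),
        nu_r=_pick(msec, "material", {"nu_r": 1.0}),
        nu_z=_pick(msec, "material", {"nu_z": 1.0}),
        alpha=_pick(msec, "material", {"alpha": 1.0}),
        alpha_prime=_pick(msec, "material", {"alpha_prime": 1.0}),
        N_biot=_pick(msec, "material", {"N_GPa": 1e9, "N_Pa": 1.0}),
        mu_fluid=_pick(msec, "material", {"mu_Pa_s": 1.0}),
    )

    gsec = _section(raw, "geometry")
    lsec = _section(raw, "layers")
    k_raw = lsec.get("k_m2")
    if k_raw is None:
        raise ValidationError("[layers] requires k_m2 (list of per-layer permeabilities)")
    k = np.atleast_1d(np.asarray(k_raw, dtype=float))

    if "radii_um" in gsec or "radii_m" in gsec:
        scale = 1e-6 if "radii_um" in gsec else 1.0
        key = "radii_um" if "radii_um" in gsec else "radii_m"
        radii = np.asarray(gsec[key], dtype=float) * scale
    else:
        a = _pick(gsec, "geometry", {"a_um": 1e-6, "a_m": 1.0})
        b = _pick(gsec, "geometry", {"b_um": 1e-6, "b_m": 1.0})
        n_layers = gsec.get("n_layers", k.size)
        if not isinstance(n_layers, int) or n_layers < 1:
            raise ValidationError(f"[geometry] n_layers must be a positive integer, got {n_layers!r}")
        if k.size == 1 and n_layers > 1:
            k = np.full(n_layers, k[0])
        radii = np.linspace(a, b, n_layers + 1)
    try:
        stack = LayerStack(radii=radii, k=k)
    except ValidationError as exc:
        raise ValidationError(f"[geometry]/[layers]: {exc}") from None

    osec = _section(raw, "loading")
    eps_z0 = _pick(osec, "loading", {"eps_z0": 1.0})
    omega = _pick(osec, "loading", {"frequency_hz": 2.0 * math.pi, "omega_rad_s": 1.0})
    try:
        loading = Loading(eps_z0=eps_z0, omega=omega)
    except ValidationError as exc:
        raise ValidationError(f"[loading]: {exc}") from None

    return mat, stack, loading


def load_config(path: str | Path) -> tuple[MaterialConstants, LayerStack, Loading]:
    """Parse and validate a TOML configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return validate_config(raw)
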