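"""Profile CSV serialization and run manifests."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import FieldProfile

__all__ = ["PROFILE_COLUMNS", "profile_to_frame", "write_profile_csv",
           "read_profile_csv", "write_manifest"]

PROFILE_COLUMNS = [
    "r_um", "layer",
    "re_p_Pa", "im_p_Pa", "abs_p_Pa",
    "re_u_m", "im_u_m",
    "re_q_m_s", "im_q_m_s", "abs_q_m_s",
    "re_sigma_rr_Pa", "im_sigma_rr_Pa",
]


def profile_to_frame(profile: FieldProfile) -> pd.DataFrame:
    """Tidy frame, one row per (r, layer) sample; SI units except r_um."""
    return pd.DataFrame(
        {
            "r_um": profile.r * 1e6,
            "layer": profile.layer_index,
            "re_p_Pa": profile.p0.real,
            "im_p_Pa": profile.p0.imag,
            "abs_p_Pa": np.abs(profile.p0),
            "re_u_m": profile.u0.real,
            "im_u_m": profile.u0.imag,
            "re_q_m_s": profile.q0.real,
            "im_q_m_s": profile.q0.imag,
            "abs_q_m_s": np.abs(profile.q0),
            "re_sigma_rr_Pa": profile.sigma_rr0.real,
            "im_sigma_rr_Pa": profile.sigma_rr0.imag,
        }
    )


def write_profile_csv(profile: FieldProfile, path: str | Path, omega: float | None = None) -> None:
    """Write a profile with 17 significant digits so read-back is lossless.

    The angular frequency is stored in a leading comment line so a profile
    file round-trips to a fully usable :class:`FieldProfile`.
    """
    path = Path(path)
    omega = profile.omega if omega is None else omega
    try:
        with open(path, "w") as fh:
            fh.write(f"# omega_rad_s = {omega!r}\n")
            profile_to_frame(profile).to_csv(fh, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write profile CSV to {path}: {exc}") from exc


def read_profile_csv(path: str | Path) -> FieldProfile:
    """Read a profile CSV back into a :class:`FieldProfile`.

    Raises ``ValueError`` naming the first missing column on a malformed
    header.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            first = fh.readline()
            omega = float("nan")
            if first.startswith("#"):
                if "omega_rad_s" in first:
                    omega = float(first.split("=", 1)[1])
            else:
                fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    except OSError as exc:
        raise OSError(f"cannot read profile CSV from {path}: {exc}") from exc
    for col in PROFILE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"malformed profile CSV {path}: missing column {col!r}")
    return FieldProfile(
        r=df["r_um"].to_numpy() * 1e-6,
        layer_index=df["layer"].to_numpy(dtype=int),
        p0=df["re_p_Pa"].to_numpy() + 1j * df["im_p_Pa"].to_numpy(),
        u0=df["re_u_m"].to_numpy() + 1j * df["im_u_m"].to_numpy(),
        q0=df["re_q_m_s"].to_numpy() + 1j * df["im_q_m_s"].to_numpy(),
        sigma_rr0=df["re_sigma_rr_Pa"].to_numpy() + 1j * df["im_sigma_rr_Pa"].to_numpy(),
        omega=omega,
    )


def write_manifest(
    out_dir: str | Path,
    config_path: str | Path | None,
    parameters: dict,
    outputs: list[str],
) -> Path:
    """JSON run manifest written alongside every output set."""
    out_dir = Path(out_dir)
    manifest = {
        "tool": "osteonflow",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config_path": str(config_path) if config_path else None,
        "parameters": parameters,
        "outputs": outputs,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
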