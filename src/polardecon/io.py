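"""OME-TIFF + sidecar I/O for fields, stacks and kernel banks.

Arrays go to multi-channel OME-TIFF with documented axis orders
(SHField: CZYX with C the SH channel; PolarizedStack: modulation,Z,Y,X;
banks: modulation,channel,Z,Y,X).  A YAML sidecar (`<name>.yaml`) records
the band limit, channel ordering, voxel pitch, scheme and provenance.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .dipole_psf import DipolePSFBank, PolarizationState
from .forward_model import PolarizationScheme, PolarizedStack
from .reconstruction import SHField
from .sphharm import BandLimit


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _bandlimit_meta(bl: BandLimit) -> dict:
    return {
        "lmax": bl.lmax,
        "even_only": bl.even_only,
        "channel_order": [list(lm) for lm in bl.channels],
    }


def _states_meta(states) -> list:
    return [
        {"view": s.view, "psi": float(s.psi), "tilt": float(s.tilt)}
        for s in states
    ]


def _states_from_meta(meta) -> tuple:
    return tuple(
        PolarizationState(view=d["view"], psi=d["psi"], tilt=d["tilt"]) for d in meta
    )


def save_field(path, field: SHField, provenance: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(field.coeffs, dtype=np.float32),
                     metadata={"axes": "CZYX"})
    meta = {
        "type": "SHField",
        "voxel_nm": float(field.voxel),
        "bandlimit": _bandlimit_meta(field.bandlimit),
        "provenance": provenance or {},
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def load_field(path) -> SHField:
    path = Path(path)
    data = tifffile.imread(path)
    meta = yaml.safe_load(_sidecar(path).read_text())
    bl = BandLimit(meta["bandlimit"]["lmax"], meta["bandlimit"]["even_only"])
    return SHField(data, bl, voxel=meta["voxel_nm"])


def save_stack(path, stack: PolarizedStack, provenance: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.volumes, dtype=np.float32),
                     metadata={"axes": "QZYX"})
    meta = {
        "type": "PolarizedStack",
        "voxel_nm": float(stack.voxel),
        "scheme": {"name": stack.scheme.name, "states": _states_meta(stack.scheme.states)},
        "provenance": provenance or {},
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def load_stack(path) -> PolarizedStack:
    path = Path(path)
    data = tifffile.imread(path)
    meta = yaml.safe_load(_sidecar(path).read_text())
    scheme = PolarizationScheme(
        _states_from_meta(meta["scheme"]["states"]), name=meta["scheme"]["name"]
    )
    return PolarizedStack(data, scheme, voxel=meta["voxel_nm"])


def save_bank(path, bank: DipolePSFBank, provenance: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(bank.kernels, dtype=np.float32),
                     metadata={"axes": "QCZYX"})
    meta = {
        "type": "DipolePSFBank",
        "voxel_nm": float(bank.voxel),
        "bandlimit": _bandlimit_meta(bank.bandlimit),
        "states": _states_meta(bank.states),
        "provenance": provenance or {},
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def load_bank(path) -> DipolePSFBank:
    path = Path(path)
    data = tifffile.imread(path)
    meta = yaml.safe_load(_sidecar(path).read_text())
    bl = BandLimit(meta["bandlimit"]["lmax"], meta["bandlimit"]["even_only"])
    return DipolePSFBank(data, _states_from_meta(meta["states"]),
                         meta["voxel_nm"], bl)


def save_metrics(path, metrics: dict) -> None:
    """Structured-text metric report (metric: value pairs)."""
    Path(path).write_text(yaml.safe_dump({k: float(v) for k, v in metrics.items()}))
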