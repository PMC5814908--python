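"""HDF5 containers for complex k-space data and NIfTI output for magnitudes.

Schema (version 1)
------------------
Single acquisition (`kind="kspace"`): datasets ``/kspace_real``,
``/kspace_imag``, ``/acquired_mask`` plus attributes ``echo_spacing_s``,
``lines_before_center``, ``nucleus``, ``fov_readout_m``, ``matrix``.

Dynamic series (`kind="series"`): one group per metabolite, each with
``frame_NNN`` subgroups of the single-acquisition layout plus a ``times_s``
dataset and optional ``amplitudes``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import h5py
import nibabel as nib
import numpy as np

from .model import EpiKspace, ImageGrid
from .simulate import DynamicSeries

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "write_container",
    "read_container",
    "write_echoes",
    "read_echoes",
    "save_magnitude_nifti",
    "load_nifti",
    "load_mask_nifti",
]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Container file does not match the expected schema."""


def _require(node, name: str, kind: str):
    if name not in node:
        raise SchemaError("missing %s %r in %r" % (kind, name, node.name))
    return node[name]


def _require_attr(node, name: str):
    if name not in node.attrs:
        raise SchemaError("missing attribute %r on %r" % (name, node.name))
    return node.attrs[name]


def _write_kspace(g, k: EpiKspace) -> None:
    g.create_dataset("kspace_real", data=k.data.real)
    g.create_dataset("kspace_imag", data=k.data.imag)
    g.create_dataset("acquired_mask", data=k.acquired_mask)
    g.attrs["echo_spacing_s"] = k.echo_spacing
    g.attrs["lines_before_center"] = k.lines_before_center
    g.attrs["nucleus"] = k.nucleus
    g.attrs["fov_readout_m"] = k.fov_readout
    g.attrs["matrix"] = np.array(k.data.shape, dtype=np.int64)


def _read_kspace(g) -> EpiKspace:
    real = np.asarray(_require(g, "kspace_real", "dataset"))
    imag = np.asarray(_require(g, "kspace_imag", "dataset"))
    mask = np.asarray(_require(g, "acquired_mask", "dataset"), dtype=bool)
    k = EpiKspace(
        data=real + 1j * imag,
        echo_spacing=float(_require_attr(g, "echo_spacing_s")),
        acquired_mask=mask,
        lines_before_center=int(_require_attr(g, "lines_before_center")),
        nucleus=str(
            _require_attr(g, "nucleus").decode()
            if isinstance(_require_attr(g, "nucleus"), bytes)
            else _require_attr(g, "nucleus")
        ),
        fov_readout=float(_require_attr(g, "fov_readout_m")),
    )
    matrix = tuple(int(v) for v in _require_attr(g, "matrix"))
    if matrix != k.data.shape:
        raise SchemaError("matrix attribute %r does not match data shape %r"
                          % (matrix, k.data.shape))
    return k


def write_container(path: Union[str, Path],
                    obj: Union[EpiKspace, DynamicSeries]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if isinstance(obj, EpiKspace):
            f.attrs["kind"] = "kspace"
            _write_kspace(f, obj)
        elif isinstance(obj, DynamicSeries):
            f.attrs["kind"] = "series"
            for m in obj.frames:
                g = f.create_group(m)
                g.create_dataset("times_s", data=np.asarray(obj.times[m]))
                if m in obj.amplitudes:
                    g.create_dataset("amplitudes",
                                     data=np.asarray(obj.amplitudes[m]))
                for i, frame in enumerate(obj.frames[m]):
                    _write_kspace(g.create_group("frame_%03d" % i), frame)
        else:
            raise TypeError("cannot serialize %r" % type(obj))


def read_container(path: Union[str, Path]) -> Union[EpiKspace, DynamicSeries]:
    with h5py.File(path, "r") as f:
        version = int(_require_attr(f, "schema_version"))
        if version != SCHEMA_VERSION:
            raise SchemaError("unsupported schema version %d" % version)
        kind = _require_attr(f, "kind")
        kind = kind.decode() if isinstance(kind, bytes) else str(kind)
        if kind == "kspace":
            return _read_kspace(f)
        if kind == "series":
            frames, times, amps = {}, {}, {}
            for m in sorted(f.keys()):
                g = f[m]
                times[m] = np.asarray(_require(g, "times_s", "dataset"))
                if "amplitudes" in g:
                    amps[m] = np.asarray(g["amplitudes"])
                names = sorted(n for n in g.keys() if n.startswith("frame_"))
                if not names:
                    raise SchemaError("metabolite group %r has no frames" % m)
                frames[m] = [_read_kspace(g[n]) for n in names]
            return DynamicSeries(frames=frames, times=times, amplitudes=amps)
        raise SchemaError("unknown container kind %r" % kind)


def write_echoes(path: Union[str, Path], echoes: np.ndarray,
                 echo_spacing: float) -> None:
    e = np.asarray(echoes, dtype=complex)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "echoes"
        f.attrs["echo_spacing_s"] = echo_spacing
        f.create_dataset("echoes_real", data=e.real)
        f.create_dataset("echoes_imag", data=e.imag)


def read_echoes(path: Union[str, Path]) -> np.ndarray:
    with h5py.File(path, "r") as f:
        kind = _require_attr(f, "kind")
        kind = kind.decode() if isinstance(kind, bytes) else str(kind)
        if kind != "echoes":
            raise SchemaError("not an echoes container: kind=%r" % kind)
        return (np.asarray(_require(f, "echoes_real", "dataset"))
                + 1j * np.asarray(_require(f, "echoes_imag", "dataset")))


def save_magnitude_nifti(img: Union[ImageGrid, np.ndarray],
                         path: Union[str, Path]) -> None:
    data = img.magnitude if isinstance(img, ImageGrid) else np.abs(np.asarray(img))
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), np.eye(4)),
             str(path))


def load_nifti(path: Union[str, Path]) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def load_mask_nifti(path: Union[str, Path]) -> np.ndarray:
    return load_nifti(path) > 0.5
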