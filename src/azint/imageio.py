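"""Image file I/O: TIFF, EDF and HDF5 dataset paths (``file.h5::/path``)."""

from __future__ import annotations

import os
from typing import Optional

import h5py
import numpy as np

__all__ = ["read_image", "write_image"]

_EDF_HEADER_BLOCK = 512

_EDF_DTYPES = {
    "FloatValue": np.float32,
    "DoubleValue": np.float64,
    "UnsignedShort": np.uint16,
    "UnsignedInteger": np.uint32,
    "SignedInteger": np.int32,
}


def read_image(path: str) -> np.ndarray:
    """Read a 2-D image from TIFF, EDF, NPY or an HDF5 dataset path."""
    if "::" in str(path):
        fname, _, dset = str(path).partition("::")
        if not os.path.exists(fname):
            raise FileNotFoundError(fname)
        with h5py.File(fname, "r") as f:
            if dset not in f:
                raise ValueError(f"dataset {dset!r} not found in {fname}")
            return np.asarray(f[dset], dtype=np.float64)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    lower = str(path).lower()
    if lower.endswith((".tif", ".tiff")):
        import tifffile
        return np.asarray(tifffile.imread(path), dtype=np.float64)
    if lower.endswith(".edf"):
        return _read_edf(path)
    if lower.endswith(".npy"):
        return np.asarray(np.load(path), dtype=np.float64)
    raise ValueError(f"unrecognized image format: {path}")


def write_image(img: np.ndarray, path: str) -> None:
    """Write a 2-D image to TIFF, EDF, NPY or an HDF5 dataset path."""
    img = np.asarray(img)
    if "::" in str(path):
        fname, _, dset = str(path).partition("::")
        with h5py.File(fname, "a") as f:
            if dset in f:
                del f[dset]
            f.create_dataset(dset, data=img)
        return
    lower = str(path).lower()
    if lower.endswith((".tif", ".tiff")):
        import tifffile
        tifffile.imwrite(path, img.astype(np.float32))
        return
    if lower.endswith(".edf"):
        _write_edf(img.astype(np.float32), path)
        return
    if lower.endswith(".npy"):
        np.save(path, img)
        return
    raise ValueError(f"unrecognized image format: {path}")


def _read_edf(path: str) -> np.ndarray:
    with open(path, "rb") as f:
        raw = f.read()
    end = raw.find(b"}")
    if not raw.lstrip().startswith(b"{") or end < 0:
        raise ValueError(f"not an EDF file: {path}")
    header = {}
    for line in raw[:end].decode("latin1").splitlines():
        line = line.strip().rstrip(";").strip()
        if "=" in line:
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
    try:
        dim1 = int(header["Dim_1"])
        dim2 = int(header["Dim_2"])
        dtype = _EDF_DTYPES[header.get("DataType", "FloatValue")]
    except KeyError as exc:
        raise ValueError(f"EDF header missing key {exc} in {path}") from None
    start = ((end // _EDF_HEADER_BLOCK) + 1) * _EDF_HEADER_BLOCK
    count = dim1 * dim2
    data = np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<"),
                         count=count, offset=start)
    return data.reshape(dim2, dim1).astype(np.float64)


def _write_edf(img: np.ndarray, path: str) -> None:
    dim2, dim1 = img.shape
    dtype_name = {np.dtype(v): k for k, v in _EDF_DTYPES.items()}[img.dtype]
    fields = [("HeaderID", "EH:000001:000000:000000"),
              ("Image", "1"),
              ("ByteOrder", "LowByteFirst"),
              ("DataType", dtype_name),
              ("Dim_1", str(dim1)),
              ("Dim_2", str(dim2)),
              ("Size", str(img.nbytes))]
    body = "{\n" + "".join(f"{k} = {v} ;\n" for k, v in fields)
    pad = _EDF_HEADER_BLOCK - ((len(body) + 2) % _EDF_HEADER_BLOCK)
    header = body + " " * pad + "}\n"
    with open(path, "wb") as f:
        f.write(header.encode("latin1"))
        f.write(np.ascontiguousarray(img, dtype=img.dtype.newbyteorder("<")).tobytes())
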