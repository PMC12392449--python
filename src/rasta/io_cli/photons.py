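"""Photon-list file formats.

Two dialects share one schema (header + ``(image_id, k_x, k_y)`` records,
0-based nondecreasing image ids, Å⁻¹ units, every ``|k| <= kmax``):

* **text** (``.txt``/``.tsv``): ``#``-prefixed header lines
  (``# key: value``, provenance as one JSON line) followed by one
  whitespace-separated ``image_id k_x k_y`` row per photon.  Human
  readable; used for fixtures and debugging.  The header records
  ``n_images`` and ``n_records`` so empty trailing images and truncation
  are detectable.
* **binary** (``.npz``): the same header as an embedded JSON string plus
  columnar ``image_id``/``k_x``/``k_y`` arrays, for large sets.

Round trips are lossless (coordinates are written with 17 significant
digits in the text dialect, enough to reproduce float64 exactly).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import numpy as np

from rasta.forward_sim import ImageSet, ScatteringImage
from rasta.scatter_geometry import BeamParams

__all__ = [
    "FORMAT_VERSION",
    "write_imageset",
    "read_imageset",
    "iter_images_text",
]

FORMAT_VERSION = 1


class PhotonFileError(ValueError):
    """Corrupt, truncated or version-incompatible photon file."""


def _header_dict(imageset: ImageSet) -> dict:
    return {
        "format": "rasta-photons",
        "version": FORMAT_VERSION,
        "wavelength": imageset.beam.wavelength,
        "i0_eff": imageset.beam.i0_eff,
        "kmax": imageset.beam.kmax,
        "n_images": len(imageset),
        "n_records": imageset.n_photons_total,
        "provenance": imageset.provenance,
    }


def _columns(imageset: ImageSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ids = np.concatenate(
        [np.full(im.n_photons, i, dtype=np.int64) for i, im in enumerate(imageset)]
    ) if imageset.n_photons_total else np.empty(0, dtype=np.int64)
    if imageset.n_photons_total:
        k = np.vstack([im.photons for im in imageset if im.n_photons])
    else:
        k = np.empty((0, 2))
    return ids, k[:, 0], k[:, 1]


def write_imageset(imageset: ImageSet, path: "str | Path") -> None:
    """Write in the dialect chosen by extension (.npz binary, else text)."""
    path = Path(path)
    if path.suffix == ".npz":
        _write_binary(imageset, path)
    else:
        _write_text(imageset, path)


def read_imageset(path: "str | Path") -> ImageSet:
    """Read either dialect; raises :class:`PhotonFileError` on corruption."""
    path = Path(path)
    if path.suffix == ".npz":
        return _read_binary(path)
    return _read_text(path)


def _write_text(imageset: ImageSet, path: Path) -> None:
    header = _header_dict(imageset)
    prov = header.pop("provenance")
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}: {value}\n")
        fh.write(f"# provenance: {json.dumps(prov, sort_keys=True)}\n")
        fh.write("# columns: image_id k_x k_y\n")
        for i, im in enumerate(imageset):
            for kx, ky in im.photons:
                fh.write(f"{i} {kx:.17g} {ky:.17g}\n")


def _parse_text_header(path: Path):
    header: dict = {}
    n_header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header_lines += 1
            body = line[1:].strip()
            if ":" not in body:
                continue
            key, _, value = body.partition(":")
            header[key.strip()] = value.strip()
    if header.get("format") != "rasta-photons":
        raise PhotonFileError(f"{path}: not a rasta photon-list file")
    if int(header.get("version", -1)) != FORMAT_VERSION:
        raise PhotonFileError(
            f"{path}: unsupported format version {header.get('version')}"
        )
    return header, n_header_lines


def _beam_from_header(header: dict) -> BeamParams:
    return BeamParams(
        wavelength=float(header["wavelength"]),
        i0_eff=float(header["i0_eff"]),
        kmax=float(header["kmax"]),
    )


def iter_images_text(path: "str | Path") -> Iterator[ScatteringImage]:
    """Stream images one at a time from a text photon file.

    Empty images (ids with no records) are yielded as empty
    :class:`ScatteringImage` objects, in order.
    """
    path = Path(path)
    header, _ = _parse_text_header(path)
    n_images = int(header["n_images"])
    n_records = int(header["n_records"])
    seen = 0
    current_id = 0
    buffer: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) != 3:
                raise PhotonFileError(f"{path}:{lineno}: expected 3 columns")
            img_id = int(parts[0])
            if img_id < current_id:
                raise PhotonFileError(
                    f"{path}:{lineno}: image_id must be nondecreasing"
                )
            if img_id >= n_images:
                raise PhotonFileError(
                    f"{path}:{lineno}: image_id {img_id} >= n_images {n_images}"
                )
            while current_id < img_id:
                yield ScatteringImage(photons=np.array(buffer).reshape(-1, 2))
                buffer = []
                current_id += 1
            buffer.append((float(parts[1]), float(parts[2])))
            seen += 1
    if seen != n_records:
        raise PhotonFileError(
            f"{path}: header says {n_records} records, found {seen} (truncated?)"
        )
    while current_id < n_images:
        yield ScatteringImage(photons=np.array(buffer).reshape(-1, 2))
        buffer = []
        current_id += 1


def _read_text(path: Path) -> ImageSet:
    header, _ = _parse_text_header(path)
    images = list(iter_images_text(path))
    provenance = json.loads(header.get("provenance", "{}"))
    return ImageSet(images=images, beam=_beam_from_header(header), provenance=provenance)


def _write_binary(imageset: ImageSet, path: Path) -> None:
    ids, kx, ky = _columns(imageset)
    np.savez_compressed(
        path,
        header=np.array(json.dumps(_header_dict(imageset), sort_keys=True)),
        image_id=ids,
        k_x=kx,
        k_y=ky,
    )


def _read_binary(path: Path) -> ImageSet:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        if header.get("format") != "rasta-photons":
            raise PhotonFileError(f"{path}: not a rasta photon-list file")
        if int(header.get("version", -1)) != FORMAT_VERSION:
            raise PhotonFileError(f"{path}: unsupported version")
        ids = data["image_id"]
        kx = data["k_x"]
        ky = data["k_y"]
    if not (ids.shape == kx.shape == ky.shape):
        raise PhotonFileError(f"{path}: column length mismatch")
    if ids.size != int(header["n_records"]):
        raise PhotonFileError(f"{path}: record count mismatch (truncated?)")
    if ids.size and np.any(np.diff(ids) < 0):
        raise PhotonFileError(f"{path}: image_id must be nondecreasing")
    n_images = int(header["n_images"])
    images = []
    bounds = np.searchsorted(ids, np.arange(n_images + 1))
    for i in range(n_images):
        lo, hi = bounds[i], bounds[i + 1]
        images.append(
            ScatteringImage(photons=np.column_stack([kx[lo:hi], ky[lo:hi]]))
        )
    return ImageSet(
        images=images,
        beam=_beam_from_header({k: str(v) for k, v in header.items()}),
        provenance=header.get("provenance", {}),
    )
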