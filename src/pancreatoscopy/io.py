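"""Volume and fiducial I/O with exact geometry.

Volumes are read and written through SimpleITK, which already normalizes
NIfTI/NRRD/MetaImage geometry to the LPS millimetre convention used
internally. Fiducials come either from 3D Slicer ``.fcsv`` markups files
(stored in RAS; the first two coordinates are negated on load) or from a
minimal JSON point list ``{"points": [[x, y, z], ...]}`` already in LPS.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .core import FiducialSet, ScalarVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_fiducials",
    "write_fiducials",
    "ras_to_lps",
    "VOLUME_EXTENSIONS",
]

VOLUME_EXTENSIONS = (".nii", ".nii.gz", ".nrrd", ".mha", ".mhd")


def _check_extension(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in VOLUME_EXTENSIONS):
        raise ValueError(
            f"unsupported volume extension for {path!s}; expected one of {VOLUME_EXTENSIONS}"
        )


def read_volume(path: str | Path) -> ScalarVolume:
    """Read a NIfTI / NRRD / MetaImage volume with its full geometry."""
    path = Path(path)
    _check_extension(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - corrupted file branch
        raise IOError(f"could not read volume {path!s}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"{path!s}: expected a 3D volume, got {img.GetDimension()}D")
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    if np.any(spacing <= 0):
        raise ValueError(f"{path!s}: missing or invalid voxel spacing {spacing}")
    # sitk arrays come back (z, y, x); internal order is (x, y, z) = (i, j, k)
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    return ScalarVolume(values, spacing, np.asarray(img.GetOrigin()), direction)


def write_volume(vol: ScalarVolume, path: str | Path, metadata: dict[str, str] | None = None) -> None:
    """Write a volume; geometry (spacing/origin/direction) is encoded losslessly.

    Integer-typed ``values`` (e.g. a {0,1,2} label map as uint8) are written
    with their dtype preserved so they reread exactly. ``metadata`` entries
    are stored as key/value pairs for formats that support them (NRRD/MHA).
    """
    path = Path(path)
    _check_extension(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    img.SetDirection(tuple(vol.direction.ravel()))
    for key, val in (metadata or {}).items():
        img.SetMetaData(key, str(val))
    try:
        sitk.WriteImage(img, str(path), useCompression=path.name.endswith(".gz"))
    except RuntimeError as exc:
        raise IOError(f"could not write volume {path!s}: {exc}") from exc


def ras_to_lps(points: np.ndarray) -> np.ndarray:
    """Negate the first two coordinates; an involution (LPS->RAS is identical)."""
    pts = np.array(points, dtype=float, copy=True)
    pts[..., 0] *= -1.0
    pts[..., 1] *= -1.0
    return pts


def read_fiducials(path: str | Path) -> FiducialSet:
    """Read an ordered fiducial list from ``.fcsv`` (RAS) or JSON (LPS).

    Slicer ``.fcsv`` rows are ``id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,...``
    with ``#`` comment/header lines (version-4 headers tolerated and
    ignored). Coordinates are converted RAS -> LPS on load. Order of
    appearance is preserved; the first point is the duct head.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        points = np.asarray(data["points"], dtype=float)
        labels = data.get("labels")
        return FiducialSet(points, labels)

    points: list[list[float]] = []
    labels: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split(",")
        if len(fields) < 4:
            raise ValueError(f"{path!s}:{lineno}: malformed fiducial row {raw!r}")
        try:
            xyz = [float(fields[1]), float(fields[2]), float(fields[3])]
        except ValueError as exc:
            raise ValueError(f"{path!s}:{lineno}: non-numeric coordinate in {raw!r}") from exc
        points.append(xyz)
        labels.append(fields[11] if len(fields) > 11 else f"F-{len(points)}")
    if len(points) < 2:
        raise ValueError(f"{path!s}: need at least 2 fiducials, found {len(points)}")
    return FiducialSet(ras_to_lps(np.asarray(points)), labels)


def write_fiducials(fids: FiducialSet, path: str | Path) -> None:
    """Write fiducials as Slicer ``.fcsv`` (RAS) or a JSON point list (LPS)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {"points": np.asarray(fids.points).tolist()}
        if fids.labels is not None:
            payload["labels"] = list(fids.labels)
        path.write_text(json.dumps(payload, indent=2))
        return
    labels = fids.labels or [f"F-{i + 1}" for i in range(len(fids))]
    ras = ras_to_lps(fids.points)  # involution: LPS -> RAS
    lines = [
        "# Markups fiducial file version = 4.11",
        "# CoordinateSystem = 0",
        "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
    ]
    for i, (p, lab) in enumerate(zip(ras, labels), start=1):
        lines.append(
            f"vtkMRMLMarkupsFiducialNode_{i},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f},"
            f"0,0,0,1,1,1,0,{lab},,"
        )
    path.write_text("\n".join(lines) + "\n")
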