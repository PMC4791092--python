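"""Readers, writers and ROI plumbing for multi-echo magnitude images.

Supported inputs:

* a directory of single-frame magnitude DICOM files from one
  multi-echo series (echo times taken from the ``EchoTime`` attribute);
* a 3-D NIfTI volume (x, y, echo) with a plain-text or JSON sidecar
  listing the echo times in milliseconds;
* a toy tabular format for decay signals: CSV with header
  ``te_ms,pixel_0,pixel_1,...`` and one row per echo.

Pixel indexing is 0-based row-major everywhere; binary masks must match
the in-plane image shape exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import AdaptsConfig, adapts_estimate
from .exceptions import UncertaintyUnavailableError
from .signal_models import EchoProtocol
from .uncertainty import RoiPixels, estimate_uncertainty

__all__ = [
    "MultiEchoStack",
    "RoiSpec",
    "read_multiecho_dicom",
    "read_multiecho_nifti",
    "read_signal_table",
    "write_signal_table",
    "extract_roi",
    "fit_roi",
    "DEFAULT_COV_ADVISORY",
]

#: CoV above which the report advises reviewing the ROI delineation.
#: Patient-observed CoV values span roughly 0.01-0.46; 0.30 flags the
#: upper tail of that range.
DEFAULT_COV_ADVISORY = 0.30


@dataclass(frozen=True)
class MultiEchoStack:
    """A 2-D slice acquired at several echo times.

    ``data`` has shape (rows, cols, n_echoes), magnitudes non-negative,
    echoes sorted by increasing TE.
    """

    data: np.ndarray
    protocol: EchoProtocol
    pixel_spacing: tuple[float, float] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", arr)
        if arr.ndim != 3 or arr.shape[2] != len(self.protocol):
            raise ValueError("data must be (rows, cols, n_echoes) matching protocol")
        if np.any(arr < 0):
            raise ValueError("magnitudes must be non-negative")

    @property
    def plane_shape(self) -> tuple[int, int]:
        return self.data.shape[0], self.data.shape[1]


@dataclass(frozen=True)
class RoiSpec:
    """A region of interest: binary mask or explicit flat pixel indices."""

    mask: np.ndarray | None = None
    indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.mask is None) == (self.indices is None):
            raise ValueError("provide exactly one of mask or indices")
        if self.mask is not None:
            m = np.asarray(self.mask).astype(bool)
            if m.ndim != 2 or not m.any():
                raise ValueError("mask must be a non-empty 2-D binary image")
            object.__setattr__(self, "mask", m)
        else:
            idx = np.asarray(self.indices, dtype=np.int64).ravel()
            if idx.size == 0 or np.any(idx < 0):
                raise ValueError("indices must be a non-empty list of >= 0 integers")
            object.__setattr__(self, "indices", idx)

    def flat_indices(self, plane_shape: tuple[int, int]) -> np.ndarray:
        """Row-major flat pixel indices of the ROI within a given plane."""
        n = plane_shape[0] * plane_shape[1]
        if self.mask is not None:
            if self.mask.shape != tuple(plane_shape):
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match image {plane_shape}"
                )
            return np.flatnonzero(self.mask.ravel())
        if np.any(self.indices >= n):
            raise ValueError("pixel index outside image bounds")
        return self.indices


def read_multiecho_dicom(directory: str | Path) -> MultiEchoStack:
    """Load one single-frame magnitude DICOM series as a TE-sorted stack.

    Files are grouped by ``EchoTime`` (milliseconds in DICOM); the file
    order on disk is irrelevant.  Missing ``EchoTime`` metadata, mixed
    ``SeriesInstanceUID`` values or duplicate echo times raise; images
    not flagged as magnitude only warn.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"no files in {directory}")
    frames: list[tuple[float, np.ndarray]] = []
    series_uids = set()
    spacing = None
    for path in files:
        ds = pydicom.dcmread(path)
        te = ds.get("EchoTime")
        if te is None:
            raise ValueError(f"file {path.name} is missing EchoTime metadata")
        uid = ds.get("SeriesInstanceUID")
        if uid is not None:
            series_uids.add(str(uid))
        image_type = [str(v).upper() for v in ds.get("ImageType", [])]
        if image_type and "M" not in image_type and "MAGNITUDE" not in image_type:
            warnings.warn(
                f"file {path.name} is not flagged as a magnitude image", stacklevel=2
            )
        if spacing is None and ds.get("PixelSpacing") is not None:
            spacing = tuple(float(v) for v in ds.PixelSpacing)
        frames.append((float(te), ds.pixel_array.astype(np.float64)))
    if len(series_uids) > 1:
        raise ValueError(f"directory mixes {len(series_uids)} DICOM series")
    tes = [t for t, _ in frames]
    if len(set(tes)) != len(tes):
        raise ValueError("duplicate EchoTime values within the series")
    frames.sort(key=lambda f: f[0])
    data = np.stack([img for _, img in frames], axis=-1)
    protocol = EchoProtocol(tuple(t for t, _ in frames), name=directory.name)
    return MultiEchoStack(data, protocol, pixel_spacing=spacing, source="dicom")


def _parse_te_sidecar(path: Path) -> list[float]:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        parsed = json.loads(text)
        if isinstance(parsed, dict):
            parsed = parsed.get("EchoTimes", parsed.get("te_ms"))
        if parsed is None:
            raise ValueError(f"sidecar {path.name} has no echo-time list")
        return [float(v) for v in parsed]
    return [float(tok) for tok in text.replace(",", " ").split()]


def read_multiecho_nifti(
    volume_path: str | Path, te_sidecar_path: str | Path
) -> MultiEchoStack:
    """Load a 3-D NIfTI volume (x, y, echo) plus a TE sidecar in ms."""
    import nibabel as nib

    volume_path = Path(volume_path)
    te_sidecar_path = Path(te_sidecar_path)
    img = nib.load(volume_path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D (x, y, echo) volume, got {data.ndim}-D")
    tes = _parse_te_sidecar(te_sidecar_path)
    if len(tes) != data.shape[2]:
        raise ValueError(
            f"sidecar lists {len(tes)} echo times but volume has {data.shape[2]} echoes"
        )
    if all(t < 1.0 for t in tes):
        raise ValueError(
            "all sidecar echo times are below 1; they look like seconds — "
            "provide echo times in milliseconds"
        )
    order = np.argsort(tes)
    data = np.clip(data[:, :, order], 0.0, None)
    protocol = EchoProtocol(tuple(np.asarray(tes)[order]), name=volume_path.stem)
    zooms = img.header.get_zooms()[:2]
    return MultiEchoStack(
        data, protocol, pixel_spacing=(float(zooms[0]), float(zooms[1])),
        source="nifti",
    )


def write_signal_table(path: str | Path, roi: RoiPixels) -> None:
    """Write pixel decays in the toy CSV format (one row per echo)."""
    path = Path(path)
    n_px = roi.n_pixels
    header = "te_ms," + ",".join(f"pixel_{i}" for i in range(n_px))
    lines = [header]
    for j, te in enumerate(roi.protocol.tes):
        vals = ",".join(repr(float(v)) for v in roi.pixel_signals[:, j])
        lines.append(f"{te!r},{vals}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_signal_table(path: str | Path) -> RoiPixels:
    """Read the toy CSV format back into per-pixel decay vectors."""
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    header = lines[0].split(",")
    if header[0] != "te_ms":
        raise ValueError(f"{path.name}: expected a 'te_ms' header column")
    n_px = len(header) - 1
    tes = []
    rows = []
    for ln in lines[1:]:
        parts = ln.split(",")
        if len(parts) != n_px + 1:
            raise ValueError(f"{path.name}: ragged row with {len(parts)} fields")
        tes.append(float(parts[0]))
        rows.append([float(v) for v in parts[1:]])
    protocol = EchoProtocol(tuple(tes), name=path.stem)
    signals = np.asarray(rows, dtype=np.float64).T  # (n_pixels, n_echoes)
    return RoiPixels(protocol=protocol, pixel_signals=signals)


def extract_roi(stack: MultiEchoStack, roi: RoiSpec) -> RoiPixels:
    """Pull the ROI's per-pixel decay vectors out of an image stack."""
    idx = roi.flat_indices(stack.plane_shape)
    flat = stack.data.reshape(-1, stack.data.shape[2])
    return RoiPixels(
        protocol=stack.protocol, pixel_signals=flat[idx], pixel_ids=idx
    )


def fit_roi(
    stack: MultiEchoStack,
    roi: RoiSpec,
    config: AdaptsConfig | None = None,
    with_uncertainty: bool = False,
    fraction: float = 0.04,
    cov_threshold: float = DEFAULT_COV_ADVISORY,
) -> dict:
    """ADAPTS on the ROI mean, optionally with the subregion CI estimate.

    Returns a flat report record.  The record carries ``advisory=True``
    — suggesting the delineation be reviewed — when the estimated CoV
    exceeds ``cov_threshold`` (heterogeneous or noise-dominated ROI) or
    when the estimate is pinned at the no-decay ceiling of 10 x max TE
    (no measurable decay in the ROI, e.g. a background region).
    """
    if config is None:
        config = AdaptsConfig()
    pixels = extract_roi(stack, roi)
    result = adapts_estimate(pixels.mean_signal(), config)
    degenerate = result.t2 >= 0.999 * 10.0 * stack.protocol.tes[-1]
    report = {
        "t2_ms": result.t2,
        "branch": result.branch,
        "t2_initial_ms": result.t2_initial,
        "n_echoes": len(stack.protocol),
        "n_kept_echoes": len(result.kept_te_indices),
        "n_pixels": pixels.n_pixels,
        "converged": result.diagnostics.converged,
    }
    if with_uncertainty:
        try:
            unc = estimate_uncertainty(pixels, config, fraction)
        except UncertaintyUnavailableError as exc:
            report.update(
                {"ci95_ms": None, "cov": None, "advisory": True,
                 "uncertainty_note": str(exc)}
            )
        else:
            report.update(
                {
                    "ci95_ms": unc.ci95_size,
                    "cov": unc.cov,
                    "n_subregions": len(unc.subregion_t2s),
                    "advisory": bool(unc.cov > cov_threshold or degenerate),
                }
            )
    return report
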