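"""TIFF I/O, result serialization and run records."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from vesselmetrics import __version__
from vesselmetrics.config import AnalysisConfig
from vesselmetrics.images import CalibratedImage, InputError
from vesselmetrics.morphometry import Heatmap, MorphometryResult
from vesselmetrics.plexus import PlexusComparison
from vesselmetrics.skeleton import SkeletonGraph


class FormatError(ValueError):
    """Unreadable or unsupported image file."""


_SUPPORTED_DTYPES = ("uint8", "uint16", "float32", "float64")


def read_stack(
    path,
    pixel_size: float | tuple[float, float, float],
    roi: np.ndarray | None = None,
    center: tuple[float, float] | None = None,
) -> CalibratedImage:
    """Read a single- or multi-page TIFF as a calibrated image.

    Multi-page files come back as (z, y, x); the caller-supplied pixel size
    overrides any calibration embedded in the file.
    """
    path = Path(path)
    try:
        pixels = tifffile.imread(path)
    except (FileNotFoundError, OSError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if pixels.dtype.name not in _SUPPORTED_DTYPES:
        raise FormatError(
            f"{path}: unsupported bit depth {pixels.dtype}; expected one of {_SUPPORTED_DTYPES}"
        )
    if pixels.ndim not in (2, 3):
        raise FormatError(f"{path}: expected 2 or 3 dimensions, got {pixels.ndim}")
    return CalibratedImage(
        pixels, pixel_size, roi=roi, center=center, metadata={"source": str(path)}
    )


def read_roi_mask(path) -> np.ndarray:
    """Read a binary ROI mask from a TIFF or PNG file."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except (FileNotFoundError, OSError, ValueError) as exc:
        raise FormatError(f"cannot read ROI mask {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_image(path, image: CalibratedImage) -> None:
    tifffile.imwrite(Path(path), np.asarray(image.pixels))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunRecord:
    """Provenance of one analysis run: inputs, config, warnings, outputs."""

    inputs: list[str]
    config: dict[str, Any]
    warnings: list[str]
    manifest: dict[str, str]  # file name -> sha256
    version: str = __version__
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "inputs": self.inputs,
            "config": self.config,
            "warnings": self.warnings,
            "manifest": self.manifest,
            "version": self.version,
            "metadata": self.metadata,
        }


def results_frame(results: list[MorphometryResult]) -> pd.DataFrame:
    """Tidy DataFrame, one unit-suffixed row per image x plexus x label."""
    columns = list(MorphometryResult(0, 0, 0, 0, 0, None, 1, 0).to_row().keys())
    if not results:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame([r.to_row() for r in results], columns=columns)


def write_results(
    results: list[MorphometryResult],
    out_dir,
    comparison: PlexusComparison | None = None,
    heatmaps: dict[str, Heatmap] | None = None,
    config: AnalysisConfig | None = None,
    inputs: list[str] | None = None,
    log_lines: list[str] | None = None,
) -> RunRecord:
    """Write all result artifacts to a directory and return the run record.

    Always writes ``morphometry.csv`` (full precision; rounding applies
    only to the deviation fields inside the comparison JSON), the resolved
    config, a plain-text log and a ``run_record.json`` manifest with
    checksums; a plexus comparison JSON and per-label heatmap TIFF+CSV pairs
    are added when supplied.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise InputError(f"output directory {out_dir} is not writable: {exc}") from exc

    written: list[Path] = []
    t0 = time.time()

    csv_path = out_dir / "morphometry.csv"
    results_frame(results).to_csv(csv_path, index=False)
    written.append(csv_path)

    if comparison is not None:
        cmp_path = out_dir / "plexus_comparison.json"
        with open(cmp_path, "w") as fh:
            json.dump(comparison.to_dict(), fh, indent=2)
        written.append(cmp_path)

    for label, hm in (heatmaps or {}).items():
        tif_path = out_dir / f"heatmap_{label}.tif"
        tifffile.imwrite(tif_path, hm.tiles.astype(np.float32))
        written.append(tif_path)
        hist_path = out_dir / f"heatmap_{label}_histogram.csv"
        pd.DataFrame(
            {
                "bin_lo": hm.bin_edges[:-1],
                "bin_hi": hm.bin_edges[1:],
                "count": hm.histogram,
            }
        ).to_csv(hist_path, index=False)
        written.append(hist_path)

    config = config or AnalysisConfig()
    cfg_path = out_dir / "resolved_config.yaml"
    config.to_yaml(cfg_path)
    written.append(cfg_path)

    log_path = out_dir / "run.log"
    lines = list(log_lines or [])
    lines.append(f"wrote {len(written) + 1} files")
    log_path.write_text("\n".join(lines) + "\n")
    written.append(log_path)

    record = RunRecord(
        inputs=list(inputs or []),
        config=config.__dict__ | {},
        warnings=[ln for ln in lines if "warning" in ln.lower()],
        manifest={p.name: _sha256(p) for p in written},
    )
    rec_path = out_dir / "run_record.json"
    with open(rec_path, "w") as fh:
        json.dump(record.to_dict(), fh, indent=2, default=str)
    return record


def render_heatmap_png(hm: Heatmap, path) -> Path:
    """Render the tiled area-fraction grid with a perceptual LUT.

    Purely cosmetic; the numeric grid written alongside is the contract.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(hm.tiles, cmap="inferno", vmin=0.0, vmax=1.0, interpolation="nearest")
    ax.set_title(f"area fraction per {hm.tile_um:g} µm tile")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="area fraction")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def write_skeleton_graph(graph: SkeletonGraph, out_dir, label: str = "skeleton") -> list[Path]:
    """Export a skeleton graph as a class-map TIFF plus segment CSV and JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    tif_path = out_dir / f"{label}_classes.tif"
    tifffile.imwrite(tif_path, graph.class_map())
    paths.append(tif_path)
    rows = [
        {
            "id": i,
            "length_um": s.length_um,
            "centroid_x_um": s.centroid_um[1],
            "centroid_y_um": s.centroid_um[0],
        }
        for i, s in enumerate(graph.segments)
    ]
    csv_path = out_dir / f"{label}_segments.csv"
    pd.DataFrame(rows, columns=["id", "length_um", "centroid_x_um", "centroid_y_um"]).to_csv(
        csv_path, index=False
    )
    paths.append(csv_path)
    json_path = out_dir / f"{label}_graph.json"
    with open(json_path, "w") as fh:
        json.dump(
            {
                "pixel_size": graph.pixel_size,
                "n_segments": graph.n_segments,
                "n_junctions": len(graph.junctions),
                "n_endpoints": len(graph.endpoints),
                "segments": rows,
                "junctions": [
                    {
                        "centroid_x_um": j.centroid_um[1],
                        "centroid_y_um": j.centroid_um[0],
                        "n_pixels": len(j.pixels),
                    }
                    for j in graph.junctions
                ],
            },
            fh,
        )
    paths.append(json_path)
    return paths
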