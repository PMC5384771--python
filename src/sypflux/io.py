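"""File formats: TIFF stacks, CSV truth tables, JSON manifests."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import tifffile

from .render import ImagingParams, TimeSeriesStack
from .synthetic import GonadLayout

__all__ = [
    "write_stack",
    "read_stack",
    "write_series",
    "write_truth",
    "read_truth",
]


def write_stack(
    stack: np.ndarray, path, voxel_xy_um: float = 0.1, voxel_z_um: float = 0.24
) -> None:
    """Write a ZYX stack as an ImageJ-compatible multi-page TIFF.

    Voxel data are stored as float32; lateral calibration goes in the
    resolution tags (pixels per µm) and z spacing in the ImageJ metadata.
    """
    arr = np.asarray(stack, dtype=np.float32)
    if arr.ndim != 3:
        raise ValueError("expected a 3D ZYX stack")
    tifffile.imwrite(
        str(path),
        arr,
        imagej=True,
        resolution=(1.0 / voxel_xy_um, 1.0 / voxel_xy_um),
        metadata={"spacing": voxel_z_um, "unit": "um", "axes": "ZYX"},
    )


def read_stack(path) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Read a stack written by :func:`write_stack`; returns (ZYX array,
    (voxel_xy_um, voxel_z_um))."""
    p = Path(path)
    try:
        with tifffile.TiffFile(str(p)) as tf:
            arr = tf.asarray()
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            vxy = 1.0
            if xres is not None:
                num, den = xres.value
                vxy = den / num
            meta = tf.imagej_metadata or {}
            vz = float(meta.get("spacing", 1.0))
    except (tifffile.TiffFileError, ValueError) as exc:
        raise ValueError(f"cannot parse TIFF stack {p}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"unsupported TIFF layout in {p}: expected ZYX pages, got shape {arr.shape}"
        )
    return arr.astype(float), (vxy, vz)


def write_series(
    series: TimeSeriesStack, out_dir, prefix: str = "t"
) -> list:
    """One TIFF per time point per channel; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, (t, frame) in enumerate(zip(series.times_min, series.frames)):
        for ch, stack in frame.items():
            p = out / f"{prefix}{i:03d}_{ch}_t{t:+07.2f}min.tif"
            write_stack(
                stack, p, series.imaging.voxel_xy_um, series.imaging.voxel_z_um
            )
            paths.append(p)
    return paths


def write_truth(layout: GonadLayout, out_dir, extra_manifest: Optional[dict] = None):
    """Write ground-truth tables and a run manifest for a layout.

    Produces ``nuclei.csv`` (one row per nucleus), ``traces.csv``,
    ``foci.csv`` and ``manifest.json`` recording the seed and parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nuc_rows, trace_rows, focus_rows = [], [], []
    for n in layout.nuclei:
        nuc_rows.append(
            dict(
                nucleus_id=n.nucleus_id, row=n.row, x=n.x, stage=n.stage,
                genotype=layout.genotype.label, base_density=n.base_density,
                mobile_fraction_f=n.mobile_fraction_f,
                exchange_rate_k=n.exchange_rate_k,
                n_foci=n.n_foci, n_focus_traces=n.n_focus_traces,
            )
        )
        total = n.total_trace_intensity
        for t in n.traces:
            trace_rows.append(
                dict(
                    nucleus_id=n.nucleus_id, trace_id=t.trace_id,
                    chromosome=t.chromosome_label, length_um=t.length_um,
                    enrichment=t.enrichment,
                    conservation_scale=t.conservation_scale,
                    intensity_share=t.total_intensity / total,
                    n_foci=len(t.foci),
                )
            )
            for s in t.foci:
                p = t.point_at_arclength(s)
                focus_rows.append(
                    dict(
                        nucleus_id=n.nucleus_id, trace_id=t.trace_id,
                        chromosome=t.chromosome_label, arc_position_um=s,
                        x_um=p[0], y_um=p[1], z_um=p[2],
                    )
                )
    pd.DataFrame(nuc_rows).to_csv(out / "nuclei.csv", index=False)
    pd.DataFrame(trace_rows).to_csv(out / "traces.csv", index=False)
    cols = ["nucleus_id", "trace_id", "chromosome", "arc_position_um",
            "x_um", "y_um", "z_um"]
    pd.DataFrame(focus_rows, columns=cols).to_csv(out / "foci.csv", index=False)
    manifest = {
        "seed": layout.seed,
        "genotype": layout.genotype.label,
        "n_nuclei": len(layout.nuclei),
        "spec": {
            "n_rows": layout.spec.n_rows,
            "nuclei_per_row": layout.spec.nuclei_per_row,
            "nucleus_radius_um": layout.spec.nucleus_radius_um,
            "n_pairs": layout.spec.n_pairs,
            "ramp_fold": layout.spec.ramp_fold,
            "stage_boundaries": list(layout.spec.stage_boundaries),
            "base_density": layout.spec.base_density,
        },
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def read_truth(out_dir):
    """Read back the truth tables; returns (nuclei, traces, foci, manifest)."""
    out = Path(out_dir)
    nuclei = pd.read_csv(out / "nuclei.csv")
    traces = pd.read_csv(out / "traces.csv")
    foci = pd.read_csv(out / "foci.csv")
    manifest = json.loads((out / "manifest.json").read_text())
    return nuclei, traces, foci, manifest
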