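"""Writers for the synthetic fixtures.

Images go to 16-bit TIFF (plus 8-bit PNG previews), masks to 8-bit PNG
with values {0, 255}, tables to CSV with documented headers, pathway sets
to GMT, and each fixture directory gets a JSON manifest recording the
configuration and seeds used.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .images import ImageDataset
from .omics import OmicsFixture

__all__ = ["write_image_dataset", "write_gmt", "read_gmt", "write_omics_fixture"]


def _manifest(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=str))


def write_image_dataset(dataset: ImageDataset, outdir: str | Path, cfg=None) -> Path:
    """Write images, masks, ground-truth tables and a manifest."""
    out = Path(outdir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    (out / "previews").mkdir(exist_ok=True)
    count_rows, gt_rows = [], []
    for i, (im, gt) in enumerate(zip(dataset.images, dataset.truths)):
        name = f"img{i:04d}"
        px = np.asarray(im.pixels, dtype=np.float64)
        tifffile.imwrite(out / "images" / f"{name}.tif", (px * 65535).astype(np.uint16))
        iio.imwrite(out / "previews" / f"{name}.png", (px * 255).astype(np.uint8))
        iio.imwrite(out / "masks" / f"{name}.png", gt.true_mask.pixels.astype(np.uint8) * 255)
        count_rows.append((name, gt.true_count))
        for (r, c), s in zip(gt.centers, gt.sigmas):
            gt_rows.append((name, r, c, s))
    pd.DataFrame(count_rows, columns=["image", "true_count"]).to_csv(out / "counts.csv", index=False)
    pd.DataFrame(gt_rows, columns=["image", "center_row", "center_col", "sigma"]).to_csv(
        out / "ground_truth.csv", index=False
    )
    _manifest(
        out / "manifest.json",
        {
            "n_images": len(dataset),
            "seeds": dataset.seeds,
            "config": dataclasses.asdict(cfg) if cfg is not None else None,
        },
    )
    return out


def write_gmt(sets: dict, path: str | Path, description: str = "") -> Path:
    """Write name -> member-set mappings as tab-delimited GMT."""
    path = Path(path)
    lines = [
        "\t".join([name, description] + sorted(str(m) for m in members))
        for name, members in sets.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gmt(path: str | Path) -> dict:
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        sets[parts[0]] = set(parts[2:])
    return sets


def write_omics_fixture(fixture: OmicsFixture, outdir: str | Path) -> Path:
    """Write the omics fixture as CSV/GMT files plus a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fixture.deg_table.to_csv(out / "deg_table.csv", index=False)
    fixture.mirna_edges.to_csv(out / "mirna_edges.csv", index=False)
    fixture.lnc_edges.to_csv(out / "lnc_edges.csv", index=False)
    fixture.features.to_csv(out / "features.csv", index=False)
    fixture.intensities.to_csv(out / "intensities.csv")
    fixture.sample_groups.rename("group").to_csv(out / "sample_groups.csv")
    fixture.annotation_library.to_csv(out / "annotation_library.csv", index=False)
    for ns in ("genes", "mirnas", "metabolites"):
        write_gmt({pw: s.get(ns, set()) for pw, s in fixture.pathway_db.items()}, out / f"pathways_{ns}.gmt")
    _manifest(out / "manifest.json", {"truth": fixture.truth, "files": sorted(p.name for p in out.iterdir())})
    return out
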