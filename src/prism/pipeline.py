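"""End-to-end confocal profiling pipeline: image set -> synapse feature table.

Ties the stages together for a single field of view (or a simulated one):
flat-field correction, round registration, segmentation of every synaptic
channel, synapse gating on synapsin, colocalization, and feature
extraction.  Every intermediate is persisted when an output directory is
given, together with a machine-readable provenance log.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import extract_features
from .preprocess import (
    estimate_background,
    estimate_illumination_profile,
    flat_field_correct,
    register_rounds,
)
from .segmentation import (
    SegmentationParams,
    colocalize,
    detect_synapses,
    nuclear_mask,
    segment_channel,
)
from .types import ImageSet

__all__ = ["profile_image_set", "run_simulated_pipeline"]


def profile_image_set(
    image_set: ImageSet,
    synapse_channel: str = "synapsin",
    reference_channel: str = "MAP2",
    nuclear_channel: str = "DAPI",
    non_synaptic_channels: tuple[str, ...] = (),
    min_area_um2: float = 0.42,
    coloc_radius_um: float = 1.0,
    flatfield_disk_px: int = 100,
    max_shift: int = 50,
    seg_params: SegmentationParams = SegmentationParams(),
    well: str = "A1",
    image_id: str = "0",
    out_dir: str | Path | None = None,
) -> dict:
    """Run the confocal profiling chain on one image set.

    Returns a dict with the corrected image set, shift table, punctae sets,
    synapse set and the per-synapse feature table.
    """
    disk_px = min(flatfield_disk_px, (min(image_set.images[0].data.shape) - 2) // 2)
    corrected = []
    for im in image_set.images:
        bg = estimate_background(im.data, disk_px)
        profile = estimate_illumination_profile([bg], channel=im.channel)
        corrected.append(im.with_data(flat_field_correct(im.data, profile)))
    corrected_set = ImageSet(corrected, pixel_size_nm=image_set.pixel_size_nm)

    registered, shifts = register_rounds(
        corrected_set, reference_channel=reference_channel, max_shift=max_shift
    )
    shift_table = pd.DataFrame(
        [{"round": s.round_id, "dx": s.dx, "dy": s.dy} for s in shifts]
    )

    channels = [
        c
        for c in registered.channels()
        if c not in (reference_channel, nuclear_channel)
    ]
    img_of = {c: registered.get(c) for c in channels}
    try:
        nuc = nuclear_mask(
            registered.get(nuclear_channel).data, registered.pixel_size_nm
        )
    except KeyError:
        nuc = None

    puncta = {
        c: segment_channel(
            img_of[c].data,
            channel=c,
            pixel_size_nm=registered.pixel_size_nm,
            params=seg_params,
            mask=img_of[c].mask,
        )
        for c in channels
    }
    synapses = detect_synapses(puncta[synapse_channel], nuc, min_area_um2)
    assignments = {
        c: colocalize(synapses, puncta[c], coloc_radius_um)
        for c in channels
        if c != synapse_channel
    }
    # the synapsin channel colocalizes with itself trivially
    self_assign = pd.DataFrame(
        {
            "synapse_id": synapses.table["id"],
            "punctum_id": synapses.table["id"],
            "distance_um": 0.0,
        }
    )
    assignments = {synapse_channel: self_assign, **assignments}

    puncta_for_features = dict(puncta)
    puncta_for_features["__synapsin_labels__"] = puncta[synapse_channel].labels
    corrected_images = {
        c: registered.get(c).data
        for c in non_synaptic_channels
        if c in registered.channels()
    }
    features = extract_features(
        synapses,
        assignments,
        puncta_for_features,
        corrected_images=corrected_images,
        non_synaptic_channels=tuple(
            c for c in non_synaptic_channels if c in corrected_images
        ),
        well=well,
        image_id=image_id,
    )
    result = {
        "registered": registered,
        "shifts": shift_table,
        "puncta": puncta,
        "nuclear_mask": nuc,
        "synapses": synapses,
        "assignments": assignments,
        "features": features,
    }
    if out_dir is not None:
        _persist(result, Path(out_dir), seg_params)
    return result


def _persist(result: dict, out: Path, seg_params: SegmentationParams) -> None:
    import tifffile

    out.mkdir(parents=True, exist_ok=True)
    result["shifts"].to_csv(out / "shifts.csv", index=False)
    result["features"].to_csv(out / "synapse_features.csv", index=False)
    result["synapses"].table.to_csv(out / "synapses.csv", index=False)
    for c, ps in result["puncta"].items():
        ps.table.to_csv(out / f"puncta_{c}.csv", index=False)
        tifffile.imwrite(out / f"labels_{c}.tif", ps.labels.astype(np.uint16))
    if result["nuclear_mask"] is not None:
        tifffile.imwrite(
            out / "nuclear_mask.tif", result["nuclear_mask"].astype(np.uint8)
        )
    provenance = {
        "package_version": __version__,
        "python": platform.python_version(),
        "segmentation_params": asdict(seg_params),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))


def run_simulated_pipeline(sim_config=None, out_dir: str | Path | None = None) -> dict:
    """Simulate a confocal dataset and profile it end to end."""
    from .simulate import SimConfig, simulate_confocal_dataset

    cfg = sim_config or SimConfig()
    image_set, gt = simulate_confocal_dataset(cfg)
    result = profile_image_set(
        image_set,
        synapse_channel=cfg.synaptic_channels[0],
        reference_channel=cfg.reference_channel,
        nuclear_channel=cfg.nuclear_channel,
        max_shift=max(cfg.drift_max_px + 2, 5),
        out_dir=out_dir,
    )
    result["ground_truth"] = gt
    result["sim_config"] = cfg
    return result
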