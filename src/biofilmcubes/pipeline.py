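"""End-to-end pipeline: synthetic scene -> render -> segment -> cubes -> profiles.

One global seed is split deterministically into per-stage substreams (scene,
optics, events) so stages are reproducible yet statistically independent.
Every run writes a manifest (config echo, seeds, library versions, per-stage
parameters such as the Otsu thresholds) sufficient to re-run it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cytometry, quantification, segmentation, synthetic
from .config import RunConfig
from .image_io import ImageStack, write_cube_table, write_mask, write_stack

__all__ = ["run_pipeline", "split_seed", "segment_stack"]

logger = logging.getLogger(__name__)


def split_seed(seed: int, n: int = 3) -> list[int]:
    """Deterministically derive n independent per-stage seeds (< 2**31)."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def segment_stack(
    stack: ImageStack,
    channels: list[str],
    smooth_radius_vox: int = 1,
    n_bins: int = 256,
):
    """Upsample, smooth and segment each channel; return masks + thresholds.

    Returns ``(iso_raw, per_channel_masks, merged_mask, otsu_results)`` where
    ``iso_raw`` is the isotropic but *unsmoothed* stack (raw intensities for
    downstream measurement) and masks come from the smoothed volume.
    """
    iso = segmentation.upsample_to_isotropic(stack)
    smoothed = segmentation.smooth(iso, smooth_radius_vox)
    masks: dict[str, segmentation.BinaryMask] = {}
    otsu: dict[str, segmentation.OtsuResult] = {}
    for ch in channels:
        mask, result = segmentation.segment(smoothed, ch, n_bins=n_bins)
        masks[ch] = mask
        otsu[ch] = result
    merged = segmentation.merge_masks(list(masks.values()))
    return iso, masks, merged, otsu


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full synthetic pipeline and write all artifacts.

    Stages: scene generation -> rendering -> per-channel segmentation ->
    mask merge -> cube dissection -> local density -> positivity
    classification -> surface/roughness -> z profile -> event gating.
    Any stage failure is re-raised with the stage name in the message.
    """
    out = Path(out_dir if out_dir is not None else config.paths.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene_seed, optics_seed, events_seed = split_seed(config.seed, 3)
    artifacts: dict[str, object] = {}
    manifest: dict = {
        "biofilmcubes_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.model_dump(),
        "seed": config.seed,
        "stage_seeds": {
            "scene": scene_seed,
            "optics": optics_seed,
            "events": events_seed,
        },
    }

    stage = "synth"
    try:
        scene = synthetic.generate_scene(
            config.synthetic.scene.to_params(),
            domain_size_um=config.synthetic.scene.domain_size_um,
            seed=scene_seed,
        )
        truth = synthetic.scene_to_table(scene)
        truth.to_csv(out / "scene_truth.csv", index=False, lineterminator="\n")
        channels = list(config.synthetic.channels)
        optics = config.synthetic.optics.to_params(channels, seed=optics_seed)
        stack = synthetic.render_scene(scene, optics, channels)
        write_stack(stack, out / "stack.tif")

        stage = "segment"
        seg_channels = [c for c in config.segmentation.channels if c in channels]
        if not seg_channels:
            seg_channels = channels[:1]
        iso, masks, merged, otsu = segment_stack(
            stack,
            seg_channels,
            smooth_radius_vox=config.segmentation.smooth_radius_vox,
            n_bins=config.segmentation.n_bins,
        )
        for ch, m in masks.items():
            write_mask(m, out / f"mask_{ch}.tif")
        write_mask(merged, out / "mask_merged.tif")
        manifest["otsu"] = {
            ch: {
                "t1": r.t1,
                "t2": r.t2,
                "foreground_fraction": float(masks[ch].voxels.mean()),
            }
            for ch, r in otsu.items()
        }

        stage = "quantify"
        q = config.quantification
        cubes = quantification.dissect(
            merged, iso, cube_side_vox=q.cube_side_vox, min_occupancy=q.min_occupancy
        )
        cubes = quantification.annotate_local_density(
            cubes, merged, radius_um=q.density_radius_um
        )
        if len(masks) > 1:
            cubes = quantification.classify_cubes(
                cubes, masks, cube_side_vox=q.cube_side_vox,
                min_overlap_vox=q.min_overlap_vox,
            )
        write_cube_table(cubes, out / "cubes.csv")
        artifacts["cubes"] = cubes

        stage = "profiles"
        surface = quantification.height_map(merged)
        surface = quantification.roughness_map(surface, window_px=q.roughness_window_px)
        np.savetxt(out / "height_um.csv", surface.height_um, delimiter=",", fmt="%.6g")
        np.savetxt(
            out / "roughness_um.csv", surface.roughness_um, delimiter=",", fmt="%.6g"
        )
        profile = quantification.density_z_profile(cubes, z_bin_um=q.z_bin_um)
        pd.DataFrame(
            {
                "z_lo_um": profile.bin_edges[:-1],
                "z_hi_um": profile.bin_edges[1:],
                "mean_local_density": profile.values,
                "n_cubes": profile.n_per_bin,
            }
        ).to_csv(out / "density_z_profile.csv", index=False, lineterminator="\n")
        artifacts["surface"] = surface
        artifacts["profile"] = profile

        stage = "gate"
        mix = config.synthetic.mixture.to_params(seed=events_seed)
        events = synthetic.generate_events(mix)
        events.to_csv(out / "events.csv", index=False, lineterminator="\n")
        gate = cytometry.gate_on_off(
            events,
            config.cytometry.channel,
            threshold=config.cytometry.threshold,
            cofactor=config.cytometry.cofactor,
        )
        pd.DataFrame(
            [
                {
                    "channel": config.cytometry.channel,
                    "threshold": gate.threshold,
                    "fraction_on_pct": gate.fraction_on,
                    "fraction_off_pct": gate.fraction_off,
                    "n_events": gate.n_events,
                }
            ]
        ).to_csv(out / "gates.csv", index=False, float_format="%.10g", lineterminator="\n")
        artifacts["gate"] = gate
        manifest["gate"] = {
            "threshold": gate.threshold,
            "fraction_on_pct": gate.fraction_on,
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = manifest
    artifacts["out_dir"] = out
    return artifacts
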