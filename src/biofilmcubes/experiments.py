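"""Reproducible in-silico validation experiments.

Each function builds a ground-truthed synthetic scene, runs the full
measurement chain (render -> upsample -> smooth -> per-channel Otsu ->
merge -> dissect -> local density -> classification), and returns both the
pipeline's readout and the scene truth, so recovery can be judged without
access to any intermediate.  These are the package's own end-to-end checks
of the biology the generator encodes: mutually exclusive curli/flagella
expression, curli confined to dense aggregates, partially sigma-S-coupled
curli, slow-growing (high TIMER ratio) aggregates, and bimodal ON/OFF
cytometry distributions.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from . import quantification as quant
from . import synthetic
from .cytometry import gate_on_off
from .image_io import BinaryMask
from .pipeline import segment_stack, split_seed
from .synthetic import MixtureParams, OpticsParams, SceneParams

__all__ = [
    "dual_reporter_recovery",
    "sigmaS_subpopulation_recovery",
    "timer_ratio_recovery",
    "gating_recovery",
    "roughness_contrast",
]

_DOMAIN = (64.0, 64.0, 64.0)


def _run_scene(
    scene_params: SceneParams,
    optics: OpticsParams,
    channels: tuple[str, ...],
    segment_channels: list[str],
    seed: int,
    cube_side_vox: int = 5,
    density_radius_um: float = 3.0,
):
    """Generate, render and quantify one scene; return (scene, masks, cubes)."""
    scene_seed, optics_seed = split_seed(seed, 2)
    scene = synthetic.generate_scene(scene_params, domain_size_um=_DOMAIN, seed=scene_seed)
    stack = synthetic.render_scene(
        scene, synthetic.with_seed(optics, optics_seed), channels
    )
    iso, masks, merged, _ = segment_stack(stack, segment_channels)
    cubes = quant.dissect(merged, iso, cube_side_vox=cube_side_vox)
    cubes = quant.annotate_local_density(cubes, merged, radius_um=density_radius_um)
    cubes = quant.classify_cubes(cubes, masks, cube_side_vox=cube_side_vox)
    return scene, masks, merged, cubes


def dual_reporter_recovery(seed: int) -> dict:
    """Exclusivity and density association of curli vs flagella reporters.

    Default scene (no double positives by construction, curli concentrated in
    aggregates) imaged with default blur and noise in dual-reporter mode (no
    constitutive marker: each channel segmented individually, masks merged).
    Returns the double-positive cube fraction, the rank correlation between
    per-cube raw curli and flagella intensities, and the mean local density
    of curli-positive vs flagella-positive cubes.
    """
    params = SceneParams(epsilon_double=0.0)
    _, _, _, cubes = _run_scene(
        params,
        OpticsParams(),
        ("curli", "flagella"),
        ["curli", "flagella"],
        seed,
    )
    double = cubes["positive_curli"] & cubes["positive_flagella"]
    rho = spearmanr(cubes["mean_curli"], cubes["mean_flagella"]).statistic
    return {
        "n_cubes": len(cubes),
        "double_positive_fraction": float(double.mean()),
        "rank_correlation": float(rho),
        "density_curli": float(cubes.loc[cubes["positive_curli"], "local_density"].mean()),
        "density_flagella": float(
            cubes.loc[cubes["positive_flagella"], "local_density"].mean()
        ),
    }


def sigmaS_subpopulation_recovery(seed: int) -> dict:
    """Detection of the sigma-S-high / curli-OFF subpopulation.

    A singles-only scene with partial sigma-S/curli coupling is imaged with a
    constitutive marker (so all cells contribute biomass cubes) plus curli
    and sigma-S reporters.  Every cell has the same footprint, so the cube
    fraction is directly comparable to the cell fraction.  The curli-ON share
    is set to 0.35, a bimodal planktonic population in which both reporter
    classes carry enough signal mass for global thresholding.  The detected
    fraction is the share of biomass cubes positive for sigma-S but not for
    curli; the truth is the corresponding cell fraction in the scene.
    """
    params = SceneParams(
        n_single=1200,
        n_aggregates=0,
        p_curli_given_single=0.35,
        rho_sigmaS=0.8,
        p_sigmaS_high_given_curli_off=0.2,
    )
    scene, _, _, cubes = _run_scene(
        params,
        OpticsParams(),
        ("constitutive", "curli", "sigmaS"),
        ["constitutive", "curli", "sigmaS"],
        seed,
    )
    truth = synthetic.scene_truth_summary(scene)["on_fractions"]["sigmaS_high_curli_off"]
    detected = float(
        (cubes["positive_sigmaS"] & ~cubes["positive_curli"]).mean()
    )
    return {"detected_fraction": detected, "truth_fraction": float(truth)}


def timer_ratio_recovery(seed: int) -> dict:
    """Recovery of class-wise TIMER orange/green ratios and density ordering.

    Slow-growing aggregates carry ratio 2.0, fast singles 0.5.  The render is
    noise-free (the criterion isolates ratio arithmetic from shot noise);
    segmentation runs on the green channel, which labels every cell.  Cubes
    are assigned to their true class by proximity to the known aggregate
    centres.
    """
    params = SceneParams(timer_ratio_aggregate=2.0, timer_ratio_single=0.5)
    optics = OpticsParams(
        poisson_noise=False, read_noise_sd=0.0, background_level=0.0
    )
    scene, _, _, cubes = _run_scene(
        params,
        optics,
        ("timer_green", "timer_orange"),
        ["timer_green"],
        seed,
    )
    ratios = quant.timer_ratio(cubes)
    cubes = cubes.loc[ratios.index]
    centers = np.asarray(scene.aggregate_centers_um)
    pts = cubes[["com_z_um", "com_y_um", "com_x_um"]].to_numpy()
    d = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2).min(axis=1)
    is_agg = d <= params.aggregate_radius_um + 1.0
    tertiles = np.quantile(cubes["local_density"], [1 / 3, 2 / 3])
    top = cubes["local_density"] >= tertiles[1]
    bottom = cubes["local_density"] <= tertiles[0]
    return {
        "mean_ratio_aggregate": float(ratios[is_agg].mean()),
        "mean_ratio_single": float(ratios[~is_agg].mean()),
        "truth_ratio_aggregate": params.timer_ratio_aggregate,
        "truth_ratio_single": params.timer_ratio_single,
        "mean_ratio_top_density_tertile": float(ratios[top.to_numpy()].mean()),
        "mean_ratio_bottom_density_tertile": float(ratios[bottom.to_numpy()].mean()),
    }


def gating_recovery(seed: int, mix: MixtureParams | None = None) -> dict:
    """Auto-threshold ON-fraction estimate vs the seeded truth labels."""
    if mix is None:
        mix = MixtureParams()
    events = synthetic.generate_events(synthetic.with_seed(mix, seed))
    truth = 100.0 * float((events["truth_label"] == "on").mean())
    result = gate_on_off(events, "value")
    return {
        "estimated_on_pct": result.fraction_on,
        "truth_on_pct": truth,
        "abs_error_pp": abs(result.fraction_on - truth),
    }


def roughness_contrast(seed: int, window_px: int = 11) -> dict:
    """Mean surface roughness of an aggregate scene vs an ideal flat slab."""
    scene_seed, optics_seed = split_seed(seed, 2)
    scene = synthetic.generate_scene(SceneParams(), domain_size_um=_DOMAIN, seed=scene_seed)
    stack = synthetic.render_scene(
        scene, synthetic.with_seed(OpticsParams(), optics_seed), ("constitutive",)
    )
    _, _, merged, _ = segment_stack(stack, ["constitutive"])

    surface = quant.roughness_map(quant.height_map(merged), window_px=window_px)
    structured = float(np.nanmean(surface.roughness_um))

    slab_vox = np.zeros_like(merged.voxels)
    slab_vox[: merged.voxels.shape[0] // 3] = True
    slab = BinaryMask(slab_vox, merged.spacing_um)
    flat_surface = quant.roughness_map(quant.height_map(slab), window_px=window_px)
    flat = float(np.nanmean(flat_surface.roughness_um))
    return {"structured_mean_roughness_um": structured, "flat_mean_roughness_um": flat}
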