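"""Ground-truthed synthetic biofilm scenes, renders and cytometry events.

The generator emulates the structure of a static submerged *E. coli* biofilm
as seen by confocal microscopy: dense spherical aggregates/microcolonies of
curli-expressing cells concentrated in the lower tens of micrometres of the
well, motile flagella-expressing single cells suspended in the surrounding
volume, and an optional pellicle slab near the liquid surface.  Every cell
carries a full expression state (curli, flagella, sigma-S level, TIMER
green/orange amounts), so each downstream pipeline stage can be checked
against known truth.

Three expression subpopulations are modelled: flagella-ON motile singles,
curli-ON stationary aggregate cells, and stationary cells expressing neither.
Curli and flagella are mutually exclusive except for a mixing probability
``epsilon_double`` with which a cell is forced double-positive.  Sigma-S
activity is only partially coupled to curli state: curli-OFF cells are
sigma-S-high with probability ``p_sigmaS_high_given_curli_off``, and the
coupling strength ``rho_sigmaS`` interpolates the curli-ON probability
between that baseline (rho = 0) and certainty (rho = 1).

TIMER is modelled through its orange/green ratio: green amount fixed at 1,
orange amount equal to the class ratio (slow-growing aggregates high, fast
singles low).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import ImageStack

__all__ = [
    "CellClass",
    "Cell",
    "SceneParams",
    "Scene",
    "OpticsParams",
    "MixtureParams",
    "PackingError",
    "CHANNELS",
    "generate_scene",
    "render_scene",
    "generate_events",
    "scene_truth_summary",
    "scene_to_table",
]

#: Channels the renderer understands.
CHANNELS = (
    "constitutive",
    "curli",
    "flagella",
    "sigmaS",
    "timer_green",
    "timer_orange",
)


class PackingError(ValueError):
    """Requested aggregates cannot fit in the domain."""


class CellClass(str, Enum):
    SINGLE = "single"
    AGGREGATE = "aggregate"
    PELLICLE = "pellicle"


@dataclass(frozen=True)
class Cell:
    """One bacterium: position, shape and expression state."""

    center_um: tuple[float, float, float]  # (z, y, x)
    radii_um: tuple[float, float, float]  # spheroid semi-axes (z, y, x)
    cell_class: CellClass
    curli_on: bool
    flagella_on: bool
    sigmaS_level: float
    timer_green: float
    timer_orange: float

    @property
    def timer_ratio(self) -> float:
        return self.timer_orange / self.timer_green


@dataclass(frozen=True)
class SceneParams:
    """Population structure of a synthetic scene.

    Counts, probabilities and geometry defaults describe a 24-h submerged
    biofilm: a handful of dense aggregates low in the well, a dilute field
    of motile singles, curli expression concentrated in aggregates
    (p = 0.9 there vs 0.05 among singles) and flagellar expression confined
    to singles.  All values are configurable; none is calibrated to a
    particular imaging system.
    """

    n_single: int = 1000
    n_aggregates: int = 6
    cells_per_aggregate: int = 150
    aggregate_radius_um: float = 5.0
    aggregate_zmax_um: float = 40.0
    singles_clearance_um: float = 2.0
    p_curli_given_aggregate: float = 0.9
    p_curli_given_single: float = 0.05
    p_flagella_given_single: float = 0.9
    p_flagella_given_aggregate: float = 0.0
    epsilon_double: float = 0.0
    rho_sigmaS: float = 0.8
    p_sigmaS_high_given_curli_off: float = 0.2
    sigmaS_low_level: float = 0.05
    timer_ratio_aggregate: float = 2.0
    timer_ratio_single: float = 0.5
    timer_ratio_pellicle: float = 1.5
    pellicle: bool = False
    n_pellicle: int = 400
    pellicle_thickness_um: float = 12.0
    cell_radii_um: tuple[float, float, float] = (1.0, 0.5, 0.5)

    def __post_init__(self) -> None:
        probs = {
            "p_curli_given_aggregate": self.p_curli_given_aggregate,
            "p_curli_given_single": self.p_curli_given_single,
            "p_flagella_given_single": self.p_flagella_given_single,
            "p_flagella_given_aggregate": self.p_flagella_given_aggregate,
            "epsilon_double": self.epsilon_double,
            "p_sigmaS_high_given_curli_off": self.p_sigmaS_high_given_curli_off,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]; got {p}")
        if not -1.0 <= self.rho_sigmaS <= 1.0:
            raise ValueError(f"rho_sigmaS must be in [-1, 1]; got {self.rho_sigmaS}")
        for name in ("n_single", "n_aggregates", "cells_per_aggregate", "n_pellicle"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class Scene:
    """Ground truth: cells with positions, classes and expression states."""

    cells: list[Cell]
    domain_size_um: tuple[float, float, float]  # (z, y, x) extents
    pellicle_z_um: float | None
    params: SceneParams
    seed: int
    aggregate_centers_um: list[tuple[float, float, float]] = field(default_factory=list)


@dataclass(frozen=True)
class OpticsParams:
    """Imaging model: voxel grid, Gaussian PSF, photon and read noise.

    Defaults approximate a confocal microscope sampling at (1.0, 0.5, 0.5) um
    with a PSF sigma of 0.4 um axially and 0.15 um laterally; signal photons
    are Poisson distributed on top of a uniform background, with additive
    Gaussian read noise.
    """

    voxel_spacing_um: tuple[float, float, float] = (1.0, 0.5, 0.5)
    psf_sigma_um: tuple[float, float, float] = (0.4, 0.15, 0.15)
    amplitude_per_state: dict = field(
        default_factory=lambda: {c: (150.0, 0.0) for c in CHANNELS}
    )
    read_noise_sd: float = 2.0
    poisson_noise: bool = True
    background_level: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing_um):
            raise ValueError("voxel spacings must be positive")
        for ch, (on, off) in self.amplitude_per_state.items():
            if not on >= off >= 0:
                raise ValueError(
                    f"channel {ch!r}: need on_level >= off_level >= 0; got ({on}, {off})"
                )


@dataclass(frozen=True)
class MixtureParams:
    """Two-component ON/OFF mixture for flow-cytometry-like events.

    OFF events are drawn from a signed normal component centred near zero
    (the scale left after background subtraction; negative values are
    expected).  ON events are log-normal: ``exp(N(mu_on, sd_on))``.
    """

    f_on: float = 0.30
    mu_off: float = 0.0
    sd_off: float = 60.0
    mu_on: float = 8.0
    sd_on: float = 0.5
    n_events: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_on <= 1.0:
            raise ValueError(f"f_on must be in [0, 1]; got {self.f_on}")
        if self.sd_off <= 0 or self.sd_on <= 0:
            raise ValueError("sd_off and sd_on must be positive")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


def _p_sigmaS_high_given_curli_on(params: SceneParams) -> float:
    """Interpolate between the curli-OFF baseline (rho=0) and certainty (rho=1)."""
    p0 = params.p_sigmaS_high_given_curli_off
    rho = params.rho_sigmaS
    if rho >= 0:
        return p0 + rho * (1.0 - p0)
    return p0 * (1.0 + rho)


def _draw_states(
    rng: np.random.Generator,
    params: SceneParams,
    cell_class: CellClass,
    n: int,
):
    """Vectorized expression-state draws for n cells of one class."""
    if cell_class is CellClass.AGGREGATE:
        p_curli = params.p_curli_given_aggregate
        p_flag = params.p_flagella_given_aggregate
        ratio = params.timer_ratio_aggregate
    elif cell_class is CellClass.SINGLE:
        p_curli = params.p_curli_given_single
        p_flag = params.p_flagella_given_single
        ratio = params.timer_ratio_single
    else:
        p_curli = params.p_curli_given_aggregate
        p_flag = params.p_flagella_given_aggregate
        ratio = params.timer_ratio_pellicle

    double = rng.random(n) < params.epsilon_double
    curli = rng.random(n) < p_curli
    flagella = ~curli & (rng.random(n) < p_flag)
    curli = curli | double
    flagella = flagella | double

    p_high_on = _p_sigmaS_high_given_curli_on(params)
    p_high = np.where(curli, p_high_on, params.p_sigmaS_high_given_curli_off)
    sigma_high = rng.random(n) < p_high
    sigma_level = np.where(sigma_high, 1.0, params.sigmaS_low_level)

    green = np.ones(n)
    orange = np.full(n, ratio)
    return curli, flagella, sigma_level, green, orange


def generate_scene(
    params: SceneParams,
    domain_size_um: tuple[float, float, float] = (64.0, 64.0, 64.0),
    seed: int = 0,
) -> Scene:
    """Draw a ground-truthed scene: positions, classes and expression states.

    Aggregate centres are uniform in x/y and confined below
    ``aggregate_zmax_um``; members are uniform in a ball of
    ``aggregate_radius_um`` around their centre.  Singles are uniform in the
    free volume, i.e. rejected from aggregate balls inflated by
    ``singles_clearance_um`` (a single cell cannot sit inside a dense
    aggregate).  Pellicle cells, if enabled, fill a slab of
    ``pellicle_thickness_um`` at the top of the domain.

    Identical ``(params, seed)`` reproduce an identical scene.
    """
    rng = np.random.default_rng(seed)
    dz, dy, dx = (float(v) for v in domain_size_um)
    r_agg = params.aggregate_radius_um

    agg_volume = params.n_aggregates * (4.0 / 3.0) * np.pi * r_agg**3
    if agg_volume > dz * dy * dx:
        raise PackingError(
            f"requested aggregate volume ({agg_volume:.0f} um^3) exceeds the "
            f"domain volume ({dz * dy * dx:.0f} um^3)"
        )
    zmax_centers = min(params.aggregate_zmax_um, dz)
    if params.n_aggregates > 0 and zmax_centers < r_agg:
        raise PackingError(
            "aggregate_zmax_um too small to hold an aggregate of radius "
            f"{r_agg} um"
        )

    cells: list[Cell] = []
    agg_centers: list[tuple[float, float, float]] = []

    # aggregate cluster centres: uniform in x/y (with margin), low in z
    for _ in range(params.n_aggregates):
        cz = rng.uniform(r_agg, zmax_centers)
        cy = rng.uniform(r_agg, max(dy - r_agg, r_agg))
        cx = rng.uniform(r_agg, max(dx - r_agg, r_agg))
        agg_centers.append((cz, cy, cx))

    def _append(centers: np.ndarray, cell_class: CellClass) -> None:
        n = len(centers)
        curli, flagella, sigma, green, orange = _draw_states(rng, params, cell_class, n)
        for i in range(n):
            cells.append(
                Cell(
                    center_um=tuple(float(v) for v in centers[i]),
                    radii_um=params.cell_radii_um,
                    cell_class=cell_class,
                    curli_on=bool(curli[i]),
                    flagella_on=bool(flagella[i]),
                    sigmaS_level=float(sigma[i]),
                    timer_green=float(green[i]),
                    timer_orange=float(orange[i]),
                )
            )

    for center in agg_centers:
        # uniform in a ball around the cluster centre, clipped into the domain
        u = rng.normal(size=(params.cells_per_aggregate, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        rad = r_agg * rng.random(params.cells_per_aggregate) ** (1.0 / 3.0)
        pos = np.asarray(center) + u * rad[:, None]
        pos = np.clip(pos, 0.0, [dz, dy, dx])
        _append(pos, CellClass.AGGREGATE)

    # singles: rejection sampling outside inflated aggregate balls
    singles: list[np.ndarray] = []
    r_excl = r_agg + params.singles_clearance_um
    centers_arr = np.asarray(agg_centers).reshape(-1, 3)
    max_tries = 1000 * max(params.n_single, 1)
    tries = 0
    while len(singles) < params.n_single:
        tries += 1
        if tries > max_tries:
            raise PackingError(
                "free volume too small to place the requested single cells"
            )
        p = rng.uniform([0.0, 0.0, 0.0], [dz, dy, dx])
        if centers_arr.size and (
            np.linalg.norm(centers_arr - p, axis=1) < r_excl
        ).any():
            continue
        singles.append(p)
    if singles:
        _append(np.asarray(singles), CellClass.SINGLE)

    pellicle_z = None
    if params.pellicle and params.n_pellicle > 0:
        half = params.pellicle_thickness_um / 2.0
        pellicle_z = dz - half
        lo = max(dz - params.pellicle_thickness_um, 0.0)
        pos = rng.uniform([lo, 0.0, 0.0], [dz, dy, dx], size=(params.n_pellicle, 3))
        _append(pos, CellClass.PELLICLE)

    return Scene(
        cells=cells,
        domain_size_um=(dz, dy, dx),
        pellicle_z_um=pellicle_z,
        params=params,
        seed=seed,
        aggregate_centers_um=agg_centers,
    )


def _cell_amplitude(cell: Cell, channel: str, on: float, off: float) -> float:
    if channel == "constitutive":
        return on
    if channel == "curli":
        return on if cell.curli_on else off
    if channel == "flagella":
        return on if cell.flagella_on else off
    if channel == "sigmaS":
        return off + (on - off) * cell.sigmaS_level
    if channel == "timer_green":
        return on * cell.timer_green
    if channel == "timer_orange":
        return on * cell.timer_orange
    raise KeyError(f"unknown channel {channel!r}; known: {CHANNELS}")


def render_scene(
    scene: Scene,
    optics: OpticsParams,
    channels: tuple[str, ...] | list[str] = ("constitutive",),
) -> ImageStack:
    """Rasterize a scene to a noisy multi-channel stack.

    Each cell is a solid spheroid: every voxel whose centre lies inside the
    ellipsoid receives the cell's state-dependent amplitude (amplitudes of
    overlapping cells add, as photons do).  The volume is then blurred by a
    Gaussian PSF, background is added, and Poisson shot noise plus Gaussian
    read noise are applied if enabled.
    """
    for ch in channels:
        if ch not in CHANNELS:
            raise KeyError(f"unknown channel {ch!r}; known: {CHANNELS}")
        if ch not in optics.amplitude_per_state:
            raise KeyError(f"no amplitude configured for channel {ch!r}")

    sz, sy, sx = optics.voxel_spacing_um
    dz, dy, dx = scene.domain_size_um
    shape = (
        max(int(round(dz / sz)), 1),
        max(int(round(dy / sy)), 1),
        max(int(round(dx / sx)), 1),
    )
    spacing = np.array([sz, sy, sx])

    vol = np.zeros((len(channels),) + shape, dtype=np.float64)
    amps = {ch: optics.amplitude_per_state[ch] for ch in channels}

    for cell in scene.cells:
        c = np.asarray(cell.center_um)
        r = np.asarray(cell.radii_um)
        lo = np.maximum(np.floor((c - r) / spacing - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil((c + r) / spacing - 0.5).astype(int) + 1, shape)
        if (hi <= lo).any():
            continue
        zz = ((np.arange(lo[0], hi[0]) + 0.5) * sz - c[0]) / r[0]
        yy = ((np.arange(lo[1], hi[1]) + 0.5) * sy - c[1]) / r[1]
        xx = ((np.arange(lo[2], hi[2]) + 0.5) * sx - c[2]) / r[2]
        inside = (
            zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
        ) <= 1.0
        if not inside.any():
            continue
        for ci, ch in enumerate(channels):
            on, off = amps[ch]
            a = _cell_amplitude(cell, ch, on, off)
            if a != 0.0:
                vol[ci, lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]][inside] += a

    sigma_vox = np.asarray(optics.psf_sigma_um) / spacing
    if (sigma_vox > 0).any():
        for ci in range(len(channels)):
            vol[ci] = ndimage.gaussian_filter(vol[ci], sigma=sigma_vox, mode="constant")

    vol += optics.background_level
    rng = np.random.default_rng(optics.seed)
    if optics.poisson_noise:
        vol = rng.poisson(np.maximum(vol, 0.0)).astype(np.float64)
    if optics.read_noise_sd > 0:
        vol = vol + rng.normal(0.0, optics.read_noise_sd, size=vol.shape)
    return ImageStack(
        voxels=vol.astype(np.float32),
        spacing_um=(sz, sy, sx),
        channel_names=list(channels),
    )


def generate_events(mix: MixtureParams) -> pd.DataFrame:
    """Draw a flow-cytometry-like event table from a two-component mixture.

    Returns a DataFrame with a signed ``value`` column and a ground-truth
    ``truth_label`` column ("on"/"off").  ON values are log-normal (always
    positive); OFF values are normal around ``mu_off`` and may be negative,
    as expected after background subtraction.
    """
    rng = np.random.default_rng(mix.seed)
    on = rng.random(mix.n_events) < mix.f_on
    values = np.empty(mix.n_events)
    n_on = int(on.sum())
    values[on] = np.exp(rng.normal(mix.mu_on, mix.sd_on, size=n_on))
    values[~on] = rng.normal(mix.mu_off, mix.sd_off, size=mix.n_events - n_on)
    return pd.DataFrame(
        {"value": values, "truth_label": np.where(on, "on", "off")}
    )


def scene_to_table(scene: Scene) -> pd.DataFrame:
    """Flatten a scene to one row per cell (the ground-truth table on disk)."""
    rows = [
        {
            "z_um": c.center_um[0],
            "y_um": c.center_um[1],
            "x_um": c.center_um[2],
            "cell_class": c.cell_class.value,
            "curli_on": c.curli_on,
            "flagella_on": c.flagella_on,
            "sigmaS_level": c.sigmaS_level,
            "timer_green": c.timer_green,
            "timer_orange": c.timer_orange,
        }
        for c in scene.cells
    ]
    return pd.DataFrame(rows)


def scene_truth_summary(scene: Scene) -> dict:
    """Recovery targets for end-to-end tests.

    Returns per-class counts, per-reporter ON fractions, the double-positive
    fraction and per-class mean TIMER orange/green ratios.
    """
    table = scene_to_table(scene)
    if table.empty:
        return {
            "class_counts": {},
            "on_fractions": {},
            "double_positive_fraction": 0.0,
            "timer_ratio_by_class": {},
        }
    n = len(table)
    sigma_high = table["sigmaS_level"] >= 0.5
    return {
        "class_counts": table["cell_class"].value_counts().to_dict(),
        "on_fractions": {
            "curli": float(table["curli_on"].mean()),
            "flagella": float(table["flagella_on"].mean()),
            "sigmaS_high": float(sigma_high.mean()),
            "sigmaS_high_curli_off": float((sigma_high & ~table["curli_on"]).mean()),
        },
        "double_positive_fraction": float(
            (table["curli_on"] & table["flagella_on"]).sum() / n
        ),
        "timer_ratio_by_class": (
            (table["timer_orange"] / table["timer_green"])
            .groupby(table["cell_class"])
            .mean()
            .to_dict()
        ),
    }


def with_seed(params: MixtureParams | OpticsParams, seed: int):
    """Copy a frozen parameter object with a new seed."""
    return replace(params, seed=seed)
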