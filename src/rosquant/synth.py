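"""Synthetic phantom stacks with known ground truth.

A phantom scene is an elliptical shell ring (bright in CH1 and, scaled by
the bleed-through ratio, in CH2), a dimmer interior tissue baseline in CH2,
circular ROS foci in CH2 only, and an optional gut blob in CH3.  The scene
is spread across z-slices with a per-slice intensity profile whose maximum
is 1, so the per-pixel maximum over slices recovers the scene, and additive
Gaussian sensor noise is drawn independently per channel and slice.

The experiment simulator draws per-individual true ROS fractions from a
two-level Gaussian hierarchy (treatment mean -> container offset ->
individual offset, truncated to [0, 0.99]) and renders one phantom per
individual, reproducing a containers-within-treatment design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .image_io import DEFAULT_CHANNEL_ORDER, MaskImage, ZStack, write_stack

_MAX_RESTARTS = 10
_BISECT_STEPS = 40
_AREA_RTOL = 0.02


class PhantomError(RuntimeError):
    """The requested scene is unachievable (e.g. ROS fraction too large)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic individual.

    ``ros_fraction`` is the target true ROS area as a fraction of the filled
    shell footprint; the renderer adjusts focus radii until the rasterised
    truth mask is within 2% relative of the target.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_slices: int = 3
    shell_semi_axes: tuple[float, float] = (180.0, 110.0)
    shell_orientation_deg: float = 20.0
    ring_thickness_px: float = 12.0
    shell_intensity_ch1: float = 200.0
    shell_intensity_ch2: float = 200.0
    tissue_intensity: float = 20.0
    ros_fraction: float = 0.0
    ros_object_count: int = 5
    ros_intensity: float = 180.0
    gut_present: bool = True
    gut_intensity: float = 120.0
    noise_sd: float = 3.0
    bit_depth: int = 16
    pixel_size_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ros_fraction < 1:
            raise ValueError("ros_fraction must lie in [0, 1)")
        for name in (
            "shell_intensity_ch1",
            "shell_intensity_ch2",
            "tissue_intensity",
            "ros_intensity",
            "gut_intensity",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_slices < 1:
            raise ValueError("need at least one slice")
        if self.ros_object_count < 1:
            raise ValueError("need at least one ROS focus")

    @property
    def bleed_through_ratio(self) -> float:
        return self.shell_intensity_ch2 / self.shell_intensity_ch1


def default_phantom(shape: tuple[int, int] = (512, 512), **overrides) -> PhantomSpec:
    """A plausibly proportioned spec for an arbitrary frame size."""
    m = min(shape)
    base = dict(
        image_shape=tuple(shape),
        shell_semi_axes=(0.35 * m, 0.22 * m),
        ring_thickness_px=max(3.0, m / 42.0),
    )
    base.update(overrides)
    return PhantomSpec(**base)


@dataclass(frozen=True)
class Phantom:
    """A rendered phantom with its ground-truth masks."""

    stack: ZStack
    truth_shell: MaskImage
    truth_ros: MaskImage
    spec: PhantomSpec

    @property
    def true_fraction(self) -> float:
        return self.truth_ros.area_px / self.truth_shell.area_px


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    orientation_deg: float,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    if grid is None:
        grid = np.indices(shape, dtype=np.float64)
    rows, cols = grid
    dr = rows - center[0]
    dc = cols - center[1]
    th = math.radians(orientation_deg)
    u = dc * math.cos(th) + dr * math.sin(th)
    v = -dc * math.sin(th) + dr * math.cos(th)
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _paint_foci(
    shape: tuple[int, int],
    centers: np.ndarray,
    radius: float,
    allowed: np.ndarray,
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for r, c in centers:
        rr, cc = draw_disk((r, c), radius, shape=shape)
        mask[rr, cc] = True
    return mask & allowed


def _place_foci(
    rng: np.random.Generator,
    allowed: np.ndarray,
    target_px: int,
    n_foci: int,
) -> np.ndarray:
    """Rasterise ``n_foci`` discs inside ``allowed`` whose union area equals
    ``target_px`` exactly.

    A shared radius is bisected to the smallest value whose rasterised union
    reaches the target, then the overshoot (a thin rim) is trimmed pixel by
    pixel, farthest-from-centre first, so the contract holds at any scale.
    """
    shape = allowed.shape
    candidates = np.argwhere(allowed)
    if len(candidates) == 0:
        raise PhantomError("no interior region to place ROS foci in")
    r0 = math.sqrt(target_px / (n_foci * math.pi))
    for _ in range(_MAX_RESTARTS):
        centers = candidates[rng.integers(0, len(candidates), size=n_foci)].astype(np.float64)
        hi = 1.0
        while hi < 64 and _paint_foci(shape, centers, hi * r0, allowed).sum() < target_px:
            hi *= 2.0
        if _paint_foci(shape, centers, hi * r0, allowed).sum() < target_px:
            continue  # union saturated below target; try other centers
        lo = 0.0
        for _ in range(_BISECT_STEPS):
            mid = 0.5 * (lo + hi)
            if _paint_foci(shape, centers, mid * r0, allowed).sum() >= target_px:
                hi = mid
            else:
                lo = mid
        mask = _paint_foci(shape, centers, hi * r0, allowed)
        excess = int(mask.sum()) - target_px
        if excess > 0:
            rr, cc = np.nonzero(mask)
            dist = np.min(
                (rr[:, None] - centers[:, 0]) ** 2 + (cc[:, None] - centers[:, 1]) ** 2, axis=1
            )
            drop = np.argsort(-dist, kind="stable")[:excess]
            mask[rr[drop], cc[drop]] = False
        return mask
    raise PhantomError(
        f"could not reach ROS area {target_px} px with {n_foci} foci "
        f"inside a {int(allowed.sum())} px region"
    )


def _slice_weights(n_slices: int) -> np.ndarray:
    """Per-slice scene attenuation; peaks at exactly 1 mid-stack."""
    if n_slices == 1:
        return np.ones(1)
    k = np.arange(n_slices, dtype=np.float64)
    mid = (n_slices - 1) / 2.0
    w = 1.0 - 0.5 * np.abs(k - mid) / max(mid, 1.0)
    w[int(round(mid))] = 1.0
    return w


def render_phantom(spec: PhantomSpec) -> Phantom:
    """Render one phantom stack plus its ground-truth masks.

    Deterministic for a given spec (all randomness from ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    center = (shape[0] / 2.0, shape[1] / 2.0)
    a, b = spec.shell_semi_axes
    t = spec.ring_thickness_px
    if min(a, b) <= t:
        raise PhantomError("ring thickness exceeds the shell semi-axes")

    grid = np.indices(shape, dtype=np.float64)
    outer = _ellipse_mask(shape, center, (a, b), spec.shell_orientation_deg, grid)
    inner = _ellipse_mask(shape, center, (a - t, b - t), spec.shell_orientation_deg, grid)
    ring = outer & ~inner
    if not ring.any() or not outer.any():
        raise PhantomError("shell ellipse does not intersect the frame")

    target = int(round(spec.ros_fraction * outer.sum()))
    if target > 0:
        margin = max(2.0, t / 3.0)
        core = _ellipse_mask(
            shape, center, (a - t - margin, b - t - margin), spec.shell_orientation_deg, grid
        )
        truth_ros = _place_foci(rng, core, target, spec.ros_object_count)
    else:
        truth_ros = np.zeros(shape, dtype=bool)

    ch1 = ring * spec.shell_intensity_ch1
    ch2 = (
        ring * spec.shell_intensity_ch2
        + inner * spec.tissue_intensity
        + truth_ros * spec.ros_intensity
    )
    scenes = [ch1, ch2]
    roles = list(DEFAULT_CHANNEL_ORDER[:2])
    if spec.gut_present:
        gut = _ellipse_mask(
            shape,
            (center[0], center[1] + 0.2 * b),
            (0.35 * a, 0.3 * b),
            spec.shell_orientation_deg,
            grid,
        ) & inner
        scenes.append(gut * spec.gut_intensity)
        roles.append(DEFAULT_CHANNEL_ORDER[2])

    weights = _slice_weights(spec.n_slices)
    max_val = 2**spec.bit_depth - 1
    voxels = np.empty((len(scenes), spec.n_slices, *shape), dtype=np.uint16)
    for ci, scene in enumerate(scenes):
        for zi, w in enumerate(weights):
            plane = scene * w
            if spec.noise_sd > 0:
                plane = plane + rng.normal(0.0, spec.noise_sd, size=shape)
            voxels[ci, zi] = np.clip(np.rint(plane), 0, max_val).astype(np.uint16)

    stack = ZStack(
        voxels=voxels,
        channels=tuple(roles),
        pixel_size_um=spec.pixel_size_um,
        bit_depth=spec.bit_depth,
        source=f"phantom-seed{spec.seed}",
    )
    return Phantom(
        stack=stack,
        truth_shell=MaskImage(outer, role="truth_shell"),
        truth_ros=MaskImage(truth_ros, role="truth_ros"),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# experiment simulation


@dataclass(frozen=True)
class TreatmentSpec:
    label: str
    mean_fraction: float
    between_container_sd: float = 0.0
    within_container_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.mean_fraction < 1:
            raise ValueError("mean_fraction must lie in [0, 1)")
        if self.between_container_sd < 0 or self.within_container_sd < 0:
            raise ValueError("SDs must be non-negative")


@dataclass(frozen=True)
class ExperimentDesign:
    treatments: tuple[TreatmentSpec, ...]
    containers_per_treatment: int = 3
    individuals_per_container: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.treatments) < 1:
            raise ValueError("need at least one treatment")
        if self.containers_per_treatment < 1 or self.individuals_per_container < 1:
            raise ValueError("degenerate design: containers and individuals must be >= 1")
        object.__setattr__(self, "treatments", tuple(self.treatments))

    @property
    def n_individuals(self) -> int:
        return len(self.treatments) * self.containers_per_treatment * self.individuals_per_container


def reference_design(
    containers_per_treatment: int = 3,
    individuals_per_container: int = 10,
    between_container_sd: float = 0.03,
    within_container_sd: float = 0.06,
    seed: int = 0,
) -> ExperimentDesign:
    """The six-group emersion-stress layout with reported group mean
    fractions: control 5%, dead 30%, 1h-H 26%, 1h-M 38%, 20h-H 31%,
    20h-M 16%."""
    means = {
        "control": 0.05,
        "dead": 0.30,
        "1h-H": 0.26,
        "1h-M": 0.38,
        "20h-H": 0.31,
        "20h-M": 0.16,
    }
    return ExperimentDesign(
        treatments=tuple(
            TreatmentSpec(label, m, between_container_sd, within_container_sd)
            for label, m in means.items()
        ),
        containers_per_treatment=containers_per_treatment,
        individuals_per_container=individuals_per_container,
        seed=seed,
    )


_TRUNC_LO, _TRUNC_HI = 0.0, 0.99


def simulate_true_fractions(design: ExperimentDesign) -> pd.DataFrame:
    """Draw the hierarchy of true per-individual ROS fractions.

    Returns a tidy table with one row per individual: treatment, container,
    individual_id, true_fraction, and the phantom seed that will render it.
    Deterministic for a given design seed.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    n_truncated = 0
    for trt in design.treatments:
        for ci in range(design.containers_per_treatment):
            container = f"{trt.label}-c{ci + 1}"
            offset = rng.normal(0.0, trt.between_container_sd) if trt.between_container_sd else 0.0
            for ii in range(design.individuals_per_container):
                frac = trt.mean_fraction + offset
                if trt.within_container_sd:
                    frac += rng.normal(0.0, trt.within_container_sd)
                clipped = min(max(frac, _TRUNC_LO), _TRUNC_HI)
                if clipped != frac:
                    n_truncated += 1
                rows.append(
                    {
                        "treatment": trt.label,
                        "container": container,
                        "individual_id": f"{container}-i{ii + 1}",
                        "true_fraction": clipped,
                    }
                )
    table = pd.DataFrame(rows)
    table["phantom_seed"] = rng.integers(0, 2**31 - 1, size=len(table))
    if n_truncated:
        import logging

        logging.getLogger(__name__).info(
            "truncated %d simulated fractions to [%g, %g]", n_truncated, _TRUNC_LO, _TRUNC_HI
        )
    return table


@dataclass(frozen=True)
class SimulatedExperiment:
    """Lazy handle over a simulated experiment: the truth table plus a
    deterministic per-individual phantom renderer."""

    design: ExperimentDesign
    phantom_base: PhantomSpec
    truth_table: pd.DataFrame

    def render_individual(self, row_index: int) -> Phantom:
        row = self.truth_table.iloc[row_index]
        spec = replace(
            self.phantom_base,
            ros_fraction=float(row.true_fraction),
            seed=int(row.phantom_seed),
        )
        phantom = render_phantom(spec)
        return replace(phantom, stack=phantom.stack.with_source(str(row.individual_id)))

    def iter_individuals(self) -> Iterator[tuple[pd.Series, Phantom]]:
        for i in range(len(self.truth_table)):
            yield self.truth_table.iloc[i], self.render_individual(i)

    def write(self, out_dir: str | Path, save_truth_masks: bool = False) -> pd.DataFrame:
        """Render every individual to ``out_dir`` as OME-TIFF; returns the
        labels table (file, treatment, container)."""
        from .image_io import write_mask

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        label_rows = []
        for row, phantom in self.iter_individuals():
            fname = f"{row.individual_id}.ome.tif"
            write_stack(phantom.stack, out_dir / fname)
            if save_truth_masks:
                write_mask(phantom.truth_shell, out_dir / f"{row.individual_id}_truth_shell.tif")
                write_mask(phantom.truth_ros, out_dir / f"{row.individual_id}_truth_ros.tif")
            label_rows.append(
                {"file": fname, "treatment": row.treatment, "container": row.container}
            )
        labels = pd.DataFrame(label_rows)
        labels.to_csv(out_dir / "labels.csv", index=False)
        self.truth_table.to_csv(out_dir / "truth_table.csv", index=False)
        return labels


def simulate_experiment(
    design: ExperimentDesign, phantom_base: PhantomSpec | None = None
) -> SimulatedExperiment:
    """Build the truth table and a deterministic renderer for the design."""
    phantom_base = phantom_base or default_phantom((256, 256))
    truth = simulate_true_fractions(design)
    return SimulatedExperiment(design=design, phantom_base=phantom_base, truth_table=truth)
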