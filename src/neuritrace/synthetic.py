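"""Synthetic two-channel micrographs with exact ground truth.

The generator emulates the relevant features of fixed-cell fluorescence
micrographs of neuronal cultures: bright elliptical nuclei (optionally
placed in touching pairs, as clumped nuclei are the hard case for
segmentation), somata with arborized curvilinear neurites of known total
length and branch count in the neurite channel, small staining artifacts on
both sides of the plausibility-area criterion, additive Gaussian intensity
noise and exposure variation.

Neurite polylines are generated in physical units (micrometres) and
rasterized at the frame's pixel size, so ground-truth lengths are exact by
construction and independent of resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import Calibration, Condition, MicrographFrame

#: Default synthetic frame geometry: 512 x 384 px at the reference pixel size.
DEFAULT_FRAME_WIDTH = 512
DEFAULT_FRAME_HEIGHT = 384


@dataclass(frozen=True)
class FrameSpec:
    """Generation parameters for one synthetic frame.

    Lengths are micrometres; intensities are 16-bit units.
    """

    width_px: int = DEFAULT_FRAME_WIDTH
    height_px: int = DEFAULT_FRAME_HEIGHT
    pixel_size_um: float = Calibration().pixel_size_um
    n_neurons: int = 5
    n_non_neuron_nuclei: int = 5
    soma_radius_range_px: Tuple[int, int] = (10, 15)
    nucleus_radius_range_px: Tuple[int, int] = (8, 12)
    neurites_per_neuron: Tuple[int, int] = (2, 4)
    neurite_length_um_range: Tuple[float, float] = (60.0, 160.0)
    neurite_width_px: int = 3
    branch_probability_per_um: float = 0.004
    turn_sigma_rad: float = 0.12
    step_um: float = 2.0
    clump_fraction: float = 0.0
    n_artifacts_small: int = 3
    n_artifacts_large: int = 1
    artifact_radius_small_px: Tuple[int, int] = (3, 6)
    artifact_radius_large_px: Tuple[int, int] = (10, 14)
    background_intensity: int = 1500
    neurite_intensity: int = 20000
    nucleus_intensity: int = 30000
    noise_sigma: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.neurite_width_px < 2:
            raise ValueError("neurite_width_px must be >= 2")
        for lo, hi in (
            self.soma_radius_range_px,
            self.nucleus_radius_range_px,
            self.neurite_length_um_range,
        ):
            if lo <= 0 or hi < lo:
                raise ValueError("ranges must be positive and ordered")
        for v in (self.background_intensity, self.neurite_intensity, self.nucleus_intensity):
            if not 0 <= v <= 65535:
                raise ValueError("intensities must fit 16-bit range")

    @property
    def calibration(self) -> Calibration:
        s = self.pixel_size_um
        return Calibration(self.width_px, self.height_px,
                           self.width_px * s, self.height_px * s)


@dataclass
class GroundTruth:
    """Exact per-frame generation record."""

    nuclei_count: int
    neuron_count: int
    neurite_polylines_um: List[np.ndarray] = field(default_factory=list)
    neurite_lengths_um: List[float] = field(default_factory=list)
    branch_point_count: int = 0
    soma_centers_px: List[Tuple[float, float]] = field(default_factory=list)
    soma_radii_px: List[float] = field(default_factory=list)
    artifacts: List[dict] = field(default_factory=list)

    @property
    def total_neurite_length_um(self) -> float:
        return float(sum(self.neurite_lengths_um))


def _polyline_length(points: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def _place_points(
    rng: np.random.Generator,
    n: int,
    height: int,
    width: int,
    margin: float,
    min_separation: float,
    existing: List[Tuple[float, float]],
    max_tries: int = 2000,
) -> List[Tuple[float, float]]:
    placed: List[Tuple[float, float]] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} objects without overlap (spec overcrowded)"
            )
        r = rng.uniform(margin, height - margin)
        c = rng.uniform(margin, width - margin)
        ok = all(
            math.hypot(r - pr, c - pc) >= min_separation
            for pr, pc in placed + existing
        )
        if ok:
            placed.append((r, c))
    return placed


def _grow_neurite(
    rng: np.random.Generator,
    start_px: Tuple[float, float],
    direction: float,
    length_um: float,
    spec: FrameSpec,
) -> Tuple[List[np.ndarray], int]:
    """Random-walk polyline(s) in um coordinates, with optional branching.

    Returns the list of polylines (each an (N, 2) array of (row_um, col_um))
    and the number of branch points spawned.  The walk steers away from the
    frame border so neurites stay inside the imaged field.
    """
    s = spec.pixel_size_um
    h_um, w_um = spec.height_px * s, spec.width_px * s
    margin = 4.0 * s

    queue = [(np.array([start_px[0] * s, start_px[1] * s]), direction, length_um)]
    polylines: List[np.ndarray] = []
    branch_points = 0
    while queue:
        pos, ang, remaining = queue.pop(0)
        pts = [pos.copy()]
        while remaining > 1e-9:
            step = min(spec.step_um, remaining)
            ang += rng.normal(0.0, spec.turn_sigma_rad)
            nxt = pos + step * np.array([math.sin(ang), math.cos(ang)])
            # steer back from the border instead of clipping (keeps length exact)
            if not (margin < nxt[0] < h_um - margin and margin < nxt[1] < w_um - margin):
                center = np.array([h_um / 2, w_um / 2])
                ang = math.atan2(*(center - pos))
                nxt = pos + step * np.array([math.sin(ang), math.cos(ang)])
            pos = nxt
            pts.append(pos.copy())
            remaining -= step
            if (
                remaining > 10.0
                and rng.uniform() < spec.branch_probability_per_um * step
            ):
                branch_points += 1
                split = rng.uniform(0.3, 0.7) * remaining
                queue.append((pos.copy(), ang + rng.choice([-1, 1]) * rng.uniform(0.5, 1.0), split))
                remaining -= split
        if len(pts) > 1:
            polylines.append(np.array(pts))
    return polylines, branch_points


def _rasterize_polylines(
    polylines_um: Sequence[np.ndarray], spec: FrameSpec, canvas: np.ndarray
) -> None:
    from skimage.draw import line

    s = spec.pixel_size_um
    for poly in polylines_um:
        px = np.round(poly / s).astype(int)
        px[:, 0] = np.clip(px[:, 0], 0, spec.height_px - 1)
        px[:, 1] = np.clip(px[:, 1], 0, spec.width_px - 1)
        for (r0, c0), (r1, c1) in zip(px[:-1], px[1:]):
            rr, cc = line(r0, c0, r1, c1)
            canvas[rr, cc] = True


def generate_frame(spec: FrameSpec) -> Tuple[MicrographFrame, GroundTruth]:
    """Generate one synthetic two-channel frame with exact ground truth.

    Deterministic for a given spec (including its seed).
    """
    from skimage.draw import disk as draw_disk, ellipse as draw_ellipse
    from skimage.morphology import disk as disk_fp

    rng = np.random.default_rng(spec.seed)
    H, W = spec.height_px, spec.width_px
    truth = GroundTruth(nuclei_count=0, neuron_count=spec.n_neurons)

    soma_margin = max(spec.soma_radius_range_px[1] + 6, 20)
    soma_sep = 4.0 * spec.soma_radius_range_px[1]
    soma_centers = _place_points(rng, spec.n_neurons, H, W, soma_margin, soma_sep, [])

    neurite_fg = np.zeros((H, W), dtype=bool)
    soma_mask = np.zeros((H, W), dtype=bool)
    nucleus_mask = np.zeros((H, W), dtype=bool)

    # --- somata + neurites (neurite channel) -----------------------------
    for (r, c) in soma_centers:
        radius = rng.integers(spec.soma_radius_range_px[0], spec.soma_radius_range_px[1] + 1)
        truth.soma_centers_px.append((r, c))
        truth.soma_radii_px.append(float(radius))
        rr, cc = draw_disk((r, c), radius, shape=(H, W))
        soma_mask[rr, cc] = True

        n_neurites = int(rng.integers(spec.neurites_per_neuron[0], spec.neurites_per_neuron[1] + 1))
        base = rng.uniform(0, 2 * math.pi)
        for k in range(n_neurites):
            ang = base + 2 * math.pi * k / n_neurites + rng.normal(0, 0.2)
            start = (r + radius * math.sin(ang), c + radius * math.cos(ang))
            length = rng.uniform(*spec.neurite_length_um_range)
            polys, nb = _grow_neurite(rng, start, ang, length, spec)
            truth.branch_point_count += nb
            for p in polys:
                truth.neurite_polylines_um.append(p)
                truth.neurite_lengths_um.append(_polyline_length(p))
            _rasterize_polylines(polys, spec, neurite_fg)

    if spec.neurite_width_px > 1:
        neurite_fg = ndimage.binary_dilation(neurite_fg, structure=disk_fp(spec.neurite_width_px // 2))
    neurite_fg |= soma_mask

    # --- nuclei (nuclear channel): one inside each soma, extras elsewhere.
    # Non-neuron nuclei are kept clear of the neurite stain (in a real
    # culture the stain is intracellular, so a stain-free cell's nucleus
    # does not overlap it); their exclusion zone rejects such placements.
    nucleus_centers: List[Tuple[float, float]] = []
    for (r, c), sr in zip(truth.soma_centers_px, truth.soma_radii_px):
        nucleus_centers.append((r, c))
    n_extra = spec.n_non_neuron_nuclei
    n_clumped = int(round(spec.clump_fraction * n_extra))
    n_clumped -= n_clumped % 2  # clumps are pairs
    n_single = n_extra - n_clumped
    nuc_margin = spec.nucleus_radius_range_px[1] + 4
    nuc_sep = 3.0 * spec.nucleus_radius_range_px[1]
    r_max = spec.nucleus_radius_range_px[1]
    clearance = ndimage.binary_dilation(
        neurite_fg, structure=disk_fp(min(r_max + 2, 15))
    )

    def place_clear(n: int, existing: List[Tuple[float, float]]) -> List[Tuple[float, float]]:
        placed: List[Tuple[float, float]] = []
        tries = 0
        while len(placed) < n:
            tries += 1
            if tries > 4000:
                raise RuntimeError("could not place nuclei clear of neurites (spec overcrowded)")
            r = rng.uniform(nuc_margin, H - nuc_margin)
            c = rng.uniform(nuc_margin, W - nuc_margin)
            if clearance[int(r), int(c)]:
                continue
            if all(math.hypot(r - pr, c - pc) >= nuc_sep for pr, pc in placed + existing):
                placed.append((r, c))
        return placed

    singles = place_clear(n_single + n_clumped // 2, nucleus_centers)
    for i, (r, c) in enumerate(singles):
        nucleus_centers.append((r, c))
        if i >= n_single and n_clumped:
            # partner nucleus placed touching, centres ~1.2 radii apart
            ang = rng.uniform(0, 2 * math.pi)
            d = 1.2 * spec.nucleus_radius_range_px[1]
            partner = (r + d * math.sin(ang), c + d * math.cos(ang))
            nucleus_centers.append(partner)

    for (r, c) in nucleus_centers:
        a = rng.uniform(*spec.nucleus_radius_range_px)
        b = rng.uniform(*spec.nucleus_radius_range_px)
        rot = rng.uniform(0, math.pi)
        rr, cc = draw_ellipse(r, c, a, b, shape=(H, W), rotation=rot)
        nucleus_mask[rr, cc] = True
    truth.nuclei_count = len(nucleus_centers)

    # --- artifacts (neurite channel, isolated from real structures) ------
    artifact_mask = np.zeros((H, W), dtype=bool)
    n_art = spec.n_artifacts_small + spec.n_artifacts_large
    if n_art:
        art_centers = _place_points(
            rng, n_art, H, W, 20, 3.0 * spec.artifact_radius_large_px[1],
            existing=soma_centers + nucleus_centers,
        )
        for i, (r, c) in enumerate(art_centers):
            small = i < spec.n_artifacts_small
            lo, hi = (spec.artifact_radius_small_px if small else spec.artifact_radius_large_px)
            radius = int(rng.integers(lo, hi + 1))
            rr, cc = draw_disk((r, c), radius, shape=(H, W))
            # artifacts must stay clear of genuine structures: closing in the
            # preprocessing chain would otherwise merge them with a neurite
            rr_c, cc_c = draw_disk((r, c), radius + 5, shape=(H, W))
            if neurite_fg[rr_c, cc_c].any() or nucleus_mask[rr_c, cc_c].any():
                continue
            artifact_mask[rr, cc] = True
            truth.artifacts.append(
                {
                    "row": r, "col": c, "radius_px": radius,
                    "area_px": int(len(rr)),
                    "below_plausibility": small,
                }
            )

    # --- intensities + noise ---------------------------------------------
    neurite_img = np.full((H, W), float(spec.background_intensity))
    neurite_img[neurite_fg | artifact_mask] = spec.neurite_intensity
    nuclear_img = np.full((H, W), float(spec.background_intensity))
    nuclear_img[nucleus_mask] = spec.nucleus_intensity
    if spec.noise_sigma > 0:
        neurite_img += rng.normal(0, spec.noise_sigma, size=(H, W))
        nuclear_img += rng.normal(0, spec.noise_sigma, size=(H, W))
    neurite_img = np.clip(neurite_img, 0, 65535).astype(np.uint16)
    nuclear_img = np.clip(nuclear_img, 0, 65535).astype(np.uint16)

    frame = MicrographFrame(
        nuclear_channel=nuclear_img,
        neurite_channel=neurite_img,
        calibration=spec.calibration,
        frame_id=f"synthetic-{spec.seed}",
    )
    return frame, truth


def generate_dose_response_plate(
    base_spec: FrameSpec,
    concentrations_nM: Sequence[float],
    lesion_model: dict,
    frames_per_condition: int = 6,
    control_frames: int = 6,
    compound: str = "Rotenone",
    control_compound: str = "DMSO",
    experiment_id: str = "exp1",
    frame_sigma: float = 0.05,
) -> Tuple[List[Tuple[MicrographFrame, GroundTruth]], pd.DataFrame]:
    """Generate a full dose-response plate of synthetic frames.

    The expected per-neuron neurite length at each concentration follows the
    four-parameter-logistic lesion model (``top``/``bottom`` in percent of
    control, ``ld50`` in nM, ``hill``); per-frame lengths are drawn with a
    multiplicative Gaussian jitter (``frame_sigma``) around the expectation.
    """
    top = lesion_model["top"]
    rng = np.random.default_rng(base_spec.seed)
    frames: List[Tuple[MicrographFrame, GroundTruth]] = []
    rows = []

    conditions = [(control_compound, 0.0, True)] * control_frames
    for c in concentrations_nM:
        conditions += [(compound, float(c), False)] * frames_per_condition

    lo, hi = base_spec.neurite_length_um_range
    for i, (cmpd, conc, is_ctrl) in enumerate(conditions):
        if is_ctrl:
            expected = 1.0
        else:
            # decreasing lesion curve: full response at c << ld50, floor at c >> ld50
            y = lesion_model["bottom"] + (top - lesion_model["bottom"]) / (
                1.0 + (conc / lesion_model["ld50"]) ** lesion_model["hill"]
            )
            expected = y / top
        factor = expected * float(np.exp(rng.normal(0.0, frame_sigma)))
        factor = max(factor, 0.05)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            base_spec,
            seed=sub_seed,
            neurite_length_um_range=(lo * factor, hi * factor),
        )
        frame, truth = generate_frame(spec)
        frame.frame_id = f"{experiment_id}-{cmpd}-{conc:g}nM-{i:03d}"
        frame.condition = Condition(
            compound=cmpd, concentration_nM=conc,
            is_control=is_ctrl, experiment_id=experiment_id,
        )
        frames.append((frame, truth))
        rows.append(
            {
                "frame_id": frame.frame_id,
                "compound": cmpd,
                "concentration_nM": conc,
                "is_control": is_ctrl,
                "experiment_id": experiment_id,
                "true_total_neurite_length_um": truth.total_neurite_length_um,
                "true_nuclei_count": truth.nuclei_count,
                "true_neuron_count": truth.neuron_count,
                "true_branch_point_count": truth.branch_point_count,
                "expected_fraction_of_control": expected,
            }
        )
    return frames, pd.DataFrame(rows)


def write_plate(
    frames: Sequence[Tuple[MicrographFrame, GroundTruth]],
    truth_table: pd.DataFrame,
    out_dir,
) -> pd.DataFrame:
    """Write plate frames as two-page TIFFs plus ground-truth and manifest CSVs."""
    from pathlib import Path

    from .calibration import write_frame

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame, _truth in frames:
        p = out / f"{frame.frame_id}.tif"
        write_frame(frame, p)
        paths.append(str(p))
    manifest = pd.DataFrame(
        {
            "frame": paths,
            "frame_id": [f.frame_id for f, _ in frames],
            "experiment_id": [f.condition.experiment_id for f, _ in frames],
            "compound": [f.condition.compound for f, _ in frames],
            "concentration_nM": [f.condition.concentration_nM for f, _ in frames],
            "is_control": [f.condition.is_control for f, _ in frames],
        }
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    truth_table.to_csv(out / "ground_truth.csv", index=False)
    return manifest
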