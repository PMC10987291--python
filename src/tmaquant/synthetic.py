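"""Ground-truthed synthetic TMA cores and survival cohorts.

Core images are rendered through the same Beer–Lambert forward model that
the deconvolution stage inverts: hematoxylin-stained nuclear disks, a faint
hematoxylin wash over the cytoplasm, chromogen (DAB) on the cytoplasm of
positive cells and on nuclei-free mucus blobs, multiplied into RGB through
two unit-norm stain absorbance vectors, plus truncated Gaussian sensor
noise.  Every rendered structure is returned as ground truth, so each
downstream stage (unmixing, nucleus detection, cell partition, scoring) can
be tested against planted values.

Survival cohorts carry a planted score–hazard relationship: event times are
exponential with the hazard multiplied by a fixed ratio for patients whose
score exceeds a planted cutpoint, under independent exponential censoring
and an administrative follow-up cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from skimage.draw import disk

from .stains import DEFAULT_STAIN_MATRIX

__all__ = [
    "MANUAL_CATEGORIES",
    "CoreImageConfig",
    "CoreGroundTruth",
    "CohortConfig",
    "PlacementError",
    "generate_core_image",
    "generate_cohort",
]

#: Ordinal vocabulary of the 4-level manual score, weakest first.
MANUAL_CATEGORIES = ("negative", "inconclusive", "scattered positive", "positive")

#: Minimum clearance between a mucus blob rim and any cell rim, in microns.
#: Keeps blobs strictly beyond the reach of the default 10 um cell-radius
#: cap (cell_radius + clearance > max_radius), so the "mucus must yield no
#: positive cell" ground truth is unambiguous.
MUCUS_CLEARANCE_UM = 6.0


class PlacementError(RuntimeError):
    """Raised when non-overlapping object placement fails: scene too dense."""


@dataclass
class CoreImageConfig:
    """Parameters of the synthetic core renderer.

    Lengths are in microns; intensities are normalized chromogen
    concentrations in [0, 1] with 1.0 = reference saturated DAB optical
    density.  The default pixel scale of 0.25 um/px corresponds to 40x
    brightfield scanning.
    """

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.25
    n_cells: int = 30
    fraction_positive: float = 0.3
    positive_intensity: float = 0.8
    nucleus_radius_um: float = 3.0
    cell_radius_um: float = 7.0
    n_mucus_blobs: int = 0
    mucus_intensity: float = 0.8
    mucus_radius_um: float = 8.0
    noise_sd: float = 0.5
    background_intensity: float | tuple[float, float, float] = 255.0
    nucleus_hematoxylin: float = 1.0
    cytoplasm_hematoxylin: float = 0.15
    stain_vectors: NDArray[np.float64] = field(
        default_factory=lambda: DEFAULT_STAIN_MATRIX.T.copy()
    )
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.fraction_positive <= 1.0:
            raise ValueError("fraction_positive must lie in [0, 1]")
        if not (self.cell_radius_um > self.nucleus_radius_um > 0):
            raise ValueError("require cell_radius_um > nucleus_radius_um > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        sv = np.asarray(self.stain_vectors, dtype=float)
        if sv.shape != (2, 3):
            raise ValueError("stain_vectors must be a (2, 3) array of row vectors")
        if not np.allclose(np.linalg.norm(sv, axis=1), 1.0, atol=1e-8):
            raise ValueError("stain vectors must be unit-norm")
        if np.linalg.matrix_rank(sv, tol=1e-6) < 2:
            raise ValueError("stain vectors must be linearly independent")
        if np.any(np.asarray(self.background_intensity) <= 0):
            raise ValueError("background_intensity must be positive")

    @property
    def background_rgb(self) -> NDArray[np.float64]:
        return np.broadcast_to(
            np.asarray(self.background_intensity, dtype=float), (3,)
        ).copy()


@dataclass
class CoreGroundTruth:
    """Planted structures of one rendered core.

    ``cell_positivity[i]`` is the true class of cell label ``i + 1``.  The
    planted concentration maps ``c_h`` / ``c_d`` enable exact round-trip
    checks of the deconvolution stage.
    """

    nucleus_centroids: NDArray[np.float64]  # (n, 2) row/col
    cell_labels: NDArray[np.int32]
    cell_positivity: NDArray[np.bool_]
    mucus_mask: NDArray[np.bool_]
    nucleus_labels: NDArray[np.int32]
    c_h: NDArray[np.float64]
    c_d: NDArray[np.float64]


def _place_disks(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    radius_px: float,
    min_center_sep_px: float,
    existing: NDArray[np.float64] | None = None,
    existing_clearance_px: float = 0.0,
    max_attempts_per_object: int = 2000,
    what: str = "cells",
) -> NDArray[np.float64]:
    """Rejection-sample n disk centers with pairwise and border margins."""
    margin = radius_px + 1.0
    if shape[0] <= 2 * margin or shape[1] <= 2 * margin:
        raise PlacementError(f"image too small for {what} of radius {radius_px:.1f} px")
    # Random sequential placement jams near ~55% coverage of the exclusion
    # disks; refuse clearly impossible requests before sampling.
    coverage = n * np.pi * (min_center_sep_px / 2.0) ** 2 / (shape[0] * shape[1])
    if coverage > 0.55:
        raise PlacementError(
            f"requested {n} {what} at exclusion radius {min_center_sep_px / 2:.1f} px "
            f"exceeds the packing density limit for a {shape[0]}x{shape[1]} image"
        )
    centers: list[NDArray[np.float64]] = []
    attempts = 0
    budget = max_attempts_per_object * max(n, 1)
    while len(centers) < n:
        if attempts >= budget:
            raise PlacementError(
                f"could not place {n} non-overlapping {what} after {budget} attempts; "
                f"scene density exceeds the packing limit for radius "
                f"{radius_px:.1f} px in a {shape[0]}x{shape[1]} image"
            )
        attempts += 1
        c = np.array(
            [
                rng.uniform(margin, shape[0] - margin),
                rng.uniform(margin, shape[1] - margin),
            ]
        )
        ok = all(np.hypot(*(c - p)) >= min_center_sep_px for p in centers)
        if ok and existing is not None and existing.size:
            d = np.hypot(existing[:, 0] - c[0], existing[:, 1] - c[1])
            ok = bool(np.all(d >= existing_clearance_px))
        if ok:
            centers.append(c)
    return np.array(centers).reshape(n, 2)


def generate_core_image(
    config: CoreImageConfig,
) -> tuple[NDArray[np.float64], CoreGroundTruth]:
    """Render one synthetic TMA core and its ground truth.

    Each RGB channel is ``I_c = I0_c * 10**(-(C_H*s_H_c + C_D*s_D_c))``
    with the planted concentration maps, plus Gaussian noise of standard
    deviation ``noise_sd`` grey-levels truncated to ``[0, I0]``.  The image
    is returned as float64; quantize to uint8 only when writing to disk.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.image_size_px)
    px = config.pixel_size_um
    r_cell = config.cell_radius_um / px
    r_nuc = config.nucleus_radius_um / px

    centers = _place_disks(
        rng, shape, config.n_cells, r_cell, min_center_sep_px=2.0 * r_cell + 1.0
    )

    n_pos = int(round(config.fraction_positive * config.n_cells))
    positivity = np.zeros(config.n_cells, dtype=bool)
    if config.n_cells:
        positivity[rng.permutation(config.n_cells)[:n_pos]] = True

    c_h = np.zeros(shape)
    c_d = np.zeros(shape)
    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    for i, (cy, cx) in enumerate(centers, start=1):
        rr, cc = disk((cy, cx), r_cell, shape=shape)
        cell_labels[rr, cc] = i
        c_h[rr, cc] = config.cytoplasm_hematoxylin
        if positivity[i - 1]:
            c_d[rr, cc] = config.positive_intensity
        rr, cc = disk((cy, cx), r_nuc, shape=shape)
        nucleus_labels[rr, cc] = i
        c_h[rr, cc] = config.nucleus_hematoxylin
        c_d[rr, cc] = 0.0  # chromogen sits in the cytoplasm, not the nucleus

    mucus_mask = np.zeros(shape, dtype=bool)
    if config.n_mucus_blobs:
        r_muc = config.mucus_radius_um / px
        clearance = r_cell + r_muc + MUCUS_CLEARANCE_UM / px
        blob_centers = _place_disks(
            rng,
            shape,
            config.n_mucus_blobs,
            r_muc,
            min_center_sep_px=2.0 * r_muc + 1.0,
            existing=centers,
            existing_clearance_px=clearance,
            what="mucus blobs",
        )
        for cy, cx in blob_centers:
            rr, cc = disk((cy, cx), r_muc, shape=shape)
            mucus_mask[rr, cc] = True
        c_d[mucus_mask] = config.mucus_intensity

    s_h, s_d = np.asarray(config.stain_vectors, dtype=float)
    od = c_h[..., None] * s_h + c_d[..., None] * s_d
    i0 = config.background_rgb
    image = i0 * np.power(10.0, -od)
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, image.shape)
    image = np.clip(image, 0.0, i0)

    truth = CoreGroundTruth(
        nucleus_centroids=centers,
        cell_labels=cell_labels,
        cell_positivity=positivity,
        mucus_mask=mucus_mask,
        nucleus_labels=nucleus_labels,
        c_h=c_h,
        c_d=c_d,
    )
    return image, truth


@dataclass
class CohortConfig:
    """Parameters of the synthetic survival cohort.

    Times are in months.  ``score_distribution`` is ``(family, params)``
    with family one of ``"lognormal"`` (params ``median``, ``sigma``),
    ``"normal"`` (``loc``, ``scale``) or ``"uniform"`` (``low``, ``high``).
    The default lognormal reflects that the score is a positive/negative
    cell-count ratio: positive and right-skewed.

    Patients with score strictly above ``true_cutpoint`` have their event
    hazard multiplied by ``hazard_ratio``.  ``follow_up_cap`` is an
    administrative censoring horizon (default ten years).
    """

    n_patients: int = 400
    score_distribution: tuple[str, dict] = (
        "lognormal",
        None,  # filled in __post_init__ to avoid a mutable default
    )
    true_cutpoint: float = 0.25
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.01
    censoring_rate: float = 0.003
    follow_up_cap: float = 120.0
    subgroup_labels: tuple[str, ...] = ("all",)
    manual_noise_sigma: float = 0.5
    include_manual: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        family, params = self.score_distribution
        if params is None:
            params = {"median": 0.25, "sigma": 0.6}
            self.score_distribution = (family, params)

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        if self.follow_up_cap <= 0:
            raise ValueError("follow_up_cap must be > 0")
        family, _ = self.score_distribution
        if family not in ("lognormal", "normal", "uniform"):
            raise ValueError(f"unknown score distribution family {family!r}")


def _draw_scores(rng: np.random.Generator, config: CohortConfig) -> NDArray[np.float64]:
    family, params = config.score_distribution
    n = config.n_patients
    if family == "lognormal":
        return rng.lognormal(np.log(params["median"]), params["sigma"], n)
    if family == "normal":
        return rng.normal(params["loc"], params["scale"], n)
    return rng.uniform(params["low"], params["high"], n)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a patient cohort with a planted score–hazard effect.

    Returns a DataFrame with columns ``patient_id, score, time, event,
    subgroup, manual_category``.  Event times are exponential with hazard
    ``baseline_hazard * hazard_ratio**(score > true_cutpoint)``; censoring
    is independent exponential at ``censoring_rate`` plus the
    administrative cap.  Manual categories, when included, bin a
    multiplicative-noise-corrupted copy of the score at its cohort
    quartiles, emulating an ordinal observer read.

    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    scores = _draw_scores(rng, config)
    hazards = config.baseline_hazard * np.where(
        scores > config.true_cutpoint, config.hazard_ratio, 1.0
    )
    t_event = rng.exponential(1.0 / hazards)
    if config.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / config.censoring_rate, n)
    else:
        t_cens = np.full(n, np.inf)
    horizon = np.minimum(t_cens, config.follow_up_cap)
    time = np.minimum(t_event, horizon)
    event = (t_event <= horizon).astype(int)

    subgroup = rng.choice(list(config.subgroup_labels), size=n)

    if config.include_manual:
        observed = scores * rng.lognormal(0.0, config.manual_noise_sigma, n)
        qs = np.quantile(observed, [0.25, 0.5, 0.75])
        idx = np.searchsorted(qs, observed, side="right")
        manual = np.asarray(MANUAL_CATEGORIES)[idx]
    else:
        manual = np.full(n, "", dtype=object)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(1, n + 1)],
            "score": scores,
            "time": time,
            "event": event,
            "subgroup": subgroup,
            "manual_category": manual,
        }
    )
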