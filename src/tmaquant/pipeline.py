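"""End-to-end orchestration: cores in, cutpoint report out.

`run_pipeline` binds the stages together — render or load core images,
unmix each into stain concentration maps, detect nuclei, partition cells,
score the core, join the per-core scores to a patient table, then run the
constrained minimum-p cutpoint search and per-subgroup Kaplan–Meier
re-tests.  A failure on one core is recorded in the manifest and does not
abort the cohort, mirroring TMA spot dropout.

All tabular exchange is CSV, images are 8-bit RGB TIFF/PNG, label images
16-bit TIFF, structured reports JSON.  Every stochastic stage derives its
randomness from the single pipeline seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from . import geometry, scoring, stains, synthetic, survival

__all__ = [
    "PipelineConfig",
    "ValidatedTable",
    "read_patient_table",
    "read_core_image",
    "write_core_image",
    "write_label_image",
    "write_concentration_map",
    "process_core",
    "run_pipeline",
]

logger = logging.getLogger("tmaquant")

REQUIRED_COLUMNS = ("patient_id", "score", "time", "event")


# ---------------------------------------------------------------------------
# IO helpers


def read_core_image(path: str | Path) -> np.ndarray:
    """Read an RGB core image (TIFF or PNG) as float64 in [0, 255]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    return arr


def write_core_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float RGB image as 8-bit TIFF or PNG."""
    path = Path(path)
    arr = np.clip(np.asarray(image), 0, 255).round().astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr).save(path)


def write_label_image(path: str | Path, labels: np.ndarray) -> None:
    """Write a label image as 16-bit single-channel TIFF."""
    tifffile.imwrite(Path(path), np.asarray(labels).astype(np.uint16))


def write_concentration_map(path: str | Path, conc: np.ndarray) -> None:
    """Write a concentration map as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), np.asarray(conc, dtype=np.float32))


# ---------------------------------------------------------------------------
# Patient table


@dataclass
class ValidatedTable:
    """Validated patient records plus per-row rejection diagnostics."""

    records: pd.DataFrame
    errors: list[str] = field(default_factory=list)


def read_patient_table(path: str | Path, require_score: bool = True) -> ValidatedTable:
    """Read and validate a cohort CSV.

    Required columns: patient_id, score (unless ``require_score=False``),
    time, event.  Rows with a non-binary event flag, negative or
    non-finite time, or a manual category outside the 4-level vocabulary
    are rejected with a diagnostic naming the row; valid rows are kept.
    Unknown subgroup labels are preserved verbatim.
    """
    df = pd.read_csv(path)
    required = [c for c in REQUIRED_COLUMNS if require_score or c != "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    errors: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in df.iterrows():
        problems = []
        if row["event"] not in (0, 1):
            problems.append(f"event={row['event']!r} is not binary")
        t = row["time"]
        if not np.isfinite(t) or t < 0:
            problems.append(f"time={t!r} is not a non-negative number")
        mc = row.get("manual_category")
        if isinstance(mc, str) and mc and mc not in synthetic.MANUAL_CATEGORIES:
            problems.append(
                f"manual_category={mc!r} not in allowed vocabulary "
                f"{list(synthetic.MANUAL_CATEGORIES)}"
            )
        if problems:
            keep[i] = False
            msg = f"row {i} (patient_id={row['patient_id']!r}): " + "; ".join(problems)
            errors.append(msg)
            logger.warning("rejected %s", msg)
    return ValidatedTable(df.loc[keep].reset_index(drop=True), errors)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PipelineConfig:
    """Nested configuration of the full pipeline.

    When ``image_dir`` is None, ``n_cores`` synthetic cores are rendered
    from ``core_config`` (per-core positive fractions drawn uniformly from
    ``fraction_positive_range`` to create inter-patient score variation);
    otherwise TIFF/PNG images are loaded from the directory.  When
    ``patient_table`` is None, survival follows the planted score–hazard
    model of ``cohort_config`` applied to the *measured* core scores.
    """

    n_cores: int = 20
    # Default cores include stain-saturated mucus blobs: per-image stain
    # estimation needs a near-pure population of each stain to identify its
    # absorbance direction (see docs/methods.md).
    core_config: synthetic.CoreImageConfig = field(
        default_factory=lambda: synthetic.CoreImageConfig(
            cell_radius_um=6.0, n_mucus_blobs=2, mucus_radius_um=6.0
        )
    )
    fraction_positive_range: tuple[float, float] = (0.05, 0.6)
    scoring_params: scoring.ScoringParams = field(default_factory=scoring.ScoringParams)
    cutpoint_params: survival.CutpointParams = field(default_factory=survival.CutpointParams)
    cohort_config: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    max_radius_um: float = 10.0
    tissue_floor: float = 0.05
    alpha: float = 1.0
    beta: float = 0.15
    image_dir: str | None = None
    patient_table: str | None = None
    out_dir: str = "tmaquant_run"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (list, tuple)):
                return [convert(v) for v in obj]
            if isinstance(obj, dict):
                return {k: convert(v) for k, v in obj.items()}
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return convert(self)

    @property
    def parameter_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stages


def process_core(
    image: np.ndarray,
    config: PipelineConfig,
    core_id: str = "core",
    stain_matrix: stains.StainMatrix | None = None,
) -> tuple[scoring.CoreScore, list[scoring.CellScore], stains.StainMatrix]:
    """Unmix, segment and score one core image.

    The stain matrix is estimated per image; degenerate cores (too little
    tissue, effectively single-stained) fall back to the fixed reference
    hematoxylin/DAB matrix.
    """
    od = stains.rgb_to_od(image, background=255.0)
    if stain_matrix is None:
        try:
            stain_matrix = stains.estimate_stain_matrix(od, config.alpha, config.beta)
        except (stains.InsufficientTissueError, stains.SingleStainError) as exc:
            logger.info("%s: %s; using reference stain matrix", core_id, exc)
            stain_matrix = stains.StainMatrix.reference()
    c_h, c_d = stains.unmix(od, stain_matrix)
    px = config.core_config.pixel_size_um
    nuclei = geometry.detect_nuclei(
        c_h,
        pixel_size_um=px,
        nucleus_radius_um=config.core_config.nucleus_radius_um,
    )
    tissue = geometry.tissue_mask_from_concentrations(c_h, c_d, config.tissue_floor)
    partition = geometry.partition_cells(nuclei, tissue, config.max_radius_um, px)
    core_score, cell_scores = scoring.score_core(
        partition, c_d, config.scoring_params, core_id=core_id
    )
    return core_score, cell_scores, stain_matrix


def _survival_from_scores(
    scores: np.ndarray, cfg: synthetic.CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Planted score–hazard survival for measured (not simulated) scores."""
    hazards = cfg.baseline_hazard * np.where(
        scores > cfg.true_cutpoint, cfg.hazard_ratio, 1.0
    )
    t_event = rng.exponential(1.0 / hazards)
    t_cens = (
        rng.exponential(1.0 / cfg.censoring_rate, scores.size)
        if cfg.censoring_rate > 0
        else np.full(scores.size, np.inf)
    )
    horizon = np.minimum(t_cens, cfg.follow_up_cap)
    return np.minimum(t_event, horizon), (t_event <= horizon).astype(int)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write a run manifest.

    Returns the manifest dict (also written to ``out_dir/manifest.json``):
    versions, seed, parameter hash, per-core scores and errors, the
    cutpoint report, and per-subgroup results at the selected threshold.
    Per-core failures are recorded and skipped; the manifest's ``status``
    is ``"partial"`` when any core failed.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # ---- collect core images -------------------------------------------
    images: list[tuple[str, "np.ndarray | None", str | None]] = []
    if config.image_dir is not None:
        paths = sorted(
            p
            for p in Path(config.image_dir).iterdir()
            if p.suffix.lower() in (".tif", ".tiff", ".png")
        )
        for p in paths:
            try:
                images.append((p.stem, read_core_image(p), None))
            except Exception as exc:  # noqa: BLE001 - per-core fault isolation
                images.append((p.stem, None, f"unreadable image: {exc}"))
    else:
        lo, hi = config.fraction_positive_range
        for i in range(config.n_cores):
            cfg_i = dataclasses.replace(
                config.core_config,
                fraction_positive=float(rng.uniform(lo, hi)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            try:
                img, _ = synthetic.generate_core_image(cfg_i)
                images.append((f"core_{i:03d}", img, None))
            except Exception as exc:  # noqa: BLE001 - per-core fault isolation
                images.append((f"core_{i:03d}", None, f"generation failed: {exc}"))

    # ---- unmix / segment / score per core ------------------------------
    rows = []
    errors: dict[str, str] = {}
    for core_id, img, err in images:
        if err is not None:
            errors[core_id] = err
            continue
        try:
            core_score, _, _ = process_core(img, config, core_id)
            rows.append(
                {
                    "patient_id": core_id,
                    "n_positive": core_score.n_positive,
                    "n_negative": core_score.n_negative,
                    "ratio": core_score.ratio,
                    "fraction_positive": core_score.fraction_positive,
                    "uninterpretable": core_score.uninterpretable,
                }
            )
        except Exception as exc:  # noqa: BLE001 - per-core fault isolation
            logger.warning("core %s failed: %s", core_id, exc)
            errors[core_id] = str(exc)
    scores_df = pd.DataFrame(rows)
    scores_df.to_csv(out / "core_scores.csv", index=False)

    # ---- patient table --------------------------------------------------
    if config.patient_table is not None:
        table = read_patient_table(config.patient_table, require_score=False)
        cohort = table.records.merge(
            scores_df[["patient_id", "ratio"]], on="patient_id", how="inner"
        )
        cohort["score"] = cohort["ratio"]
    else:
        usable = scores_df[~scores_df["uninterpretable"]].copy()
        s = usable["ratio"].to_numpy(dtype=float)
        time, event = _survival_from_scores(s, config.cohort_config, rng)
        cohort = pd.DataFrame(
            {
                "patient_id": usable["patient_id"],
                "score": s,
                "time": time,
                "event": event,
                "subgroup": "all",
                "manual_category": "",
            }
        )
    cohort.to_csv(out / "cohort.csv", index=False)

    # ---- survival analytics ---------------------------------------------
    cutpoint = None
    subgroups: dict[str, dict] = {}
    finite = np.isfinite(cohort["score"].to_numpy(dtype=float))
    min_n = int(np.ceil(1.0 / config.cutpoint_params.min_group_fraction))
    if finite.sum() >= min_n:
        result = survival.cutpoint_search(cohort, config.cutpoint_params)
        cutpoint = result.to_dict()
        (out / "cutpoint.json").write_text(json.dumps(cutpoint, indent=2))
        if result.best_threshold is not None:
            for name in sorted(cohort["subgroup"].unique()):
                r = survival.subgroup_km(cohort, result.best_threshold, name)
                subgroups[name] = {
                    "evaluable": r.evaluable,
                    "n_high": r.n_high,
                    "n_low": r.n_low,
                    "p_value": r.p_value,
                }
                if r.evaluable:
                    survival.plot_km(
                        {"high score": r.km_high, "low score": r.km_low},
                        title=f"{name}: cutpoint {result.best_threshold:.3g} "
                        f"(log-rank p = {r.p_value:.3g})",
                        path=out / f"km_{name}.png",
                    )

    import skimage

    manifest = {
        "status": "partial" if errors else "ok",
        "seed": config.seed,
        "parameter_hash": config.parameter_hash,
        "versions": {
            "tmaquant": _version(),
            "numpy": np.__version__,
            "scikit-image": skimage.__version__,
            "pandas": pd.__version__,
        },
        "n_cores_scored": len(rows),
        "n_cores_failed": len(errors),
        "core_errors": errors,
        "outputs": {
            "core_scores": str(out / "core_scores.csv"),
            "cohort": str(out / "cohort.csv"),
            "cutpoint": str(out / "cutpoint.json") if cutpoint else None,
        },
        "cutpoint": cutpoint,
        "subgroups": subgroups,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _version() -> str:
    from . import __version__

    return __version__
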