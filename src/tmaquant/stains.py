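"""Color deconvolution of brightfield immunohistochemistry images.

Brightfield stains obey the Beer–Lambert law: per channel c,
``I_c = I0_c * 10**(-OD_c)`` where the optical density ``OD_c`` is a linear
mixture of the per-stain absorbances.  Separating a hematoxylin/DAB image
therefore amounts to (i) transforming RGB intensities to optical density,
(ii) estimating the two unit-norm stain absorbance vectors, and (iii)
solving a per-pixel least-squares problem for the stain concentrations.

The stain-matrix estimator is the singular-plane / angle-percentile method
of Macenko: foreground OD pixels are projected onto the plane spanned by
the top two singular vectors, and the extreme directions at the alpha and
(100 - alpha) angle percentiles are taken as the stain vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "DEFAULT_STAIN_MATRIX",
    "StainMatrix",
    "InsufficientTissueError",
    "SingleStainError",
    "rgb_to_od",
    "estimate_stain_matrix",
    "unmix",
]

#: Reference hematoxylin / DAB absorbance matrix (columns, unit norm),
#: after Ruifrok & Johnston's published values.  Used as the documented
#: fallback when per-image estimation is degenerate.
DEFAULT_STAIN_MATRIX = np.array(
    [
        [0.650, 0.269],
        [0.704, 0.568],
        [0.286, 0.778],
    ]
)
DEFAULT_STAIN_MATRIX /= np.linalg.norm(DEFAULT_STAIN_MATRIX, axis=0, keepdims=True)


class InsufficientTissueError(ValueError):
    """Raised when too few foreground pixels exceed the OD floor."""


class SingleStainError(ValueError):
    """Raised when the two extreme stain directions are near-collinear.

    Callers should fall back to :data:`DEFAULT_STAIN_MATRIX`.
    """


@dataclass(frozen=True)
class StainMatrix:
    """Unit-norm absorbance vectors of the nuclear and chromogen stains.

    Attributes
    ----------
    hematoxylin, dab:
        Unit Euclidean-norm 3-vectors (absorbance per RGB channel).
    alpha, beta:
        Estimation parameters: angle percentile and OD floor (recorded for
        provenance; irrelevant when the matrix was supplied directly).
    """

    hematoxylin: NDArray[np.float64]
    dab: NDArray[np.float64]
    alpha: float = 1.0
    beta: float = 0.15

    def __post_init__(self) -> None:
        for name in ("hematoxylin", "dab"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            n = np.linalg.norm(v)
            if not np.isfinite(n) or n == 0:
                raise ValueError(f"{name} stain vector must be finite and nonzero")
            object.__setattr__(self, name, v / n)

    @property
    def matrix(self) -> NDArray[np.float64]:
        """3x2 matrix with columns (hematoxylin, dab)."""
        return np.stack([self.hematoxylin, self.dab], axis=1)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "hematoxylin": self.hematoxylin.tolist(),
            "dab": self.dab.tolist(),
            "alpha": self.alpha,
            "beta": self.beta,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StainMatrix":
        d = json.loads(Path(path).read_text())
        return cls(
            np.asarray(d["hematoxylin"]),
            np.asarray(d["dab"]),
            float(d.get("alpha", 1.0)),
            float(d.get("beta", 0.15)),
        )

    @classmethod
    def reference(cls) -> "StainMatrix":
        """The fixed fallback hematoxylin/DAB matrix."""
        return cls(DEFAULT_STAIN_MATRIX[:, 0], DEFAULT_STAIN_MATRIX[:, 1])


def rgb_to_od(
    image: ArrayLike, background: ArrayLike = 255.0, eps: float = 1.0
) -> NDArray[np.float64]:
    """Transform an RGB image to optical density.

    ``OD_c = -log10(max(I_c, eps) / I0_c)``, clipped at zero.  The floor
    ``eps`` (one grey-level) only guards against ``log(0)``; intensities at
    or above one grey-level transform exactly.

    Parameters
    ----------
    image:
        ``(..., 3)`` RGB array, integer or float, in ``[0, background]``.
    background:
        Per-channel white point ``I0`` (scalar or length-3), strictly positive.

    Returns
    -------
    Optical-density array of the same shape, non-negative and finite.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim < 1 or image.shape[-1] != 3:
        raise ValueError(f"expected trailing RGB axis of length 3, got shape {image.shape}")
    i0 = np.broadcast_to(np.asarray(background, dtype=float), (3,))
    if np.any(i0 <= 0):
        raise ValueError("background white-point must be > 0 per channel")
    od = -np.log10(np.maximum(image, eps) / i0)
    return np.clip(od, 0.0, None)


def estimate_stain_matrix(
    od: ArrayLike,
    alpha: float = 1.0,
    beta: float = 0.15,
    min_foreground: int = 100,
) -> StainMatrix:
    """Estimate the hematoxylin/DAB stain matrix from an OD image (Macenko).

    Pixels whose maximum-channel OD is at or below ``beta`` are discarded as
    background.  The remaining OD vectors are projected onto the plane of
    their top two singular vectors; the extreme directions at the ``alpha``
    and ``100 - alpha`` angle percentiles become the stain vectors.  The
    column whose blue-channel absorbance is smaller — i.e. the stain that
    *looks* blue in transmitted light — is labeled hematoxylin.

    Raises
    ------
    InsufficientTissueError
        Fewer than ``min_foreground`` pixels exceed the OD floor.
    SingleStainError
        The two extreme directions are less than 5 degrees apart; use
        :meth:`StainMatrix.reference` instead.
    """
    od = np.asarray(od, dtype=float).reshape(-1, 3)
    fg = od[od.max(axis=1) > beta]
    if fg.shape[0] < min_foreground:
        raise InsufficientTissueError(
            f"insufficient tissue: {fg.shape[0]} pixels above OD floor {beta} "
            f"(need >= {min_foreground})"
        )

    # Top-2 right singular vectors span the stain plane.
    _, _, vt = np.linalg.svd(fg, full_matrices=False)
    plane = vt[:2].T  # (3, 2)
    # Orient the basis so projections are predominantly positive.
    proj = fg @ plane
    for j in range(2):
        if proj[:, j].sum() < 0:
            plane[:, j] *= -1
            proj[:, j] *= -1

    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, [alpha, 100.0 - alpha])
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    # Absorbances are physically non-negative; flip any inverted direction.
    v1 = v1 if v1.sum() >= 0 else -v1
    v2 = v2 if v2.sum() >= 0 else -v2
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)

    sep = np.degrees(np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0)))
    if sep < 5.0:
        raise SingleStainError(
            f"extreme stain directions only {sep:.2f} degrees apart; "
            "image appears single-stained — fall back to StainMatrix.reference()"
        )

    # Hematoxylin transmits blue, i.e. absorbs the least in the blue channel.
    if v1[2] <= v2[2]:
        h, d = v1, v2
    else:
        h, d = v2, v1
    return StainMatrix(h, d, alpha=alpha, beta=beta)


def unmix(
    od: ArrayLike, stains: StainMatrix, max_condition: float = 1e3
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Solve the per-pixel mixture ``OD = S @ C`` for stain concentrations.

    Least squares via the pseudo-inverse of the 3x2 stain matrix; negative
    components (noise leaking past the simplex) are clipped to zero.

    Returns
    -------
    (c_h, c_d):
        Non-negative concentration maps for the nuclear stain and the
        chromogen, same spatial shape as ``od``.
    """
    if stains.condition_number > max_condition:
        raise ValueError(
            f"stain matrix condition number {stains.condition_number:.3g} "
            f"exceeds {max_condition:.3g}; unmixing would be unstable"
        )
    od = np.asarray(od, dtype=float)
    if od.shape[-1] != 3:
        raise ValueError("OD image must have trailing channel axis of length 3")
    pinv = np.linalg.pinv(stains.matrix)  # (2, 3)
    conc = od @ pinv.T
    conc = np.clip(conc, 0.0, None)
    return conc[..., 0], conc[..., 1]
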