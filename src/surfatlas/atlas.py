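"""Probabilistic map construction, thresholding, MPM, and leave-one-out CV.

The central quantity is the dice coefficient between a thresholded group
probabilistic map G and a held-out individual ROI I,

    dc = 2 |I ∩ G| / (|I| + |G|),

swept over group-map thresholds from unthresholded (every vertex present in
at least one subject) up to consensus (vertices present in all subjects) in
steps of 1/n for a group of n subjects.  Threshold comparison is *inclusive*
(values >= t), so with n = 8 a threshold of 0.375 keeps exactly the vertices
shared by three or more subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .surface import Cohort, Hemisphere, ProbabilisticMap, RoiLabel, _as_hemisphere

__all__ = [
    "ThresholdGrid",
    "CvResult",
    "dice",
    "build_prob_map",
    "threshold_map",
    "build_mpm",
    "loocv_dice",
    "BACKGROUND",
]

logger = logging.getLogger(__name__)

#: MPM code for vertices assigned to no ROI.
BACKGROUND = -1


@dataclass(frozen=True)
class ThresholdGrid:
    """The threshold sweep {0, 1/n, 2/n, ..., 1} for a group of n subjects."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")

    @property
    def levels(self) -> np.ndarray:
        return np.arange(self.n + 1) / self.n


@dataclass(frozen=True)
class CvResult:
    """Per-fold, per-threshold dice for one ROI under one condition.

    ``dice_matrix`` has shape (n_folds, n_thresholds); ``fold_subjects`` names
    the left-out subject of each fold.  ``se`` is the sample SD across folds
    (n-1 denominator) divided by sqrt(n_folds).
    """

    condition: str
    roi_id: str
    hemisphere: Hemisphere
    thresholds: np.ndarray
    fold_subjects: tuple[str, ...]
    dice_matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.dice_matrix, float)
        if m.shape != (len(self.fold_subjects), len(self.thresholds)):
            raise ValueError("dice_matrix shape mismatch")
        if m.min() < 0 or m.max() > 1:
            raise ValueError("dice values outside [0, 1]")
        object.__setattr__(self, "dice_matrix", m)

    @property
    def n_folds(self) -> int:
        return len(self.fold_subjects)

    @property
    def mean(self) -> np.ndarray:
        return self.dice_matrix.mean(axis=0)

    @property
    def se(self) -> np.ndarray:
        if self.n_folds < 2:
            return np.zeros(len(self.thresholds))
        return self.dice_matrix.std(axis=0, ddof=1) / np.sqrt(self.n_folds)

    def nearest_threshold(self, t: float) -> float:
        """The grid threshold closest to ``t`` (grids shrink when folds do)."""
        return float(self.thresholds[int(np.argmin(np.abs(self.thresholds - t)))])

    def dice_at(self, t: float) -> np.ndarray:
        """Per-fold dice at the grid threshold closest to ``t`` (must match)."""
        j = int(np.argmin(np.abs(self.thresholds - t)))
        if not np.isclose(self.thresholds[j], t, atol=1e-9):
            raise KeyError(f"threshold {t} not on the grid")
        return self.dice_matrix[:, j]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (fold, threshold)."""
        rows = [
            {
                "condition": self.condition,
                "roi": self.roi_id,
                "hemisphere": self.hemisphere.value,
                "fold": s,
                "threshold": float(t),
                "dice": float(self.dice_matrix[i, j]),
            }
            for i, s in enumerate(self.fold_subjects)
            for j, t in enumerate(self.thresholds)
        ]
        return pd.DataFrame(rows)


def dice(
    I: "frozenset[int] | set[int]",
    G: "frozenset[int] | set[int]",
    *,
    vertex_weights: np.ndarray | None = None,
) -> float:
    """Dice coefficient 2|I n G| / (|I| + |G|) between two vertex sets.

    Symmetric, in [0, 1]; raises if both sets are empty (the statistic is
    undefined there — never silently 0).  ``vertex_weights`` switches the
    cardinalities to weighted sums (e.g. per-vertex areas); the default is the
    unweighted set-cardinality form.
    """
    if not I and not G:
        raise ValueError("dice undefined for two empty sets")
    if vertex_weights is None:
        return 2 * len(I & G) / (len(I) + len(G))
    w = np.asarray(vertex_weights, float)
    wi = w[list(I)].sum() if I else 0.0
    wg = w[list(G)].sum() if G else 0.0
    wig = w[list(I & G)].sum() if I & G else 0.0
    return float(2 * wig / (wi + wg))


def build_prob_map(
    cohort: Cohort,
    roi_id: str,
    hemisphere: "Hemisphere | str",
    subjects: Sequence[str] | None = None,
) -> ProbabilisticMap:
    """Per-vertex subject counts for one ROI over a subject subset.

    Subjects lacking the ROI (explicitly absent labels) are excluded with a
    logged note; the recorded ``n_subjects`` is the number actually included.
    """
    hemi = _as_hemisphere(hemisphere)
    if subjects is None:
        subjects = cohort.subjects
    if not subjects:
        raise ValueError("empty subject subset")
    counts = np.zeros(cohort.mesh.n_vertices, dtype=np.int64)
    included = 0
    for s in subjects:
        lab = cohort.get(s, roi_id, hemi)
        if lab is None:
            logger.info("subject %s lacks %s/%s; excluded from group map",
                        s, roi_id, hemi.value)
            continue
        counts[lab.indices()] += 1
        included += 1
    if included == 0:
        raise ValueError(f"no subject in subset possesses {roi_id}/{hemi.value}")
    return ProbabilisticMap(
        roi_id=roi_id,
        hemisphere=hemi,
        condition=cohort.condition,
        n_subjects=included,
        counts=counts,
    )


def threshold_map(pmap: ProbabilisticMap, t: float) -> frozenset[int]:
    """Vertices of the group map at threshold ``t`` (inclusive comparison).

    ``t = 0`` means the *unthresholded* map: the support (counts >= 1), not
    the whole mesh.  ``t = 1`` keeps only vertices present in all subjects.
    With n = 8, ``t = 0.375`` keeps vertices with subject count >= 3.
    """
    if not 0 <= t <= 1:
        raise ValueError("threshold must be in [0, 1]")
    if t == 0:
        keep = pmap.counts >= 1
    else:
        keep = pmap.values >= t - 1e-12  # inclusive despite float rounding
    return frozenset(np.flatnonzero(keep).tolist())


def build_mpm(
    pmaps: Sequence[ProbabilisticMap], min_prob: float = 0.0
) -> np.ndarray:
    """Maximum probability map: per-vertex hard assignment to the winning ROI.

    Returns an integer array over vertices; entry k is the index of the
    winning map in *canonical order* (maps sorted by roi_id), or
    :data:`BACKGROUND` where no map reaches ``min_prob`` (and, always, where
    no map has support).  Ties go to the lowest roi_id in canonical order, so
    the assignment is invariant to the input ordering of ``pmaps``.
    """
    if not pmaps:
        raise ValueError("empty map list")
    order = sorted(range(len(pmaps)), key=lambda i: pmaps[i].roi_id)
    values = np.stack([pmaps[i].values for i in order])  # (K, n_vertices)
    counts = np.stack([pmaps[i].counts for i in order])
    winner = values.argmax(axis=0)  # first max wins -> lowest roi_id on ties
    best = values.max(axis=0)
    supported = counts.max(axis=0) > 0
    out = np.where(supported & (best >= min_prob), winner, BACKGROUND)
    return out.astype(np.int64)


def loocv_dice(
    cohort: Cohort,
    roi_id: str,
    hemisphere: "Hemisphere | str",
    grid: ThresholdGrid | None = None,
) -> CvResult:
    """Exhaustive leave-one-out cross-validation of one ROI's group map.

    Each subject possessing the ROI is left out once; the group probabilistic
    map built from the remaining subjects is thresholded over the grid and
    scored by dice against the left-out subject's ROI.  The grid defaults to
    steps of 1/(n-1) where n is the number of subjects possessing the ROI
    (the group map in each fold has n-1 subjects).
    """
    hemi = _as_hemisphere(hemisphere)
    have = cohort.subjects_with(roi_id, hemi)
    if len(have) < 3:
        raise ValueError(
            f"loocv needs >= 3 subjects with {roi_id}/{hemi.value}, got {len(have)}"
        )
    if grid is None:
        grid = ThresholdGrid(len(have) - 1)
    levels = grid.levels
    mat = np.empty((len(have), len(levels)))
    for i, left_out in enumerate(have):
        rest = [s for s in have if s != left_out]
        pmap = build_prob_map(cohort, roi_id, hemi, rest)
        held = cohort.get(left_out, roi_id, hemi)
        assert held is not None
        for j, t in enumerate(levels):
            mat[i, j] = dice(held.vertex_set, threshold_map(pmap, float(t)))
    return CvResult(
        condition=cohort.condition,
        roi_id=roi_id,
        hemisphere=hemi,
        thresholds=levels,
        fold_subjects=tuple(have),
        dice_matrix=mat,
    )
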