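"""Labeled-dataset assembly, refractive-index labeling and fold planning.

The binary target follows the refractive-index ranges of healthy versus
neoplastic cervical tissue analogs: liquids with label index 1.30-1.38 are
"healthy" (0), 1.39-1.50 are "sick" (1).  On the default 21-liquid panel
with 10 replicates this yields 90 healthy / 120 sick rows (43% / 57%).

Model selection uses a stratified hold-out validation split taken before a
stratified k-fold cross-validation plan (k = 3 by default).  The default
split is row-level stratified; ``group_aware=True`` instead holds out whole
liquids so that no replicate of a validation liquid is seen in training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .exceptions import FPScreenError
from .features import FEATURE_NAMES

__all__ = [
    "LABEL_EPS",
    "HEALTHY_MAX_INDEX",
    "SICK_MIN_INDEX",
    "LabeledDataset",
    "FoldPlan",
    "assign_label",
    "build_dataset",
    "split_validation",
    "stratified_kfold",
]

logger = logging.getLogger(__name__)

#: guard for float representation of the 0.01 refractive-index grid.
LABEL_EPS = 1e-6
HEALTHY_MAX_INDEX = 1.38
SICK_MIN_INDEX = 1.39


def assign_label(refractive_index: float) -> int:
    """Binary tissue-analog label from the liquid's (label-scale) index.

    0 = healthy for indices up to 1.38, 1 = cancer for 1.39 and above; an
    epsilon of 1e-6 guards against float representation of the 0.01 grid.
    Indices outside [1.30, 1.50] are rejected.
    """
    if not (1.30 - LABEL_EPS <= refractive_index <= 1.50 + LABEL_EPS):
        raise FPScreenError(
            f"refractive index {refractive_index} outside the calibrated range [1.30, 1.50]"
        )
    if refractive_index <= HEALTHY_MAX_INDEX + LABEL_EPS:
        return 0
    return 1


@dataclass
class LabeledDataset:
    """Feature rows with the target slot filled plus per-row provenance."""

    frame: pd.DataFrame  # columns F1..F18 plus provenance columns

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_NAMES if c not in self.frame.columns]
        if missing:
            raise FPScreenError(f"dataset is missing feature columns: {missing}")
        if len(self.frame) and not self.frame["F18"].isin([0, 1]).all():
            raise FPScreenError("every row must carry a binary F18 target")

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[list(FEATURE_NAMES[:-1])]

    @property
    def y(self) -> pd.Series:
        return self.frame["F18"].astype(int)

    @property
    def class_counts(self) -> dict[int, int]:
        counts = self.y.value_counts().to_dict()
        return {0: int(counts.get(0, 0)), 1: int(counts.get(1, 0))}

    def subset(self, indices: np.ndarray | list[int]) -> "LabeledDataset":
        return LabeledDataset(self.frame.loc[list(indices)])

    def __len__(self) -> int:
        return len(self.frame)


def build_dataset(
    features: list[dict[str, float]] | pd.DataFrame,
    indices: list[float] | np.ndarray,
) -> LabeledDataset:
    """Fill the F18 target of each feature row from its refractive index."""
    frame = pd.DataFrame(features).copy()
    if len(frame) != len(indices):
        raise FPScreenError(
            f"{len(frame)} feature rows but {len(indices)} refractive indices"
        )
    if len(frame) == 0:
        frame = pd.DataFrame(columns=list(FEATURE_NAMES) + ["refractive_index"])
        return LabeledDataset(frame)
    frame["refractive_index"] = np.asarray(indices, dtype=float)
    frame["F18"] = [assign_label(n) for n in frame["refractive_index"]]
    frame = frame.reset_index(drop=True)
    ds = LabeledDataset(frame)
    logger.info(
        "built dataset: %d rows (%d healthy, %d sick)",
        len(ds), ds.class_counts[0], ds.class_counts[1],
    )
    return ds


@dataclass
class FoldPlan:
    """Stratified partition of the training rows plus the held-out split.

    ``folds`` maps each training-row positional id to a fold in [0, k);
    ``validation_indices`` are dataset row labels disjoint from training.
    """

    k: int
    train_indices: np.ndarray
    folds: np.ndarray  # fold id per entry of train_indices
    validation_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if set(self.train_indices) & set(self.validation_indices):
            raise FPScreenError("validation rows overlap the training rows")
        if len(self.folds) != len(self.train_indices):
            raise FPScreenError("fold assignment length mismatch")

    def fold_split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train rows, held-out rows) for one CV iteration."""
        held = self.train_indices[self.folds == fold]
        rest = self.train_indices[self.folds != fold]
        return rest, held


def split_validation(
    ds: LabeledDataset,
    fraction: float,
    seed: int,
    *,
    group_aware: bool = False,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified hold-out split preserving class proportions.

    Row-level by default: each class contributes ``fraction`` of its rows
    (within one row per class), so replicates of one liquid may appear on
    both sides.  With ``group_aware=True`` whole liquids (grouped by their
    refractive index) are held out instead, class-stratified at the liquid
    level; this removes leakage between near-identical replicate spectra at
    the cost of rounding the fraction to whole liquids.
    """
    if not 0.0 < fraction < 1.0:
        raise FPScreenError(f"validation fraction must be in (0, 1), got {fraction}")
    counts = ds.class_counts
    if counts[0] == 0 or counts[1] == 0:
        raise FPScreenError("both classes must be present to stratify the split")
    if not group_aware:
        tr, va = train_test_split(
            ds.frame.index.to_numpy(),
            test_size=fraction,
            stratify=ds.y.to_numpy(),
            random_state=seed,
        )
    else:
        rng = np.random.default_rng(seed)
        groups = ds.frame["refractive_index"].to_numpy()
        va_groups: list[float] = []
        for cls in (0, 1):
            cls_groups = np.unique(groups[ds.y.to_numpy() == cls])
            n_hold = max(1, round(fraction * len(cls_groups)))
            if n_hold >= len(cls_groups):
                raise FPScreenError("validation fraction would hold out an entire class")
            va_groups.extend(rng.choice(cls_groups, size=n_hold, replace=False))
        mask = np.isin(groups, va_groups)
        va = ds.frame.index.to_numpy()[mask]
        tr = ds.frame.index.to_numpy()[~mask]
    tr_ds, va_ds = ds.subset(np.sort(tr)), ds.subset(np.sort(va))
    logger.info(
        "validation split: %d train / %d validation rows (group_aware=%s)",
        len(tr_ds), len(va_ds), group_aware,
    )
    return tr_ds, va_ds


def stratified_kfold(train: LabeledDataset, k: int, seed: int) -> FoldPlan:
    """Stratified k-fold plan over the training rows (default study: k = 3).

    Folds partition the rows; per-fold class counts deviate from exact
    proportionality by less than one row per class.
    """
    if k < 2:
        raise FPScreenError(f"k must be >= 2, got {k}")
    counts = train.class_counts
    if min(counts.values()) < k:
        raise FPScreenError(
            f"k={k} exceeds the smallest class size {min(counts.values())}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    indices = train.frame.index.to_numpy()
    folds = np.empty(len(indices), dtype=int)
    for fold_id, (_, test_pos) in enumerate(skf.split(indices, train.y.to_numpy())):
        folds[test_pos] = fold_id
    return FoldPlan(k=k, train_indices=indices, folds=folds)
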