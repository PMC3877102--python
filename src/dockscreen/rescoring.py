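"""Machine learning system A: Random-Forest re-scoring of binding modes.

A pose is described by its 36 interatomic-contact counts concatenated with
the compound's 74 physicochemical descriptors (110 features, schema-hashed
to prevent silent misalignment).  The regression target is experimental
binding affinity on the pKd/pKi scale; inactive compounds enter the
training table as dummy entries with the label pinned to pKd = 1, so the
model carries information about both bound and unbound compounds.

Default hyperparameters follow the classic regression Random Forest
convention: 500 trees, p/3 candidate features per split, fully grown trees.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .contacts import CONTACT_TYPES, ContactVector
from .descriptors import DESCRIPTOR_NAMES, DescriptorVector
from .errors import DegenerateLabelsError, SchemaMismatchError
from .structures import Pose

#: Canonical feature order: 36 contacts then 74 descriptors.
FEATURE_NAMES: tuple[str, ...] = CONTACT_TYPES + DESCRIPTOR_NAMES
N_FEATURES: int = len(FEATURE_NAMES)

INACTIVE_PKD: float = 1.0  # dummy label assigned to confirmed-inactive entries

#: Fixed tool priority used everywhere a tie must break deterministically.
TOOL_PRIORITY: tuple[str, ...] = ("eHiTS", "GOLD", "VINA")


def schema_hash(names: Sequence[str] = FEATURE_NAMES) -> str:
    return hashlib.sha256("\n".join(names).encode()).hexdigest()[:16]


def feature_vector(contact: ContactVector, descriptors: DescriptorVector) -> np.ndarray:
    return np.concatenate([contact.counts.astype(float), descriptors.values])


@dataclass
class TrainingExample:
    """One (pose features, affinity) row of the training table."""

    contact: ContactVector
    descriptors: DescriptorVector
    label_pkd: float
    active: bool = True

    @property
    def features(self) -> np.ndarray:
        return feature_vector(self.contact, self.descriptors)


def build_training_table(
    actives: Sequence[tuple[ContactVector, DescriptorVector, float]],
    inactives: Sequence[tuple[ContactVector, DescriptorVector]] = (),
) -> list[TrainingExample]:
    """Assemble the training table, pinning every inactive's label to pKd = 1.

    Output order is deterministic: actives (input order) then inactives.
    """
    table: list[TrainingExample] = []
    for i, entry in enumerate(actives):
        try:
            contact, desc, pkd = entry
        except (TypeError, ValueError) as exc:
            raise SchemaMismatchError(f"active entry {i} is not (contact, descriptors, pkd)") from exc
        table.append(TrainingExample(contact, desc, float(pkd), active=True))
    for i, entry in enumerate(inactives):
        try:
            contact, desc = entry
        except (TypeError, ValueError) as exc:
            raise SchemaMismatchError(f"inactive entry {i} is not (contact, descriptors)") from exc
        table.append(TrainingExample(contact, desc, INACTIVE_PKD, active=False))
    return table


@dataclass
class RescoringModel:
    """A fitted re-scoring forest plus the metadata needed to use it safely."""

    forest: RandomForestRegressor
    feature_schema_hash: str
    label_range: tuple[float, float]
    n_training: int
    seed: int
    hyperparams: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != N_FEATURES:
            raise SchemaMismatchError(
                f"expected {N_FEATURES} features, got {X.shape[1]}"
            )
        return self.forest.predict(X)

    def save(self, path: str | Path) -> None:
        joblib.dump({"format_version": 1, "model": self}, path)

    @classmethod
    def load(cls, path: str | Path) -> "RescoringModel":
        payload = joblib.load(path)
        model = payload["model"]
        if model.feature_schema_hash != schema_hash():
            raise SchemaMismatchError(
                "model was trained under a different feature schema "
                f"({model.feature_schema_hash} != {schema_hash()})"
            )
        return model


def train_rescorer(
    examples: Sequence[TrainingExample],
    seed: int = 0,
    n_estimators: int = 500,
    max_features: float | int | None = None,
    **forest_kwargs,
) -> RescoringModel:
    """Fit system A on a training table; deterministic given (data, seed, params)."""
    if len(examples) < 20:
        raise DegenerateLabelsError(
            f"need at least 20 training examples, got {len(examples)}"
        )
    y = np.array([ex.label_pkd for ex in examples], dtype=float)
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("training labels are all identical")
    X = np.vstack([ex.features for ex in examples])
    if max_features is None:
        max_features = max(1, N_FEATURES // 3)
    forest = RandomForestRegressor(
        n_estimators=n_estimators,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
        **forest_kwargs,
    )
    forest.fit(X, y)
    return RescoringModel(
        forest=forest,
        feature_schema_hash=schema_hash(),
        label_range=(float(y.min()), float(y.max())),
        n_training=len(examples),
        seed=seed,
        hyperparams={"n_estimators": n_estimators, "max_features": max_features, **forest_kwargs},
    )


def rescore_pose(
    model: RescoringModel, contact: ContactVector, descriptors: DescriptorVector
) -> float:
    """Predicted binding affinity (pKd scale) for one pose.

    Being a mean over tree leaves, the prediction is bounded by the training
    label range.
    """
    return float(model.predict(feature_vector(contact, descriptors))[0])


@dataclass
class ScoredPose:
    pose: Pose
    contact: ContactVector
    rescore: float


def rank_poses(
    model: RescoringModel,
    tool_poses: dict[str, list[tuple[Pose, ContactVector]]],
    descriptors: DescriptorVector,
) -> tuple[dict[str, list[ScoredPose]], dict[str, ScoredPose]]:
    """Re-score every pose and retain the top candidate per tool.

    Within a tool, poses are ordered by re-score descending; score ties break
    toward the lower ``rank_in_tool``.  Returns (full per-tool ranking,
    top-1 candidate per available tool).
    """
    if not any(tool_poses.values()):
        raise ValueError("no poses supplied for any tool")
    ranked: dict[str, list[ScoredPose]] = {}
    top: dict[str, ScoredPose] = {}
    for tool, poses in tool_poses.items():
        if not poses:
            continue
        scored = [
            ScoredPose(pose, contact, rescore_pose(model, contact, descriptors))
            for pose, contact in poses
        ]
        scored.sort(key=lambda s: (-s.rescore, s.pose.rank_in_tool))
        ranked[tool] = scored
        top[tool] = scored[0]
    return ranked, top


# ---------------------------------------------------------------------------
# Tabular helpers (CSV interchange)
# ---------------------------------------------------------------------------


def table_to_arrays(examples: Sequence[TrainingExample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([ex.features for ex in examples])
    y = np.array([ex.label_pkd for ex in examples], dtype=float)
    return X, y
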