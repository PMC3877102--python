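"""End-to-end consensus screening and its validation protocol.

One docking study runs: load protein + per-tool pose sets, count contacts
for every pose, re-score with system A, keep each tool's top candidate,
let system B pick the most reliable mode — its re-score is the compound's
final docking score on the pKd scale.

Model validation follows the repeated random-partition protocol: hold out
15% of the labelled complexes, train on the remaining 85%, predict the
held-out set, measure the Pearson correlation with experimental affinity,
and repeat 25 times to assess sensitivity to the partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .contacts import count_contacts
from .descriptors import compute_descriptors
from .errors import UndefinedCorrelationError
from .mode_selection import Candidate, CandidateTriple, ModeSelectorModel, select_mode
from .rescoring import RescoringModel, rank_poses
from .structures import MolecularStructure, PoseSetManifest, read_pose_set, read_protein

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """Outcome of docking one compound against one protein."""

    compound_id: str
    protein_id: str
    status: str  # "ok" | "no_structure" | "no_modes"
    final_score: float | None = None
    chosen_tool: str | None = None
    candidate_scores: dict[str, float] = field(default_factory=dict)
    selector_probabilities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.status == "ok") != (self.final_score is not None):
            raise ValueError("final_score must be present iff status == 'ok'")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; refuses zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson_r needs two equal-length 1-d arrays of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def screen_compound(
    manifest: PoseSetManifest,
    compound: MolecularStructure,
    model_a: RescoringModel,
    model_b: ModeSelectorModel,
    compound_id: str | None = None,
) -> ScreenResult:
    """Run the full two-stage pipeline for one (compound, protein) pair."""
    compound_id = compound_id or compound.id
    try:
        protein = read_protein(manifest.protein_path)
    except (FileNotFoundError, OSError):
        logger.warning("protein structure unavailable: %s", manifest.protein_path)
        return ScreenResult(compound_id, manifest.protein_path.stem, "no_structure")

    pose_set = read_pose_set(manifest)
    if pose_set.n_poses == 0:
        return ScreenResult(compound_id, protein.id, "no_modes")

    descriptors = compute_descriptors(compound)
    tool_features = {
        tool: [(pose, count_contacts(protein, pose)) for pose in poses]
        for tool, poses in pose_set.poses.items()
    }
    _, top = rank_poses(model_a, tool_features, descriptors)

    triple = CandidateTriple(
        candidates=[
            Candidate(tool=tool, contact=sp.contact, rescore=sp.rescore)
            for tool, sp in sorted(top.items())
        ],
        descriptors=descriptors,
    )
    chosen, probs = select_mode(model_b, triple)
    final = next(c.rescore for c in triple.candidates if c.tool == chosen)
    return ScreenResult(
        compound_id=compound_id,
        protein_id=protein.id,
        status="ok",
        final_score=float(final),
        chosen_tool=chosen,
        candidate_scores={t: float(sp.rescore) for t, sp in top.items()},
        selector_probabilities={t: float(p) for t, p in probs.items()},
    )


@dataclass
class ValidationReport:
    """Per-iteration and summary correlations of the repeated-partition protocol."""

    per_iteration_r: list[float]
    fraction_test: float
    seeds: list[int]
    systems: tuple[str, ...] = ("A",)

    def __post_init__(self) -> None:
        for r in self.per_iteration_r:
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"correlation {r} outside [-1, 1]")
        if len(self.per_iteration_r) != len(self.seeds):
            raise ValueError("one seed per iteration required")

    @property
    def iterations(self) -> int:
        return len(self.per_iteration_r)

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.per_iteration_r))

    @property
    def sd_r(self) -> float:
        return float(np.std(self.per_iteration_r, ddof=1)) if self.iterations > 1 else 0.0

    def as_dict(self) -> dict:
        return {
            "per_iteration_r": self.per_iteration_r,
            "mean_r": self.mean_r,
            "sd_r": self.sd_r,
            "fraction_test": self.fraction_test,
            "iterations": self.iterations,
            "seeds": self.seeds,
            "systems": list(self.systems),
        }


def validation_split(n: int, fraction_test: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic random train/test index split for one iteration."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * fraction_test)))
    return perm[n_test:], perm[:n_test]


def run_validation(
    X: np.ndarray,
    y: np.ndarray,
    fraction_test: float = 0.15,
    iterations: int = 25,
    seeds: Sequence[int] | None = None,
    rf_params: dict | None = None,
) -> ValidationReport:
    """Repeated random-partition validation of the re-scoring system.

    Operating on a labelled feature table (one row per complex), each
    iteration re-trains system A from scratch on its own 85% partition —
    no state leaks between iterations.  Binding-mode selection needs
    labelled pose triples, which a plain feature table does not carry, so
    this protocol validates system A alone and says so in the report.
    """
    if not 0.0 < fraction_test < 1.0:
        raise ValueError(f"fraction_test must be in (0, 1), got {fraction_test}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y) or len(X) < 20:
        raise ValueError("need an aligned dataset of at least 20 rows")
    if seeds is None:
        seeds = list(range(1, iterations + 1))
    seeds = list(seeds)[:iterations]

    from sklearn.ensemble import RandomForestRegressor

    params = {"n_estimators": 500, "max_features": max(1, X.shape[1] // 3), "n_jobs": 1}
    params.update(rf_params or {})
    rs = []
    for seed in seeds:
        train_idx, test_idx = validation_split(len(X), fraction_test, seed)
        forest = RandomForestRegressor(random_state=seed, **params)
        forest.fit(X[train_idx], y[train_idx])
        pred = forest.predict(X[test_idx])
        rs.append(pearson_r(pred, y[test_idx]))
        logger.info("validation iteration seed=%d r=%.4f", seed, rs[-1])
    return ValidationReport(per_iteration_r=rs, fraction_test=fraction_test, seeds=seeds)
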