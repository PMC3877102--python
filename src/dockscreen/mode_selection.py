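"""Machine learning system B: multinomial-logistic binding-mode selection.

After system A has reduced each tool's pose set to its single top-scoring
candidate, system B assigns a probability to each candidate being the most
predictive one and picks the arg-max.  Training labels come from
``label_best_mode``: the candidate whose re-score lies closest to the
experimentally measured affinity.

The selector sees the candidates jointly: its feature vector concatenates
every tool slot's contact vector (zero-filled when a tool produced nothing),
the availability mask, and the shared compound descriptors.  Candidate
re-scores are deliberately not features.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression

from .contacts import N_CONTACT_TYPES, ContactVector
from .descriptors import N_DESCRIPTORS, DescriptorVector
from .errors import DegenerateLabelsError, SchemaMismatchError
from .rescoring import TOOL_PRIORITY

DEFAULT_TOOLS: tuple[str, ...] = TOOL_PRIORITY


def tool_priority_key(tool: str) -> tuple[int, str]:
    """Sort key implementing the fixed tie-break priority eHiTS > GOLD > VINA."""
    try:
        return (TOOL_PRIORITY.index(tool), tool)
    except ValueError:
        return (len(TOOL_PRIORITY), tool)


@dataclass
class Candidate:
    tool: str
    contact: ContactVector
    rescore: float | None = None


@dataclass
class CandidateTriple:
    """The per-tool top candidates for one docking study (<= one per tool)."""

    candidates: list[Candidate]
    descriptors: DescriptorVector

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("a candidate set needs at least one candidate")
        tools = [c.tool for c in self.candidates]
        if len(set(tools)) != len(tools):
            raise ValueError(f"duplicate tool labels in candidate set: {tools}")

    @property
    def tools(self) -> list[str]:
        return [c.tool for c in self.candidates]

    def candidate_for(self, tool: str) -> Candidate | None:
        for c in self.candidates:
            if c.tool == tool:
                return c
        return None


def label_best_mode(triple: CandidateTriple, experimental_pkd: float) -> str:
    """Tool whose candidate re-score is closest to the experimental affinity.

    Ties break by the fixed priority eHiTS > GOLD > VINA (then alphabetical
    for adapter-defined tools).
    """
    scored = [c for c in triple.candidates if c.rescore is not None]
    if not scored:
        raise ValueError("no candidate carries a re-score; cannot label best mode")
    return min(
        scored,
        key=lambda c: (abs(c.rescore - experimental_pkd), tool_priority_key(c.tool)),
    ).tool


def selector_features(
    triple: CandidateTriple, tools: Sequence[str] = DEFAULT_TOOLS
) -> np.ndarray:
    """Joint feature vector: per-slot contacts + availability mask + descriptors."""
    parts = []
    mask = np.zeros(len(tools))
    for i, tool in enumerate(tools):
        cand = triple.candidate_for(tool)
        if cand is None:
            parts.append(np.zeros(N_CONTACT_TYPES))
        else:
            mask[i] = 1.0
            parts.append(cand.contact.counts.astype(float))
    parts.append(mask)
    parts.append(triple.descriptors.values)
    return np.concatenate(parts)


def _selector_schema_hash(tools: Sequence[str]) -> str:
    spec = f"tools={','.join(tools)};contacts={N_CONTACT_TYPES};descriptors={N_DESCRIPTORS}"
    return hashlib.sha256(spec.encode()).hexdigest()[:16]


@dataclass
class ModeSelectorModel:
    """Fitted multinomial logit over the tool categories."""

    clf: LogisticRegression
    tools: tuple[str, ...]
    feature_schema_hash: str
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None
    n_training: int = 0
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def _transform(self, x: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return x
        return (x - self.feature_mean) / self.feature_scale

    def probabilities(self, triple: CandidateTriple) -> dict[str, float]:
        """Probability per available tool, renormalized when a tool is absent."""
        x = self._transform(selector_features(triple, self.tools))
        if _selector_schema_hash(self.tools) != self.feature_schema_hash:
            raise SchemaMismatchError("selector schema hash mismatch")
        raw = self.clf.predict_proba(x.reshape(1, -1))[0]
        by_tool = dict(zip(self.clf.classes_, raw))
        available = [t for t in self.tools if triple.candidate_for(t) is not None]
        if not available:
            raise ValueError("no candidate from any known tool")
        probs = np.array([by_tool.get(t, 0.0) for t in available])
        total = probs.sum()
        if total <= 0:  # model assigns ~0 to every available tool: fall back to uniform
            probs = np.full(len(available), 1.0 / len(available))
        else:
            probs = probs / total
        return dict(zip(available, probs))

    def save(self, path: str | Path) -> None:
        joblib.dump({"format_version": 1, "model": self}, path)

    @classmethod
    def load(cls, path: str | Path) -> "ModeSelectorModel":
        return joblib.load(path)["model"]


def train_selector(
    triples: Sequence[CandidateTriple],
    labels: Sequence[str],
    seed: int = 0,
    tools: Sequence[str] | None = None,
    ridge: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> ModeSelectorModel:
    """Maximum-likelihood multinomial-logit fit, lightly ridge-stabilized.

    Features are standardized internally (the scaler travels with the
    model), which conditions the quasi-Newton optimisation on raw count
    scales.  The tiny L2 penalty keeps the optimum finite on separable
    data; it is applied per observation, so duplicating every training row
    leaves the fit unchanged.  Deterministic given (data, seed).
    """
    if len(triples) != len(labels):
        raise ValueError("triples and labels must align")
    observed = sorted(set(labels), key=tool_priority_key)
    if len(observed) < 2:
        raise DegenerateLabelsError(
            f"only one category observed ({observed}); a constant selector is trivial"
        )
    if tools is None:
        tools = tuple(
            sorted({t for tr in triples for t in tr.tools} | set(observed), key=tool_priority_key)
        )
    X = np.vstack([selector_features(tr, tools) for tr in triples])
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0  # constant columns (e.g. availability mask) pass through
    clf = LogisticRegression(
        C=1.0 / (ridge * len(X)),  # per-observation penalty: sufficiency-preserving
        tol=tol,
        max_iter=max_iter,
        solver="lbfgs",
        random_state=seed,
    )
    clf.fit((X - mean) / scale, np.asarray(labels))
    return ModeSelectorModel(
        clf=clf,
        tools=tuple(tools),
        feature_schema_hash=_selector_schema_hash(tools),
        feature_mean=mean,
        feature_scale=scale,
        n_training=len(triples),
        seed=seed,
        metadata={"ridge": ridge, "tol": tol, "max_iter": max_iter},
    )


def select_mode(
    model: ModeSelectorModel, triple: CandidateTriple
) -> tuple[str, dict[str, float]]:
    """Pick the most reliable candidate: arg-max probability, priority tie-break."""
    probs = model.probabilities(triple)
    chosen = min(probs, key=lambda t: (-probs[t], tool_priority_key(t)))
    return chosen, probs
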