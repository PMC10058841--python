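"""Coordinate-matched accuracy evaluation.

Predicted labels are scored against an independently annotated truth set
by pairing points at the same spatial position, then counting per class:
T_j correct points out of H_j truth points of class j give the per-class
accuracy K_j = T_j / H_j, and the overall accuracy is

    K_Overall = sum_j T_j / sum_j H_j,

i.e. all correctly classified matched points over all matched points.
K_Overall is therefore always the H_j-weighted mean of the K_j.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .cloud import LABEL_NAMES, ComponentLabel, SpectralPointCloud

__all__ = ["ClassificationReport", "match_points", "score", "MatchError"]


class MatchError(ValueError):
    """Raised when coordinate matching between clouds is ambiguous."""


@dataclass
class ClassificationReport:
    """Per-class and overall accuracy plus the full confusion matrix.

    ``confusion[i, j]`` counts truth class ``i+1`` predicted as ``j+1``
    (codes 1..4); row sums are the truth totals H_j, the diagonal the
    correct counts T_j.  Classes absent from the truth set have K_j
    reported as NaN and contribute nothing to K_Overall.
    """

    confusion: np.ndarray
    n_unmatched_predicted: int = 0
    n_unmatched_truth: int = 0

    @property
    def correct(self) -> np.ndarray:  # T_j
        return np.diag(self.confusion)

    @property
    def totals(self) -> np.ndarray:  # H_j
        return self.confusion.sum(axis=1)

    @property
    def per_class_accuracy(self) -> np.ndarray:  # K_j
        H = self.totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(H > 0, self.correct / H, np.nan)

    @property
    def overall_accuracy(self) -> float:  # K_Overall
        H = self.totals.sum()
        return float(self.correct.sum() / H) if H else float("nan")

    def to_dict(self) -> dict:
        K = self.per_class_accuracy
        return {
            "per_class": {
                LABEL_NAMES[lab]: {
                    "correct": int(self.correct[lab - 1]),
                    "total": int(self.totals[lab - 1]),
                    "accuracy": None if np.isnan(K[lab - 1]) else float(K[lab - 1]),
                }
                for lab in ComponentLabel
            },
            "overall_accuracy": self.overall_accuracy,
            "confusion": self.confusion.tolist(),
            "n_unmatched_predicted": self.n_unmatched_predicted,
            "n_unmatched_truth": self.n_unmatched_truth,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def __str__(self) -> str:
        K = self.per_class_accuracy
        lines = [f"{'class':>12} {'correct':>8} {'total':>8} {'K_j':>8}"]
        for lab in ComponentLabel:
            kj = K[lab - 1]
            lines.append(
                f"{LABEL_NAMES[lab]:>12} {self.correct[lab - 1]:>8d} "
                f"{self.totals[lab - 1]:>8d} "
                f"{'--' if np.isnan(kj) else f'{kj:.4f}':>8}"
            )
        lines.append(f"{'Overall':>12} {self.correct.sum():>8d} "
                     f"{self.totals.sum():>8d} {self.overall_accuracy:>8.4f}")
        return "\n".join(lines)


def match_points(
    predicted: SpectralPointCloud,
    truth: SpectralPointCloud,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Pair predicted and truth points at identical coordinates.

    Both clouds must carry labels.  Points are matched one-to-one when
    their coordinates agree within ``tol`` metres; a predicted point with
    two truth candidates inside ``tol`` is an ambiguity error.  Returns
    ``(predicted_labels, truth_labels, info)`` for the matched pairs,
    where ``info`` reports unmatched counts on either side.
    """
    if predicted.labels is None or truth.labels is None:
        raise ValueError("both clouds must carry labels")
    if len(predicted) == 0 or len(truth) == 0:
        raise ValueError("clouds must be non-empty")

    tree = cKDTree(truth.coords)
    neighbors = tree.query_ball_point(predicted.coords, r=tol)
    pred_lab, true_lab = [], []
    matched_truth = np.zeros(len(truth), dtype=bool)
    unmatched_pred = 0
    for i, cand in enumerate(neighbors):
        if len(cand) > 1:
            raise MatchError(
                f"predicted point {i} matches {len(cand)} truth points "
                f"within {tol} m"
            )
        if not cand:
            unmatched_pred += 1
            continue
        j = cand[0]
        if matched_truth[j]:
            raise MatchError(
                f"truth point {j} matches multiple predicted points within {tol} m"
            )
        matched_truth[j] = True
        pred_lab.append(predicted.labels[i])
        true_lab.append(truth.labels[j])
    info = {
        "n_matched": len(pred_lab),
        "n_unmatched_predicted": unmatched_pred,
        "n_unmatched_truth": int((~matched_truth).sum()),
    }
    return (
        np.asarray(pred_lab, dtype=np.int64),
        np.asarray(true_lab, dtype=np.int64),
        info,
    )


def score(
    predicted_labels: np.ndarray,
    truth_labels: np.ndarray,
    n_unmatched_predicted: int = 0,
    n_unmatched_truth: int = 0,
) -> ClassificationReport:
    """Build the accuracy report from paired label lists."""
    predicted_labels = np.asarray(predicted_labels, dtype=np.int64)
    truth_labels = np.asarray(truth_labels, dtype=np.int64)
    if predicted_labels.shape != truth_labels.shape:
        raise ValueError("paired label lists must have equal length")
    if predicted_labels.size == 0:
        raise ValueError("no matched pairs to score")
    k = len(ComponentLabel)
    confusion = np.zeros((k, k), dtype=np.int64)
    np.add.at(confusion, (truth_labels - 1, predicted_labels - 1), 1)
    return ClassificationReport(
        confusion=confusion,
        n_unmatched_predicted=n_unmatched_predicted,
        n_unmatched_truth=n_unmatched_truth,
    )


def evaluate_clouds(
    predicted: SpectralPointCloud,
    truth: SpectralPointCloud,
    tol: float = 1e-9,
) -> ClassificationReport:
    """Match by coordinates then score; the full evaluation in one call.

    When both labels live on the same cloud object, matching by index is
    equivalent and cheaper: call :func:`score` directly on the two label
    arrays.
    """
    pred_lab, true_lab, info = match_points(predicted, truth, tol=tol)
    return score(
        pred_lab,
        true_lab,
        n_unmatched_predicted=info["n_unmatched_predicted"],
        n_unmatched_truth=info["n_unmatched_truth"],
    )
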