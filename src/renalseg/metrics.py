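"""Volumetric overlap evaluation: Dice, precision, recall and cohort summaries."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import read_labels

logger = logging.getLogger(__name__)

__all__ = ["dsc", "precision", "recall", "EvalReport", "evaluate_cases", "score_labels"]

CLASS_NAMES = {1: "medulla", 2: "cortex"}


def _check(G: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    G = np.asarray(G) > 0
    S = np.asarray(S) > 0
    if G.shape != S.shape:
        raise ValueError(f"shape mismatch: {G.shape} vs {S.shape}")
    return G, S


def dsc(G: np.ndarray, S: np.ndarray) -> float:
    """Dice similarity 2|G n S| / (|G| + |S|); 1 when both are empty."""
    G, S = _check(G, S)
    denom = G.sum() + S.sum()
    if denom == 0:
        warnings.warn("both volumes empty: DSC defined as 1", stacklevel=2)
        return 1.0
    return float(2.0 * np.logical_and(G, S).sum() / denom)


def precision(G: np.ndarray, S: np.ndarray) -> float:
    """|S n G| / |S|; 0 for empty S against non-empty G, 1 when both empty."""
    G, S = _check(G, S)
    if S.sum() == 0:
        if G.sum() == 0:
            warnings.warn("both volumes empty: precision defined as 1", stacklevel=2)
            return 1.0
        return 0.0
    return float(np.logical_and(G, S).sum() / S.sum())


def recall(G: np.ndarray, S: np.ndarray) -> float:
    """|S n G| / |G|; 0 for empty G against non-empty S, 1 when both empty."""
    return precision(S, G)


def score_labels(
    truth: np.ndarray, pred: np.ndarray, classes: dict[int, str] = CLASS_NAMES
) -> dict[str, dict[str, float]]:
    """Per-class DSC/PC/RC for two label volumes, plus the whole kidney."""
    out = {}
    for value, name in classes.items():
        out[name] = {
            "dsc": dsc(truth == value, pred == value),
            "pc": precision(truth == value, pred == value),
            "rc": recall(truth == value, pred == value),
        }
    out["kidney"] = {
        "dsc": dsc(truth > 0, pred > 0),
        "pc": precision(truth > 0, pred > 0),
        "rc": recall(truth > 0, pred > 0),
    }
    return out


@dataclass
class EvalReport:
    per_case: pd.DataFrame  # columns: case, stratum, class, dsc, pc, rc
    summary: pd.DataFrame  # mean and sample SD per class and stratum

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.per_case.to_csv(path, index=False)
        self.summary.to_csv(path.with_name(path.stem + "_summary.csv"))


def summarize(per_case: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD (ddof=1; 0 for singletons) per stratum and class."""
    def _sd(x):
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    groups = per_case.groupby(["stratum", "class"])[["dsc", "pc", "rc"]]
    return groups.agg(["mean", _sd]).rename(columns={"_sd": "sd"})


def evaluate_cases(
    pred_dir: str | Path,
    truth_dir: str | Path,
    strata: dict[str, str] | None = None,
    pattern: str = "*.nii*",
) -> EvalReport:
    """Score every prediction NIfTI against its same-named ground truth.

    ``strata`` maps case id to a stratum label (e.g. normal/abnormal);
    unmatched cases are warned about and excluded.
    """
    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    rows = []
    for pred_path in sorted(pred_dir.glob(pattern)):
        case = pred_path.name.split(".")[0]
        matches = sorted(truth_dir.glob(f"{case}.nii*"))
        if not matches:
            logger.warning("no ground truth for case %s: excluded", case)
            continue
        truth = read_labels(matches[0]).data
        pred = read_labels(pred_path).data
        stratum = (strata or {}).get(case, "all")
        for cls, scores in score_labels(truth, pred).items():
            rows.append({"case": case, "stratum": stratum, "class": cls, **scores})
    per_case = pd.DataFrame(rows, columns=["case", "stratum", "class", "dsc", "pc", "rc"])
    return EvalReport(per_case=per_case, summary=summarize(per_case) if len(per_case) else pd.DataFrame())
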