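"""Per-species WSS cut-off calibration from labelled training pairs.

The cut-off separating related from unrelated strain pairs is learned
from labelled score lists, emulating a calibration design where
related pairs are the same individual re-sampled at separate times and
unrelated pairs come from different individuals.  When the two score
distributions are separable the cut-off is the midpoint between the
highest unrelated and the lowest related score; otherwise the
threshold maximising Youden's J over the empirical ROC is used, with
ties resolved toward the higher threshold (favouring specificity).
Species lacking training pairs in either class receive no cut-off and
are excluded from downstream classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SpeciesCutoff:
    species_id: str
    cutoff: float
    n_related_train: int
    n_unrelated_train: int
    training_error: float


class InsufficientTrainingPairs(ValueError):
    """Raised when a species lacks related or unrelated training scores."""


def _validate_scores(scores, name: str) -> np.ndarray:
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise InsufficientTrainingPairs(f"insufficient training pairs: no {name} scores")
    if not np.isfinite(arr).all() or (arr < 0).any() or (arr > 100).any():
        raise ValueError(f"{name} scores must be finite and in [0, 100]")
    return arr


def _training_error(related: np.ndarray, unrelated: np.ndarray, cutoff: float) -> float:
    # classification rule: related iff score > cutoff
    wrong = int((related <= cutoff).sum()) + int((unrelated > cutoff).sum())
    return wrong / (related.size + unrelated.size)


def calibrate_cutoff(
    related_scores, unrelated_scores, species_id: str = ""
) -> SpeciesCutoff:
    """Derive one species' cut-off from labelled training scores."""
    related = _validate_scores(related_scores, "related")
    unrelated = _validate_scores(unrelated_scores, "unrelated")
    if related.min() > unrelated.max():
        cutoff = float((unrelated.max() + related.min()) / 2.0)
    else:
        # Youden's J = TPR - FPR over candidate thresholds; candidates are
        # the observed scores plus a threshold below all of them.
        candidates = np.concatenate(([min(related.min(), unrelated.min()) - 1.0],
                                     np.unique(np.concatenate([related, unrelated]))))
        best_j, cutoff = -np.inf, float(candidates[0])
        for t in candidates:
            tpr = float((related > t).mean())
            fpr = float((unrelated > t).mean())
            j = tpr - fpr
            if j > best_j or (j == best_j and t > cutoff):
                best_j, cutoff = j, float(t)
    err = _training_error(related, unrelated, cutoff)
    if err > 0:
        warnings.warn(
            f"species {species_id or '?'}: related/unrelated training scores "
            f"overlap (training error {err:.3f})",
            stacklevel=2,
        )
    return SpeciesCutoff(species_id, cutoff, related.size, unrelated.size, err)


def calibrate_all(
    score_table: pd.DataFrame, labels: pd.DataFrame
) -> tuple[dict[str, SpeciesCutoff], list[dict[str, str]]]:
    """Calibrate every species in a scores table.

    ``score_table`` needs columns species, sample_a, sample_b, score;
    ``labels`` needs species, sample_a, sample_b, label
    (related/unrelated).  Returns the cut-off map plus an exclusion
    report listing species that could not be calibrated.
    """
    merged = score_table.merge(
        labels, on=["species", "sample_a", "sample_b"], how="left", validate="one_to_one"
    )
    if merged["label"].isna().any():
        missing = merged[merged["label"].isna()][["species", "sample_a", "sample_b"]]
        raise ValueError(f"unlabelled training pairs:\n{missing.to_string(index=False)}")
    cutoffs: dict[str, SpeciesCutoff] = {}
    excluded: list[dict[str, str]] = []
    for species, df in merged.groupby("species", sort=True):
        scored = df[df["score"].notna()]
        rel = scored.loc[scored["label"] == "related", "score"]
        unrel = scored.loc[scored["label"] == "unrelated", "score"]
        try:
            cutoffs[str(species)] = calibrate_cutoff(rel, unrel, str(species))
        except InsufficientTrainingPairs as exc:
            excluded.append({"species": str(species), "reason": str(exc)})
    return cutoffs, excluded


def write_cutoffs_tsv(cutoffs: dict[str, SpeciesCutoff], path) -> None:
    rows = [
        {
            "species": c.species_id,
            "cutoff": c.cutoff,
            "n_related_train": c.n_related_train,
            "n_unrelated_train": c.n_unrelated_train,
            "training_error": c.training_error,
        }
        for c in sorted(cutoffs.values(), key=lambda c: c.species_id)
    ]
    pd.DataFrame(
        rows,
        columns=["species", "cutoff", "n_related_train", "n_unrelated_train", "training_error"],
    ).to_csv(path, sep="\t", index=False)


def read_cutoffs_tsv(path) -> dict[str, SpeciesCutoff]:
    """Read a cut-offs TSV, e.g. one holding published per-species values."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, SpeciesCutoff] = {}
    for _, row in df.iterrows():
        out[str(row["species"])] = SpeciesCutoff(
            str(row["species"]),
            float(row["cutoff"]),
            int(row.get("n_related_train", 1) or 1),
            int(row.get("n_unrelated_train", 1) or 1),
            float(row.get("training_error", 0.0) or 0.0),
        )
    return out
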