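"""Night-comparison augmentation.

A subject contributes only a few nights, and very few pre-migraine ones, so
single nights make too small a training set for cross-validation.  The
augmentation therefore uses *differences between nights* as observations:

* every pre-migraine night minus every non-migraine night, labelled as a
  migraine comparison (sign fixed at +1);
* every unordered pair of non-migraine nights, labelled as a non-migraine
  comparison, computed in one direction only with a uniformly random sign —
  otherwise the mirrored pair would leak the same information twice.

From ``a`` migraine nights and ``b`` non-migraine nights this yields
``a·b + b·(b−1)/2`` observations.  Because of the random signs the matrix
is stochastic; downstream evaluation regenerates it per repetition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import FEATURE_NAMES, NightFeatureVector

MIGRAINE_COMPARISON = "migraine_comparison"
NON_MIGRAINE_COMPARISON = "non_migraine_comparison"


@dataclass(frozen=True)
class ComparisonObservation:
    """One signed night-difference vector with provenance.

    ``values = sign × (left − right)``; the label is a migraine comparison
    exactly when the left night is pre-migraine, and a migraine night never
    appears on the right.
    """

    values: np.ndarray
    label: str
    left_night_id: str
    right_night_id: str
    sign: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.sign not in (-1, 1):
            raise ValidationError("sign must be +1 or -1")
        if self.label not in (MIGRAINE_COMPARISON, NON_MIGRAINE_COMPARISON):
            raise ValidationError(f"unknown label {self.label!r}")
        if self.label == MIGRAINE_COMPARISON and self.sign != 1:
            raise ValidationError("migraine comparisons carry a fixed +1 sign")


def count_observations(n_mig: int, n_non: int) -> int:
    """Closed-form size of the comparison set: ``n_mig·n_non + C(n_non, 2)``."""
    if n_mig < 0 or n_non < 0:
        raise ValidationError("night counts must be nonnegative")
    return n_mig * n_non + (n_non * (n_non - 1)) // 2


def build_comparison_matrix(nights: list[NightFeatureVector],
                            seed: int) -> list[ComparisonObservation]:
    """All comparison observations for one subject's nights.

    Nights are ordered lexicographically by ``night_id`` before the sign
    draws so the map ``seed -> matrix`` is deterministic.
    """
    mig = sorted((n for n in nights if n.label == "pre_migraine"), key=lambda n: n.night_id)
    non = sorted((n for n in nights if n.label == "non_migraine"), key=lambda n: n.night_id)
    if not (len(non) >= 2 or (len(mig) >= 1 and len(non) >= 1)):
        raise ValidationError(
            f"need >=2 non-migraine nights or >=1 of each class; "
            f"got {len(mig)} migraine, {len(non)} non-migraine")
    rng = np.random.default_rng(seed)
    obs: list[ComparisonObservation] = []
    for m in mig:
        for nj in non:
            obs.append(ComparisonObservation(
                m.values - nj.values, MIGRAINE_COMPARISON,
                m.night_id, nj.night_id, 1, m.subject_id))
    for i, ni in enumerate(non):
        for nj in non[i + 1:]:
            s = 1 if rng.random() < 0.5 else -1
            obs.append(ComparisonObservation(
                s * (ni.values - nj.values), NON_MIGRAINE_COMPARISON,
                ni.night_id, nj.night_id, s, ni.subject_id))
    assert len(obs) == count_observations(len(mig), len(non))
    return obs


def observations_matrix(obs: list[ComparisonObservation]) -> tuple[np.ndarray, np.ndarray]:
    """Stack observations into ``(X, y)`` arrays."""
    X = np.vstack([o.values for o in obs]) if obs else np.empty((0, len(FEATURE_NAMES)))
    y = np.array([o.label for o in obs])
    return X, y


def observations_to_frame(obs: list[ComparisonObservation]) -> pd.DataFrame:
    rows = [{"subject_id": o.subject_id, "label": o.label,
             "left_night_id": o.left_night_id, "right_night_id": o.right_night_id,
             "sign": o.sign, **dict(zip(FEATURE_NAMES, o.values))} for o in obs]
    return pd.DataFrame(rows, columns=["subject_id", "label", "left_night_id",
                                       "right_night_id", "sign", *FEATURE_NAMES])
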