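"""Fragment-size-distribution (FSD) features.

Fragment lengths on 100–220 bp are binned into 24 five-bp intervals
(100–104, 105–109, …, 215–219; both bounds inclusive, 220 bp excluded) on
each of the 39 canonical chromosome arms, giving a fixed 936-entry vector.
Per arm, bin counts are divided by the arm's in-range total (arms with no
in-range fragments emit zeros). Raw proportions are then converted to
z-scores over the full 936-entry vector *within* the sample — cohort-free
normalization, so the features are portable across datasets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from fragdecipher.fragments import FragmentSet, assign_intervals
from fragdecipher.synthetic import ARM_NAMES, GenomeModel

__all__ = ["FSD_BIN_EDGES", "fsd_bin_labels", "fsd_proportions", "zscore_within_sample", "fsd_feature_matrix"]

#: Left edges of the 24 five-bp bins: 100, 105, ..., 215.
FSD_BIN_EDGES: np.ndarray = np.arange(100, 220, 5)


def fsd_bin_labels() -> list[str]:
    """Feature names ARM_loLEN_hiLEN in arm-major order (24 per arm, 936 total)."""
    return [f"{arm}_{lo}_{lo + 4}" for arm in ARM_NAMES for lo in FSD_BIN_EDGES]


def fsd_proportions(fragset: FragmentSet, model: GenomeModel,
                    per_genome: bool = False) -> pd.Series:
    """Per-arm (default) or per-genome length-bin proportions.

    Arms in the canonical vocabulary that are absent from the model, or have
    no in-range fragments, occupy zero-valued slots so the output dimension
    is always 936.
    """
    model_arms = set(model.arm_names)
    unknown = model_arms - set(ARM_NAMES)
    if unknown:
        raise ValueError(f"unknown arm names in model: {sorted(unknown)}")
    assigned = assign_intervals(fragset, model.arm_intervals())
    lengths = fragset.lengths
    in_range = (lengths >= 100) & (lengths <= 219)
    bin_idx = (lengths - 100) // 5

    values = np.zeros(len(ARM_NAMES) * 24)
    total_in_range = 0
    counts_by_arm: dict[str, np.ndarray] = {}
    for a, arm in enumerate(ARM_NAMES):
        m = (assigned == arm) & in_range
        counts = np.bincount(bin_idx[m].astype(int), minlength=24)[:24].astype(float)
        counts_by_arm[arm] = counts
        total_in_range += counts.sum()
        if arm in model_arms and counts.sum() == 0:
            warnings.warn(f"arm {arm}: no in-range fragments; emitting zeros", stacklevel=2)
    for a, arm in enumerate(ARM_NAMES):
        counts = counts_by_arm[arm]
        denom = total_in_range if per_genome else counts.sum()
        if denom > 0:
            values[a * 24 : (a + 1) * 24] = counts / denom
    return pd.Series(values, index=fsd_bin_labels(), name=fragset.sample_id)


def zscore_within_sample(vector: pd.Series) -> pd.Series:
    """z = (x - mean) / SD over this sample's full vector, population SD;
    a degenerate (constant) vector maps to all zeros."""
    x = vector.to_numpy(dtype=float)
    sd = x.std()  # population (ddof=0) by design, for bit-reproducibility
    if sd == 0:
        return pd.Series(np.zeros_like(x), index=vector.index, name=vector.name)
    return pd.Series((x - x.mean()) / sd, index=vector.index, name=vector.name)


def fsd_feature_matrix(fragsets: dict[str, FragmentSet], model: GenomeModel,
                       per_genome: bool = False) -> pd.DataFrame:
    """Samples x 936 z-scored FSD matrix."""
    rows = {
        sid: zscore_within_sample(fsd_proportions(fs, model, per_genome=per_genome))
        for sid, fs in fragsets.items()
    }
    return pd.DataFrame(rows).T
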