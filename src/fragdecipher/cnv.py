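"""Copy-number features: bin counts, healthy baseline, log2 ratios and a
simplified 3-state HMM segmentation.

For sample *s* with normalized per-bin fragment proportions ``r`` and a
healthy-panel baseline ``h`` (per-bin median of normalized proportions,
renormalized to sum 1), the bin-level log2 copy ratio is
``l_t = log2(r_t / h_t)``, defined only where ``h_t > 0``. Segmentation uses
a Viterbi path over {loss, neutral, gain} with Gaussian emissions at means
(-mu, 0, +mu), shared sigma, and symmetric stay-probability transitions —
a deliberately simple smoother, not a tumor-fraction caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fragdecipher.fragments import FragmentSet, assign_intervals
from fragdecipher.synthetic import ARM_NAMES, GenomeModel

__all__ = [
    "CNVProfile",
    "HMMParams",
    "bin_counts",
    "build_baseline",
    "log2_ratio",
    "segment_states",
    "cnv_profile",
    "cnv_feature_vector",
    "cnv_feature_matrix",
]

STATES = ("loss", "neutral", "gain")


@dataclass
class CNVProfile:
    bins: list[str]
    r: np.ndarray            # normalized sample proportions (sum 1 over usable bins)
    h: np.ndarray            # baseline proportions
    l: np.ndarray            # log2(r/h); NaN where the baseline is unusable
    states: list[str] | None = None
    arm_of_bin: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class HMMParams:
    mu: float = 0.3
    sigma: float = 0.15
    stay_prob: float = 0.99

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.stay_prob < 1:
            raise ValueError("stay_prob must be in (0, 1)")


def bin_counts(fragset: FragmentSet, model: GenomeModel) -> pd.Series:
    """Midpoint-assigned fragment counts per CNV bin (ordered as in the model)."""
    intervals = model.bin_intervals()
    names = [n for n, _, _, _ in intervals]
    assigned = assign_intervals(fragset, intervals)
    counts = pd.Series(assigned).value_counts()
    return pd.Series([int(counts.get(n, 0)) for n in names], index=names, name=fragset.sample_id)


def baseline_to_frame(h: pd.Series, model: GenomeModel) -> pd.DataFrame:
    """Baseline as a bin_id/chrom/start/end/h table for TSV interchange."""
    coords = pd.DataFrame(model.cnv_bins, columns=["chrom", "start", "end"],
                          index=[n for n, _, _, _ in model.bin_intervals()])
    out = coords.loc[h.index].copy()
    out["h"] = h
    out.index.name = "bin_id"
    return out


def gc_correct(counts: pd.Series, gc: pd.Series, n_deciles: int = 10) -> pd.Series:
    """Median-by-decile GC normalization hook for real data.

    Bins are grouped into GC-content deciles; each bin's count is divided by
    its decile's median count and rescaled by the global median. Synthetic
    data carry no GC bias, so this is not applied by default anywhere.
    """
    gc = gc.reindex(counts.index)
    if gc.isna().any():
        raise ValueError("GC track does not cover all bins")
    dec = pd.qcut(gc, q=n_deciles, labels=False, duplicates="drop")
    med = counts.groupby(dec).transform("median").astype(float)
    med[med == 0] = np.nan
    corrected = counts / med * float(counts.median())
    return corrected.fillna(0.0)


def _normalize(counts: pd.Series) -> np.ndarray:
    total = counts.to_numpy().sum()
    if total == 0:
        raise ValueError("no fragments assigned to any bin")
    return counts.to_numpy(dtype=float) / total


def build_baseline(healthy_counts: list[pd.Series]) -> pd.Series:
    """Per-bin median of each healthy sample's normalized proportions,
    renormalized to sum 1. Bins with zero median are unusable (baseline 0).
    """
    if len(healthy_counts) < 2:
        raise ValueError("baseline panel needs at least 2 healthy samples")
    index = healthy_counts[0].index
    props = np.stack([_normalize(c.reindex(index, fill_value=0)) for c in healthy_counts])
    med = np.median(props, axis=0)
    usable = med > 0
    if usable.any():
        med = med / med[usable].sum()
    return pd.Series(med, index=index, name="h")


def log2_ratio(r: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Elementwise log2(r/h); bins with h == 0 return NaN, never +/-inf."""
    r = np.asarray(r, dtype=float)
    h = np.asarray(h, dtype=float)
    if r.shape != h.shape:
        raise ValueError("r and h must be aligned")
    if (r < 0).any():
        raise ValueError("negative sample proportion")
    l = np.full(r.shape, np.nan)
    ok = h > 0
    with np.errstate(divide="ignore"):
        l[ok] = np.log2(r[ok] / h[ok])
    l[ok & (r == 0)] = np.nan  # empty bin against a usable baseline: missing, not -inf
    return l


def segment_states(l: np.ndarray, params: HMMParams = HMMParams()) -> list[str]:
    """Viterbi path over {loss, neutral, gain}; missing (NaN) bins are
    skipped for emissions and bridged by the transition matrix, and labeled
    by the state carried across them."""
    l = np.asarray(l, dtype=float)
    usable = ~np.isnan(l)
    if not usable.any():
        raise ValueError("no usable bins to segment")
    obs = l[usable]
    means = np.array([-params.mu, 0.0, params.mu])
    log_trans = np.log(
        np.where(
            np.eye(3, dtype=bool),
            params.stay_prob,
            (1.0 - params.stay_prob) / 2.0,
        )
    )
    # Gaussian log-likelihood up to a shared constant
    ll = -0.5 * ((obs[:, None] - means[None, :]) / params.sigma) ** 2
    n = len(obs)
    delta = np.full((n, 3), -np.inf)
    psi = np.zeros((n, 3), dtype=int)
    delta[0] = np.log(1.0 / 3.0) + ll[0]
    for t in range(1, n):
        cand = delta[t - 1][:, None] + log_trans
        psi[t] = np.argmax(cand, axis=0)
        delta[t] = cand[psi[t], np.arange(3)] + ll[t]
    path = np.zeros(n, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]

    out: list[str] = []
    j = 0
    last = STATES[path[0]]
    for t in range(len(l)):
        if usable[t]:
            last = STATES[path[j]]
            j += 1
        out.append(last)
    return out


def cnv_profile(
    counts: pd.Series,
    baseline: pd.Series,
    model: GenomeModel,
    hmm: HMMParams | None = None,
) -> CNVProfile:
    """Assemble the per-bin profile (r, h, l and optional states) for one sample."""
    counts = counts.reindex(baseline.index, fill_value=0)
    r = _normalize(counts)
    h = baseline.to_numpy(dtype=float)
    l = log2_ratio(r, h)
    bin_arm = _bin_arms(model)
    states = segment_states(l, hmm) if hmm is not None else None
    return CNVProfile(bins=list(baseline.index), r=r, h=h, l=l, states=states, arm_of_bin=bin_arm)


def _bin_arms(model: GenomeModel) -> list[str]:
    arms = model.arm_intervals()
    out = []
    for chrom, start, end in model.cnv_bins:
        mid = (start + end) // 2
        name = next(
            (a for a, c, s, e in arms if c == chrom and s <= mid < e), "unassigned"
        )
        out.append(name)
    return out


def cnv_feature_vector(profile: CNVProfile, use_segments: bool = False) -> pd.Series:
    """Model-facing CNV features: per-bin log2 ratios plus per-arm means
    over the canonical 39-arm vocabulary (absent arms contribute 0).

    With ``use_segments=True`` the per-bin values are replaced by the mean
    log2 ratio of the Viterbi segment containing each bin.
    """
    l = profile.l.copy()
    if use_segments:
        if profile.states is None:
            raise ValueError("profile has no segmentation")
        states = np.array(profile.states, dtype=object)
        seg_id = np.concatenate([[0], np.cumsum(states[1:] != states[:-1])])
        for sid in np.unique(seg_id):
            m = (seg_id == sid) & ~np.isnan(profile.l)
            if m.any():
                l[seg_id == sid] = np.nanmean(profile.l[seg_id == sid])
    values = {f"CNV_{b}": (0.0 if np.isnan(v) else float(v)) for b, v in zip(profile.bins, l)}
    arm_arr = np.array(profile.arm_of_bin, dtype=object)
    for arm in ARM_NAMES:
        m = (arm_arr == arm) & ~np.isnan(profile.l)
        values[f"CNV_armmean_{arm}"] = float(np.mean(profile.l[m])) if m.any() else 0.0
    return pd.Series(values)


def cnv_feature_matrix(
    fragsets: dict[str, FragmentSet],
    baseline: pd.Series,
    model: GenomeModel,
    use_segments: bool = False,
    hmm: HMMParams | None = None,
) -> pd.DataFrame:
    """Samples x CNV-features matrix (rows ordered as the input mapping)."""
    if use_segments and hmm is None:
        hmm = HMMParams()
    rows = {}
    for sid, fs in fragsets.items():
        prof = cnv_profile(bin_counts(fs, model), baseline, model, hmm=hmm)
        rows[sid] = cnv_feature_vector(prof, use_segments=use_segments)
    return pd.DataFrame(rows).T
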