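"""PFE depth-stability analysis.

Within a label stratum (cancer / non-cancer), individual samples are merged
into composite reference samples holding ``target_multiple`` times the
nominal per-sample fragment count (the stand-in for a 50x reference built
from ~5x samples). Each composite is randomly downsampled to the fractions
{40, 30, 20, 10, 5}/50 and the full PFE pipeline — prior, control
entropies, gene scores, within-sample normalization — is recomputed from
scratch at every depth. Concordance is the Pearson correlation of each
depth's normalized gene-score vector with the reference vector (genes
missing at either depth dropped pairwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from fragdecipher.fragments import FragmentSet, downsample, merge_fragment_sets
from fragdecipher.pfe import PFEConfig, pfe_scores
from fragdecipher.synthetic import GenomeModel

__all__ = ["DEFAULT_DEPTH_FRACTIONS", "build_composite", "depth_series",
           "depth_correlation", "depth_stability_report"]

#: target depths 40x/30x/20x/10x/5x relative to the 50x composite reference
DEFAULT_DEPTH_FRACTIONS: tuple[float, ...] = (40 / 50, 30 / 50, 20 / 50, 10 / 50, 5 / 50)


def build_composite(fragsets: list[FragmentSet], target_multiple: float,
                    nominal_count: int, composite_id: str) -> FragmentSet:
    """Union samples (in order) until the composite holds at least
    ``target_multiple * nominal_count`` fragments."""
    if len(fragsets) < 2:
        raise ValueError("a composite needs at least 2 samples")
    target = int(round(target_multiple * nominal_count))
    chosen: list[FragmentSet] = []
    total = 0
    for fs in fragsets:
        chosen.append(fs)
        total += len(fs)
        if total >= target:
            break
    if total < target:
        raise ValueError(f"insufficient fragments: have {total}, need {target}")
    return merge_fragment_sets(chosen, sample_id=composite_id)


def depth_series(composite: FragmentSet, model: GenomeModel,
                 config: PFEConfig = PFEConfig(),
                 fractions: tuple[float, ...] = DEFAULT_DEPTH_FRACTIONS,
                 seed: int = 0,
                 reuse_reference_prior: bool = False) -> dict[float, pd.Series]:
    """Normalized PFE vector at each depth fraction (1.0 = the reference).

    Each fraction is an independent random downsample of the composite; the
    entire PFE computation (including the NDR-flank prior and the control
    entropies) is redone on the downsampled data — the stricter reading.
    ``reuse_reference_prior=True`` instead carries the composite's
    full-depth prior into every downsampled recomputation.
    """
    from fragdecipher.pfe import prior_distribution

    ref_prior = (prior_distribution(composite, model, config)
                 if reuse_reference_prior else None)
    out: dict[float, pd.Series] = {}
    for i, frac in enumerate(fractions):
        if frac == 1.0:
            sub = composite
        else:
            sub = downsample(composite, fraction=frac,
                             seed=int(np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0]))
            sub.sample_id = f"{composite.sample_id}@{frac:.2f}"
        out[frac] = pfe_scores(sub, model, config, prior=ref_prior).normalized_scores
    return out


def depth_correlation(series: dict[float, pd.Series], reference: pd.Series) -> pd.DataFrame:
    """Pearson r of each depth's PFE vector against the reference vector."""
    rows = []
    for frac, vec in sorted(series.items()):
        joined = pd.concat([vec, reference], axis=1, keys=["depth", "ref"]).dropna()
        if len(joined) < 3:
            raise ValueError(f"fraction {frac}: fewer than 3 shared genes")
        r = stats.pearsonr(joined["depth"], joined["ref"]).statistic
        rows.append({"fraction": frac, "pearson_r": float(r), "n_genes": len(joined)})
    return pd.DataFrame(rows)


@dataclass
class CompositePlan:
    composite_id: str
    stratum: str  # cancer | non-cancer
    sample_ids: list[str]


def depth_stability_report(
    fragsets: dict[str, FragmentSet],
    labels: dict[str, str],
    model: GenomeModel,
    nominal_count: int,
    config: PFEConfig = PFEConfig(),
    target_multiple: float = 10.0,
    samples_per_composite: int | None = None,
    fractions: tuple[float, ...] = DEFAULT_DEPTH_FRACTIONS,
    seed: int = 0,
) -> pd.DataFrame:
    """Full analysis: split each stratum into composites, compute the PFE
    vector at the reference and every depth fraction, report Pearson r.

    Returns a tidy frame (composite_id, stratum, fraction, pearson_r,
    n_genes). Strata are never mixed within a composite.
    """
    strata: dict[str, list[str]] = {"cancer": [], "non-cancer": []}
    for sid in fragsets:
        stratum = "cancer" if labels[sid] == "cancer" else "non-cancer"
        strata[stratum].append(sid)
    if samples_per_composite is None:
        samples_per_composite = max(2, int(np.ceil(target_multiple)))

    rows = []
    for stratum, sids in strata.items():
        n_comp = len(sids) // samples_per_composite
        for c in range(n_comp):
            members = sids[c * samples_per_composite : (c + 1) * samples_per_composite]
            comp_id = f"{stratum}_comp{c:02d}"
            comp = build_composite([fragsets[s] for s in members],
                                   target_multiple, nominal_count, comp_id)
            import hashlib

            key = int.from_bytes(hashlib.sha256(comp_id.encode()).digest()[:4], "big")
            comp_seed = int(np.random.SeedSequence(seed, spawn_key=(key,)).generate_state(1)[0])
            reference = pfe_scores(comp, model, config).normalized_scores
            series = depth_series(comp, model, config, fractions, seed=comp_seed)
            corr = depth_correlation(series, reference)
            for rec in corr.itertuples():
                rows.append({
                    "composite_id": comp_id, "stratum": stratum,
                    "fraction": rec.fraction, "pearson_r": rec.pearson_r,
                    "n_genes": rec.n_genes,
                })
    if not rows:
        raise ValueError("no composites could be formed; too few samples per stratum")
    return pd.DataFrame(rows)
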