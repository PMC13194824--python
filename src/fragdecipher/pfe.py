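"""Promoter fragmentation entropy (PFE).

The PFE score asks, for each gene, how confident we are that the fragment-
length distribution in its promoter (TSS +/- 1 kb) is more entropic than
background. The ingredients:

* a *prior* length distribution pooled from regions 750 bp–1 kb up/downstream
  of nucleosome-depleted regions (nucleosome-protected flanks);
* five *control entropies*, each the Shannon entropy of the pooled promoter
  length distribution of 20 genes drawn without replacement from a
  330-gene background set (genes minimally expressed in the tissues that
  shed cfDNA);
* a Dirichlet posterior per gene with parameter
  ``alpha = W * p_prior + gene_counts`` (pseudo-count weight W = 20).

2,000 distributions are drawn from the posterior; for draw *j* with Shannon
entropy E_j the ratios ``q_ij = E_j / control_i`` are formed and the draw
contributes the probability that all five ratios exceed a random margin
``1 + k`` with ``k ~ Gamma(shape 0.5, rate 1)``. With a single shared k this
is the closed form ``F_Gamma(min_i q_ij - 1)`` (zero when ``min_i q_ij <= 1``).
The PFE score is the mean contribution over draws — a number in [0, 1] that
rises with promoter entropy. Entropies are in nats; the base cancels in the
ratios.

Gene scores are z-normalized across genes within each sample, and feature
selection (training cohort only) keeps genes with a two-sided Wilcoxon
rank-sum p < 0.01 and a positive cancer-minus-noncancer mean difference.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from fragdecipher.fragments import FragmentSet, assign_intervals
from fragdecipher.synthetic import GenomeModel

__all__ = [
    "PFEConfig",
    "PFEResult",
    "length_histogram",
    "prior_distribution",
    "shannon_entropy",
    "control_entropies",
    "margin_probability",
    "gene_pfe",
    "pfe_scores",
    "pfe_matrix",
    "select_pfe_features",
    "pfe_summary",
]


@dataclass(frozen=True)
class PFEConfig:
    prior_weight: float = 20.0      # Dirichlet pseudo-count mass W
    n_dirichlet: int = 2000         # posterior draws per gene
    n_controls: int = 5             # control-entropy repeats
    genes_per_control: int = 20     # background genes pooled per repeat
    gamma_shape: float = 0.5        # margin k ~ Gamma(shape, rate)
    gamma_rate: float = 1.0
    tss_halfwidth: int = 1000       # promoter window, bp each side of TSS
    ndr_flank: tuple[int, int] = (750, 1000)  # prior flanks, bp beyond the NDR
    length_range: tuple[int, int] = (100, 220)  # inclusive support, 1-bp cells
    shared_k: bool = True           # one margin k across the five controls
    control_size_match: bool = True  # subsample control pools to the median gene depth
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prior_weight", "n_dirichlet", "n_controls",
                     "genes_per_control", "gamma_shape", "gamma_rate",
                     "tss_halfwidth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_cells(self) -> int:
        return self.length_range[1] - self.length_range[0] + 1


@dataclass
class PFEResult:
    gene_scores: pd.Series          # score in [0,1], NaN for genes with no fragments
    normalized_scores: pd.Series    # within-sample z-scores (NaN preserved)
    control_entropies: np.ndarray   # the five values, nats
    prior: np.ndarray               # prior probability vector over length cells


def _rng_for(config: PFEConfig, tag: str) -> np.random.Generator:
    """Deterministic per-sample generator: config.seed plus a stable hash of
    the sample id (so cohort order cannot change any sample's result)."""
    h = int.from_bytes(hashlib.sha256(tag.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(h,)))


def length_histogram(lengths: np.ndarray, config: PFEConfig) -> np.ndarray:
    """Counts over the 1-bp support cells (lengths outside the range dropped)."""
    lo, hi = config.length_range
    lengths = np.asarray(lengths)
    lengths = lengths[(lengths >= lo) & (lengths <= hi)]
    return np.bincount((lengths - lo).astype(int), minlength=config.n_cells).astype(float)


def prior_distribution(fragset: FragmentSet, model: GenomeModel,
                       config: PFEConfig = PFEConfig()) -> np.ndarray:
    """Pooled, normalized length histogram of fragments in NDR flanks."""
    flanks = model.ndr_flank_intervals(config.ndr_flank)
    assigned = assign_intervals(fragset, flanks)
    lengths = fragset.lengths[assigned != "unassigned"]
    hist = length_histogram(lengths, config)
    total = hist.sum()
    if total == 0:
        raise ValueError(
            "no fragments in NDR flanks; widen the simulation or check the "
            "NDR annotation"
        )
    return hist / total


def shannon_entropy(mass: np.ndarray) -> float:
    """Shannon entropy in nats of a probability vector; 0*ln 0 := 0."""
    p = np.asarray(mass, dtype=float)
    if (p < 0).any():
        raise ValueError("negative probability mass")
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total mass")
    p = p / total
    return float(special.entr(p).sum())


def _gene_length_counts(fragset: FragmentSet, model: GenomeModel,
                        config: PFEConfig) -> dict[str, np.ndarray]:
    assigned = assign_intervals(fragset, model.promoter_intervals(config.tss_halfwidth))
    lengths = fragset.lengths
    out: dict[str, np.ndarray] = {}
    df = pd.DataFrame({"gene": assigned, "length": lengths})
    for gene, grp in df[df["gene"] != "unassigned"].groupby("gene", sort=False):
        out[str(gene)] = length_histogram(grp["length"].to_numpy(), config)
    return out


def control_entropies(
    fragset: FragmentSet,
    model: GenomeModel,
    config: PFEConfig = PFEConfig(),
    gene_counts: dict[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Five control entropy values, each from the pooled promoter length
    distribution of ``genes_per_control`` background genes drawn without
    replacement (draws independent across repeats).

    With ``control_size_match`` (default) each pooled control histogram is
    first subsampled without replacement to the median per-gene promoter
    fragment count. The plug-in Shannon entropy is biased downward by an
    amount that grows as counts shrink; a 20-gene pool holds ~20x the
    fragments of a single gene, so an unmatched control entropy is
    systematically higher than any gene-level entropy at low sequencing
    depth and the entropy ratios degenerate. Size matching puts the
    controls on the gene-level bias scale, which is the comparison the
    score is built on.
    """
    background = list(model.background_genes)
    if len(background) < config.genes_per_control:
        raise ValueError("background gene set smaller than genes_per_control")
    if gene_counts is None:
        gene_counts = _gene_length_counts(fragset, model, config)
    if rng is None:
        rng = _rng_for(config, f"controls:{fragset.sample_id}")
    totals = [c.sum() for c in gene_counts.values() if c.sum() > 0]
    n_ref = int(np.median(totals)) if totals else 0
    values = []
    for rep in range(config.n_controls):
        chosen = rng.choice(background, size=config.genes_per_control, replace=False)
        pooled = np.zeros(config.n_cells)
        for g in chosen:
            pooled += gene_counts.get(g, 0.0)
        if pooled.sum() == 0:
            raise ValueError(f"control repeat {rep}: no pooled fragments")
        if config.control_size_match and n_ref and pooled.sum() > n_ref:
            pooled = rng.multivariate_hypergeometric(
                pooled.astype(np.int64), n_ref).astype(float)
        values.append(shannon_entropy(pooled))
    return np.asarray(values)


def margin_probability(entropies: np.ndarray, controls: np.ndarray,
                       config: PFEConfig = PFEConfig()) -> np.ndarray:
    """Per-draw probability that every entropy/control ratio exceeds 1 + k,
    k ~ Gamma(shape, rate).

    Shared k (default): ``F_Gamma(min_i q_i - 1)`` when the minimum ratio
    exceeds 1, else 0. Independent k per control: the product of the
    per-ratio CDF terms.
    """
    controls = np.asarray(controls, dtype=float)
    if (controls <= 0).any():
        raise ValueError("control entropies must be positive")
    q = np.asarray(entropies, dtype=float)[:, None] / controls[None, :]
    scale = 1.0 / config.gamma_rate
    if config.shared_k:
        qmin = q.min(axis=1)
        p = np.where(qmin > 1.0,
                     stats.gamma.cdf(np.maximum(qmin - 1.0, 0.0),
                                     a=config.gamma_shape, scale=scale),
                     0.0)
    else:
        terms = np.where(q > 1.0,
                         stats.gamma.cdf(np.maximum(q - 1.0, 0.0),
                                         a=config.gamma_shape, scale=scale),
                         0.0)
        p = terms.prod(axis=1)
    return p


def gene_pfe(
    gene_counts: np.ndarray,
    prior: np.ndarray,
    controls: np.ndarray,
    config: PFEConfig = PFEConfig(),
    rng: np.random.Generator | None = None,
) -> float:
    """PFE score for one gene: the mean margin probability over
    ``n_dirichlet`` draws from Dirichlet(W * prior + counts)."""
    alpha = config.prior_weight * np.asarray(prior, dtype=float) + np.asarray(gene_counts, dtype=float)
    if alpha.sum() <= 0:
        raise ValueError("Dirichlet parameter has zero total mass")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    # standard-gamma construction; cells with alpha == 0 stay at exactly 0
    g = rng.standard_gamma(alpha, size=(config.n_dirichlet, alpha.size))
    draws = g / g.sum(axis=1, keepdims=True)
    entropies = special.entr(draws).sum(axis=1)
    return float(margin_probability(entropies, controls, config).mean())


def pfe_scores(fragset: FragmentSet, model: GenomeModel,
               config: PFEConfig = PFEConfig(),
               prior: np.ndarray | None = None) -> PFEResult:
    """All gene scores for one sample, plus the within-sample z-normalization.

    Genes with zero promoter fragments get a missing (NaN) score and are
    excluded from the normalization mean/SD. A precomputed ``prior`` (e.g.
    from a reference-depth dataset) may be supplied instead of re-deriving
    it from this sample's NDR flanks.
    """
    gene_counts = _gene_length_counts(fragset, model, config)
    if prior is None:
        prior = prior_distribution(fragset, model, config)
    controls = control_entropies(fragset, model, config, gene_counts=gene_counts)
    rng = _rng_for(config, f"pfe:{fragset.sample_id}")
    genes = model.genes["gene_id"].tolist()
    scores = pd.Series(np.nan, index=genes, name=fragset.sample_id)
    for gene in genes:
        counts = gene_counts.get(gene)
        if counts is None or counts.sum() == 0:
            continue
        scores[gene] = gene_pfe(counts, prior, controls, config, rng=rng)
    if scores.notna().sum() == 0:
        raise ValueError(f"sample {fragset.sample_id}: every gene is missing")
    x = scores.to_numpy(dtype=float)
    ok = ~np.isnan(x)
    sd = x[ok].std()
    z = np.full_like(x, np.nan)
    z[ok] = 0.0 if sd == 0 else (x[ok] - x[ok].mean()) / sd
    return PFEResult(
        gene_scores=scores,
        normalized_scores=pd.Series(z, index=genes, name=fragset.sample_id),
        control_entropies=controls,
        prior=prior,
    )


def pfe_matrix(fragsets: dict[str, FragmentSet], model: GenomeModel,
               config: PFEConfig = PFEConfig(), impute: bool = False) -> pd.DataFrame:
    """Samples x genes matrix of within-sample-normalized PFE scores.

    ``impute=True`` replaces missing genes by 0 (the sample mean after
    z-scoring) for model-facing matrices.
    """
    rows = {sid: pfe_scores(fs, model, config).normalized_scores
            for sid, fs in fragsets.items()}
    mat = pd.DataFrame(rows).T
    if impute:
        mat = mat.fillna(0.0)
    return mat


def select_pfe_features(training_matrix: pd.DataFrame, labels: pd.Series,
                        alpha: float = 0.01) -> list[str]:
    """Training-only selection: genes with two-sided Wilcoxon rank-sum
    p < ``alpha`` AND mean(cancer) > mean(non-cancer).

    ``labels`` is boolean/0-1 (1 = cancer), indexed like the matrix rows.
    The exact null distribution is used when both groups have <= 12 samples,
    else the normal approximation with continuity correction.
    """
    labels = labels.reindex(training_matrix.index)
    y = labels.to_numpy().astype(bool)
    if y.all() or not y.any():
        raise ValueError("training set must contain both classes")
    selected = []
    for gene in training_matrix.columns:
        col = training_matrix[gene].to_numpy(dtype=float)
        a = col[y]
        b = col[~y]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if len(a) == 0 or len(b) == 0:
            continue
        method = "exact" if max(len(a), len(b)) <= 12 else "asymptotic"
        try:
            p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method=method, use_continuity=True).pvalue
        except ValueError:  # all-identical degenerate columns
            continue
        if p < alpha and a.mean() - b.mean() > 0:
            selected.append(gene)
    return selected


def pfe_summary(matrix: pd.DataFrame, selected_genes: list[str]) -> pd.Series:
    """Integrated PFE score per sample: mean of the selected normalized features."""
    if not selected_genes:
        raise ValueError("no selected genes")
    return matrix[selected_genes].mean(axis=1, skipna=True)
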