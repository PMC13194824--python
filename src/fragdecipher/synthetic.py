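"""Synthetic cfDNA cohort generator.

Generates labeled fragment collections with the statistical structure the
downstream analysis assumes, on a 1/1000-scale genome (100 kb chromosome
arms, 10 kb copy-number bins) so that a full cohort simulates in seconds:

* fragment lengths follow a two-component mixture — a mononucleosomal mode
  near 167 bp and a short component uniform on 100–150 bp whose weight grows
  with ``tumor_fraction * short_fragment_boost`` (tumor-derived cfDNA is
  short-enriched);
* genomic placement is proportional to arm length scaled by per-arm copy
  factors mixed by tumor fraction (arm-level gains/losses);
* every gene carries a baseline promoter "activity" drawn once per genome
  model; at a gene's promoter a fragment is drawn from the disordered
  (near-uniform) length distribution with probability
  ``DISORDER_COEF * activity`` and otherwise from a mononucleosomal normal
  whose sigma also widens with activity — open chromatin cuts more randomly,
  giving genuine between-gene entropy heterogeneity in all subjects (the
  substrate of the promoter-entropy feature);
* in tumor-bearing samples, fragments at promoters of a designated boosted
  gene set are redrawn, with probability equal to the tumor fraction, from a
  near-uniform length distribution on the full 100-220 bp support —
  nucleosome-free cleavage at hyper-accessible tumor promoters produces
  maximally disordered fragment lengths.

Per-sample randomness derives from a master seed through
``numpy.random.SeedSequence(master_seed, spawn_key=(sample_index,))`` so a
cohort regenerates identically, in any order, from one integer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from fragdecipher.fragments import FragmentSet, write_fragments

__all__ = [
    "ARM_NAMES",
    "GenomeModel",
    "SampleProfile",
    "SimulationConfig",
    "CohortConfig",
    "build_genome_model",
    "simulate_sample",
    "simulate_cohort",
]

#: The 39 chromosome arms used for arm-level features (acrocentric p arms
#: 13p/14p/15p/21p/22p and chrY are excluded, as is standard in cfDNA
#: fragmentation profiling).
ARM_NAMES: tuple[str, ...] = (
    "1p", "1q", "2p", "2q", "3p", "3q", "4p", "4q", "5p", "5q",
    "6p", "6q", "7p", "7q", "8p", "8q", "9p", "9q", "10p", "10q",
    "11p", "11q", "12p", "12q", "13q", "14q", "15q", "16p", "16q",
    "17p", "17q", "18p", "18q", "19p", "19q", "20p", "20q", "21q", "22q",
)

MONO_MEAN = 167.0          # mononucleosomal mode, bp
MONO_SIGMA = 10.0          # bulk (non-promoter) sigma, bp
PROMOTER_BASE_SIGMA = 4.0  # closed promoter: tightly phased nucleosomes
OPEN_SIGMA_GAIN = 8.0      # promoter sigma = PROMOTER_BASE_SIGMA + OPEN_SIGMA_GAIN * activity
SHORT_RANGE = (100, 150)   # short-fragment component support, bp (inclusive)
LENGTH_RANGE = (100, 220)  # global truncation, bp (inclusive)
BASE_SHORT_FRACTION = 0.12  # healthy-baseline weight of the short component
DISORDER_COEF = 0.5        # P(disordered promoter fragment) = DISORDER_COEF * activity


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for the scaled synthetic genome."""

    n_arms: int = 39
    arm_length: int = 100_000
    bin_width: int = 10_000
    genes_per_arm: int = 14
    n_active: int = 30
    background_size: int = 330
    ndr_halfwidth: int = 150
    promoter_halfwidth: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_arms <= len(ARM_NAMES):
            raise ValueError(f"n_arms must be in [1, {len(ARM_NAMES)}]")
        if self.arm_length % self.bin_width:
            raise ValueError("bin_width must divide arm_length")


@dataclass
class GenomeModel:
    """Scaled genome annotation: arms, CNV bins, genes with promoters/NDRs,
    and the background (low/ubiquitously-expressed) control gene set."""

    arms: list[tuple[str, str, int, int]]
    cnv_bins: list[tuple[str, int, int]]
    genes: pd.DataFrame  # gene_id, chrom, tss, strand, active_flag, activity
    ndr_regions: pd.DataFrame  # gene_id, chrom, start, end
    background_genes: list[str]
    config: SimulationConfig

    @property
    def arm_names(self) -> list[str]:
        return [a[0] for a in self.arms]

    @property
    def active_genes(self) -> list[str]:
        return self.genes.loc[self.genes["active_flag"], "gene_id"].tolist()

    def arm_intervals(self) -> list[tuple[str, str, int, int]]:
        return [(name, chrom, start, end) for name, chrom, start, end in self.arms]

    def bin_intervals(self) -> list[tuple[str, str, int, int]]:
        return [
            (f"bin_{i:04d}", chrom, start, end)
            for i, (chrom, start, end) in enumerate(self.cnv_bins)
        ]

    def promoter_intervals(self, halfwidth: int | None = None) -> list[tuple[str, str, int, int]]:
        """TSS +/- halfwidth windows, one per gene (non-overlapping by construction)."""
        hw = self.config.promoter_halfwidth if halfwidth is None else halfwidth
        return [
            (g.gene_id, g.chrom, int(g.tss) - hw, int(g.tss) + hw)
            for g in self.genes.itertuples()
        ]

    def ndr_flank_intervals(self, flank: tuple[int, int] = (750, 1000)) -> list[tuple[str, str, int, int]]:
        """Regions ``flank[0]``–``flank[1]`` bp up/downstream of each gene's
        nucleosome-depleted region; these supply the fragment-length prior."""
        near, far = flank
        out = []
        for r in self.ndr_regions.itertuples():
            out.append((f"{r.gene_id}:up", r.chrom, int(r.start) - far, int(r.start) - near))
            out.append((f"{r.gene_id}:dn", r.chrom, int(r.end) + near, int(r.end) + far))
        return out

    def to_dir(self, path: str | Path) -> Path:
        """Serialize the annotation as plain TSV/text files plus the config."""
        import json

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.arms, columns=["arm", "chrom", "start", "end"]).to_csv(
            path / "arms.tsv", sep="\t", index=False)
        self.genes.to_csv(path / "genes.tsv", sep="\t", index=False)
        self.ndr_regions.to_csv(path / "ndr.tsv", sep="\t", index=False)
        (path / "background_genes.txt").write_text("\n".join(self.background_genes) + "\n")
        (path / "config.json").write_text(
            json.dumps(dataclasses.asdict(self.config), indent=2) + "\n")
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "GenomeModel":
        import json

        path = Path(path)
        config = SimulationConfig(**json.loads((path / "config.json").read_text()))
        arms_df = pd.read_csv(path / "arms.tsv", sep="\t")
        arms = [tuple(r) for r in arms_df.itertuples(index=False)]
        cnv_bins = [
            (chrom, s, s + config.bin_width)
            for _, chrom, start, end in arms
            for s in range(start, end, config.bin_width)
        ]
        return cls(
            arms=arms,
            cnv_bins=cnv_bins,
            genes=pd.read_csv(path / "genes.tsv", sep="\t"),
            ndr_regions=pd.read_csv(path / "ndr.tsv", sep="\t"),
            background_genes=(path / "background_genes.txt").read_text().split(),
            config=config,
        )


def build_genome_model(config: SimulationConfig | None = None) -> GenomeModel:
    """Build a scaled GenomeModel; deterministic given ``config.seed``.

    Arms tile their chromosome sequentially (the p arm before the q arm),
    CNV bins tile each arm, genes sit at evenly spaced TSS positions, each
    gene gets one NDR (TSS +/- ``ndr_halfwidth``) and a baseline promoter
    activity level in [0, 1]. The "active" set is the ``n_active`` genes with
    the highest activity; the background control set is drawn from the
    remainder and must not overlap it.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    names = ARM_NAMES[: config.n_arms]

    arms: list[tuple[str, str, int, int]] = []
    offsets: dict[str, int] = {}
    for name in names:
        chrom = "chr" + name.rstrip("pq")
        start = offsets.get(chrom, 0)
        end = start + config.arm_length
        offsets[chrom] = end
        arms.append((name, chrom, start, end))

    cnv_bins = [
        (chrom, s, s + config.bin_width)
        for _, chrom, start, end in arms
        for s in range(start, end, config.bin_width)
    ]

    rows = []
    spacing = config.arm_length // config.genes_per_arm
    for name, chrom, start, _ in arms:
        for i in range(config.genes_per_arm):
            rows.append(
                {
                    "gene_id": f"G_{name}_{i:02d}",
                    "chrom": chrom,
                    "tss": start + spacing * i + spacing // 2,
                    "strand": "+" if i % 2 == 0 else "-",
                }
            )
    genes = pd.DataFrame(rows)
    # Baseline promoter activity in the cfDNA background (blood-derived):
    # right-skewed, since most promoters are silent in the tissues that shed
    # cfDNA, with a minority strongly active. The tumor-marker set
    # (active_flag: disordered in tumor-bearing samples) is sampled from the
    # lower 60% of activities — tissue-specific genes largely silent in
    # plasma background — and the background control set is the lowest-
    # activity remainder, emulating a curated low-expression control list.
    # The two sets are disjoint by construction.
    genes["activity"] = rng.beta(1.0, 3.0, size=len(genes))
    n_active = min(config.n_active, len(genes))
    order = np.argsort(genes["activity"].to_numpy(), kind="stable")  # ascending
    lower = order[: max(n_active, int(0.6 * len(genes)))]
    tumor_idx = rng.choice(lower, size=n_active, replace=False)
    genes["active_flag"] = False
    genes.loc[genes.index[tumor_idx], "active_flag"] = True
    non_tumor = [i for i in order if i not in set(tumor_idx.tolist())]
    if config.background_size > len(non_tumor):
        raise ValueError(
            f"background_size {config.background_size} exceeds the "
            f"{len(non_tumor)} genes outside the tumor-marker set"
        )
    background = sorted(
        genes.loc[genes.index[non_tumor[: config.background_size]], "gene_id"].tolist())

    ndr = pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "chrom": genes["chrom"],
            "start": genes["tss"] - config.ndr_halfwidth,
            "end": genes["tss"] + config.ndr_halfwidth,
        }
    )
    return GenomeModel(
        arms=arms,
        cnv_bins=cnv_bins,
        genes=genes,
        ndr_regions=ndr,
        background_genes=background,
        config=config,
    )


@dataclass
class SampleProfile:
    """Generative parameters for one synthetic sample."""

    label: str  # cancer | benign | healthy
    tumor_fraction: float = 0.0
    short_fragment_boost: float = 0.5
    arm_copy_factors: Mapping[str, float] = field(default_factory=dict)
    entropy_boost_genes: Sequence[str] = ()
    target_fragment_count: int = 120_000
    seed: int = 0
    inflammation_shift: float = 0.0  # benign-disease short-fraction shift, default off

    def __post_init__(self) -> None:
        if not 0 <= self.tumor_fraction <= 1:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if any(v <= 0 for v in self.arm_copy_factors.values()):
            raise ValueError("arm_copy_factors must be positive")


def _truncated_normal(rng: np.random.Generator, loc: np.ndarray, scale: np.ndarray,
                      lo: float, hi: float) -> np.ndarray:
    """Elementwise truncated-normal draw by rejection (tails are small here)."""
    loc = np.broadcast_to(loc, np.broadcast_shapes(np.shape(loc), np.shape(scale)))
    scale = np.broadcast_to(scale, loc.shape)
    x = rng.normal(loc, scale)
    bad = (x < lo) | (x > hi)
    for _ in range(100):
        if not bad.any():
            break
        x[bad] = rng.normal(loc[bad], scale[bad])
        bad = (x < lo) | (x > hi)
    return np.clip(x, lo, hi)


def simulate_sample(model: GenomeModel, profile: SampleProfile) -> FragmentSet:
    """Draw exactly ``target_fragment_count`` fragments for one sample.

    Arm placement probabilities are proportional to
    ``arm_length * (1 + tumor_fraction * (copy_factor - 1))``; the short
    component weight is
    ``BASE_SHORT_FRACTION + tumor_fraction * short_fragment_boost``
    (plus any inflammation shift), so a tumor fraction of zero reproduces
    the healthy baseline exactly.
    """
    if not model.arms:
        raise ValueError("empty genome model")
    n = profile.target_fragment_count
    if n <= 0:
        raise ValueError("target_fragment_count must be positive")
    rng = np.random.default_rng(profile.seed)
    tf = profile.tumor_fraction

    arm_arr = model.arms
    arm_len = np.array([end - start for _, _, start, end in arm_arr], dtype=float)
    factors = np.array(
        [profile.arm_copy_factors.get(name, 1.0) for name, _, _, _ in arm_arr]
    )
    weights = arm_len * (1.0 + tf * (factors - 1.0))
    p = weights / weights.sum()

    arm_idx = rng.choice(len(arm_arr), size=n, p=p)
    arm_start = np.array([s for _, _, s, _ in arm_arr])[arm_idx]
    mid = arm_start + (rng.random(n) * arm_len[arm_idx]).astype(np.int64)

    # per-fragment mononucleosomal sigma from promoter activity
    sigma = np.full(n, MONO_SIGMA)
    hw = model.config.promoter_halfwidth
    tss = model.genes["tss"].to_numpy()
    tss_chrom = model.genes["chrom"].to_numpy()
    activity = model.genes["activity"].to_numpy()
    gene_ids = model.genes["gene_id"].to_numpy()
    boosted = np.isin(gene_ids, np.asarray(list(profile.entropy_boost_genes), dtype=object))
    chrom_per_arm = np.array([c for _, c, _, _ in arm_arr], dtype=object)
    frag_chrom = chrom_per_arm[arm_idx]
    for chrom in pd.unique(frag_chrom):
        gmask = tss_chrom == chrom
        if not gmask.any():
            continue
        gt = tss[gmask]
        order = np.argsort(gt)
        gt = gt[order]
        gact = activity[gmask][order]
        gboost = boosted[gmask][order]
        fmask = frag_chrom == chrom
        pos = mid[fmask]
        j = np.searchsorted(gt, pos)
        # nearest TSS (windows are disjoint, so at most one can contain pos)
        jl = np.clip(j - 1, 0, len(gt) - 1)
        jr = np.clip(j, 0, len(gt) - 1)
        near = np.where(np.abs(pos - gt[jl]) <= np.abs(pos - gt[jr]), jl, jr)
        inwin = np.abs(pos - gt[near]) < hw
        s = np.full(fmask.sum(), MONO_SIGMA)
        s[inwin] = PROMOTER_BASE_SIGMA + OPEN_SIGMA_GAIN * gact[near[inwin]]
        disordered = inwin & (rng.random(fmask.sum()) < DISORDER_COEF * gact[near])
        if tf > 0 and gboost.any():
            hit = inwin & gboost[near]
            disordered |= hit & (rng.random(fmask.sum()) < tf)
        s[disordered] = np.inf  # marker: draw uniform over the full support
        sigma[fmask] = s

    w_short = float(
        np.clip(BASE_SHORT_FRACTION + tf * profile.short_fragment_boost
                + profile.inflammation_shift, 0.0, 0.95)
    )
    is_short = rng.random(n) < w_short
    lengths = np.empty(n, dtype=np.int64)
    lengths[is_short] = rng.integers(SHORT_RANGE[0], SHORT_RANGE[1] + 1, size=int(is_short.sum()))
    mono = ~is_short
    disordered = mono & np.isinf(sigma)
    lengths[disordered] = rng.integers(LENGTH_RANGE[0], LENGTH_RANGE[1] + 1,
                                       size=int(disordered.sum()))
    normal = mono & ~disordered
    lengths[normal] = np.round(
        _truncated_normal(rng, np.full(int(normal.sum()), MONO_MEAN), sigma[normal],
                          LENGTH_RANGE[0], LENGTH_RANGE[1])
    ).astype(np.int64)

    start = mid - lengths // 2
    arm_end = arm_start + arm_len[arm_idx].astype(np.int64)
    start = np.clip(start, arm_start, arm_end - lengths)
    df = pd.DataFrame({"chrom": frag_chrom, "start": start, "end": start + lengths})
    return FragmentSet(
        sample_id=f"{profile.label}_seed{profile.seed}",
        records=df,
        metadata={
            "label": profile.label,
            "tumor_fraction": tf,
            "seed": profile.seed,
            "n_kept": n,
        },
    )


# recurrent arm-level alterations used for cancer profiles (gains on 1q/5p/6q,
# losses on 4p/6p/8p — cohort-consistent so the copy-number family is learnable)
DEFAULT_ARM_GAINS: dict[str, float] = {"1q": 1.5, "5p": 1.5, "6q": 1.5}
DEFAULT_ARM_LOSSES: dict[str, float] = {"4p": 0.6, "6p": 0.6, "8p": 0.6}


@dataclass(frozen=True)
class CohortConfig:
    """Group sizes and effect sizes for a simulated cohort."""

    n_cancer: int = 20
    n_benign: int = 0
    n_healthy: int = 20
    target_fragment_count: int = 120_000
    # stage mix and the stage -> tumor-fraction map (not a claim about the
    # clinical mapping; exposed as configuration)
    stage_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.15, "II": 0.65, "III": 0.20}
    )
    stage_tumor_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.02, "II": 0.05, "III": 0.12}
    )
    tumor_fraction: float | None = None  # fixed override for all cancers
    short_fragment_boost: float = 0.5
    arm_gains: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ARM_GAINS))
    arm_losses: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ARM_LOSSES))
    inflammation_shift: float = 0.0
    cohort_name: str = "synthetic"


def sample_seed(master_seed: int, index: int) -> int:
    """Documented per-sample seed rule: the first 32-bit word of
    ``SeedSequence(master_seed, spawn_key=(index,))``."""
    return int(np.random.SeedSequence(master_seed, spawn_key=(index,)).generate_state(1)[0])


def simulate_cohort(
    model: GenomeModel,
    config: CohortConfig,
    master_seed: int,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, FragmentSet], pd.DataFrame]:
    """Simulate a labeled cohort; optionally write one BED per sample plus a
    TSV sample sheet (columns: sample_id cohort label stage timepoint path).
    """
    rng = np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(0xFFFF,)))
    copy_factors = {**config.arm_gains, **config.arm_losses}
    stages = list(config.stage_fractions)
    stage_p = np.array([config.stage_fractions[s] for s in stages], dtype=float)
    stage_p /= stage_p.sum()

    profiles: list[tuple[str, str, str, SampleProfile]] = []
    index = 0
    for _ in range(config.n_cancer):
        stage = str(rng.choice(stages, p=stage_p))
        tf = (
            config.tumor_fraction
            if config.tumor_fraction is not None
            else config.stage_tumor_fraction[stage] * float(rng.uniform(0.7, 1.3))
        )
        profiles.append(
            (
                f"{config.cohort_name}_CAN_{index:03d}",
                "cancer",
                stage,
                SampleProfile(
                    label="cancer",
                    tumor_fraction=tf,
                    short_fragment_boost=config.short_fragment_boost,
                    arm_copy_factors=copy_factors,
                    entropy_boost_genes=tuple(model.active_genes),
                    target_fragment_count=config.target_fragment_count,
                    seed=sample_seed(master_seed, index),
                ),
            )
        )
        index += 1
    for _ in range(config.n_benign):
        profiles.append(
            (
                f"{config.cohort_name}_BEN_{index:03d}",
                "benign",
                "",
                SampleProfile(
                    label="benign",
                    inflammation_shift=config.inflammation_shift,
                    target_fragment_count=config.target_fragment_count,
                    seed=sample_seed(master_seed, index),
                ),
            )
        )
        index += 1
    for _ in range(config.n_healthy):
        profiles.append(
            (
                f"{config.cohort_name}_HEA_{index:03d}",
                "healthy",
                "",
                SampleProfile(
                    label="healthy",
                    target_fragment_count=config.target_fragment_count,
                    seed=sample_seed(master_seed, index),
                ),
            )
        )
        index += 1

    ids = [sid for sid, _, _, _ in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in cohort")

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    fragsets: dict[str, FragmentSet] = {}
    rows = []
    for sid, label, stage, profile in profiles:
        fs = simulate_sample(model, profile)
        fs.sample_id = sid
        fs.metadata["sample_id"] = sid
        fragsets[sid] = fs
        path = ""
        if out_dir is not None:
            path = str(write_fragments(fs, out_dir / f"{sid}.bed"))
        rows.append(
            {
                "sample_id": sid,
                "cohort": config.cohort_name,
                "label": label,
                "stage": stage,
                "timepoint": "baseline",
                "path": path,
            }
        )
    sheet = pd.DataFrame(rows)
    if out_dir is not None:
        sheet.to_csv(out_dir / "sample_sheet.tsv", sep="\t", index=False)
    return fragsets, sheet
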