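"""Out-of-fold-ranked ensemble risk model.

For each feature family (CNV / FSD / PFE) a randomized search draws
candidate base learners (regularized logistic regression, gradient-boosted
trees, random forests, plus logistic stacked combiners over other
candidates' fold predictions). Every candidate is trained with stratified
5-fold cross-validation on the training cohort only; its held-out
predictions form one out-of-fold (OOF) vector covering each training sample
exactly once. Candidates are ranked by OOF AUC (ties broken by candidate
id), the top K (default 10) per family are refit on the full training set,
and their averaged predictions give the per-family ensemble score. The
risk score is the equal-weight mean of the three family scores; the
decision cutoff is chosen on the training OOF risk scores at a target
sensitivity (default 0.95). Validation data never enter any of these steps.

Fold membership is derived from a hash of (seed, sample_id) within each
class, so it is reproducible and independent of input row order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from fragdecipher.metrics import choose_cutoff, roc_auc

__all__ = [
    "EnsembleConfig",
    "CandidateModel",
    "TrainedEnsemble",
    "stratified_folds",
    "candidate_search",
    "rank_and_select",
    "per_feature_score",
    "risk_score",
    "fit_ensemble",
]

FAMILIES = ("CNV", "FSD", "PFE")
ALGORITHM_CLASSES = ("regularized-linear", "gradient-boosted-trees",
                     "random-forest", "stacked-combiner")


@dataclass(frozen=True)
class EnsembleConfig:
    n_candidates: int = 30      # per feature family (paper-scale searches are larger)
    top_k: int = 10
    folds: int = 5
    target_sensitivity: float = 0.95
    stacked_fraction: float = 0.15  # share of candidates that are stacked combiners
    seed: int = 0


@dataclass
class CandidateModel:
    id: int
    family: str
    algorithm: str
    hyperparameters: dict
    oof_predictions: np.ndarray | None = None
    oof_auc: float = np.nan
    fitted: object = None           # refit on the full training set
    base_ids: tuple[int, ...] = ()  # stacked combiners: ids of combined candidates


def _hash_u32(seed: int, sample_id: str) -> int:
    return int.from_bytes(hashlib.sha256(f"{seed}:{sample_id}".encode()).digest()[:4], "big")


def stratified_folds(sample_ids, labels, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment from a (seed, sample_id)
    hash: within each class, samples are ordered by hash and dealt
    round-robin, so membership does not depend on input order."""
    sample_ids = list(sample_ids)
    y = np.asarray(labels).astype(int)
    folds = np.empty(len(sample_ids), dtype=int)
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        order = sorted(idx, key=lambda i: (_hash_u32(seed, sample_ids[i]), sample_ids[i]))
        for rank, i in enumerate(order):
            folds[i] = rank % n_folds
    return folds


def _make_estimator(algorithm: str, params: dict):
    if algorithm == "regularized-linear":
        return LogisticRegression(C=params["C"], l1_ratio=params["l1_ratio"],
                                  solver="liblinear", max_iter=2000,
                                  random_state=params["random_state"])
    if algorithm == "gradient-boosted-trees":
        return GradientBoostingClassifier(
            n_estimators=params["n_estimators"], max_depth=params["max_depth"],
            learning_rate=params["learning_rate"], subsample=params["subsample"],
            random_state=params["random_state"])
    if algorithm == "random-forest":
        return RandomForestClassifier(
            n_estimators=params["n_estimators"], max_depth=params["max_depth"],
            max_features=params["max_features"], random_state=params["random_state"])
    if algorithm == "stacked-combiner":
        return LogisticRegression(C=params["C"], solver="liblinear", max_iter=2000,
                                  random_state=params["random_state"])
    raise ValueError(f"unknown algorithm class {algorithm}")


def _draw_hyperparameters(algorithm: str, rng: np.random.Generator) -> dict:
    rs = int(rng.integers(0, 2**31 - 1))
    if algorithm == "regularized-linear":
        return {"C": float(10 ** rng.uniform(-3, 2)),
                "l1_ratio": float(rng.choice([0.0, 1.0])), "random_state": rs}
    if algorithm == "gradient-boosted-trees":
        return {"n_estimators": int(rng.integers(30, 151)),
                "max_depth": int(rng.integers(2, 5)),
                "learning_rate": float(10 ** rng.uniform(-2, -0.3)),
                "subsample": float(rng.uniform(0.6, 1.0)), "random_state": rs}
    if algorithm == "random-forest":
        return {"n_estimators": int(rng.integers(50, 301)),
                "max_depth": int(rng.integers(3, 11)),
                "max_features": float(rng.uniform(0.1, 0.9)), "random_state": rs}
    if algorithm == "stacked-combiner":
        return {"C": float(10 ** rng.uniform(-2, 1)), "random_state": rs}
    raise ValueError(algorithm)


def _proba(est, X: np.ndarray) -> np.ndarray:
    return est.predict_proba(X)[:, 1]


def candidate_search(X: pd.DataFrame, labels: pd.Series, family: str,
                     config: EnsembleConfig = EnsembleConfig()) -> list[CandidateModel]:
    """Randomized candidate search with 5-fold OOF prediction bookkeeping.

    Returns candidates whose ``oof_predictions`` cover every training sample
    exactly once; fully deterministic given ``config.seed``.
    """
    y = np.asarray(labels.reindex(X.index)).astype(int)
    if y.all() or not y.any():
        raise ValueError("training labels must contain both classes")
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_hash_u32(config.seed, family),)))
    folds = stratified_folds(X.index, y, config.folds, config.seed)
    Xv = X.to_numpy(dtype=float)

    n_stacked = int(round(config.stacked_fraction * config.n_candidates))
    n_base = config.n_candidates - n_stacked
    base_algos = [a for a in ALGORITHM_CLASSES if a != "stacked-combiner"]

    candidates: list[CandidateModel] = []
    for cid in range(n_base):
        algo = base_algos[cid % len(base_algos)]
        params = _draw_hyperparameters(algo, rng)
        oof = np.empty(len(y))
        for f in range(config.folds):
            tr, te = folds != f, folds == f
            est = _make_estimator(algo, params)
            est.fit(Xv[tr], y[tr])
            oof[te] = _proba(est, Xv[te])
        cand = CandidateModel(id=cid, family=family, algorithm=algo,
                              hyperparameters=params, oof_predictions=oof)
        cand.oof_auc = roc_auc(oof, y)["auc"]
        candidates.append(cand)

    # stacked combiners: logistic over the fold-wise predictions of a random
    # subset of base candidates, trained inside the same CV loop
    for k in range(n_stacked):
        cid = n_base + k
        n_pick = int(rng.integers(3, max(4, min(8, n_base)) + 1))
        picked = tuple(sorted(rng.choice(n_base, size=min(n_pick, n_base), replace=False).tolist()))
        params = _draw_hyperparameters("stacked-combiner", rng)
        Z = np.column_stack([candidates[i].oof_predictions for i in picked])
        oof = np.empty(len(y))
        for f in range(config.folds):
            tr, te = folds != f, folds == f
            est = _make_estimator("stacked-combiner", params)
            est.fit(Z[tr], y[tr])
            oof[te] = _proba(est, Z[te])
        cand = CandidateModel(id=cid, family=family, algorithm="stacked-combiner",
                              hyperparameters=params, oof_predictions=oof,
                              base_ids=picked)
        cand.oof_auc = roc_auc(oof, y)["auc"]
        candidates.append(cand)
    return candidates


def rank_and_select(candidates: list[CandidateModel], k: int = 10) -> list[CandidateModel]:
    """Top-k by OOF AUC, exact ties broken by lower candidate id; if fewer
    than k candidates exist, all are returned (scaled runs)."""
    ranked = sorted(candidates, key=lambda c: (-c.oof_auc, c.id))
    if len(ranked) < k:
        import warnings

        warnings.warn(f"only {len(ranked)} candidates available (< k={k})", stacklevel=2)
        return ranked
    return ranked[:k]


def per_feature_score(selected: list[CandidateModel], X: pd.DataFrame,
                      feature_names: list[str], all_candidates: Mapping[int, CandidateModel]) -> np.ndarray:
    """Unweighted mean of the selected (refit) models' predicted
    probabilities on ``X`` (schema-checked against training)."""
    if list(X.columns) != list(feature_names):
        raise ValueError("feature columns do not match the training schema")
    Xv = X.to_numpy(dtype=float)
    preds = []
    for cand in selected:
        if cand.algorithm == "stacked-combiner":
            Z = np.column_stack([_proba(all_candidates[i].fitted, Xv) for i in cand.base_ids])
            preds.append(_proba(cand.fitted, Z))
        else:
            preds.append(_proba(cand.fitted, Xv))
    return np.mean(preds, axis=0)


def risk_score(cnv_score, fsd_score, pfe_score) -> np.ndarray:
    """Equal-weight mean of the three per-family ensemble scores."""
    arrs = [np.asarray(s, dtype=float) for s in (cnv_score, fsd_score, pfe_score)]
    if any(a is None or a.size == 0 for a in arrs):
        raise ValueError("all three family scores are required")
    return np.mean(arrs, axis=0)


@dataclass
class TrainedEnsemble:
    config: EnsembleConfig
    families: dict = field(default_factory=dict)
    # per family: {"selected": [CandidateModel], "all": {id: CandidateModel},
    #              "feature_names": [...], "oof_score": np.ndarray}
    training_ids: list[str] = field(default_factory=list)
    training_oof_scores: np.ndarray | None = None
    cutoff: float = np.nan

    def oof_scores(self) -> pd.Series:
        """Training risk scores via the out-of-fold pathway (unbiased)."""
        return pd.Series(self.training_oof_scores, index=self.training_ids, name="oof_risk")

    def predict(self, matrices: Mapping[str, pd.DataFrame],
                allow_training_ids: bool = False) -> pd.Series:
        """Risk scores via the refit pathway. Refuses sample ids seen in
        training unless explicitly allowed (leakage guard)."""
        ids = None
        for fam in FAMILIES:
            if fam not in matrices:
                raise ValueError(f"missing feature family {fam}")
            fam_ids = list(matrices[fam].index)
            if ids is None:
                ids = fam_ids
            elif fam_ids != ids:
                raise ValueError("feature matrices must share sample order")
        if not allow_training_ids:
            overlap = set(ids) & set(self.training_ids)
            if overlap:
                raise ValueError(f"sample ids seen in training: {sorted(overlap)[:5]}")
        fam_scores = []
        for fam in FAMILIES:
            info = self.families[fam]
            fam_scores.append(per_feature_score(info["selected"], matrices[fam],
                                                info["feature_names"], info["all"]))
        return pd.Series(risk_score(*fam_scores), index=ids, name="risk")

    def manifest(self) -> dict:
        """Deterministic JSON-serializable description of the fitted model."""
        return {
            "config": {
                "n_candidates": self.config.n_candidates, "top_k": self.config.top_k,
                "folds": self.config.folds, "seed": self.config.seed,
                "target_sensitivity": self.config.target_sensitivity,
            },
            "cutoff": self.cutoff,
            "training_oof_scores": [round(float(v), 12) for v in self.training_oof_scores],
            "selected": [
                {"family": fam, "id": c.id, "algorithm": c.algorithm,
                 "oof_auc": round(float(c.oof_auc), 12)}
                for fam in FAMILIES for c in self.families[fam]["selected"]
            ],
        }

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "manifest.json").write_text(
            json.dumps(self.manifest(), indent=2, sort_keys=True) + "\n")
        pd.DataFrame(self.manifest()["selected"]).to_csv(
            out_dir / "selected_models.tsv", sep="\t", index=False)
        import pickle

        with open(out_dir / "models.pkl", "wb") as fh:
            pickle.dump(self, fh)
        return out_dir


def fit_ensemble(matrices: Mapping[str, pd.DataFrame], labels: pd.Series,
                 config: EnsembleConfig = EnsembleConfig()) -> TrainedEnsemble:
    """Search -> rank -> refit -> cutoff, on training data only.

    ``matrices`` maps family name -> samples x features DataFrame (shared
    sample order); ``labels`` is 1 = cancer indexed by sample id.
    """
    ids = None
    for fam in FAMILIES:
        if fam not in matrices:
            raise ValueError(f"missing feature family {fam}")
        fam_ids = list(matrices[fam].index)
        if ids is None:
            ids = fam_ids
        elif fam_ids != ids:
            raise ValueError("training matrices must share sample order")
    y = np.asarray(labels.reindex(ids)).astype(int)

    ens = TrainedEnsemble(config=config, training_ids=ids)
    fam_oof = []
    for fam in FAMILIES:
        X = matrices[fam]
        candidates = candidate_search(X, labels, fam, config)
        selected = rank_and_select(candidates, config.top_k)
        # refit every base candidate any selected model needs, on full training
        needed = {c.id for c in selected}
        for c in selected:
            needed.update(c.base_ids)
        by_id = {c.id: c for c in candidates}
        Xv = X.to_numpy(dtype=float)
        for cid in sorted(needed):
            c = by_id[cid]
            if c.algorithm == "stacked-combiner":
                continue
            est = _make_estimator(c.algorithm, c.hyperparameters)
            est.fit(Xv, y)
            c.fitted = est
        for cid in sorted(needed):
            c = by_id[cid]
            if c.algorithm != "stacked-combiner":
                continue
            Z = np.column_stack([by_id[i].oof_predictions for i in c.base_ids])
            est = _make_estimator("stacked-combiner", c.hyperparameters)
            est.fit(Z, y)
            c.fitted = est
        oof_score = np.mean([c.oof_predictions for c in selected], axis=0)
        fam_oof.append(oof_score)
        ens.families[fam] = {
            "selected": selected,
            "all": by_id,
            "feature_names": list(X.columns),
            "oof_score": oof_score,
        }
    ens.training_oof_scores = risk_score(*fam_oof)
    ens.cutoff = choose_cutoff(ens.training_oof_scores, y, config.target_sensitivity)
    return ens
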