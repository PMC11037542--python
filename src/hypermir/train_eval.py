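"""Training loop, data splitting, negative sampling, metrics and the
cross-validation / independent-test evaluation protocols.

The evaluation protocol mirrors the common practice for bipartite
association prediction: hold out 1/10 of the known associations as an
independent test set, run 5-fold cross-validation (repeated 5 times) on the
remainder, and, because unobserved pairs vastly outnumber observed ones,
score each fold's positives against 10 independent draws of
equally-many sampled negatives, reporting the average AUC, AUPR and F1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from .hypergraph import (build_node_features, kmeans_hypergraph,
                         knn_hypergraph, normalized_adjacency,
                         propagation_operator)
from .io import (AssociationMatrix, Config, DiseaseDAG, HypermirError,
                 InvalidInputError, SimilarityMatrix)
from .model import Adam, ModelState, forward, init_params
from .similarity import build_integrated_similarities

__all__ = ["SplitPlan", "EvalReport", "make_split", "sample_negatives",
           "train", "score_metrics", "run_cv", "run_independent_test",
           "rank_candidates"]


class TrainingDivergedError(HypermirError):
    """Raised when the loss becomes non-finite during training."""


# ------------------------------------------------------------------ splitting

@dataclass
class SplitPlan:
    """Positive pairs split into a CV pool (5 folds) and an independent
    test set, plus per-repeat negative draws for the independent test."""

    cv_positives: np.ndarray
    folds: list
    independent: np.ndarray
    independent_negatives: list
    seed: int


def _sub_seed(base: int, *key: int) -> int:
    """Deterministic sub-seed below 2**31 derived from a base seed."""
    ss = np.random.SeedSequence(entropy=int(base), spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def make_split(T: AssociationMatrix, seed: int, n_folds: int = 5,
               n_neg_repeats: int = 10) -> SplitPlan:
    """9/10 of positives to a CV pool partitioned into `n_folds` folds,
    1/10 held out as the independent test set; deterministic given seed."""
    positives = T.positives()
    n = len(positives)
    if n < 10:
        raise InvalidInputError(f"need at least 10 positive entries, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = n // 10
    independent = positives[perm[:n_test]]
    cv_positives = positives[perm[n_test:]]
    folds = [np.asarray(f) for f in
             np.array_split(cv_positives, n_folds)]
    neg = sample_negatives(T, n_test, excluded=set(map(tuple, positives)),
                           seed=_sub_seed(seed, 1), repeats=n_neg_repeats)
    return SplitPlan(cv_positives, folds, independent, neg, seed)


def sample_negatives(T: AssociationMatrix, n: int, excluded: set,
                     seed: int, repeats: int = 1) -> list:
    """`repeats` independent draws of `n` distinct zero-entry pairs,
    uniformly without replacement, never overlapping `excluded`."""
    zeros = np.argwhere(np.asarray(T.T) == 0)
    if excluded:
        keep = [idx for idx, pair in enumerate(map(tuple, zeros))
                if pair not in excluded]
        zeros = zeros[keep]
    if len(zeros) < n:
        raise InvalidInputError(
            f"cannot draw {n} negatives from {len(zeros)} available "
            "zero entries")
    children = np.random.SeedSequence(seed).spawn(repeats)
    draws = []
    for child in children:
        rng = np.random.default_rng(child)
        draws.append(zeros[rng.choice(len(zeros), size=n, replace=False)])
    return draws


# ------------------------------------------------------------------- metrics

def score_metrics(scores, labels, f1_mode: str = "raw"):
    """(AUC, AUPR, F1) for a score vector against binary labels.

    AUC uses the rank (Mann-Whitney) formulation with half credit for
    ties; AUPR is the average-precision form of the precision-recall
    integral.  F1 needs a binarization convention for the unbounded
    reconstruction scores: ``raw`` (default) thresholds them at 0.5, the
    midpoint of the 0/1 regression targets; ``logistic`` maps them through
    the logistic function first (degenerate when all scores are
    nonnegative, as with ReLU decoders); ``best-threshold`` sweeps all
    observed scores.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise InvalidInputError("both classes must be present to compute "
                                "ranking metrics")
    auc = roc_auc_score(labels, scores)
    aupr = average_precision_score(labels, scores)
    if f1_mode == "raw":
        f1 = f1_score(labels, scores >= 0.5, zero_division=0)
    elif f1_mode == "logistic":
        f1 = f1_score(labels, expit(scores) >= 0.5, zero_division=0)
    elif f1_mode == "best-threshold":
        f1 = max(f1_score(labels, scores >= t, zero_division=0)
                 for t in np.unique(scores))
    else:
        raise InvalidInputError(f"unknown f1_mode {f1_mode!r}")
    return float(auc), float(aupr), float(f1)


# -------------------------------------------------------------------- training

def train(T_train: AssociationMatrix, sims: dict, config: Config,
          omega: np.ndarray | None = None) -> ModelState:
    """Train the full pipeline on a (possibly fold-masked) association
    matrix and return the final state with the reconstructed score matrix.

    `sims` must hold integrated similarities ``IM``/``ID`` and the GIP
    kernels ``GPSM``/``GPSD`` (the GCN ablation builds its two plain-graph
    views from the integrated and the GIP similarity respectively).
    """
    feat_m = build_node_features(T_train, sims["IM"], "mirna")
    feat_d = build_node_features(T_train, sims["ID"], "disease")

    if config.ablation == "gcn_amir":
        Pm1 = normalized_adjacency(sims["IM"])
        Pm2 = normalized_adjacency(sims["GPSM"])
        Pd1 = normalized_adjacency(sims["ID"])
        Pd2 = normalized_adjacency(sims["GPSD"])
    else:
        k_m = min(config.k, T_train.n_mirnas - 1)
        k_d = min(config.k, T_train.n_diseases - 1)
        c_m = min(config.c, T_train.n_mirnas)
        c_d = min(config.c, T_train.n_diseases)
        Pm1 = propagation_operator(knn_hypergraph(feat_m, k_m))
        Pm2 = propagation_operator(
            kmeans_hypergraph(feat_m, c_m, _sub_seed(config.seed, 11)))
        Pd1 = propagation_operator(knn_hypergraph(feat_d, k_d))
        Pd2 = propagation_operator(
            kmeans_hypergraph(feat_d, c_d, _sub_seed(config.seed, 12)))

    rng = np.random.default_rng(config.seed)
    params = init_params(config, feat_m.X.shape[1], feat_d.X.shape[1], rng)
    optimizer = Adam(params, lr=config.beta)
    T_arr = np.asarray(T_train.T, dtype=float)

    trace = []
    best, stale = np.inf, 0
    t_hat = None
    for epoch in range(config.epochs):
        total, breakdown, T_hat = forward(
            params, config, feat_m.X, feat_d.X, Pm1, Pm2, Pd1, Pd2,
            T_arr, omega=omega)
        for name, value in (("reconstruction", breakdown.reconstruction),
                            ("contrastive_mirna", breakdown.contrastive_mirna),
                            ("contrastive_disease",
                             breakdown.contrastive_disease)):
            if not np.isfinite(value):
                raise TrainingDivergedError(
                    f"non-finite {name} loss at epoch {epoch}")
        trace.append(breakdown)
        optimizer.zero_grad()
        total.backward()
        optimizer.step()
        t_hat = T_hat.data
        if config.early_stop:
            if breakdown.total < best - 1e-12:
                best, stale = breakdown.total, 0
            else:
                stale += 1
                if stale >= config.early_stop_patience:
                    break

    # score matrix from the final parameters
    _, _, T_hat = forward(params, config, feat_m.X, feat_d.X,
                          Pm1, Pm2, Pd1, Pd2, T_arr, omega=omega)
    return ModelState(params=params, config=config,
                      mirna_ids=list(T_train.mirna_ids),
                      disease_ids=list(T_train.disease_ids),
                      t_hat=T_hat.data, t_train=T_arr.copy(),
                      loss_trace=trace)


# ----------------------------------------------------------------- evaluation

@dataclass
class EvalReport:
    """Per-(repeat, fold, negative-draw) metrics with aggregates."""

    auc: np.ndarray
    aupr: np.ndarray
    f1: np.ndarray
    config: Config | None = None

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc))

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.aupr))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1))

    def summary(self) -> dict:
        return {
            "auc_mean": self.mean_auc, "auc_std": float(np.std(self.auc)),
            "aupr_mean": self.mean_aupr, "aupr_std": float(np.std(self.aupr)),
            "f1_mean": self.mean_f1, "f1_std": float(np.std(self.f1)),
        }

    def to_json(self, path=None) -> str:
        payload = {
            "summary": self.summary(),
            "auc": self.auc.tolist(),
            "aupr": self.aupr.tolist(),
            "f1": self.f1.tolist(),
        }
        if self.config is not None:
            payload["config"] = {
                f: getattr(self.config, f)
                for f in self.config.__dataclass_fields__}
        text = json.dumps(payload, sort_keys=True, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _similarities_for(T: AssociationMatrix, dag, delta, mirna_sim,
                      disease_sim) -> dict:
    return build_integrated_similarities(T, dag=dag, delta=delta,
                                         mirna_sim=mirna_sim,
                                         disease_sim=disease_sim)


def run_cv(T: AssociationMatrix, config: Config,
           dag: DiseaseDAG | None = None, delta: float = 0.5,
           mirna_sim: SimilarityMatrix | None = None,
           disease_sim: SimilarityMatrix | None = None) -> EvalReport:
    """Repeated k-fold cross-validation over the known associations of `T`.

    For each repeat the positives are re-partitioned into folds; each
    fold's positives are zeroed out of the training matrix (their entries
    are weighted as unobserved in the reconstruction loss) and, after
    training, scored against `config.n_neg_draws` negative draws.

    In ``leakage_safe`` mode the association-derived similarities (miRNA
    functional similarity mask and GIP kernels) are recomputed per fold
    from the training folds only; the default mode computes them once from
    the full matrix, matching the common evaluation regime.
    """
    positives = T.positives()
    pos_set = set(map(tuple, positives))
    n_pos = len(positives)
    if n_pos < config.n_folds:
        raise InvalidInputError("fewer positives than folds")

    if not config.leakage_safe:
        sims_full = _similarities_for(T, dag, delta, mirna_sim, disease_sim)

    R, F, K = config.n_repeats, config.n_folds, config.n_neg_draws
    auc = np.zeros((R, F, K))
    aupr = np.zeros((R, F, K))
    f1 = np.zeros((R, F, K))
    for r in range(R):
        rng = np.random.default_rng(_sub_seed(config.seed, 2, r))
        folds = np.array_split(positives[rng.permutation(n_pos)], F)
        for f, fold in enumerate(folds):
            T_train = T.copy()
            T_train.T[fold[:, 0], fold[:, 1]] = 0
            if config.leakage_safe:
                sims = _similarities_for(T_train, dag, delta, mirna_sim,
                                         disease_sim)
            else:
                sims = sims_full
            fold_cfg = config.replace(seed=_sub_seed(config.seed, 3, r, f))
            state = train(T_train, sims, fold_cfg)
            pos_scores = state.t_hat[fold[:, 0], fold[:, 1]]
            neg_draws = sample_negatives(
                T, len(fold), excluded=pos_set,
                seed=_sub_seed(config.seed, 4, r, f), repeats=K)
            for kdx, neg in enumerate(neg_draws):
                neg_scores = state.t_hat[neg[:, 0], neg[:, 1]]
                scores = np.concatenate([pos_scores, neg_scores])
                labels = np.concatenate([np.ones(len(fold), dtype=int),
                                         np.zeros(len(neg), dtype=int)])
                auc[r, f, kdx], aupr[r, f, kdx], f1[r, f, kdx] = \
                    score_metrics(scores, labels, config.f1_mode)
    return EvalReport(auc=auc, aupr=aupr, f1=f1, config=config)


def run_independent_test(T: AssociationMatrix, config: Config,
                         dag: DiseaseDAG | None = None, delta: float = 0.5,
                         mirna_sim: SimilarityMatrix | None = None,
                         disease_sim: SimilarityMatrix | None = None
                         ) -> EvalReport:
    """Train once on the 9/10 CV pool and score the held-out 1/10
    positives against the plan's negative draws."""
    plan = make_split(T, config.seed, n_folds=config.n_folds,
                      n_neg_repeats=config.n_neg_draws)
    T_train = T.copy()
    T_train.T[:] = 0
    T_train.T[plan.cv_positives[:, 0], plan.cv_positives[:, 1]] = 1
    sims = _similarities_for(T_train if config.leakage_safe else T,
                             dag, delta, mirna_sim, disease_sim)
    state = train(T_train, sims, config)
    pos_scores = state.t_hat[plan.independent[:, 0], plan.independent[:, 1]]
    K = len(plan.independent_negatives)
    auc = np.zeros((1, 1, K))
    aupr = np.zeros((1, 1, K))
    f1 = np.zeros((1, 1, K))
    for kdx, neg in enumerate(plan.independent_negatives):
        neg_scores = state.t_hat[neg[:, 0], neg[:, 1]]
        scores = np.concatenate([pos_scores, neg_scores])
        labels = np.concatenate([np.ones(len(pos_scores), dtype=int),
                                 np.zeros(len(neg), dtype=int)])
        auc[0, 0, kdx], aupr[0, 0, kdx], f1[0, 0, kdx] = \
            score_metrics(scores, labels, config.f1_mode)
    return EvalReport(auc=auc, aupr=aupr, f1=f1, config=config)


# -------------------------------------------------------------------- ranking

def rank_candidates(model: ModelState, disease: str,
                    exclude_known: bool = True) -> list:
    """miRNAs ranked by descending predicted score for one disease
    (ties broken by miRNA id)."""
    if disease not in model.disease_ids:
        raise KeyError(disease)
    j = model.disease_ids.index(disease)
    scores = model.t_hat[:, j]
    entries = []
    for i, mid in enumerate(model.mirna_ids):
        if exclude_known and model.t_train is not None \
                and model.t_train[i, j] == 1:
            continue
        entries.append((mid, float(scores[i])))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return entries
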