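"""Biological similarity construction for miRNAs and diseases.

Four similarity notions feed the model:

* **Disease semantic similarity (DSS)** from a MeSH-style descriptor DAG,
  averaging two per-ancestor contribution models: a decay model where an
  ancestor at distance ``n`` above a disease contributes ``delta**n``
  (decay factor ``delta``, conventionally 0.5), and an information-content
  model where an ancestor appearing in few disease DAGs contributes
  ``-ln(n_DAGs_containing / n_diseases)``.  A disease pair scores highly
  when their DAGs share many, strongly-contributing ancestors.
* **miRNA functional similarity (MFS)**: miRNAs associated with
  semantically similar diseases are taken to be functionally similar; each
  disease in one miRNA's association set is matched to its best semantic
  counterpart in the other's, and the best-match sums are normalized by the
  set sizes.
* **Gaussian interaction-profile (GIP) kernel** on binary association
  profiles, with the bandwidth set by the mean squared profile norm.
* **Integrated similarities (IM, ID)**: the average of the primary
  similarity and the GIP kernel where the primary notion is defined, the
  GIP kernel alone where it is not.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from math import log

import numpy as np
from scipy.spatial.distance import cdist

from .io import (AssociationMatrix, DegenerateInputError, DiseaseDAG,
                 InvalidInputError, SimilarityMatrix)

__all__ = [
    "SemanticContributions",
    "semantic_contributions_model1", "semantic_contributions_model2",
    "disease_semantic_similarity", "mirna_functional_similarity",
    "gip_kernel", "integrate_similarity", "build_integrated_similarities",
]


@dataclass
class SemanticContributions:
    """Per-ancestor semantic contribution scores for one disease."""

    disease: str
    contrib1: dict | None = None
    contrib2: dict | None = None
    sv1: float | None = None
    sv2: float | None = None


def _dag_child_to_parents(dag: DiseaseDAG, disease: str) -> dict:
    """Child -> {parents} adjacency restricted to DAG(disease)."""
    adj: dict = {}
    for parent, child in dag.edges[disease]:
        adj.setdefault(child, set()).add(parent)
    return adj


def semantic_contributions_model1(dag: DiseaseDAG, disease: str,
                                  delta: float = 0.5) -> SemanticContributions:
    """Decay-model contributions: an ancestor's score is ``delta`` to the
    power of its shortest hop distance above `disease` (max over paths)."""
    if disease not in dag:
        raise KeyError(disease)
    if not 0.0 < delta < 1.0:
        raise InvalidInputError("delta must be in (0, 1)")
    adj = _dag_child_to_parents(dag, disease)
    # BFS upward: the max over downward paths of a product of deltas is
    # delta ** (shortest distance).
    dist = {disease: 0}
    queue = deque([disease])
    while queue:
        node = queue.popleft()
        for parent in adj.get(node, ()):
            if parent not in dist:
                dist[parent] = dist[node] + 1
                queue.append(parent)
    contrib = {node: delta ** d for node, d in dist.items()}
    return SemanticContributions(disease, contrib1=contrib,
                                 sv1=float(sum(contrib.values())))


def _dag_membership_counts(dag: DiseaseDAG) -> dict:
    """For each disease, in how many disease DAGs (ancestor sets) it appears."""
    counts: dict = {d: 0 for d in dag.disease_ids}
    for d in dag.disease_ids:
        for a in dag.ancestors[d]:
            counts[a] = counts.get(a, 0) + 1
    return counts


def semantic_contributions_model2(dag: DiseaseDAG,
                                  disease: str) -> SemanticContributions:
    """Information-content contributions: ``-ln(n_DAGs_containing / n)``."""
    if disease not in dag:
        raise KeyError(disease)
    counts = _dag_membership_counts(dag)
    n = dag.n
    contrib = {a: -log(counts[a] / n) for a in dag.ancestors[disease]}
    return SemanticContributions(disease, contrib2=contrib,
                                 sv2=float(sum(contrib.values())))


def disease_semantic_similarity(dag: DiseaseDAG, delta: float = 0.5,
                                return_components: bool = False):
    """Average of the decay-model and information-content semantic
    similarities over all disease pairs of the DAG table.

    With ``return_components=True`` returns ``(DSS, DSS1, DSS2)`` where
    DSS1 is the decay-model similarity and DSS2 the information-content
    one."""
    if dag.n < 2:
        raise InvalidInputError("need at least 2 diseases")
    ids = dag.disease_ids
    n = dag.n
    counts = _dag_membership_counts(dag)
    c1, sv1, c2, sv2 = {}, {}, {}, {}
    for d in ids:
        sc = semantic_contributions_model1(dag, d, delta)
        c1[d], sv1[d] = sc.contrib1, sc.sv1
        contrib2 = {a: -log(counts[a] / n) for a in dag.ancestors[d]}
        c2[d] = contrib2
        sv2[d] = float(sum(contrib2.values()))

    S1 = np.zeros((n, n))
    S2 = np.zeros((n, n))
    for i, di in enumerate(ids):
        for j in range(i, n):
            dj = ids[j]
            shared = dag.ancestors[di] & dag.ancestors[dj]
            den1 = sv1[di] + sv1[dj]
            num1 = sum(c1[di].get(t, 0.0) + c1[dj].get(t, 0.0) for t in shared)
            dss1 = num1 / den1 if den1 > 0 else (1.0 if i == j else 0.0)
            den2 = sv2[di] + sv2[dj]
            num2 = sum(c2[di].get(t, 0.0) + c2[dj].get(t, 0.0) for t in shared)
            dss2 = num2 / den2 if den2 > 0 else (1.0 if i == j else 0.0)
            S1[i, j] = S1[j, i] = dss1
            S2[i, j] = S2[j, i] = dss2
    dss = SimilarityMatrix(list(ids), 0.5 * (S1 + S2))
    if return_components:
        return (dss, SimilarityMatrix(list(ids), S1),
                SimilarityMatrix(list(ids), S2))
    return dss


def mirna_functional_similarity(T: AssociationMatrix,
                                DSS: SimilarityMatrix) -> SimilarityMatrix:
    """Best-match average of disease semantic similarities between the
    association sets of each miRNA pair.

    A pair is *defined* only when both miRNAs have at least one associated
    disease; undefined entries hold 0 and carry ``defined=False`` so
    integration can fall back to the GIP kernel.
    """
    missing = [d for d in T.disease_ids if d not in set(DSS.ids)]
    if missing:
        raise InvalidInputError(
            f"DSS does not cover {len(missing)} diseases of the association "
            f"matrix (e.g. {missing[:3]})")
    d_pos = {d: i for i, d in enumerate(DSS.ids)}
    col_map = np.array([d_pos[d] for d in T.disease_ids])
    M = T.n_mirnas
    disease_sets = [col_map[np.flatnonzero(T.T[i])] for i in range(M)]
    nonempty = np.array([len(s) > 0 for s in disease_sets])

    S = np.zeros((M, M))
    for i in range(M):
        Di = disease_sets[i]
        if len(Di) == 0:
            continue
        for j in range(i, M):
            Dj = disease_sets[j]
            if len(Dj) == 0:
                continue
            sub = DSS.S[np.ix_(Di, Dj)]
            num = sub.max(axis=1).sum() + sub.max(axis=0).sum()
            S[i, j] = S[j, i] = num / (len(Di) + len(Dj))
    defined = np.outer(nonempty, nonempty)
    return SimilarityMatrix(list(T.mirna_ids), S, defined=defined)


def gip_kernel(T: AssociationMatrix, axis: str,
               gamma_prime: float = 1.0) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over row (miRNA) or column
    (disease) association profiles.

    The bandwidth is ``gamma_prime`` divided by the mean squared profile
    norm, so the kernel adapts to the overall density of the matrix.
    """
    if axis == "mirna":
        profiles = np.asarray(T.T, dtype=float)
        ids = T.mirna_ids
    elif axis == "disease":
        profiles = np.asarray(T.T, dtype=float).T
        ids = T.disease_ids
    else:
        raise InvalidInputError(f"axis must be 'mirna' or 'disease', "
                                f"got {axis!r}")
    mean_sq_norm = float((profiles ** 2).sum(axis=1).mean())
    if mean_sq_norm == 0.0:
        raise DegenerateInputError(
            "all interaction profiles are zero; GIP bandwidth undefined")
    gamma = gamma_prime / mean_sq_norm
    D2 = cdist(profiles, profiles, metric="sqeuclidean")
    S = np.exp(-gamma * D2)
    np.fill_diagonal(S, 1.0)
    S = (S + S.T) / 2.0
    return SimilarityMatrix(list(ids), S)


def integrate_similarity(primary: SimilarityMatrix,
                         gip: SimilarityMatrix) -> SimilarityMatrix:
    """(primary + GIP)/2 where the primary similarity is defined, GIP
    elsewhere; unit diagonal."""
    if primary.ids != gip.ids or primary.S.shape != gip.S.shape:
        raise InvalidInputError("primary and GIP similarity matrices must "
                                "share ids and shape")
    defined = (primary.defined if primary.defined is not None
               else np.ones_like(primary.S, dtype=bool))
    S = np.where(defined, 0.5 * (primary.S + gip.S), gip.S)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(list(primary.ids), S)


def _align_to(sim: SimilarityMatrix, ids: list) -> SimilarityMatrix:
    """Reorder (and subset) a similarity matrix to a target id list."""
    if sim.ids == list(ids):
        return sim
    pos = {x: i for i, x in enumerate(sim.ids)}
    missing = [x for x in ids if x not in pos]
    if missing:
        raise InvalidInputError(
            f"similarity matrix lacks {len(missing)} required ids "
            f"(e.g. {missing[:3]})")
    idx = [pos[x] for x in ids]
    defined = (sim.defined[np.ix_(idx, idx)]
               if sim.defined is not None else None)
    return SimilarityMatrix(list(ids), sim.S[np.ix_(idx, idx)],
                            defined=defined)


def build_integrated_similarities(T: AssociationMatrix,
                                  dag: DiseaseDAG | None = None,
                                  delta: float = 0.5,
                                  mirna_sim: SimilarityMatrix | None = None,
                                  disease_sim: SimilarityMatrix | None = None,
                                  ) -> dict:
    """Convenience pipeline: DSS/MFS (or supplied primaries) + GIP -> IM, ID.

    Returns a dict with keys ``DSS, MFS, GPSM, GPSD, IM, ID``.  Supplied
    primary matrices take precedence over DAG-derived ones; this is how
    externally computed (or simulated) similarities enter the pipeline.
    """
    gpsm = gip_kernel(T, "mirna")
    gpsd = gip_kernel(T, "disease")

    if disease_sim is not None:
        dss = _align_to(disease_sim, T.disease_ids)
    elif dag is not None:
        dss_all = disease_semantic_similarity(dag, delta)
        pos = {d: i for i, d in enumerate(dss_all.ids)}
        in_dag = np.array([d in pos for d in T.disease_ids])
        idx = [pos[d] for d, ok in zip(T.disease_ids, in_dag) if ok]
        S = np.zeros((T.n_diseases, T.n_diseases))
        sel = np.flatnonzero(in_dag)
        S[np.ix_(sel, sel)] = dss_all.S[np.ix_(idx, idx)]
        # semantic similarity is defined only when both diseases have codes
        dss = SimilarityMatrix(list(T.disease_ids), S,
                               defined=np.outer(in_dag, in_dag))
    else:
        raise InvalidInputError("need a disease DAG or a precomputed "
                                "disease similarity matrix")

    mfs = (_align_to(mirna_sim, T.mirna_ids) if mirna_sim is not None
           else mirna_functional_similarity(T, dss))

    return {
        "DSS": dss, "MFS": mfs, "GPSM": gpsm, "GPSD": gpsd,
        "IM": integrate_similarity(mfs, gpsm),
        "ID": integrate_similarity(dss, gpsd),
    }
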