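"""Seeded generators for planted-structure association worlds.

The generator emulates the statistical premise of the prediction task: a
low-rank association matrix whose row and column entities fall into a small
number of latent blocks, with similarity matrices derived from the same
latent factors, so that entities with similar profiles really are
associated with similar partners.  A random MeSH-style tree-number forest
is generated alongside so the semantic-similarity pipeline can be exercised
end to end without external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .io import AssociationMatrix, InvalidInputError, SimilarityMatrix

__all__ = ["SyntheticWorld", "generate_world", "generate_dag_table",
           "corrupt_labels", "shuffle_associations"]


@dataclass
class SyntheticWorld:
    """Latent factors, sampled associations and derived similarities."""

    U: np.ndarray
    V: np.ndarray
    T: AssociationMatrix
    sim_m: SimilarityMatrix
    sim_d: SimilarityMatrix
    dag_rows: list
    seed: int


def _block_latents(n: int, r: int, noise_sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Latents drawn from r one-hot block centers plus Gaussian jitter;
    blocks are contiguous index ranges."""
    blocks = (np.arange(n) * r) // n
    centers = np.eye(r)
    return centers[blocks] + noise_sd * rng.normal(size=(n, r))


def _noisy_cosine_similarity(X: np.ndarray, noise_sd: float,
                             rng: np.random.Generator) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms = np.where(norms > 0, norms, 1.0)
    C = (X / norms) @ (X / norms).T
    noise = noise_sd * rng.normal(size=C.shape)
    C = C + (noise + noise.T) / 2.0
    C = np.clip((C + C.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def generate_world(M: int = 60, D: int = 40, r: int = 4,
                   density_target: float = 0.1, noise_sd: float = 0.05,
                   seed: int = 0, slope: float = 10.0) -> SyntheticWorld:
    """Sample a planted low-rank binary association world.

    Association probabilities are ``sigmoid(slope * <U_i, V_j> + b)`` with
    the bias ``b`` calibrated by bisection so the expected density matches
    `density_target`.  Similarities are clipped noisy cosines of the same
    latent factors.
    """
    if r > min(M, D):
        raise InvalidInputError("r must be <= min(M, D)")
    if not 0.0 < density_target < 0.5:
        raise InvalidInputError("density_target must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    U = _block_latents(M, r, noise_sd, rng)
    V = _block_latents(D, r, noise_sd, rng)
    logits = slope * (U @ V.T)

    lo, hi = -50.0, 50.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if expit(logits + mid).mean() > density_target:
            hi = mid
        else:
            lo = mid
    bias = (lo + hi) / 2.0

    T = (rng.random(size=logits.shape) < expit(logits + bias)).astype(np.int8)
    mirna_ids = [f"mir-{i + 1:04d}" for i in range(M)]
    disease_ids = [f"dis-{j + 1:03d}" for j in range(D)]
    am = AssociationMatrix(mirna_ids, disease_ids, T)
    sim_m = SimilarityMatrix(mirna_ids,
                             _noisy_cosine_similarity(U, noise_sd, rng))
    sim_d = SimilarityMatrix(disease_ids,
                             _noisy_cosine_similarity(V, noise_sd, rng))
    dag_rows = generate_dag_table(D, max_depth=4, branching=3,
                                  seed=seed + 1, disease_ids=disease_ids)
    return SyntheticWorld(U, V, am, sim_m, sim_d, dag_rows, seed)


def generate_dag_table(n_diseases: int, max_depth: int = 4,
                       branching: int = 3, seed: int = 0,
                       disease_ids: list | None = None) -> list:
    """Random tree-number forest: (disease_id, tree_number) rows.

    Every disease owns exactly one node; a new disease either starts a new
    root or attaches beneath a random existing node with spare child slots,
    so every prefix of every code is owned and the table round-trips
    through the DAG reader without orphan warnings.
    """
    if n_diseases < 2:
        raise InvalidInputError("need at least 2 diseases")
    rng = np.random.default_rng(seed)
    if disease_ids is None:
        disease_ids = [f"dis-{j + 1:03d}" for j in range(n_diseases)]
    codes: list = []
    rows: list = []
    n_roots = 0
    children_count: dict = {}
    for d in disease_ids:
        depth_ok = [c for c in codes
                    if c.count(".") + 1 < max_depth
                    and children_count.get(c, 0) < branching]
        if not depth_ok or rng.random() < 0.15:
            n_roots += 1
            code = f"C{n_roots:02d}"
        else:
            parent = depth_ok[rng.integers(len(depth_ok))]
            children_count[parent] = children_count.get(parent, 0) + 1
            code = f"{parent}.{children_count[parent] * 100:03d}"
        codes.append(code)
        rows.append((d, code))
    return rows


def corrupt_labels(world: SyntheticWorld, fraction: float,
                   seed: int) -> SyntheticWorld:
    """Toggle a random fraction of association-matrix entries."""
    if not 0.0 <= fraction <= 1.0:
        raise InvalidInputError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    T = world.T.T.copy()
    n_cells = T.size
    n_flip = int(round(fraction * n_cells))
    flat = rng.choice(n_cells, size=n_flip, replace=False)
    T.flat[flat] = 1 - T.flat[flat]
    am = AssociationMatrix(list(world.T.mirna_ids),
                           list(world.T.disease_ids), T)
    return replace(world, T=am)


def shuffle_associations(world: SyntheticWorld, seed: int) -> SyntheticWorld:
    """Permute all entries of T, destroying any relation between the
    associations and the latent factors (null-model control).  Density is
    preserved; similarities are left untouched."""
    rng = np.random.default_rng(seed)
    T = world.T.T.copy()
    flat = T.flatten()
    rng.shuffle(flat)
    am = AssociationMatrix(list(world.T.mirna_ids),
                           list(world.T.disease_ids),
                           flat.reshape(T.shape))
    return replace(world, T=am)
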