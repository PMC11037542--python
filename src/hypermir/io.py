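"""Data model, file readers/writers and run configuration.

The package works from three plain-text inputs:

* an association list (two delimited columns: miRNA id, disease id) that
  becomes a binary M x D matrix ``T``;
* a disease hierarchy table (two columns: disease id, dot-separated tree
  number such as ``C04.588.180``) describing where each disease sits in a
  MeSH-style descriptor forest;
* optional precomputed square similarity matrices (dense TSV with an id
  header row and id first column).

Identifier order is always first-appearance order so that matrix layouts are
reproducible across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml

logger = logging.getLogger("hypermir")

__all__ = [
    "HypermirError", "ParseError", "InvalidInputError", "DegenerateInputError",
    "AssociationMatrix", "SimilarityMatrix", "DiseaseDAG", "Config",
    "read_association_table", "write_association_table",
    "read_dag_table", "read_similarity_matrix", "write_similarity_matrix",
]

ABLATIONS = ("full", "gcn_amir", "hgcn_amir", "hgclam_concat", "hgcl_ir")


class HypermirError(Exception):
    """Base class for package errors."""


class ParseError(HypermirError):
    """A line of an input file could not be parsed."""


class InvalidInputError(HypermirError, ValueError):
    """Structurally invalid input (shape/id mismatch, out-of-range argument)."""


class DegenerateInputError(HypermirError, ValueError):
    """Input that makes a quantity mathematically undefined (e.g. all-zero T)."""


# --------------------------------------------------------------------- types

@dataclass
class AssociationMatrix:
    """Binary known-association matrix with ordered identifiers.

    ``T[i, j] == 1`` iff miRNA ``mirna_ids[i]`` is a verified association of
    disease ``disease_ids[j]``; every other entry is 0 (unknown/unobserved).
    """

    mirna_ids: list
    disease_ids: list
    T: np.ndarray

    def __post_init__(self):
        self.T = np.asarray(self.T)
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise InvalidInputError("duplicate miRNA ids")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise InvalidInputError("duplicate disease ids")
        if self.T.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise InvalidInputError(
                f"matrix shape {self.T.shape} does not match id counts "
                f"({len(self.mirna_ids)}, {len(self.disease_ids)})")
        if not np.isin(self.T, (0, 1)).all():
            raise InvalidInputError("association matrix entries must be 0/1")

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    def positives(self) -> np.ndarray:
        """(n_pos, 2) array of (row, col) indices of known associations."""
        return np.argwhere(self.T == 1)

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(list(self.mirna_ids), list(self.disease_ids),
                                 self.T.copy())


@dataclass
class SimilarityMatrix:
    """Square similarity matrix over an ordered id list.

    ``defined`` is an optional boolean mask marking entries where the primary
    similarity notion exists (e.g. both miRNAs have at least one associated
    disease); undefined entries hold 0 and are replaced by the Gaussian
    interaction-profile kernel during integration.
    """

    ids: list
    S: np.ndarray
    defined: np.ndarray | None = None

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.ids)
        if self.S.shape != (n, n):
            raise InvalidInputError(
                f"similarity matrix shape {self.S.shape} does not match "
                f"{n} ids")
        if np.abs(self.S - self.S.T).max(initial=0.0) > 1e-9:
            raise InvalidInputError("similarity matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class DiseaseDAG:
    """Per-disease ancestor structure derived from hierarchical tree numbers.

    ``ancestors[d]`` is the node set of the DAG rooted walk from ``d``
    upward, including ``d`` itself; ``edges[d]`` holds the parent->child
    disease pairs of that DAG (links between a node and the owner of its
    immediate tree-number prefix).
    """

    disease_ids: list
    codes: dict
    ancestors: dict
    edges: dict

    def __contains__(self, disease: str) -> bool:
        return disease in self.codes

    @property
    def n(self) -> int:
        return len(self.disease_ids)


# -------------------------------------------------------------------- config

@dataclass
class Config:
    """All tunable knobs of the pipeline.

    Graph construction: ``k`` nearest neighbours per hyperedge and ``c``
    K-means clusters.  Loss: ``alpha`` trades observed vs unobserved entries
    in the reconstruction term, ``lam``/``gam`` weight the miRNA/disease
    contrastive terms, ``eta`` balances the two anchoring directions and
    ``tau`` is the InfoNCE temperature.  ``beta`` is the Adam learning rate.
    """

    k: int = 13
    c: int = 9
    alpha: float = 0.11
    beta: float = 1e-4
    eta: float = 0.5
    lam: float = 1.0
    gam: float = 1.0
    tau: float = 0.5
    embed_dim: int = 128
    n_layers: int = 2
    n_heads: int = 4
    proj_hidden: int | None = None
    epochs: int = 500
    seed: int = 0
    leakage_safe: bool = False
    ablation: str = "full"
    # evaluation protocol
    n_repeats: int = 5
    n_folds: int = 5
    n_neg_draws: int = 10
    f1_mode: str = "raw"
    contrastive_reduction: str = "sum"
    early_stop: bool = False
    early_stop_patience: int = 50

    def __post_init__(self):
        if self.k < 1:
            raise InvalidInputError("k must be >= 1")
        if self.c < 1:
            raise InvalidInputError("c must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidInputError("alpha must be in (0, 1)")
        if not 0.0 <= self.eta <= 1.0:
            raise InvalidInputError("eta must be in [0, 1]")
        if self.tau <= 0:
            raise InvalidInputError("tau must be > 0")
        if self.lam < 0 or self.gam < 0:
            raise InvalidInputError("lam and gam must be >= 0")
        if self.ablation not in ABLATIONS:
            raise InvalidInputError(
                f"ablation must be one of {ABLATIONS}, got {self.ablation!r}")
        if self.embed_dim % self.n_heads != 0:
            raise InvalidInputError("embed_dim must be divisible by n_heads")
        if self.proj_hidden is None:
            self.proj_hidden = self.embed_dim

    def replace(self, **kw) -> "Config":
        return replace(self, **kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)},
                           fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ------------------------------------------------------------------- readers

def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_association_table(path) -> AssociationMatrix:
    """Read a two-column miRNA/disease association list into a binary matrix.

    Identifier order is first-appearance order; duplicate pairs collapse.
    """
    mirna_ids, disease_ids = [], []
    m_index, d_index = {}, {}
    pairs = []
    delim = None
    for lineno, line in _data_lines(path):
        if delim is None:
            delim = _sniff_delimiter(line)
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise ParseError(f"{path}:{lineno}: expected at least two "
                             f"delimited fields, got {line!r}")
        m, d = parts[0], parts[1]
        if m not in m_index:
            m_index[m] = len(mirna_ids)
            mirna_ids.append(m)
        if d not in d_index:
            d_index[d] = len(disease_ids)
            disease_ids.append(d)
        pairs.append((m_index[m], d_index[d]))
    if len(mirna_ids) < 2 or len(disease_ids) < 2:
        raise InvalidInputError(
            f"need at least 2 distinct ids per axis, got {len(mirna_ids)} "
            f"miRNAs and {len(disease_ids)} diseases")
    T = np.zeros((len(mirna_ids), len(disease_ids)), dtype=np.int8)
    for i, j in pairs:
        T[i, j] = 1
    return AssociationMatrix(mirna_ids, disease_ids, T)


def write_association_table(am: AssociationMatrix, path) -> None:
    with open(path, "w") as fh:
        for i, j in am.positives():
            fh.write(f"{am.mirna_ids[i]}\t{am.disease_ids[j]}\n")


def read_dag_table(path) -> DiseaseDAG:
    """Read a (disease_id, tree_number) table into ancestor/edge structure.

    A disease's ancestors are itself plus every disease owning a strict
    dot-prefix of any of its tree numbers.  Edges link each node to the
    owner(s) of its immediate prefix; prefixes owned by no disease are
    skipped silently (logged at debug level).
    """
    disease_ids: list = []
    codes: dict = {}
    owners: dict = {}  # tree number -> set of disease ids
    for lineno, line in _data_lines(path):
        delim = _sniff_delimiter(line)
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise ParseError(f"{path}:{lineno}: expected (disease_id, "
                             f"tree_number), got {line!r}")
        d, tn = parts[0], parts[1]
        if d not in codes:
            codes[d] = set()
            disease_ids.append(d)
        codes[d].add(tn)
        owners.setdefault(tn, set()).add(d)

    ancestors: dict = {}
    edges: dict = {}
    for d in disease_ids:
        anc = {d}
        dag_edges = set()
        # every prefix (including full codes) relevant to this disease's DAG
        relevant = set()
        for code in codes[d]:
            toks = code.split(".")
            for depth in range(1, len(toks) + 1):
                relevant.add(".".join(toks[:depth]))
        for node_code in relevant:
            toks = node_code.split(".")
            node_owners = owners.get(node_code, set())
            if not node_owners:
                logger.debug("orphan tree-number prefix %r (no owning "
                             "disease); skipped", node_code)
                continue
            anc.update(node_owners)
            if len(toks) > 1:
                parent_code = ".".join(toks[:-1])
                parent_owners = owners.get(parent_code, set())
                for p in parent_owners:
                    for child in node_owners:
                        dag_edges.add((p, child))
        ancestors[d] = anc
        edges[d] = dag_edges
    return DiseaseDAG(disease_ids, codes, ancestors, edges)


def write_dag_table(rows, path) -> None:
    """Write (disease_id, tree_number) rows as a TSV."""
    with open(path, "w") as fh:
        for d, tn in rows:
            fh.write(f"{d}\t{tn}\n")


def read_similarity_matrix(path) -> SimilarityMatrix:
    """Read a dense similarity TSV with id header row and id first column."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        delim = _sniff_delimiter(header)
        col_ids = [c for c in header.split(delim)[1:] if c != ""]
        row_ids, rows = [], []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split(delim)
            row_ids.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    S = np.asarray(rows, dtype=float)
    if S.shape[0] != S.shape[1] or S.shape[0] != len(col_ids):
        raise InvalidInputError(f"{path}: similarity matrix is not square "
                                f"({S.shape[0]} rows, {len(col_ids)} columns)")
    if row_ids != col_ids:
        raise InvalidInputError(f"{path}: header ids and first-column ids "
                                "differ")
    asym = np.abs(S - S.T).max(initial=0.0)
    if asym > 1e-12:
        logger.warning("%s: asymmetry up to %.3g; symmetrized as (S+S')/2",
                       path, asym)
        S = (S + S.T) / 2.0
    return SimilarityMatrix(row_ids, S)


def write_similarity_matrix(sim: SimilarityMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(sim.ids) + "\n")
        for i, rid in enumerate(sim.ids):
            fh.write(rid + "\t" +
                     "\t".join(format(x, ".17g") for x in sim.S[i]) + "\n")
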