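"""Weighted term-document matrix, truncated SVD knowledge space, ranking.

Latent semantic analysis over the per-factor corpus: documents are bags of
dictionary words, weighted (log-entropy by default), factorized by a
truncated singular value decomposition, and compared to free-text queries
by cosine similarity in the reduced eigen space. A factor — which owns many
documents — is represented by one vector (normalized centroid of its
documents' coordinates by default, or a folded-in pseudo-document).

Coordinate conventions. For A ≈ U_k S_k V_k^T, a document's coordinates
are the rows of V_k·S_k. A query with weighted count vector w is folded in
as q = U_k^T·w, so folding an indexed document's own column reproduces its
stored coordinates exactly: U_k^T(U S V^T e_d) = S·V^T e_d. At k = rank
with identity weighting the machinery reduces to the plain vector-space
model for any in-span query.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .corpus import DocumentCollection, document_text
from .dictionary import Dictionary, load_dictionary, save_dictionary, tokenize_text
from .errors import InputError, QueryError, UndefinedScoreError

__all__ = [
    "TermDocMatrix",
    "EigenSpace",
    "QueryResult",
    "count_terms",
    "build_matrix",
    "decompose",
    "fold_in",
    "cosine",
    "rank_factors",
    "save_model",
    "load_model",
    "WEIGHTING_SCHEMES",
]

WEIGHTING_SCHEMES = ("none", "log-entropy", "tf-idf")

#: vectors with norm below this are treated as zero vectors
NORM_FLOOR = 1e-12

#: above this minimum matrix dimension, decompose uses sparse iterative SVD
_DENSE_SVD_LIMIT = 1500


def count_terms(text: str, dictionary: Dictionary) -> np.ndarray:
    """Bag-of-words counts over the dictionary (out-of-dictionary ignored)."""
    if len(dictionary) == 0:
        raise InputError("dictionary is empty")
    counts = np.zeros(len(dictionary))
    index = dictionary.index_of
    for tok in tokenize_text(text):
        i = index.get(tok)
        if i is not None:
            counts[i] += 1.0
    return counts


def _local_weight(counts, scheme: str):
    """Local (within-document) term weight."""
    if scheme == "none":
        return counts
    return np.log1p(counts)  # log(1+c) for log-entropy and tf-idf


def _global_weights(raw: sp.csr_matrix, scheme: str) -> np.ndarray:
    """Global (per-term) weight from corpus-wide statistics.

    log-entropy: g_t = 1 + sum_d p_td log(p_td) / log(n_docs) with
    p_td = c_td / gf_t; terms absent from the corpus get weight 1.
    tf-idf: g_t = log(n_docs / df_t), absent terms df clipped to 1.
    """
    n_terms, n_docs = raw.shape
    if scheme == "none":
        return np.ones(n_terms)
    if scheme == "tf-idf":
        df = np.asarray((raw > 0).sum(axis=1)).ravel()
        return np.log(n_docs / np.clip(df, 1, None))
    if scheme == "log-entropy":
        gf = np.asarray(raw.sum(axis=1)).ravel()
        gw = np.ones(n_terms)
        if n_docs > 1:
            csc = raw.tocsr()
            gf_safe = np.where(gf > 0, gf, 1.0)
            p = csc.copy().astype(float)
            # scale each row by 1/gf_t
            p = sp.diags(1.0 / gf_safe) @ p
            plogp = p.copy()
            plogp.data = p.data * np.log(p.data)
            ent = np.asarray(plogp.sum(axis=1)).ravel()  # sum p log p (<= 0)
            gw = 1.0 + ent / np.log(n_docs)
            gw[gf == 0] = 1.0
        return gw
    raise InputError(f"unknown weighting scheme {scheme!r}")


@dataclass
class TermDocMatrix:
    """Sparse weighted term-document matrix (terms x documents)."""

    dictionary: Dictionary
    doc_ids: list[tuple[str, int]]  # (factor name, citation index)
    values: sp.csr_matrix
    weighting: str
    global_weights: np.ndarray

    def __post_init__(self):
        if self.values.shape != (len(self.dictionary), len(self.doc_ids)):
            raise InputError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.dictionary)} terms x {len(self.doc_ids)} documents"
            )


def build_matrix(
    collection: DocumentCollection,
    dictionary: Dictionary,
    weighting: str = "log-entropy",
) -> TermDocMatrix:
    """Count dictionary terms per citation and apply the weighting scheme.

    Column order follows collection iteration order (factors in list order,
    citations in file order). Rejects a corpus sharing no vocabulary with
    the dictionary.
    """
    if weighting not in WEIGHTING_SCHEMES:
        raise InputError(
            f"unknown weighting {weighting!r}; choose from {WEIGHTING_SCHEMES}"
        )
    rows, cols, data = [], [], []
    doc_ids: list[tuple[str, int]] = []
    for factor in collection.factors:
        for j, rec in enumerate(collection.documents_of[factor.name]):
            col = len(doc_ids)
            doc_ids.append((factor.name, j))
            counts = count_terms(document_text(rec), dictionary)
            nz = np.nonzero(counts)[0]
            rows.extend(nz.tolist())
            cols.extend([col] * len(nz))
            data.extend(counts[nz].tolist())
    raw = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(dictionary), len(doc_ids))
    )
    if raw.nnz == 0:
        raise InputError("dictionary shares no vocabulary with the corpus")
    gw = _global_weights(raw, weighting)
    weighted = raw.copy().astype(float)
    weighted.data = _local_weight(weighted.data, weighting)
    weighted = sp.diags(gw) @ weighted
    return TermDocMatrix(
        dictionary=dictionary,
        doc_ids=doc_ids,
        values=weighted.tocsr(),
        weighting=weighting,
        global_weights=gw,
    )


@dataclass
class EigenSpace:
    """Truncated decomposition of the weighted matrix plus factor vectors."""

    k: int
    term_basis: np.ndarray          # terms x k, orthonormal columns
    singular_values: np.ndarray     # k positive, non-increasing
    doc_vectors: np.ndarray         # documents x k (= V_k S_k)
    doc_ids: list[tuple[str, int]]
    factor_vectors: dict[str, np.ndarray]
    dictionary: Dictionary
    weighting: str
    global_weights: np.ndarray
    factor_mode: str = "centroid"

    def __post_init__(self):
        sv = np.asarray(self.singular_values, dtype=float)
        if sv.ndim != 1 or len(sv) != self.k:
            raise InputError("singular_values must have length k")
        if np.any(sv <= 0) or np.any(np.diff(sv) > 1e-9 * sv[0]):
            raise InputError("singular values must be positive, non-increasing")


def _matrix_rank(s: np.ndarray, shape) -> int:
    if len(s) == 0 or s[0] <= 0:
        return 0
    tol = max(shape) * np.finfo(float).eps * s[0]
    return int(np.sum(s > tol))


def _auto_k(s: np.ndarray, fraction: float, cap: int) -> int:
    mass = np.cumsum(s**2) / np.sum(s**2)
    k = int(np.searchsorted(mass, fraction) + 1)
    return min(k, cap, len(s))


def decompose(
    matrix: TermDocMatrix,
    k: int | None = None,
    variance_fraction: float = 0.8,
    k_cap: int = 300,
    factor_mode: str = "centroid",
) -> EigenSpace:
    """Best rank-k factorization of the weighted matrix.

    ``k=None`` selects the smallest k capturing ``variance_fraction`` of
    squared singular-value mass, capped at ``k_cap``. Asking for k above
    the numerical rank is rejected, reporting the achievable maximum.
    """
    A = matrix.values
    n_terms, n_docs = A.shape
    small = min(n_terms, n_docs)
    if small <= _DENSE_SVD_LIMIT:
        U, s, Vt = np.linalg.svd(A.toarray(), full_matrices=False)
    else:
        # iterative solver cannot reach full rank; leave headroom
        n_req = min(small - 1, max(k or 0, k_cap) + 10)
        U, s, Vt = spla.svds(A.astype(float), k=n_req)
        order = np.argsort(s)[::-1]
        U, s, Vt = U[:, order], s[order], Vt[order]
    rank = _matrix_rank(s, A.shape)
    if rank == 0:
        raise InputError("matrix is identically zero; nothing to decompose")
    if k is None:
        k = _auto_k(s[:rank], variance_fraction, k_cap)
    elif not (1 <= k <= rank):
        raise InputError(
            f"k={k} outside valid range 1..{rank} (numerical rank {rank})"
        )
    U_k, s_k, Vt_k = U[:, :k], s[:k], Vt[:k]
    doc_vectors = Vt_k.T * s_k  # documents x k
    space = EigenSpace(
        k=k,
        term_basis=U_k,
        singular_values=s_k,
        doc_vectors=doc_vectors,
        doc_ids=list(matrix.doc_ids),
        factor_vectors={},
        dictionary=matrix.dictionary,
        weighting=matrix.weighting,
        global_weights=matrix.global_weights,
        factor_mode=factor_mode,
    )
    space.factor_vectors = _compute_factor_vectors(space, matrix, factor_mode)
    return space


def _compute_factor_vectors(
    space: EigenSpace, matrix: TermDocMatrix, mode: str
) -> dict[str, np.ndarray]:
    """One k-vector per factor.

    centroid: mean of the factor's document coordinates, re-normalized to
    unit length (robust to collection-size imbalance). pseudo-doc: the
    factor's summed weighted counts folded into the space.
    """
    cols_of: dict[str, list[int]] = {}
    for col, (name, _) in enumerate(space.doc_ids):
        cols_of.setdefault(name, []).append(col)
    vectors = {}
    for name, cols in cols_of.items():
        if mode == "centroid":
            v = space.doc_vectors[cols].mean(axis=0)
            norm = np.linalg.norm(v)
            vectors[name] = v / norm if norm >= NORM_FLOOR else np.zeros_like(v)
        elif mode == "pseudo-doc":
            summed = np.asarray(
                matrix.values[:, cols].sum(axis=1)
            ).ravel()
            vectors[name] = space.term_basis.T @ summed
        else:
            raise InputError(f"unknown factor mode {mode!r}")
    return vectors


def _weight_query_counts(counts: np.ndarray, space: EigenSpace) -> np.ndarray:
    local = _local_weight(counts, space.weighting)
    return local * space.global_weights


def fold_in(text: str, dictionary: Dictionary, space: EigenSpace) -> np.ndarray:
    """Project a free-text query into the eigen space.

    Counts the query's dictionary words, applies the model's weighting, and
    projects onto the term basis. A query with no dictionary words is
    rejected, listing the unrecognized tokens.
    """
    counts = count_terms(text, dictionary)
    if not counts.any():
        unknown = tuple(
            t for t in dict.fromkeys(tokenize_text(text)) if t not in dictionary
        )
        raise QueryError(
            f"query contains no dictionary words; unrecognized: {unknown}",
            unrecognized=unknown,
        )
    return space.term_basis.T @ _weight_query_counts(counts, space)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; undefined (raised) for zero vectors, never 0.0."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < NORM_FLOOR or nv < NORM_FLOOR:
        raise UndefinedScoreError("cosine undefined for zero vector")
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class QueryResult:
    """Factors ranked by cosine to the folded query, descending."""

    query: str
    scores: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        vals = [s for _, s in self.scores]
        if any(not (-1.0 - 1e-9 <= s <= 1.0 + 1e-9) for s in vals):
            raise InputError("cosine scores must lie in [-1, 1]")
        if any(b > a + 1e-12 for a, b in zip(vals, vals[1:])):
            raise InputError("scores must be sorted descending")

    @property
    def factor_names(self) -> list[str]:
        return [n for n, _ in self.scores]

    def score_of(self, factor: str) -> float:
        return dict(self.scores)[factor]

    def rank_of(self, factor: str) -> int:
        """1-based rank of a factor."""
        return self.factor_names.index(factor) + 1


def rank_factors(
    query: str, space: EigenSpace, dictionary: Dictionary | None = None
) -> QueryResult:
    """Cosine of the folded query against every factor vector, sorted.

    Descending by score; ties broken lexicographically by factor name.
    """
    dictionary = dictionary if dictionary is not None else space.dictionary
    q = fold_in(query, dictionary, space)
    scored = []
    for name in sorted(space.factor_vectors):
        scored.append((name, cosine(q, space.factor_vectors[name])))
    scored.sort(key=lambda item: (-item[1], item[0]))
    return QueryResult(query=query, scores=scored)


def save_model(space: EigenSpace, out_dir: str | Path) -> None:
    """Persist a model bundle: dictionary, metadata JSON, arrays, factor TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_dictionary(space.dictionary, out)
    meta = {
        "k": space.k,
        "weighting": space.weighting,
        "factor_mode": space.factor_mode,
        "n_documents": len(space.doc_ids),
        "doc_ids": [[n, i] for n, i in space.doc_ids],
    }
    (out / "model.json").write_text(
        json.dumps(meta, indent=2) + "\n", encoding="utf-8"
    )
    np.save(out / "term_basis.npy", space.term_basis)
    np.save(out / "singular_values.npy", space.singular_values)
    np.save(out / "doc_vectors.npy", space.doc_vectors)
    np.save(out / "global_weights.npy", space.global_weights)
    with open(out / "factor_vectors.tsv", "w", encoding="utf-8") as fh:
        for name in sorted(space.factor_vectors):
            vec = "\t".join(f"{x:.17g}" for x in space.factor_vectors[name])
            fh.write(f"{name}\t{vec}\n")


def load_model(in_dir: str | Path) -> EigenSpace:
    """Inverse of :func:`save_model`."""
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "model.json").read_text(encoding="utf-8"))
    factor_vectors = {}
    for line in (in_dir / "factor_vectors.tsv").read_text(
        encoding="utf-8"
    ).splitlines():
        parts = line.split("\t")
        factor_vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
    return EigenSpace(
        k=meta["k"],
        term_basis=np.load(in_dir / "term_basis.npy"),
        singular_values=np.load(in_dir / "singular_values.npy"),
        doc_vectors=np.load(in_dir / "doc_vectors.npy"),
        doc_ids=[(n, i) for n, i in meta["doc_ids"]],
        factor_vectors=factor_vectors,
        dictionary=load_dictionary(in_dir),
        weighting=meta["weighting"],
        global_weights=np.load(in_dir / "global_weights.npy"),
        factor_mode=meta["factor_mode"],
    )
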