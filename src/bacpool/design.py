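"""Shifted transversal designs (STD) for combinatorial clone pooling.

An STD with parameters (P, L, Gamma) distributes up to ``P**(Gamma+1)``
clones into ``L`` *layers* of ``P`` pools each.  Every clone lands in
exactly one pool per layer; the resulting set of L pool indices is the
clone's *signature*.  Writing clone index ``i`` in base P as digits
``(i_0, ..., i_Gamma)``, the pool of clone ``i`` in layer ``j`` is

    j * P + (sum_c i_c * j**c) mod P        for j = 0 .. L-1.

Because two distinct degree-Gamma polynomials over GF(P) agree on at most
Gamma points, any two signatures share at most Gamma pools.  That bound is
what makes pooled sequencing deconvolutable: unions of up to
``floor((L-1)/Gamma)`` signatures remain pairwise distinct, and at least
``2*(L-Gamma)`` observation errors are needed to turn one signature into
another.

Pool numbering is layer-major throughout: layer j owns the global pool
indices ``[j*P, (j+1)*P)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sympy import isprime


class DesignParameterError(ValueError):
    """A pooling-design parameter violates its constraint."""


class ManifestFormatError(ValueError):
    """A pooling manifest file is malformed or inconsistent."""


@dataclass(frozen=True)
class DesignParams:
    """Parameters of a shifted transversal design.

    Attributes
    ----------
    P : int
        Prime number of pools per layer.
    L : int
        Number of layers (1 <= L <= P).  Total pools = L * P.
    Gamma : int
        Collision bound: two signatures share at most Gamma pools.
    n : int
        Number of items (clones) to pool; at most P**(Gamma+1).
    """

    P: int
    L: int
    Gamma: int
    n: int

    def __post_init__(self) -> None:
        if self.P <= 1 or not isprime(self.P):
            raise DesignParameterError(f"P must be prime and > 1, got P={self.P}")
        if not 1 <= self.L <= self.P:
            raise DesignParameterError(
                f"L must satisfy 1 <= L <= P, got L={self.L}, P={self.P}"
            )
        if self.Gamma < 1:
            raise DesignParameterError(f"Gamma must be >= 1, got {self.Gamma}")
        if not 1 <= self.n <= self.capacity:
            raise DesignParameterError(
                f"n must satisfy 1 <= n <= P**(Gamma+1) = {self.capacity}, got n={self.n}"
            )

    @property
    def capacity(self) -> int:
        """Maximum number of items the design can pool: P**(Gamma+1)."""
        return self.P ** (self.Gamma + 1)

    @property
    def n_pools(self) -> int:
        """Total number of pools, L * P."""
        return self.L * self.P


@dataclass
class PoolingDesign:
    """A constructed STD: per-item signatures and their pool transpose.

    ``signatures`` is an (n, L) integer array; row i holds the global pool
    indices of item i, column j lying in ``[j*P, (j+1)*P)``.
    """

    params: DesignParams
    signatures: np.ndarray
    _members: dict[int, np.ndarray] | None = field(default=None, repr=False)

    def signature(self, item: int) -> tuple[int, ...]:
        """Ordered pool indices (one per layer) of one item."""
        return tuple(int(p) for p in self.signatures[item])

    def signature_set(self, item: int) -> frozenset[int]:
        return frozenset(self.signature(item))

    @property
    def members(self) -> dict[int, np.ndarray]:
        """Pool index -> sorted array of member item indices (transpose of signatures)."""
        if self._members is None:
            members: dict[int, list[int]] = {p: [] for p in range(self.params.n_pools)}
            for item, sig in enumerate(self.signatures):
                for p in sig:
                    members[int(p)].append(item)
            self._members = {p: np.asarray(v, dtype=np.int64) for p, v in members.items()}
        return self._members

    def pool_masks(self) -> list[int]:
        """Signature of each item as a bitmask over global pool indices."""
        return [sum(1 << int(p) for p in sig) for sig in self.signatures]


def construct_std(params: DesignParams) -> PoolingDesign:
    """Construct the shifted transversal design for ``params``.

    Deterministic; item ``i`` joins pool ``j*P + poly_i(j) mod P`` in layer
    ``j``, where ``poly_i`` has the base-P digits of ``i`` as coefficients.
    """
    P, L, G, n = params.P, params.L, params.Gamma, params.n
    items = np.arange(n, dtype=np.int64)
    # base-P digits, least significant first: shape (n, Gamma+1)
    digits = np.empty((n, G + 1), dtype=np.int64)
    rem = items.copy()
    for c in range(G + 1):
        digits[:, c] = rem % P
        rem //= P
    shifts = np.arange(L, dtype=np.int64)
    # powers[j, c] = j**c mod P
    powers = np.empty((L, G + 1), dtype=np.int64)
    powers[:, 0] = 1 % P
    for c in range(1, G + 1):
        powers[:, c] = (powers[:, c - 1] * shifts) % P
    within = (digits @ powers.T) % P  # (n, L)
    signatures = within + shifts[np.newaxis, :] * P
    return PoolingDesign(params=params, signatures=signatures)


def validate_design(design: PoolingDesign) -> None:
    """Raise if any PoolingDesign invariant is violated.

    Checks layer ranges, one-pool-per-layer, the pairwise collision bound
    (O(n^2 L); intended for n up to a few thousand), and full-capacity
    pool regularity.
    """
    p = design.params
    sig = design.signatures
    if sig.shape != (p.n, p.L):
        raise ValueError(f"signatures shape {sig.shape} != (n={p.n}, L={p.L})")
    layers = np.arange(p.L)
    if not ((sig >= layers * p.P) & (sig < (layers + 1) * p.P)).all():
        raise ValueError("a signature entry lies outside its layer's pool range")
    inter = pairwise_intersection_matrix(design)
    if p.n >= 2:
        off = inter[np.triu_indices(p.n, k=1)]
        if off.max(initial=0) > p.Gamma:
            raise ValueError("two signatures share more than Gamma pools")
    if p.n == p.capacity:
        sizes = {len(v) for v in design.members.values()}
        if sizes != {p.P**p.Gamma}:
            raise ValueError("full-capacity design is not pool-regular")


def pairwise_intersection_matrix(design: PoolingDesign) -> np.ndarray:
    """(n, n) matrix of signature intersection sizes.

    Pools in different layers can never coincide, so the intersection size
    is the number of layers where two signatures pick the same pool.
    """
    sig = design.signatures
    n = sig.shape[0]
    inter = np.zeros((n, n), dtype=np.uint8)
    for j in range(sig.shape[1]):
        col = sig[:, j]
        inter += col[:, None] == col[None, :]
    return inter


def pairwise_intersection_histogram(
    design: PoolingDesign,
) -> dict[int, tuple[int, float]]:
    """Distribution of |sig(a) ∩ sig(b)| over all unordered item pairs.

    Returns ``{t: (count, percentage)}`` for every intersection size t that
    occurs.  Percentages are over all n*(n-1)/2 pairs.
    """
    n = design.params.n
    if n < 2:
        return {}
    inter = pairwise_intersection_matrix(design)
    vals = inter[np.triu_indices(n, k=1)]
    counts = np.bincount(vals)
    total = vals.size
    return {
        int(t): (int(c), 100.0 * c / total) for t, c in enumerate(counts) if c > 0
    }


def _triple_deficit(sig: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Collision deficit 3L - |sig(a) ∪ sig(b) ∪ sig(c)| for index triples."""
    L = sig.shape[1]
    A, B, C = sig[a], sig[b], sig[c]
    ab = A == B
    ac = A == C
    bc = B == C
    pairs_equal = ab.astype(np.int64) + ac + bc
    # per layer: 0 equal pairs -> 3 distinct pools, 1 -> 2, 3 -> 1
    distinct = 3 - pairs_equal + (pairs_equal == 3)
    union = distinct.sum(axis=1)
    return 3 * L - union


def triple_collision_histogram(
    design: PoolingDesign,
    n_samples: int | str = "all",
    seed: int = 0,
) -> dict[int, float]:
    """Distribution of the triple shared-pool statistic over item triples.

    The statistic for a triple {a, b, c} is the *union deficit*
    ``3L - |sig(a) ∪ sig(b) ∪ sig(c)|``, i.e. the total number of pool
    collisions within the triple; its maximum is 3*Gamma.  With
    ``n_samples="all"`` every C(n,3) triple is enumerated (small n only);
    otherwise ``n_samples`` distinct triples are sampled uniformly using
    ``seed``.  Returns ``{x: percentage}``.
    """
    n = design.params.n
    if n < 3:
        raise ValueError(f"need at least 3 items for triples, got n={n}")
    sig = design.signatures
    if n_samples == "all":
        idx = np.array(list(itertools.combinations(range(n), 3)), dtype=np.int64)
        deficits = _triple_deficit(sig, idx[:, 0], idx[:, 1], idx[:, 2])
    else:
        m = int(n_samples)
        total = n * (n - 1) * (n - 2) // 6
        if m > total:
            raise ValueError(f"cannot sample {m} distinct triples from C({n},3)={total}")
        rng = np.random.default_rng(seed)
        # sequential rejection sampling: keep the first m distinct triples in
        # draw order (truncating a sorted unique array would bias the sample)
        keys = np.empty(0, dtype=np.int64)
        while True:
            need = m - np.unique(keys).size
            if need <= 0:
                break
            draw = rng.integers(0, n, size=(int(need * 1.1) + 16, 3))
            distinct = (
                (draw[:, 0] != draw[:, 1])
                & (draw[:, 0] != draw[:, 2])
                & (draw[:, 1] != draw[:, 2])
            )
            draw = np.sort(draw[distinct], axis=1)
            keys = np.concatenate([keys, (draw[:, 0] * n + draw[:, 1]) * n + draw[:, 2]])
        _, first = np.unique(keys, return_index=True)
        keep = keys[np.sort(first)[:m]]
        a, rest = keep // (n * n), keep % (n * n)
        deficits = _triple_deficit(sig, a, rest // n, rest % n)
    counts = np.bincount(deficits)
    total_triples = deficits.size
    return {int(x): 100.0 * c / total_triples for x, c in enumerate(counts) if c > 0}


def decodability(params: DesignParams) -> int:
    """Decodability of the design at full capacity: floor((L-1)/Gamma).

    Unions of up to this many signatures are pairwise distinct, so sequence
    shared by up to that many clones can still be attributed exactly.
    """
    return (params.L - 1) // params.Gamma


def verify_decodability(design: PoolingDesign, d: int) -> bool:
    """Exhaustively check that unions of <= d signatures are pairwise distinct.

    Exponential in d; intended for small designs (n <= ~200, d <= 3).
    """
    n = design.params.n
    sets = [design.signature_set(i) for i in range(n)]
    unions: dict[frozenset[int], tuple[int, ...]] = {}
    for size in range(1, d + 1):
        for combo in itertools.combinations(range(n), size):
            u = frozenset().union(*(sets[i] for i in combo))
            if u in unions and unions[u] != combo:
                return False
            unions[u] = combo
    return True


def min_signature_distance(design: PoolingDesign) -> int:
    """Minimum symmetric-difference distance between two signatures.

    Equals ``2*(L - max pairwise intersection)`` and is bounded below by
    ``2*(L - Gamma)``: the number of observation errors needed to convert
    one clone's signature into another's.
    """
    p = design.params
    if p.n < 2:
        raise ValueError("signature distance needs at least 2 items")
    inter = pairwise_intersection_matrix(design)
    max_inter = int(inter[np.triu_indices(p.n, k=1)].max())
    return 2 * (p.L - max_inter)


# ---------------------------------------------------------------------------
# manifest I/O

_MANIFEST_META = ("P", "L", "Gamma", "n")


def write_manifest(design: PoolingDesign, clone_ids: list[str], path) -> None:
    """Write the clone -> pool assignment as TSV.

    Header comment lines carry the design parameters; columns are
    ``clone_id`` then ``pool_layer_j`` (global pool index) for each layer.
    """
    p = design.params
    if len(clone_ids) != p.n:
        raise ManifestFormatError(
            f"got {len(clone_ids)} clone ids for n={p.n} items"
        )
    if len(set(clone_ids)) != len(clone_ids):
        raise ManifestFormatError("clone ids must be unique")
    with open(path, "w") as fh:
        for key, val in zip(_MANIFEST_META, (p.P, p.L, p.Gamma, p.n)):
            fh.write(f"#{key}={val}\n")
        cols = "\t".join(f"pool_layer_{j}" for j in range(p.L))
        fh.write(f"clone_id\t{cols}\n")
        for cid, sig in zip(clone_ids, design.signatures):
            fh.write(cid + "\t" + "\t".join(str(int(x)) for x in sig) + "\n")


def read_manifest(path) -> tuple[PoolingDesign, list[str]]:
    """Read a manifest written by :func:`write_manifest`; validates fully."""
    meta: dict[str, int] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        key, _, val = line[1:].strip().partition("=")
        meta[key] = int(val)
    missing = [k for k in _MANIFEST_META if k not in meta]
    if missing:
        raise ManifestFormatError(f"manifest missing parameter header(s): {missing}")
    params = DesignParams(P=meta["P"], L=meta["L"], Gamma=meta["Gamma"], n=meta["n"])
    header = lines[body_start].rstrip("\n").split("\t")
    expected = ["clone_id"] + [f"pool_layer_{j}" for j in range(params.L)]
    if header != expected:
        raise ManifestFormatError(f"unknown manifest header {header!r}")
    rows = [ln.rstrip("\n").split("\t") for ln in lines[body_start + 1 :] if ln.strip()]
    if len(rows) != params.n:
        raise ManifestFormatError(f"manifest has {len(rows)} rows, expected n={params.n}")
    clone_ids = [r[0] for r in rows]
    if len(set(clone_ids)) != len(clone_ids):
        raise ManifestFormatError("duplicate clone ids in manifest")
    try:
        signatures = np.array([[int(x) for x in r[1:]] for r in rows], dtype=np.int64)
    except ValueError as exc:
        raise ManifestFormatError(f"non-integer pool index: {exc}") from exc
    design = PoolingDesign(params=params, signatures=signatures)
    layers = np.arange(params.L)
    if signatures.shape[1] != params.L or not (
        (signatures >= layers * params.P) & (signatures < (layers + 1) * params.P)
    ).all():
        raise ManifestFormatError("a pool index lies outside its layer's range")
    validate_design(design)
    return design, clone_ids


def design_stats_frame(design: PoolingDesign, triple_samples: int | str | None = None,
                       seed: int = 0) -> pd.DataFrame:
    """Tidy summary of the design's combinatorial statistics (for the CLI)."""
    p = design.params
    rows = [
        ("n_pools", p.n_pools),
        ("pools_per_clone", p.L),
        ("capacity", p.capacity),
        ("decodability", decodability(p)),
    ]
    if p.n == p.capacity:
        rows.append(("clones_per_pool", p.P**p.Gamma))
    if p.n >= 2:
        rows.append(("min_signature_distance", min_signature_distance(design)))
        for t, (cnt, pct) in sorted(pairwise_intersection_histogram(design).items()):
            rows.append((f"pair_pct_share_{t}", round(pct, 4)))
    if triple_samples is not None and p.n >= 3:
        hist = triple_collision_histogram(design, n_samples=triple_samples, seed=seed)
        for x, pct in sorted(hist.items()):
            rows.append((f"triple_pct_share_{x}", round(pct, 4)))
    frame = pd.DataFrame(rows, columns=["statistic", "value"])
    # keep integer statistics printing as integers alongside percentages
    frame["value"] = pd.array([v for _, v in rows], dtype=object)
    return frame
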