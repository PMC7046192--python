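"""Genealogical congruence machinery: missing-aware distance matrices,
neighbor-joining trees (plumbing for visual checks), principal-coordinate
embedding with Cailliez correction, and a Procrustes permutation test of
host/symbiont congruence (the PACo approach).

The congruence statistic is the normalised Procrustes residual
m2 = 1 - (sum of singular values of Xc'Yc)^2 / (tr(Xc'Xc) tr(Yc'Yc)),
which is invariant under translation, rotation and global rescaling of
either configuration.  The null distribution is generated by permuting the
host-parasite pairing; p uses the add-one convention so that perfect
congruence reports the smallest achievable p = 1/(n_perm + 1), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj


def distance_matrix(alleles: np.ndarray, labels, min_sites: int = 1
                    ) -> DistanceMatrix:
    """Pairwise mismatch-proportion matrix, missing-aware.

    ``alleles`` is (n_taxa, n_sites) with allele codes and -1 for missing.
    A pair with fewer than ``min_sites`` pairwise-complete sites raises an
    error naming the pair.
    """
    a = np.asarray(alleles)
    labels = list(labels)
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (a[i] >= 0) & (a[j] >= 0)
            m = int(ok.sum())
            if m < max(min_sites, 1):
                raise ValueError(
                    f"pair ({labels[i]}, {labels[j]}) has {m} complete "
                    f"sites (< {min_sites})")
            d[i, j] = d[j, i] = np.sum(a[i, ok] != a[j, ok]) / m
    return DistanceMatrix(d, ids=labels)


def mutation_set_distance_matrix(sets: dict) -> DistanceMatrix:
    """Distance matrix from labelled mutation-position sets (e.g. clonal
    symbiont genomes): the symmetric-difference count between each pair."""
    labels = list(sets)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    as_sets = {k: set(np.asarray(v).tolist()) for k, v in sets.items()}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = len(
                as_sets[labels[i]] ^ as_sets[labels[j]])
    return DistanceMatrix(d, ids=labels)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree as newick text (deterministic for a given
    input order)."""
    if not np.all(np.isfinite(dm.data)):
        raise ValueError("non-finite distance in matrix")
    import io as _io

    buf = _io.StringIO()
    nj(dm).write(buf)
    return buf.getvalue().strip()


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest constant c such that d + c (off-diagonal) is Euclidean."""
    n = d.shape[0]
    d2 = d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    delta1 = -0.5 * J @ d2 @ J
    delta2 = -0.5 * J @ d @ J
    upper = np.hstack([np.zeros((n, n)), 2 * delta1])
    lower = np.hstack([-np.eye(n), -4 * delta2])
    special = np.vstack([upper, lower])
    ev = np.linalg.eigvals(special)
    return float(np.max(ev.real))


@dataclass
class PCoAResult:
    coords: np.ndarray          # (n, k) coordinates, decreasing eigenvalue
    eigenvalues: np.ndarray     # full spectrum of the Gower matrix
    cailliez: float             # additive constant applied (0 if none)


def pcoa(dm: DistanceMatrix | np.ndarray, neg_tol: float = 1e-8
         ) -> PCoAResult:
    """Classical principal-coordinate embedding (Gower double-centring).

    Mismatch-proportion matrices need not be Euclidean; when the Gower
    matrix has an eigenvalue below -neg_tol the Cailliez additive constant
    is applied to the off-diagonal distances and the embedding recomputed,
    so all retained axes are real.
    """
    d = dm.data if isinstance(dm, DistanceMatrix) else np.asarray(dm, float)
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n

    def embed(dist):
        G = -0.5 * J @ (dist ** 2) @ J
        w, v = np.linalg.eigh(G)
        order = np.argsort(w)[::-1]
        return w[order], v[:, order]

    w, v = embed(d)
    c = 0.0
    if np.any(w < -neg_tol * max(1.0, w.max(initial=1.0))):
        c = _cailliez_constant(d)
        if c > 0:
            d = d + c * (1 - np.eye(n))
            w, v = embed(d)
    keep = w > max(neg_tol, neg_tol * max(w.max(initial=0.0), 1.0))
    coords = v[:, keep] * np.sqrt(w[keep])
    if coords.shape[1] == 0:
        coords = np.zeros((n, 1))
    return PCoAResult(coords, w, c)


def procrustes_m2(x: np.ndarray, y: np.ndarray) -> float:
    """Normalised Procrustes residual between two configurations.

    Rows are paired observations.  Both configurations are centred; the
    statistic is 1 - (sum sigma_i(Xc' Yc))^2 / (tr(Xc'Xc) tr(Yc'Yc)),
    i.e. the fraction of Y's variation not explained by the best
    translation + rotation + scaling onto X.
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    k = max(xc.shape[1], yc.shape[1])
    if xc.shape[1] < k:
        xc = np.hstack([xc, np.zeros((xc.shape[0], k - xc.shape[1]))])
    if yc.shape[1] < k:
        yc = np.hstack([yc, np.zeros((yc.shape[0], k - yc.shape[1]))])
    denom = np.sum(xc ** 2) * np.sum(yc ** 2)
    if denom == 0:
        return 0.0
    s = np.linalg.svd(xc.T @ yc, compute_uv=False)
    return float(1.0 - s.sum() ** 2 / denom)


@dataclass
class PacoResult:
    m2: float
    p: float
    n_perm: int
    seed: object

    def to_json(self) -> dict:
        return {"m2": self.m2, "p": self.p, "n_perm": self.n_perm,
                "seed": self.seed}


def paco_test(host: DistanceMatrix, parasite: DistanceMatrix,
              pairing: dict, n_perm: int = 100_000, seed=None) -> PacoResult:
    """Procrustes permutation test of congruence between two distance
    matrices under a one-to-one host-parasite pairing.

    The parasite embedding is superimposed on the host embedding; the null
    is generated by permuting which parasite taxon pairs with which host
    taxon.  p = (1 + #{m2_perm <= m2_obs}) / (1 + n_perm).
    """
    hosts = list(host.ids)
    if set(pairing.keys()) != set(hosts):
        raise ValueError("pairing must map every host taxon")
    parasites = [pairing[h] for h in hosts]
    if len(set(parasites)) != len(parasites) or \
            set(parasites) != set(parasite.ids):
        raise ValueError("pairing must be a bijection onto parasite taxa")
    X = pcoa(host).coords
    Y_full = pcoa(parasite).coords
    p_index = {t: i for i, t in enumerate(parasite.ids)}
    order = np.array([p_index[t] for t in parasites])
    Y = Y_full[order]
    m2_obs = procrustes_m2(X, Y)
    rng = np.random.default_rng(seed)
    n = len(hosts)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if procrustes_m2(X, Y[perm]) <= m2_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PacoResult(m2_obs, p, n_perm, seed)
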