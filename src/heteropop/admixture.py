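"""Admixture model fitting, K selection by masking cross-validation, Fst,
the Fst tree, and PCA coordinates.

Model.  Line i at biallelic locus j carries dosage g_ij in {0,1,2}; with
admixture proportions Q (rows sum to 1) and ancestral group alt-allele
frequencies P, each of its two alleles is alt with probability
pi_ij = sum_k Q_ik P_kj.  The log-likelihood is the binomial

    l(Q, P) = sum_ij g_ij ln pi_ij + (2 - g_ij) ln(1 - pi_ij)

over non-missing entries.  Fitting is by EM: the E-step allocates each
observed alt (ref) allele to source k proportionally to Q_ik P_kj
(Q_ik (1 - P_kj)); the M-step renormalizes the expected allele counts into
Q and P.  The likelihood is non-decreasing every iteration.  Label
switching is resolved by ordering groups by descending total Q mass.

K is selected by masking cross-validation: a random fold of non-missing
entries is held out, the model refit on the rest, and the mean squared
deviation between the held-out dosages and their fitted expectation
2*pi_ij is averaged over folds; the K minimizing this error is chosen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .genotype_io import MISSING, GenotypeMatrix, alt_freq

EPS = 1e-6


# ---------------------------------------------------------------------------
# likelihood and EM

def loglik(g: np.ndarray, Q: np.ndarray, P: np.ndarray) -> float:
    """Binomial admixture log-likelihood; missing entries skipped."""
    g = np.asarray(g)
    if Q.shape[0] != g.shape[0] or P.shape[1] != g.shape[1] \
            or Q.shape[1] != P.shape[0]:
        raise ValueError("shape mismatch between G, Q and P")
    obs = g != MISSING
    pi = np.clip(Q @ P, EPS, 1.0 - EPS)
    gg = np.where(obs, g, 0).astype(float)
    ll = gg * np.log(pi) + (2.0 - gg) * np.log1p(-pi)
    return float(ll[obs].sum())


def _em_fit(g, K, rng, max_iter, tol, obs=None):
    n, m = g.shape
    obs = (g != MISSING) if obs is None else obs
    gg = np.where(obs, g, 0).astype(float)
    ref = np.where(obs, 2.0 - g, 0.0)
    n_alleles = 2.0 * obs.sum(axis=1)     # per line
    p0 = alt_freq(np.where(obs, g, MISSING))
    p0 = np.where(np.isnan(p0), 0.5, p0)
    P = np.clip(p0[None, :] + rng.uniform(-0.1, 0.1, size=(K, m)), EPS, 1 - EPS)
    Q = rng.dirichlet(np.ones(K), size=n)
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        # E-step ratios; the 3-D allocation tensors reduce to matmuls
        pi = np.clip(Q @ P, EPS, 1 - EPS)
        ggp = gg / pi                               # alt alleles / pi
        rom = ref / (1.0 - pi)                      # ref alleles / (1 - pi)
        alt_k = P * (Q.T @ ggp)                     # (K, m) expected alt
        ref_k = (1.0 - P) * (Q.T @ rom)             # (K, m) expected ref
        Q = Q * (ggp @ P.T + rom @ (1.0 - P).T) / n_alleles[:, None]
        P = np.clip(alt_k / np.clip(alt_k + ref_k, 1e-12, None), EPS, 1 - EPS)
        Q = np.clip(Q, 0.0, 1.0)
        Q /= Q.sum(axis=1, keepdims=True)
        ll = loglik(g, Q, P)
        trace.append(ll)
        if np.isfinite(prev) and ll - prev < tol * max(1.0, abs(ll)):
            break
        prev = ll
    return Q, P, trace


def fit_admixture(G: GenotypeMatrix | np.ndarray, K: int, seed: int = 0,
                  max_iter: int = 2000, tol: float = 1e-6,
                  n_restarts: int = 5):
    """Fit Q and P for a given K by EM with random restarts.

    Returns (Q, P, loglik_trace) from the best restart.  Groups are ordered
    by descending total Q mass.  Deterministic given ``seed``.
    """
    g = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
    n = g.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError("K cannot exceed the number of lines")
    if K == 1:  # closed form: Q all ones, P = observed frequencies
        p = alt_freq(g)
        p = np.clip(np.where(np.isnan(p), 0.5, p), EPS, 1 - EPS)
        Q = np.ones((n, 1))
        P = p[None, :]
        return Q, P, [loglik(g, Q, P)]
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(max(1, n_restarts))]
    best = None
    for rng in rngs:
        Q, P, trace = _em_fit(g, K, rng, max_iter, tol)
        if best is None or trace[-1] > best[2][-1]:
            best = (Q, P, trace)
    Q, P, trace = best
    order = np.argsort(-Q.sum(axis=0), kind="stable")
    return Q[:, order], P[order, :], trace


def cv_error(G: GenotypeMatrix | np.ndarray, K: int, n_folds: int = 5,
             mask_rate: float | None = None, seed: int = 0,
             max_iter: int = 300, tol: float = 1e-5,
             n_restarts: int = 1) -> float:
    """Masking cross-validation error for one K.

    Non-missing entries are partitioned into ``n_folds`` random folds (or,
    when ``mask_rate`` is given, each fold holds out that fraction of
    entries).  Each fold is masked in turn, the model refit on the rest,
    and the error is the mean of (g - 2*pi_hat)^2 over the held-out
    entries, averaged over folds.
    """
    g = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
    obs_idx = np.argwhere(g != MISSING)
    rng = np.random.default_rng(seed)
    n_obs = obs_idx.shape[0]
    if mask_rate is not None:
        n_hold = int(round(mask_rate * n_obs))
        if n_hold == 0:
            raise ValueError("mask_rate leaves an empty held-out set")
        folds = [rng.choice(n_obs, size=n_hold, replace=False)
                 for _ in range(n_folds)]
    else:
        perm = rng.permutation(n_obs)
        folds = np.array_split(perm, n_folds)
        if any(f.size == 0 for f in folds):
            raise ValueError("fold with no held-out entries")
    errs = []
    fold_seeds = np.random.SeedSequence(seed).spawn(len(folds))
    for fold, fseed in zip(folds, fold_seeds):
        held = obs_idx[fold]
        g_train = g.copy()
        g_train[held[:, 0], held[:, 1]] = MISSING
        if K == 1:
            Q, P, _ = fit_admixture(g_train, 1)
        else:
            frng = np.random.default_rng(fseed)
            Q, P, _ = max(
                (_em_fit(g_train, K, frng, max_iter, tol)
                 for _ in range(max(1, n_restarts))),
                key=lambda t: t[2][-1])
        pi = np.clip(Q @ P, EPS, 1 - EPS)
        pred = 2.0 * pi[held[:, 0], held[:, 1]]
        truth = g[held[:, 0], held[:, 1]].astype(float)
        errs.append(float(np.mean((truth - pred) ** 2)))
    return float(np.mean(errs))


def select_k(G, k_values, seed: int = 0, **cv_kwargs) -> pd.DataFrame:
    """CV error for each K; the row with the minimum is the chosen K."""
    rows = [{"K": int(k), "cv_error": cv_error(G, int(k), seed=seed,
                                               **cv_kwargs)}
            for k in k_values]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fst

def fst_pairwise(freqs_a: np.ndarray, freqs_b: np.ndarray,
                 method: str = "nei",
                 n_a: np.ndarray | None = None,
                 n_b: np.ndarray | None = None) -> float:
    """Pairwise Fst from per-locus allele frequencies.

    "nei": ratio of sums sum(H_T - H_S) / sum(H_T) with H_S the mean of the
    two within-group gene diversities and H_T the gene diversity of the
    pooled mean frequency.  "hudson": ratio of averages with sample-size
    bias correction (requires allele sample counts n_a, n_b).
    """
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.any():
        raise ValueError("no loci with defined frequencies in both groups")
    a, b = a[ok], b[ok]
    if method == "nei":
        hs = 0.5 * (2 * a * (1 - a) + 2 * b * (1 - b))
        pbar = 0.5 * (a + b)
        ht = 2 * pbar * (1 - pbar)
        denom = ht.sum()
        if denom == 0:
            return 0.0
        return float(np.clip((ht - hs).sum() / denom, 0.0, 1.0))
    if method == "hudson":
        if n_a is None or n_b is None:
            raise ValueError("hudson method needs allele sample counts")
        na = np.asarray(n_a, dtype=float)[ok]
        nb = np.asarray(n_b, dtype=float)[ok]
        num = ((a - b) ** 2
               - a * (1 - a) / np.clip(na - 1, 1, None)
               - b * (1 - b) / np.clip(nb - 1, 1, None))
        den = a * (1 - b) + b * (1 - a)
        if den.sum() == 0:
            return 0.0
        return float(np.clip(num.sum() / den.sum(), 0.0, 1.0))
    raise ValueError(f"unknown Fst method: {method}")


def fst_matrix(freq_table: np.ndarray, labels=None,
               method: str = "nei") -> pd.DataFrame:
    """All pairwise Fst values from a groups x loci frequency matrix."""
    F = np.asarray(freq_table, dtype=float)
    K = F.shape[0]
    labels = list(labels) if labels is not None else [f"G{k+1}"
                                                      for k in range(K)]
    out = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            out[i, j] = out[j, i] = fst_pairwise(F[i], F[j], method=method)
    return pd.DataFrame(out, index=labels, columns=labels)


def fst_tree(fst: pd.DataFrame) -> str:
    """UPGMA tree (Newick text) on the Fst distance matrix.

    A two-group matrix yields a single cherry whose two branches each have
    length Fst/2; heights are ultrametric.  Ties are broken by scipy's
    deterministic ordering of the condensed matrix (label order).
    """
    from scipy.spatial.distance import squareform

    labels = list(fst.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for a tree")
    Z = linkage(squareform(fst.to_numpy(), checks=False), method="average")
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    newick = {i: labels[i] for i in range(n)}
    for k, (a, b, dist, _) in enumerate(Z):
        a, b = int(a), int(b)
        h = dist / 2.0
        la = h - heights[a]
        lb = h - heights[b]
        node = n + k
        newick[node] = f"({newick[a]}:{la:.6f},{newick[b]}:{lb:.6f})"
        heights[node] = h
    return newick[n + len(Z) - 1] + ";"


# ---------------------------------------------------------------------------
# PCA

def pca_coordinates(G: GenotypeMatrix, n_components: int = 10,
                    standardize: bool = False) -> pd.DataFrame:
    """Line coordinates on the leading principal components of the centered
    (optionally frequency-standardized) dosage matrix.

    Missing dosages are imputed to the column mean; monomorphic loci are
    dropped.  Components are ordered by explained variance; each component's
    sign is fixed so its largest-magnitude loading is positive.
    """
    p = alt_freq(G.values)
    poly = (p > 0) & (p < 1)
    if G.n_lines < 2 or poly.sum() < 2:
        raise ValueError("need >= 2 lines and >= 2 polymorphic loci")
    v = G.values[:, poly].astype(float)
    pj = p[poly]
    v = np.where(v == MISSING, 2 * pj[None, :], v)
    Z = v - 2 * pj[None, :]
    if standardize:
        Z = Z / np.sqrt(2 * pj * (1 - pj))[None, :]
    n_comp = min(n_components, min(Z.shape) - 1)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    coords = U[:, :n_comp] * S[:n_comp]
    for c in range(coords.shape[1]):
        load = Vt[c]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, c] = -coords[:, c]
    return pd.DataFrame(coords, index=G.line_names,
                        columns=[f"PC{i+1}" for i in range(coords.shape[1])])
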