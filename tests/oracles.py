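"""Independent oracle computations for the test suite.

These deliberately avoid the package's own code paths wherever the quantity
being checked is the package's responsibility:

* profile counting — a vectorized scan over all 2^k bit patterns built from
  explicit bit extraction (not the package's enumeration kernel);
* constrained Gaussian MLE — an edge-sweep iterative-proportional-fitting
  routine, distinct from the package's clique-based refit, whose output is
  verified against the defining optimality certificate (model covariance
  matches the sample covariance on the support and diagonal; precision is
  exactly zero off the support);
* exhaustive EBIC support search — scores every sparsity pattern, not just
  the penalty path.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_count(rule) -> int:
    """Count eligible patterns by explicit bit extraction over all 2^k."""
    k = rule.k
    codes = np.arange(2**k, dtype=np.int64)
    bits = (codes[:, None] >> np.arange(k - 1, -1, -1)) & 1  # item 1 first
    counts = bits.sum(axis=1)
    if rule.rule_kind == "threshold":
        ok = counts * rule.max_item_score >= rule.threshold
    else:
        core = np.array(sorted(rule.core_items)) - 1
        ok = (counts >= rule.min_count) & (bits[:, core].sum(axis=1) > 0)
    return int(ok.sum())


def constrained_mle_oracle(
    S: np.ndarray,
    support: list[tuple[int, int]],
    tol: float = 1e-10,
    max_iter: int = 5000,
) -> np.ndarray:
    """Edge-sweep IPF for the zero-constrained Gaussian MLE."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    K = np.diag(1.0 / np.diag(S))
    blocks = [[i] for i in range(p)] + [list(e) for e in support]
    for _ in range(max_iter):
        delta = 0.0
        for B in blocks:
            sigma = np.linalg.inv(K)
            block = sigma[np.ix_(B, B)]
            delta = max(delta, float(np.abs(block - S[np.ix_(B, B)]).max()))
            K[np.ix_(B, B)] += np.linalg.inv(S[np.ix_(B, B)]) - np.linalg.inv(block)
        if delta < tol:
            break
    return (K + K.T) / 2.0


def mle_certificate_holds(
    S: np.ndarray,
    K: np.ndarray,
    support: list[tuple[int, int]],
    tol: float = 1e-6,
) -> bool:
    """Optimality conditions of the constrained Gaussian MLE."""
    p = S.shape[0]
    sigma = np.linalg.inv(K)
    on = {tuple(sorted(e)) for e in support}
    for i in range(p):
        if abs(sigma[i, i] - S[i, i]) > tol:
            return False
        for j in range(i + 1, p):
            if (i, j) in on:
                if abs(sigma[i, j] - S[i, j]) > tol:
                    return False
            elif abs(K[i, j]) > tol:
                return False
    return True


def ebic_for_support(
    S: np.ndarray, n: int, support: list[tuple[int, int]], gamma: float = 0.5
) -> float:
    K = constrained_mle_oracle(S, support)
    assert mle_certificate_holds(S, K, support)
    _, logdet = np.linalg.slogdet(K)
    ll = (n / 2.0) * (logdet - float(np.sum(S * K)))
    p = S.shape[0]
    return -2.0 * ll + len(support) * (np.log(n) + 4.0 * gamma * np.log(p))


def exhaustive_ebic_support(
    S: np.ndarray, n: int, gamma: float = 0.5
) -> frozenset[tuple[int, int]]:
    """Minimum-EBIC support over every sparsity pattern (p <= 5 feasible)."""
    p = S.shape[0]
    pairs = list(itertools.combinations(range(p), 2))
    best, best_support = np.inf, frozenset()
    for mask in itertools.product([0, 1], repeat=len(pairs)):
        support = [pairs[i] for i, m in enumerate(mask) if m]
        ebic = ebic_for_support(S, n, support, gamma)
        if ebic < best - 1e-6:
            best, best_support = ebic, frozenset(support)
    return best_support
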