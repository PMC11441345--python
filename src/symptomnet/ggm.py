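"""Per-profile Gaussian graphical model estimation.

Within one symptom profile's subsample, the association structure among the
present symptoms is modelled as a pairwise Markov random field over the
continuous 0-3 item scores: edges are partial correlations, computed from
the precision (inverse covariance) matrix as

    pcor_ij = -K_ij / sqrt(K_ii * K_jj).

Two estimators are provided:

* ``ebic_glasso`` — the graphical lasso solved along a log-spaced penalty
  path from ``lambda_max`` (the largest absolute off-diagonal sample
  correlation, at which the solution is diagonal) down to
  ``lambda_min_ratio * lambda_max``.  Each candidate sparsity pattern on
  the path is refit by constrained maximum likelihood (iterative
  proportional fitting with zeros held off the support), and the model
  minimizing the extended Bayesian information criterion

      EBIC = -2*ll + E*log(n) + 4*E*gamma*log(p),
      ll   = (n/2) * (log det K - trace(S K)),

  is selected, with ties resolved toward the sparser (larger-penalty)
  solution.  ``E`` is the number of nonzero upper-triangle precision
  entries and ``ll`` the maximized log-likelihood of the refit ``K`` — the
  criterion's original formulation, which evaluates each *model* rather
  than each shrunken estimate and is therefore selection-consistent
  (evaluating EBIC at the penalized estimates instead systematically
  favours denser models, because weakening the shrinkage of strong edges
  buys likelihood).  The per-penalty solver is scikit-learn's
  ``graphical_lasso``.
* ``nonreg_threshold`` — the unregularized partial correlations from the
  inverted correlation matrix, with each edge tested by the Fisher
  z-transform at effective degrees of freedom ``n - p`` (conditioning on
  the remaining ``p - 2`` variables); edges with two-sided p >= alpha are
  set to zero, with no multiplicity correction.  This is the fallback used
  when the regularized path fails on a small subsample.

Strength centrality (the sum of absolute incident edge weights) and a
seeded Fruchterman-Reingold layout complete the module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .cohort import NO_PROFILE, ResponseMatrix
from .exceptions import (
    DegenerateItemError,
    EstimationError,
    InvalidArgumentError,
    TooSmallSampleError,
)
from .profiles import ProfileCatalog

logger = logging.getLogger(__name__)

#: Entries of an estimated precision below this magnitude count as exact zeros.
ZERO_TOL = 1e-10

#: Default seed for stochastic steps (layout jitter).
DEFAULT_SEED = 1


@dataclass(frozen=True)
class GGMConfig:
    """Estimation settings for a per-profile network.

    Parameters
    ----------
    gamma
        EBIC hyperparameter; 0.5 is the conventional conservative choice.
    lambda_min_ratio
        Smallest penalty as a fraction of ``lambda_max`` (default 0.01).
    n_lambda
        Number of log-spaced penalties on the path (default 100).
    method
        ``"ebic_glasso"`` or ``"nonreg_threshold"``.
    alpha
        Two-sided significance level for the non-regularized edge test.
    min_variance
        Numeric floor below which an item is treated as constant.
    """

    gamma: float = 0.5
    lambda_min_ratio: float = 0.01
    n_lambda: int = 100
    method: str = "ebic_glasso"
    alpha: float = 0.05
    min_variance: float = 1e-10

    def __post_init__(self) -> None:
        if not 0 < self.lambda_min_ratio < 1:
            raise InvalidArgumentError("lambda_min_ratio must be in (0, 1)")
        if self.n_lambda < 2:
            raise InvalidArgumentError("n_lambda must be >= 2")
        if not 0 < self.alpha <= 1:
            raise InvalidArgumentError("alpha must be in (0, 1]")
        if self.gamma < 0:
            raise InvalidArgumentError("gamma must be >= 0")
        if self.method not in ("ebic_glasso", "nonreg_threshold"):
            raise InvalidArgumentError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class NetworkModel:
    """A symmetric partial-correlation network over retained items.

    ``pcor`` has an exactly-zero diagonal; zero off-diagonal entries encode
    conditional independence.  ``dropped_items`` records instrument items
    absent from the profile (constant 0 in the subsample), which cannot
    enter a Gaussian model.
    """

    items: tuple[str, ...]
    pcor: np.ndarray
    method: str
    n: int
    lambda_: float | None = None
    alpha: float | None = None
    ebic: float | None = None
    dropped_items: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pcor = np.asarray(self.pcor, dtype=float)
        p = len(self.items)
        if pcor.shape != (p, p):
            raise InvalidArgumentError("pcor dimension must match items")
        if not np.allclose(pcor, pcor.T, atol=1e-8):
            raise InvalidArgumentError("pcor must be symmetric")
        if np.any(np.abs(pcor) > 1 + 1e-8):
            raise InvalidArgumentError("partial correlations must lie in [-1, 1]")
        if np.any(np.diag(pcor) != 0):
            raise InvalidArgumentError("pcor diagonal must be exactly zero")
        object.__setattr__(self, "pcor", pcor)

    @property
    def p(self) -> int:
        return len(self.items)

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.count_nonzero(self.pcor[iu]))

    def edge_list(self) -> pd.DataFrame:
        """Nonzero edges as (item_a, item_b, pcor), upper triangle."""
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.pcor[i, j]
                if w != 0:
                    rows.append((self.items[i], self.items[j], float(w)))
        return pd.DataFrame(rows, columns=["item_a", "item_b", "pcor"])

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.items)
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = float(self.pcor[i, j])
                if w != 0:
                    g.add_edge(self.items[i], self.items[j], weight=w)
        return g

    def pcor_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pcor, index=list(self.items), columns=list(self.items))


@dataclass(frozen=True)
class PathPoint:
    """One solution along the graphical-lasso penalty path.

    ``precision`` is the constrained-ML refit of the penalty point's
    sparsity pattern; ``ebic`` is evaluated at that refit.
    """

    lambda_: float
    precision: np.ndarray
    ebic: float
    n_edges: int


def constrained_mle(
    S: np.ndarray,
    support: Sequence[tuple[int, int]],
    tol: float = 1e-8,
    max_iter: int = 500,
) -> np.ndarray:
    """Gaussian MLE of the precision matrix under zero constraints.

    Fits the graphical model whose only allowed off-diagonal nonzeros are
    the (i, j) pairs in ``support``, by iterative proportional fitting over
    the maximal cliques of the support graph: each sweep resets the model
    covariance on a clique to the sample covariance there, leaving the
    off-support precision entries exactly zero.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(p))
    g.add_edges_from(support)
    cliques = [list(sorted(c)) for c in nx.find_cliques(g)]
    K = np.diag(1.0 / np.diag(S))
    for _ in range(max_iter):
        delta = 0.0
        for C in cliques:
            sigma = np.linalg.inv(K)
            block = sigma[np.ix_(C, C)]
            delta = max(delta, float(np.abs(block - S[np.ix_(C, C)]).max()))
            K[np.ix_(C, C)] += np.linalg.inv(S[np.ix_(C, C)]) - np.linalg.inv(block)
        if delta < tol:
            break
    else:
        warnings.warn("constrained MLE: IPF did not reach tolerance", stacklevel=2)
    return (K + K.T) / 2.0


def subsample_for_profile(
    responses: ResponseMatrix,
    profile_id: int,
    catalog: ProfileCatalog | None = None,
    min_members: int = 10,
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Continuous item scores of one profile's members, present items only.

    Returns the subsample as a DataFrame (columns = present-item labels)
    together with the labels of the dropped (absent, constant-zero) items.
    Refuses profiles with fewer than ``min_members`` members.
    """
    if not responses.matched:
        raise InvalidArgumentError("responses must be matched before subsampling")
    members = np.flatnonzero(responses.profile_ids == profile_id)
    if profile_id == NO_PROFILE or members.size == 0:
        raise InvalidArgumentError(f"no respondents matched to profile {profile_id}")
    if members.size < min_members:
        raise TooSmallSampleError(
            f"profile {profile_id} has {members.size} members, below the "
            f"estimation floor of {min_members}"
        )
    if members.size < 100:
        warnings.warn(
            f"profile {profile_id}: only {members.size} members; network "
            "estimates will be unstable at this sample size",
            stacklevel=2,
        )
    if catalog is not None:
        presence = np.asarray(catalog.profile(profile_id).presence, dtype=bool)
    else:
        presence = responses.scores[members[0]] >= 1
    present_cols = [lab for lab, p in zip(responses.item_labels, presence) if p]
    dropped = tuple(lab for lab, p in zip(responses.item_labels, presence) if not p)
    data = pd.DataFrame(
        responses.scores[np.ix_(members, np.flatnonzero(presence))],
        columns=present_cols,
    )
    if dropped:
        logger.info(
            "profile %d: dropped absent items %s", profile_id, ", ".join(dropped)
        )
    return data, dropped


def _as_matrix(data: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), tuple(str(c) for c in data.columns)
    arr = np.asarray(data, dtype=float)
    return arr, tuple(f"item{i + 1}" for i in range(arr.shape[1]))


def sample_correlation(
    data: pd.DataFrame | np.ndarray, min_variance: float = 1e-10
) -> np.ndarray:
    """Pearson correlation matrix of the columns (listwise-complete data).

    Raises :class:`DegenerateItemError` naming the first column whose
    variance is at or below ``min_variance``.
    """
    X, labels = _as_matrix(data)
    if X.ndim != 2 or X.shape[1] < 2:
        raise InvalidArgumentError("need at least 2 item columns")
    variances = X.var(axis=0)
    low = np.flatnonzero(variances <= min_variance)
    if low.size:
        raise DegenerateItemError(
            f"item {labels[low[0]]!r} is constant (variance "
            f"{variances[low[0]]:.3g}); drop it before estimation"
        )
    S = np.corrcoef(X, rowvar=False)
    return (S + S.T) / 2.0


def glasso_path(
    S: np.ndarray, n: int, config: GGMConfig | None = None
) -> list[PathPoint]:
    """Graphical-lasso solutions along a log-spaced penalty path.

    The path runs from ``lambda_max`` (largest absolute off-diagonal of
    ``S``; fully shrunk, diagonal solution) down to
    ``lambda_min_ratio * lambda_max`` in ``n_lambda`` log-spaced steps, each
    solve warm-started from its predecessor.  Penalty points where the
    solver fails numerically are flagged and skipped with a warning.
    """
    config = config or GGMConfig()
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p):
        raise InvalidArgumentError("S must be square")
    if n < p + 1:
        raise TooSmallSampleError(f"need n >= p + 1 (= {p + 1}), got n={n}")
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = max(float(off.max()), 1e-8)
    lams = np.logspace(
        np.log10(lam_max), np.log10(config.lambda_min_ratio * lam_max), config.n_lambda
    )
    path: list[PathPoint] = []
    n_failed = 0
    iu = np.triu_indices(p, k=1)
    refit_cache: dict[frozenset, tuple[np.ndarray, float]] = {}
    for lam in lams:
        try:
            with warnings.catch_warnings():
                # Loose dual gaps at tiny penalties are numerically benign;
                # hard failures are caught below.
                warnings.simplefilter("ignore", ConvergenceWarning)
                _, K_pen = graphical_lasso(S, alpha=float(lam), max_iter=200)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError):
            n_failed += 1
            continue
        if not np.all(np.isfinite(K_pen)):
            n_failed += 1
            continue
        support = frozenset(
            (int(i), int(j))
            for i, j in zip(*iu)
            if abs(K_pen[i, j]) > ZERO_TOL
        )
        if support in refit_cache:
            K, ebic = refit_cache[support]
        else:
            K = constrained_mle(S, sorted(support))
            sign, logdet = np.linalg.slogdet(K)
            if sign <= 0:
                n_failed += 1
                continue
            E = len(support)
            ll = (n / 2.0) * (logdet - float(np.sum(S * K)))
            ebic = -2.0 * ll + E * np.log(n) + 4.0 * E * config.gamma * np.log(p)
            refit_cache[support] = (K, float(ebic))
        path.append(
            PathPoint(
                lambda_=float(lam), precision=K, ebic=float(ebic),
                n_edges=len(support),
            )
        )
    if n_failed:
        warnings.warn(
            f"glasso path: {n_failed} of {config.n_lambda} penalty points "
            "failed to converge and were skipped",
            stacklevel=2,
        )
    if not path:
        raise EstimationError(
            "graphical lasso failed at every penalty; consider the "
            "non-regularized (significance-threshold) method"
        )
    return path


def precision_to_pcor(K: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix; exact zeros preserved."""
    K = np.asarray(K, dtype=float)
    d = np.sqrt(np.diag(K))
    pcor = -K / np.outer(d, d)
    pcor[np.abs(K) <= ZERO_TOL] = 0.0
    np.fill_diagonal(pcor, 0.0)
    pcor = np.clip((pcor + pcor.T) / 2.0, -1.0, 1.0)
    return pcor


def select_ebic(
    path: Sequence[PathPoint],
    items: Sequence[str] | None = None,
    n: int = 0,
    dropped_items: tuple[str, ...] = (),
) -> NetworkModel:
    """Pick the minimum-EBIC path point (ties -> larger penalty, i.e.
    sparser) and convert its precision to a partial-correlation network."""
    if not path:
        raise InvalidArgumentError("empty path")
    best = None
    for point in sorted(path, key=lambda q: -q.lambda_):
        if best is None or point.ebic < best.ebic - 1e-12:
            best = point
    p = best.precision.shape[0]
    labels = tuple(items) if items is not None else tuple(f"item{i+1}" for i in range(p))
    return NetworkModel(
        items=labels,
        pcor=precision_to_pcor(best.precision),
        method="ebic_glasso",
        n=int(n),
        lambda_=best.lambda_,
        ebic=best.ebic,
        dropped_items=dropped_items,
    )


def nonreg_network(
    data: pd.DataFrame | np.ndarray,
    config: GGMConfig | None = None,
    dropped_items: tuple[str, ...] = (),
) -> NetworkModel:
    """Non-regularized network: full partial correlations thresholded by a
    two-sided Fisher-z significance test at level ``alpha``.

    The z-statistic for an edge is ``atanh(r) * sqrt(n - p - 1)``, the
    Fisher transform at effective degrees of freedom ``n - p``
    (equivalently ``n - 2 - (p - 2)``: two focal variables plus ``p - 2``
    conditioning variables).  No multiplicity correction is applied.
    """
    config = config or GGMConfig(method="nonreg_threshold")
    X, labels = _as_matrix(data)
    n, p = X.shape
    if n <= p + 2:
        raise TooSmallSampleError(
            f"non-regularized estimation needs n > p + 2 (p={p}), got n={n}"
        )
    S = sample_correlation(X, config.min_variance)
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e12:
        raise EstimationError(
            "correlation matrix is (near-)singular; use the regularized "
            "(ebic_glasso) method"
        )
    K = np.linalg.inv(S)
    pcor = precision_to_pcor(K)
    df_eff = n - p  # n - 2 - (p - 2)
    z = np.arctanh(np.clip(pcor, -1 + 1e-12, 1 - 1e-12))
    stat = np.abs(z) * np.sqrt(df_eff - 1)
    pvals = 2.0 * stats.norm.sf(stat)
    if config.alpha < 1:
        pcor = np.where(pvals < config.alpha, pcor, 0.0)
    np.fill_diagonal(pcor, 0.0)
    return NetworkModel(
        items=labels,
        pcor=pcor,
        method="nonreg_threshold",
        n=n,
        alpha=config.alpha,
        dropped_items=dropped_items,
    )


def estimate_network(
    data: pd.DataFrame | np.ndarray,
    config: GGMConfig | None = None,
    dropped_items: tuple[str, ...] = (),
) -> NetworkModel:
    """Estimate a network with the method named in ``config``."""
    config = config or GGMConfig()
    if config.method == "nonreg_threshold":
        return nonreg_network(data, config, dropped_items)
    X, labels = _as_matrix(data)
    S = sample_correlation(X, config.min_variance)
    path = glasso_path(S, X.shape[0], config)
    return select_ebic(path, items=labels, n=X.shape[0], dropped_items=dropped_items)


@dataclass
class CentralityTable:
    """Per-item strength centrality with standardized values and ranks."""

    table: pd.DataFrame
    standardized_defined: bool = True

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def strength_centrality(network: NetworkModel) -> CentralityTable:
    """Strength centrality: per item, the sum of absolute incident edge
    weights; the z-scored version is standardized across items.  Rank 1 is
    the highest strength, ties broken by item order."""
    if network.p < 2:
        raise InvalidArgumentError("centrality needs at least 2 items")
    strength = np.abs(network.pcor).sum(axis=0)
    sd = strength.std()
    defined = sd > 0
    z = (strength - strength.mean()) / sd if defined else np.full_like(strength, np.nan)
    order = np.lexsort((np.arange(network.p), -strength))
    rank = np.empty(network.p, dtype=int)
    rank[order] = np.arange(1, network.p + 1)
    df = pd.DataFrame(
        {
            "item": list(network.items),
            "strength": strength,
            "z_strength": z,
            "rank": rank,
        }
    )
    return CentralityTable(table=df, standardized_defined=bool(defined))


def layout_fr(network: NetworkModel, seed: int = DEFAULT_SEED) -> pd.DataFrame:
    """Seeded Fruchterman-Reingold layout with |pcor| as attraction weights,
    rescaled to the unit square."""
    if network.p < 1:
        raise InvalidArgumentError("layout needs at least 1 item")
    if network.p == 1:
        return pd.DataFrame({"item": [network.items[0]], "x": [0.5], "y": [0.5]})
    g = nx.Graph()
    g.add_nodes_from(network.items)
    for i in range(network.p):
        for j in range(i + 1, network.p):
            w = abs(float(network.pcor[i, j]))
            if w > 0:
                g.add_edge(network.items[i], network.items[j], weight=w)
    pos = nx.spring_layout(g, seed=int(seed), weight="weight")
    coords = np.array([pos[item] for item in network.items], dtype=float)
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    span = hi - lo
    scaled = np.where(span > 0, (coords - lo) / np.where(span > 0, span, 1.0), 0.5)
    return pd.DataFrame(
        {"item": list(network.items), "x": scaled[:, 0], "y": scaled[:, 1]}
    )
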