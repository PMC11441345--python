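"""Synthetic questionnaire cohorts with known ground truth.

Respondents are drawn from a mixture of subpopulations.  Each subpopulation
plants (a) a symptom profile — items absent from the profile score exactly
0 — and (b) a partial-correlation network over the present items.  Present
items arise from a latent multivariate Gaussian with unit variances whose
precision matrix encodes the planted network; each latent value is cut by
strictly increasing thresholds into the ordinal scores ``1..max_item_score``
(never 0), so a generated respondent's dichotomized pattern equals the
planted profile *exactly, by construction*.  This separates
profile-identification tests from network-estimation tests.

Default thresholds are the standard-normal tertile cut points (equal 1/3
mass on scores 1, 2 and 3); skewed items (e.g. rare suicidal ideation) can
be emulated by supplying other cut points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import ResponseMatrix
from .exceptions import InvalidArgumentError, SpecError
from .ggm import GGMConfig, NetworkModel, estimate_network, precision_to_pcor
from .profiles import SymptomProfile

from scipy import stats

#: Standard-normal tertile cut points: 1/3 mass per ordinal bin.
TERTILE_THRESHOLDS = tuple(float(stats.norm.ppf(q)) for q in (1 / 3, 2 / 3))


def pcor_to_precision(pcor: np.ndarray) -> np.ndarray:
    """Precision matrix with unit diagonal encoding the given partial
    correlations: ``K_ii = 1``, ``K_ij = -pcor_ij``.

    Raises :class:`SpecError` when the result is not positive definite
    (the planted network does not correspond to any Gaussian model).
    """
    pcor = np.asarray(pcor, dtype=float)
    p = pcor.shape[0]
    if pcor.shape != (p, p) or not np.allclose(pcor, pcor.T, atol=1e-10):
        raise InvalidArgumentError("pcor must be a symmetric square matrix")
    K = -pcor.copy()
    np.fill_diagonal(K, 1.0)
    try:
        np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        raise SpecError(
            "planted partial correlations imply a non-positive-definite "
            "precision matrix; reduce the edge weights"
        ) from None
    return K


def _covariance_from_pcor(pcor: np.ndarray) -> np.ndarray:
    """Latent correlation matrix implied by a planted pcor network.

    The inverse precision is rescaled to unit variances; partial
    correlations are invariant under this diagonal rescaling, so the
    planted network is preserved on the latent correlation scale.
    """
    K = pcor_to_precision(pcor)
    sigma = np.linalg.inv(K)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


@dataclass(frozen=True)
class Subpopulation:
    """One mixture component: planted profile, weight, network, thresholds.

    ``thresholds`` holds ``max_item_score - 1`` strictly increasing latent
    cut points, either shared across present items (1-D) or per present
    item (2-D, one row per present item).
    """

    profile: SymptomProfile
    weight: float
    pcor: np.ndarray
    thresholds: np.ndarray = field(
        default_factory=lambda: np.asarray(TERTILE_THRESHOLDS)
    )

    def __post_init__(self) -> None:
        m = self.profile.n_present
        pcor = np.asarray(self.pcor, dtype=float)
        if pcor.shape != (m, m):
            raise SpecError(
                f"pcor must be {m}x{m} (profile has {m} present items), "
                f"got {pcor.shape}"
            )
        pcor_to_precision(pcor)  # validates positive definiteness
        object.__setattr__(self, "pcor", pcor)
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.ndim == 1:
            thr = np.tile(thr, (m, 1))
        if thr.shape[0] != m:
            raise SpecError("need one threshold row per present item")
        if not np.all(np.diff(thr, axis=1) > 0):
            raise SpecError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", thr)
        if self.weight <= 0:
            raise SpecError("mixing weights must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """A full synthetic-cohort specification."""

    n_respondents: int
    subpopulations: tuple[Subpopulation, ...]
    k: int = 9
    max_item_score: int = 3
    threshold: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        subs = tuple(self.subpopulations)
        if not subs:
            raise SpecError("need at least one subpopulation")
        for sub in subs:
            if sub.profile.k != self.k:
                raise SpecError("every planted profile must have k items")
            if sub.thresholds.shape[1] != self.max_item_score - 1:
                raise SpecError(
                    f"need {self.max_item_score - 1} thresholds per item"
                )
        total = sum(s.weight for s in subs)
        if abs(total - 1.0) > 1e-8:
            raise SpecError(f"mixing weights must sum to 1, got {total}")
        object.__setattr__(self, "subpopulations", subs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        """Load a spec from YAML: top-level n, seed, and a list of
        subpopulations with pattern, weight, edges [[i, j, pcor], ...]
        (1-based indices into the *present* items) and optional thresholds."""
        raw = yaml.safe_load(Path(path).read_text())
        subs = []
        for entry in raw["subpopulations"]:
            profile = SymptomProfile.from_pattern(str(entry["pattern"]))
            m = profile.n_present
            pcor = np.zeros((m, m))
            for i, j, w in entry.get("edges", []):
                pcor[i - 1, j - 1] = pcor[j - 1, i - 1] = float(w)
            thr = np.asarray(
                entry.get("thresholds", TERTILE_THRESHOLDS), dtype=float
            )
            subs.append(
                Subpopulation(
                    profile=profile, weight=float(entry["weight"]),
                    pcor=pcor, thresholds=thr,
                )
            )
        return cls(
            n_respondents=int(raw["n_respondents"]),
            subpopulations=tuple(subs),
            k=int(raw.get("k", 9)),
            max_item_score=int(raw.get("max_item_score", 3)),
            threshold=int(raw.get("threshold", 10)),
            seed=int(raw.get("seed", 0)),
        )


def _discretize(latent: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Map latent normals through per-item cut points into 1..max_score."""
    scores = np.empty_like(latent, dtype=np.int64)
    for j in range(latent.shape[1]):
        scores[:, j] = np.searchsorted(thresholds[j], latent[:, j]) + 1
    return scores


def sample_cohort(spec: SyntheticSpec) -> ResponseMatrix:
    """Generate a cohort; deterministic given ``spec.seed``.

    Present items never score 0, so every respondent's dichotomized pattern
    equals their subpopulation's planted profile.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_respondents
    weights = np.array([s.weight for s in spec.subpopulations])
    assignment = rng.choice(len(weights), size=n, p=weights)
    scores = np.zeros((n, spec.k), dtype=np.int64)
    for s_idx, sub in enumerate(spec.subpopulations):
        rows = np.flatnonzero(assignment == s_idx)
        if rows.size == 0:
            continue
        sigma = _covariance_from_pcor(sub.pcor)
        chol = np.linalg.cholesky(sigma)
        latent = rng.standard_normal((rows.size, sub.profile.n_present)) @ chol.T
        sub_scores = _discretize(latent, sub.thresholds)
        present = [i - 1 for i in sub.profile.items_present()]
        scores[np.ix_(rows, present)] = sub_scores
    ids = tuple(f"s{i + 1:05d}" for i in range(n))
    labels = tuple(f"phq{i + 1}" for i in range(spec.k))
    return ResponseMatrix(
        scores=scores,
        respondent_ids=ids,
        item_labels=labels,
        max_item_score=spec.max_item_score,
        threshold=spec.threshold,
    )


def truth_table(spec: SyntheticSpec) -> pd.DataFrame:
    """Ground-truth edge list for scoring: one row per planted nonzero edge
    (subpopulation, 1-based instrument item indices, pcor)."""
    rows = []
    for s_idx, sub in enumerate(spec.subpopulations):
        present = sub.profile.items_present()
        m = len(present)
        for i in range(m):
            for j in range(i + 1, m):
                w = float(sub.pcor[i, j])
                if w != 0:
                    rows.append(
                        {
                            "subpopulation": s_idx,
                            "pattern": sub.profile.pattern,
                            "item_a": present[i],
                            "item_b": present[j],
                            "pcor": w,
                        }
                    )
    return pd.DataFrame(rows, columns=["subpopulation", "pattern", "item_a", "item_b", "pcor"])


def random_network(
    p: int,
    n_edges: int,
    weight_range: tuple[float, float] = (0.25, 0.35),
    rng: np.random.Generator | int | None = None,
    max_tries: int = 200,
) -> np.ndarray:
    """A random sparse pcor ground truth: ``n_edges`` distinct edges with
    weights drawn uniformly from ``weight_range``, rejection-sampled until
    the implied precision matrix is positive definite."""
    rng = np.random.default_rng(rng)
    n_pairs = p * (p - 1) // 2
    if n_edges > n_pairs:
        raise InvalidArgumentError(f"at most {n_pairs} edges for p={p}")
    iu = np.triu_indices(p, k=1)
    for _ in range(max_tries):
        pcor = np.zeros((p, p))
        chosen = rng.choice(n_pairs, size=n_edges, replace=False)
        w = rng.uniform(*weight_range, size=n_edges)
        pcor[iu[0][chosen], iu[1][chosen]] = w
        pcor = pcor + pcor.T
        K = -pcor.copy()
        np.fill_diagonal(K, 1.0)
        if np.linalg.eigvalsh(K).min() > 1e-3:
            return pcor
    raise SpecError(
        f"could not find a positive definite network with {n_edges} edges "
        f"of weight {weight_range} in {max_tries} tries"
    )


@dataclass
class RecoveryResult:
    """Outcome of a parameter-recovery experiment on planted ground truth."""

    edge_correlation: float
    sensitivity: float
    specificity: float
    n_true_edges: int
    n_estimated_edges: int
    network: NetworkModel


def recovery_experiment(
    spec: SyntheticSpec, config: GGMConfig | None = None
) -> RecoveryResult:
    """Generate a single-subpopulation cohort, estimate its network, and
    score recovery of the planted edges.

    Reports the Pearson correlation between true and estimated
    upper-triangle edge weights, plus sensitivity (planted edges estimated
    nonzero) and specificity (true zeros estimated exactly zero).
    """
    if len(spec.subpopulations) != 1:
        raise InvalidArgumentError("recovery_experiment needs a single subpopulation")
    config = config or GGMConfig()
    sub = spec.subpopulations[0]
    rm = sample_cohort(spec)
    present = [i - 1 for i in sub.profile.items_present()]
    data = pd.DataFrame(
        rm.scores[:, present],
        columns=[rm.item_labels[i] for i in present],
    )
    net = estimate_network(data, config)
    iu = np.triu_indices(sub.profile.n_present, k=1)
    true_w = sub.pcor[iu]
    est_w = net.pcor[iu]
    true_nz = true_w != 0
    est_nz = est_w != 0
    if true_w.std() > 0 and est_w.std() > 0:
        corr = float(np.corrcoef(true_w, est_w)[0, 1])
    else:
        corr = float("nan")
    sens = float(np.mean(est_nz[true_nz])) if true_nz.any() else float("nan")
    spec_ = float(np.mean(~est_nz[~true_nz])) if (~true_nz).any() else float("nan")
    return RecoveryResult(
        edge_correlation=corr,
        sensitivity=sens,
        specificity=spec_,
        n_true_edges=int(true_nz.sum()),
        n_estimated_edges=int(est_nz.sum()),
        network=net,
    )
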