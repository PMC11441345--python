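"""Bootstrap diagnostics: edge-weight accuracy and centrality stability.

Two procedures, both re-running the configured network estimator:

* nonparametric bootstrap — ``n_boot`` row resamples with replacement, each
  re-estimated; per-edge mean and 2.5/97.5 percentile intervals quantify
  edge-weight accuracy.
* case-dropping subset bootstrap — for each drop proportion, ``n_boot`` row
  subsamples without replacement of size ``round((1 - proportion) * n)``;
  the Pearson correlation between each subsample's strength-centrality
  vector and the full-sample vector is recorded.  The correlation-stability
  (CS) coefficient is the largest proportion at which at least
  ``cs_probability`` of the resamples reach ``cs_correlation``; centrality
  is conventionally considered interpretable when CS exceeds 0.25.

Resamples where estimation fails (e.g. a constant column after resampling)
are dropped from the distribution and counted, so the choice is auditable.
Correlations are computed on raw (non-standardized) strengths: per-vector
standardization is an affine map and leaves Pearson correlation unchanged,
while raw values avoid zero-variance corner cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, StabilityError, SymptomNetError
from .ggm import GGMConfig, NetworkModel, estimate_network, strength_centrality

DEFAULT_DROP_PROPORTIONS = tuple(round(0.05 * i, 2) for i in range(1, 16))


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling settings for the stability diagnostics."""

    n_boot: int = 1000
    drop_proportions: tuple[float, ...] = DEFAULT_DROP_PROPORTIONS
    cs_correlation: float = 0.7
    cs_probability: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise InvalidArgumentError("n_boot must be >= 1")
        if not all(0 < q < 1 for q in self.drop_proportions):
            raise InvalidArgumentError("drop proportions must lie in (0, 1)")
        if not 0 < self.cs_correlation < 1:
            raise InvalidArgumentError("cs_correlation must be in (0, 1)")
        if not 0 < self.cs_probability <= 1:
            raise InvalidArgumentError("cs_probability must be in (0, 1]")


@dataclass
class EdgeAccuracy:
    """Per-edge bootstrap summaries (upper-triangle order)."""

    items: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    sample: np.ndarray       # observed edge weights
    boot_mean: np.ndarray
    lower: np.ndarray        # 2.5 percentile
    upper: np.ndarray        # 97.5 percentile
    n_boot: int
    n_failed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_a": [a for a, _ in self.edges],
                "item_b": [b for _, b in self.edges],
                "pcor": self.sample,
                "boot_mean": self.boot_mean,
                "ci_lower": self.lower,
                "ci_upper": self.upper,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class StabilityReport:
    """Combined stability diagnostics for one network.

    ``cs_coefficient`` is None when every drop proportion was unusable
    (too-small subsamples or universal estimation failure); otherwise it is
    a member of the tested grid or 0.0.
    """

    cs_coefficient: float | None
    interpretable: bool
    cs_correlation: float
    cs_probability: float
    by_proportion: pd.DataFrame
    edge_accuracy: EdgeAccuracy | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "cs_coefficient": self.cs_coefficient,
            "interpretable": self.interpretable,
            "cs_correlation": self.cs_correlation,
            "cs_probability": self.cs_probability,
            "by_proportion": self.by_proportion.to_dict(orient="records"),
            "diagnostics": self.diagnostics,
        }
        if self.edge_accuracy is not None:
            out["edge_accuracy"] = self.edge_accuracy.to_frame().to_dict(
                orient="records"
            )
            out["edge_accuracy_n_failed"] = self.edge_accuracy.n_failed
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))


FitFn = Callable[[pd.DataFrame | np.ndarray, GGMConfig], NetworkModel]


def _default_fit(data, config: GGMConfig) -> NetworkModel:
    return estimate_network(data, config)


def edge_accuracy(
    data: pd.DataFrame | np.ndarray,
    config: GGMConfig | None = None,
    boot: BootstrapConfig | None = None,
    fit_fn: FitFn = _default_fit,
) -> EdgeAccuracy:
    """Nonparametric bootstrap of the edge weights.

    Draws ``n_boot`` size-``n`` row resamples with replacement, re-estimates
    the network on each with the same configuration, and reports the
    per-edge bootstrap mean and 2.5/97.5 percentile interval.  More than
    50% failed resamples raises :class:`StabilityError`.

    ``fit_fn`` is an extension hook (used e.g. to study alternative
    estimators); the default re-runs :func:`~symptomnet.ggm.estimate_network`.
    """
    config = config or GGMConfig()
    boot = boot or BootstrapConfig()
    frame = data if isinstance(data, pd.DataFrame) else pd.DataFrame(np.asarray(data))
    full = fit_fn(frame, config)
    p = full.p
    iu = np.triu_indices(p, k=1)
    edges = tuple(
        (full.items[i], full.items[j]) for i, j in zip(*iu)
    )
    rng = np.random.default_rng(boot.seed)
    n = len(frame)
    draws = []
    n_failed = 0
    for _ in range(boot.n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            net = fit_fn(frame.iloc[idx].reset_index(drop=True), config)
        except SymptomNetError:
            n_failed += 1
            continue
        draws.append(net.pcor[iu])
    if n_failed > boot.n_boot / 2:
        raise StabilityError(
            f"{n_failed}/{boot.n_boot} bootstrap re-estimations failed"
        )
    stack = np.vstack(draws)
    return EdgeAccuracy(
        items=full.items,
        edges=edges,
        sample=full.pcor[iu],
        boot_mean=stack.mean(axis=0),
        lower=np.percentile(stack, 2.5, axis=0),
        upper=np.percentile(stack, 97.5, axis=0),
        n_boot=boot.n_boot,
        n_failed=n_failed,
    )


def cs_coefficient(
    data: pd.DataFrame | np.ndarray,
    config: GGMConfig | None = None,
    boot: BootstrapConfig | None = None,
    min_members: int = 10,
    fit_fn: FitFn = _default_fit,
) -> StabilityReport:
    """Case-dropping subset bootstrap and the CS coefficient.

    For each drop proportion the strength vector of every subsample is
    correlated (Pearson, raw strengths) with the full-sample strength
    vector.  CS is the largest proportion whose correlation distribution
    has at least ``cs_probability`` mass at or above ``cs_correlation``
    (0.0 if none qualifies; None if no proportion was usable at all).
    """
    config = config or GGMConfig()
    boot = boot or BootstrapConfig()
    frame = data if isinstance(data, pd.DataFrame) else pd.DataFrame(np.asarray(data))
    n = len(frame)
    full = fit_fn(frame, config)
    s_full = strength_centrality(full).table["strength"].to_numpy()
    rng = np.random.default_rng(boot.seed)
    rows = []
    for prop in sorted(boot.drop_proportions):
        n_sub = int(round((1.0 - prop) * n))
        if n_sub < max(min_members, 3):
            rows.append(
                {"proportion": prop, "n_sub": n_sub, "usable": False,
                 "n_failed": boot.n_boot, "prob_at_threshold": np.nan,
                 "corr_mean": np.nan, "corr_q05": np.nan, "corr_q50": np.nan,
                 "corr_q95": np.nan}
            )
            continue
        corrs = []
        n_failed = 0
        for _ in range(boot.n_boot):
            idx = rng.choice(n, size=n_sub, replace=False)
            try:
                net = fit_fn(frame.iloc[idx].reset_index(drop=True), config)
            except SymptomNetError:
                n_failed += 1
                continue
            s_sub = strength_centrality(net).table["strength"].to_numpy()
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(s_full, s_sub)[0, 1]
            if np.isnan(r):
                n_failed += 1
                continue
            corrs.append(r)
        corrs = np.asarray(corrs)
        usable = corrs.size > 0
        prob = float(np.mean(corrs >= boot.cs_correlation)) if usable else np.nan
        rows.append(
            {
                "proportion": prop,
                "n_sub": n_sub,
                "usable": usable,
                "n_failed": n_failed,
                "prob_at_threshold": prob,
                "corr_mean": float(corrs.mean()) if usable else np.nan,
                "corr_q05": float(np.percentile(corrs, 5)) if usable else np.nan,
                "corr_q50": float(np.percentile(corrs, 50)) if usable else np.nan,
                "corr_q95": float(np.percentile(corrs, 95)) if usable else np.nan,
            }
        )
    by_prop = pd.DataFrame(rows)
    usable_mask = by_prop["usable"].to_numpy(dtype=bool)
    if not usable_mask.any():
        return StabilityReport(
            cs_coefficient=None,
            interpretable=False,
            cs_correlation=boot.cs_correlation,
            cs_probability=boot.cs_probability,
            by_proportion=by_prop,
            diagnostics={"reason": "no usable drop proportion", "n": n},
        )
    qualifying = by_prop.loc[
        usable_mask & (by_prop["prob_at_threshold"] >= boot.cs_probability),
        "proportion",
    ]
    cs = float(qualifying.max()) if len(qualifying) else 0.0
    return StabilityReport(
        cs_coefficient=cs,
        interpretable=cs > 0.25,
        cs_correlation=boot.cs_correlation,
        cs_probability=boot.cs_probability,
        by_proportion=by_prop,
        diagnostics={"n": n, "method": config.method},
    )


def stability_report(
    data: pd.DataFrame | np.ndarray,
    config: GGMConfig | None = None,
    boot: BootstrapConfig | None = None,
    min_members: int = 10,
) -> StabilityReport:
    """Edge accuracy plus CS coefficient in one combined report."""
    acc = edge_accuracy(data, config, boot)
    report = cs_coefficient(data, config, boot, min_members=min_members)
    report.edge_accuracy = acc
    return report
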