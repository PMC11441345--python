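"""Model/Results front-end for per-profile symptom networks.

:class:`SymptomNetwork` is built from an item-score table (or directly from
a matched cohort via :meth:`SymptomNetwork.from_cohort`); :meth:`fit`
returns a :class:`NetworkResults` carrying the selected partial-correlation
matrix, estimation metadata, a text ``summary()``, centrality, layout, and
bootstrap diagnostics.

Example
-------
>>> from symptomnet import SymptomNetwork
>>> model = SymptomNetwork(scores_df, method="ebic_glasso")
>>> res = model.fit()
>>> print(res.summary())
>>> res.strength().table
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import ResponseMatrix
from .exceptions import InvalidArgumentError
from .ggm import (
    DEFAULT_SEED,
    CentralityTable,
    GGMConfig,
    NetworkModel,
    estimate_network,
    layout_fr,
    strength_centrality,
    subsample_for_profile,
)
from .profiles import ProfileCatalog
from .stability import (
    BootstrapConfig,
    EdgeAccuracy,
    StabilityReport,
    cs_coefficient,
    edge_accuracy,
)


class SymptomNetwork:
    """A Gaussian graphical model of one symptom profile's item scores.

    Parameters
    ----------
    data
        Respondent-by-item table of continuous (0-3) scores for the
        profile's present items; a DataFrame's column names become the
        node labels.
    method, config, **kwargs
        Either a full :class:`~symptomnet.ggm.GGMConfig`, or a method name
        with keyword overrides (``gamma=``, ``alpha=``, ...).
    """

    def __init__(
        self,
        data: pd.DataFrame | np.ndarray,
        config: GGMConfig | None = None,
        method: str | None = None,
        dropped_items: tuple[str, ...] = (),
        **kwargs,
    ) -> None:
        if config is not None and (method is not None or kwargs):
            raise InvalidArgumentError("pass either config or method/kwargs, not both")
        if config is None:
            config = GGMConfig(method=method or "ebic_glasso", **kwargs)
        self.data = (
            data if isinstance(data, pd.DataFrame) else pd.DataFrame(np.asarray(data))
        )
        self.config = config
        self.dropped_items = tuple(dropped_items)

    @classmethod
    def from_cohort(
        cls,
        responses: ResponseMatrix,
        profile_id: int,
        catalog: ProfileCatalog | None = None,
        min_members: int = 10,
        config: GGMConfig | None = None,
        **kwargs,
    ) -> "SymptomNetwork":
        """Build the model from one profile's subsample of a matched cohort;
        items absent from the profile are dropped and recorded."""
        data, dropped = subsample_for_profile(
            responses, profile_id, catalog=catalog, min_members=min_members
        )
        return cls(data, config=config, dropped_items=dropped, **kwargs)

    @property
    def nobs(self) -> int:
        return len(self.data)

    def fit(self) -> "NetworkResults":
        """Estimate the network under the configured method."""
        network = estimate_network(
            self.data, self.config, dropped_items=self.dropped_items
        )
        return NetworkResults(self, network)


class NetworkResults:
    """Fitted partial-correlation network with diagnostics.

    Attributes
    ----------
    network
        The underlying :class:`~symptomnet.ggm.NetworkModel`.
    pcor
        Labelled partial-correlation matrix (DataFrame).
    """

    def __init__(self, model: SymptomNetwork, network: NetworkModel) -> None:
        self.model = model
        self.network = network

    @property
    def pcor(self) -> pd.DataFrame:
        return self.network.pcor_frame()

    @property
    def nobs(self) -> int:
        return self.network.n

    @property
    def n_edges(self) -> int:
        return self.network.n_edges

    def edge_list(self) -> pd.DataFrame:
        return self.network.edge_list()

    def strength(self) -> CentralityTable:
        """Strength centrality (raw, standardized, rank) per item."""
        return strength_centrality(self.network)

    def layout(self, seed: int = DEFAULT_SEED) -> pd.DataFrame:
        """Seeded Fruchterman-Reingold node coordinates in the unit square."""
        return layout_fr(self.network, seed=seed)

    def bootstrap_edges(
        self, boot: BootstrapConfig | None = None, **kwargs
    ) -> EdgeAccuracy:
        """Nonparametric bootstrap intervals for the edge weights."""
        boot = boot or BootstrapConfig(**kwargs)
        return edge_accuracy(self.model.data, self.model.config, boot)

    def cs(self, boot: BootstrapConfig | None = None, **kwargs) -> StabilityReport:
        """Case-dropping bootstrap and the correlation-stability coefficient."""
        boot = boot or BootstrapConfig(**kwargs)
        return cs_coefficient(self.model.data, self.model.config, boot)

    def summary(self) -> str:
        """Human-readable estimation summary (statsmodels style)."""
        net = self.network
        p = net.p
        density = net.n_edges / (p * (p - 1) / 2) if p > 1 else 0.0
        lines = [
            "        Symptom Network Results",
            "=" * 46,
            f"Method:            {net.method}",
            f"No. observations:  {net.n}",
            f"No. items:         {p}",
            f"Edges (nonzero):   {net.n_edges}  (density {density:.2f})",
        ]
        if net.method == "ebic_glasso":
            lines.append(f"Selected lambda:   {net.lambda_:.4f}")
            lines.append(f"EBIC at selection: {net.ebic:.1f}")
        else:
            lines.append(f"Edge test alpha:   {net.alpha}")
        if net.dropped_items:
            lines.append(f"Dropped items:     {', '.join(net.dropped_items)}")
        lines.append("-" * 46)
        cent = self.strength().table.sort_values("rank")
        lines.append("Strength centrality (rank order):")
        for _, row in cent.iterrows():
            z = f"{row.z_strength:+.2f}" if np.isfinite(row.z_strength) else "  n/a"
            lines.append(
                f"  {int(row['rank']):>2}. {row['item']:<16} "
                f"strength {row.strength:.3f}  z {z}"
            )
        lines.append("=" * 46)
        return "\n".join(lines)

    def to_graphml(self, path: str | Path, seed: int = DEFAULT_SEED) -> None:
        """Write the network (with layout coordinates) as GraphML."""
        g = self.network.to_graph()
        pos = self.layout(seed=seed).set_index("item")
        for item in g.nodes:
            g.nodes[item]["x"] = float(pos.loc[item, "x"])
            g.nodes[item]["y"] = float(pos.loc[item, "y"])
        nx.write_graphml(g, path)

    def to_json(self, path: str | Path, seed: int = DEFAULT_SEED) -> None:
        """Write a node-link JSON artifact with layout coordinates."""
        g = self.network.to_graph()
        pos = self.layout(seed=seed).set_index("item")
        payload = {
            "method": self.network.method,
            "n": self.network.n,
            "lambda": self.network.lambda_,
            "alpha": self.network.alpha,
            "dropped_items": list(self.network.dropped_items),
            "nodes": [
                {
                    "id": item,
                    "x": float(pos.loc[item, "x"]),
                    "y": float(pos.loc[item, "y"]),
                }
                for item in self.network.items
            ],
            "links": [
                {"source": a, "target": b, "pcor": w}
                for a, b, w in self.network.edge_list().itertuples(index=False)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))
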