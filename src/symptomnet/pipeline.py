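"""End-to-end orchestration: enumerate -> match -> networks -> stability.

``run_pipeline`` executes the full analysis on a cohort file and writes all
artifacts (catalog, matched cohort, frequency and descriptive tables,
per-profile network exports, optional stability reports) plus a
machine-readable ``report.json`` and a markdown ``report.md``.

Per-profile estimation tries the regularized (EBIC-glasso) method first
and falls back to the non-regularized significance-threshold estimator when
the path fails to converge, logging the fallback — mirroring standard
practice for small profile subsamples.

Seeding: the global seed deterministically derives one sub-seed per
stochastic stage (simulation, layout, stability) via
``numpy.random.SeedSequence([global_seed, stage_code])``, so any stage can
be re-run in isolation with identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import (
    ColumnConfig,
    ProfileFrequencyTable,
    ResponseMatrix,
    frequency_table,
    load_responses,
    match_profiles,
)
from .exceptions import EstimationError, SymptomNetError, TooSmallSampleError
from .ggm import GGMConfig
from .model import SymptomNetwork
from .profiles import ProfileCatalog, ProfileRule, enumerate_catalog
from .stability import BootstrapConfig, stability_report

logger = logging.getLogger(__name__)

_STAGE_CODES = {"simulate": 0, "layout": 1, "stability": 2}


def stage_seed(global_seed: int, stage: str, extra: int = 0) -> int:
    """Deterministic per-stage sub-seed (< 2^31)."""
    code = _STAGE_CODES.get(stage, 99)
    ss = np.random.SeedSequence([int(global_seed), code, int(extra)])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    input: str | Path
    outdir: str | Path
    rule: ProfileRule = field(default_factory=ProfileRule)
    ggm: GGMConfig = field(default_factory=GGMConfig)
    boot: BootstrapConfig = field(default_factory=BootstrapConfig)
    columns: ColumnConfig = field(default_factory=ColumnConfig)
    selectors: tuple[int, ...] = (1, 2, 3)  # frequency ranks
    run_stability: bool = False
    min_members: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        rule = ProfileRule(**raw.get("rule", {}))
        ggm = GGMConfig(**raw.get("ggm", {}))
        boot = BootstrapConfig(**{
            k: tuple(v) if k == "drop_proportions" else v
            for k, v in raw.get("boot", {}).items()
        })
        cols = raw.get("columns", {})
        columns = ColumnConfig(
            item_columns=tuple(cols.get("item_columns", ColumnConfig().item_columns)),
            id_column=cols.get("id_column", "respondent_id"),
            covariate_columns=tuple(cols.get("covariate_columns", ())),
        )
        return cls(
            input=raw["input"],
            outdir=raw["outdir"],
            rule=rule,
            ggm=ggm,
            boot=boot,
            columns=columns,
            selectors=tuple(raw.get("selectors", (1, 2, 3))),
            run_stability=bool(raw.get("run_stability", False)),
            min_members=int(raw.get("min_members", 10)),
            seed=int(raw.get("seed", 0)),
        )

    def fingerprint(self) -> str:
        """Stable hash of the analysis configuration plus package version.

        File locations are excluded so the same analysis run in two
        directories fingerprints identically.
        """
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (frozenset, set)):
                return sorted(obj)
            if isinstance(obj, (np.ndarray,)):
                return obj.tolist()
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        payload = {
            "version": __version__,
            **{
                f.name: encode(getattr(self, f.name))
                for f in dataclasses.fields(self)
                if f.name not in ("input", "outdir")
            },
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ProfileArtifacts:
    """Index entry for one analyzed profile."""

    rank: int
    profile_id: int
    pattern: str
    n: int
    method: str
    fell_back: bool
    n_items: int
    directory: str
    cs_coefficient: float | None = None
    interpretable: bool | None = None
    top_strength: tuple[str, ...] = ()


@dataclass
class RunReport:
    """Stage counts, per-profile artifact index, and config fingerprint."""

    catalog_size: int
    rows_read: int
    rows_excluded_invalid: int
    n_included: int
    n_excluded_below_threshold: int
    n_profiles_observed: int
    coverage_top8: float
    profiles: list[ProfileArtifacts] = field(default_factory=list)
    fingerprint: str = ""
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "catalog_size": self.catalog_size,
            "rows_read": self.rows_read,
            "rows_excluded_invalid": self.rows_excluded_invalid,
            "n_included": self.n_included,
            "n_excluded_below_threshold": self.n_excluded_below_threshold,
            "n_profiles_observed": self.n_profiles_observed,
            "coverage_top8": self.coverage_top8,
            "profiles": [dataclasses.asdict(p) for p in self.profiles],
            "fingerprint": self.fingerprint,
            "warnings": self.warnings,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))


def _analyze_profile(
    config: RunConfig,
    matched: ResponseMatrix,
    catalog: ProfileCatalog,
    rank: int,
    profile_id: int,
    n_members: int,
    outdir: Path,
    report: RunReport,
) -> ProfileArtifacts:
    pattern = catalog.profile(profile_id).pattern
    pdir = outdir / f"profile_rank{rank:02d}_id{profile_id}"
    pdir.mkdir(parents=True, exist_ok=True)
    fell_back = False
    try:
        model = SymptomNetwork.from_cohort(
            matched, profile_id, catalog=catalog,
            min_members=config.min_members, config=config.ggm,
        )
        results = model.fit()
    except (EstimationError, np.linalg.LinAlgError) as exc:
        if config.ggm.method != "ebic_glasso":
            raise
        fell_back = True
        msg = f"profile {profile_id}: EBIC-glasso failed ({exc}); falling back to nonreg_threshold"
        logger.warning(msg)
        report.warnings.append(msg)
        fallback = dataclasses.replace(config.ggm, method="nonreg_threshold")
        model = SymptomNetwork.from_cohort(
            matched, profile_id, catalog=catalog,
            min_members=config.min_members, config=fallback,
        )
        results = model.fit()

    layout_seed = stage_seed(config.seed, "layout", profile_id)
    results.edge_list().to_csv(pdir / "edges.csv", index=False)
    results.strength().to_csv(pdir / "centrality.csv")
    results.to_json(pdir / "network.json", seed=layout_seed)
    results.to_graphml(pdir / "network.graphml", seed=layout_seed)
    (pdir / "summary.txt").write_text(results.summary() + "\n")

    art = ProfileArtifacts(
        rank=rank,
        profile_id=profile_id,
        pattern=pattern,
        n=n_members,
        method=results.network.method,
        fell_back=fell_back,
        n_items=results.network.p,
        directory=str(pdir),
        top_strength=tuple(
            results.strength().table.sort_values("rank")["item"].head(3)
        ),
    )
    if config.run_stability:
        boot = dataclasses.replace(
            config.boot, seed=stage_seed(config.seed, "stability", profile_id)
        )
        stab = stability_report(
            model.data, model.config, boot, min_members=config.min_members
        )
        stab.to_json(pdir / "stability.json")
        if stab.edge_accuracy is not None:
            stab.edge_accuracy.to_csv(pdir / "edge_intervals.csv")
        art.cs_coefficient = stab.cs_coefficient
        art.interpretable = stab.interpretable
    return art


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; returns (and writes) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    catalog = enumerate_catalog(config.rule)
    catalog.to_csv(outdir / "catalog.csv")

    responses = load_responses(
        config.input,
        config.columns,
        max_item_score=config.rule.max_item_score,
        threshold=config.rule.threshold,
    )
    matched = match_profiles(responses, catalog)
    matched.to_csv(outdir / "matched.csv")

    report = RunReport(
        catalog_size=len(catalog),
        rows_read=responses.n_respondents + responses.n_dropped_invalid,
        rows_excluded_invalid=responses.n_dropped_invalid,
        n_included=matched.n_included,
        n_excluded_below_threshold=responses.n_respondents - matched.n_included,
        n_profiles_observed=0,
        coverage_top8=0.0,
        fingerprint=config.fingerprint(),
    )

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        table = frequency_table(matched, catalog)
        for w in caught:
            report.warnings.append(str(w.message))
    table.to_csv(outdir / "frequency.csv")
    report.n_profiles_observed = table.n_profiles_observed
    if table.n_profiles_observed:
        report.coverage_top8 = table.coverage(min(8, table.n_profiles_observed))

    if matched.n_included == 0:
        msg = "no respondents at/above the inclusion threshold; network stage skipped"
        logger.warning(msg)
        report.warnings.append(msg)
    else:
        for rank in config.selectors:
            row = table.table[table.table["rank"] == rank]
            if row.empty:
                report.warnings.append(f"no observed profile at rank {rank}; skipped")
                continue
            pid = int(row["profile_id"].iloc[0])
            n_members = int(row["n"].iloc[0])
            try:
                art = _analyze_profile(
                    config, matched, catalog, rank, pid, n_members, outdir, report
                )
            except TooSmallSampleError as exc:
                report.warnings.append(f"rank {rank} (profile {pid}): {exc}")
                continue
            report.profiles.append(art)

    report.to_json(outdir / "report.json")
    (outdir / "report.md").write_text(render_report(report))
    return report


def render_report(report: RunReport) -> str:
    """Deterministic markdown summary of a run (tables-1/2 shape)."""
    lines = [
        "# Symptom-profile network analysis — run report",
        "",
        f"- Theoretical catalog size: {report.catalog_size}",
        f"- Rows read: {report.rows_read} "
        f"(excluded invalid: {report.rows_excluded_invalid})",
        f"- Included respondents (total >= threshold): {report.n_included}",
        f"- Excluded below threshold: {report.n_excluded_below_threshold}",
        f"- Distinct profiles observed: {report.n_profiles_observed}",
        f"- Coverage by top 8 profiles: {report.coverage_top8:.1f}%",
        f"- Config fingerprint: {report.fingerprint}",
        "",
    ]
    if report.profiles:
        lines.append("## Analyzed profiles")
        lines.append("")
        lines.append(
            "| rank | profile | pattern | n | items | method | CS | top strength |"
        )
        lines.append("|---|---|---|---|---|---|---|---|")
        for art in report.profiles:
            cs = "" if art.cs_coefficient is None else f"{art.cs_coefficient:.2f}"
            method = art.method + (" (fallback)" if art.fell_back else "")
            lines.append(
                f"| {art.rank} | {art.profile_id} | {art.pattern} | {art.n} | "
                f"{art.n_items} | {method} | {cs} | {', '.join(art.top_strength)} |"
            )
        lines.append("")
    if report.warnings:
        lines.append("## Warnings")
        lines.append("")
        for msg in report.warnings:
            lines.append(f"- {msg}")
        lines.append("")
    return "\n".join(lines)
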