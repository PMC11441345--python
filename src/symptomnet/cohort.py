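"""Respondent ingestion, inclusion filtering, profile matching and tables.

Reads respondent-by-item integer scores from delimited text, applies the
clinical inclusion threshold on the raw total (PHQ-9 total >= 10 by
default), dichotomizes each included respondent's responses and matches the
pattern to a :class:`~symptomnet.profiles.ProfileCatalog`, then summarizes
profile frequencies, coverage and per-profile descriptives.

Missing-data handling is listwise: a respondent with any missing or
out-of-range item value is excluded up front, with a warning and a count
retained on the returned matrix — no imputation is attempted in this
descriptive stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConsistencyError,
    EmptyInputError,
    FormatError,
    InvalidArgumentError,
)
from .profiles import ProfileCatalog, SymptomProfile

logger = logging.getLogger(__name__)

#: Default item column names for a 9-item instrument.
DEFAULT_ITEM_COLUMNS = tuple(f"phq{i}" for i in range(1, 10))

#: Unmatched / not-included marker in the profile_id vector.
NO_PROFILE = -1


@dataclass(frozen=True)
class ColumnConfig:
    """Column mapping for delimited-text cohort files."""

    item_columns: tuple[str, ...] = DEFAULT_ITEM_COLUMNS
    id_column: str | None = "respondent_id"
    covariate_columns: tuple[str, ...] = ()


def severity_band(total: int) -> str:
    """PHQ-9 severity band of an included total score.

    Bands follow the convention used for screening-positive respondents:
    "moderate" for totals of 14 or below, "moderately severe" for 15-19,
    "severe" for 20 and above.
    """
    if total <= 14:
        return "moderate"
    if total <= 19:
        return "moderately severe"
    return "severe"


@dataclass
class ResponseMatrix:
    """Respondent x item integer scores with inclusion/matching metadata.

    Attributes
    ----------
    scores
        ``(n_respondents, k)`` integer array, entries in
        ``0..max_item_score``.
    respondent_ids
        Ordered respondent identifiers (strings).
    item_labels
        Item column labels, length ``k``.
    threshold
        Inclusion cutoff applied to the raw row total.
    profile_ids
        Per-respondent catalog ID (``NO_PROFILE`` until matched / for
        respondents below the threshold).
    n_dropped_invalid
        Rows removed at load time for missing or out-of-range values.
    """

    scores: np.ndarray
    respondent_ids: tuple[str, ...]
    item_labels: tuple[str, ...] = DEFAULT_ITEM_COLUMNS
    max_item_score: int = 3
    threshold: int = 10
    covariates: pd.DataFrame | None = None
    profile_ids: np.ndarray | None = None
    n_dropped_invalid: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int64)
        if self.scores.ndim != 2:
            raise InvalidArgumentError("scores must be a 2-D array")
        n, k = self.scores.shape
        if len(self.respondent_ids) != n:
            raise InvalidArgumentError("respondent_ids length mismatch")
        if len(self.item_labels) != k:
            raise InvalidArgumentError("item_labels length mismatch")
        if self.scores.size and (
            self.scores.min() < 0 or self.scores.max() > self.max_item_score
        ):
            raise InvalidArgumentError(
                f"scores must lie in 0..{self.max_item_score}"
            )
        if self.profile_ids is None:
            self.profile_ids = np.full(n, NO_PROFILE, dtype=np.int64)
        else:
            self.profile_ids = np.asarray(self.profile_ids, dtype=np.int64)
            if self.profile_ids.shape != (n,):
                raise InvalidArgumentError("profile_ids length mismatch")

    @property
    def n_respondents(self) -> int:
        return self.scores.shape[0]

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    @property
    def totals(self) -> np.ndarray:
        return self.scores.sum(axis=1)

    @property
    def included(self) -> np.ndarray:
        return self.totals >= self.threshold

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    @property
    def matched(self) -> bool:
        return bool(np.any(self.profile_ids != NO_PROFILE)) or self.n_included == 0

    def to_frame(self) -> pd.DataFrame:
        """Full tabular view: ids, scores, total, inclusion, match, band."""
        df = pd.DataFrame(self.scores, columns=list(self.item_labels))
        df.insert(0, "respondent_id", list(self.respondent_ids))
        df["total"] = self.totals
        df["included"] = self.included
        df["profile_id"] = self.profile_ids
        df["severity_band"] = [
            severity_band(t) if inc else ""
            for t, inc in zip(self.totals, self.included)
        ]
        if self.covariates is not None:
            for col in self.covariates.columns:
                df[col] = self.covariates[col].to_numpy()
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        config: ColumnConfig | None = None,
        max_item_score: int = 3,
        threshold: int = 10,
    ) -> "ResponseMatrix":
        """Re-import a matrix exported with :meth:`to_csv` (round-trip safe:
        scores, inclusion flags and matched IDs are preserved)."""
        config = config or ColumnConfig()
        rm = load_responses(
            path, config, max_item_score=max_item_score, threshold=threshold
        )
        df = pd.read_csv(path)
        if "profile_id" in df.columns:
            # load_responses may have dropped invalid rows; re-align by id.
            keep = df[config.id_column].astype(str).isin(rm.respondent_ids)
            rm.profile_ids = df.loc[keep, "profile_id"].to_numpy(dtype=np.int64)
        return rm


def load_responses(
    path: str | Path,
    config: ColumnConfig | None = None,
    max_item_score: int = 3,
    threshold: int = 10,
) -> ResponseMatrix:
    """Read a delimited cohort file into a validated :class:`ResponseMatrix`.

    The delimiter is sniffed (CSV/TSV both accepted).  Rows with any missing
    or out-of-range item value are excluded with a warning; a non-numeric or
    fractional cell raises :class:`FormatError` naming the row and column.
    """
    config = config or ColumnConfig()
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=object)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty")
    missing = [c for c in config.item_columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: unmapped item columns {missing}")
    if df.empty:
        raise EmptyInputError(f"{path}: no respondent rows (header only)")

    raw = df[list(config.item_columns)]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    # A cell that is present but non-numeric, or numeric but fractional,
    # is a format defect rather than a missing value.
    bad_text = numeric.isna() & raw.notna()
    fractional = numeric.notna() & (numeric != numeric.round())
    for mask, what in ((bad_text, "non-numeric"), (fractional, "non-integer")):
        if mask.to_numpy().any():
            r, c = np.argwhere(mask.to_numpy())[0]
            raise FormatError(
                f"{path}: {what} cell at data row {r + 1}, "
                f"column {config.item_columns[c]!r}: {raw.iat[r, c]!r}"
            )
    in_range = numeric.notna() & (numeric >= 0) & (numeric <= max_item_score)
    valid_rows = in_range.all(axis=1).to_numpy()
    n_dropped = int((~valid_rows).sum())
    if n_dropped:
        warnings.warn(
            f"{path}: excluded {n_dropped} respondent(s) with missing or "
            f"out-of-range item values (listwise)",
            stacklevel=2,
        )
        logger.info("%s: dropped %d invalid rows", path, n_dropped)
    if not valid_rows.any():
        raise EmptyInputError(f"{path}: no valid respondent rows after screening")

    scores = numeric.to_numpy(dtype=float)[valid_rows].astype(np.int64)
    if config.id_column and config.id_column in df.columns:
        ids = tuple(str(v) for v in df.loc[valid_rows, config.id_column])
    else:
        ids = tuple(f"r{i + 1}" for i in range(int(valid_rows.sum())))
    cov = None
    cov_cols = [c for c in config.covariate_columns if c in df.columns]
    if cov_cols:
        cov = df.loc[valid_rows, cov_cols].reset_index(drop=True)
        for col in cov_cols:
            converted = pd.to_numeric(cov[col], errors="coerce")
            if not (converted.isna() & cov[col].notna()).any():
                cov[col] = converted
    return ResponseMatrix(
        scores=scores,
        respondent_ids=ids,
        item_labels=tuple(config.item_columns),
        max_item_score=max_item_score,
        threshold=threshold,
        covariates=cov,
        n_dropped_invalid=n_dropped,
    )


def dichotomize(scores: Sequence[int]) -> SymptomProfile:
    """Dichotomize one respondent's item scores: present iff score >= 1."""
    return SymptomProfile(tuple(int(s >= 1) for s in scores))


def match_profiles(responses: ResponseMatrix, catalog: ProfileCatalog) -> ResponseMatrix:
    """Assign each included respondent the catalog ID of their dichotomized
    pattern.  Respondents below the inclusion threshold stay unmatched.

    Raises :class:`ConsistencyError` if an included respondent's pattern is
    not in the catalog — impossible when the catalog was enumerated under
    the same threshold rule, so it signals a configuration mismatch.
    """
    if catalog.rule.rule_kind == "threshold" and (
        catalog.rule.threshold != responses.threshold
        or catalog.rule.max_item_score != responses.max_item_score
    ):
        raise InvalidArgumentError(
            "catalog rule (threshold "
            f"{catalog.rule.threshold}, max {catalog.rule.max_item_score}) does "
            f"not match the inclusion settings (threshold {responses.threshold}, "
            f"max {responses.max_item_score})"
        )
    ids = np.full(responses.n_respondents, NO_PROFILE, dtype=np.int64)
    included = responses.included
    for i in np.flatnonzero(included):
        pattern = tuple(int(v) for v in (responses.scores[i] >= 1))
        try:
            ids[i] = catalog.id_of[pattern]
        except KeyError:
            raise ConsistencyError(
                f"included respondent {responses.respondent_ids[i]!r} (total "
                f"{int(responses.totals[i])}) has pattern "
                f"{''.join(map(str, pattern))} absent from the catalog; the "
                "catalog was likely built under a different rule"
            ) from None
    out = replace(responses, profile_ids=ids)
    return out


@dataclass
class ProfileFrequencyTable:
    """Observed profile frequencies with coverage and descriptives.

    One row per profile with nonzero frequency, ranked by descending
    frequency (ties broken by ascending catalog ID).  ``percent`` is of the
    included sample; ``cumulative_percent`` supports "top-m profiles cover
    q%" statements.
    """

    table: pd.DataFrame
    n_included: int

    def coverage(self, top_m: int) -> float:
        """Summed percent of the ``top_m`` highest-ranked profiles."""
        if top_m < 1:
            raise InvalidArgumentError("top_m must be >= 1")
        if top_m > len(self.table):
            warnings.warn(
                f"top_m={top_m} exceeds the {len(self.table)} observed "
                "profiles; returning total coverage",
                stacklevel=2,
            )
            top_m = len(self.table)
        if not len(self.table):
            return 0.0
        return float(self.table["percent"].iloc[:top_m].sum())

    @property
    def n_profiles_observed(self) -> int:
        return len(self.table)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def frequency_table(
    responses: ResponseMatrix,
    catalog: ProfileCatalog,
    covariates: pd.DataFrame | None = None,
) -> ProfileFrequencyTable:
    """Tabulate matched-profile frequencies, ranks and descriptives.

    ``covariates`` (optional, one row per respondent, aligned with the
    matrix) are summarized per profile as means; the matrix's own attached
    covariates are used when the argument is omitted.
    """
    if not responses.matched:
        raise InvalidArgumentError("responses must be matched first")
    if covariates is None:
        covariates = responses.covariates
    included = responses.included
    if not included.any():
        warnings.warn("no respondents at/above the inclusion threshold", stacklevel=2)
        return ProfileFrequencyTable(
            table=pd.DataFrame(
                columns=[
                    "rank", "profile_id", "pattern", "n_present", "n",
                    "percent", "cumulative_percent", "mean_total", "sd_total",
                ]
            ),
            n_included=0,
        )
    ids = responses.profile_ids[included]
    totals = responses.totals[included]
    n_inc = int(included.sum())
    rows = []
    for pid in np.unique(ids):
        sel = ids == pid
        profile = catalog.profile(int(pid))
        row = {
            "profile_id": int(pid),
            "pattern": profile.pattern,
            "n_present": profile.n_present,
            "n": int(sel.sum()),
            "mean_total": float(totals[sel].mean()),
            "sd_total": float(totals[sel].std(ddof=1)) if sel.sum() > 1 else 0.0,
        }
        if covariates is not None:
            cov_inc = covariates.loc[np.asarray(included)].reset_index(drop=True)
            for col in covariates.columns:
                vals = pd.to_numeric(cov_inc.loc[sel, col], errors="coerce")
                row[f"mean_{col}"] = float(vals.mean()) if vals.notna().any() else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(["n", "profile_id"], ascending=[False, True]).reset_index(
        drop=True
    )
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df["percent"] = 100.0 * df["n"] / n_inc
    df["cumulative_percent"] = df["percent"].cumsum()
    order = [
        "rank", "profile_id", "pattern", "n_present", "n", "percent",
        "cumulative_percent", "mean_total", "sd_total",
    ]
    order += [c for c in df.columns if c not in order]
    return ProfileFrequencyTable(table=df[order], n_included=n_inc)


def coverage(table: ProfileFrequencyTable, top_m: int) -> float:
    """Percent of the included sample covered by the ``top_m`` most frequent
    profiles (functional alias of :meth:`ProfileFrequencyTable.coverage`)."""
    return table.coverage(top_m)
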