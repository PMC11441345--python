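"""Enumeration of dichotomized symptom profiles under a diagnostic rule.

A *symptom profile* is a presence/absence pattern over the ``k`` items of an
ordinal questionnaire (PHQ-9 convention: 9 items scored 0-3).  A respondent's
item scores are dichotomized at score >= 1, and the resulting 0/1 pattern is
matched against a catalog of all patterns that can, in principle, satisfy a
clinical rule:

* ``threshold`` rule — the pattern can reach a total-score cutoff when every
  present item takes its maximum score.  Under the PHQ-9 screening cutoff of
  10 (items scored 0-3) this retains every pattern with at least
  ``ceil(10 / 3) = 4`` present items, i.e. ``sum_{r=4}^{9} C(9, r) = 382``
  distinct profiles.
* ``dsm`` rule — a DSM-style polythetic criterion: at least ``min_count``
  symptoms present, of which at least one is a designated core symptom
  (depressed mood or anhedonia).  With 5-of-9 and two core symptoms this
  yields 227 combinations.

Item indices are 1-based everywhere a user sees them and follow PHQ-9 order:
1 anhedonia, 2 low mood, 3 sleep, 4 energy, 5 appetite, 6 worthlessness,
7 concentration, 8 psychomotor, 9 suicidal ideation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import CapacityError, FormatError, InvalidArgumentError

#: Canonical PHQ-9 item labels, index 0 = item 1.
PHQ9_ITEMS: tuple[str, ...] = (
    "anhedonia",
    "low_mood",
    "sleep",
    "energy",
    "appetite",
    "worthlessness",
    "concentration",
    "psychomotor",
    "suicidal",
)

#: Hard cap on exhaustive 2^k enumeration.
MAX_ENUMERATION_ITEMS = 24


def binomial_coefficient(n: int, r: int) -> int:
    """Exact number of ways of selecting ``r`` objects out of ``n``.

    Integer arithmetic throughout; exact for any ``k <= 64`` instrument.
    """
    if not (isinstance(n, (int, np.integer)) and isinstance(r, (int, np.integer))):
        raise InvalidArgumentError("binomial_coefficient requires integer arguments")
    if n < 0 or r < 0:
        raise InvalidArgumentError(f"negative arguments not allowed: n={n}, r={r}")
    if r > n:
        raise InvalidArgumentError(f"r={r} exceeds n={n}")
    return math.comb(int(n), int(r))


@dataclass(frozen=True)
class SymptomProfile:
    """A presence/absence pattern over ``k`` questionnaire items.

    ``presence[i]`` is 1 if item ``i + 1`` is present (raw score 1-3) and 0
    if absent (raw score 0).
    """

    presence: tuple[int, ...]

    def __post_init__(self) -> None:
        if not all(v in (0, 1) for v in self.presence):
            raise InvalidArgumentError("presence entries must be 0 or 1")
        object.__setattr__(self, "presence", tuple(int(v) for v in self.presence))

    @property
    def k(self) -> int:
        return len(self.presence)

    @property
    def n_present(self) -> int:
        return sum(self.presence)

    @property
    def pattern(self) -> str:
        """The profile as a ``k``-character 0/1 string, item 1 first."""
        return "".join(str(v) for v in self.presence)

    def items_present(self) -> tuple[int, ...]:
        """1-based indices of present items."""
        return tuple(i + 1 for i, v in enumerate(self.presence) if v)

    @classmethod
    def from_pattern(cls, pattern: str) -> "SymptomProfile":
        if not set(pattern) <= {"0", "1"}:
            raise InvalidArgumentError(f"pattern must be a 0/1 string, got {pattern!r}")
        return cls(tuple(int(c) for c in pattern))

    def __len__(self) -> int:
        return len(self.presence)


@dataclass(frozen=True)
class ProfileRule:
    """Eligibility rule deciding which dichotomized patterns enter a catalog.

    Parameters
    ----------
    rule_kind
        ``"threshold"``: a pattern is eligible iff its maximum achievable
        total (present items at ``max_item_score``, absent items at 0)
        reaches ``threshold``.
        ``"dsm"``: eligible iff at least ``min_count`` items are present and
        at least one of ``core_items`` is among them.
    k
        Number of items on the instrument (default 9).
    threshold
        Total-score cutoff for the threshold rule (default 10, the PHQ-9
        screening cutoff for clinically significant depression).
    max_item_score
        Maximum per-item score (default 3).
    min_count, core_items
        DSM-rule parameters; defaults are 5-of-9 with core symptoms
        {1, 2} (anhedonia, depressed mood).
    """

    rule_kind: str = "threshold"
    k: int = 9
    threshold: int = 10
    max_item_score: int = 3
    min_count: int = 5
    core_items: frozenset[int] = field(default_factory=lambda: frozenset({1, 2}))

    def __post_init__(self) -> None:
        if self.rule_kind not in ("threshold", "dsm"):
            raise InvalidArgumentError(f"unknown rule_kind {self.rule_kind!r}")
        if self.k < 1:
            raise InvalidArgumentError("k must be >= 1")
        if self.threshold < 1:
            raise InvalidArgumentError("threshold must be >= 1")
        if self.max_item_score < 1:
            raise InvalidArgumentError("max_item_score must be >= 1")
        if self.min_count < 1:
            raise InvalidArgumentError("min_count must be >= 1")
        core = frozenset(int(i) for i in self.core_items)
        if self.rule_kind == "dsm" and not core <= set(range(1, self.k + 1)):
            raise InvalidArgumentError(
                f"core_items {sorted(core)} not within 1..{self.k}"
            )
        object.__setattr__(self, "core_items", core)


def is_eligible(profile: SymptomProfile, rule: ProfileRule) -> bool:
    """Whether a dichotomized pattern can satisfy the rule.

    Threshold rule: true iff ``n_present * max_item_score >= threshold``
    (every present item at its maximum score).  DSM rule: true iff at least
    ``min_count`` items are present including at least one core item.
    """
    if profile.k != rule.k:
        raise InvalidArgumentError(
            f"profile has {profile.k} items but rule expects {rule.k}"
        )
    if rule.rule_kind == "threshold":
        return profile.n_present * rule.max_item_score >= rule.threshold
    present = {i + 1 for i, v in enumerate(profile.presence) if v}
    return len(present) >= rule.min_count and bool(present & rule.core_items)


def count_by_closed_form(rule: ProfileRule) -> int:
    """Closed-form catalog size for a threshold rule.

    Sums ``C(k, r)`` over ``r`` from ``ceil(threshold / max_item_score)``
    to ``k`` — the number of presence patterns whose maximum achievable
    total reaches the cutoff.
    """
    if rule.rule_kind != "threshold":
        raise InvalidArgumentError("closed form is defined for threshold rules only")
    r_min = math.ceil(rule.threshold / rule.max_item_score)
    if r_min > rule.k:
        return 0
    return sum(binomial_coefficient(rule.k, r) for r in range(r_min, rule.k + 1))


@dataclass(frozen=True)
class ProfileCatalog:
    """The enumerated set of rule-eligible profiles with canonical IDs.

    Profiles are ordered by descending symptom count, then descending
    lexicographic pattern (item 1 most significant), so ID 1 is always the
    all-present profile, ID 2 drops only the last item, and so on.  IDs are
    1-based and stable across runs.
    """

    rule: ProfileRule
    profiles: tuple[SymptomProfile, ...]
    id_of: Mapping[tuple[int, ...], int]

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[SymptomProfile]:
        return iter(self.profiles)

    def profile(self, catalog_id: int) -> SymptomProfile:
        """Look up a profile by 1-based catalog ID."""
        if not 1 <= catalog_id <= len(self.profiles):
            raise InvalidArgumentError(
                f"catalog ID {catalog_id} outside 1..{len(self.profiles)}"
            )
        return self.profiles[catalog_id - 1]

    def id_for(self, presence: Sequence[int] | SymptomProfile) -> int:
        """Catalog ID of a presence pattern; KeyError if not eligible."""
        if isinstance(presence, SymptomProfile):
            presence = presence.presence
        return self.id_of[tuple(int(v) for v in presence)]

    def __contains__(self, presence: object) -> bool:
        if isinstance(presence, SymptomProfile):
            presence = presence.presence
        try:
            return tuple(presence) in self.id_of  # type: ignore[arg-type]
        except TypeError:
            return False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "profile_id": np.arange(1, len(self.profiles) + 1),
                "pattern": [p.pattern for p in self.profiles],
                "n_present": [p.n_present for p in self.profiles],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, rule: ProfileRule) -> "ProfileCatalog":
        """Rebuild a catalog from its CSV export, validating it against
        the rule (every row must be eligible; IDs must be 1..m)."""
        df = pd.read_csv(path, dtype={"pattern": str})
        for col in ("profile_id", "pattern"):
            if col not in df.columns:
                raise FormatError(f"catalog file missing column {col!r}")
        profiles = tuple(SymptomProfile.from_pattern(p) for p in df["pattern"])
        ids = df["profile_id"].to_numpy()
        if not np.array_equal(ids, np.arange(1, len(profiles) + 1)):
            raise FormatError("catalog IDs must be consecutive starting at 1")
        for p in profiles:
            if not is_eligible(p, rule):
                raise FormatError(f"catalog pattern {p.pattern} not eligible under rule")
        id_of = {p.presence: i + 1 for i, p in enumerate(profiles)}
        if len(id_of) != len(profiles):
            raise FormatError("catalog contains duplicate patterns")
        return cls(rule=rule, profiles=profiles, id_of=id_of)


def _eligible_pattern_ints(rule: ProfileRule) -> np.ndarray:
    """Integers encoding all eligible patterns, item 1 as most significant bit."""
    k = rule.k
    codes = np.arange(2**k, dtype=np.uint32)
    counts = np.bitwise_count(codes)
    if rule.rule_kind == "threshold":
        mask = counts * rule.max_item_score >= rule.threshold
    else:
        core_bits = np.uint32(0)
        for item in rule.core_items:
            core_bits |= np.uint32(1 << (k - item))
        mask = (counts >= rule.min_count) & ((codes & core_bits) != 0)
    return codes[mask]


def enumerate_catalog(rule: ProfileRule) -> ProfileCatalog:
    """Exhaustively enumerate every eligible dichotomized profile.

    Scans all ``2^k`` presence patterns (``k <= 24``), retains those passing
    :func:`is_eligible`, and assigns canonical 1-based IDs in descending
    symptom count / descending lexicographic order.
    """
    if rule.k > MAX_ENUMERATION_ITEMS:
        raise CapacityError(
            f"exhaustive enumeration over 2^{rule.k} patterns exceeds the "
            f"{MAX_ENUMERATION_ITEMS}-item capacity"
        )
    codes = _eligible_pattern_ints(rule)
    counts = np.bitwise_count(codes)
    # Descending n_present, then descending binary value (item 1 = MSB).
    order = np.lexsort((-codes.astype(np.int64), -counts.astype(np.int64)))
    codes = codes[order]
    k = rule.k
    profiles = tuple(
        SymptomProfile(tuple((int(c) >> (k - 1 - i)) & 1 for i in range(k)))
        for c in codes
    )
    id_of = {p.presence: i + 1 for i, p in enumerate(profiles)}
    return ProfileCatalog(rule=rule, profiles=profiles, id_of=id_of)
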