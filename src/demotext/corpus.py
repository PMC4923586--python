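"""Core data types, JSON-lines corpus I/O, and demographic binning.

A corpus is a pair of files: ``posts.jsonl`` (one post per line) and a
sibling ``users.jsonl`` holding author profiles. Demographic attributes on a
profile are either *reported* by the source, *classified* by an inference
step, or *missing*; every downstream per-attribute analysis simply drops
authors for whom the attribute is missing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

SOURCES = ("social_network", "drug_review", "forum")
GENDERS = ("male", "female")
ETHNICITIES = ("white", "black", "asian", "hispanic")
REGIONS = ("Northeast", "Midwest", "South", "West")
AGE_GROUPS = ("0-17", "18-34", "35-44", "45-64", "65+")
WRITING_LEVEL_BINS = ("0-5", "6-9", "10-16")
ATTRIBUTES = ("gender", "age_group", "ethnicity", "region", "writing_level_bin")
PROVENANCE = ("reported", "classified", "missing")

# US Census Bureau four-region assignment (50 states + DC).
_CENSUS_REGION = {
    "CT": "Northeast", "ME": "Northeast", "MA": "Northeast", "NH": "Northeast",
    "RI": "Northeast", "VT": "Northeast", "NJ": "Northeast", "NY": "Northeast",
    "PA": "Northeast",
    "IL": "Midwest", "IN": "Midwest", "MI": "Midwest", "OH": "Midwest",
    "WI": "Midwest", "IA": "Midwest", "KS": "Midwest", "MN": "Midwest",
    "MO": "Midwest", "NE": "Midwest", "ND": "Midwest", "SD": "Midwest",
    "DE": "South", "FL": "South", "GA": "South", "MD": "South", "NC": "South",
    "SC": "South", "VA": "South", "DC": "South", "WV": "South", "AL": "South",
    "KY": "South", "MS": "South", "TN": "South", "AR": "South", "LA": "South",
    "OK": "South", "TX": "South",
    "AZ": "West", "CO": "West", "ID": "West", "MT": "West", "NV": "West",
    "NM": "West", "UT": "West", "WY": "West", "AK": "West", "CA": "West",
    "HI": "West", "OR": "West", "WA": "West",
}


class CorpusError(ValueError):
    """Raised for structurally invalid corpora (duplicates, empty files...)."""


@dataclass(frozen=True)
class Post:
    post_id: str
    user_id: str
    text: str
    source: str = "social_network"
    timestamp: str | None = None

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise CorpusError(f"post {self.post_id!r}: empty text")
        if self.source not in SOURCES:
            raise CorpusError(f"post {self.post_id!r}: unknown source {self.source!r}")

    def to_json(self) -> dict:
        d = {"post_id": self.post_id, "user_id": self.user_id,
             "text": self.text, "source": self.source}
        if self.timestamp is not None:
            d["timestamp"] = self.timestamp
        return d

    @classmethod
    def from_json(cls, d: Mapping) -> "Post":
        return cls(post_id=str(d["post_id"]), user_id=str(d["user_id"]),
                   text=str(d["text"]), source=d.get("source", "social_network"),
                   timestamp=d.get("timestamp"))


@dataclass(frozen=True)
class UserProfile:
    """Author demographics, observed or inferred.

    ``provenance`` records, per attribute name, whether the value was
    reported by the source, classified by an inference step, or missing.
    Attributes whose provenance is "missing" hold ``None``.
    """

    user_id: str
    first_name: str | None = None
    last_name: str | None = None
    gender: str | None = None
    age_years: int | None = None
    location_state: str | None = None
    region: str | None = None
    ethnicity: str | None = None
    writing_level_grade: float | None = None
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gender is not None and self.gender not in GENDERS:
            raise CorpusError(f"user {self.user_id!r}: bad gender {self.gender!r}")
        if self.ethnicity is not None and self.ethnicity not in ETHNICITIES:
            raise CorpusError(f"user {self.user_id!r}: bad ethnicity {self.ethnicity!r}")
        if self.age_years is not None and self.age_years < 0:
            raise CorpusError(f"user {self.user_id!r}: negative age")
        if self.region is not None and self.region not in REGIONS:
            raise CorpusError(f"user {self.user_id!r}: bad region {self.region!r}")
        for attr, prov in self.provenance.items():
            if prov not in PROVENANCE:
                raise CorpusError(f"user {self.user_id!r}: bad provenance {prov!r}")
            if prov == "missing" and self.attribute_value(attr) is not None:
                raise CorpusError(
                    f"user {self.user_id!r}: {attr} marked missing but has a value")

    # -- demographic attribute accessors -------------------------------------

    def attribute_value(self, attribute: str) -> str | None:
        """Return this user's value for one of the five analysis attributes."""
        if attribute == "gender":
            return self.gender
        if attribute == "age_group":
            return None if self.age_years is None else bin_age(self.age_years)
        if attribute == "ethnicity":
            return self.ethnicity
        if attribute == "region":
            if self.region is not None:
                return self.region
            if self.location_state is not None:
                return map_region(self.location_state)
            return None
        if attribute == "writing_level_bin":
            if self.writing_level_grade is None:
                return None
            return bin_writing_level(self.writing_level_grade)
        raise CorpusError(f"unknown attribute {attribute!r}")

    def to_json(self) -> dict:
        d: dict = {"user_id": self.user_id}
        for key, val in (("first_name", self.first_name), ("last_name", self.last_name),
                         ("gender", self.gender), ("age", self.age_years),
                         ("state", self.location_state), ("region", self.region),
                         ("ethnicity", self.ethnicity),
                         ("writing_level_grade", self.writing_level_grade)):
            if val is not None:
                d[key] = val
        if self.provenance:
            d["provenance"] = dict(self.provenance)
        return d

    @classmethod
    def from_json(cls, d: Mapping) -> "UserProfile":
        return cls(user_id=str(d["user_id"]),
                   first_name=d.get("first_name"), last_name=d.get("last_name"),
                   gender=d.get("gender"), age_years=d.get("age"),
                   location_state=d.get("state"), region=d.get("region"),
                   ethnicity=d.get("ethnicity"),
                   writing_level_grade=d.get("writing_level_grade"),
                   provenance=d.get("provenance", {}))

    def with_classified(self, **updates) -> "UserProfile":
        """Return a copy with classified attribute values and provenance set."""
        prov = dict(self.provenance)
        for attr in updates:
            prov[attr] = "classified"
        return replace(self, provenance=prov, **updates)


# -- binning ------------------------------------------------------------------

def bin_age(age_years: int) -> str:
    """Map an integer age to the study's closed age bins."""
    if age_years < 0:
        raise CorpusError("age must be non-negative")
    if age_years <= 17:
        return "0-17"
    if age_years <= 34:
        return "18-34"
    if age_years <= 44:
        return "35-44"
    if age_years <= 64:
        return "45-64"
    return "65+"


def bin_writing_level(grade: float) -> str:
    """Map a (clamped) Flesch-Kincaid grade to the three writing-level bins.

    Edges: [0, 6) -> "0-5", [6, 10) -> "6-9", [10, 16] -> "10-16".
    """
    if grade < 0:
        raise CorpusError("writing level grade must be non-negative")
    if grade < 6:
        return "0-5"
    if grade < 10:
        return "6-9"
    return "10-16"


def map_region(location_state: str) -> str | None:
    """US Census Bureau four-region assignment; None (logged) for unknown codes."""
    region = _CENSUS_REGION.get(location_state.upper())
    if region is None:
        log.warning("unknown state code %r; region left missing", location_state)
    return region


# -- corpus I/O ----------------------------------------------------------------

def read_corpus(posts_path: str | Path,
                users_path: str | Path | None = None,
                ) -> tuple[list[Post], dict[str, UserProfile]]:
    """Read a JSON-lines corpus: posts plus the sibling users file.

    Malformed lines are counted and logged; they are fatal only when they
    exceed half the file. Duplicate post ids are always fatal.
    """
    posts_path = Path(posts_path)
    if users_path is None:
        users_path = posts_path.with_name("users.jsonl")
    users_path = Path(users_path)
    if not posts_path.exists():
        raise CorpusError(f"no such corpus file: {posts_path}")

    posts: list[Post] = []
    seen: dict[str, int] = {}
    dupes: list[str] = []
    bad = 0
    total = 0
    with open(posts_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            total += 1
            try:
                post = Post.from_json(json.loads(line))
            except (json.JSONDecodeError, KeyError, CorpusError) as exc:
                bad += 1
                log.warning("%s:%d: malformed post record (%s)", posts_path, lineno, exc)
                continue
            if post.post_id in seen:
                dupes.append(post.post_id)
            seen[post.post_id] = lineno
            posts.append(post)
    if dupes:
        raise CorpusError(f"duplicate post_id(s): {sorted(set(dupes))}")
    if total == 0:
        raise CorpusError(f"empty corpus: {posts_path}")
    if bad > total / 2:
        raise CorpusError(f"{posts_path}: {bad}/{total} lines malformed")
    if bad:
        log.warning("%s: skipped %d malformed line(s)", posts_path, bad)

    profiles: dict[str, UserProfile] = {}
    if users_path.exists():
        with open(users_path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    prof = UserProfile.from_json(json.loads(line))
                except (json.JSONDecodeError, KeyError, CorpusError) as exc:
                    log.warning("%s:%d: malformed user record (%s)",
                                users_path, lineno, exc)
                    continue
                profiles[prof.user_id] = prof
    return posts, profiles


def write_corpus(posts: Iterable[Post], profiles: Iterable[UserProfile],
                 posts_path: str | Path,
                 users_path: str | Path | None = None) -> None:
    posts_path = Path(posts_path)
    if users_path is None:
        users_path = posts_path.with_name("users.jsonl")
    posts_path.parent.mkdir(parents=True, exist_ok=True)
    with open(posts_path, "w", encoding="utf-8") as fh:
        for post in posts:
            fh.write(json.dumps(post.to_json(), sort_keys=True) + "\n")
    with open(users_path, "w", encoding="utf-8") as fh:
        for prof in profiles:
            fh.write(json.dumps(prof.to_json(), sort_keys=True) + "\n")


def partition_posts(posts: Iterable[Post],
                    profiles: Mapping[str, UserProfile],
                    attribute: str) -> dict[str, list[Post]]:
    """Split posts by their author's value of one demographic attribute.

    Posts whose author is unknown or lacks the attribute are excluded, so the
    parts are disjoint and their union is exactly the annotated posts.
    """
    if attribute not in ATTRIBUTES:
        raise CorpusError(f"unknown attribute {attribute!r} "
                          f"(expected one of {ATTRIBUTES})")
    parts: dict[str, list[Post]] = {}
    for post in posts:
        prof = profiles.get(post.user_id)
        if prof is None:
            continue
        value = prof.attribute_value(attribute)
        if value is None:
            continue
        parts.setdefault(value, []).append(post)
    if not parts:
        log.warning("partition by %r is empty (no annotated authors)", attribute)
    return parts
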