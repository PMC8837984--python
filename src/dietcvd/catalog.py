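"""Food-group catalog for the plant-centered diet quality score.

The A Priori Diet Quality Score (APDQS) rates 46 food groups as
*beneficial* (scored 0-4 by ascending intake quintile), *adverse*
(scored 4-0, i.e. reverse), or *neutral* (always 0).  The default
catalog bundled with the package carries the canonical 20/13/13 split
used in the CARDIA cohort, together with a typical mean intake
(servings/day) per group that the synthetic-cohort generator uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

RATING_BENEFICIAL = "beneficial"
RATING_ADVERSE = "adverse"
RATING_NEUTRAL = "neutral"
VALID_RATINGS = (RATING_BENEFICIAL, RATING_ADVERSE, RATING_NEUTRAL)

#: expected composition of the default catalog
N_GROUPS = 46
N_BENEFICIAL = 20
N_ADVERSE = 13
N_NEUTRAL = 13

#: maximum attainable APDQS: 33 rated groups x 4 points
APDQS_MAX = (N_BENEFICIAL + N_ADVERSE) * 4


class CatalogError(ValueError):
    """Raised when a food-group catalog violates its invariants."""


@dataclass(frozen=True)
class FoodGroup:
    group_id: str
    name: str
    rating: str
    typical_servings: float = float("nan")


@dataclass
class FoodGroupCatalog:
    """The 46-group catalog with beneficial/adverse/neutral ratings.

    Parameters
    ----------
    entries
        One :class:`FoodGroup` per food group; ``group_id`` must be unique.
    strict
        When True (default) the catalog must have exactly 46 entries with
        the canonical 20 beneficial / 13 adverse / 13 neutral composition.
        Relaxed catalogs (``strict=False``) are allowed for toy cohorts in
        tests, but scoring then loses its 0-132 calibration.
    """

    entries: list[FoodGroup] = field(default_factory=list)
    strict: bool = True

    def __post_init__(self) -> None:
        ids = [e.group_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise CatalogError(f"duplicate group_ids in catalog: {dupes}")
        for e in self.entries:
            if e.rating not in VALID_RATINGS:
                raise CatalogError(
                    f"group {e.group_id!r}: rating {e.rating!r} not one of {VALID_RATINGS}"
                )
        if self.strict:
            counts = self.rating_counts()
            expected = {
                RATING_BENEFICIAL: N_BENEFICIAL,
                RATING_ADVERSE: N_ADVERSE,
                RATING_NEUTRAL: N_NEUTRAL,
            }
            if len(self.entries) != N_GROUPS or counts != expected:
                raise CatalogError(
                    f"catalog must have {N_GROUPS} groups "
                    f"({N_BENEFICIAL} beneficial, {N_ADVERSE} adverse, {N_NEUTRAL} neutral); "
                    f"got {len(self.entries)} with {counts}"
                )

    def rating_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in VALID_RATINGS}
        for e in self.entries:
            counts[e.rating] += 1
        return counts

    @property
    def group_ids(self) -> list[str]:
        return [e.group_id for e in self.entries]

    def rating_of(self, group_id: str) -> str:
        try:
            return self._rating_map[group_id]
        except AttributeError:
            self._rating_map = {e.group_id: e.rating for e in self.entries}
            return self._rating_map[group_id]

    def groups_with_rating(self, rating: str) -> list[str]:
        return [e.group_id for e in self.entries if e.rating == rating]

    @property
    def rated_groups(self) -> list[str]:
        """Beneficial and adverse groups, the ones that contribute points."""
        return [e.group_id for e in self.entries if e.rating != RATING_NEUTRAL]

    def typical_servings_map(self) -> dict[str, float]:
        return {e.group_id: e.typical_servings for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_id": [e.group_id for e in self.entries],
                "name": [e.name for e in self.entries],
                "rating": [e.rating for e in self.entries],
                "typical_servings": [e.typical_servings for e in self.entries],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, strict: bool = True) -> "FoodGroupCatalog":
        required = {"group_id", "name", "rating"}
        missing = required - set(df.columns)
        if missing:
            raise CatalogError(f"catalog table missing columns: {sorted(missing)}")
        entries = [
            FoodGroup(
                group_id=str(row.group_id),
                name=str(row.name),
                rating=str(row.rating),
                typical_servings=float(getattr(row, "typical_servings", float("nan"))),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(entries=entries, strict=strict)

    @classmethod
    def from_file(cls, path: str | Path, strict: bool = True) -> "FoodGroupCatalog":
        df = pd.read_csv(path, sep="\t")
        return cls.from_frame(df, strict=strict)


def default_catalog() -> FoodGroupCatalog:
    """Load the bundled 46-group catalog."""
    with resources.files("dietcvd.data").joinpath("food_groups.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t")
    return FoodGroupCatalog.from_frame(df, strict=True)


def reference_extreme_quintile_means() -> pd.DataFrame:
    """Bundled reference table of mean intakes (servings/day) in the extreme
    quintiles of each diet score at baseline, one row per food group.

    Columns: ``group_id, rating, apdqs_q1, apdqs_q5, keys_q1, keys_q5``.
    Used by the reporting stage's contrast-table worked example.
    """
    with resources.files("dietcvd.data").joinpath("extreme_quintile_means.tsv").open("r") as fh:
        return pd.read_csv(fh, sep="\t")
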