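"""Diet profiles and primary-diet classification.

Per-species, per-study prey-item importances (e.g. percent volume of stomach
contents) are averaged across studies, summed into prey-category importances
through a :class:`~ecomorph.prey.CategorySet`, and each species is assigned
the category carrying the largest summed importance ("synthetic" diet).  A
conventional coarse label (insectivore, piscivore, ...) is assigned when one
prey type exceeds 50% of the diet.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .prey import CategorySet

__all__ = [
    "DietRecord",
    "DietRecordSet",
    "DietProfile",
    "CategoryAssignment",
    "DietValidationError",
    "equalize_description",
    "aggregate_importances",
    "categorize_profile",
    "assign_primary_diet",
    "assign_coarse_diet",
    "concentration_summary",
]

ROW_SUM_TOL = 1e-6


class DietValidationError(ValueError):
    """Raised for malformed or unresolvable diet records."""


@dataclass(frozen=True)
class DietRecord:
    species: str
    study: str
    prey_item: str
    importance: float
    life_stage: str = "adult"


@dataclass
class DietRecordSet:
    """Long-format per-study diet records.

    Importances are proportions in [0, 1]; a (species, study) total may fall
    short of 1 (unclassified remainder) but must not exceed 1 beyond rounding
    tolerance.
    """

    records: list[DietRecord]

    def __post_init__(self) -> None:
        totals: dict[tuple[str, str], float] = defaultdict(float)
        for r in self.records:
            if r.importance < 0:
                raise DietValidationError(
                    f"negative importance for {r.species}/{r.prey_item}"
                )
            totals[(r.species, r.study)] += r.importance
        for (sp, st), t in totals.items():
            if t > 1 + ROW_SUM_TOL:
                raise DietValidationError(
                    f"importances for ({sp}, {st}) sum to {t:.6f} > 1"
                )

    def species(self) -> list[str]:
        return sorted({r.species for r in self.records})

    def filter_life_stage(self, prefer: str = "adult") -> "DietRecordSet":
        """Keep records of the preferred life stage; fall back to whatever a
        species has when the preferred stage is absent (some species are only
        known from juvenile diet data)."""
        by_sp: dict[str, list[DietRecord]] = defaultdict(list)
        for r in self.records:
            by_sp[r.species].append(r)
        kept: list[DietRecord] = []
        for recs in by_sp.values():
            preferred = [r for r in recs if r.life_stage == prefer]
            kept.extend(preferred if preferred else recs)
        return DietRecordSet(records=kept)


@dataclass(frozen=True)
class DietProfile:
    """A species' mean per-item importances and per-category sums."""

    species: str
    item_importance: dict[str, float]
    category_importance: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return sum(self.item_importance.values())


@dataclass(frozen=True)
class CategoryAssignment:
    species: str
    category: str
    importance: float
    tie: bool
    coarse: str | None = None
    habitat: str | None = None


def equalize_description(items: Sequence[str]) -> dict[str, float]:
    """Equal importance 1/len(items) for a descriptive account that lists
    prey items without quantifying them."""
    if not items:
        raise DietValidationError("empty prey-item list")
    w = 1.0 / len(items)
    return {item: w for item in items}


def aggregate_importances(
    records: DietRecordSet, known_items: Iterable[str] | None = None
) -> dict[str, DietProfile]:
    """Per-species mean importance of each prey item across studies.

    A study in which an item is not reported contributes 0 for that item, so
    the mean divides by the number of studies for the species, not the number
    of studies mentioning the item.
    """
    known = set(known_items) if known_items is not None else None
    by_sp: dict[str, dict[str, float]] = defaultdict(lambda: defaultdict(float))
    studies: dict[str, set[str]] = defaultdict(set)
    for r in records.records:
        if known is not None and r.prey_item not in known:
            raise DietValidationError(
                f"prey item {r.prey_item!r} (species {r.species}) does not "
                "resolve against the category set"
            )
        by_sp[r.species][r.prey_item] += r.importance
        studies[r.species].add(r.study)
    out = {}
    for sp, sums in by_sp.items():
        ns = len(studies[sp])
        out[sp] = DietProfile(
            species=sp,
            item_importance={item: v / ns for item, v in sums.items()},
        )
    return out


def categorize_profile(profile: DietProfile, cats: CategorySet) -> DietProfile:
    """Sum the importance of each constituent prey item within each category.

    Conservation: the category importances sum to the item importances.
    """
    cat_imp = {c: 0.0 for c in cats.categories}
    for item, v in profile.item_importance.items():
        if item not in cats.membership:
            raise DietValidationError(
                f"prey item {item!r} of {profile.species} has no category"
            )
        cat_imp[cats.membership[item]] += v
    return DietProfile(
        species=profile.species,
        item_importance=dict(profile.item_importance),
        category_importance=cat_imp,
    )


def assign_primary_diet(
    cat_importances: Mapping[str, float],
    species: str = "",
    tie_rule: str = "rare",
    category_totals: Mapping[str, float] | None = None,
    rounding: float = 0.0,
) -> CategoryAssignment:
    """Argmax classification of the primary diet category.

    ``tie_rule`` resolves exact ties (at ``rounding`` precision):

    - ``"rare"`` (default): prefer the category with the smaller dataset-wide
      total importance, i.e. the rarer niche (requires ``category_totals``);
    - ``"first"``: first in the mapping's iteration order;
    - ``"error"``: raise.
    """
    if not cat_importances or max(cat_importances.values()) <= 0:
        raise DietValidationError(f"all-zero diet profile for {species!r}")
    mx = max(cat_importances.values())
    tol = rounding if rounding > 0 else 1e-12
    winners = [c for c, v in cat_importances.items() if v >= mx - tol]
    tie = len(winners) > 1
    if not tie:
        winner = winners[0]
    elif tie_rule == "first":
        winner = winners[0]
    elif tie_rule == "error":
        raise DietValidationError(f"tied categories {winners} for {species!r}")
    elif tie_rule == "rare":
        if category_totals is None:
            raise DietValidationError(
                "tie_rule='rare' needs dataset-wide category totals"
            )
        winner = min(winners, key=lambda c: (category_totals[c], c))
    else:
        raise DietValidationError(f"unknown tie_rule {tie_rule!r}")
    return CategoryAssignment(
        species=species, category=winner, importance=mx, tie=tie
    )


def assign_coarse_diet(
    profile: DietProfile,
    type_map: Mapping[str, str],
    fallback: str = "omnivore",
) -> str:
    """Coarse label via the strict >50% rule.

    ``type_map`` sends each prey item to a coarse prey type whose label is
    returned when its total importance strictly exceeds 0.5; otherwise the
    ``fallback`` label (by default "omnivore") is returned.
    """
    totals: dict[str, float] = defaultdict(float)
    missing = [i for i in profile.item_importance if i not in type_map]
    if missing:
        raise DietValidationError(
            f"no coarse type for items {sorted(missing)} ({profile.species})"
        )
    for item, v in profile.item_importance.items():
        totals[type_map[item]] += v
    for label, t in totals.items():
        if t > 0.5:
            return label
    return fallback


def concentration_summary(
    assignments: Sequence[CategoryAssignment],
    profiles: Mapping[str, DietProfile],
    threshold: float = 0.5,
    focal: str | None = None,
    focal_thresholds: Sequence[float] = (0.70, 0.90),
) -> dict:
    """Counts describing how concentrated diets are on single categories.

    Returns the number of species whose largest category importance exceeds
    ``threshold`` (strictly), per-category species counts, and -- for the
    ``focal`` category -- how many of its species exceed each secondary
    threshold (strict for the first, inclusive for later ones, matching the
    ">70% / >=90% at printed precision" style of summary).
    """
    n_over = sum(1 for a in assignments if a.importance > threshold)
    per_cat: dict[str, int] = defaultdict(int)
    for a in assignments:
        per_cat[a.category] += 1
    out = {
        "n_species": len(assignments),
        "n_over_threshold": n_over,
        "below_threshold": sorted(
            a.species for a in assignments if not a.importance > threshold
        ),
        "per_category": dict(per_cat),
    }
    if focal is not None:
        focal_counts = {}
        members = [a.species for a in assignments if a.category == focal]
        for i, t in enumerate(focal_thresholds):
            if i == 0:
                hits = sum(
                    1
                    for sp in members
                    if profiles[sp].category_importance.get(focal, 0.0) > t
                )
            else:
                hits = sum(
                    1
                    for sp in members
                    if profiles[sp].category_importance.get(focal, 0.0) >= t - 1e-9
                )
            focal_counts[t] = hits
        out["focal"] = focal
        out["focal_counts"] = focal_counts
    return out
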