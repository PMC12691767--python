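"""Austrian care-needs assessment: hour thresholds, qualitative criteria, payouts.

The long-term-care allowance (Pflegegeld) is a needs-tested cash benefit in
seven levels. Levels 1-4 are defined purely by assessed monthly hours of care
need; levels 5-7 additionally require a qualitative criterion (an
extraordinary amount of care, uncoordinated day-and-night care or permanent
day-and-night presence, or the impossibility of purposeful movements of the
four extremities). Dementia adds an automatic 40 h/month premium to the
assessed need before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "FLAG_EXTRAORDINARY",
    "FLAG_DAY_NIGHT",
    "FLAG_NO_MOVEMENT",
    "QUALITATIVE_FLAGS",
    "DEMENTIA_PREMIUM_HOURS",
    "LevelRule",
    "AssessmentRuleTable",
    "CareNeed",
    "DEFAULT_RULES",
    "total_hours",
    "classify_level",
    "payout",
]

FLAG_EXTRAORDINARY = "extraordinary_care"
FLAG_DAY_NIGHT = "uncoordinated_day_night"
FLAG_NO_MOVEMENT = "no_purposeful_movements"
QUALITATIVE_FLAGS = (FLAG_EXTRAORDINARY, FLAG_DAY_NIGHT, FLAG_NO_MOVEMENT)

#: Automatic addition to assessed monthly care need for persons with dementia.
DEMENTIA_PREMIUM_HOURS = 40.0


@dataclass(frozen=True)
class LevelRule:
    """Criteria and payout for one allowance level.

    ``min_hours`` is an exclusive lower bound by default (">65 h" style);
    ``required_flag`` is ``None`` for levels defined by hours alone.
    """

    level: int
    min_hours: float
    required_flag: str | None
    payout_eur: float

    def __post_init__(self) -> None:
        if self.min_hours < 0:
            raise ValueError(f"level {self.level}: negative hour bound")
        if self.required_flag is not None and self.required_flag not in QUALITATIVE_FLAGS:
            raise ValueError(f"level {self.level}: unknown flag {self.required_flag!r}")
        if self.payout_eur < 0:
            raise ValueError(f"level {self.level}: negative payout")

    @property
    def payout_cents(self) -> int:
        return round(self.payout_eur * 100)


@dataclass(frozen=True)
class AssessmentRuleTable:
    """The 7-level rule schedule.

    ``inclusive`` switches the hour comparison from strict (">65 h", the
    level criteria as printed) to weak ("at least 65 h").
    """

    rules: tuple[LevelRule, ...]
    inclusive: bool = False

    def __post_init__(self) -> None:
        levels = [r.level for r in self.rules]
        if levels != list(range(1, len(self.rules) + 1)):
            raise ValueError("rules must be consecutive levels starting at 1")
        hours = [r.min_hours for r in self.rules]
        if any(b < a for a, b in zip(hours, hours[1:])):
            raise ValueError("min_hours must be non-decreasing in level")
        pays = [r.payout_eur for r in self.rules]
        if any(b <= a for a, b in zip(pays, pays[1:])):
            raise ValueError("payout must be strictly increasing in level")

    @property
    def n_levels(self) -> int:
        return len(self.rules)

    def payout_cents(self, level: int) -> int:
        if level == 0:
            return 0
        if not 1 <= level <= self.n_levels:
            raise ValueError(f"level {level} out of range 0..{self.n_levels}")
        return self.rules[level - 1].payout_cents

    def payout_cents_vector(self):
        """Payout in integer cents indexed by level 0..7 (numpy array)."""
        import numpy as np

        return np.array([0] + [r.payout_cents for r in self.rules], dtype=np.int64)


#: 2025 schedule: hour thresholds 65/95/120/160/180 and EUR/month amounts.
DEFAULT_RULES = AssessmentRuleTable(
    rules=(
        LevelRule(1, 65.0, None, 200.80),
        LevelRule(2, 95.0, None, 370.30),
        LevelRule(3, 120.0, None, 577.00),
        LevelRule(4, 160.0, None, 865.10),
        LevelRule(5, 180.0, FLAG_EXTRAORDINARY, 1175.20),
        LevelRule(6, 180.0, FLAG_DAY_NIGHT, 1641.10),
        LevelRule(7, 180.0, FLAG_NO_MOVEMENT, 2156.60),
    )
)


@dataclass(frozen=True)
class CareNeed:
    """Assessed care need of one person before classification."""

    base_hours: float
    dementia: bool = False
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.base_hours < 0:
            raise ValueError("base_hours must be non-negative")
        unknown = set(self.flags) - set(QUALITATIVE_FLAGS)
        if unknown:
            raise ValueError(f"unknown qualitative flags: {sorted(unknown)}")


def total_hours(need: CareNeed) -> float:
    """Assessed monthly hours including the 40 h dementia premium."""
    return need.base_hours + (DEMENTIA_PREMIUM_HOURS if need.dementia else 0.0)


def classify_level(hours: float, flags=(), rules: AssessmentRuleTable = DEFAULT_RULES) -> int:
    """Classify assessed hours (+ qualitative flags) into level 0..7.

    Returns the highest level whose hour bound is met and whose required
    flag, if any, is present; 0 means no benefit. When several flagged
    levels qualify the highest wins.
    """
    if hours < 0:
        raise ValueError("hours must be non-negative")
    flags = frozenset(flags)
    unknown = flags - set(QUALITATIVE_FLAGS)
    if unknown:
        raise ValueError(f"unknown qualitative flags: {sorted(unknown)}")
    for rule in reversed(rules.rules):
        ok_hours = hours >= rule.min_hours if rules.inclusive else hours > rule.min_hours
        if ok_hours and (rule.required_flag is None or rule.required_flag in flags):
            return rule.level
    return 0


def payout(level: int, rules: AssessmentRuleTable = DEFAULT_RULES) -> float:
    """Monthly allowance in EUR for a level (0 pays nothing)."""
    return rules.payout_cents(level) / 100.0


def classify_need(need: CareNeed, rules: AssessmentRuleTable = DEFAULT_RULES) -> int:
    """Classify a :class:`CareNeed`, applying the dementia premium first."""
    return classify_level(total_hours(need), need.flags, rules)


def classify_levels(hours, flag_matrix=None, rules: AssessmentRuleTable = DEFAULT_RULES):
    """Vectorised classification of many assessed needs.

    ``flag_matrix`` is a boolean array of shape (n, 3) with columns ordered
    as :data:`QUALITATIVE_FLAGS`; ``None`` means no flags anywhere.
    """
    import numpy as np

    hours = np.asarray(hours, dtype=float)
    if np.any(hours < 0):
        raise ValueError("hours must be non-negative")
    if flag_matrix is None:
        flag_matrix = np.zeros((hours.shape[0], len(QUALITATIVE_FLAGS)), dtype=bool)
    flag_matrix = np.asarray(flag_matrix, dtype=bool)
    levels = np.zeros(hours.shape[0], dtype=np.int8)
    for rule in rules.rules:
        ok = hours >= rule.min_hours if rules.inclusive else hours > rule.min_hours
        if rule.required_flag is not None:
            ok &= flag_matrix[:, QUALITATIVE_FLAGS.index(rule.required_flag)]
        levels[ok] = rule.level
    return levels
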