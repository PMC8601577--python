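"""Item-level scoring rules, subtest accuracies and the GAQ composite.

Raw responses arrive as coder annotations (choice correctness for the
automatically scored comprehension subtests; error codes, criterion
booleans or rating scales for the expressive subtests).  Scoring turns
them into item points on each subtest's legal lattice, sums them into a
raw subtest total, expresses the total as percent of the maximum, and
averages the 13 subtest percentages into the General Aphasia Quotient
(GAQ).

Annotation semantics the engine relies on (they are coder-level
conventions, not recomputed here): only the final verbal response is
scored, self-corrections carry no penalty; a single requested repetition
of the stimulus carries no penalty; dysarthric distortions are never
penalized; the "more than half of the target spared and recognizable"
judgement behind a phonological-paraphasia code is the coder's.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .catalogue import SUBTEST_IDS, SUBTESTS, SubtestDefinition, get_subtest


class ScoringError(ValueError):
    """Raised when an annotation violates its subtest's scoring rule."""


#: Points per word-level code in sentence repetition.
SENTENCE_WORD_POINTS: dict[str, float] = {
    "correct": 1.0,
    "phonological_paraphasia": 0.5,
    "word_form_error": 0.5,
    "omission": 0.0,
    "other_error": 0.0,
}

#: Points per code in nonword/word repetition ("all other types of
#: errors" score 0, so a word-form error gets no half credit here).
REPETITION_POINTS: dict[str, float] = {
    "correct": 1.0,
    "phonological_paraphasia": 0.5,
    "word_form_error": 0.0,
    "omission": 0.0,
    "other_error": 0.0,
}

#: Coder codes for binary (choice/naming) items.
BINARY_CORRECT = frozenset({"correct"})
BINARY_INCORRECT = frozenset(
    {"incorrect", "phonological_paraphasia", "word_form_error", "omission",
     "other_error", "no_response"}
)


@dataclass(frozen=True)
class ItemAnnotation:
    """One coded response.  Exactly one payload variant must be set,
    matching the subtest's scoring rule."""

    subtest_id: str
    item_id: str
    correct: bool | None = None                      # binary choice / naming
    code: str | None = None                          # nonword/word repetition
    word_codes: tuple[str, ...] | None = None        # sentence repetition
    order_error: bool = False                        # sentence repetition
    criteria: tuple[bool, ...] | None = None         # sentence production
    ratings: tuple[int, ...] | None = None           # discourse production
    repetition_requested: bool = False               # allowed, no penalty


@dataclass(frozen=True)
class ItemScore:
    subtest_id: str
    item_id: str
    points: float
    max_points: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.points <= self.max_points):
            raise ScoringError(
                f"{self.subtest_id}/{self.item_id}: points {self.points} "
                f"outside [0, {self.max_points}]"
            )


@dataclass(frozen=True)
class SubtestResult:
    subtest_id: str
    raw_total: float
    max_total: float
    accuracy: float  # percent, full precision

    @property
    def accuracy2(self) -> float:
        """Accuracy rounded half-up to 2 decimals (presentation)."""
        return round2(self.accuracy)


@dataclass
class ParticipantProfile:
    participant_id: str
    group: str  # "NHI" | "PWA"
    age_cohort: str  # "young" | "elderly"
    subtest_results: dict[str, SubtestResult] = field(default_factory=dict)
    fluency_group: str | None = None
    gaq: float | None = None

    @property
    def accuracies(self) -> dict[str, float]:
        return {s: r.accuracy for s, r in self.subtest_results.items()}


def round2(x: float) -> float:
    """Round half-up to 2 decimals (23/24 -> 95.83, not banker's)."""
    return float(
        decimal.Decimal(repr(float(x))).quantize(
            decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP
        )
    )


def _require(condition: bool, ann: ItemAnnotation, message: str) -> None:
    if not condition:
        raise ScoringError(f"{ann.subtest_id}/{ann.item_id}: {message}")


def score_binary_item(ann: ItemAnnotation) -> ItemScore:
    """One point for a correct response, zero for any error type."""
    if ann.correct is None and ann.code is not None:
        if ann.code in BINARY_CORRECT:
            value = True
        elif ann.code in BINARY_INCORRECT:
            value = False
        else:
            raise ScoringError(
                f"{ann.subtest_id}/{ann.item_id}: unknown code {ann.code!r}"
            )
    else:
        _require(ann.correct is not None, ann, "binary item needs a correctness flag")
        value = bool(ann.correct)
    return ItemScore(ann.subtest_id, ann.item_id, 1.0 if value else 0.0, 1.0)


def score_repetition_item(ann: ItemAnnotation) -> ItemScore:
    """1 for correct, 0.5 for a phonological paraphasia, 0 otherwise."""
    _require(ann.code is not None, ann, "repetition item needs an error code")
    try:
        points = REPETITION_POINTS[ann.code]  # type: ignore[index]
    except KeyError:
        raise ScoringError(
            f"{ann.subtest_id}/{ann.item_id}: unknown repetition code {ann.code!r}"
        ) from None
    return ItemScore(ann.subtest_id, ann.item_id, points, 1.0)


def score_sentence_repetition(ann: ItemAnnotation) -> ItemScore:
    """Per-word credits minus a single order penalty, floored at 0.

    Every content and function word is coded separately: 1 point if
    correct, 0.5 for a phonological paraphasia or word-form error, 0
    for an omission or other error.  Any word-order alteration
    (regardless of how many) costs exactly one point.  The sentence
    maximum is its word count.
    """
    _require(bool(ann.word_codes), ann, "sentence repetition needs per-word codes")
    points = 0.0
    for code in ann.word_codes:  # type: ignore[union-attr]
        try:
            points += SENTENCE_WORD_POINTS[code]
        except KeyError:
            raise ScoringError(
                f"{ann.subtest_id}/{ann.item_id}: unknown word code {code!r}"
            ) from None
    if ann.order_error:
        points -= 1.0
    points = max(points, 0.0)
    return ItemScore(ann.subtest_id, ann.item_id, points, float(len(ann.word_codes)))


def score_sentence_production_item(ann: ItemAnnotation) -> ItemScore:
    """Number of the four phrase criteria met (0..4)."""
    _require(
        ann.criteria is not None and len(ann.criteria) == 4,
        ann,
        "sentence production needs exactly 4 criterion booleans",
    )
    return ItemScore(
        ann.subtest_id, ann.item_id, float(sum(bool(c) for c in ann.criteria)), 4.0
    )


def score_discourse_production(ann: ItemAnnotation) -> ItemScore:
    """Sum of four 5-point analytic ratings (4..20), higher is better."""
    _require(
        ann.ratings is not None and len(ann.ratings) == 4,
        ann,
        "discourse production needs exactly 4 ratings",
    )
    for r in ann.ratings:  # type: ignore[union-attr]
        _require(isinstance(r, int) and 1 <= r <= 5, ann, f"rating {r!r} outside 1..5")
    return ItemScore(ann.subtest_id, ann.item_id, float(sum(ann.ratings)), 20.0)


def score_discourse_comprehension(
    pair_responses: Sequence[Sequence[bool]],
    *,
    per_statement: bool = False,
) -> list[ItemScore]:
    """Score the story-verification subtest.

    ``pair_responses`` holds 8 pairs of per-statement correctness flags;
    the two statements of a pair probe the same story element.  In the
    default pair-gated mode one credit is awarded per pair only when
    both statements are correct (max 8) — the built-in safeguard against
    yes/no guessing.  ``per_statement=True`` instead credits each of the
    16 statements individually (max 16), mirroring the application's raw
    automatic log.
    """
    scores: list[ItemScore] = []
    for i, pair in enumerate(pair_responses, start=1):
        if len(pair) != 2:
            raise ScoringError(
                f"discourse_comprehension/pair{i}: expected 2 statements, "
                f"got {len(pair)}"
            )
        a, b = (bool(x) for x in pair)
        if per_statement:
            scores.append(
                ItemScore("discourse_comprehension", f"pair{i}", float(a) + float(b), 2.0)
            )
        else:
            scores.append(
                ItemScore("discourse_comprehension", f"pair{i}", float(a and b), 1.0)
            )
    return scores


_RULE_DISPATCH = {
    "binary": score_binary_item,
    "repetition": score_repetition_item,
    "sentence_repetition": score_sentence_repetition,
    "criteria4": score_sentence_production_item,
    "ratings4": score_discourse_production,
}


def score_item(ann: ItemAnnotation) -> ItemScore:
    """Dispatch an annotation to its subtest's scoring rule."""
    definition = get_subtest(ann.subtest_id)
    if definition.rule_id == "pair_gated":
        raise ScoringError(
            "discourse_comprehension is scored pairwise; use "
            "score_discourse_comprehension on the full statement list"
        )
    return _RULE_DISPATCH[definition.rule_id](ann)


def subtest_accuracy(
    scores: Iterable[ItemScore], definition: SubtestDefinition
) -> SubtestResult:
    """Percent of the maximum possible score over all defined items.

    Unattempted or abandoned items must be supplied as zero-point
    scores (they count as incorrect); the item count must match the
    catalogue definition.
    """
    scores = list(scores)
    if len(scores) != definition.n_items:
        raise ScoringError(
            f"{definition.subtest_id}: expected {definition.n_items} item "
            f"scores, got {len(scores)}"
        )
    wrong = [s.subtest_id for s in scores if s.subtest_id != definition.subtest_id]
    if wrong:
        raise ScoringError(
            f"{definition.subtest_id}: scores from foreign subtest {wrong[0]!r}"
        )
    raw = float(sum(s.points for s in scores))
    max_total = float(sum(s.max_points for s in scores))
    return SubtestResult(definition.subtest_id, raw, max_total, 100.0 * raw / max_total)


def compute_gaq(
    profile: ParticipantProfile | Mapping[str, float],
    proxy_subset: Sequence[str] | None = None,
) -> float:
    """Unweighted mean of subtest accuracy percentages.

    Default mode requires all 13 subtests (the GAQ is defined only when
    every subtest was administered, fully or partially); with
    ``proxy_subset`` an explicit named subset is averaged instead and
    the result is a GAQ-proxy.
    """
    accuracies: Mapping[str, float]
    if isinstance(profile, ParticipantProfile):
        accuracies = profile.accuracies
    else:
        accuracies = profile
    wanted = tuple(proxy_subset) if proxy_subset is not None else SUBTEST_IDS
    if proxy_subset is not None:
        unknown = [s for s in wanted if s not in SUBTESTS]
        if unknown:
            raise ScoringError(f"unknown subtests in proxy subset: {unknown}")
        if not wanted:
            raise ScoringError("proxy subset is empty")
    missing = [s for s in wanted if s not in accuracies]
    if missing:
        raise ScoringError(
            "GAQ requires accuracies for all requested subtests; missing: "
            + ", ".join(missing)
        )
    values = [float(accuracies[s]) for s in wanted]
    return float(sum(values)) / len(values)


def build_profile(
    participant_id: str,
    group: str,
    age_cohort: str,
    results: Mapping[str, SubtestResult],
    fluency_group: str | None = None,
) -> ParticipantProfile:
    """Assemble a profile; the GAQ is attached only when complete."""
    profile = ParticipantProfile(
        participant_id, group, age_cohort, dict(results), fluency_group
    )
    if all(s in results for s in SUBTEST_IDS):
        profile.gaq = compute_gaq(profile)
    return profile
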