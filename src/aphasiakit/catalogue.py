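"""Static catalogue of the 13 battery subtests.

Each subtest targets one linguistic level within one of three domains.
The catalogue records the item structure (item counts, per-item maxima,
scoring rule, score lattice) that the scoring engine, the normative
pipeline and the synthetic-cohort generator all share.

Scoring-rule tags:

``binary``
    One point per correct response, zero otherwise (all comprehension
    choice subtests and both naming subtests).
``repetition``
    1 / 0.5 / 0 per item: full credit, half credit for a phonological
    paraphasia, zero for any other error (nonword and word repetition).
``sentence_repetition``
    Per-word 1 / 0.5 / 0 credits summed over the sentence, minus a
    single one-point penalty if word order was altered anywhere.
``pair_gated``
    Discourse comprehension: 16 verification statements grouped into 8
    pairs about the same story element; one credit per pair only when
    both statements are answered correctly (a guessing safeguard).
``criteria4``
    Sentence production: four binary criteria (consistency with the
    prime, grammaticality, lexical-semantic adequacy, phrase
    appropriateness) summed to 0..4.
``ratings4``
    Discourse production: four 5-point analytic scales (fluency,
    grammatical complexity, paraphasias, informational content) summed
    to 4..20.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class SubtestDefinition:
    """Item structure of one subtest.

    Attributes
    ----------
    subtest_id : str
        Canonical snake_case identifier, unique in the catalogue.
    domain : str
        One of ``comprehension``, ``repetition``, ``production``.
    n_items : int
        Number of scored items (credit units).  For discourse
        comprehension this is the number of statement *pairs*.
    per_item_max : float | None
        Maximum points per item; ``None`` when the maximum varies by
        item (sentence repetition, where it equals the word count).
    rule_id : str
        Scoring-rule tag, see module docstring.
    lattice_step : float
        Smallest increment of the raw-score lattice (used for the
        "next achievable score" cutoff adjustment).
    item_maxima : tuple[float, ...]
        Per-item maxima.  For variable-maximum subtests this is the
        default template; real data may override it per transcript.
    """

    subtest_id: str
    domain: str
    n_items: int
    per_item_max: float | None
    rule_id: str
    lattice_step: float = 1.0
    item_maxima: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_items <= 0:
            raise ValueError(f"{self.subtest_id}: n_items must be positive")
        if not self.item_maxima:
            if self.per_item_max is None:
                raise ValueError(
                    f"{self.subtest_id}: variable-maximum subtest needs item_maxima"
                )
            object.__setattr__(
                self, "item_maxima", (float(self.per_item_max),) * self.n_items
            )
        if len(self.item_maxima) != self.n_items:
            raise ValueError(f"{self.subtest_id}: item_maxima length != n_items")
        if any(m <= 0 for m in self.item_maxima):
            raise ValueError(f"{self.subtest_id}: per-item maxima must be positive")

    @property
    def max_total(self) -> float:
        return float(sum(self.item_maxima))

    @property
    def min_total(self) -> float:
        """Lowest raw score reachable while the subtest is attempted.

        Zero everywhere except discourse production, whose four rating
        scales bottom out at 1 point each (raw 4 of 20).
        """
        return 4.0 if self.rule_id == "ratings4" else 0.0


COMPREHENSION = (
    "nonword_discrimination",
    "lexical_decision",
    "noun_comprehension",
    "verb_comprehension",
    "sentence_comprehension",
    "discourse_comprehension",
)
REPETITION = ("nonword_repetition", "word_repetition", "sentence_repetition")
PRODUCTION = (
    "object_naming",
    "action_naming",
    "sentence_production",
    "discourse_production",
)

# Default sentence-repetition template: six short sentences (3 words)
# and six long ones (5 words), raw maximum 48.  Real transcripts carry
# their own word counts.
_SENT_REP_WORDS = (3, 3, 3, 3, 3, 3, 5, 5, 5, 5, 5, 5)

SUBTESTS: dict[str, SubtestDefinition] = {
    d.subtest_id: d
    for d in (
        SubtestDefinition("nonword_discrimination", "comprehension", 22, 1, "binary"),
        SubtestDefinition("lexical_decision", "comprehension", 24, 1, "binary"),
        SubtestDefinition("noun_comprehension", "comprehension", 24, 1, "binary"),
        SubtestDefinition("verb_comprehension", "comprehension", 24, 1, "binary"),
        SubtestDefinition("sentence_comprehension", "comprehension", 24, 1, "binary"),
        SubtestDefinition("discourse_comprehension", "comprehension", 8, 1, "pair_gated"),
        SubtestDefinition("nonword_repetition", "repetition", 24, 1, "repetition", 0.5),
        SubtestDefinition("word_repetition", "repetition", 24, 1, "repetition", 0.5),
        SubtestDefinition(
            "sentence_repetition", "repetition", 12, None, "sentence_repetition",
            0.5, tuple(float(w) for w in _SENT_REP_WORDS),
        ),
        SubtestDefinition("object_naming", "production", 24, 1, "binary"),
        SubtestDefinition("action_naming", "production", 24, 1, "binary"),
        SubtestDefinition("sentence_production", "production", 24, 4, "criteria4"),
        SubtestDefinition("discourse_production", "production", 1, 20, "ratings4"),
    )
}

SUBTEST_IDS: tuple[str, ...] = tuple(SUBTESTS)

assert len(SUBTESTS) == 13

DOMAIN_OF: dict[str, str] = {s: SUBTESTS[s].domain for s in SUBTESTS}

#: Subtests scored by a human rater (expressive language); the
#: comprehension subtests are scored automatically by the tablet app.
EXPRESSIVE_SUBTESTS: tuple[str, ...] = REPETITION + PRODUCTION


def get_subtest(subtest_id: str) -> SubtestDefinition:
    try:
        return SUBTESTS[subtest_id]
    except KeyError:
        raise KeyError(
            f"unknown subtest {subtest_id!r}; expected one of {', '.join(SUBTESTS)}"
        ) from None
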