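"""Normative cutoffs, ROC-based diagnostic cutoff, severity bands.

Subtest cutoffs are the 5th percentile of the control (NHI) score
distribution, computed separately per age cohort after a one-pass
outlier screen; performance at or below the cutoff is abnormal.  The
diagnostic GAQ cutoff is chosen per cohort from a ROC scan maximizing
sensitivity + specificity (Youden-type), with "GAQ <= threshold" as the
positive (aphasia) call.  Severity bands (mild / moderate / severe) are
the 34th and 67th percentiles of the impaired patients' scores, pooled
across the two age cohorts; the bands are therefore shared while the
cutoffs stay cohort-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .catalogue import SubtestDefinition
from .scoring import ParticipantProfile, round2

#: numpy quantile method used throughout.  "linear" is the classical
#: type-7 interpolation between order statistics, the default of the
#: mainstream statistical environments; configurable because printed
#: per-subtest percentiles rarely pin the convention down.
DEFAULT_QUANTILE_METHOD = "linear"

SEVERITY_LEVELS = ("normal", "mild", "moderate", "severe")


class NormError(ValueError):
    """Raised on invalid inputs to the normative pipeline."""


@dataclass(frozen=True)
class NormEntry:
    """Cutoff and severity-band boundaries for one subtest (or the GAQ)
    in one age cohort.  All values are percent accuracies."""

    measure: str  # subtest_id or "gaq"
    age_cohort: str
    cutoff: float
    band_34: float
    band_67: float
    n_controls_used: int = 0
    n_outliers_removed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.band_34 <= self.band_67 <= self.cutoff <= 100.0):
            raise NormError(
                f"{self.measure}/{self.age_cohort}: need "
                f"0 <= band_34 <= band_67 <= cutoff <= 100, got "
                f"({self.band_34}, {self.band_67}, {self.cutoff})"
            )


@dataclass
class NormTable:
    """Complete set of norm entries plus provenance metadata."""

    entries: dict[tuple[str, str], NormEntry] = field(default_factory=dict)
    quantile_method: str = DEFAULT_QUANTILE_METHOD
    cohort_sizes: dict[str, int] = field(default_factory=dict)
    version: str = "1"

    def add(self, entry: NormEntry) -> None:
        self.entries[(entry.measure, entry.age_cohort)] = entry

    def get(self, measure: str, age_cohort: str) -> NormEntry:
        try:
            return self.entries[(measure, age_cohort)]
        except KeyError:
            raise NormError(f"no norm entry for {measure}/{age_cohort}") from None

    def has(self, measure: str, age_cohort: str) -> bool:
        return (measure, age_cohort) in self.entries


@dataclass(frozen=True)
class ROCResult:
    age_cohort: str
    thresholds: tuple[float, ...]
    sens: tuple[float, ...]
    spec: tuple[float, ...]
    selected_cutoff: float
    selected_sens: float
    selected_spec: float


@dataclass(frozen=True)
class ClassificationResult:
    participant_id: str
    subtest_status: dict[str, str]
    aphasia_flag: bool
    gaq_severity: str


def remove_norm_outliers(
    control_scores: Sequence[float],
) -> tuple[list[float], list[float]]:
    """One-pass outlier screen for control subtest scores.

    A score is removed iff it is below 90 percent AND more than three
    standard deviations below the cohort mean, where mean and SD come
    from the full input (no iteration).  This trims single aberrant
    control values without touching the genuinely imperfect tail.
    """
    scores = [float(s) for s in control_scores]
    if not scores:
        raise NormError("no control scores supplied")
    if len(scores) < 3:
        raise NormError("need at least 3 control scores for the outlier screen")
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1))
    kept, removed = [], []
    for s in scores:
        if s < 90.0 and (mean - s) > 3.0 * sd:
            removed.append(s)
        else:
            kept.append(s)
    return kept, removed


def next_achievable_below_max(definition: SubtestDefinition) -> float:
    """Largest accuracy strictly below 100% on the subtest's lattice.

    Binary 24-item subtest: 23/24 = 95.83%; half-point lattices lose
    half a point, rating scales one point, etc.
    """
    return 100.0 * (definition.max_total - definition.lattice_step) / definition.max_total


def compute_subtest_cutoff(
    kept_scores: Sequence[float],
    definition: SubtestDefinition,
    quantile_method: str = DEFAULT_QUANTILE_METHOD,
) -> float:
    """5th percentile of the (outlier-screened) control scores.

    If the percentile equals the subtest maximum — as happens when at
    least 95% of controls are at ceiling — even a perfect score would
    be flagged, so the cutoff is adjusted down to the next achievable
    score on the subtest's lattice.
    """
    scores = np.asarray(kept_scores, dtype=float)
    if scores.size < 2:
        raise NormError(
            f"{definition.subtest_id}: need at least 2 control scores for a cutoff"
        )
    cutoff = float(np.quantile(scores, 0.05, method=quantile_method))
    if cutoff >= 100.0:
        cutoff = next_achievable_below_max(definition)
    return cutoff


def classify_subtest_performance(accuracy: float, cutoff: float) -> bool:
    """True (impaired) iff performance is at or below the cutoff."""
    return accuracy <= cutoff


def fit_roc(
    gaq_nhi: Sequence[float], gaq_pwa: Sequence[float], age_cohort: str = ""
) -> ROCResult:
    """ROC scan over GAQ thresholds for one age cohort.

    Candidate thresholds are the midpoints between consecutive distinct
    pooled GAQ values plus -inf/+inf sentinels; a participant is called
    positive (aphasia) when GAQ <= threshold.  The selected cutoff
    maximizes sensitivity + specificity; ties break toward the larger
    threshold (favoring sensitivity at matched sums).  No outlier
    removal is applied: the GAQ averages 13 subtests and is not
    derailed by single aberrant subtest values.
    """
    nhi = np.asarray(gaq_nhi, dtype=float)
    pwa = np.asarray(gaq_pwa, dtype=float)
    if nhi.size == 0 or pwa.size == 0:
        raise NormError("fit_roc needs non-empty NHI and PWA GAQ samples")
    pooled = np.unique(np.concatenate([nhi, pwa]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(pwa <= t).mean() for t in thresholds])
    spec = np.array([(nhi > t).mean() for t in thresholds])
    total = sens + spec
    # argmax of sens+spec; ties (within float noise) -> larger threshold
    best = int(np.flatnonzero(total >= total.max() - 1e-9)[-1])
    return ROCResult(
        age_cohort,
        tuple(thresholds),
        tuple(sens),
        tuple(spec),
        float(thresholds[best]),
        float(sens[best]),
        float(spec[best]),
    )


def evaluate_classifier(
    gaq_values: Sequence[float], labels: Sequence[str], cutoff: float
) -> tuple[float, float, dict[str, int]]:
    """Sensitivity/specificity of the rule "GAQ <= cutoff => aphasia".

    Sensitivity = TP/(TP+FN) over PWA; specificity = TN/(TN+FP) over
    NHI.  Returns the confusion counts as well.
    """
    gaq = np.asarray(gaq_values, dtype=float)
    lab = np.asarray(labels)
    if gaq.shape != lab.shape:
        raise NormError("gaq_values and labels must have equal length")
    bad = set(np.unique(lab)) - {"NHI", "PWA"}
    if bad:
        raise NormError(f"labels must be NHI/PWA, found {sorted(bad)}")
    positive = gaq <= cutoff
    is_pwa = lab == "PWA"
    tp = int(np.sum(positive & is_pwa))
    fn = int(np.sum(~positive & is_pwa))
    fp = int(np.sum(positive & ~is_pwa))
    tn = int(np.sum(~positive & ~is_pwa))
    if tp + fn == 0 or tn + fp == 0:
        raise NormError("both NHI and PWA labels must be present")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return sens, spec, {"tp": tp, "fn": fn, "fp": fp, "tn": tn}


def derive_severity_bands(
    impaired_scores: Sequence[float],
    quantile_method: str = DEFAULT_QUANTILE_METHOD,
) -> tuple[float, float]:
    """34th and 67th percentiles of impaired patients' scores.

    The input must already be restricted to performances at or below
    the cutoff on that measure, pooled across both age cohorts (pooling
    increases sample size and washes out the cohorts' imbalance in
    aphasia types).
    """
    scores = np.asarray(impaired_scores, dtype=float)
    if scores.size < 3:
        raise NormError(
            "need at least 3 impaired scores to place severity bands; "
            "collect more impaired performances or skip banding for this measure"
        )
    band_34 = float(np.quantile(scores, 0.34, method=quantile_method))
    band_67 = float(np.quantile(scores, 0.67, method=quantile_method))
    return band_34, band_67


def assign_severity(accuracy: float, norm: NormEntry) -> str:
    """Map an accuracy onto the four-way severity partition.

    normal:   X > cutoff
    mild:     band_67 <= X <= cutoff
    moderate: band_34 <  X <  band_67
    severe:   0 <= X <= band_34

    When band_34 == band_67 the moderate interval is empty and scores
    at the shared value are severe (the "at or below band_34" rule has
    precedence).
    """
    x = float(accuracy)
    if x > norm.cutoff:
        return "normal"
    if x <= norm.band_34:
        return "severe"
    if x < norm.band_67:
        return "moderate"
    return "mild"


def build_norm_table(
    control_profiles: Iterable[ParticipantProfile],
    pwa_profiles: Iterable[ParticipantProfile],
    definitions: Mapping[str, SubtestDefinition],
    quantile_method: str = DEFAULT_QUANTILE_METHOD,
) -> tuple[NormTable, dict[str, ROCResult]]:
    """Derive the full norm table from scored cohorts.

    Per subtest and age cohort: outlier screen on controls, 5th
    percentile cutoff (with ceiling adjustment).  Per age cohort: ROC
    scan on the GAQ.  Severity bands per measure from the pooled
    impaired PWA scores.  Returns the table plus the per-cohort ROC
    results.
    """
    controls = list(control_profiles)
    patients = list(pwa_profiles)
    cohorts = sorted({p.age_cohort for p in controls})
    table = NormTable(quantile_method=quantile_method)
    table.cohort_sizes = {c: sum(p.age_cohort == c for p in controls) for c in cohorts}

    cutoffs: dict[tuple[str, str], float] = {}
    removed_counts: dict[tuple[str, str], int] = {}
    used_counts: dict[tuple[str, str], int] = {}
    for subtest_id, definition in definitions.items():
        for cohort in cohorts:
            scores = [
                p.subtest_results[subtest_id].accuracy
                for p in controls
                if p.age_cohort == cohort and subtest_id in p.subtest_results
            ]
            kept, removed = remove_norm_outliers(scores)
            cutoffs[(subtest_id, cohort)] = compute_subtest_cutoff(
                kept, definition, quantile_method
            )
            removed_counts[(subtest_id, cohort)] = len(removed)
            used_counts[(subtest_id, cohort)] = len(kept)

    roc_results: dict[str, ROCResult] = {}
    for cohort in cohorts:
        nhi_gaq = [p.gaq for p in controls if p.age_cohort == cohort and p.gaq is not None]
        pwa_gaq = [p.gaq for p in patients if p.age_cohort == cohort and p.gaq is not None]
        roc_results[cohort] = fit_roc(nhi_gaq, pwa_gaq, cohort)
        cutoffs[("gaq", cohort)] = roc_results[cohort].selected_cutoff
        used_counts[("gaq", cohort)] = len(nhi_gaq)
        removed_counts[("gaq", cohort)] = 0

    for measure in list(definitions) + ["gaq"]:
        impaired: list[float] = []
        for p in patients:
            if measure == "gaq":
                x = p.gaq
            else:
                r = p.subtest_results.get(measure)
                x = r.accuracy if r is not None else None
            if x is not None and x <= cutoffs[(measure, p.age_cohort)]:
                impaired.append(x)
        band_34, band_67 = derive_severity_bands(impaired, quantile_method)
        for cohort in cohorts:
            cutoff = cutoffs[(measure, cohort)]
            table.add(
                NormEntry(
                    measure,
                    cohort,
                    cutoff,
                    min(band_34, cutoff),
                    min(band_67, cutoff),
                    used_counts[(measure, cohort)],
                    removed_counts[(measure, cohort)],
                )
            )
    return table, roc_results


def classify_profile(
    profile: ParticipantProfile, table: NormTable
) -> ClassificationResult:
    """Per-subtest severity labels plus the GAQ-based aphasia call."""
    cohort = profile.age_cohort
    status: dict[str, str] = {}
    for subtest_id, result in profile.subtest_results.items():
        status[subtest_id] = assign_severity(
            result.accuracy, table.get(subtest_id, cohort)
        )
    if profile.gaq is None:
        raise NormError(
            f"{profile.participant_id}: GAQ unavailable (incomplete battery); "
            "aphasia classification requires all 13 subtests"
        )
    gaq_norm = table.get("gaq", cohort)
    gaq_severity = assign_severity(profile.gaq, gaq_norm)
    return ClassificationResult(
        profile.participant_id,
        status,
        aphasia_flag=profile.gaq <= gaq_norm.cutoff,
        gaq_severity=gaq_severity,
    )


def presentation_cutoff(cutoff: float) -> float:
    """Cutoffs are printed to two decimals (e.g. 23/24 -> 95.83)."""
    return round2(cutoff)
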