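"""Synthetic NHI/PWA cohorts with the battery's statistical structure.

A single latent language ability theta drives every subtest (the
battery's strong inter-subtest correlations justify one dominant
factor).  Binary items follow a two-parameter logistic model with a
guessing floor at the task's chance level; multi-point items use nested
step thresholds (an adjacent-category-style graded model) sharing one
uniform draw per credit unit, which keeps every score on the legal
lattice and monotone in theta.

Defaults are the study conditions: cohort sizes 69/37 young/elderly
controls and 44/41 young/elderly patients; patient theta ~ N(0, 1);
control theta ~ N(3.3, 0.45); per-subtest difficulty centers are solved
numerically so the patients' mean item passing rates land at the
subtest-family levels a standardization cohort exhibits (comprehension
well above repetition, repetition above production); an elderly
difficulty shift is applied to controls on the four phonology/
memory-loaded subtests that show age effects (discourse comprehension,
nonword repetition, sentence repetition, sentence production).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .catalogue import (
    EXPRESSIVE_SUBTESTS,
    SUBTEST_IDS,
    SUBTESTS,
    SubtestDefinition,
)
from .scoring import ParticipantProfile, SubtestResult, build_profile

__all__ = [
    "CohortSpec",
    "RaterModel",
    "SyntheticDataset",
    "simulate_nhi",
    "simulate_pwa",
    "simulate_cohorts",
    "simulate_raters",
    "simulate_retest",
    "simulate_concurrent_severity",
]


class SimulationError(ValueError):
    pass


# ------------------------------------------------------------- spec

@dataclass(frozen=True)
class SubtestSim:
    """Generative parameters for one subtest.

    ``a`` is the discrimination (slope on the latent scale), ``guess``
    the chance-level floor of the response format, ``pwa_target`` the
    mean normalized passing rate the patient population should show,
    ``spread`` the half-range of item difficulties around the solved
    center, ``elderly_shift`` the extra difficulty for elderly
    controls (0 where no age effect is modelled).
    """

    a: float
    guess: float
    pwa_target: float
    spread: float
    elderly_shift: float = 0.0


def _default_subtest_sims() -> dict[str, SubtestSim]:
    # Discrimination is high for choice comprehension tasks (near-
    # ceiling controls, steep group separation) and lower for the
    # discourse tasks, which stay off-ceiling even in controls.
    return {
        "nonword_discrimination": SubtestSim(1.8, 0.50, 0.85, 0.8),
        "lexical_decision":       SubtestSim(1.8, 0.50, 0.88, 0.8),
        "noun_comprehension":     SubtestSim(2.2, 0.25, 0.93, 0.6),
        "verb_comprehension":     SubtestSim(2.2, 0.25, 0.92, 0.6),
        "sentence_comprehension": SubtestSim(1.6, 0.50, 0.82, 0.8),
        "discourse_comprehension": SubtestSim(0.35, 0.50, 0.78, 0.4, 0.6),
        "nonword_repetition":     SubtestSim(1.4, 0.0, 0.55, 0.9, 0.35),
        "word_repetition":        SubtestSim(1.5, 0.0, 0.72, 0.9),
        "sentence_repetition":    SubtestSim(1.3, 0.0, 0.60, 0.6, 0.3),
        "object_naming":          SubtestSim(1.5, 0.0, 0.62, 1.0),
        "action_naming":          SubtestSim(1.5, 0.0, 0.58, 1.0),
        "sentence_production":    SubtestSim(0.9, 0.0, 0.50, 0.7, 0.3),
        "discourse_production":   SubtestSim(0.7, 0.0, 0.55, 0.0),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for synthetic control/patient cohorts.

    The seed is mandatory: identical (spec, seed) must regenerate the
    dataset byte-identically.
    """

    seed: int
    n_nhi_young: int = 69
    n_nhi_elderly: int = 37
    n_pwa_young: int = 44
    n_pwa_elderly: int = 41
    pwa_theta_mean: float = 0.0
    pwa_theta_sd: float = 1.0
    nhi_theta_mean: float = 3.3
    nhi_theta_sd: float = 0.45
    #: reference patient population the item difficulties are calibrated
    #: against.  Fixed at the main standardization cohort's severity
    #: distribution so that item parameters are properties of the test:
    #: drawing a milder or more severe sample (e.g. a chronic retest
    #: group) does not silently re-calibrate the items.
    calibration_theta_mean: float = 0.0
    calibration_theta_sd: float = 1.0
    subtest_sims: Mapping[str, SubtestSim] = field(
        default_factory=_default_subtest_sims
    )

    def __post_init__(self) -> None:
        for n in (self.n_nhi_young, self.n_nhi_elderly, self.n_pwa_young,
                  self.n_pwa_elderly):
            if n < 0:
                raise SimulationError("cohort sizes must be non-negative")
        if self.pwa_theta_sd <= 0 or self.nhi_theta_sd <= 0:
            raise SimulationError("theta scales must be positive")
        missing = set(SUBTEST_IDS) - set(self.subtest_sims)
        if missing:
            raise SimulationError(f"subtest_sims missing entries: {sorted(missing)}")
        for s, sim in self.subtest_sims.items():
            if sim.a <= 0:
                raise SimulationError(f"{s}: discrimination must be positive")
            if not (0 < sim.pwa_target < 1):
                raise SimulationError(f"{s}: pwa_target must be in (0, 1)")


@dataclass(frozen=True)
class RaterModel:
    """Second-rater perturbation of expressive item scores."""

    rater_sd: float = 0.25          # points of per-item noise before snapping
    systematic_shift: float = 0.0   # points, positive = rater 2 more lenient
    discourse_scale_sd: float = 0.8  # noise on the 4..20 discourse total

    def __post_init__(self) -> None:
        if self.rater_sd < 0 or self.discourse_scale_sd < 0:
            raise SimulationError("rater SDs must be non-negative")


# ----------------------------------------------- calibration machinery

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(61)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()

#: half-gap between the half-credit and full-credit thresholds of
#: 0/0.5/1 repetition lattices
_HALF_STEP = 0.7
#: step offsets of 4-step graded units (criteria, rating scales)
_STEP_OFFSETS = np.array([-0.9, -0.3, 0.3, 0.9])
#: scale offsets of the four discourse-production rating scales
_SCALE_OFFSETS = np.array([-0.45, -0.15, 0.15, 0.45])
#: word-order-error model for sentence repetition
_ORDER_MAX, _ORDER_SLOPE, _ORDER_CENTER = 0.30, 1.0, -0.5
#: extra word difficulty of long (5-word) vs short (3-word) sentences
_LENGTH_SHIFT = 0.6

_calibration_cache: dict[tuple, float] = {}


def _theta_grid(mean: float, sd: float) -> tuple[np.ndarray, np.ndarray]:
    return mean + sd * _GH_NODES, _GH_WEIGHTS


def _item_difficulties(center: float, spread: float, n: int) -> np.ndarray:
    if n == 1:
        return np.array([center])
    return center + spread * np.linspace(-1.0, 1.0, n)


def _expected_rate(subtest_id: str, sim: SubtestSim, center: float,
                   theta: np.ndarray, w: np.ndarray) -> float:
    """Population mean normalized passing rate for a difficulty center."""
    d = SUBTESTS[subtest_id]
    if d.rule_id == "binary":
        b = _item_difficulties(center, sim.spread, d.n_items)
        p = sim.guess + (1 - sim.guess) * expit(sim.a * (theta[:, None] - b))
        return float((w @ p).mean())
    if d.rule_id == "repetition":
        b = _item_difficulties(center, sim.spread, d.n_items)
        p = 0.5 * expit(sim.a * (theta[:, None] - b + _HALF_STEP)) \
            + 0.5 * expit(sim.a * (theta[:, None] - b - _HALF_STEP))
        return float((w @ p).mean())
    if d.rule_id == "sentence_repetition":
        # calibrated on word credits; the order penalty is compensated
        # by the target inflation applied by the caller
        b = _sentence_word_difficulties(center, sim.spread)
        p = 0.5 * expit(sim.a * (theta[:, None] - b + _HALF_STEP)) \
            + 0.5 * expit(sim.a * (theta[:, None] - b - _HALF_STEP))
        return float((w @ p).mean())
    if d.rule_id == "criteria4":
        b = _item_difficulties(center, sim.spread, d.n_items)
        th = theta[:, None, None] - b[None, :, None] - _STEP_OFFSETS[None, None, :]
        return float((w @ expit(sim.a * th).mean(axis=(1, 2))))
    if d.rule_id == "ratings4":
        th = (theta[:, None, None] - center - _SCALE_OFFSETS[None, :, None]
              - _STEP_OFFSETS[None, None, :])
        step_mean = expit(sim.a * th).mean(axis=(1, 2))
        return float(w @ (4 + 16 * step_mean) / 20.0)
    if d.rule_id == "pair_gated":
        b = _item_difficulties(center, sim.spread, d.n_items)  # per pair
        p = sim.guess + (1 - sim.guess) * expit(sim.a * (theta[:, None] - b))
        return float((w @ (p**2)).mean())
    raise SimulationError(f"no generative rule for {d.rule_id}")


def _sentence_word_difficulties(center: float, spread: float) -> np.ndarray:
    """Flat vector of word difficulties across the 12 sentences."""
    d = SUBTESTS["sentence_repetition"]
    parts = []
    sent_shift = _item_difficulties(0.0, spread, d.n_items)
    for i, wc in enumerate(d.item_maxima):
        shift = _LENGTH_SHIFT if wc > 3 else 0.0
        parts.append(np.full(int(wc), center + sent_shift[i] + shift))
    return np.concatenate(parts)


def _solve_center(subtest_id: str, sim: SubtestSim, spec: CohortSpec) -> float:
    """Difficulty center hitting the patient-population target rate."""
    target = sim.pwa_target
    mean, sd = spec.calibration_theta_mean, spec.calibration_theta_sd
    if subtest_id == "sentence_repetition":
        # inflate the word-credit target to absorb the expected order
        # penalty drag (~1 point out of ~4 per affected sentence)
        theta, w = _theta_grid(mean, sd)
        p_ord = float(w @ (_ORDER_MAX * expit(-_ORDER_SLOPE * (theta - _ORDER_CENTER))))
        target = min(0.98, target + p_ord / 4.0)
    key = (subtest_id, sim, mean, sd, target)
    if key in _calibration_cache:
        return _calibration_cache[key]
    theta, w = _theta_grid(mean, sd)

    def gap(center: float) -> float:
        return _expected_rate(subtest_id, sim, center, theta, w) - target

    center = float(brentq(gap, -25.0, 25.0, xtol=1e-8))
    _calibration_cache[key] = center
    return center


# ------------------------------------------------------------ dataset

@dataclass
class SyntheticDataset:
    """Item-level scores plus generation metadata.

    ``scores[s]`` is an (n_participants x n_items) matrix of item
    points on subtest ``s``'s lattice; ``detail`` keeps the richer
    structures (per-word credits, criteria, ratings, statements) that
    item points are derived from, so trial-level exports are faithful.
    """

    spec: CohortSpec
    participants: pd.DataFrame  # participant_id, group, age_cohort, theta
    scores: dict[str, np.ndarray]
    detail: dict[str, dict]
    version: str = "1"

    @property
    def n(self) -> int:
        return len(self.participants)

    def accuracies(self) -> pd.DataFrame:
        """Percent accuracy per participant x subtest."""
        data = {
            s: 100.0 * self.scores[s].sum(axis=1) / SUBTESTS[s].max_total
            for s in SUBTEST_IDS
        }
        return pd.DataFrame(data, index=self.participants["participant_id"])

    def gaq(self) -> pd.Series:
        return self.accuracies().mean(axis=1).rename("gaq")

    def profiles(self) -> list[ParticipantProfile]:
        acc = self.accuracies()
        out = []
        for i, row in self.participants.iterrows():
            pid = row["participant_id"]
            results = {
                s: SubtestResult(
                    s,
                    float(self.scores[s][i].sum()),
                    SUBTESTS[s].max_total,
                    float(acc.loc[pid, s]),
                )
                for s in SUBTEST_IDS
            }
            out.append(build_profile(pid, row["group"], row["age_cohort"], results))
        return out

    def subset(self, mask: np.ndarray) -> "SyntheticDataset":
        idx = np.flatnonzero(mask)
        return SyntheticDataset(
            self.spec,
            self.participants.iloc[idx].reset_index(drop=True),
            {s: m[idx] for s, m in self.scores.items()},
            _subset_detail(self.detail, idx),
            self.version,
        )


def _subset_detail(detail: dict[str, dict], idx: np.ndarray) -> dict[str, dict]:
    out: dict[str, dict] = {}
    for s, d in detail.items():
        out[s] = {k: (v[idx] if isinstance(v, np.ndarray) else v) for k, v in d.items()}
    return out


# ----------------------------------------------------------- generation

def _draw_subtest(
    subtest_id: str,
    sim: SubtestSim,
    center: float,
    theta: np.ndarray,
    shift: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Draw item scores for all participants of one group-cohort.

    ``shift`` is a per-participant extra difficulty (elderly penalty).
    Returns the (n x n_items) points matrix and the detail dict.
    """
    d = SUBTESTS[subtest_id]
    n = theta.size
    eff = (theta - shift)[:, None]
    if d.rule_id == "binary":
        b = _item_difficulties(center, sim.spread, d.n_items)
        p = sim.guess + (1 - sim.guess) * expit(sim.a * (eff - b))
        correct = rng.random((n, d.n_items)) < p
        return correct.astype(float), {"correct": correct}
    if d.rule_id == "repetition":
        b = _item_difficulties(center, sim.spread, d.n_items)
        p_half = expit(sim.a * (eff - b + _HALF_STEP))
        p_full = expit(sim.a * (eff - b - _HALF_STEP))
        u = rng.random((n, d.n_items))
        pts = 0.5 * (u < p_half) + 0.5 * (u < p_full)
        return pts, {"points": pts}
    if d.rule_id == "sentence_repetition":
        b = _sentence_word_difficulties(center, sim.spread)
        p_half = expit(sim.a * (eff - b + _HALF_STEP))
        p_full = expit(sim.a * (eff - b - _HALF_STEP))
        u = rng.random((n, b.size))
        word_pts = 0.5 * (u < p_half) + 0.5 * (u < p_full)
        p_ord = _ORDER_MAX * expit(-_ORDER_SLOPE * (theta - shift - _ORDER_CENTER))
        order = rng.random((n, d.n_items)) < p_ord[:, None]
        bounds = np.cumsum([0] + [int(w) for w in d.item_maxima])
        pts = np.empty((n, d.n_items))
        for i in range(d.n_items):
            s = word_pts[:, bounds[i]:bounds[i + 1]].sum(axis=1)
            pts[:, i] = np.maximum(s - order[:, i], 0.0)
        return pts, {"word_points": word_pts, "order": order, "bounds": bounds}
    if d.rule_id == "criteria4":
        b = _item_difficulties(center, sim.spread, d.n_items)
        th = eff[:, :, None] - b[None, :, None] - _STEP_OFFSETS[None, None, :]
        u = rng.random((n, d.n_items, 1))
        met = u < expit(sim.a * th)
        return met.sum(axis=2).astype(float), {"criteria": met}
    if d.rule_id == "ratings4":
        th = (eff[:, :, None] - center - _SCALE_OFFSETS[None, :, None]
              - _STEP_OFFSETS[None, None, :])
        u = rng.random((n, 4, 1))
        ratings = 1 + (u < expit(sim.a * th)).sum(axis=2)
        return ratings.sum(axis=1, keepdims=True).astype(float), {"ratings": ratings}
    if d.rule_id == "pair_gated":
        b = _item_difficulties(center, sim.spread, d.n_items)
        p = sim.guess + (1 - sim.guess) * expit(sim.a * (eff - b))
        stmts = rng.random((n, d.n_items, 2)) < p[:, :, None]
        credits = stmts.all(axis=2).astype(float)
        return credits, {"statements": stmts}
    raise SimulationError(f"no generative rule for {d.rule_id}")


_GROUP_CODE = {"NHI": 1, "PWA": 2}
_COHORT_CODE = {"young": 1, "elderly": 2}
_ELDERLY_SUBTESTS = frozenset(
    {"discourse_comprehension", "nonword_repetition", "sentence_repetition",
     "sentence_production"}
)


def _simulate_group(
    spec: CohortSpec,
    group: str,
    stream: int = 0,
    theta_override: np.ndarray | None = None,
    participant_groups: np.ndarray | None = None,
    participant_cohorts: np.ndarray | None = None,
) -> SyntheticDataset:
    """Draw one group's item data.

    Randomness is split into sub-streams: theta has its own stream per
    group-cohort, and every subtest draws from an item stream keyed by
    (seed, group, cohort, stream, subtest index).  Session-2 data can
    therefore either reuse the session-1 item stream (``stream=0``,
    isolating the theta shift) or use a fresh one (``stream=1``).
    """
    frames, scores_parts, detail_parts = [], {s: [] for s in SUBTEST_IDS}, {}
    for cohort in ("young", "elderly"):
        n = {
            ("NHI", "young"): spec.n_nhi_young,
            ("NHI", "elderly"): spec.n_nhi_elderly,
            ("PWA", "young"): spec.n_pwa_young,
            ("PWA", "elderly"): spec.n_pwa_elderly,
        }[(group, cohort)]
        if n == 0:
            continue
        gc, cc = _GROUP_CODE[group], _COHORT_CODE[cohort]
        rng_theta = np.random.default_rng(
            np.random.SeedSequence([spec.seed, gc, cc, 7])
        )
        if group == "PWA":
            theta = rng_theta.normal(spec.pwa_theta_mean, spec.pwa_theta_sd, n)
        else:
            theta = rng_theta.normal(spec.nhi_theta_mean, spec.nhi_theta_sd, n)
        if theta_override is not None:
            theta = theta_override[
                (participant_groups == group) & (participant_cohorts == cohort)
            ]
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": [
                        f"{group}-{cohort[0]}{i + 1:04d}" for i in range(n)
                    ],
                    "group": group,
                    "age_cohort": cohort,
                    "theta": theta,
                }
            )
        )
        for idx, s in enumerate(SUBTEST_IDS):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, gc, cc, stream, idx])
            )
            sim = spec.subtest_sims[s]
            center = _solve_center(s, sim, spec)
            if group == "NHI" and cohort == "elderly" and s in _ELDERLY_SUBTESTS:
                shift = np.full(n, sim.elderly_shift)
            else:
                shift = np.zeros(n)
            pts, det = _draw_subtest(s, sim, center, theta, shift, rng)
            scores_parts[s].append(pts)
            detail_parts.setdefault(s, []).append(det)

    if not frames:
        raise SimulationError(f"spec defines no {group} participants")
    participants = pd.concat(frames, ignore_index=True)
    scores = {s: np.concatenate(scores_parts[s], axis=0) for s in SUBTEST_IDS}
    detail: dict[str, dict] = {}
    for s, parts in detail_parts.items():
        merged: dict = {}
        for k in parts[0]:
            if k == "bounds":
                merged[k] = parts[0][k]
            else:
                merged[k] = np.concatenate([p[k] for p in parts], axis=0)
        detail[s] = merged
    return SyntheticDataset(spec, participants, scores, detail)


def simulate_nhi(spec: CohortSpec) -> SyntheticDataset:
    """Generate the neurologically healthy control cohorts (near
    ceiling on most subtests; off-ceiling on the discourse tasks and
    sentence production; elderly penalty on the four age-sensitive
    subtests)."""
    return _simulate_group(spec, "NHI")


def simulate_pwa(spec: CohortSpec) -> SyntheticDataset:
    """Generate the patient cohorts along a latent severity gradient."""
    return _simulate_group(spec, "PWA")


def simulate_cohorts(spec: CohortSpec) -> tuple[SyntheticDataset, SyntheticDataset]:
    return simulate_nhi(spec), simulate_pwa(spec)


# -------------------------------------------------- raters and retest

def _snap_to_lattice(x: np.ndarray, step: float, lo: float, hi: float) -> np.ndarray:
    return np.clip(np.round(x / step) * step, lo, hi)


def simulate_raters(
    dataset: SyntheticDataset,
    rater_model: RaterModel,
    subtests: tuple[str, ...] = EXPRESSIVE_SUBTESTS,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Second-rater scores for the expressive subtests.

    Comprehension subtests are scored automatically by the application,
    so requesting rater noise on them is an error.  The second rater's
    item scores are the first rater's perturbed by Gaussian noise (plus
    a systematic shift) and snapped back to the legal lattice.
    """
    for s in subtests:
        if SUBTESTS[s].domain == "comprehension":
            raise SimulationError(
                f"{s} is scored automatically; inter-rater noise applies only "
                "to expressive (repetition/production) subtests"
            )
    rng = np.random.default_rng(
        np.random.SeedSequence([dataset.spec.seed if seed is None else seed, 91])
    )
    out: dict[str, np.ndarray] = {}
    for s in subtests:
        d = SUBTESTS[s]
        first = dataset.scores[s]
        if d.rule_id == "ratings4":
            noise = rng.normal(
                rater_model.systematic_shift, rater_model.discourse_scale_sd,
                first.shape,
            )
            out[s] = _snap_to_lattice(first + noise, 1.0, 4.0, 20.0)
        else:
            noise = rng.normal(
                rater_model.systematic_shift, rater_model.rater_sd, first.shape
            )
            maxima = np.asarray(d.item_maxima)
            out[s] = _snap_to_lattice(first + noise, d.lattice_step, 0.0, maxima)
    return out


def simulate_retest(
    dataset: SyntheticDataset,
    session_sd: float = 0.15,
    item_stream: int = 1,
    chronic: bool = True,
) -> SyntheticDataset:
    """Session-2 dataset: theta' = theta + N(0, session_sd), items
    regenerated.  Requires the chronic-phase stability assumption (no
    treatment or spontaneous recovery between sessions).

    ``item_stream=0`` reuses the session-1 item stream, so with
    ``session_sd=0`` the second session reproduces the first exactly;
    the default fresh stream models independent sessions.
    """
    if not chronic:
        raise SimulationError(
            "retest simulation assumes a chronic, stable phase; score change "
            "under treatment is out of scope"
        )
    if session_sd < 0:
        raise SimulationError("session_sd must be non-negative")
    rng = np.random.default_rng(
        np.random.SeedSequence([dataset.spec.seed, 92, item_stream])
    )
    theta2 = dataset.participants["theta"].to_numpy() + rng.normal(
        0.0, session_sd, dataset.n
    )
    groups = dataset.participants["group"].to_numpy()
    cohorts = dataset.participants["age_cohort"].to_numpy()
    parts = []
    for group in pd.unique(dataset.participants["group"]):
        parts.append(
            _simulate_group(
                dataset.spec, group, stream=item_stream,
                theta_override=theta2, participant_groups=groups,
                participant_cohorts=cohorts,
            )
        )
    if len(parts) == 1:
        session2 = parts[0]
    else:
        merged_participants = pd.concat(
            [p.participants for p in parts], ignore_index=True
        )
        session2 = SyntheticDataset(
            dataset.spec,
            merged_participants,
            {
                s: np.concatenate([p.scores[s] for p in parts], axis=0)
                for s in SUBTEST_IDS
            },
            {
                s: {
                    k: (
                        np.concatenate([p.detail[s][k] for p in parts], axis=0)
                        if k != "bounds"
                        else parts[0].detail[s][k]
                    )
                    for k in parts[0].detail[s]
                }
                for s in SUBTEST_IDS
            },
        )
    if not np.array_equal(
        session2.participants["participant_id"].to_numpy(),
        dataset.participants["participant_id"].to_numpy(),
    ):
        raise SimulationError(
            "retest regeneration requires an unmodified group dataset "
            "(participant order must match the generator's)"
        )
    return session2


def simulate_concurrent_severity(
    dataset: SyntheticDataset,
    target_r: float = 0.925,
    seed: int | None = None,
) -> pd.Series:
    """External severity totals (an ASA-like 0-100 score) for patients.

    The external total is a monotone logistic transform of the latent
    trait plus Gaussian noise whose variance is calibrated from sample
    moments so that corr(GAQ, external) ~ target_r at the dataset's
    size.
    """
    if not (0.0 < target_r < 1.0):
        raise SimulationError("target_r must be in (0, 1)")
    pwa = dataset.participants["group"] == "PWA"
    if not pwa.any():
        raise SimulationError("concurrent severity is defined for PWA rows")
    theta = dataset.participants.loc[pwa, "theta"].to_numpy()
    gaq = dataset.gaq().to_numpy()[pwa.to_numpy()]
    f = 100.0 * expit(0.9 * theta + 0.8)
    r_gf = float(np.corrcoef(gaq, f)[0, 1])
    sigma_f = float(np.std(f, ddof=1))
    if r_gf <= target_r:
        noise_sd = 0.0
    else:
        noise_sd = sigma_f * np.sqrt((r_gf / target_r) ** 2 - 1.0)
    rng = np.random.default_rng(
        np.random.SeedSequence([dataset.spec.seed if seed is None else seed, 93])
    )
    external = np.clip(f + rng.normal(0.0, noise_sd, f.size), 0.0, 100.0)
    return pd.Series(
        external,
        index=dataset.participants.loc[pwa, "participant_id"],
        name="external_severity",
    )


def with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    return replace(spec, seed=seed)


def chronic_retest_spec(
    seed: int, n_young: int = 10, n_elderly: int = 10
) -> CohortSpec:
    """Spec for a test-retest patient sample: chronic, milder aphasia
    (recruited pre-admission, at least six months post-onset), drawn
    against the items calibrated on the main standardization cohort.
    Single-word comprehension sits near ceiling for such a sample,
    which is what depresses its test-retest reliability."""
    return CohortSpec(
        seed=seed,
        n_nhi_young=0,
        n_nhi_elderly=0,
        n_pwa_young=n_young,
        n_pwa_elderly=n_elderly,
        pwa_theta_mean=1.2,
        pwa_theta_sd=0.7,
    )
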