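"""File formats: trial-level CSV, participant profiles, norm tables.

The trial dialect mirrors the tablet application's per-trial exports:
one row per scored trial, long format, with a versioned comment header.
Reaction times (``rt_ms``) are parsed when present but never used by
scoring.  All files are UTF-8, RFC-4180 CSV.

Trial payload encodings by subtest rule:

binary            ``correct`` / ``incorrect``
repetition        error code (``correct``, ``phonological_paraphasia``, ...)
sentence rep.     pipe-joined per-word codes, optional ``;order`` suffix
sentence prod.    four pipe-joined criterion bits, e.g. ``1|1|0|1``
discourse prod.   four pipe-joined ratings 1..5, e.g. ``5|4|3|5``
discourse comp.   one row per statement (items s01..s16; consecutive
                  statements form a pair), ``correct`` / ``incorrect``
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalogue import SUBTEST_IDS, SUBTESTS, get_subtest
from .norms import NormEntry, NormError, NormTable
from .scoring import (
    ItemAnnotation,
    ItemScore,
    ParticipantProfile,
    ScoringError,
    SubtestResult,
    build_profile,
    score_discourse_comprehension,
    score_item,
    subtest_accuracy,
)
from .simulate import SyntheticDataset

TRIAL_HEADER = "# aphasiakit-trials v1"
NORMS_HEADER = "# aphasiakit-norms v1"
TRIAL_COLUMNS = [
    "participant_id", "group", "age_cohort", "subtest_id", "item_id",
    "payload", "rt_ms",
]

_BINARY_LIKE = {"binary", "pair_gated"}


class TrialFormatError(ValueError):
    """Malformed trial file; message carries the offending row number."""


def cohort_from_age(age: float, boundary: int = 60) -> str:
    """Age-cohort label for normative lookups: young below the
    boundary (default 60), elderly at or above it."""
    if boundary <= 0:
        raise ValueError("age-cohort boundary must be positive")
    if age < 0:
        raise ValueError("age must be non-negative")
    return "young" if age < boundary else "elderly"


# ------------------------------------------------------------- trials

def write_trial_csv(trials: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    cols = [c for c in TRIAL_COLUMNS if c in trials.columns]
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(TRIAL_HEADER + "\n")
        trials.to_csv(fh, index=False, columns=cols, lineterminator="\n")


def read_trial_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial file.

    Raises :class:`TrialFormatError` with the 1-based data row number
    for missing columns, illegal payloads, or duplicate
    (participant, subtest, item) triples.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("# aphasiakit-trials"):
            raise TrialFormatError(
                f"{path}: missing versioned header line {TRIAL_HEADER!r}"
            )
        if first != TRIAL_HEADER:
            raise TrialFormatError(f"{path}: unsupported trial dialect {first!r}")
        df = pd.read_csv(fh, dtype=str, keep_default_na=False)
    required = [c for c in TRIAL_COLUMNS if c != "rt_ms"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrialFormatError(f"{path}: missing required columns {missing}")
    dup = df.duplicated(subset=["participant_id", "subtest_id", "item_id"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0]) + 1
        raise TrialFormatError(f"{path}: duplicate (participant, subtest, item) at data row {row}")
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            _validate_payload(rec.subtest_id, rec.item_id, rec.payload)
        except (ScoringError, KeyError, ValueError) as exc:
            raise TrialFormatError(f"{path}: data row {i}: {exc}") from None
    return df


def _validate_payload(subtest_id: str, item_id: str, payload: str) -> None:
    annotation_from_payload(subtest_id, item_id, payload)


def annotation_from_payload(
    subtest_id: str, item_id: str, payload: str
) -> ItemAnnotation:
    d = get_subtest(subtest_id)
    if d.rule_id in _BINARY_LIKE:
        if payload not in ("correct", "incorrect"):
            raise ScoringError(
                f"{subtest_id}/{item_id}: choice payload must be "
                f"correct/incorrect, got {payload!r}"
            )
        return ItemAnnotation(subtest_id, item_id, correct=(payload == "correct"))
    if d.rule_id == "repetition":
        return ItemAnnotation(subtest_id, item_id, code=payload)
    if d.rule_id == "sentence_repetition":
        order = False
        body = payload
        if ";" in payload:
            body, flag = payload.split(";", 1)
            if flag != "order":
                raise ScoringError(
                    f"{subtest_id}/{item_id}: unknown payload flag {flag!r}"
                )
            order = True
        codes = tuple(c for c in body.split("|") if c)
        if not codes:
            raise ScoringError(f"{subtest_id}/{item_id}: empty word-code list")
        return ItemAnnotation(subtest_id, item_id, word_codes=codes, order_error=order)
    if d.rule_id == "criteria4":
        bits = payload.split("|")
        if len(bits) != 4 or any(b not in ("0", "1") for b in bits):
            raise ScoringError(
                f"{subtest_id}/{item_id}: expected 4 criterion bits, got {payload!r}"
            )
        return ItemAnnotation(
            subtest_id, item_id, criteria=tuple(b == "1" for b in bits)
        )
    if d.rule_id == "ratings4":
        parts = payload.split("|")
        if len(parts) != 4:
            raise ScoringError(
                f"{subtest_id}/{item_id}: expected 4 ratings, got {payload!r}"
            )
        ratings = tuple(int(p) for p in parts)
        if any(not 1 <= r <= 5 for r in ratings):
            raise ScoringError(
                f"{subtest_id}/{item_id}: rating outside 1..5 in {payload!r}"
            )
        return ItemAnnotation(subtest_id, item_id, ratings=ratings)
    raise ScoringError(f"{subtest_id}: unknown scoring rule")


def _repetition_code(points: float) -> str:
    if points >= 1.0:
        return "correct"
    if points >= 0.5:
        return "phonological_paraphasia"
    return "other_error"


def _word_code(points: float) -> str:
    if points >= 1.0:
        return "correct"
    if points >= 0.5:
        return "phonological_paraphasia"
    return "omission"


def trials_from_dataset(dataset: SyntheticDataset) -> pd.DataFrame:
    """Export a synthetic dataset in the trial CSV dialect."""
    rows: list[dict] = []
    parts = dataset.participants
    for i in range(dataset.n):
        pid = parts["participant_id"].iloc[i]
        group = parts["group"].iloc[i]
        cohort = parts["age_cohort"].iloc[i]

        def add(subtest_id: str, item_id: str, payload: str) -> None:
            rows.append(
                {
                    "participant_id": pid, "group": group, "age_cohort": cohort,
                    "subtest_id": subtest_id, "item_id": item_id,
                    "payload": payload, "rt_ms": "",
                }
            )

        for s in SUBTEST_IDS:
            d = SUBTESTS[s]
            det = dataset.detail[s]
            if d.rule_id == "binary":
                for j in range(d.n_items):
                    add(s, f"i{j + 1:02d}",
                        "correct" if det["correct"][i, j] else "incorrect")
            elif d.rule_id == "pair_gated":
                stmts = det["statements"][i]  # (8, 2)
                k = 0
                for pj in range(stmts.shape[0]):
                    for half in range(2):
                        k += 1
                        add(s, f"s{k:02d}",
                            "correct" if stmts[pj, half] else "incorrect")
            elif d.rule_id == "repetition":
                for j in range(d.n_items):
                    add(s, f"i{j + 1:02d}", _repetition_code(det["points"][i, j]))
            elif d.rule_id == "sentence_repetition":
                bounds = det["bounds"]
                for j in range(d.n_items):
                    words = det["word_points"][i, bounds[j]:bounds[j + 1]]
                    body = "|".join(_word_code(w) for w in words)
                    if det["order"][i, j]:
                        body += ";order"
                    add(s, f"i{j + 1:02d}", body)
            elif d.rule_id == "criteria4":
                for j in range(d.n_items):
                    bits = "|".join(
                        "1" if c else "0" for c in dataset.detail[s]["criteria"][i, j]
                    )
                    add(s, f"i{j + 1:02d}", bits)
            elif d.rule_id == "ratings4":
                add(s, "i01", "|".join(str(int(r)) for r in det["ratings"][i]))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


# ------------------------------------------------------------- scoring

def score_trials(
    trials: pd.DataFrame, *, per_statement_discourse: bool = False
) -> list[ParticipantProfile]:
    """Score a validated trial table into participant profiles.

    Items missing from a partially administered subtest are scored 0
    (abandoned items count as incorrect).  Participants missing whole
    subtests get no GAQ (with a warning); their available subtest
    results are still reported.
    """
    profiles: list[ParticipantProfile] = []
    for pid, block in trials.groupby("participant_id", sort=True):
        group = block["group"].iloc[0]
        cohort = block["age_cohort"].iloc[0]
        results: dict[str, SubtestResult] = {}
        for s, sub in block.groupby("subtest_id"):
            d = get_subtest(s)
            sub = sub.sort_values("item_id")
            if d.rule_id == "pair_gated":
                flags: dict[str, bool] = {
                    r.item_id: r.payload == "correct"
                    for r in sub.itertuples(index=False)
                }
                responses = [
                    [flags.get(f"s{2 * p + 1:02d}", False),
                     flags.get(f"s{2 * p + 2:02d}", False)]
                    for p in range(d.n_items)
                ]
                scores: list[ItemScore] = score_discourse_comprehension(
                    responses, per_statement=per_statement_discourse
                )
            else:
                by_item = {
                    r.item_id: annotation_from_payload(s, r.item_id, r.payload)
                    for r in sub.itertuples(index=False)
                }
                scores = []
                seen = 0
                for j in range(d.n_items):
                    item_id = f"i{j + 1:02d}"
                    if item_id in by_item:
                        scores.append(score_item(by_item[item_id]))
                        seen += 1
                    else:
                        maximum = d.item_maxima[j]
                        scores.append(ItemScore(s, item_id, 0.0, float(maximum)))
                if seen != len(by_item):
                    # non-canonical item ids: score them positionally
                    scores = [score_item(a) for a in by_item.values()]
                    while len(scores) < d.n_items:
                        scores.append(
                            ItemScore(s, f"pad{len(scores)}", 0.0,
                                      float(d.item_maxima[len(scores)]))
                        )
            results[s] = subtest_accuracy(scores, d)
        profile = build_profile(str(pid), group, cohort, results)
        if profile.gaq is None:
            missing = sorted(set(SUBTEST_IDS) - set(results))
            warnings.warn(
                f"{pid}: GAQ omitted; missing subtests: {missing}", stacklevel=2
            )
        profiles.append(profile)
    return profiles


def item_matrices(trials: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Participants x items matrices of raw item points per subtest
    (pair-gated credits for discourse comprehension)."""
    out: dict[str, dict[str, dict[str, float]]] = {s: {} for s in SUBTEST_IDS}
    for pid, block in trials.groupby("participant_id", sort=True):
        for s, sub in block.groupby("subtest_id"):
            d = get_subtest(s)
            if d.rule_id == "pair_gated":
                flags = {
                    r.item_id: r.payload == "correct"
                    for r in sub.itertuples(index=False)
                }
                for p in range(d.n_items):
                    a = flags.get(f"s{2 * p + 1:02d}", False)
                    b = flags.get(f"s{2 * p + 2:02d}", False)
                    out[s].setdefault(f"pair{p + 1}", {})[pid] = float(a and b)
            else:
                for r in sub.itertuples(index=False):
                    score = score_item(
                        annotation_from_payload(s, r.item_id, r.payload)
                    )
                    out[s].setdefault(r.item_id, {})[pid] = score.points
    return {
        s: pd.DataFrame(items).sort_index(axis=1)
        for s, items in out.items()
        if items
    }


# ------------------------------------------------------------ profiles

def profiles_to_frame(profiles: Iterable[ParticipantProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row: dict = {
            "participant_id": p.participant_id,
            "group": p.group,
            "age_cohort": p.age_cohort,
        }
        for s in SUBTEST_IDS:
            r = p.subtest_results.get(s)
            row[s] = r.accuracy if r is not None else np.nan
        row["gaq"] = p.gaq if p.gaq is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles_csv(profiles: Iterable[ParticipantProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, index=False, lineterminator="\n")


def read_profiles_csv(path: str | Path) -> list[ParticipantProfile]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        results = {}
        for s in SUBTEST_IDS:
            if s in df.columns and pd.notna(row[s]):
                max_total = SUBTESTS[s].max_total
                acc = float(row[s])
                results[s] = SubtestResult(s, acc / 100.0 * max_total, max_total, acc)
        out.append(
            build_profile(
                str(row["participant_id"]), row["group"], row["age_cohort"], results
            )
        )
    return out


def write_profiles_json(
    profiles: Iterable[ParticipantProfile], path: str | Path
) -> None:
    payload = {
        "schema": "aphasiakit-profiles/1",
        "profiles": [
            {
                "participant_id": p.participant_id,
                "group": p.group,
                "age_cohort": p.age_cohort,
                "subtests": {
                    s: {
                        "raw": r.raw_total,
                        "max": r.max_total,
                        "accuracy": round(r.accuracy, 2),
                    }
                    for s, r in p.subtest_results.items()
                },
                "gaq": None if p.gaq is None else round(p.gaq, 2),
            }
            for p in profiles
        ],
    }
    Path(path).write_text(
        json.dumps(payload, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------- norm tables

def write_norm_table(table: NormTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(NORMS_HEADER + "\n")
        fh.write(f"# quantile_method={table.quantile_method}\n")
        sizes = ";".join(f"{c}={n}" for c, n in sorted(table.cohort_sizes.items()))
        fh.write(f"# cohort_sizes={sizes}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["measure", "age_cohort", "cutoff", "band_34", "band_67",
             "n_controls_used", "n_outliers_removed"]
        )
        for key in sorted(table.entries):
            e = table.entries[key]
            writer.writerow(
                [e.measure, e.age_cohort, repr(e.cutoff), repr(e.band_34),
                 repr(e.band_67), e.n_controls_used, e.n_outliers_removed]
            )


def read_norm_table(path: str | Path) -> NormTable:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("# aphasiakit-norms"):
            raise NormError(f"{path}: missing norm-table header")
        if header != NORMS_HEADER:
            raise NormError(f"{path}: unsupported norm-table version {header!r}")
        meta: dict[str, str] = {}
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        reader = csv.DictReader(fh)
        table = NormTable(quantile_method=meta.get("quantile_method", "linear"))
        if meta.get("cohort_sizes"):
            table.cohort_sizes = {
                k: int(v)
                for k, v in (kv.split("=") for kv in meta["cohort_sizes"].split(";"))
            }
        for rec in reader:
            table.add(
                NormEntry(
                    rec["measure"], rec["age_cohort"], float(rec["cutoff"]),
                    float(rec["band_34"]), float(rec["band_67"]),
                    int(rec["n_controls_used"]), int(rec["n_outliers_removed"]),
                )
            )
    expected = set(SUBTEST_IDS) | {"gaq"}
    present = {m for m, _ in table.entries}
    if expected - present:
        warnings.warn(
            f"norm table incomplete; missing measures: {sorted(expected - present)}",
            stacklevel=2,
        )
    return table


def write_norm_table_json(table: NormTable, path: str | Path) -> None:
    payload = {
        "schema": "aphasiakit-norms/1",
        "quantile_method": table.quantile_method,
        "cohort_sizes": table.cohort_sizes,
        "entries": [
            {
                "measure": e.measure, "age_cohort": e.age_cohort,
                "cutoff": e.cutoff, "band_34": e.band_34, "band_67": e.band_67,
                "n_controls_used": e.n_controls_used,
                "n_outliers_removed": e.n_outliers_removed,
            }
            for _, e in sorted(table.entries.items())
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
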