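"""Perceptual evaluation: the 12-syllable corpus, binary coding, and PCC.

The stimulus corpus holds 12 consonant-vowel (CV/CVV) monosyllables over
nine tongue-dominant Mandarin consonants in three place-of-articulation
groups: alveolar /d t n l/, alveolo-palatal /j q x/ (pinyin), and velar
/g k/.  A listener codes each syllable production as correct (1) or
deviated (0); percent consonants correct (PCC) summarizes the proportion
correct at the group level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import FEATURE_NAMES

__all__ = [
    "PLACE_GROUPS",
    "default_corpus",
    "validate_corpus",
    "pcc",
    "label_join",
]

logger = logging.getLogger(__name__)

PLACE_GROUPS = ("alveolar", "alveolo-palatal", "velar")
_CONSONANTS = {
    "alveolar": ("d", "t", "n", "l"),
    "alveolo-palatal": ("j", "q", "x"),
    "velar": ("g", "k"),
}

# Default 12-entry corpus: each of the nine consonants appears at least
# once; three carry a second vowel context to reach 12 stimuli.  The exact
# stimulus list is configuration data, not code — swap it via
# ``validate_corpus`` on your own table if a different corpus is in use.
_DEFAULT_CORPUS = [
    # syllable_id, consonant, place_group, vowel_context
    ("da", "d", "alveolar", "a"),
    ("du", "d", "alveolar", "u"),
    ("ta", "t", "alveolar", "a"),
    ("nu", "n", "alveolar", "u"),
    ("la", "l", "alveolar", "a"),
    ("ji", "j", "alveolo-palatal", "i"),
    ("jia", "j", "alveolo-palatal", "ia"),
    ("qi", "q", "alveolo-palatal", "i"),
    ("xi", "x", "alveolo-palatal", "i"),
    ("ga", "g", "velar", "a"),
    ("gu", "g", "velar", "u"),
    ("ka", "k", "velar", "a"),
]


def default_corpus() -> pd.DataFrame:
    """The default 12-syllable stimulus corpus as a validated DataFrame."""
    corpus = pd.DataFrame(
        _DEFAULT_CORPUS, columns=["syllable_id", "consonant", "place_group", "vowel_context"]
    )
    validate_corpus(corpus)
    return corpus


def validate_corpus(corpus: pd.DataFrame) -> pd.DataFrame:
    """Check corpus invariants: 12 unique ids, listed phonemes, no empty group."""
    if len(corpus) != 12:
        raise ValueError("corpus must contain exactly 12 syllables")
    if corpus["syllable_id"].duplicated().any():
        raise ValueError("syllable ids must be unique")
    allowed = {c for group in _CONSONANTS.values() for c in group}
    bad = set(corpus["consonant"]) - allowed
    if bad:
        raise ValueError(f"consonants outside the nine listed phonemes: {sorted(bad)}")
    for _, row in corpus.iterrows():
        if row["consonant"] not in _CONSONANTS[row["place_group"]]:
            raise ValueError(
                f"{row['syllable_id']}: /{row['consonant']}/ is not {row['place_group']}"
            )
    for g in PLACE_GROUPS:
        if not (corpus["place_group"] == g).any():
            raise ValueError(f"place group {g} has no syllables")
    return corpus


def pcc(
    records: pd.DataFrame,
    group_by: str = "overall",
    corpus: pd.DataFrame | None = None,
    gender: pd.Series | None = None,
) -> pd.DataFrame:
    """Percent consonants correct with trial counts.

    ``records`` is a session x syllable 0/1 table (index = session id).
    ``group_by`` is "overall", "place", or "gender-place" (the latter needs
    ``gender``: a session-id-indexed Series).
    """
    if len(records) == 0:
        raise ValueError("PCC requires at least one perceptual record")
    corpus = corpus if corpus is not None else default_corpus()
    syls = list(corpus["syllable_id"])
    missing = set(syls) - set(records.columns)
    if missing:
        raise ValueError(f"records lack syllables: {sorted(missing)}")
    long = records[syls].stack().rename("correct").reset_index()
    long.columns = ["session_id", "syllable_id", "correct"]
    long = long.merge(corpus[["syllable_id", "place_group"]], on="syllable_id")

    if group_by == "overall":
        grouped = [("overall", long)]
    elif group_by == "place":
        grouped = list(long.groupby("place_group"))
    elif group_by == "gender-place":
        if gender is None:
            raise ValueError("gender-place grouping requires a gender series")
        long["gender"] = long["session_id"].map(gender)
        grouped = list(long.groupby(["gender", "place_group"]))
    else:
        raise ValueError("group_by must be 'overall', 'place', or 'gender-place'")

    rows = []
    for key, sub in grouped:
        rows.append(
            {
                "group": key if isinstance(key, str) else "/".join(map(str, key)),
                "pcc": 100.0 * sub["correct"].mean(),
                "n_correct": int(sub["correct"].sum()),
                "n_trials": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)


def label_join(
    feature_table: pd.DataFrame,
    records: pd.DataFrame,
    syllable_id: str,
) -> dict[str, tuple[pd.DataFrame, np.ndarray]]:
    """Pair the 15-metric features with one syllable's binary labels, per gender.

    Sessions missing from either side or with incomplete derived metrics are
    dropped (with a logged count).  Returns ``{gender: (X, y)}`` where ``X``
    is the 15-column feature frame indexed by session id and ``y`` the 0/1
    label vector (1 = correct).
    """
    if syllable_id not in records.columns:
        raise ValueError(f"unknown syllable id {syllable_id!r}")
    feats = feature_table.set_index("session_id") if "session_id" in feature_table else feature_table
    common = feats.index.intersection(records.index)
    if len(common) == 0:
        raise ValueError("no overlapping sessions between features and outcomes")
    feats = feats.loc[common]
    complete = (
        feats["complete"].astype(bool)
        if "complete" in feats
        else np.isfinite(feats[list(FEATURE_NAMES)]).all(axis=1)
    )
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("label_join: dropped %d session(s) with incomplete metrics", n_dropped)
    feats = feats[complete]
    out = {}
    for gender, sub in feats.groupby("gender"):
        X = sub[list(FEATURE_NAMES)]
        y = records.loc[X.index, syllable_id].to_numpy(dtype=int)
        out[str(gender)] = (X, y)
    return out
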