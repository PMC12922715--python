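"""Trial-table schema, readers/writers, and behavioural filtering rules.

One row per trial of the speeded 8-way identification experiment:
observer, session/round/block/set position, image, true and responded
category, presentation time in display frames (120 Hz) and ms, corruption
condition, response time, and practice/repeat flags.  The filters
implement the pre-analysis rules: practice trials (the first three
uncorrupted images of each block) are discarded, and an optional median
split on response time — computed within each (observer, time, corruption)
cell — isolates the faster half of responses.

`correctness_series` turns a filtered table into the aligned binary
correct/incorrect sequences that the error-consistency stage consumes;
misses (no response inside the deadline) count as incorrect by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation import SUPERCLASSES
from .consistency import AlignmentError, BinaryOutcomePair

__all__ = [
    "SchemaError",
    "ConditionKey",
    "NO_RESPONSE",
    "REFRESH_HZ",
    "DESIGN_FRAMES",
    "CORRUPTIONS",
    "REQUIRED_COLUMNS",
    "frames_to_ms",
    "validate_trials",
    "read_trials",
    "write_trials",
    "filter_practice",
    "filter_repeats",
    "median_split_by_rt",
    "add_correctness",
    "correctness_series",
    "aligned_pair",
]

log = logging.getLogger(__name__)

NO_RESPONSE = "NO_RESPONSE"
REFRESH_HZ = 120.0
DESIGN_FRAMES = (1, 2, 4, 8, 16, 32)
CORRUPTIONS = ("none", "noise", "lowpass", "grayscale")
_MS_TOL = 0.01

REQUIRED_COLUMNS = (
    "observer_id", "session", "round", "block", "set_index", "trial_index",
    "image_id", "true_class", "response_class", "presentation_frames",
    "presentation_ms", "corruption", "rt_ms", "is_practice", "is_repeat",
)


class SchemaError(ValueError):
    """A trial table violates the documented schema."""


@dataclass(frozen=True)
class ConditionKey:
    """One analysis cell: presentation time x corruption."""

    presentation_frames: int
    corruption: str

    def __post_init__(self) -> None:
        if self.corruption not in CORRUPTIONS:
            raise SchemaError(f"unknown corruption {self.corruption!r}")


def frames_to_ms(frames: int, refresh_hz: float = REFRESH_HZ) -> float:
    """Display frames to milliseconds (1 frame at 120 Hz = 8.33 ms)."""
    if frames < 1:
        raise ValueError("frames must be >= 1")
    return frames * 1000.0 / refresh_hz


def validate_trials(
    df: pd.DataFrame,
    design_frames=DESIGN_FRAMES,
    refresh_hz: float = REFRESH_HZ,
) -> pd.DataFrame:
    """Validate a trial table against the schema; returns the table.

    Raises :class:`SchemaError` naming offending columns/rows for missing
    required columns, out-of-design frame counts, class labels outside the
    8 superclasses, inconsistent frames↔ms conversion, or nonpositive RTs.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    bad_frames = ~df["presentation_frames"].isin(design_frames)
    if bad_frames.any():
        raise SchemaError(
            f"presentation_frames outside design set {tuple(design_frames)} "
            f"in rows {df.index[bad_frames].tolist()[:10]}"
        )
    bad_true = ~df["true_class"].isin(SUPERCLASSES)
    if bad_true.any():
        raise SchemaError(
            f"unknown true_class in rows {df.index[bad_true].tolist()[:10]}"
        )
    ok_resp = df["response_class"].isin(SUPERCLASSES) | (
        df["response_class"] == NO_RESPONSE
    )
    if (~ok_resp).any():
        raise SchemaError(
            f"unknown response_class in rows {df.index[~ok_resp].tolist()[:10]}"
        )
    bad_corr = ~df["corruption"].isin(CORRUPTIONS)
    if bad_corr.any():
        raise SchemaError(
            f"unknown corruption in rows {df.index[bad_corr].tolist()[:10]}"
        )
    expected_ms = df["presentation_frames"] * 1000.0 / refresh_hz
    off = (df["presentation_ms"] - expected_ms).abs() > _MS_TOL
    if off.any():
        raise SchemaError(
            f"presentation_ms inconsistent with frames at {refresh_hz} Hz "
            f"in rows {df.index[off].tolist()[:10]}"
        )
    rt = df["rt_ms"]
    bad_rt = rt.notna() & (rt <= 0)
    if bad_rt.any():
        raise SchemaError(f"nonpositive rt_ms in rows {df.index[bad_rt].tolist()[:10]}")
    return df


def read_trials(path, **validate_kwargs) -> pd.DataFrame:
    """Read and validate a delimited trial table (unknown columns kept)."""
    df = pd.read_csv(
        path,
        dtype={"observer_id": str, "image_id": str, "true_class": str,
               "response_class": str, "corruption": str},
    )
    validate_trials(df, **validate_kwargs)
    log.info("read %d trials from %s", len(df), path)
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table as comma-delimited text with header."""
    df.to_csv(path, index=False)


def filter_practice(df: pd.DataFrame) -> pd.DataFrame:
    """Drop practice trials (responses to them were discarded by design)."""
    n_removed = int(df["is_practice"].sum())
    log.info("filter_practice: removed %d of %d rows", n_removed, len(df))
    return df.loc[~df["is_practice"].astype(bool)].copy()


def filter_repeats(df: pd.DataFrame) -> pd.DataFrame:
    """Drop repeated-image trials (kept only for self-consistency analyses)."""
    n_removed = int(df["is_repeat"].sum())
    log.info("filter_repeats: removed %d of %d rows", n_removed, len(df))
    return df.loc[~df["is_repeat"].astype(bool)].copy()


def median_split_by_rt(df: pd.DataFrame, keep: str = "faster") -> pd.DataFrame:
    """Keep one half of a median split on response time.

    The median is computed within each (observer, presentation_frames,
    corruption) cell so that condition-level RT differences do not leak
    into the split.  Ties at the median go to the faster half.  Cells with
    no recorded RTs are skipped with a warning (their rows are dropped).
    """
    if keep not in ("faster", "slower"):
        raise ValueError("keep must be 'faster' or 'slower'")
    cells = []
    keys = ["observer_id", "presentation_frames", "corruption"]
    for key, cell in df.groupby(keys):
        rt = cell["rt_ms"]
        if rt.notna().sum() == 0:
            log.warning("median_split_by_rt: no RTs in cell %s; skipped", (key,))
            continue
        med = rt.median()
        fast = rt <= med  # tie at the median counts as faster
        mask = fast if keep == "faster" else ~fast
        cells.append(cell.loc[mask.fillna(False)])
    out = pd.concat(cells) if cells else df.iloc[0:0]
    log.info("median_split_by_rt(keep=%s): %d -> %d rows", keep, len(df), len(out))
    return out.copy()


def add_correctness(df: pd.DataFrame, misses_incorrect: bool = True) -> pd.DataFrame:
    """Add a boolean ``correct`` column comparing response to truth.

    With ``misses_incorrect`` (default) a missing response counts as
    incorrect; otherwise missed-deadline rows are dropped.
    """
    out = df.copy()
    missed = out["response_class"] == NO_RESPONSE
    if not misses_incorrect:
        log.info("add_correctness: dropping %d missed-deadline rows", int(missed.sum()))
        out = out.loc[~missed].copy()
    out["correct"] = (out["response_class"] == out["true_class"]).astype(bool)
    return out


def correctness_series(
    df: pd.DataFrame,
    observer_id: str,
    condition: ConditionKey,
    misses_incorrect: bool = True,
    repeat_mode: bool = False,
) -> pd.Series:
    """Per-image correctness flags for one observer in one condition.

    Returns a boolean Series indexed by ``image_id``, sorted by image id so
    that two observers' series align positionally.  Outside ``repeat_mode``
    each (observer, image) may appear only once; in repeat mode the first
    and second presentations are returned side by side for self-consistency
    analyses (as a two-column frame via :func:`aligned_pair`).
    """
    sel = df.loc[
        (df["observer_id"] == observer_id)
        & (df["presentation_frames"] == condition.presentation_frames)
        & (df["corruption"] == condition.corruption)
    ]
    if not repeat_mode:
        sel = sel.loc[~sel["is_repeat"].astype(bool)]
        if sel["image_id"].duplicated().any():
            dups = sel.loc[sel["image_id"].duplicated(), "image_id"].tolist()[:5]
            raise SchemaError(
                f"duplicate (observer, image) rows outside repeat mode: {dups}"
            )
    sel = add_correctness(sel, misses_incorrect=misses_incorrect)
    sel = sel.sort_values("image_id")
    return pd.Series(sel["correct"].values, index=sel["image_id"].values, dtype=bool)


def aligned_pair(
    df: pd.DataFrame,
    observer_a: str,
    observer_b: str,
    condition: ConditionKey,
    misses_incorrect: bool = True,
    intersect: bool = False,
) -> BinaryOutcomePair:
    """Build the aligned correctness pair for two observers in a condition.

    By default both observers must have seen identical image sets; with
    ``intersect=True`` the comparison silently restricts to the shared
    images instead.
    """
    sa = correctness_series(df, observer_a, condition, misses_incorrect)
    sb = correctness_series(df, observer_b, condition, misses_incorrect)
    ids_a, ids_b = set(sa.index), set(sb.index)
    if ids_a != ids_b:
        if not intersect:
            raise AlignmentError(
                f"observers saw different images ({len(ids_a ^ ids_b)} unshared); "
                "pass intersect=True to compare the shared subset"
            )
        shared = sorted(ids_a & ids_b)
        sa, sb = sa.loc[shared], sb.loc[shared]
    return BinaryOutcomePair(
        tuple(sa.index), sa.values, sb.values
    )


def self_consistency_pair(
    df: pd.DataFrame,
    observer_id: str,
    condition: ConditionKey,
    misses_incorrect: bool = True,
) -> BinaryOutcomePair:
    """First vs. second presentation of repeated images for one observer.

    Feeds the same kappa machinery to quantify intra-observer consistency.
    """
    sel = df.loc[
        (df["observer_id"] == observer_id)
        & (df["presentation_frames"] == condition.presentation_frames)
        & (df["corruption"] == condition.corruption)
    ]
    sel = add_correctness(sel, misses_incorrect=misses_incorrect)
    repeated = sel.loc[sel["image_id"].duplicated(keep=False)]
    firsts, seconds, ids = [], [], []
    for img, grp in repeated.sort_values("trial_index").groupby("image_id"):
        if len(grp) < 2:
            continue
        ids.append(img)
        firsts.append(bool(grp["correct"].iloc[0]))
        seconds.append(bool(grp["correct"].iloc[1]))
    if not ids:
        raise AlignmentError(f"no repeated images for {observer_id} in {condition}")
    return BinaryOutcomePair(tuple(ids), np.array(firsts), np.array(seconds))
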