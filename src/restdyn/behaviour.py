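"""Motor-performance indices from finger-tapping keypress streams.

A 30-s block of the five-element finger-tapping task (cyclic sequence
4-1-3-2-4) is scored with a Global Performance Index (GPI) combining speed
and accuracy. From the 20 learning blocks we derive the Best Motor
Performance (BMP, mean of the two best blocks), a Learning Index (LI,
percent change from early-practice baseline to BMP) and offline changes
from BMP to the best block of each post-learning test window. Group
statistics run on within-subject Z-normalised scores to cancel baseline
offsets between groups.

GPI formula
-----------
The scoring rule used throughout is

    GPI = (n_correct / duration) * (n_correct / n_presses)

i.e. correct-press rate times accuracy: strictly increasing in both speed
and accuracy. The rule sits behind ``score_block(..., scorer=...)`` so an
alternative scoring function can be dropped in; scores carry
``formula="rate_times_accuracy"`` metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import FTT_SEQUENCE

#: Learning blocks are 1..20; test windows are pairs of blocks.
LEARNING_BLOCKS = tuple(range(1, 21))
TEST_WINDOWS = {"T1": (21, 22), "T2": (23, 24), "T3": (25, 26)}

GPI_FORMULA = "rate_times_accuracy"


@dataclass
class BlockScore:
    """Per-block press counts and performance score."""

    block_index: int
    n_presses: int
    n_correct: int
    duration: float
    gpi: float
    formula: str = GPI_FORMULA


def count_correct(keys: np.ndarray, sequence: tuple[int, ...] = FTT_SEQUENCE) -> int:
    """Count presses matching the expected cyclic-sequence position.

    A press is correct when it equals the expected next element. After an
    error the expected position resynchronises to the nearest forward
    occurrence of the pressed key within one cycle (best local alignment),
    so a single slip does not cascade into a run of errors.
    """
    seq = np.asarray(sequence)
    L = seq.size
    pos = 0
    n_correct = 0
    for key in np.asarray(keys, dtype=int):
        if key == seq[pos]:
            n_correct += 1
            pos = (pos + 1) % L
        else:
            # forward distances (in cycle steps) to each occurrence of `key`
            occ = np.nonzero(seq == key)[0]
            if occ.size:
                ahead = (occ - pos) % L
                pos = (int(occ[np.argmin(ahead)]) + 1) % L
            # key not in sequence: keep position
    return n_correct


def gpi(n_presses: int, n_correct: int, duration: float) -> float:
    """Global Performance Index: correct-press rate x accuracy."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if n_presses == 0:
        return 0.0
    return (n_correct / duration) * (n_correct / n_presses)


def score_block(
    events: pd.DataFrame,
    block_index: int,
    duration: float = 30.0,
    sequence: tuple[int, ...] = FTT_SEQUENCE,
    scorer=gpi,
) -> BlockScore:
    """Score one block of keypress events (columns ``t_ms``, ``key``)."""
    if len(events) and (events["t_ms"] < 0).any():
        raise ValueError("negative timestamps")
    keys = events.sort_values("t_ms")["key"].to_numpy() if len(events) else np.empty(0, int)
    n_correct = count_correct(keys, sequence)
    return BlockScore(
        block_index=block_index,
        n_presses=int(keys.size),
        n_correct=int(n_correct),
        duration=duration,
        gpi=float(scorer(keys.size, n_correct, duration)),
    )


def score_stream(events: pd.DataFrame, duration: float = 30.0) -> pd.DataFrame:
    """Score every block of a keypress stream (columns block, t_ms, key)."""
    rows = []
    for b, grp in events.groupby("block", sort=True):
        s = score_block(grp, int(b), duration=duration)
        rows.append((s.block_index, s.n_presses, s.n_correct, s.duration, s.gpi))
    return pd.DataFrame(rows, columns=["block", "n_presses", "n_correct", "duration", "gpi"])


def best_motor_performance(learning_gpis) -> float:
    """Mean of the two largest GPI values among the learning blocks."""
    vals = np.asarray(list(learning_gpis), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 learning blocks")
    top2 = np.sort(vals)[-2:]
    return float(top2.mean())


def learning_index(learning_gpis, baseline_blocks: tuple[int, int] = (2, 3)) -> float:
    """Percent change from early-practice baseline to BMP.

    Baseline is the mean GPI of learning blocks 2-3 (block 1 is excluded
    as task discovery). Returns NaN with a warning when the baseline is
    not positive.
    """
    vals = np.asarray(list(learning_gpis), dtype=float)
    base = np.mean([vals[b - 1] for b in baseline_blocks])
    if base <= 0:
        warnings.warn("learning_index undefined: baseline <= 0")
        return float("nan")
    return float(100.0 * (best_motor_performance(vals) - base) / base)


def offline_change(bmp: float, test_gpis) -> float:
    """Best test-block GPI minus BMP (one value per test window)."""
    vals = np.asarray(list(test_gpis), dtype=float)
    if vals.size == 0 or not np.isfinite(vals).any():
        return float("nan")
    return float(np.nanmax(vals) - bmp)


def z_normalise(block_table: pd.DataFrame, learning_blocks=LEARNING_BLOCKS) -> pd.DataFrame:
    """Within-subject Z-scores of GPI, referenced to the learning blocks.

    For each subject, z = (gpi - mean) / SD with moments taken over that
    subject's learning blocks, then applied to all blocks. Removes
    additive and multiplicative between-group baseline offsets. A subject
    with zero learning-block SD gets NaN z-scores and a warning.
    """
    out = block_table.reset_index(drop=True).copy()
    zs = np.full(len(out), np.nan)
    for subj, grp in out.groupby("subject"):
        learn = grp[grp["block"].isin(learning_blocks)]["gpi"]
        mu, sd = learn.mean(), learn.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"zero learning-block SD for subject {subj}; z undefined")
            continue
        zs[grp.index] = (grp["gpi"] - mu) / sd
    out["z"] = zs
    return out


def subject_indices(block_table: pd.DataFrame, use_z: bool = False) -> pd.DataFrame:
    """Per-subject BMP, LI and offline changes from a scored block table.

    ``block_table`` needs columns subject, block, gpi (and z when
    ``use_z``). Returns one row per subject with bmp, li,
    offline_T1..offline_T3.
    """
    col = "z" if use_z else "gpi"
    rows = []
    for subj, grp in block_table.groupby("subject"):
        grp = grp.set_index("block")[col]
        learn = [grp.get(b, np.nan) for b in LEARNING_BLOCKS]
        bmp = best_motor_performance([v for v in learn if np.isfinite(v)])
        li = learning_index(learn) if not use_z else np.nan
        offs = {
            f"offline_{w}": offline_change(bmp, [grp.get(b, np.nan) for b in blocks])
            for w, blocks in TEST_WINDOWS.items()
        }
        rows.append({"subject": subj, "bmp": bmp, "li": li, **offs})
    return pd.DataFrame(rows)
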