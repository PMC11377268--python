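"""Reading, windowing, standardization and splitting of gait recordings.

The raw insole format is whitespace-delimited numeric text with 19 columns
(timestamp, 8 sensors per foot, 2 per-foot sums) at 100 frames/s; optical
floor-sensor data comes as 116-channel windows at 20 frames/s. Processing
follows the order: drop timestamp -> chunk into fixed windows -> per-channel
standardize x_hat = (x - mu) / theta over the whole dataset -> random
train/val/test split (default 60/20/20; 70/10/20 and subject-level splits
also supported).
"""
from __future__ import annotations

import os
import warnings
from glob import glob
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import GaitDataset, GaitSample, RawRecording, StandardizationStats

__all__ = [
    "read_gaitpdb",
    "read_demographics",
    "drop_timestamp",
    "chunk",
    "standardize",
    "fit_standardization",
    "split",
    "count_windows",
]


def read_gaitpdb(path: str) -> RawRecording:
    """Parse one 19-column insole recording from whitespace-delimited text.

    The source identifier is taken from the filename stem and the sample
    rate is fixed at 100 frames/s. A line with the wrong column count or a
    non-numeric token raises a ``ValueError`` naming the offending line.
    """
    rows: List[List[float]] = []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) != 19:
                raise ValueError(
                    f"{path}:{lineno}: expected 19 columns, found {len(tokens)}"
                )
            try:
                rows.append([float(t) for t in tokens])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric token in line")
    values = np.array(rows, dtype=float).reshape(-1, 19)
    source_id = os.path.splitext(os.path.basename(path))[0]
    return RawRecording(
        "gaitpdb-19col", values, sample_rate=100.0, source_id=source_id, has_timestamp=True
    )


def read_demographics(path: str) -> pd.DataFrame:
    """Read the tab-delimited demographics table of a gaitpdb-style accession.

    Returns a DataFrame with at least ``ID``, ``Group`` (1 = patient,
    2 = control) and ``HoehnYahr`` columns; severity labels for the
    classifier are taken from ``HoehnYahr`` (0 for controls).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"ID", "Group", "HoehnYahr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"demographics table missing columns {sorted(missing)}")
    return df


def drop_timestamp(raw: RawRecording) -> RawRecording:
    """Remove the timestamp column, leaving the 18 force channels.

    Column order is preserved (L1..L8, R1..R8, Lsum, Rsum). Applying to a
    recording without a timestamp is a warned no-op, so the operation is
    idempotent.
    """
    if not raw.has_timestamp:
        warnings.warn(f"recording {raw.source_id!r} has no timestamp; nothing dropped")
        return raw
    return RawRecording(
        raw.dialect,
        raw.values[:, 1:].copy(),
        raw.sample_rate,
        raw.source_id,
        has_timestamp=False,
    )


def chunk(raw: RawRecording, window_len: int) -> List[GaitSample]:
    """Cut a recording into consecutive non-overlapping fixed windows.

    Windows start at frame 0; a trailing remainder shorter than
    ``window_len`` is discarded, so the output count is
    ``floor(n_frames / window_len)``.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    n = raw.values.shape[0] // window_len
    return [
        GaitSample(
            values=raw.values[i * window_len : (i + 1) * window_len].copy(),
            subject_id=raw.source_id,
            window_index=i,
        )
        for i in range(n)
    ]


def count_windows(
    raw_dir: str, pattern: str = "*.txt", window_len: int = 500
) -> Tuple[int, Dict[str, int]]:
    """Total and per-record window counts for all recordings matching a glob.

    The record-type glob makes both inclusion conventions computable (e.g.
    ``Ga*_??.txt`` for all walks vs ``Ga*_01.txt`` for first walks only).
    """
    per_record: Dict[str, int] = {}
    for path in sorted(glob(os.path.join(raw_dir, pattern))):
        rec = read_gaitpdb(path)
        per_record[rec.source_id] = rec.n_frames // window_len
    return sum(per_record.values()), per_record


def fit_standardization(values: np.ndarray) -> StandardizationStats:
    """Per-channel population mean/sd over all samples and frames."""
    flat = values.reshape(-1, values.shape[-1])
    mu = flat.mean(axis=0)
    theta = flat.std(axis=0)  # population convention (divide by N)
    zero = np.nonzero(theta == 0)[0]
    if zero.size:
        raise ValueError(f"zero-variance channels: {zero.tolist()}")
    return StandardizationStats(mu, theta)


def standardize(
    dataset: GaitDataset, stats: Optional[StandardizationStats] = None
) -> Tuple[GaitDataset, StandardizationStats]:
    """Rescale every channel to mean 0 / sd 1 over the whole dataset.

    When ``stats`` is given (e.g. reusing training-population statistics)
    they are applied as-is; otherwise they are fitted on ``dataset``.
    """
    if stats is None:
        stats = fit_standardization(dataset.values)
    out = dataset.subset(np.arange(len(dataset)))
    out.values = stats.apply(dataset.values)
    out.stats = stats
    return out, stats


def split(
    dataset: GaitDataset,
    fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    mode: str = "window",
    test_subjects: Optional[Sequence[str]] = None,
) -> GaitDataset:
    """Assign every sample to exactly one of train/val/test.

    ``mode='window'`` permutes windows (the default scheme; note that
    windows of one subject can then land in different sets, which leaks
    subject identity across the split). ``mode='subject'`` permutes
    subjects instead. Passing ``test_subjects`` holds those subjects out as
    the test set (leave-subjects-out) and divides the remaining subjects'
    windows between train and val by the renormalized first two fractions.
    Reproducible under ``seed``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(dataset)
    rng = np.random.default_rng(seed)
    assignment = np.array([""] * n, dtype=object)

    if test_subjects is not None:
        test_subjects = set(map(str, test_subjects))
        known = set(map(str, dataset.subject_ids))
        unknown = test_subjects - known
        if unknown:
            raise ValueError(f"unknown test subjects {sorted(unknown)}")
        is_test = np.array([str(s) in test_subjects for s in dataset.subject_ids])
        assignment[is_test] = "test"
        rest = np.nonzero(~is_test)[0]
        rng.shuffle(rest)
        f_train = fractions[0] / (fractions[0] + fractions[1])
        n_train = int(round(f_train * rest.size))
        assignment[rest[:n_train]] = "train"
        assignment[rest[n_train:]] = "val"
    elif mode == "window":
        if n < 3:
            raise ValueError("fewer samples than split groups")
        perm = rng.permutation(n)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        assignment[perm[:n_train]] = "train"
        assignment[perm[n_train : n_train + n_val]] = "val"
        assignment[perm[n_train + n_val :]] = "test"
    elif mode == "subject":
        subjects = np.array(sorted(set(map(str, dataset.subject_ids))))
        if subjects.size < 3:
            raise ValueError("fewer subjects than split groups")
        perm = rng.permutation(subjects.size)
        n_train = int(round(fractions[0] * subjects.size))
        n_val = int(round(fractions[1] * subjects.size))
        groups = {
            s: "train" for s in subjects[perm[:n_train]]
        }
        groups.update({s: "val" for s in subjects[perm[n_train : n_train + n_val]]})
        groups.update({s: "test" for s in subjects[perm[n_train + n_val :]]})
        assignment = np.array([groups[str(s)] for s in dataset.subject_ids], dtype=object)
    else:
        raise ValueError(f"unknown split mode {mode!r}")

    out = dataset.subset(np.arange(n))
    out.split = assignment
    return out
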