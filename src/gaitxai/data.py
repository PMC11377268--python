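"""In-memory containers for gait recordings and windowed datasets."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence

import h5py
import numpy as np

#: Recognized raw-recording dialects and their column counts.
DIALECTS = {"gaitpdb-19col": 19, "pof-116col": 116}


@dataclass
class RawRecording:
    """One variable-length multichannel gait recording.

    ``values`` is a frames x columns matrix. For the ``gaitpdb-19col``
    dialect the first column is a strictly increasing timestamp in seconds,
    followed by 8 force sensors per foot (left then right) and the two
    per-foot sum columns. The ``pof-116col`` dialect carries 116 optical
    floor-sensor channels and no timestamp.
    """

    dialect: str
    values: np.ndarray
    sample_rate: float
    source_id: str = ""
    has_timestamp: bool = True

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D frames x columns matrix")
        if self.dialect == "pof-116col":
            self.has_timestamp = False
        # a gaitpdb recording has 19 columns raw and 18 once the timestamp
        # has been dropped
        expected = DIALECTS[self.dialect]
        if self.dialect == "gaitpdb-19col" and not self.has_timestamp:
            expected = 18
        if self.values.shape[1] != expected:
            raise ValueError(
                f"dialect {self.dialect} requires {expected} columns, "
                f"got {self.values.shape[1]}"
            )
        if self.has_timestamp and self.values.shape[0] > 1:
            ts = self.values[:, 0]
            if not np.all(np.diff(ts) > 0):
                raise ValueError("timestamp column must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class StandardizationStats:
    """Per-channel standardization parameters x_hat = (x - mu) / theta."""

    mu: np.ndarray
    theta: np.ndarray
    scope: str = "per-channel-per-dataset"

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.theta <= 0):
            bad = np.nonzero(self.theta <= 0)[0].tolist()
            raise ValueError(f"theta must be > 0 for every channel; offending channels {bad}")

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mu) / self.theta

    def invert(self, values: np.ndarray) -> np.ndarray:
        return values * self.theta + self.mu


@dataclass
class GaitSample:
    """One fixed-length windowed sample."""

    values: np.ndarray  # window_len x n_channels
    label: object = None
    subject_id: str = ""
    dataset_tag: str = "synthetic"
    window_index: int = 0


class GaitDataset:
    """A windowed gait dataset: tensor of samples plus labels and metadata.

    Attributes
    ----------
    values : ndarray, shape (n_samples, window_len, n_channels)
    labels : ndarray of per-sample class labels (may be None entries when
        windows are not yet labeled)
    subject_ids : ndarray of str
    classes : ordered label vocabulary
    split : ndarray of str in {"train", "val", "test", ""}
    stats : StandardizationStats or None
    event_windows : bool ndarray (n_samples, window_len) marking the frames
        where a class effect was planted (synthetic data only), or None
    planted_events : dict class-label -> event label (synthetic data only)
    """

    def __init__(
        self,
        values: np.ndarray,
        labels: Optional[Sequence] = None,
        subject_ids: Optional[Sequence[str]] = None,
        classes: Optional[Sequence] = None,
        split: Optional[Sequence[str]] = None,
        stats: Optional[StandardizationStats] = None,
        dataset_tag: str = "synthetic",
        sample_rate: float = 100.0,
        window_indices: Optional[Sequence[int]] = None,
        event_windows: Optional[np.ndarray] = None,
        planted_events: Optional[Dict] = None,
        strike_frames: Optional[List[np.ndarray]] = None,
    ) -> None:
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (n_samples, window_len, n_channels)")
        n = self.values.shape[0]
        self.labels = np.asarray(labels if labels is not None else [None] * n, dtype=object)
        self.subject_ids = np.asarray(
            subject_ids if subject_ids is not None else [""] * n, dtype=object
        )
        if classes is None:
            seen = [l for l in dict.fromkeys(self.labels.tolist()) if l is not None]
            classes = seen
        self.classes = list(classes)
        self.split = np.asarray(split if split is not None else [""] * n, dtype=object)
        self.stats = stats
        self.dataset_tag = dataset_tag
        self.sample_rate = float(sample_rate)
        self.window_indices = np.asarray(
            window_indices if window_indices is not None else np.arange(n), dtype=int
        )
        self.event_windows = None if event_windows is None else np.asarray(event_windows, bool)
        self.planted_events = dict(planted_events) if planted_events else {}
        #: ground-truth reference-foot heel-strike frames per window
        #: (synthetic data only)
        self.strike_frames = (
            None if strike_frames is None
            else [np.asarray(s, dtype=int) for s in strike_frames]
        )
        if self.strike_frames is not None and len(self.strike_frames) != n:
            raise ValueError("strike_frames length mismatch")
        for arr, name in [
            (self.labels, "labels"),
            (self.subject_ids, "subject_ids"),
            (self.split, "split"),
            (self.window_indices, "window_indices"),
        ]:
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n_samples {n}")

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def window_len(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    def __iter__(self) -> Iterator[GaitSample]:
        for i in range(len(self)):
            yield GaitSample(
                values=self.values[i],
                label=self.labels[i],
                subject_id=str(self.subject_ids[i]),
                dataset_tag=self.dataset_tag,
                window_index=int(self.window_indices[i]),
            )

    def label_indices(self) -> np.ndarray:
        """Integer class index per sample, following ``classes`` order."""
        lookup = {c: i for i, c in enumerate(self.classes)}
        try:
            return np.array([lookup[l] for l in self.labels], dtype=int)
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} not in class vocabulary {self.classes}")

    def subset(self, mask: np.ndarray) -> "GaitDataset":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.nonzero(mask)[0]
        return GaitDataset(
            self.values[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            classes=self.classes,
            split=self.split[idx],
            stats=self.stats,
            dataset_tag=self.dataset_tag,
            sample_rate=self.sample_rate,
            window_indices=self.window_indices[idx],
            event_windows=None if self.event_windows is None else self.event_windows[idx],
            planted_events=self.planted_events,
            strike_frames=None if self.strike_frames is None
            else [self.strike_frames[i] for i in np.atleast_1d(idx)],
        )

    def split_subset(self, name: str) -> "GaitDataset":
        if name not in ("train", "val", "test"):
            raise ValueError(f"unknown split {name!r}")
        return self.subset(self.split == name)

    # -- persistence -------------------------------------------------------
    def to_h5(self, path: str) -> None:
        """Write the processed-dataset container (HDF5)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            str_dt = h5py.string_dtype()
            f.create_dataset(
                "labels", data=[json.dumps(l) for l in self.labels.tolist()], dtype=str_dt
            )
            f.create_dataset("subject_ids", data=[str(x) for x in self.subject_ids], dtype=str_dt)
            f.create_dataset("split", data=[str(x) for x in self.split], dtype=str_dt)
            f.create_dataset("window_indices", data=self.window_indices)
            if self.event_windows is not None:
                f.create_dataset("event_windows", data=self.event_windows.astype(np.uint8))
            if self.strike_frames is not None:
                width = max((len(s) for s in self.strike_frames), default=0)
                padded = -np.ones((len(self.strike_frames), width), dtype=int)
                for i, s in enumerate(self.strike_frames):
                    padded[i, : len(s)] = s
                f.create_dataset("strike_frames", data=padded)
            if self.stats is not None:
                f.create_dataset("stats_mu", data=self.stats.mu)
                f.create_dataset("stats_theta", data=self.stats.theta)
            f.attrs["classes"] = json.dumps(self.classes)
            f.attrs["dataset_tag"] = self.dataset_tag
            f.attrs["sample_rate"] = self.sample_rate
            f.attrs["planted_events"] = json.dumps(self.planted_events)

    @classmethod
    def from_h5(cls, path: str) -> "GaitDataset":
        with h5py.File(path, "r") as f:
            stats = None
            if "stats_mu" in f:
                stats = StandardizationStats(f["stats_mu"][:], f["stats_theta"][:])
            labels = [json.loads(s) for s in f["labels"].asstr()[:]]
            return cls(
                f["values"][:],
                labels=labels,
                subject_ids=list(f["subject_ids"].asstr()[:]),
                classes=json.loads(f.attrs["classes"]),
                split=list(f["split"].asstr()[:]),
                stats=stats,
                dataset_tag=str(f.attrs["dataset_tag"]),
                sample_rate=float(f.attrs["sample_rate"]),
                window_indices=f["window_indices"][:],
                event_windows=f["event_windows"][:].astype(bool)
                if "event_windows" in f
                else None,
                planted_events=json.loads(f.attrs.get("planted_events", "{}")),
                strike_frames=[row[row >= 0] for row in f["strike_frames"][:]]
                if "strike_frames" in f
                else None,
            )


def concatenate(datasets: List[GaitDataset]) -> GaitDataset:
    """Stack datasets sample-wise; vocabularies and shapes must agree."""
    if not datasets:
        raise ValueError("nothing to concatenate")
    first = datasets[0]
    for d in datasets[1:]:
        if d.classes != first.classes:
            raise ValueError("class vocabularies differ")
        if d.values.shape[1:] != first.values.shape[1:]:
            raise ValueError("window shapes differ")
    ew = None
    if all(d.event_windows is not None for d in datasets):
        ew = np.concatenate([d.event_windows for d in datasets])
    return GaitDataset(
        np.concatenate([d.values for d in datasets]),
        labels=np.concatenate([d.labels for d in datasets]),
        subject_ids=np.concatenate([d.subject_ids for d in datasets]),
        classes=first.classes,
        split=np.concatenate([d.split for d in datasets]),
        stats=first.stats,
        dataset_tag=first.dataset_tag,
        sample_rate=first.sample_rate,
        window_indices=np.concatenate([d.window_indices for d in datasets]),
        event_windows=ew,
        planted_events=first.planted_events,
    )
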