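"""Trial container, preprocessing, label encoding and file I/O.

The universal in-memory object is :class:`TrialSet`: a stack of epoched
multi-channel EEG trials (``n_trials x C x T``) with one integer class label
and one integer subject id per trial.  Everything downstream — the spiking
autoencoder, the per-subject associative memories, the evaluation helpers —
consumes TrialSets.

Conventions
-----------
* trials are channel-major ``(C, T)``, time in samples, 0-based indexing;
* after :func:`preprocess` the trial length ``T`` is divisible by 4, because
  the encoder halves the time axis twice;
* class labels are dense integers ``0 .. n_class-1``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

SD_FLOOR = 1e-8


@dataclass
class TrialSet:
    """Epoched multi-subject EEG trials.

    Parameters
    ----------
    data : ndarray, shape (n_trials, C, T)
        Trial waveforms, volts or normalized units.
    labels : ndarray of int, shape (n_trials,)
        Class labels in ``0 .. n_class-1``.
    subject_ids : ndarray of int, shape (n_trials,)
        Which subject produced each trial.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    meta : dict
        Free-form provenance (e.g. original trial length before padding).
    """

    data: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D (n_trials, C, T), got {self.data.shape}")
        n = self.data.shape[0]
        if n < 1:
            raise ValueError("need at least one trial")
        if self.labels.shape != (n,) or self.subject_ids.shape != (n,):
            raise ValueError(
                "labels/subject_ids must match n_trials="
                f"{n}, got {self.labels.shape} and {self.subject_ids.shape}"
            )
        if self.data.shape[1] < 1 or self.data.shape[2] < 4:
            raise ValueError("need C >= 1 and T >= 4")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must equal C")

    # -- convenience ------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids)

    def select(self, idx: np.ndarray) -> "TrialSet":
        return TrialSet(
            data=self.data[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            fs=self.fs,
            channel_names=list(self.channel_names),
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def savez_deterministic(path: str | Path, **arrays: np.ndarray) -> None:
    """Write an ``.npz`` container byte-identically for identical arrays.

    ``np.savez`` stamps zip entries with the wall clock, so two otherwise
    identical writes differ.  This writer pins the entry timestamps, making
    containers reproducible artifacts.  Files remain ordinary npz archives
    readable by ``np.load``.
    """
    import io
    import zipfile

    with zipfile.ZipFile(Path(path), "w", compression=zipfile.ZIP_STORED) as zf:
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.lib.format.write_array(buf, np.asarray(arr), allow_pickle=True)
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def save_trials(ts: TrialSet, path: str | Path) -> None:
    """Write a TrialSet to the native ``.npz`` array-bundle container.

    Arrays ``data``, ``labels``, ``subject_ids`` plus scalar ``fs`` and the
    channel-name list.  Loading the file back reproduces ``data`` bit-exactly,
    and identical TrialSets produce byte-identical files.
    """
    savez_deterministic(
        Path(path),
        data=ts.data,
        labels=ts.labels,
        subject_ids=ts.subject_ids,
        fs=np.float64(ts.fs),
        channel_names=np.array(ts.channel_names, dtype=object),
    )


def load_trials(path: str | Path, format: str = "npz") -> TrialSet:
    """Read trials from disk.

    Parameters
    ----------
    path : path
    format : {"npz", "csv", "gdf"}
        ``npz``: the native array-bundle container written by
        :func:`save_trials`.  ``csv``: delimited text, one row per
        (trial, channel): ``trial,subject,label,channel,s0,...,s{T-1}``.
        ``gdf``: raw GDF/EDF recordings via :mod:`mne` (optional extra);
        for BCI-competition-IV-IIa-style files only the EEG channels are
        kept (EOG dropped) and trials are epoched from annotations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "npz":
        return _load_npz(path)
    if format == "csv":
        return _load_csv(path)
    if format in ("gdf", "edf"):
        return _load_gdf(path)
    raise ValueError(f"unknown format {format!r}")


def _load_npz(path: Path) -> TrialSet:
    with np.load(path, allow_pickle=True) as f:
        if "labels" not in f:
            raise ValueError("labels required: container has no 'labels' array")
        if "data" not in f:
            raise ValueError("data required: container has no 'data' array")
        data = f["data"]
        labels = f["labels"]
        subject_ids = f["subject_ids"] if "subject_ids" in f else np.zeros(len(labels), int)
        fs = float(f["fs"]) if "fs" in f else 1.0
        names = [str(c) for c in f["channel_names"]] if "channel_names" in f else []
    return TrialSet(data=data, labels=labels, subject_ids=subject_ids, fs=fs,
                    channel_names=names)


def _load_csv(path: Path) -> TrialSet:
    """Delimited-text import for toy data: trial,subject,label,channel,samples..."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"trial", "subject", "label", "channel"}
    if "label" not in df.columns:
        raise ValueError("labels required: csv has no 'label' column")
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"csv missing columns: {sorted(missing)}")
    sample_cols = [c for c in df.columns if c not in required]
    trials = sorted(df["trial"].unique())
    rows, labels, subjects = [], [], []
    t_len = None
    for tr in trials:
        sub = df[df["trial"] == tr].sort_values("channel")
        mat = sub[sample_cols].to_numpy(dtype=float)
        vals = mat[:, ~np.isnan(mat).all(axis=0)]
        if t_len is None:
            t_len = vals.shape[1]
        elif vals.shape[1] != t_len:
            raise ValueError(
                f"non-uniform trial length: trial {tr} has T={vals.shape[1]}, expected {t_len}"
            )
        rows.append(vals)
        labels.append(int(sub["label"].iloc[0]))
        subjects.append(int(sub["subject"].iloc[0]))
    return TrialSet(data=np.stack(rows), labels=np.array(labels),
                    subject_ids=np.array(subjects), fs=1.0)


def _load_gdf(path: Path, tmin: float = 0.0, tmax: float = 3.0) -> TrialSet:
    """GDF/EDF epoching via mne; keeps EEG channels only (EOG dropped)."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("reading GDF/EDF requires the optional 'mne' dependency") from e
    raw = mne.io.read_raw(path, preload=True, verbose="error")
    raw.pick("eeg")
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    epochs = mne.Epochs(raw, events, event_id=event_id, tmin=tmin, tmax=tmax,
                        baseline=None, preload=True, verbose="error")
    labels = epochs.events[:, 2]
    # densify labels to 0..K-1
    uniq = np.unique(labels)
    dense = np.searchsorted(uniq, labels)
    return TrialSet(data=epochs.get_data(), labels=dense,
                    subject_ids=np.zeros(len(dense), int), fs=float(raw.info["sfreq"]),
                    channel_names=list(epochs.ch_names))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(ts: TrialSet, pad_policy: str = "zero-pad") -> TrialSet:
    """Z-score each channel per trial and make T divisible by 4.

    Each channel of each trial is standardised to mean 0, sd 1 (sd floored at
    ``1e-8``; an all-constant channel becomes zeros and logs a warning).  The
    time axis is then cropped (``pad_policy="crop"``) or zero-padded
    (``"zero-pad"``, default) to the nearest multiple of 4, as required by the
    encoder's two stride-2 poolings.  The original length is recorded under
    ``meta["original_T"]``.
    """
    if pad_policy not in ("crop", "zero-pad"):
        raise ValueError(f"unknown pad_policy {pad_policy!r}")
    x = ts.data
    mu = x.mean(axis=2, keepdims=True)
    sd = x.std(axis=2, keepdims=True)
    n_const = int((sd < SD_FLOOR).sum())
    if n_const:
        msg = f"{n_const} constant channel(s); z-score uses sd floor {SD_FLOOR}"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    z = (x - mu) / np.maximum(sd, SD_FLOOR)

    t = z.shape[2]
    if t % 4 == 0:
        out = z
    elif pad_policy == "crop":
        out = z[:, :, : (t // 4) * 4]
    else:
        pad = (-t) % 4
        out = np.pad(z, ((0, 0), (0, 0), (0, pad)))
    meta = dict(ts.meta)
    meta["original_T"] = t
    meta["pad_policy"] = pad_policy
    return TrialSet(data=out, labels=ts.labels.copy(), subject_ids=ts.subject_ids.copy(),
                    fs=ts.fs, channel_names=list(ts.channel_names), meta=meta)


# ---------------------------------------------------------------------------
# Label encoding
# ---------------------------------------------------------------------------

def encode_bipolar_onehot(label: int, n_class: int) -> np.ndarray:
    """Bipolar one-hot code: +1 at the target class, -1 elsewhere.

    The associative memory operates on {-1, +1} states, so class ``c`` of
    ``K`` is coded as a K-vector summing to ``2 - K``.
    """
    label = int(label)
    if not 0 <= label < n_class:
        raise ValueError(f"label {label} out of range for n_class={n_class}")
    y = -np.ones(n_class, dtype=np.int64)
    y[label] = 1
    return y


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_by_subject(ts: TrialSet, train_fraction: float, seed: int) -> tuple[TrialSet, TrialSet]:
    """Stratified train/test split, per subject and per class.

    Every (subject, class) cell is split independently so each subject's
    training set contains every class.  Deterministic under ``seed``; the two
    outputs partition the input.

    Raises
    ------
    ValueError
        if ``train_fraction`` is outside (0, 1) or any (subject, class) cell
        has fewer than 2 trials (it could not appear on both sides).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for s in ts.subjects():
        for c in np.unique(ts.labels):
            cell = np.flatnonzero((ts.subject_ids == s) & (ts.labels == c))
            if cell.size < 2:
                raise ValueError(
                    f"(subject={s}, class={c}) has {cell.size} trial(s); need >= 2 to split"
                )
            perm = rng.permutation(cell)
            k = int(round(train_fraction * cell.size))
            k = min(max(k, 1), cell.size - 1)  # both sides non-empty
            train_idx.append(perm[:k])
            test_idx.append(perm[k:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return ts.select(tr), ts.select(te)
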