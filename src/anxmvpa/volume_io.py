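"""Reading, writing and matrix assembly for block-design task fMRI.

This module turns the on-disk currency of a task-fMRI study — 4D BOLD
NIfTI volumes, an integer-labeled parcellation atlas with a region lookup
table, BIDS-style event tables and a participants table — into the in-memory
matrix dataset every downstream analysis consumes
(:class:`TimePointDataset`: subjects x task time points x voxels, with a
stimulus label per time point and a diagnostic group label per subject).

Conventions
-----------
* Voxel order within a region is the ascending flattened index with the
  first (x) axis varying fastest, so matrix columns are reproducible.
* A volume's acquisition time is the middle of its repetition interval,
  ``t_i = (i + 0.5) * TR``; event intervals are half-open
  ``[onset, onset + duration)``.
* Task time-point extraction shifts acquisition times by a configurable
  hemodynamic lag (default 4 s) before testing block membership.
* Per-voxel standardization (z-scoring) uses full-run statistics — task
  plus fixation volumes — so that task activation relative to the fixation
  baseline is preserved in the extracted rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "BoldRun",
    "AtlasParcellation",
    "TimePointDataset",
    "TASK_CONDITIONS",
    "DEFAULT_TR_SECONDS",
    "DEFAULT_HRF_LAG_SECONDS",
    "read_bold_nifti",
    "write_bold_nifti",
    "read_atlas",
    "write_atlas",
    "read_events",
    "write_events",
    "read_participants",
    "parcellate",
    "extract_task_timepoints",
    "assemble_dataset",
]

#: Stimulus conditions of the face-processing task.
TASK_CONDITIONS = ("fear", "anger")
#: All trial types an event table may contain.
VALID_TRIAL_TYPES = ("fixation",) + TASK_CONDITIONS

DEFAULT_TR_SECONDS = 2.0
DEFAULT_HRF_LAG_SECONDS = 4.0

EVENT_COLUMNS = ["onset", "duration", "trial_type"]


@dataclass
class BoldRun:
    """One subject's 4D BOLD series (x, y, z, t) plus acquisition metadata."""

    subject_id: str
    data: np.ndarray
    tr_seconds: float = DEFAULT_TR_SECONDS
    run_id: str = "01"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(
                f"BOLD data must be 3D or 4D, got {self.data.ndim}D"
            )
        if not np.issubdtype(self.data.dtype, np.number):
            raise ValueError("BOLD data must be numeric")
        n_nan = int(np.isnan(self.data).sum())
        if n_nan:
            raise ValueError(f"BOLD data contains {n_nan} NaN voxel values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class AtlasParcellation:
    """Integer-labeled 3D parcellation plus its region lookup table.

    ``labels`` uses 0 for background and 1..R for region ids; the region
    table carries (region_id, name, centroid in the volume's coordinates).
    """

    labels: np.ndarray
    region_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("atlas labels must be integers")
            self.labels = np.round(self.labels).astype(np.int32)
        required = {"region_id", "name", "x", "y", "z"}
        missing = required - set(self.region_table.columns)
        if missing:
            raise ValueError(f"region table missing columns: {sorted(missing)}")
        ids = self.region_table["region_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("region ids in the region table must be unique")
        present = set(np.unique(self.labels)) - {0}
        listed = set(int(i) for i in ids)
        if not present <= listed:
            raise ValueError(
                f"atlas labels {sorted(present - listed)} missing from region table"
            )
        empty = [rid for rid in listed if rid not in present]
        if empty:
            raise ValueError(f"listed regions with no voxels: {sorted(empty)}")

    @property
    def region_ids(self) -> list[int]:
        return sorted(int(i) for i in self.region_table["region_id"])

    def n_voxels(self, region_id: int) -> int:
        return int((self.labels == region_id).sum())


@dataclass
class TimePointDataset:
    """Subjects x task time points x voxels — the common classifier currency.

    All subjects share the task time-point count T and the stimulus label
    sequence (time points are temporally aligned across subjects: the m-th
    time point shows the same stimulus for everyone). Every voxel column
    belongs to exactly one atlas region; ``region_index`` maps region id to
    its column slice.
    """

    features: np.ndarray  # (n_subjects, T, V)
    stimulus_labels: np.ndarray  # (T,) in TASK_CONDITIONS
    group_labels: np.ndarray  # (n_subjects,)
    subject_ids: list[str]
    region_index: dict[int, slice] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.stimulus_labels = np.asarray(self.stimulus_labels)
        self.group_labels = np.asarray(self.group_labels)
        if self.features.ndim != 3:
            raise ValueError("features must be (n_subjects, T, V)")
        n, t, _ = self.features.shape
        if len(self.stimulus_labels) != t:
            raise ValueError("stimulus label length must equal T")
        if len(self.group_labels) != n or len(self.subject_ids) != n:
            raise ValueError("per-subject metadata length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.features.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.features.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.features.shape[2]

    def region_view(self, region_id: int) -> np.ndarray:
        """Return the (n_subjects, T, V_r) feature block of one region.

        ``region_id`` of ``WHOLE_BRAIN`` (-1) returns every voxel column —
        the whole-brain pseudo-region.
        """
        if region_id == WHOLE_BRAIN:
            return self.features
        if region_id not in self.region_index:
            raise KeyError(f"region {region_id} not in dataset")
        return self.features[:, :, self.region_index[region_id]]

    def subject_index(self, subject_id: str) -> int:
        return self.subject_ids.index(subject_id)


#: Pseudo region id meaning "all voxels in scope".
WHOLE_BRAIN = -1


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_bold_nifti(
    path: str | Path,
    subject_id: str = "",
    run_id: str = "01",
    tr_seconds: float | None = None,
) -> BoldRun:
    """Load a 3D/4D NIfTI volume as a :class:`BoldRun`.

    The repetition time is taken from the NIfTI header when available and
    can be overridden with ``tr_seconds``. 3D input becomes t=1. NaN voxels
    are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim not in (3, 4):
        raise ValueError(f"expected 3D or 4D NIfTI, got {data.ndim}D")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else DEFAULT_TR_SECONDS
    sid = subject_id or path.stem.split("_")[0].replace(".nii", "")
    return BoldRun(subject_id=sid, data=data, tr_seconds=tr_seconds, run_id=run_id)


def write_bold_nifti(run: BoldRun, path: str | Path) -> None:
    """Write a BOLD run as float32 NIfTI-1, recording TR in the header."""
    img = nib.Nifti1Image(np.asarray(run.data, dtype=np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, float(run.tr_seconds)))
    nib.save(img, str(path))


def read_atlas(nifti_path: str | Path, table_path: str | Path) -> AtlasParcellation:
    """Load a labeled parcellation volume plus its region lookup TSV."""
    img = nib.load(str(nifti_path))
    labels = np.round(np.asarray(img.get_fdata())).astype(np.int32)
    table = pd.read_csv(table_path, sep="\t")
    return AtlasParcellation(labels=labels, region_table=table)


def write_atlas(atlas: AtlasParcellation, nifti_path: str | Path, table_path: str | Path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), affine=np.eye(4))
    nib.save(img, str(nifti_path))
    atlas.region_table.to_csv(table_path, sep="\t", index=False)


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check the event-table contract: sorted, non-overlapping, known types."""
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    ev = events[EVENT_COLUMNS].copy()
    if (ev["onset"] < 0).any():
        raise ValueError("event onsets must be non-negative")
    if (ev["duration"] <= 0).any():
        raise ValueError("event durations must be positive")
    bad = set(ev["trial_type"]) - set(VALID_TRIAL_TYPES)
    if bad:
        raise ValueError(f"unknown trial types: {sorted(bad)}")
    if not ev["onset"].is_monotonic_increasing:
        raise ValueError("events must be sorted by onset")
    ends = (ev["onset"] + ev["duration"]).to_numpy()
    if (ev["onset"].to_numpy()[1:] < ends[:-1] - 1e-9).any():
        raise ValueError("events overlap within the run")
    return ev


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a BIDS-style events TSV (onset, duration, trial_type)."""
    return validate_events(pd.read_csv(path, sep="\t"))


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events).to_csv(path, sep="\t", index=False)


def read_participants(path: str | Path) -> pd.DataFrame:
    """Read a participants TSV with at least participant_id and group."""
    table = pd.read_csv(path, sep="\t")
    missing = {"participant_id", "group"} - set(table.columns)
    if missing:
        raise ValueError(f"participants table missing columns: {sorted(missing)}")
    return table


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

def _flat_spatial(data: np.ndarray) -> np.ndarray:
    """Flatten (x, y, z, t) to (V, t) with x varying fastest.

    Computes in float64 so that in-memory and disk-round-tripped float32
    volumes yield bit-identical downstream matrices.
    """
    nx, ny, nz, t = data.shape
    return np.asarray(data, dtype=np.float64).reshape((nx * ny * nz, t), order="F")


def region_voxel_indices(atlas: AtlasParcellation, region_id: int) -> np.ndarray:
    """Ascending x-fastest flattened indices of one region's voxels."""
    flat = atlas.labels.reshape(-1, order="F")
    idx = np.flatnonzero(flat == region_id)
    if idx.size == 0:
        raise KeyError(f"region {region_id} absent from atlas")
    return idx


def parcellate(
    run: BoldRun,
    atlas: AtlasParcellation,
    region_ids: Sequence[int] | None = None,
) -> dict[int, np.ndarray]:
    """Split a run into per-region (T x V_r) matrices.

    Voxels appear in ascending flattened (x-fastest) order; background
    (label 0) is excluded. The union over all regions partitions the
    nonzero-labeled mask.
    """
    if run.spatial_shape != atlas.labels.shape:
        raise ValueError(
            f"spatial shape mismatch: run {run.spatial_shape} vs atlas {atlas.labels.shape}"
        )
    ids = list(region_ids) if region_ids is not None else atlas.region_ids
    present = set(atlas.region_ids)
    absent = [rid for rid in ids if rid not in present]
    if absent:
        raise KeyError(f"regions {absent} absent from atlas")
    flat = _flat_spatial(run.data)
    return {rid: flat[region_voxel_indices(atlas, rid), :].T for rid in ids}


def extract_task_timepoints(
    run: BoldRun,
    events: pd.DataFrame,
    hrf_lag_seconds: float = DEFAULT_HRF_LAG_SECONDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Select task volumes and their stimulus labels from a run.

    A volume with mid-acquisition time ``t_i = (i + 0.5) * TR`` is assigned
    to a task block when ``t_i - hrf_lag_seconds`` falls inside the block's
    half-open interval; fixation volumes are excluded.

    Returns (volume indices, condition labels), both deterministic.
    """
    ev = validate_events(events)
    t_mid = (np.arange(run.n_timepoints) + 0.5) * run.tr_seconds
    stim_time = t_mid - hrf_lag_seconds
    run_end = run.n_timepoints * run.tr_seconds
    indices: list[int] = []
    labels: list[str] = []
    for row in ev.itertuples(index=False):
        if row.trial_type == "fixation":
            continue
        if row.onset + row.duration > run_end + 1e-9:
            raise ValueError("event extends beyond the run duration")
        sel = np.flatnonzero(
            (stim_time >= row.onset) & (stim_time < row.onset + row.duration)
        )
        indices.extend(int(i) for i in sel)
        labels.extend([row.trial_type] * len(sel))
    if not indices:
        raise ValueError("empty selection: no task volumes within fear/anger blocks")
    order = np.argsort(indices, kind="stable")
    return np.asarray(indices)[order], np.asarray(labels)[order]


def _standardize_full_run(data: np.ndarray) -> np.ndarray:
    """Per-voxel z-score of a (V, t) matrix using full-run statistics.

    Zero-variance voxels standardize to zeros so masks with dead voxels
    survive.
    """
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    out = data - mean
    nonzero = sd[:, 0] > 0
    out[nonzero] /= sd[nonzero]
    out[~nonzero] = 0.0
    return out


def assemble_dataset(
    runs_by_subject: Mapping[str, Sequence[BoldRun]],
    atlas: AtlasParcellation,
    events_by_run: Mapping[tuple[str, str], pd.DataFrame],
    participants: pd.DataFrame,
    hrf_lag_seconds: float = DEFAULT_HRF_LAG_SECONDS,
) -> TimePointDataset:
    """Build the :class:`TimePointDataset` from runs + atlas + events.

    Per subject, task time points from each run are extracted (in run
    order) and concatenated; features are per-voxel z-scores against each
    run's full time series. All subjects must yield the same T and the same
    stimulus label sequence. Subject rows follow the participants table
    order.

    ``events_by_run`` maps (subject_id, run_id) to an event table.
    """
    group_of = dict(
        zip(participants["participant_id"].astype(str), participants["group"].astype(str))
    )
    subject_ids = [str(s) for s in participants["participant_id"]]
    for sid in subject_ids:
        if sid not in runs_by_subject:
            raise ValueError(f"subject {sid} in metadata has no runs")

    rids = atlas.region_ids
    voxel_idx = {rid: region_voxel_indices(atlas, rid) for rid in rids}
    region_index: dict[int, slice] = {}
    start = 0
    for rid in rids:
        region_index[rid] = slice(start, start + voxel_idx[rid].size)
        start += voxel_idx[rid].size
    all_idx = np.concatenate([voxel_idx[rid] for rid in rids])

    feats: list[np.ndarray] = []
    label_seq: np.ndarray | None = None
    for sid in subject_ids:
        rows: list[np.ndarray] = []
        labels: list[np.ndarray] = []
        for run in runs_by_subject[sid]:
            if run.spatial_shape != atlas.labels.shape:
                raise ValueError(f"run {sid}/{run.run_id} shape mismatch with atlas")
            events = events_by_run[(sid, run.run_id)]
            idx, lab = extract_task_timepoints(run, events, hrf_lag_seconds)
            flat = _flat_spatial(run.data)[all_idx, :]
            rows.append(_standardize_full_run(flat)[:, idx].T)
            labels.append(lab)
        mat = np.vstack(rows)
        seq = np.concatenate(labels)
        if label_seq is None:
            label_seq = seq
        elif len(seq) != len(label_seq) or (seq != label_seq).any():
            raise ValueError(
                f"subject {sid} has an inconsistent task time-point sequence"
            )
        feats.append(mat)

    assert label_seq is not None
    return TimePointDataset(
        features=np.stack(feats),
        stimulus_labels=label_seq,
        group_labels=np.array([group_of[s] for s in subject_ids]),
        subject_ids=subject_ids,
        region_index=region_index,
    )
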