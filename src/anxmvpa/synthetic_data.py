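"""Synthetic block-design fMRI cohorts with planted, recoverable structure.

The generator emulates the statistical skeleton of a two-group pediatric
face-processing study: 23 control and 22 anxious children, a multi-region
parcellation in which exactly one designated region carries a
group-discriminative signal, and stimulus-evoked responses that are shared
across subjects only up to a subject-specific orthonormal map — so
cross-subject stimulus decoding is near chance before functional alignment
and high after it.

Generative model (per subject, signal region, task volumes only)::

    BOLD = baseline
         + group_effect * noise_sd     [anxious subjects, all task volumes]
         + W_i @ s_condition           [subject map W_i, shared s_fear/s_anger]
         + coupling * zeta_i(t)        [seed + coupled regions, if configured]
         + N(0, noise_sd)              [i.i.d., everywhere, all volumes]

``W_i`` is a random orthonormal V_r x k map drawn per subject; ``s_fear``
and ``s_anger`` are drawn once per cohort (orthogonal, norm scaled so the
per-voxel stimulus RMS equals ``stim_effect``) — subjects differ only
through W_i and noise, which is exactly the sharing assumption functional
alignment exploits.

Two block layouts are available. The "full" layout mirrors the acquisition
protocol (two runs, each 16 s lead/trail fixation and six 15-s task blocks
separated by 12-s fixation, 182 s per run). The default "compact" layout is
a single run with five 15-s task blocks separated by 13-s fixation whose
mid-volume extraction at the default 4-s lag yields exactly T = 35
temporally aligned task time points per subject — the time-point count all
downstream analyses assume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import (
    AtlasParcellation,
    BoldRun,
    DEFAULT_HRF_LAG_SECONDS,
    DEFAULT_TR_SECONDS,
    TimePointDataset,
    assemble_dataset,
    extract_task_timepoints,
    read_atlas,
    read_bold_nifti,
    read_events,
    read_participants,
    region_voxel_indices,
    validate_events,
    write_atlas,
    write_bold_nifti,
    write_events,
)

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "Cohort",
    "make_block_design",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

GROUPS = ("non_anxious", "anxious")


@dataclass
class CohortSpec:
    """Study-condition knobs of the synthetic cohort.

    Defaults are the study conditions: 23 controls vs 22 anxious subjects,
    35 task time points, ~800 voxels across 20 regions, a planted
    group-effect of 2 noise SD and a shared stimulus response of amplitude
    2 noise SD living in ``signal_region_id`` only.
    """

    n_anxious: int = 22
    n_control: int = 23
    atlas_shape: tuple[int, int, int] = (12, 12, 12)
    n_regions: int = 20
    voxels_per_region: int = 40
    T: int = 35
    signal_region_id: int = 7
    group_effect: float = 2.0
    stim_effect: float = 2.0
    k_shared: int = 3
    noise_sd: float = 1.0
    baseline: float = 100.0
    coupled_region_ids: tuple[int, ...] = ()
    coupling: float = 0.5
    tr_seconds: float = DEFAULT_TR_SECONDS
    hrf_lag_seconds: float = DEFAULT_HRF_LAG_SECONDS
    design: str = "compact"  # "compact" (T=35, one run) or "full" (protocol layout)
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if not 1 <= self.signal_region_id <= self.n_regions:
            raise ValueError("signal_region_id must be in 1..n_regions")
        if self.k_shared > self.voxels_per_region:
            raise ValueError("k_shared must not exceed voxels_per_region")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.group_effect < 0 or self.stim_effect < 0:
            raise ValueError("effect sizes must be non-negative")
        if int(np.prod(self.atlas_shape)) < self.n_regions * self.voxels_per_region:
            raise ValueError("atlas_shape too small for the requested regions")
        if self.design not in ("compact", "full"):
            raise ValueError("design must be 'compact' or 'full'")
        bad = [r for r in self.coupled_region_ids if not 1 <= r <= self.n_regions]
        if bad:
            raise ValueError(f"coupled regions out of range: {bad}")


@dataclass
class GroundTruth:
    """What was planted: subject maps, shared responses, and the signal region."""

    W: dict[str, np.ndarray]  # subject -> (V_r, k) orthonormal
    s_fear: np.ndarray  # (k,)
    s_anger: np.ndarray  # (k,)
    signal_region_id: int
    group_of: dict[str, str]
    group_means: dict[str, float]


@dataclass
class Cohort:
    """In-memory synthetic cohort: runs, atlas, events, metadata, truth."""

    spec: CohortSpec
    runs_by_subject: dict[str, list[BoldRun]]
    atlas: AtlasParcellation
    events_by_run: dict[tuple[str, str], pd.DataFrame]
    participants: pd.DataFrame
    truth: GroundTruth

    def to_dataset(self) -> TimePointDataset:
        return assemble_dataset(
            self.runs_by_subject,
            self.atlas,
            self.events_by_run,
            self.participants,
            hrf_lag_seconds=self.spec.hrf_lag_seconds,
        )


# ---------------------------------------------------------------------------
# block design
# ---------------------------------------------------------------------------

def make_block_design(
    rng: np.random.Generator | int = 0,
    n_runs: int = 2,
    blocks_per_run: int = 6,
    block_seconds: float = 15.0,
    gap_seconds: float = 12.0,
    lead_seconds: float = 16.0,
    trail_seconds: float = 16.0,
) -> list[pd.DataFrame]:
    """Build per-run event tables for the block-design face task.

    Defaults mirror the acquisition protocol: each run opens and closes
    with a 16-s fixation block and holds six 15-s task blocks (three fear,
    three anger, order randomized) separated by 12-s fixation — 182 s per
    run, two runs per subject. Deterministic given the seed/generator.
    """
    rng = np.random.default_rng(rng)
    tables = []
    for _ in range(n_runs):
        n_fear = (blocks_per_run + 1) // 2
        conditions = ["fear"] * n_fear + ["anger"] * (blocks_per_run - n_fear)
        order = rng.permutation(len(conditions))
        conditions = [conditions[i] for i in order]
        rows = [(0.0, lead_seconds, "fixation")]
        t = lead_seconds
        for j, cond in enumerate(conditions):
            rows.append((t, block_seconds, cond))
            t += block_seconds
            if j < blocks_per_run - 1:
                rows.append((t, gap_seconds, "fixation"))
                t += gap_seconds
        rows.append((t, trail_seconds, "fixation"))
        tables.append(
            validate_events(pd.DataFrame(rows, columns=["onset", "duration", "trial_type"]))
        )
    return tables


def _design_for_spec(spec: CohortSpec, rng: np.random.Generator) -> list[pd.DataFrame]:
    if spec.design == "full":
        return make_block_design(rng)
    # compact: one run, five 15-s blocks, 13-s gaps keep every onset on an
    # even second so each block contributes exactly 7 mid-volume samples.
    return make_block_design(
        rng,
        n_runs=1,
        blocks_per_run=5,
        block_seconds=15.0,
        gap_seconds=13.0,
    )


def _run_n_volumes(events: pd.DataFrame, tr: float) -> int:
    total = float((events["onset"] + events["duration"]).max())
    return int(np.ceil(total / tr - 1e-9))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _random_orthonormal(rng: np.random.Generator, v: int, k: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((v, k)))
    return q * np.sign(np.diag(r))


def _build_atlas(spec: CohortSpec) -> AtlasParcellation:
    """Contiguous flattened-index parcellation: region r owns voxels
    [(r-1)*V_r, r*V_r) in x-fastest order; the remainder is background."""
    n_vox = int(np.prod(spec.atlas_shape))
    flat = np.zeros(n_vox, dtype=np.int32)
    for rid in range(1, spec.n_regions + 1):
        flat[(rid - 1) * spec.voxels_per_region : rid * spec.voxels_per_region] = rid
    labels = flat.reshape(spec.atlas_shape, order="F")
    rows = []
    for rid in range(1, spec.n_regions + 1):
        coords = np.argwhere(labels == rid)
        cx, cy, cz = coords.mean(axis=0)
        rows.append((rid, f"region_{rid:03d}", cx, cy, cz))
    table = pd.DataFrame(rows, columns=["region_id", "name", "x", "y", "z"])
    return AtlasParcellation(labels=labels, region_table=table)


def generate_cohort(spec: CohortSpec | None = None, **overrides) -> Cohort:
    """Generate a full synthetic cohort (runs + atlas + events + truth).

    All randomness flows from ``spec.seed`` through named child streams of
    one :class:`numpy.random.SeedSequence` (design, shared responses,
    subject maps, per-subject noise), so regeneration is bit-identical.
    """
    spec = dataclasses.replace(spec or CohortSpec(), **overrides)
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    ss_design, ss_shared, ss_subjects = root.spawn(3)

    events = _design_for_spec(spec, np.random.default_rng(ss_design))
    atlas = _build_atlas(spec)
    vr = spec.voxels_per_region
    sig_idx = region_voxel_indices(atlas, spec.signal_region_id)
    coupled_idx = [region_voxel_indices(atlas, r) for r in spec.coupled_region_ids]

    # shared condition responses: orthogonal directions, per-voxel RMS =
    # stim_effect (norm stim_effect * sqrt(V_r))
    rng_shared = np.random.default_rng(ss_shared)
    basis = _random_orthonormal(rng_shared, spec.k_shared, min(2, spec.k_shared))
    scale = spec.stim_effect * np.sqrt(vr) * spec.noise_sd
    s_fear = scale * basis[:, 0]
    s_anger = scale * basis[:, -1] if spec.k_shared > 1 else -s_fear

    # per-run task-volume membership and labels (identical for all subjects)
    tr = spec.tr_seconds
    run_meta = []
    for ri, ev in enumerate(events):
        nvol = _run_n_volumes(ev, tr)
        probe = BoldRun("probe", np.zeros((1, 1, 1, nvol)), tr, run_id=f"{ri + 1:02d}")
        idx, lab = extract_task_timepoints(probe, ev, spec.hrf_lag_seconds)
        run_meta.append((f"{ri + 1:02d}", ev, nvol, idx, lab))
    total_T = sum(len(m[3]) for m in run_meta)
    if spec.design == "compact" and total_T != spec.T:
        raise ValueError(
            f"compact design produced T={total_T}, expected {spec.T}"
        )

    subject_ids = [f"sub-{i + 1:02d}" for i in range(spec.n_control + spec.n_anxious)]
    groups = ["non_anxious"] * spec.n_control + ["anxious"] * spec.n_anxious
    group_of = dict(zip(subject_ids, groups))

    n_vox = int(np.prod(spec.atlas_shape))
    shape = spec.atlas_shape
    W: dict[str, np.ndarray] = {}
    runs_by_subject: dict[str, list[BoldRun]] = {}
    events_by_run: dict[tuple[str, str], pd.DataFrame] = {}
    subject_streams = ss_subjects.spawn(len(subject_ids))

    for sid, group, ss in zip(subject_ids, groups, subject_streams):
        rng = np.random.default_rng(ss)
        W[sid] = _random_orthonormal(rng, vr, spec.k_shared)
        runs = []
        for run_id, ev, nvol, idx, lab in run_meta:
            data = rng.standard_normal((n_vox, nvol)) * spec.noise_sd + spec.baseline
            task_cols = idx
            if group == "anxious" and spec.group_effect > 0:
                data[np.ix_(sig_idx, task_cols)] += spec.group_effect * spec.noise_sd
            if spec.stim_effect > 0:
                resp = np.where(
                    (lab == "fear")[None, :],
                    (W[sid] @ s_fear)[:, None],
                    (W[sid] @ s_anger)[:, None],
                )
                data[np.ix_(sig_idx, task_cols)] += resp
            if spec.coupled_region_ids and spec.coupling > 0:
                zeta = rng.standard_normal(len(task_cols)) * spec.noise_sd
                for cidx in [sig_idx] + coupled_idx:
                    data[np.ix_(cidx, task_cols)] += spec.coupling * zeta[None, :]
            vol = data.reshape(shape + (nvol,), order="F").astype(np.float32)
            runs.append(BoldRun(sid, vol, tr, run_id=run_id))
            events_by_run[(sid, run_id)] = ev
        runs_by_subject[sid] = runs

    participants = pd.DataFrame(
        {"participant_id": subject_ids, "group": groups}
    )
    truth = GroundTruth(
        W=W,
        s_fear=s_fear,
        s_anger=s_anger,
        signal_region_id=spec.signal_region_id,
        group_of=group_of,
        group_means={
            "anxious": spec.baseline + spec.group_effect * spec.noise_sd,
            "non_anxious": spec.baseline,
        },
    )
    return Cohort(spec, runs_by_subject, atlas, events_by_run, participants, truth)


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort as a BIDS-flavoured file tree.

    Layout: ``sub-XX/func/sub-XX_task-faces_run-RR_bold.nii.gz`` plus
    matching ``*_events.tsv``, a top-level ``participants.tsv`` and
    ``atlas.nii.gz``/``regions.tsv``. Data is stored (and generated) as
    float32, so a read-back reproduces the in-memory matrices exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_atlas(cohort.atlas, out / "atlas.nii.gz", out / "regions.tsv")
    cohort.participants.to_csv(out / "participants.tsv", sep="\t", index=False)
    for sid, runs in cohort.runs_by_subject.items():
        func = out / sid / "func"
        func.mkdir(parents=True, exist_ok=True)
        for run in runs:
            stem = f"{sid}_task-faces_run-{run.run_id}"
            write_bold_nifti(run, func / f"{stem}_bold.nii.gz")
            write_events(cohort.events_by_run[(sid, run.run_id)], func / f"{stem}_events.tsv")
    return out


def load_cohort(
    data_dir: str | Path,
) -> tuple[dict[str, list[BoldRun]], AtlasParcellation, dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """Read back a cohort tree written by :func:`write_cohort`."""
    root = Path(data_dir)
    atlas = read_atlas(root / "atlas.nii.gz", root / "regions.tsv")
    participants = read_participants(root / "participants.tsv")
    runs_by_subject: dict[str, list[BoldRun]] = {}
    events_by_run: dict[tuple[str, str], pd.DataFrame] = {}
    for sid in participants["participant_id"].astype(str):
        func = root / sid / "func"
        runs = []
        for bold in sorted(func.glob(f"{sid}_task-faces_run-*_bold.nii.gz")):
            run_id = bold.name.split("run-")[1].split("_")[0]
            runs.append(read_bold_nifti(bold, subject_id=sid, run_id=run_id))
            events_by_run[(sid, run_id)] = read_events(
                func / f"{sid}_task-faces_run-{run_id}_events.tsv"
            )
        if not runs:
            raise FileNotFoundError(f"no runs found for {sid}")
        runs_by_subject[sid] = runs
    return runs_by_subject, atlas, events_by_run, participants
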