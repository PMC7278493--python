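"""Tracking-table I/O and observable-vector assembly.

A trajectory is one animal's overhead-camera track: the marker's (x, y)
position sampled at a fixed frame rate (one frame per 0.5 s in the reference
setup), optionally annotated frame-by-frame by a human observer with one of
three behavioral states:

    0 — behavior besides approaching and standing
    1 — approaching the male
    2 — standing near the male

The male paddock is adjacent to the small-x side of the pen, so small x means
"near the male".  Units are whatever the tracker emitted (pixels or meters);
they only need to be consistent within a cohort.

From a trajectory the decoder consumes per-frame observation vectors
z_k = (x(k), y(k), L(k)), where L(k) is the step length — the Euclidean
displacement between frames k and k+1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STATES = (0, 1, 2)
#: Human-readable behavior names, indexed by state id.
STATE_NAMES = ("other", "approaching", "standing")


class TrackingParseError(ValueError):
    """Raised when a tracking table violates the trajectory contract."""


@dataclass
class Trajectory:
    """One animal's frame-indexed track.

    Frames are implicitly numbered 1..K.  ``labels`` is either None (an
    unlabeled track) or an int array with one state id per frame.
    ``true_states`` holds the generating states of a simulated track, before
    label noise; it is never serialized.
    """

    animal_id: str
    estrus: bool
    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray | None = None
    true_states: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.x) < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != self.x.shape:
                raise ValueError("labels must cover every frame")
            if not np.isin(self.labels, STATES).all():
                raise ValueError("labels must lie in {0, 1, 2}")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def n_frames(self) -> int:
        return len(self.x)

    @property
    def is_labeled(self) -> bool:
        return self.labels is not None

    @property
    def positions(self) -> np.ndarray:
        """(K, 2) array of (x, y) positions."""
        return np.column_stack([self.x, self.y])


@dataclass
class ObservationSequence:
    """Per-frame observation vectors z_k = (x, y, L), shape (K, 3)."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[1] != 3:
            raise ValueError("observations must have shape (K, 3)")
        if (self.z[:, 2] < 0).any():
            raise ValueError("step lengths must be non-negative")

    def __len__(self) -> int:
        return len(self.z)


def compute_step_lengths(traj: Trajectory, last_frame: str = "carry") -> np.ndarray:
    """Per-frame step lengths L(k) = ||pos(k+1) − pos(k)||.

    L is defined by the *next* frame, so the final frame has no step of its
    own.  ``last_frame="carry"`` (default) repeats L(K−1) at frame K so every
    frame carries a full observation vector; ``last_frame="drop"`` returns
    only the K−1 defined values.
    """
    if len(traj) < 2:
        raise ValueError("step length undefined for fewer than 2 frames")
    d = np.diff(traj.positions, axis=0)
    steps = np.hypot(d[:, 0], d[:, 1])
    if last_frame == "drop":
        return steps
    if last_frame != "carry":
        raise ValueError("last_frame must be 'carry' or 'drop'")
    return np.append(steps, steps[-1])


def assemble_observations(traj: Trajectory) -> ObservationSequence:
    """Build the (K, 3) observation matrix (x, y, L) for a trajectory."""
    length = compute_step_lengths(traj)
    return ObservationSequence(np.column_stack([traj.x, traj.y, length]))


def stack_observations(
    trajs: Iterable[Trajectory],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack labeled trajectories into a flat training matrix.

    Returns (features, labels): features is (sum K_i, 3), labels (sum K_i,).
    Every trajectory must be labeled.
    """
    feats, labs = [], []
    for traj in trajs:
        if not traj.is_labeled:
            raise ValueError(f"trajectory {traj.animal_id!r} has no labels")
        feats.append(assemble_observations(traj).z)
        labs.append(traj.labels)
    if not feats:
        raise ValueError("no trajectories given")
    return np.vstack(feats), np.concatenate(labs)


def read_tracking_csv(
    path: str | Path,
    animal_id: str | None = None,
    estrus: bool = False,
) -> Trajectory:
    """Read a trajectory table: columns ``frame,x,y`` with optional ``label``.

    Frame indices must be consecutive integers starting at 1.  ``animal_id``
    defaults to the file stem.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("frame", "x", "y"):
        if col not in df.columns:
            raise TrackingParseError(f"{path}: missing required column {col!r}")
    frames = df["frame"].to_numpy()
    if not np.issubdtype(frames.dtype, np.integer):
        raise TrackingParseError(f"{path}: non-integer frame indices")
    expected = np.arange(1, len(df) + 1)
    bad = np.nonzero(frames != expected)[0]
    if bad.size:
        row = int(bad[0]) + 1  # 1-based data row
        raise TrackingParseError(
            f"{path}: non-consecutive frame index at row {row} "
            f"(found {frames[bad[0]]}, expected {expected[bad[0]]})"
        )
    for col in ("x", "y"):
        if not np.issubdtype(df[col].dtype, np.number) or df[col].isna().any():
            raise TrackingParseError(f"{path}: non-numeric values in column {col!r}")
    labels = None
    if "label" in df.columns:
        if df["label"].isna().any():
            raise TrackingParseError(f"{path}: label column has missing entries")
        labels = df["label"].to_numpy()
    return Trajectory(
        animal_id=animal_id if animal_id is not None else path.stem,
        estrus=estrus,
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        labels=labels,
    )


def write_tracking_csv(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as ``frame,x,y[,label]`` (full float precision)."""
    data: dict[str, Sequence] = {
        "frame": np.arange(1, len(traj) + 1),
        "x": traj.x,
        "y": traj.y,
    }
    if traj.is_labeled:
        data["label"] = traj.labels
    pd.DataFrame(data).to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Cohort manifest CSV: columns ``animal_id,estrus,path``."""
    df = pd.read_csv(path)
    for col in ("animal_id", "estrus", "path"):
        if col not in df.columns:
            raise TrackingParseError(f"{path}: manifest missing column {col!r}")
    return df


def read_cohort(manifest_path: str | Path) -> list[Trajectory]:
    """Load every trajectory listed in a cohort manifest.

    Relative paths in the manifest are resolved against its directory.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    trajs = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        trajs.append(read_tracking_csv(p, animal_id=str(row.animal_id), estrus=bool(row.estrus)))
    return trajs


def write_cohort(
    trajs: Sequence[Trajectory], outdir: str | Path, manifest_name: str = "manifest.csv"
) -> Path:
    """Write one CSV per trajectory plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for traj in trajs:
        fname = f"{traj.animal_id}.csv"
        write_tracking_csv(traj, outdir / fname)
        rows.append({"animal_id": traj.animal_id, "estrus": traj.estrus, "path": fname})
    manifest = outdir / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
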