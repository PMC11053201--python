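"""Skeleton keypoint sequences: parsing, validation, normalization, graph.

A pose estimator emits, per frame and person, a 57-element prediction vector:
box center (Cx, Cy), box width/height (W, H), box confidence, class
confidence, then 17 keypoint triples (x, y, score) in COCO order.  This
module parses those records, assembles per-clip sequences, normalizes the
coordinates into a person-centric frame, derives the motion (frame
difference) stream, and defines the 17-joint skeleton graph with the
partitioned, degree-normalized adjacency stacks the graph convolution needs.

Coordinates are image pixels with the origin at the top-left and y growing
downward; all downstream kinematics (e.g. "descent" means increasing y) use
this convention.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

FALL = "fall"
NOT_FALL = "not-fall"
UNKNOWN = "unknown"

#: COCO keypoint order used throughout the package.
COCO_JOINTS = (
    "nose", "left_eye", "right_eye", "left_ear", "right_ear",
    "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
    "left_wrist", "right_wrist", "left_hip", "right_hip",
    "left_knee", "right_knee", "left_ankle", "right_ankle",
)

N_JOINTS = 17

#: Naturally connected joint pairs (0-indexed COCO skeleton): face chain,
#: ear-shoulder links, arms, trunk, and legs.  See docs/methods.md for the
#: diagram.
COCO_EDGES = (
    (0, 1), (0, 2), (1, 2), (1, 3), (2, 4),        # nose-eyes-ears
    (3, 5), (4, 6),                                 # ears to shoulders
    (5, 7), (7, 9), (6, 8), (8, 10),                # arms
    (5, 6), (5, 11), (6, 12), (11, 12),             # trunk
    (11, 13), (13, 15), (12, 14), (14, 16),         # legs
)

LEFT_HIP, RIGHT_HIP = 11, 12
LEFT_SHOULDER, RIGHT_SHOULDER = 5, 6

PARTITION_STRATEGIES = ("uni-label", "distance", "spatial")

#: A frame counts as blank when every keypoint score falls below this.
BLANK_SCORE_THRESHOLD = 0.05

POSE_VECTOR_LENGTH = 57


class FormatError(ValueError):
    """Raised for malformed keypoint records or files."""


@dataclass
class PoseVector:
    """One frame's 57-element pose prediction."""

    center_x: float
    center_y: float
    width: float
    height: float
    box_conf: float
    class_conf: float
    keypoints: np.ndarray  # (17, 3): x, y, score

    def __post_init__(self):
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        if self.keypoints.shape != (N_JOINTS, 3):
            raise FormatError(
                f"keypoints must be (17, 3), got {self.keypoints.shape}"
            )
        self._validate()

    def _validate(self):
        values = self.serialize()
        if not np.all(np.isfinite(values)):
            raise FormatError("pose vector contains non-finite values")
        for name in ("box_conf", "class_conf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FormatError(f"{name}={v} outside [0, 1]")
        if self.width < 0 or self.height < 0:
            raise FormatError("box width/height must be non-negative")
        scores = self.keypoints[:, 2]
        if np.any((scores < 0) | (scores > 1)):
            raise FormatError("keypoint scores outside [0, 1]")

    def serialize(self) -> np.ndarray:
        """Back to the flat 57-element layout."""
        head = [self.center_x, self.center_y, self.width, self.height,
                self.box_conf, self.class_conf]
        return np.concatenate([head, self.keypoints.ravel()])


def parse_pose_vector(raw) -> PoseVector:
    """Parse a flat 57-scalar record into a :class:`PoseVector`.

    Element layout: (Cx, Cy, W, H, box_conf, class_conf) followed by 17
    (x, y, score) triples, so keypoint ``i`` occupies elements ``6+3i`` to
    ``8+3i`` (0-indexed).
    """
    arr = np.asarray(raw, dtype=float).ravel()
    if arr.size != POSE_VECTOR_LENGTH:
        raise FormatError(
            f"pose vector must have exactly {POSE_VECTOR_LENGTH} elements, "
            f"got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise FormatError("pose vector contains non-finite values")
    return PoseVector(
        center_x=arr[0], center_y=arr[1], width=arr[2], height=arr[3],
        box_conf=arr[4], class_conf=arr[5],
        keypoints=arr[6:].reshape(N_JOINTS, 3),
    )


@dataclass
class SkeletonSequence:
    """One clip's pose track: (T, 17, 3) keypoints plus metadata."""

    clip_id: str
    fps: float
    keypoints: np.ndarray  # (T, 17, 3)
    label: str = UNKNOWN
    n_blank_removed: int = 0

    def __post_init__(self):
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        if self.keypoints.ndim != 3 or self.keypoints.shape[1:] != (N_JOINTS, 3):
            raise FormatError(
                f"keypoints must be (T, 17, 3), got {self.keypoints.shape}"
            )
        if self.keypoints.shape[0] < 1:
            raise FormatError("sequence must contain at least one frame")
        if self.fps <= 0:
            raise FormatError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.keypoints.shape[0]


def is_blank_frame(frame_kp: np.ndarray,
                   threshold: float = BLANK_SCORE_THRESHOLD) -> bool:
    """A frame with every keypoint score below ``threshold`` is blank."""
    return bool(np.all(frame_kp[:, 2] < threshold))


def _frames_from_json(path: Path) -> list[tuple[int, np.ndarray]]:
    with open(path) as fh:
        records = json.load(fh)
    if not isinstance(records, list) or not records:
        raise FormatError(f"{path}: expected a non-empty JSON list of frames")
    frames = []
    for idx, rec in enumerate(records):
        try:
            frame_no = int(rec["frame"])
            if "pose" in rec:
                kp = parse_pose_vector(rec["pose"]).keypoints
            else:
                kp = np.asarray(rec["keypoints"], dtype=float)
                if kp.shape != (N_JOINTS, 3):
                    raise FormatError(
                        f"keypoints entry must be 17x3, got {kp.shape}"
                    )
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: bad record at index {idx}: {exc}") from exc
        frames.append((frame_no, kp))
    return frames


CSV_HEADER = ["frame", "cx", "cy", "w", "h", "box_conf", "class_conf"] + [
    f"k{ax}{i}" for i in range(1, N_JOINTS + 1) for ax in ("x", "y", "s")
]


def _frames_from_csv(path: Path) -> list[tuple[int, np.ndarray]]:
    frames = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if len(header) != 1 + POSE_VECTOR_LENGTH:
            raise FormatError(
                f"{path}: expected {1 + POSE_VECTOR_LENGTH} columns, "
                f"got {len(header)}"
            )
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                frame_no = int(float(row[0]))
                pose = parse_pose_vector([float(v) for v in row[1:]])
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}: row {row_no}: {exc}") from exc
            frames.append((frame_no, pose.keypoints))
    return frames


def read_sequence(
    path,
    fmt: str | None = None,
    clip_id: str | None = None,
    fps: float = 25.0,
    label: str = UNKNOWN,
    blank_threshold: float = BLANK_SCORE_THRESHOLD,
) -> SkeletonSequence:
    """Read a keypoint file (JSON or CSV), drop blank frames, order by index.

    Blank frames — every keypoint score below ``blank_threshold`` — are
    eliminated; the count is kept on the returned sequence and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such keypoint file: {path}")
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "json"
    if fmt not in ("json", "csv"):
        raise FormatError(f"unknown keypoint format {fmt!r}")
    frames = _frames_from_json(path) if fmt == "json" else _frames_from_csv(path)
    if not frames:
        raise FormatError(f"{path}: no frames found")
    frames.sort(key=lambda fr: fr[0])
    kept = [kp for _, kp in frames if not is_blank_frame(kp, blank_threshold)]
    n_blank = len(frames) - len(kept)
    if n_blank:
        logger.info("%s: eliminated %d blank frame(s)", path, n_blank)
    if not kept:
        raise FormatError(f"{path}: all {len(frames)} frames are blank")
    return SkeletonSequence(
        clip_id=clip_id or path.stem,
        fps=fps,
        keypoints=np.stack(kept),
        label=label,
        n_blank_removed=n_blank,
    )


def write_sequence(seq: SkeletonSequence, path, fmt: str = "json") -> None:
    """Write a sequence in the keypoints-only JSON dialect (or CSV)."""
    path = Path(path)
    if fmt == "json":
        records = [
            {"frame": t, "keypoints": seq.keypoints[t].tolist()}
            for t in range(seq.n_frames)
        ]
        with open(path, "w") as fh:
            json.dump(records, fh)
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_HEADER)
            for t in range(seq.n_frames):
                kp = seq.keypoints[t]
                box = [kp[:, 0].mean(), kp[:, 1].mean(), 0.0, 0.0, 1.0, 1.0]
                writer.writerow([t] + [f"{v:.6g}" for v in box + kp.ravel().tolist()])
    else:
        raise FormatError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Skeleton graph
# ---------------------------------------------------------------------------


@dataclass
class SkeletonGraph:
    """17-node skeleton graph with a partitioned adjacency stack.

    ``adjacency_stack`` has shape (K, V, V) indexed [partition, target,
    source]; the stacks sum over partitions to the degree-normalized
    (A + I) support, so a constant node signal is preserved by the
    propagation operator.
    """

    n_joints: int
    edges: frozenset
    partition_strategy: str
    adjacency_stack: np.ndarray
    hop_to_root: np.ndarray = field(repr=False)

    @property
    def n_partitions(self) -> int:
        return self.adjacency_stack.shape[0]

    def support(self) -> np.ndarray:
        """Unnormalized (A + I) binary support pattern."""
        a = np.zeros((self.n_joints, self.n_joints))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        a += np.eye(self.n_joints)
        return a


def _hop_distance(n: int, edges, sources) -> np.ndarray:
    """BFS hop count from the nearest source node."""
    adj = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    dist = np.full(n, -1, dtype=int)
    queue = list(sources)
    for s in sources:
        dist[s] = 0
    while queue:
        u = queue.pop(0)
        for v in adj[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def build_skeleton_graph(
    partition_strategy: str = "spatial",
    edges=COCO_EDGES,
    n_joints: int = N_JOINTS,
    root_joints=(LEFT_HIP, RIGHT_HIP),
) -> SkeletonGraph:
    """Build the skeleton graph and its normalized partition stack.

    Partition strategies (neighborhoods are 1-hop, self included):

    - ``uni-label``: one partition holding the whole neighborhood (A + I).
    - ``distance``: self (hop 0) and neighbors (hop 1) in separate partitions.
    - ``spatial``: split by hop distance to the body root (the hips): same
      distance as the center node, closer (centripetal), farther
      (centrifugal).

    Each partition matrix is normalized by the total neighborhood degree, so
    the partitions *jointly* form a row-stochastic operator.
    """
    if partition_strategy not in PARTITION_STRATEGIES:
        raise ValueError(
            f"unknown partition strategy {partition_strategy!r}; "
            f"expected one of {PARTITION_STRATEGIES}"
        )
    a = np.zeros((n_joints, n_joints))
    for i, j in edges:
        a[i, j] = a[j, i] = 1.0
    support = a + np.eye(n_joints)
    hop = _hop_distance(n_joints, edges, root_joints)
    if np.any(hop < 0):
        raise ValueError("skeleton graph is not connected")

    if partition_strategy == "uni-label":
        parts = [support]
    elif partition_strategy == "distance":
        parts = [np.eye(n_joints), a]
    else:  # spatial configuration
        same = np.zeros_like(a)
        closer = np.zeros_like(a)
        farther = np.zeros_like(a)
        for tgt in range(n_joints):
            for src in range(n_joints):
                if support[tgt, src] == 0:
                    continue
                if hop[src] == hop[tgt]:
                    same[tgt, src] = 1.0
                elif hop[src] < hop[tgt]:
                    closer[tgt, src] = 1.0
                else:
                    farther[tgt, src] = 1.0
        parts = [same, closer, farther]

    degree = support.sum(axis=1)  # same for all nodes' full neighborhoods
    stack = np.stack([p / degree[:, None] for p in parts])
    return SkeletonGraph(
        n_joints=n_joints,
        edges=frozenset(tuple(sorted(e)) for e in edges),
        partition_strategy=partition_strategy,
        adjacency_stack=stack,
        hop_to_root=hop,
    )


def write_edge_list(graph: SkeletonGraph, path) -> None:
    """Export the edge set as a plain-text file for inspection."""
    with open(path, "w") as fh:
        fh.write("# source_index\ttarget_index\tsource_name\ttarget_name\n")
        for i, j in sorted(graph.edges):
            fh.write(f"{i}\t{j}\t{COCO_JOINTS[i]}\t{COCO_JOINTS[j]}\n")


# ---------------------------------------------------------------------------
# Normalization and motion stream
# ---------------------------------------------------------------------------


@dataclass
class NormalizedSequence:
    """Person-centric coordinates: (T, 17, C) with C=2 (or 3 with scores)."""

    tensor: np.ndarray
    clip_id: str
    fps: float
    label: str = UNKNOWN
    center: str = "hip_midpoint"
    scale: float = 1.0

    @property
    def n_frames(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[2]


def normalize_sequence(
    seq: SkeletonSequence, include_scores: bool = False
) -> NormalizedSequence:
    """Center each frame on the hip midpoint and scale by median torso length.

    The torso length is the hip-midpoint to shoulder-midpoint distance; its
    median over frames is the (single, global) scale factor.  The result is
    invariant to global translation and uniform scaling of the input.  The
    optional score channel is passed through untouched.
    """
    coords = seq.keypoints[:, :, :2].astype(float)
    scores = seq.keypoints[:, :, 2]
    hip_mid = coords[:, (LEFT_HIP, RIGHT_HIP), :].mean(axis=1)
    shoulder_mid = coords[:, (LEFT_SHOULDER, RIGHT_SHOULDER), :].mean(axis=1)
    torso = np.linalg.norm(shoulder_mid - hip_mid, axis=1)
    scale = float(np.median(torso))
    if not scale > 0:
        raise ValueError(
            "cannot normalize: median torso length is zero (all-zero or "
            "degenerate sequence)"
        )
    centered = (coords - hip_mid[:, None, :]) / scale
    tensor = (
        np.concatenate([centered, scores[:, :, None]], axis=2)
        if include_scores
        else centered
    )
    return NormalizedSequence(
        tensor=tensor,
        clip_id=seq.clip_id,
        fps=seq.fps,
        label=seq.label,
        scale=scale,
    )


def motion_stream(seq: NormalizedSequence) -> NormalizedSequence:
    """Frame-to-frame differences; frame 0 is all zeros; shape preserved."""
    if seq.n_frames < 2:
        raise ValueError("motion stream requires at least 2 frames")
    diff = np.zeros_like(seq.tensor)
    diff[1:] = seq.tensor[1:] - seq.tensor[:-1]
    return NormalizedSequence(
        tensor=diff,
        clip_id=seq.clip_id,
        fps=seq.fps,
        label=seq.label,
        center=seq.center,
        scale=seq.scale,
    )
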