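"""Core in-memory containers shared across the pipeline stages.

All containers are thin, validated wrappers around numpy arrays or pandas
frames.  Heavy computation lives in the stage modules; these classes only
guarantee shape/finiteness invariants and record provenance (stage tags).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DataError, StageError

__all__ = [
    "VertexTimeSeries",
    "MotionTrace",
    "QCThresholds",
    "QCRecord",
    "ICNTemplateSet",
    "ComponentSet",
    "SimilarityMatrix",
    "AlignedComponent",
]


def _as_float_matrix(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=np.float64)
    if arr.ndim != 2:
        raise DataError(f"{name} must be a 2-D matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class VertexTimeSeries:
    """One subject's T x V signal matrix with its sampling interval.

    ``stage_tag`` is an append-only record of the temporal transforms that
    have been applied; an operation refuses to re-apply itself silently.
    """

    data: np.ndarray  # T x V
    tr: float
    subject_id: str = "subject"
    stage_tag: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "data", _as_float_matrix(self.data, "data"))
        if self.data.shape[0] < 2:
            raise DataError("VertexTimeSeries needs at least 2 time points")
        if not (self.tr > 0):
            raise DataError(f"tr must be positive, got {self.tr}")
        object.__setattr__(self, "stage_tag", tuple(self.stage_tag))

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]

    def with_stage(self, data: np.ndarray, tag: str, *, force: bool = False) -> "VertexTimeSeries":
        """Return a copy with new data and ``tag`` appended to the stage log.

        Raises :class:`StageError` if ``tag`` is already present, unless
        ``force`` is set (re-application is then recorded twice, visibly).
        """
        if tag in self.stage_tag and not force:
            raise StageError(
                f"stage '{tag}' already applied to subject {self.subject_id!r} "
                f"(stage_tag={self.stage_tag}); pass force=True to re-apply"
            )
        return replace(self, data=data, stage_tag=self.stage_tag + (tag,))


@dataclass(frozen=True)
class MotionTrace:
    """T x 6 rigid-body head-motion parameters.

    Column order: 3 translations (mm), then 3 rotations (radians).
    """

    params: np.ndarray

    def __post_init__(self):
        p = _as_float_matrix(self.params, "motion params")
        if p.shape[1] != 6:
            raise DataError(f"motion trace must have 6 columns, got {p.shape[1]}")
        if p.shape[0] < 2:
            raise DataError("motion trace needs at least 2 frames")
        object.__setattr__(self, "params", p)

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass(frozen=True)
class QCThresholds:
    """Motion QC pass criteria (defaults: 3 mm, 3 degrees, 0.5 mm mean FD)."""

    max_tran_mm: float = 3.0
    max_rot_deg: float = 3.0
    mean_fd_mm: float = 0.5


@dataclass(frozen=True)
class QCRecord:
    subject_id: str
    max_tran: float  # mm, Euclidean distance from frame 0
    max_rot: float  # degrees, max absolute axis rotation from frame 0
    mean_fd: float  # mm
    rms_fd: float  # mm
    passes: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.passes.values())


@dataclass(frozen=True)
class ICNTemplateSet:
    """V x K matrix of labeled intrinsic-connectivity-network maps."""

    maps: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        m = _as_float_matrix(self.maps, "template maps")
        labels = tuple(self.labels)
        if len(labels) != m.shape[1]:
            raise DataError(
                f"{len(labels)} labels for {m.shape[1]} template columns"
            )
        if len(set(labels)) != len(labels):
            raise DataError("template labels must be unique")
        if np.any(m.std(axis=0) == 0):
            raise DataError("template columns must have nonzero variance")
        object.__setattr__(self, "maps", m)
        object.__setattr__(self, "labels", labels)

    @property
    def n_vertices(self) -> int:
        return self.maps.shape[0]

    @property
    def n_networks(self) -> int:
        return self.maps.shape[1]


@dataclass(frozen=True)
class ComponentSet:
    """Per-subject spatial ICA output: z-scored maps and their time courses."""

    subject_id: str
    maps: np.ndarray  # V x K_s, z-scored, skewness >= 0
    courses: np.ndarray  # T x K_s
    seed: int = 0

    def __post_init__(self):
        m = _as_float_matrix(self.maps, "component maps")
        c = _as_float_matrix(self.courses, "component courses")
        if m.shape[1] != c.shape[1]:
            raise DataError("maps and courses disagree on component count")
        if m.shape[1] < 1:
            raise DataError("need at least one component")
        object.__setattr__(self, "maps", m)
        object.__setattr__(self, "courses", c)

    @property
    def n_components(self) -> int:
        return self.maps.shape[1]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Full NMI similarity matrix over all ICs pooled across subjects.

    ``subject_index[i]`` gives the subject (as an index into ``subject_ids``)
    owning pooled component ``i``; ``component_index[i]`` its within-subject
    index.  Within-subject pairs are present in ``values`` but are never
    candidates for cross-subject matching.
    """

    values: np.ndarray
    subject_ids: tuple[str, ...]
    subject_index: np.ndarray  # int, per pooled IC
    component_index: np.ndarray  # int, per pooled IC

    def __post_init__(self):
        v = _as_float_matrix(self.values, "similarity values")
        if v.shape[0] != v.shape[1]:
            raise DataError("similarity matrix must be square")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "subject_index", np.asarray(self.subject_index, dtype=int))
        object.__setattr__(self, "component_index", np.asarray(self.component_index, dtype=int))
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))

    @property
    def n_pooled(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def pooled_row(self, subject: int, component: int) -> int:
        hits = np.flatnonzero(
            (self.subject_index == subject) & (self.component_index == component)
        )
        if hits.size != 1:
            raise DataError(f"no pooled IC for subject {subject}, component {component}")
        return int(hits[0])


@dataclass(frozen=True)
class AlignedComponent:
    """A cross-subject set of matched ICs, one per subject, with consistency
    statistics filled in by the centrality/permutation stage."""

    members: tuple[tuple[str, int], ...]  # (subject_id, component_index), one per subject
    inter_subject_similarity: np.ndarray | None = None  # N x N
    centrality: np.ndarray | None = None  # N
    centrality_p: np.ndarray | None = None  # N
    group_map: np.ndarray | None = None  # V, z-scored
    consistency: float | None = None

    def __post_init__(self):
        subs = [s for s, _ in self.members]
        if len(set(subs)) != len(subs):
            raise DataError("an aligned component holds exactly one IC per subject")
        object.__setattr__(self, "members", tuple((s, int(c)) for s, c in self.members))

    @property
    def n_subjects(self) -> int:
        return len(self.members)
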