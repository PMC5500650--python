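"""Cross-subject alignment of per-subject spatial ICA components.

The procedure follows the ranking-and-averaging family of group-ICA
alignment methods: spatial independent components are estimated per subject,
normalized mutual information (NMI) between every pair of pooled ICs yields
a full similarity matrix, a greedy search matches ICs across subjects into
aligned components (ACs, one IC per subject), each member's centrality (the
sum of its similarities to the other members) is tested against a
within-subject resampling null by permutation, and centrality-weighted
averages of the member maps give group-level network maps.  ACs whose
significant-member fraction exceeds 60% of the subjects are retained as
intrinsic-connectivity-network templates.

ICA sign indeterminacy is resolved by flipping each map to non-negative
skewness before any similarity or averaging step.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import ConfigError, DataError, DegenerateInputError, IcaConvergenceError
from .types import (
    AlignedComponent,
    ComponentSet,
    ICNTemplateSet,
    SimilarityMatrix,
    VertexTimeSeries,
)

__all__ = [
    "decompose_subject",
    "estimate_n_components",
    "nmi",
    "build_similarity_matrix",
    "match_components",
    "centrality_and_permutation",
    "group_map",
    "consistency_filter",
    "align_components",
]


def estimate_n_components(
    ts: VertexTimeSeries, variance_threshold: float = 0.9, max_components: int = 30
) -> int:
    """Model-order heuristic: smallest K whose PCA explains the requested
    variance fraction of the time dimension (capped)."""
    cap = min(max_components, ts.n_timepoints - 1, ts.n_vertices - 1)
    pca = PCA(n_components=cap).fit(ts.data.T)
    cum = np.cumsum(pca.explained_variance_ratio_)
    return int(np.searchsorted(cum, variance_threshold) + 1)


def decompose_subject(
    ts: VertexTimeSeries,
    n_components: int | str = 6,
    seed: int = 0,
    *,
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> ComponentSet:
    """Seeded spatial ICA of one subject's scan.

    The scan is decomposed as X ~ A S^T with S the V x K spatial maps
    (treated as the independent sources) and A the T x K time courses.
    Maps are z-scored and sign-aligned to non-negative skewness.
    ``n_components="auto"`` uses the 90%-variance PCA heuristic.

    Raises :class:`IcaConvergenceError` (retriable, carrying the seed and
    iteration count) if FastICA does not converge.
    """
    if n_components == "auto":
        n_components = estimate_n_components(ts)
    k = int(n_components)
    if k >= min(ts.n_timepoints, ts.n_vertices):
        raise ConfigError(
            f"n_components={k} must be below min(T, V)={min(ts.n_timepoints, ts.n_vertices)}"
        )
    ica = FastICA(
        n_components=k,
        random_state=seed,
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        maps = ica.fit_transform(ts.data.T)  # V x K sources
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        raise IcaConvergenceError(
            f"spatial ICA did not converge for subject {ts.subject_id!r} "
            f"(seed={seed}, n_iter={ica.n_iter_}); retry with another seed",
            seed=seed,
            n_iter=int(ica.n_iter_),
        )
    courses = ica.mixing_  # T x K
    maps = maps - maps.mean(axis=0)
    sd = maps.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateInputError("ICA produced a zero-variance map")
    maps = maps / sd
    flip = np.where(sps.skew(maps, axis=0) < 0, -1.0, 1.0)
    return ComponentSet(
        subject_id=ts.subject_id, maps=maps * flip, courses=courses * flip, seed=seed
    )


def nmi(map_a: np.ndarray, map_b: np.ndarray, n_bins: int = 64) -> float:
    """Normalized mutual information of two maps, in [0, 1].

    Joint histogram with ``n_bins`` equal-width bins per axis over each
    map's own range; MI normalized as MI / sqrt(H_x * H_y).  Because binning
    is re-derived per map, NMI is invariant to monotone transforms
    (including negation up to bin-edge symmetry).
    """
    a = np.asarray(map_a, dtype=np.float64).ravel()
    b = np.asarray(map_b, dtype=np.float64).ravel()
    if a.size != b.size:
        raise DataError("maps must share the vertex grid")
    if a.size < n_bins:
        raise DataError(f"need at least n_bins={n_bins} vertices, got {a.size}")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("zero-variance map has undefined NMI")
    joint, _, _ = np.histogram2d(a, b, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = px[:, None] * py[None, :]
    mi = float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))
    hx = float(-np.sum(px[px > 0] * np.log(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log(py[py > 0])))
    if hx == 0 or hy == 0:
        raise DegenerateInputError("single-bin map has zero entropy")
    return float(np.clip(mi / np.sqrt(hx * hy), 0.0, 1.0))


def build_similarity_matrix(
    components: list[ComponentSet], n_bins: int = 64
) -> SimilarityMatrix:
    """Full pooled-IC NMI matrix (symmetric, unit diagonal).

    Within-subject pairs are computed and recorded but marked non-matchable
    through the subject index carried by the result.
    """
    if len(components) < 2:
        raise DataError("need at least 2 subjects")
    subject_ids = tuple(c.subject_id for c in components)
    if len(set(subject_ids)) != len(subject_ids):
        raise DataError("duplicate subject ids in component sets")
    sub_idx, comp_idx, maps = [], [], []
    for s, cs in enumerate(components):
        for k in range(cs.n_components):
            sub_idx.append(s)
            comp_idx.append(k)
            maps.append(cs.maps[:, k])
    m = len(maps)
    values = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            try:
                v = nmi(maps[i], maps[j], n_bins=n_bins)
            except DegenerateInputError as exc:
                raise DegenerateInputError(
                    f"NMI failed for (subject {subject_ids[sub_idx[i]]}, IC {comp_idx[i]}) "
                    f"vs (subject {subject_ids[sub_idx[j]]}, IC {comp_idx[j]}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(
        values=values,
        subject_ids=subject_ids,
        subject_index=np.array(sub_idx),
        component_index=np.array(comp_idx),
    )


def match_components(sim: SimilarityMatrix) -> list[AlignedComponent]:
    """Greedy seed-and-grow matching of ICs into aligned components.

    Each AC is seeded with the globally largest unassigned cross-subject
    similarity; the remaining subjects then join best-first — at every step
    the (subject, IC) candidate with the highest mean similarity to the
    current members is added — so each remaining subject contributes its
    best-matching unassigned IC and the result does not depend on subject
    input order.  ICs are consumed (each belongs to at most one AC);
    matching stops once any subject runs out of ICs.  Exact ties break by
    (subject index, component index), keeping the procedure deterministic.
    """
    n_sub = sim.n_subjects
    avail = np.ones(sim.n_pooled, dtype=bool)
    cross = sim.subject_index[:, None] != sim.subject_index[None, :]
    acs: list[AlignedComponent] = []
    while all(avail[sim.subject_index == s].any() for s in range(n_sub)):
        masked = np.where(cross & avail[:, None] & avail[None, :], sim.values, -np.inf)
        flat = int(np.argmax(masked))  # first max in (subject, component) order
        i, j = divmod(flat, sim.n_pooled)
        if not np.isfinite(masked[i, j]):
            break
        members = {int(sim.subject_index[i]): i, int(sim.subject_index[j]): j}
        while len(members) < n_sub:
            cands = np.flatnonzero(
                avail & ~np.isin(sim.subject_index, list(members))
            )
            scores = sim.values[np.ix_(cands, list(members.values()))].mean(axis=1)
            best = int(cands[int(np.argmax(scores))])
            members[int(sim.subject_index[best])] = best
        for row in members.values():
            avail[row] = False
        acs.append(
            AlignedComponent(
                members=tuple(
                    (sim.subject_ids[s], int(sim.component_index[members[s]]))
                    for s in sorted(members)
                )
            )
        )
    return acs


def centrality_and_permutation(
    ac: AlignedComponent,
    sim: SimilarityMatrix,
    n_perm: int = 1000,
    seed=0,
    alpha: float = 0.05,
) -> AlignedComponent:
    """Centrality of each member IC and its permutation p-value.

    The observed centrality of subject i's IC is the sum of its similarities
    to the other members.  The null resamples, for every other subject, a
    uniformly random IC of that subject (the similarity matrix already holds
    all needed entries) and recomputes subject i's centrality;
    p_i = (1 + #{null >= observed}) / (n_perm + 1).  A subject whose peers
    all own a single IC has a degenerate null and p = 1.  ``consistency`` is
    the fraction of subjects with p < ``alpha``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sub_of = {sid: s for s, sid in enumerate(sim.subject_ids)}
    rows = np.array([sim.pooled_row(sub_of[sid], c) for sid, c in ac.members])
    n = rows.size
    inter = sim.values[np.ix_(rows, rows)].copy()
    np.fill_diagonal(inter, 1.0)
    centrality = inter.sum(axis=1) - np.diag(inter)
    pools = [np.flatnonzero(sim.subject_index == sub_of[sid]) for sid, _ in ac.members]
    pvals = np.empty(n)
    for i in range(n):
        null = np.zeros(n_perm)
        degenerate = True
        for j in range(n):
            if j == i:
                continue
            pool = pools[j]
            if pool.size > 1:
                degenerate = False
            vals = sim.values[rows[i], pool]
            null += vals[rng.integers(0, pool.size, size=n_perm)]
        if degenerate:
            warnings.warn(
                f"degenerate permutation null for {ac.members[i][0]} "
                "(peer subjects own a single IC); p fixed at 1",
                RuntimeWarning,
                stacklevel=2,
            )
            pvals[i] = 1.0
        else:
            pvals[i] = (1.0 + np.sum(null >= centrality[i] - 1e-12)) / (n_perm + 1.0)
    consistency = float(np.mean(pvals < alpha))
    return AlignedComponent(
        members=ac.members,
        inter_subject_similarity=inter,
        centrality=centrality,
        centrality_p=pvals,
        group_map=ac.group_map,
        consistency=consistency,
    )


def group_map(ac: AlignedComponent, components: list[ComponentSet]) -> AlignedComponent:
    """Centrality-weighted average of the member maps, z-scored.

    (Any |Z| threshold is a rendering choice, not applied here.)
    """
    if ac.centrality is None:
        raise DataError("centralities must be computed before the group map")
    w = np.asarray(ac.centrality, dtype=np.float64)
    if w.sum() <= 0:
        raise DegenerateInputError("all centralities are zero; group map undefined")
    w = w / w.sum()
    by_id = {c.subject_id: c for c in components}
    stack = np.column_stack([by_id[sid].maps[:, k] for sid, k in ac.members])
    gm = stack @ w
    sd = gm.std()
    if sd == 0:
        raise DegenerateInputError("group map has zero variance")
    gm = (gm - gm.mean()) / sd
    return AlignedComponent(
        members=ac.members,
        inter_subject_similarity=ac.inter_subject_similarity,
        centrality=ac.centrality,
        centrality_p=ac.centrality_p,
        group_map=gm,
        consistency=ac.consistency,
    )


def consistency_filter(
    acs: list[AlignedComponent], min_fraction: float = 0.6, alpha: float = 0.05
) -> ICNTemplateSet | None:
    """Retain ACs significantly consistent across more than ``min_fraction``
    of the subjects (strict inequality) and stack their group maps into a
    labeled template set (ICN01, ICN02, ...).

    Returns None (with a warning) when nothing survives.
    """
    kept = []
    for ac in acs:
        if ac.centrality_p is None:
            raise DataError("p-values must be filled before consistency filtering")
        frac = (
            ac.consistency
            if ac.consistency is not None
            else float(np.mean(ac.centrality_p < alpha))
        )
        if frac > min_fraction:
            if ac.group_map is None:
                raise DataError("group maps must be computed before filtering")
            kept.append(ac)
    if not kept:
        warnings.warn(
            "no aligned component passed the consistency filter; empty template set",
            RuntimeWarning,
            stacklevel=2,
        )
        return None
    maps = np.column_stack([ac.group_map for ac in kept])
    labels = tuple(f"ICN{i + 1:02d}" for i in range(len(kept)))
    return ICNTemplateSet(maps=maps, labels=labels)


def align_components(
    components: list[ComponentSet],
    *,
    n_bins: int = 64,
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_fraction: float = 0.6,
    seed: int = 0,
) -> tuple[list[AlignedComponent], ICNTemplateSet | None]:
    """Full alignment pass: similarity matrix -> greedy matching ->
    centrality/permutation -> group maps -> consistency filter."""
    sim = build_similarity_matrix(components, n_bins=n_bins)
    rng = np.random.default_rng(seed)
    acs = []
    for ac in match_components(sim):
        ac = centrality_and_permutation(ac, sim, n_perm=n_perm, seed=rng, alpha=alpha)
        ac = group_map(ac, components)
        acs.append(ac)
    templates = consistency_filter(acs, min_fraction=min_fraction, alpha=alpha)
    return acs, templates
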