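"""Global quartile binarization and occupancy summaries of WW maps.

The 25/50/75th percentiles are computed over the pooled multiset of every
non-missing WW cell of every subject and pair (the "global quartiles"),
using linear interpolation between order statistics.  Each WW map is then
split into four binary occupancy masks:

    Q1: v <= q25,   Q2: q25 < v <= q50,   Q3: q50 < v <= q75,   Q4: v > q75

(boundary values fall to the lower bin).  Two summary measures are taken
per mask: the cell count, and the average size of 4-connected clusters
(vertical/horizontal adjacency only; single cells count as clusters of
size one; an empty mask has average size 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as _sk_label

from .coupling import WWMap, component_pairs
from .io_core import CohortMetadata, ValidationError

MEASURES = ("cell_count", "avg_cluster_size")

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class QuartileThresholds:
    q25: float
    q50: float
    q75: float

    def as_array(self) -> np.ndarray:
        return np.array([self.q25, self.q50, self.q75])


@dataclass
class QuartileMasks:
    """The four binary occupancy masks of one WW map (a partition)."""

    masks: np.ndarray  # (4, Tw, Tw) boolean


def global_quartiles(ww_values: Iterable) -> QuartileThresholds:
    """Pooled 25/50/75th percentiles of all finite WW cells.

    Accepts any iterable of arrays (or a single array); NaN cells (missing
    in lenient mode) are excluded.
    """
    if isinstance(ww_values, np.ndarray):
        chunks = [ww_values.reshape(-1)]
    else:
        chunks = [np.asarray(c).reshape(-1) for c in ww_values]
    if not chunks:
        raise ValidationError("no WW values supplied")
    pooled = np.concatenate(chunks) if len(chunks) > 1 else chunks[0].copy()
    if not np.isfinite(pooled).all():
        pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise ValidationError("no finite WW values to pool")
    # quantile in the pooled dtype, partitioning the private copy in place
    q25, q50, q75 = np.quantile(pooled, [0.25, 0.5, 0.75], overwrite_input=True)
    return QuartileThresholds(float(q25), float(q50), float(q75))


def quartile_index(values: np.ndarray, th: QuartileThresholds) -> np.ndarray:
    """Quartile bin (0..3) per cell; -1 for missing (NaN) cells."""
    v = np.asarray(values)
    idx = np.searchsorted(th.as_array(), v, side="left").astype(np.int8)
    idx[~np.isfinite(v)] = -1
    return idx


def binarize(ww: WWMap, th: QuartileThresholds) -> QuartileMasks:
    """Split one WW map into four binary masks; missing cells are 0 in all."""
    idx = quartile_index(ww.r, th)
    return QuartileMasks(masks=np.stack([idx == q for q in range(4)]))


def cell_count(mask: np.ndarray) -> int:
    """Number of 1-cells in a binary mask."""
    return int(np.count_nonzero(mask))


def cluster_sizes(mask: np.ndarray) -> list[int]:
    """Sizes of 4-connected components (no diagonal adjacency), singletons included."""
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=_FOUR_CONN)
    if n == 0:
        return []
    return np.bincount(labels.ravel())[1:].tolist()


def avg_cluster_size(mask: np.ndarray) -> float:
    """Mean 4-connected cluster size; 0.0 for an empty mask."""
    sizes = cluster_sizes(mask)
    return float(np.mean(sizes)) if sizes else 0.0


def _summaries_one_map(qidx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cell counts and average cluster sizes per quartile from a bin-index map.

    A single connected-component labelling of the index map yields the
    clusters of all four quartile masks at once (regions of equal bin value
    are exactly the 4-connected clusters of each mask).
    """
    counts = np.bincount(qidx.ravel()[qidx.ravel() >= 0], minlength=4)[:4].astype(float)
    labels = _sk_label(qidx + 2, connectivity=1, background=1)  # missing (-1) -> background
    avg = np.zeros(4)
    nlab = labels.max()
    if nlab:
        sizes = np.bincount(labels.ravel())[1:]
        region_q = np.zeros(nlab + 1, dtype=np.int8)
        region_q[labels.ravel()] = qidx.ravel()
        rq = region_q[1:]
        for q in range(4):
            sel = sizes[rq == q]
            if sel.size:
                avg[q] = sel.mean()
    return counts, avg


def summarize_subject(
    ww_maps: list[WWMap], th: QuartileThresholds
) -> pd.DataFrame:
    """Per-pair, per-quartile cell counts and average cluster sizes.

    Returns four rows per pair with columns
    ``subject,pair_i,pair_j,quartile,cell_count,avg_cluster_size``.
    """
    records = []
    for m in ww_maps:
        qidx = quartile_index(m.r, th)
        counts, avg = _summaries_one_map(qidx)
        for q in range(4):
            records.append(
                (m.subject_id, m.pair[0], m.pair[1], q + 1, counts[q], avg[q])
            )
    return pd.DataFrame(
        records,
        columns=["subject", "pair_i", "pair_j", "quartile", "cell_count", "avg_cluster_size"],
    )


def summarize_stack(ww_stack: np.ndarray, th: QuartileThresholds) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized summaries for one subject's (n_pairs, Tw, Tw) map stack.

    Returns ``(counts, avg_sizes)`` each of shape (n_pairs, 4); equal to
    the per-map route in :func:`summarize_subject`.
    """
    n_pairs = ww_stack.shape[0]
    counts = np.empty((n_pairs, 4))
    avgs = np.empty((n_pairs, 4))
    for p in range(n_pairs):
        qidx = quartile_index(ww_stack[p], th)
        counts[p], avgs[p] = _summaries_one_map(qidx)
    return counts, avgs


def subgroup_average(
    summaries: pd.DataFrame,
    metadata: CohortMetadata,
    grouping: str,
    n_components: int,
) -> dict[tuple[str, int, str], np.ndarray]:
    """Group-mean C x C matrices per (group level, quartile, measure).

    ``grouping`` is ``"diagnosis"`` or ``"sex"``.  Cell (i, j) of a matrix
    is the mean over the group's subjects of that pair's summary value; the
    matrix is symmetric with NaN on the diagonal (self-pairs are undefined).
    """
    if grouping not in ("diagnosis", "sex"):
        raise ValidationError(f"grouping must be 'diagnosis' or 'sex', got {grouping!r}")
    group_of = dict(zip(metadata.table["subject_id"], metadata.table[grouping]))
    df = summaries.copy()
    df["group"] = df["subject"].map(group_of)
    if df["group"].isna().any():
        missing = sorted(set(df.loc[df["group"].isna(), "subject"]))
        raise ValidationError(f"subjects missing from metadata: {missing}")
    out: dict[tuple[str, int, str], np.ndarray] = {}
    grouped = df.groupby(["group", "quartile", "pair_i", "pair_j"], sort=True)[list(MEASURES)].mean()
    for (level, quartile), sub in grouped.groupby(level=["group", "quartile"]):
        for measure in MEASURES:
            mat = np.full((n_components, n_components), np.nan)
            ii = sub.index.get_level_values("pair_i").to_numpy()
            jj = sub.index.get_level_values("pair_j").to_numpy()
            vals = sub[measure].to_numpy()
            mat[ii, jj] = vals
            mat[jj, ii] = vals
            out[(str(level), int(quartile), measure)] = mat
    return out
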