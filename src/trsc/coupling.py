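"""Window-by-window (WW) spectral correlation maps.

For a pair of components (i, j), the WW map is the Tw x Tw matrix whose
entry (a, b) is the Pearson correlation, across the S frequency bins,
between component i's power spectrum in window a and component j's power
spectrum in window b.  With C components there are C(C-1)/2 unordered
pairs — 1081 for the 47-component study configuration.

A window whose power spectrum is constant across bins has no defined
correlation; ``strict`` mode (default) raises, ``lenient`` mode marks the
affected cells NaN so that downstream pooling skips them.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .io_core import ValidationError
from .spectra import Spectrogram


@dataclass
class WWMap:
    """WW spectral-correlation map of one unordered component pair (i < j)."""

    subject_id: str
    pair: tuple[int, int]
    r: np.ndarray  # Tw x Tw; NaN marks missing cells in lenient mode


def component_pairs(n_components: int) -> list[tuple[int, int]]:
    """All unordered component pairs (i, j), i < j, lexicographic."""
    if n_components < 2:
        raise ValidationError("need at least 2 components for pairwise coupling")
    return list(combinations(range(n_components), 2))


def _normalize_columns(power: np.ndarray, strict: bool, context: str = "") -> np.ndarray:
    """Zero-mean, unit-norm columns so r = Zi^T Zj is the Pearson matrix."""
    centered = power - power.mean(axis=-2, keepdims=True)
    norm = np.linalg.norm(centered, axis=-2, keepdims=True)
    degenerate = norm == 0
    if degenerate.any():
        if strict:
            where = np.argwhere(np.squeeze(degenerate, axis=-2))
            raise ValidationError(
                f"zero-variance power spectrum ({context} window(s) {where.ravel().tolist()[:5]}); "
                "use lenient mode to mark these cells missing"
            )
        norm = np.where(degenerate, np.nan, norm)
    return centered / norm


def ww_map(
    spec_i: Spectrogram, spec_j: Spectrogram, subject_id: str = "", pair: tuple[int, int] = (0, 1),
    strict: bool = True,
) -> WWMap:
    """Correlate every window of ``spec_i`` with every window of ``spec_j``."""
    pi, pj = np.asarray(spec_i.power, float), np.asarray(spec_j.power, float)
    if pi.shape != pj.shape:
        raise ValidationError(f"spectrogram shapes differ: {pi.shape} vs {pj.shape}")
    zi = _normalize_columns(pi, strict, context=f"subject {subject_id!r} component {pair[0]}")
    zj = _normalize_columns(pj, strict, context=f"subject {subject_id!r} component {pair[1]}")
    r = zi.T @ zj
    np.clip(r, -1.0, 1.0, out=r)
    return WWMap(subject_id=subject_id, pair=pair, r=r)


def all_pairs(
    spectrograms: list[Spectrogram], subject_id: str = "", strict: bool = True
) -> list[WWMap]:
    """WW maps for all C(C-1)/2 unordered pairs, ordered lexicographically."""
    pairs = component_pairs(len(spectrograms))
    return [
        ww_map(spectrograms[i], spectrograms[j], subject_id=subject_id, pair=(i, j), strict=strict)
        for i, j in pairs
    ]


def ww_map_stack(power: np.ndarray, strict: bool = True, dtype=np.float32) -> np.ndarray:
    """Vectorized WW maps for one subject.

    ``power`` is (C, S, Tw); returns (n_pairs, Tw, Tw) in pair-lexicographic
    order, equal to the per-pair :func:`ww_map` output.  Stored at reduced
    precision (float32 by default) because a full cohort of maps is the
    pipeline's largest intermediate.
    """
    power = np.asarray(power, dtype=float)
    z = _normalize_columns(power, strict)  # (C, S, Tw)
    pairs = component_pairs(power.shape[0])
    out = np.empty((len(pairs), power.shape[2], power.shape[2]), dtype=dtype)
    for p, (i, j) in enumerate(pairs):
        r = z[i].T @ z[j]
        np.clip(r, -1.0, 1.0, out=r)
        out[p] = r
    return out
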