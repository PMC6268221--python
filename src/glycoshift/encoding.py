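"""Fixed-length sorted-shift descriptors.

Every compound is encoded as 23 values C1..C23: its 13C chemical shifts
sorted in ascending order, with zeros *prepended* when fewer than 23
carbons are present.  Front padding anchors the top of the vector to the
highest-ppm carbons, so C23 always holds the most downfield resonance
(the N-acetyl carbonyl when present, otherwise an anomeric carbon) and
C6 is diagnostic for 6-deoxy methyl groups in full-size compounds.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .records import MAX_SHIFTS, PPM_HIGH, PPM_LOW, SpectrumRecord

N_DESCRIPTORS = MAX_SHIFTS


def descriptor_names() -> list[str]:
    """The 1-based external descriptor names C1..C23."""
    return [f"C{i}" for i in range(1, N_DESCRIPTORS + 1)]


def encode_shifts(shifts_ppm: Sequence[float]) -> np.ndarray:
    """Encode a raw shift list as the ascending, front-zero-padded 23-vector.

    The operation is permutation-invariant and idempotent (a sorted,
    already padded vector re-encodes to itself, zeros being rejected by
    validation only for *raw* inputs of full length; padding zeros are
    never passed back in practice because records carry raw shifts).
    """
    values = np.asarray(shifts_ppm, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a one-dimensional shift list")
    if values.size == 0:
        raise ValueError("empty shift list")
    if values.size > N_DESCRIPTORS:
        raise ValueError(f"{values.size} shifts exceed the {N_DESCRIPTORS}-slot descriptor")
    if np.any(~np.isfinite(values)) or np.any(values <= PPM_LOW) or np.any(values >= PPM_HIGH):
        raise ValueError(f"shifts must lie in ({PPM_LOW}, {PPM_HIGH}) ppm")
    out = np.zeros(N_DESCRIPTORS, dtype=float)
    out[N_DESCRIPTORS - values.size :] = np.sort(values)
    return out


def descriptor_matrix(records: Sequence[SpectrumRecord]) -> tuple[np.ndarray, list[str]]:
    """Stack per-record encodings into an (n x 23) matrix plus the id index."""
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for rec in records:
        try:
            rows.append(encode_shifts(rec.shifts_ppm))
        except ValueError as exc:
            raise ValueError(f"record {rec.id}: {exc}") from exc
        ids.append(rec.id)
    if not rows:
        return np.empty((0, N_DESCRIPTORS)), []
    return np.vstack(rows), ids
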