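"""Pairwise evolutionary distances with classical corrections.

Three models are provided, matching the menu of the distance stage:

``p``
    Raw mismatch fraction over comparable columns.
``felsenstein_nt``
    F81-type correction for nucleotides, ``d = -B * ln(1 - p/B)`` with
    ``B = 1 - sum(pi_i^2)`` from empirical base frequencies (0.75 when
    uniform).
``pam_aa``
    Kimura's approximation to the PAM protein distance,
    ``d = -ln(1 - p - 0.2 p^2)``.

A pair whose ``p`` reaches the domain boundary of its correction is
assigned the saturation ceiling ``d_max`` with a warning.  Columns where
either sequence is missing (``?``) or gapped (``-``) are excluded from
the comparison; a pair with no comparable column at all is an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger("guildphylo")

_MISSING = {"?", "-"}


@dataclass
class DistanceModel:
    kind: str = "p"  # p | felsenstein_nt | pam_aa
    B: float | None = None  # felsenstein_nt only; computed from data if None
    d_max: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("p", "felsenstein_nt", "pam_aa"):
            raise ValueError(f"unknown distance model {self.kind!r}")
        if self.B is not None and not (0 < self.B <= 1):
            raise ValueError("B must be in (0, 1]")


def _rows_of(data) -> tuple[list[str], list[str]]:
    """Accept a CharacterMatrix, an Alignment, or (taxa, rows)."""
    if hasattr(data, "taxa") and hasattr(data, "rows"):
        return list(data.taxa), list(data.rows)
    taxa, rows = data
    return list(taxa), list(rows)


def _empirical_B(rows: list[str]) -> float:
    counts: dict[str, int] = {}
    total = 0
    for row in rows:
        for c in row:
            if c in _MISSING:
                continue
            counts[c] = counts.get(c, 0) + 1
            total += 1
    if total == 0:
        return 0.75
    freqs = np.array([v / total for v in counts.values()])
    return float(1.0 - np.sum(freqs**2))


def correct_distance(p: float, model: DistanceModel, B: float | None = None) -> float:
    """Apply the model's correction to a raw mismatch fraction."""
    if p == 0.0:
        return 0.0
    if model.kind == "p":
        return p
    if model.kind == "felsenstein_nt":
        b = model.B if model.B is not None else (B if B is not None else 0.75)
        if p >= b:
            log.warning("distance saturated (p=%.4f >= B=%.4f); using d_max", p, b)
            return model.d_max
        return float(-b * np.log(1.0 - p / b))
    # pam_aa
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        log.warning("distance saturated (p=%.4f); using d_max", p)
        return model.d_max
    return float(-np.log(arg))


def pairwise_distances(data, model: DistanceModel | None = None) -> tuple[list[str], np.ndarray]:
    """Symmetric distance table over all taxon pairs.

    Returns ``(taxa, D)`` with ``D[i, i] = 0``.  Column weights may be
    supplied by pre-expanding the rows; bootstrap uses the faster
    weighted path in :mod:`guildphylo.trees.bootstrap` instead.
    """
    model = model or DistanceModel()
    taxa, rows = _rows_of(data)
    if len(taxa) < 2:
        raise ValueError("need >= 2 taxa")
    arr = np.array([list(r) for r in rows])
    ok = ~np.isin(arr, list(_MISSING))
    n = len(taxa)
    B = _empirical_B(rows) if model.kind == "felsenstein_nt" and model.B is None else None
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = ok[i] & ok[j]
            ncomp = int(comp.sum())
            if ncomp == 0:
                raise ValueError(f"no comparable columns for pair ({taxa[i]}, {taxa[j]})")
            p = float((arr[i, comp] != arr[j, comp]).sum() / ncomp)
            D[i, j] = D[j, i] = correct_distance(p, model, B)
    return taxa, D
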