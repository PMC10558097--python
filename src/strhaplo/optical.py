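"""Optical genome mapping: repeat sizing from molecule length deltas.

A molecule's repeat content is the difference between its inter-marker
size and the reference inter-marker distance, divided by the repeat unit
length (6 bp for a hexanucleotide).  Unit counts are floor-rounded: a
partial unit is not a full unit.  The spread of per-molecule sizes within
one individual reflects somatic instability of the repeat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .loci import InvalidParameterError
from .simulate import OpticalMoleculeSet


@dataclass(frozen=True)
class OpticalSummary:
    n_molecules: int
    mean_delta: float
    median_delta: float
    min_delta: float
    max_delta: float
    unit_counts: list[int]
    instability_ratio: float  # max_delta / median_delta


def molecules_to_units(deltas, unit_len: int = 6) -> np.ndarray:
    """Repeat-unit counts from molecule size deltas: floor(delta / unit_len).

    Negative deltas (molecule smaller than reference) are clipped to zero
    with a warning.
    """
    if unit_len <= 0:
        raise InvalidParameterError("unit_len must be positive")
    deltas = np.asarray(deltas, dtype=float)
    if np.any(deltas < 0):
        warnings.warn("negative molecule deltas clipped to 0", stacklevel=2)
        deltas = np.maximum(deltas, 0.0)
    return np.floor_divide(deltas, unit_len).astype(np.int64)


def summarize_molecules(mset: OpticalMoleculeSet) -> OpticalSummary:
    """Expansion size and somatic-instability summary for one molecule set."""
    deltas = np.asarray(mset.deltas, dtype=float)
    if deltas.size == 0:
        raise InvalidParameterError("empty molecule set")
    median = float(np.median(deltas))
    return OpticalSummary(
        n_molecules=int(deltas.size),
        mean_delta=float(deltas.mean()),
        median_delta=median,
        min_delta=float(deltas.min()),
        max_delta=float(deltas.max()),
        unit_counts=[int(u) for u in molecules_to_units(deltas,
                                                        mset.unit_len)],
        instability_ratio=float(deltas.max() / median) if median > 0
        else float("inf"))
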