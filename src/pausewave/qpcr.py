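"""Small qPCR quantification helpers used throughout the assay figures.

Two standard pieces of arithmetic: the delta-delta-Cq fold change with
multi-reference normalization, and percent-of-input for ChIP / RNA-IP
recovery.  Cq values are PCR quantification cycles; ``efficiency`` is the
per-cycle amplification factor (2.0 = perfect doubling), so a quantity is
proportional to ``efficiency**-Cq``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["CqRecord", "ddcq_fold_change", "percent_of_input"]


@dataclass
class CqRecord:
    """One qPCR measurement: target amplicon, sample, quantification cycle."""

    target: str
    sample: str
    cq: float
    efficiency: float = 2.0
    input_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.cq <= 0:
            raise ValueError("Cq must be positive")
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must be in (1, 2]")
        if not 0.0 < self.input_fraction <= 1.0:
            raise ValueError("input_fraction must be in (0, 1]")


def _combine_reference_cq(cq_refs: float | Sequence[float],
                          efficiency: float) -> float:
    """Effective Cq of multiple references: geometric mean of their
    quantities, i.e. the arithmetic mean of their Cq values."""
    arr = np.atleast_1d(np.asarray(cq_refs, dtype=float))
    if arr.size == 0 or np.isnan(arr).any():
        raise ValueError("reference Cq value(s) missing")
    return float(arr.mean())


def ddcq_fold_change(
    cq_target_test: float,
    cq_target_control: float,
    cq_ref_test: float | Sequence[float],
    cq_ref_control: float | Sequence[float],
    efficiency: float = 2.0,
) -> float:
    """Delta-delta-Cq fold change of the target, test vs control.

    ``fold = efficiency**(-ddCq)`` with
    ``ddCq = (Cq_target,test - Cq_ref,test) - (Cq_target,control -
    Cq_ref,control)``.  Multiple reference genes are combined as the
    geometric mean of their per-reference quantities.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    d_test = cq_target_test - _combine_reference_cq(cq_ref_test, efficiency)
    d_ctrl = cq_target_control - _combine_reference_cq(cq_ref_control, efficiency)
    ddcq = d_test - d_ctrl
    return float(efficiency ** (-ddcq))


def percent_of_input(
    cq_ip: float,
    cq_input: float,
    input_fraction: float = 1.0,
    efficiency: float = 2.0,
    cq_background: float | None = None,
) -> float:
    """Immunoprecipitated material as a percentage of the pre-IP input.

    ``percent = 100 * input_fraction * efficiency**(Cq_input - Cq_ip)``;
    when a no-antibody background Cq is supplied its percent is subtracted.
    Values above 100% are carried with a warning, never clipped.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    if not 0.0 < input_fraction <= 1.0:
        raise ValueError("input_fraction must be in (0, 1]")
    percent = 100.0 * input_fraction * efficiency ** (cq_input - cq_ip)
    if cq_background is not None:
        percent -= 100.0 * input_fraction * efficiency ** (cq_input - cq_background)
    if percent > 100.0:
        warnings.warn(
            f"percent of input {percent:.1f}% exceeds 100%; check the input "
            "fraction or Cq values",
            stacklevel=2,
        )
    return float(percent)
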