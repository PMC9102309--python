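"""Artifact-component selection rules.

Two policies are implemented.  The reference-guided rule mirrors how a
ground-truth channel is used when one is available: components are discarded
greedily, one per pass, whenever removing them strictly improves the Pearson
correlation between the reconstruction and the reference.  The
reference-free rule simply discards the lowest-frequency approximation
sub-band — motion artifacts concentrate there — and keeps everything else;
the reference is then needed only to score the result, not to produce it.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from .errors import DataError, MetricError
from .metrics import pearson
from .wpd import SubbandMatrix

__all__ = ["SelectionResult", "greedy_select", "approx_drop_select"]

#: Minimum strict correlation improvement for a removal to count; guards
#: against float-noise removals.
IMPROVEMENT_TOL = 1e-12


@dataclasses.dataclass
class SelectionResult:
    """Outcome of a component-selection pass.

    ``rho_trace`` holds, per greedy pass, the list of ``(candidate index,
    correlation if removed)`` evaluations, enabling audit of the search.
    ``final_rho``/``baseline_rho`` are the reconstruction/reference
    correlations with and without the selected removals (``None`` for the
    reference-free rule, which consults no reference).
    """

    removed: tuple[int, ...]
    rho_trace: list[list[tuple[int, float]]] = dataclasses.field(default_factory=list)
    final_rho: float | None = None
    baseline_rho: float | None = None


def greedy_select(
    n_components: int,
    reconstruct: Callable[[frozenset[int]], np.ndarray],
    reference,
    tol: float = IMPROVEMENT_TOL,
) -> SelectionResult:
    """Greedy reference-guided rejection of artifact components.

    ``reconstruct`` maps a set of removed component indices to the
    reconstructed signal; the same contract serves wavelet sub-bands
    (single-stage) and CCA sources (two-stage).  Each pass evaluates every
    remaining single-component removal against the current selection and
    commits the one with the largest strict improvement in correlation with
    the reference (ties broken toward the lowest index); the search stops
    when no removal improves the correlation by more than ``tol``.  The full
    component set is never removed.
    """
    if n_components < 2:
        raise DataError(f"need at least 2 candidate components, got {n_components}")
    reference = np.asarray(
        reference.samples if hasattr(reference, "samples") else reference, dtype=float)
    baseline = reconstruct(frozenset())
    if reference.size != baseline.size:
        raise DataError(
            f"reference length {reference.size} != reconstruction length {baseline.size}")
    baseline_rho = pearson(reference, baseline)
    removed: set[int] = set()
    current = baseline_rho
    trace: list[list[tuple[int, float]]] = []
    while len(removed) < n_components - 1:
        evals: list[tuple[int, float]] = []
        best_c, best_rho = None, current
        for c in range(n_components):
            if c in removed:
                continue
            try:
                rho_c = pearson(reference, reconstruct(frozenset(removed | {c})))
            except MetricError:
                rho_c = float("nan")
            evals.append((c, rho_c))
            if np.isfinite(rho_c) and rho_c > best_rho + tol:
                best_c, best_rho = c, rho_c
        trace.append(evals)
        if best_c is None:
            break
        removed.add(best_c)
        current = best_rho
    return SelectionResult(
        removed=tuple(sorted(removed)),
        rho_trace=trace,
        final_rho=current,
        baseline_rho=baseline_rho,
    )


def approx_drop_select(subbands: SubbandMatrix) -> SelectionResult:
    """Reference-free rule: discard the approximation sub-band only."""
    return SelectionResult(removed=(subbands.approx_index,))
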