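"""Lightweight operation counters.

The assembly and solver stages keep a global tally of the work they do
(scalar products consumed by tensor contractions, number of SVD
factorizations, number of back-substitutions).  The counters exist so that
the complexity guarantees of the separable assembly scheme and the
factorization reuse across time steps can be asserted, not just trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Counters:
    """Mutable tally of the expensive operations performed so far."""

    #: scalar products consumed by axis contractions (mask path, Eq-10 style)
    mask_contraction_products: int = 0
    #: scalar products consumed by axis contractions (data path)
    data_contraction_products: int = 0
    #: number of exponential table entries evaluated
    exponential_evaluations: int = 0
    #: number of SVD factorizations computed
    svd_calls: int = 0
    #: number of reduced-system solves (back-substitutions)
    solve_calls: int = 0
    #: per-axis contraction shapes, for inspection
    contraction_log: list = field(default_factory=list)

    def reset(self) -> None:
        self.mask_contraction_products = 0
        self.data_contraction_products = 0
        self.exponential_evaluations = 0
        self.svd_calls = 0
        self.solve_calls = 0
        self.contraction_log.clear()


#: process-global counter instance used by the whole package
counters = Counters()


def reset_counters() -> Counters:
    """Reset and return the global counters."""
    counters.reset()
    return counters
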