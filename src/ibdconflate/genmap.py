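"""Genetic-map coordinate conversion.

A single constant-rate map owns the bp <-> cM conversion used everywhere in
the package.  The default of 1 cM per Mb matches the constant recombination
rate of 1e-8 per bp per generation used by the simulations, so genetic and
physical coordinates are interchangeable up to a factor of 1e6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GeneticMap:
    """Constant-rate genetic map.

    Parameters
    ----------
    cm_per_mb
        Map density in centimorgans per megabase.  The default (1.0)
        corresponds to a uniform crossover rate of 1e-8 per bp per
        generation.
    """

    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be positive")

    def bp_to_cm(self, bp):
        """Convert physical distance (bp) to genetic distance (cM)."""
        return np.asarray(bp, dtype=float) * (self.cm_per_mb * 1e-6)

    def cm_to_bp(self, cm):
        """Convert genetic distance (cM) to physical distance (bp, float)."""
        return np.asarray(cm, dtype=float) * (1e6 / self.cm_per_mb)


#: Map shared by all defaults: 1 cM == 1 Mb.
DEFAULT_MAP = GeneticMap(1.0)
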