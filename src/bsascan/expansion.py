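"""Genetic map expansion for intermated and inbred population designs.

Intermating and inbreeding both accumulate effective recombination events
relative to a single meiosis.  With ``i`` generations of inbreeding and
``j`` generations of intermating, the per-individual effective
recombination count x scales by

    intermated + inbred:  j/2 + (2**i - 1) / 2**i
    inbred only:          (2**(i + 1) - 1) / 2**i

``i = inf`` gives the fully-inbred limits 1 and 2 respectively.  Scaling a
known effective recombination count from one design to another is a ratio
of the two factors: e.g. 57 events per individual in an intermated-then-
inbred design with j = 4 scales to 57 * 8/3 = 152 for j = 14 in the same
fully-inbred convention.  Note that applying i = 0 literally to a
noninbred intermated population gives a smaller factor (j/2 instead of
j/2 + 1); the conventional choice here is the i = inf limit, with ``i``
always exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigError

__all__ = ["ExpansionParams", "expansion_factor", "scale_effective_recombination"]

_FORMULAS = ("intermated_inbred", "inbred_only")


@dataclass(frozen=True)
class ExpansionParams:
    """A population design for map-expansion scaling.

    ``i``: generations of inbreeding (``math.inf`` = fully inbred);
    ``j``: generations of intermating; ``formula`` selects which printed
    expansion equation applies to the design.
    """

    i: float = math.inf
    j: int = 0
    formula: str = "intermated_inbred"

    def __post_init__(self):
        if self.i < 0 or self.j < 0:
            raise ConfigError(f"generation counts must be >= 0 (i={self.i}, j={self.j})")
        if self.formula not in _FORMULAS:
            raise ConfigError(f"formula must be one of {_FORMULAS}")

    @property
    def factor(self) -> float:
        return expansion_factor(self.i, self.j, self.formula)


def expansion_factor(
    i: float, j: int = 0, formula: str = "intermated_inbred"
) -> float:
    """Map-expansion factor for ``i`` inbreeding and ``j`` intermating
    generations under the chosen formula (see module docstring)."""
    if i < 0 or j < 0:
        raise ConfigError(f"generation counts must be >= 0 (i={i}, j={j})")
    if formula == "intermated_inbred":
        inbred_part = 1.0 if math.isinf(i) else (2.0**i - 1.0) / 2.0**i
        return j / 2.0 + inbred_part
    if formula == "inbred_only":
        return 2.0 if math.isinf(i) else (2.0 ** (i + 1) - 1.0) / 2.0**i
    raise ConfigError(f"formula must be one of {_FORMULAS}")


def scale_effective_recombination(
    known_events: float, known: ExpansionParams, target: ExpansionParams
) -> float:
    """Scale a known per-individual effective recombination count from one
    design to another sharing the same baseline meiosis:
    known_events * factor(target) / factor(known)."""
    f_known = known.factor
    if f_known == 0:
        raise ConfigError("known design has zero expansion factor")
    return known_events * target.factor / f_known
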