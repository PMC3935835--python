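"""Estimating how many of a unit's mutations actually cause the phenotype.

Assume every causal mutation is nonsynonymous, while non-causal mutations
are a neutral draw from the genome-wide mixture with nonsynonymous
fraction f0. The observed nonsynonymous fraction x in a unit with a
causal fraction c is then the mixture

    x = c + (1 - c) * f0,

which inverts to c = (x - f0) / (1 - f0). The estimated causal mutation
count is c * N, with N the unit's total mutation count. A unit whose
ns/syn ratio matches the background gives c = 0; a unit with no
synonymous mutations gives c = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class CausalEstimate:
    """Causal-fraction estimate for one gene or group.

    ``c_raw`` is the uninverted estimate before clamping (negative when
    the unit is *less* nonsynonymous than background — kept as a
    diagnostic); ``c`` is clamped to [0, 1]. ``n_causal`` rounds
    ``c * N`` half away from zero, matching integer reporting;
    ``n_causal_frac`` keeps the fractional value.
    """

    unit_id: str | None
    n_total: int
    x: float
    f0: float
    c_raw: float
    c: float
    n_causal: int
    n_causal_frac: float


def estimate_causal(
    ns: int,
    syn: int,
    f0: float,
    unit_id: str | None = None,
) -> CausalEstimate:
    """Invert the nonsynonymous-excess mixture for one unit.

    ``f0`` is the genome-wide nonsynonymous fraction of the filtered
    mutation set (strictly between 0 and 1); the unit must contain at
    least one mutation.
    """
    if ns < 0 or syn < 0:
        raise ValueError("counts must be nonnegative")
    n_total = ns + syn
    if n_total < 1:
        raise ValueError("unit has no mutations (N = 0)")
    if not 0.0 < f0 < 1.0:
        raise ValueError(f"f0 must be in (0, 1), got {f0}")
    x = ns / n_total
    c_raw = (x - f0) / (1.0 - f0)
    c = min(1.0, max(0.0, c_raw))
    frac = c * n_total
    return CausalEstimate(
        unit_id=unit_id,
        n_total=n_total,
        x=x,
        f0=f0,
        c_raw=c_raw,
        c=c,
        n_causal=int(math.floor(frac + 0.5)),  # half away from zero; frac >= 0
        n_causal_frac=frac,
    )
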