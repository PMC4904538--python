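"""Literature-derived relative mesotheliogenic potency constants.

Commercial chrysotile (serpentine asbestos as sold, typically carrying a
few percent amphibole contamination) is the reference fiber with potency
1.  The Hodgson–Darnton literature review placed the mesothelioma-specific
risks of commercial chrysotile, amosite and crocidolite broadly in the
ratio 1 : 100 : 500 on a lifetime-exposure basis, and about 1 : 35 : 200
for occupational-type exposures.  A coarser working figure of 50 : 1 for
a generic amphibole versus commercial chrysotile is also provided as the
``example`` scenario; mixing 90% chrysotile with 10% of that amphibole
gives a blended potency of 5.9 ("about 6").

These constants are advisory: the apportionment engine never substitutes
them silently — the operator always supplies the potency number for each
entry, using these presets (or their own judgement) to do so.  The full
table ships with the package as ``data/potency_presets.json``.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

from .risk_model import ValidationError

__all__ = [
    "FIBER_TYPES",
    "SCENARIOS",
    "preset_potency",
    "preset_table",
    "mixed_potency",
]

FIBER_TYPES = (
    "commercial_chrysotile",
    "amosite",
    "crocidolite",
    "generic_amphibole",
)
SCENARIOS = ("lifetime", "occupational", "example")


@lru_cache(maxsize=1)
def preset_table() -> tuple[dict, ...]:
    """The shipped potency preset table, one record per (fiber, scenario)."""
    text = (
        resources.files("mesoapportion")
        .joinpath("data/potency_presets.json")
        .read_text(encoding="utf-8")
    )
    return tuple(json.loads(text))


def preset_potency(fiber_type: str, scenario: str) -> float:
    """Tabulated relative potency for a fiber type under a scenario.

    Raises
    ------
    KeyError
        For an unknown (fiber_type, scenario) combination; the message
        lists the valid options.
    """
    for rec in preset_table():
        if rec["fiber_type"] == fiber_type and rec["scenario"] == scenario:
            return float(rec["relative_potency"])
    valid = ", ".join(
        f"({r['fiber_type']}, {r['scenario']})" for r in preset_table()
    )
    raise KeyError(
        f"no potency preset for ({fiber_type!r}, {scenario!r}); "
        f"valid combinations: {valid}"
    )


def mixed_potency(components: Sequence[tuple[float, float]]) -> float:
    """Potency of a fiber mixture as the fraction-weighted mean.

    ``components`` is a sequence of ``(fraction, potency)`` pairs whose
    fractions must sum to 1 (within 1e-9).  E.g. 90% chrysotile (potency
    1) plus 10% amphibole (potency 50) gives ``0.9*1 + 0.1*50 = 5.9``.
    """
    components = list(components)
    if not components:
        raise ValidationError("mixed_potency requires at least one component")
    for frac, pot in components:
        if not 0 <= frac <= 1:
            raise ValidationError(f"fraction must be in [0, 1], got {frac}")
        if pot <= 0:
            raise ValidationError(f"potency must be positive, got {pot}")
    total_frac = sum(frac for frac, _ in components)
    if abs(total_frac - 1.0) > 1e-9:
        raise ValidationError(
            f"component fractions must sum to 1, got {total_frac}"
        )
    return sum(frac * pot for frac, pot in components)
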