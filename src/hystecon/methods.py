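"""The three hysterectomy approaches compared by the analysis."""

from __future__ import annotations

import enum


class SurgicalMethod(str, enum.Enum):
    """Surgical approach to total hysterectomy for endometrial cancer.

    TAH — total abdominal hysterectomy (open laparotomy).
    TLH — total laparoscopic hysterectomy.
    TRH — robot-assisted total laparoscopic hysterectomy.

    The string value round-trips losslessly: ``SurgicalMethod(m.value) is m``.
    """

    TAH = "TAH"
    TLH = "TLH"
    TRH = "TRH"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical ordering used for deterministic iteration and tie-breaking.
METHOD_ORDER: tuple[SurgicalMethod, ...] = (
    SurgicalMethod.TAH,
    SurgicalMethod.TLH,
    SurgicalMethod.TRH,
)

#: Minimally invasive approaches, the only ones that can convert to laparotomy.
CONVERTIBLE_METHODS: frozenset[SurgicalMethod] = frozenset(
    {SurgicalMethod.TLH, SurgicalMethod.TRH}
)
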