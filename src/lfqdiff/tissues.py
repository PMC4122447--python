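"""The five ear-tissue types of the study design.

The analysis compares cholesteatoma (a destructive growth of keratinizing
squamous epithelium in the middle ear) with four surrounding tissues sampled
from the same ear: the neck of the cholesteatoma, the tympanic membrane,
external auditory canal skin and middle ear mucosa.
"""

from __future__ import annotations

import enum


class Tissue(str, enum.Enum):
    """One of the five biopsy tissue types.

    The enum value is the short code used in intensity column names
    (``Intensity.<experiment>.<code>``); :attr:`display_name` is the
    human-readable label used in report tables and dendrogram leaves.
    """

    CHOL = "CHOL"
    NECK = "NECK"
    TYMP = "TYMP"
    EACS = "EACS"
    MUC = "MUC"

    @property
    def display_name(self) -> str:
        return _DISPLAY[self]

    @classmethod
    def from_code(cls, code: str) -> "Tissue":
        try:
            return cls(code.upper())
        except ValueError:
            raise ValueError(
                f"unknown tissue code {code!r}; expected one of "
                f"{[t.value for t in cls]}"
            ) from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_DISPLAY = {
    Tissue.CHOL: "Cholesteatoma",
    Tissue.NECK: "Neck of cholesteatoma",
    Tissue.TYMP: "Tympanic membrane",
    Tissue.EACS: "External auditory canal skin",
    Tissue.MUC: "Middle ear mucosa",
}

#: Tissues in canonical (enum) order.
ALL_TISSUES: tuple[Tissue, ...] = tuple(Tissue)
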