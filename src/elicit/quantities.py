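"""Definition of the elicited quantity and its display scale.

An elicited quantity lives on a bounded interval ``[scale_min, scale_max]``.
Experts may see it either as a percentage/proportion or as a count out of a
fixed denominator (e.g. "out of 100 randomly selected patients, how many
..."), but all internal computation happens on the normalized unit interval;
conversion to and from the display scale occurs only at I/O boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


class EncodingError(ValueError):
    """Raised when elicited summaries violate a structural requirement."""


@dataclass(frozen=True)
class QuantityDefinition:
    """The quantity an expert is asked about.

    Parameters
    ----------
    name : str
        Short label used in reports and file headers.
    question_text : str
        The prose question put to the expert.
    scale_min, scale_max : float
        Bounds of the plausible scale (e.g. 0 and 1 for a proportion,
        0 and 100 for a count out of 100).
    display_mode : {"proportion_percent", "count_out_of_n"}
        How the scale is presented to the expert.
    n_total : int, optional
        Denominator for ``count_out_of_n`` quantities (e.g. 100 patients).
    """

    name: str
    question_text: str = ""
    scale_min: float = 0.0
    scale_max: float = 1.0
    display_mode: str = "proportion_percent"
    n_total: int | None = None

    def __post_init__(self) -> None:
        if not self.scale_min < self.scale_max:
            raise EncodingError(
                f"scale_min < scale_max violated: {self.scale_min} >= {self.scale_max}"
            )
        if self.display_mode not in ("proportion_percent", "count_out_of_n"):
            raise EncodingError(f"unknown display_mode {self.display_mode!r}")
        if self.display_mode == "count_out_of_n":
            if self.n_total is None or self.n_total < 1:
                raise EncodingError("count_out_of_n requires n_total >= 1")

    @property
    def width(self) -> float:
        return self.scale_max - self.scale_min

    def to_normalized(self, x: float) -> float:
        """Map a value on the quantity scale to the unit interval."""
        return (x - self.scale_min) / self.width

    def from_normalized(self, u: float) -> float:
        """Map a value on the unit interval back to the quantity scale."""
        return self.scale_min + u * self.width

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, d: dict) -> "QuantityDefinition":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "QuantityDefinition":
        return cls.from_json(json.loads(Path(path).read_text()))
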