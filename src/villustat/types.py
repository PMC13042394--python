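"""Shared domain vocabulary: compartments, immune labels, small result records.

All coordinates in this package are micrometres (µm), 0-based, origin at the
lower-left corner of the section; a spot is the centre point of a capture unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Tissue compartments a spot may be annotated with.
COMPARTMENTS = (
    "smooth_muscle",
    "crypt",
    "enterocyte",
    "lamina_propria",
    "paneth",
    "fibroblast",
)

#: Immune cell-type labels carried by a subset of spots.
CELL_TYPES = ("CD4T", "CD8T", "M1", "M2", "Monocyte", "Unclear")

#: Cell types used for headline proximity edges (``Unclear`` excluded).
HEADLINE_CELL_TYPES = ("CD4T", "CD8T", "M1", "M2", "Monocyte")

SPOT_COLUMNS = ("spot_id", "x_um", "y_um", "compartment", "cell_type")


class ValidationError(ValueError):
    """An input object or configuration violates a documented invariant."""


class FormatError(ValidationError):
    """A file does not conform to its declared dialect."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class GeneSignature:
    """A named, non-empty set of marker genes."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("GeneSignature.name must be non-empty")
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} has no genes")

    @classmethod
    def from_iterable(cls, name: str, genes) -> "GeneSignature":
        return cls(name=name, genes=frozenset(genes))


@dataclass(frozen=True)
class CryptRegion:
    """One connected component of crypt-annotated spots."""

    region_id: str
    spot_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.spot_ids)


@dataclass(frozen=True)
class PositiveRate:
    """Gene positive rate over a spot subset: n_positive / n_total."""

    gene: str
    rate: float
    n_positive: int
    n_total: int


@dataclass
class RoeMatrix:
    """Ro/e enrichment grid (groups x subsets) with the counts behind it.

    ``roe = observed / expected`` where ``expected`` is the chi-square expected
    count ``row_total * col_total / grand_total``. Cells whose expected count is
    zero are NaN (undefined), never infinity.
    """

    roe: pd.DataFrame
    observed: pd.DataFrame
    expected: pd.DataFrame

    def __post_init__(self) -> None:
        for df in (self.observed, self.expected):
            if not df.index.equals(self.roe.index) or not df.columns.equals(
                self.roe.columns
            ):
                raise ValidationError("RoeMatrix grids must share index/columns")


@dataclass
class RunReport:
    """Provenance record for one pipeline run."""

    config_echo: dict
    input_checksums: dict = field(default_factory=dict)
    stage_summaries: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
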