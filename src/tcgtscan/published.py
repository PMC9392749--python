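"""Access to the packaged published cohort counts.

The package ships the per-gene recurrence counts reported for a colorectal
cohort of 286 patients with matched tumor/normal samples (39 genes passing
the >20% tumors / <10% normals filter). These printed counts serve as
inputs for re-deriving the table's percentage columns with the package's
own formatter, and for consistency checks of the product-class vocabulary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .aggregation import format_percentage

COHORT_SIZE = 286  # matched tumor and normal sample count
N_TCGTS_CANONICAL = 44
N_TCGTS_TRUNCATED = 43
N_TCGTS_OUT_OF_FRAME = 8


@dataclass(frozen=True)
class PublishedGeneCounts:
    gene: str
    nN: int
    nT: int
    products: tuple[str, ...]

    @property
    def pctN(self) -> float:
        return format_percentage(self.nN, COHORT_SIZE)

    @property
    def pctT(self) -> float:
        return format_percentage(self.nT, COHORT_SIZE)


def load_published_counts() -> list[PublishedGeneCounts]:
    """The packaged 39-gene recurrence table (printed counts)."""
    rows: list[PublishedGeneCounts] = []
    path = resources.files("tcgtscan.data").joinpath("table1_counts.tsv")
    with path.open() as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for rec in reader:
            rows.append(
                PublishedGeneCounts(
                    gene=rec["gene"],
                    nN=int(rec["nN"]),
                    nT=int(rec["nT"]),
                    products=tuple(rec["products"].split(";")),
                )
            )
    return rows
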