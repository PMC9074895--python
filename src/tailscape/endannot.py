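"""Annotation of mRNA 3' ends from tag 3'-coordinate pileups.

Cleavage-and-polyadenylation positions are identified per gene by iterative
greedy peak assignment: the coordinate with the most tags becomes a 3' end,
every tag within 10 nt (a 21-nt window) is assigned to it and removed, and
the process repeats until no tags remain.  Ends are then retained when they
account for at least 10% of the gene's 3'-UTR-mapping tags.  Only tags with
tails >= 11 nt should enter the pileup (short-tailed tags place the 3' end
less reliably); that filter is applied by :func:`pileups_from_tags`.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "ThreePrimeEnd",
    "annotate_ends",
    "pileups_from_tags",
    "annotate_all_genes",
    "write_ends_bed",
]


@dataclass(frozen=True)
class ThreePrimeEnd:
    gene: str
    coordinate: int
    count: int
    fraction: float
    retained: bool


def annotate_ends(
    pileup: dict,
    window_halfwidth: int = 10,
    min_fraction: float = 0.10,
    gene: str = "",
    keep_dropped: bool = False,
) -> list[ThreePrimeEnd]:
    """Greedy 3'-end assignment for one gene's coordinate -> tag-count map.

    Ties at the maximum count break toward the smaller (5'-most, transcript
    orientation) coordinate.  The retention fraction's denominator is the
    gene's total 3'-UTR tag count.  With ``keep_dropped`` the sub-threshold
    ends are reported too (flagged ``retained=False``).
    """
    if any(c < 1 for c in pileup.values()):
        raise ValueError("pileup counts must be >= 1")
    remaining = dict(pileup)
    total = sum(remaining.values())
    ends: list[ThreePrimeEnd] = []
    while remaining:
        peak = min(
            remaining, key=lambda coord: (-remaining[coord], coord)
        )  # max count, then 5'-most
        assigned = [
            c for c in remaining if abs(c - peak) <= window_halfwidth
        ]
        count = sum(remaining[c] for c in assigned)
        ends.append(
            ThreePrimeEnd(
                gene=gene,
                coordinate=peak,
                count=count,
                fraction=count / total,
                retained=count / total >= min_fraction,
            )
        )
        for c in assigned:
            del remaining[c]
    if not keep_dropped:
        ends = [e for e in ends if e.retained]
    return ends


def pileups_from_tags(tags: pd.DataFrame, min_tail: int = 11) -> dict:
    """Build per-gene pileups from a tag table (gene, position, tail_length).

    Tags shorter than ``min_tail`` are excluded before compiling coordinates.
    """
    usable = tags[tags["tail_length"] >= min_tail]
    pileups: dict[str, dict[int, int]] = {}
    for (gene, pos), n in usable.groupby(["gene", "position"]).size().items():
        pileups.setdefault(gene, {})[int(pos)] = int(n)
    return pileups


def annotate_all_genes(
    tags: pd.DataFrame,
    window_halfwidth: int = 10,
    min_fraction: float = 0.10,
    min_tail: int = 11,
) -> pd.DataFrame:
    """Annotate 3' ends for every gene in a tag table.

    Returns a table with one row per retained end: gene, coordinate,
    count, fraction.
    """
    rows = []
    for gene, pileup in pileups_from_tags(tags, min_tail=min_tail).items():
        for end in annotate_ends(
            pileup, window_halfwidth=window_halfwidth, min_fraction=min_fraction, gene=gene
        ):
            rows.append(
                {
                    "gene": end.gene,
                    "coordinate": end.coordinate,
                    "count": end.count,
                    "fraction": end.fraction,
                }
            )
    return pd.DataFrame(rows, columns=["gene", "coordinate", "count", "fraction"])


def write_ends_bed(ends: pd.DataFrame, path, strand: str = "+") -> None:
    """Write annotated ends as BED6+1 (half-open; score = tag count,
    extra column = fraction)."""
    with open(path, "w") as fh:
        for _, row in ends.iterrows():
            fh.write(
                f"{row['gene']}\t{int(row['coordinate'])}\t{int(row['coordinate']) + 1}"
                f"\t{row['gene']}:3p\t{int(row['count'])}\t{strand}\t{row['fraction']:.4f}\n"
            )
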