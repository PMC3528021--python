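"""Genome model: chromosome names, lengths, and sex-genome bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping

#: Chromosome names treated as the Y chromosome by filters.
Y_NAMES = frozenset({"Y", "chrY"})


@dataclass(frozen=True)
class GenomeModel:
    """An ordered set of chromosomes with lengths in base pairs.

    Parameters
    ----------
    chromosomes
        Mapping of chromosome name to length in bp.  Insertion order is the
        canonical chromosome order.
    female
        If True (default) the genome carries no Y chromosome; constructing a
        female genome that contains one is an error.
    """

    chromosomes: Mapping[str, int]
    female: bool = True

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        for name, length in self.chromosomes.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.female and any(name in Y_NAMES for name in self.chromosomes):
            raise ValueError("female genome must not contain a Y chromosome")
        # normalize to a plain dict of ints
        object.__setattr__(
            self, "chromosomes", {str(k): int(v) for k, v in self.chromosomes.items()}
        )

    @property
    def names(self) -> tuple:
        return tuple(self.chromosomes)

    def analysis_names(self) -> tuple:
        """Chromosome names retained for analysis (Y excluded)."""
        return tuple(n for n in self.chromosomes if n not in Y_NAMES)

    def length(self, chrom: str) -> int:
        return self.chromosomes[chrom]

    def total_bp(self, exclude_y: bool = True) -> int:
        names = self.analysis_names() if exclude_y else self.names
        return sum(self.chromosomes[n] for n in names)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)


def chrom_sort_key(name: str):
    """Sort chromosomes numerically where possible (chr2 before chr10)."""
    stripped = name[3:] if name.lower().startswith("chr") else name
    if stripped.isdigit():
        return (0, int(stripped), "")
    return (1, 0, stripped)
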