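"""Genome coordinate model for the cross simulator and scan modules.

A :class:`GenomeSpec` is an ordered set of named chromosomes with lengths in
base pairs plus a single genome-wide recombination rate in cM/kb.  The default
mirrors the sixteen nuclear chromosomes of the *S. cerevisiae* S288c reference
assembly, the coordinate system yeast short-read data are mapped against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GenomeSpec", "S288C_CHROMOSOMES"]

# S288c (R64) nuclear chromosome lengths, bp.
S288C_CHROMOSOMES: tuple[tuple[str, int], ...] = (
    ("chrI", 230_218),
    ("chrII", 813_184),
    ("chrIII", 316_620),
    ("chrIV", 1_531_933),
    ("chrV", 576_874),
    ("chrVI", 270_161),
    ("chrVII", 1_090_940),
    ("chrVIII", 562_643),
    ("chrIX", 439_888),
    ("chrX", 745_751),
    ("chrXI", 666_816),
    ("chrXII", 1_078_177),
    ("chrXIII", 924_431),
    ("chrXIV", 784_333),
    ("chrXV", 1_091_291),
    ("chrXVI", 948_066),
)


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosomes (name, length in bp) and a uniform recombination rate.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs. Names must be unique, lengths > 0.
    recombination_rate
        Uniform genetic map density in centimorgan per kilobase. The default,
        0.35 cM/kb, is the yeast genome-wide average.
    """

    chromosomes: tuple[tuple[str, int], ...] = field(default=S288C_CHROMOSOMES)
    recombination_rate: float = 0.35

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [n for n, _ in chroms]
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        if not chroms:
            raise ValueError("at least one chromosome required")
        if any(l <= 0 for _, l in chroms):
            raise ValueError("chromosome lengths must be positive")
        if self.recombination_rate < 0:
            raise ValueError("recombination_rate must be >= 0")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length_of(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def genetic_length_morgans(self, name: str) -> float:
        """Genetic length of a chromosome in Morgans under the uniform map."""
        return self.length_of(name) / 1000.0 * self.recombination_rate / 100.0
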