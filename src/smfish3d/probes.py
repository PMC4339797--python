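"""Probe-tiling arithmetic for smFISH oligo sets.

Single-molecule FISH needs ~30–50 short oligo probes tiled along one
transcript; each probe occupies a fixed length (default 20 nt) and
consecutive probes must be separated by a minimum gap (default 2 nt).  This
module answers the two bounding questions: how many probes fit on a
transcript of a given length, and how long must a transcript be to carry a
required number of probes.  Probe intervals are 0-based half-open.

Sequence-content scoring (GC, Tm, uniqueness) is out of scope — this module
bounds and positions probes, it does not score them.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TilingSpec", "max_tiling", "min_length_for"]


@dataclass(frozen=True)
class TilingSpec:
    """Transcript length and probe geometry in nucleotides."""

    seq_length: int
    probe_length: int = 20
    min_gap: int = 2

    def __post_init__(self) -> None:
        if self.seq_length < 0:
            raise ValueError("seq_length must be ≥ 0")
        if self.probe_length < 1:
            raise ValueError("probe_length must be ≥ 1")
        if self.min_gap < 0:
            raise ValueError("min_gap must be ≥ 0")


def max_tiling(
    seq_length: int | TilingSpec, probe_length: int = 20, min_gap: int = 2
) -> tuple[int, list[tuple[int, int]]]:
    """Maximum number of probes that tile a transcript, with their positions.

    count = ⌊(L + g) / (p + g)⌋ for transcript length L, probe length p and
    minimum gap g; the returned intervals are the left-packed greedy tiling
    [k·(p+g), k·(p+g)+p), which achieves that maximum.  Returns (0, []) when
    nothing fits.
    """
    if isinstance(seq_length, TilingSpec):
        spec = seq_length
    else:
        spec = TilingSpec(seq_length, probe_length, min_gap)
    pitch = spec.probe_length + spec.min_gap
    count = (spec.seq_length + spec.min_gap) // pitch
    intervals = [(k * pitch, k * pitch + spec.probe_length) for k in range(count)]
    return count, intervals


def min_length_for(count: int, probe_length: int = 20, min_gap: int = 2) -> int:
    """Minimum transcript length carrying ``count`` probes.

    count·p + (count−1)·g nucleotides: probes packed end to end with exactly
    the minimum gap.  Adjoint to :func:`max_tiling`:
    ``max_tiling(min_length_for(c))[0] == c`` and one nucleotide less fits
    only c − 1 probes.
    """
    if count < 1:
        raise ValueError("count must be ≥ 1")
    if probe_length < 1 or min_gap < 0:
        raise ValueError("invalid probe geometry")
    return count * probe_length + (count - 1) * min_gap
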