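"""Synthetic secondary structures and entropy tracks with known ground truth.

Structures are geometric, not energetic: the user tiles the RNA with helix and
loop segments; helix segments are base-paired to each other outside-in in
nested order (the first helix with the last, the second with the second-last,
and so on), which yields hairpins and nested stems whose per-position paired
state is known exactly.  Entropy tracks are piecewise-constant segment levels
plus optional zero-mean Gaussian noise truncated at zero, so the contrast
between conformationally stable (low-SE) and dynamic (high-SE) regions is
controllable and reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import EntropyTrack, SecondaryStructure

__all__ = ["Segment", "FixtureSpec", "make_structure", "make_entropy",
           "half_structured_spec", "random_structure"]


@dataclass(frozen=True)
class Segment:
    """One contiguous stretch of the fixture RNA (1-based closed interval)."""

    start: int
    end: int
    kind: str  # "helix" | "loop"
    se_level: float = 0.0


@dataclass(frozen=True)
class FixtureSpec:
    """A full fixture: segments must tile [1, length] without gaps or overlap."""

    length: int
    segments: tuple[Segment, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if self.length < 1:
            raise ValueError(f"length must be positive, got {self.length}")
        cursor = 1
        for seg in self.segments:
            if seg.start != cursor:
                raise ValueError(
                    f"segments must tile [1, {self.length}]: expected start "
                    f"{cursor}, got {seg.start}"
                )
            if seg.end < seg.start:
                raise ValueError(f"segment ({seg.start}, {seg.end}) is empty")
            if seg.kind not in ("helix", "loop"):
                raise ValueError(f"unknown segment kind {seg.kind!r}")
            if seg.se_level < 0:
                raise ValueError(f"negative se_level {seg.se_level}")
            cursor = seg.end + 1
        if cursor != self.length + 1:
            raise ValueError(
                f"segments end at {cursor - 1}, expected {self.length}"
            )
        helices = [s for s in self.segments if s.kind == "helix"]
        if len(helices) % 2:
            raise ValueError("helix segments must come in complementary pairs")
        k = len(helices) // 2
        for a, b in zip(helices[:k], reversed(helices[k:])):
            if (a.end - a.start) != (b.end - b.start):
                raise ValueError(
                    f"paired helices ({a.start}-{a.end}) and ({b.start}-{b.end}) "
                    f"differ in length"
                )

    @property
    def helix_pairs(self) -> list[tuple[Segment, Segment]]:
        helices = [s for s in self.segments if s.kind == "helix"]
        k = len(helices) // 2
        return list(zip(helices[:k], reversed(helices[k:])))


def make_structure(spec: FixtureSpec) -> tuple[SecondaryStructure, np.ndarray]:
    """Build the structure and return it with the ground-truth paired mask."""
    pairing = np.zeros(spec.length, dtype=np.int64)
    for a, b in spec.helix_pairs:
        # outside-in: 5'-most base of the upstream helix pairs the 3'-most
        # base of its partner
        for offset in range(a.end - a.start + 1):
            i = a.start + offset
            j = b.end - offset
            pairing[i - 1] = j
            pairing[j - 1] = i
    structure = SecondaryStructure(sequence="N" * spec.length, pairing=pairing)
    return structure, pairing > 0


def make_entropy(
    spec: FixtureSpec, noise_sd: float = 0.0, seed: int | None = None
) -> EntropyTrack:
    """Piecewise-constant SE per segment plus truncated Gaussian noise."""
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    values = np.empty(spec.length, dtype=np.float64)
    for seg in spec.segments:
        values[seg.start - 1 : seg.end] = seg.se_level
    if noise_sd > 0:
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        values = np.maximum(values + rng.normal(0.0, noise_sd, spec.length), 0.0)
    return EntropyTrack(values=values)


def half_structured_spec(
    length: int = 120, low_se: float = 0.05, high_se: float = 0.8, seed: int = 0
) -> FixtureSpec:
    """The canonical two-regime fixture: a fully paired low-entropy 5' half
    (one long hairpin) and an unpaired high-entropy 3' half."""
    if length % 4:
        raise ValueError("length must be divisible by 4")
    q = length // 4
    return FixtureSpec(
        length=length,
        segments=(
            Segment(1, q, "helix", low_se),
            Segment(q + 1, 2 * q, "helix", low_se),
            Segment(2 * q + 1, length, "loop", high_se),
        ),
        seed=seed,
    )


def random_structure(
    n: int, rng: np.random.Generator, paired_fraction: float = 0.5
) -> SecondaryStructure:
    """A random pseudoknot-free structure: nested pairs drawn by repeatedly
    splitting intervals, targeting roughly the requested paired fraction."""
    pairing = np.zeros(n, dtype=np.int64)
    target = int(paired_fraction * n) // 2
    intervals = [(1, n)]
    made = 0
    while intervals and made < target:
        lo, hi = intervals.pop(rng.integers(len(intervals)))
        if hi - lo < 3:
            continue
        i = int(rng.integers(lo, hi))
        j = int(rng.integers(i + 1, hi + 1))
        pairing[i - 1] = j
        pairing[j - 1] = i
        made += 1
        if i + 1 <= j - 1:
            intervals.append((i + 1, j - 1))
        if j + 1 <= hi:
            intervals.append((j + 1, hi))
        if lo <= i - 1:
            intervals.append((lo, i - 1))
    return SecondaryStructure(sequence="N" * n, pairing=pairing)
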