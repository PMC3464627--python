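"""Chromatin templates and the position-dependent MNase protection model.

A template is a linear stretch of DNA carrying an ordered set of
non-overlapping nucleosomes at 100% occupancy; everything between and
around them is linker/naked DNA.  MNase cuts linker DNA freely, while
nucleosomal DNA is protected by a factor that grows from the nucleosome
edge toward the dyad (the maximally protected central base).  The
per-base cut probability used by the digestion simulator is 1 in linker
and ``1/protection(pos)`` inside a nucleosome.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

NUCLEOSOME_BP = 147

__all__ = [
    "NUCLEOSOME_BP",
    "NucleosomeSpan",
    "ChromatinTemplate",
    "ProtectionParams",
    "CutProbabilityProfile",
    "build_template",
    "figure1_template",
    "packed_template",
    "cut_probability_profile",
    "read_template_bed",
    "write_template_bed",
]


class TemplateError(ValueError):
    """Invalid template geometry."""


@dataclass(frozen=True)
class NucleosomeSpan:
    """One nucleosome footprint: ``[start, start + length)`` on a template."""

    start: int
    length: int = NUCLEOSOME_BP

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise TemplateError(f"nucleosome length must be > 0, got {self.length}")
        if self.start < 0:
            raise TemplateError(f"nucleosome start must be >= 0, got {self.start}")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def dyad(self) -> int:
        """Central (maximally protected) base, 0-based."""
        return self.start + (self.length - 1) // 2


@dataclass(frozen=True)
class ChromatinTemplate:
    """Linear DNA template with sorted, non-overlapping nucleosomes."""

    length: int
    nucleosomes: tuple[NucleosomeSpan, ...]

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise TemplateError(f"template length must be > 0, got {self.length}")
        prev_end = 0
        for span in self.nucleosomes:
            if span.start < prev_end:
                raise TemplateError(
                    f"nucleosome at {span.start}-{span.end} overlaps or is "
                    f"out of order with previous span ending at {prev_end}"
                )
            if span.end > self.length:
                raise TemplateError(
                    f"nucleosome at {span.start}-{span.end} extends past "
                    f"template length {self.length}"
                )
            prev_end = span.end

    @property
    def linkers(self) -> list[tuple[int, int]]:
        """Complement of the nucleosome spans: linker/naked intervals."""
        out = []
        pos = 0
        for span in self.nucleosomes:
            if span.start > pos:
                out.append((pos, span.start))
            pos = span.end
        if pos < self.length:
            out.append((pos, self.length))
        return out

    @property
    def internal_linkers(self) -> list[tuple[int, int]]:
        """Linkers strictly between consecutive nucleosomes."""
        out = []
        for a, b in zip(self.nucleosomes, self.nucleosomes[1:]):
            if b.start > a.end:
                out.append((a.end, b.start))
        return out


@dataclass(frozen=True)
class ProtectionParams:
    """Protection of nucleosomal DNA relative to naked DNA.

    ``min_protection`` applies at the nucleosome edge, ``max_protection``
    at the dyad; ``shape`` selects how protection is interpolated in
    between (mirrored about the dyad).
    """

    min_protection: float = 50.0
    max_protection: float = 1000.0
    shape: str = "linear"

    def __post_init__(self) -> None:
        if not (1.0 <= self.min_protection <= self.max_protection):
            raise ValueError(
                "require 1 <= min_protection <= max_protection, got "
                f"{self.min_protection}, {self.max_protection}"
            )
        if self.shape not in ("linear", "cosine"):
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class CutProbabilityProfile:
    """Per-base MNase cut probability over a template."""

    template: ChromatinTemplate
    params: ProtectionParams
    probabilities: np.ndarray = field(repr=False)

    @property
    def length(self) -> int:
        return self.template.length


def build_template(
    length: int, nucleosome_spans: Iterable[tuple[int, int] | NucleosomeSpan]
) -> ChromatinTemplate:
    """Validate and build a template from ``(start, length)`` spans."""
    spans = tuple(
        s if isinstance(s, NucleosomeSpan) else NucleosomeSpan(*s)
        for s in nucleosome_spans
    )
    return ChromatinTemplate(length=length, nucleosomes=spans)


def figure1_template(length: int = 4000) -> ChromatinTemplate:
    """Six-nucleosome array emulating the average organization upstream of
    yeast transcription start sites.

    Six 147-bp nucleosomes spaced 15 bp apart, except for a 142-bp central
    linker (between nucleosomes 3 and 4) and a 30-bp linker immediately
    upstream of nucleosome 1.  The array is placed so the midpoint of the
    142-bp central linker sits at template coordinate ``length // 2``;
    template DNA outside the array is naked.
    """
    center = length // 2
    # nucleosome 3 ends where the central linker starts
    n3_end = center - 71
    starts = [
        n3_end - 3 * NUCLEOSOME_BP - 2 * 15,  # n1
        n3_end - 2 * NUCLEOSOME_BP - 15,      # n2
        n3_end - NUCLEOSOME_BP,               # n3
        n3_end + 142,                         # n4
        n3_end + 142 + NUCLEOSOME_BP + 15,    # n5
        n3_end + 142 + 2 * (NUCLEOSOME_BP + 15),  # n6
    ]
    return build_template(length, [(s, NUCLEOSOME_BP) for s in starts])


def packed_template(
    length: int = 4000,
    linker_bp: int = 15,
    special_linkers: dict[int, int] | None = None,
    offset: int = 0,
) -> ChromatinTemplate:
    """Template tiled edge-to-edge with nucleosomes separated by linkers.

    ``special_linkers`` maps linker index (0 = linker after the first
    nucleosome) to a non-default size, letting callers build arrays with
    occasional long linkers.  Tiling starts at ``offset`` and stops when
    the next nucleosome would run off the template.
    """
    special = special_linkers or {}
    spans = []
    pos = offset
    i = 0
    while pos + NUCLEOSOME_BP <= length:
        spans.append((pos, NUCLEOSOME_BP))
        pos += NUCLEOSOME_BP + special.get(i, linker_bp)
        i += 1
    return build_template(length, spans)


def _protection_curve(half: int, params: ProtectionParams) -> np.ndarray:
    """Protection fold at distances 0..half from the nucleosome edge."""
    d = np.arange(half + 1, dtype=float)
    frac = d / half if half > 0 else np.ones_like(d)
    if params.shape == "linear":
        w = frac
    else:  # cosine: smooth ramp, flat near edge and dyad
        w = 0.5 * (1.0 - np.cos(np.pi * frac))
    return params.min_protection + (params.max_protection - params.min_protection) * w


def cut_probability_profile(
    template: ChromatinTemplate, params: ProtectionParams | None = None
) -> CutProbabilityProfile:
    """Per-base cut probability: 1 in linker/naked DNA, ``1/protection``
    inside nucleosomes, symmetric about each dyad."""
    params = params or ProtectionParams()
    p = np.ones(template.length, dtype=float)
    for span in template.nucleosomes:
        half = (span.length - 1) // 2
        prot = _protection_curve(half, params)
        # mirror edge->dyad curve; odd length shares the dyad sample
        if span.length % 2 == 1:
            full = np.concatenate([prot, prot[:-1][::-1]])
        else:
            full = np.concatenate([prot, prot[::-1]])
        p[span.start : span.end] = 1.0 / full[: span.length]
    return CutProbabilityProfile(template=template, params=params, probabilities=p)


def write_template_bed(template: ChromatinTemplate, path, name: str = "template") -> None:
    """Write nucleosome spans as BED plus a genome-size track line comment."""
    with open(path, "w") as fh:
        fh.write(f"# genome\t{name}\t{template.length}\n")
        for i, span in enumerate(template.nucleosomes, start=1):
            fh.write(f"{name}\t{span.start}\t{span.end}\tnuc{i}\n")


def read_template_bed(path) -> ChromatinTemplate:
    """Read a template written by :func:`write_template_bed`."""
    length = None
    spans: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("# genome"):
                length = int(line.split("\t")[2])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TemplateError(f"{path}:{lineno}: expected >=3 BED fields")
            start, end = int(fields[1]), int(fields[2])
            spans.append((start, end - start))
    if length is None:
        raise TemplateError(f"{path}: missing '# genome' size line")
    return build_template(length, spans)
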