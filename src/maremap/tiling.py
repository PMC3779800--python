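"""Overlapping-fragment tiling design for regulatory elements.

A regulatory element (typically ~1 kb) is converted into a library of short
double-stranded targets for microfluidic occupancy mapping by tiling it with
36-bp fragments that overlap by 24 bp, i.e. a 12-bp step.  With 24-bp genomic
flanks on either side, every interior 12-bp bin of the element is covered by
exactly three fragments (the first two and last two bins by two), which is
what lets the per-bin signal be an average over three independent
measurements downstream.

Coordinates are 0-based half-open throughout; position 0 is the first base of
the cloned element, so flank positions are negative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_FRAGMENT_LENGTH = 36
DEFAULT_OVERLAP = 24
DEFAULT_FLANK = 24
DEFAULT_CLAMP = "CCC"
# The published design appends a 3' primer-annealing tail whose sequence is
# not part of the element; any fixed 20-mer works for in-silico design.
DEFAULT_PRIMER_TAIL = "GTCTGTGTTCCGTTGTCCGT"

_VALID_DNA = re.compile(r"^[ACGT]*$")


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    m = re.search(r"[^ACGT]", seq)
    if m:
        raise ValueError(
            f"{what} contains non-ACGT character {seq[m.start()]!r} "
            f"at position {m.start()}"
        )
    return seq


@dataclass(frozen=True)
class RegulatoryElement:
    """A named DNA element with optional genomic flanking sequence."""

    id: str
    sequence: str
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_dna(self.sequence, "sequence"))
        object.__setattr__(self, "flank5", _check_dna(self.flank5, "flank5"))
        object.__setattr__(self, "flank3", _check_dna(self.flank3, "flank3"))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Fragment:
    """One tiling window.

    ``start`` is the offset of the window relative to the element start and
    may be negative (flank).  ``core`` is the element-derived sequence;
    ``oligo`` is the full synthesis string (clamp + core + primer tail).
    """

    index: int
    start: int
    core: str
    oligo: str

    @property
    def end(self) -> int:
        return self.start + len(self.core)


@dataclass
class TilingParams:
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH
    overlap: int = DEFAULT_OVERLAP
    flank: int = DEFAULT_FLANK
    clamp: str = DEFAULT_CLAMP
    primer_tail: str = DEFAULT_PRIMER_TAIL

    @property
    def step(self) -> int:
        return self.fragment_length - self.overlap


@dataclass
class FragmentLibrary:
    element_id: str
    fragments: list[Fragment]
    params: TilingParams
    element_length: int

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterable[Fragment]:
        return iter(self.fragments)

    @property
    def span(self) -> tuple[int, int]:
        """Covered interval [-flank, L+flank) in element coordinates."""
        return (-self.params.flank, self.element_length + self.params.flank)


def make_oligo(core: str, clamp: str = DEFAULT_CLAMP,
               primer_tail: str = DEFAULT_PRIMER_TAIL) -> str:
    """Assemble the synthesis string: 5' clamp + core + 3' primer tail."""
    if not core:
        raise ValueError("empty fragment core")
    core = _check_dna(core, "core")
    return clamp + core + primer_tail


def design_fragments(element: RegulatoryElement,
                     fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
                     overlap: int = DEFAULT_OVERLAP,
                     flank: int = DEFAULT_FLANK,
                     clamp: str = DEFAULT_CLAMP,
                     primer_tail: str = DEFAULT_PRIMER_TAIL) -> FragmentLibrary:
    """Tile an element (plus flanks) into overlapping fragments.

    Fragments start at ``-flank`` and advance by ``fragment_length - overlap``
    while they fit inside ``[-flank, L+flank)``.  If the covered span is not a
    multiple of the step, a terminal fragment anchored flush to the right edge
    is appended so that coverage is exact.
    """
    if not (fragment_length > overlap > 0):
        raise ValueError("require fragment_length > overlap > 0")
    if flank < 0:
        raise ValueError("flank must be non-negative")
    step = fragment_length - overlap
    L = len(element)
    span = L + 2 * flank
    if span < fragment_length:
        raise ValueError(
            f"element {element.id}: covered span {span} shorter than "
            f"fragment length {fragment_length}"
        )
    if flank > 0:
        if len(element.flank5) < flank or len(element.flank3) < flank:
            raise ValueError(
                f"element {element.id}: flank sequences must be at least "
                f"{flank} nt (got {len(element.flank5)} and {len(element.flank3)})"
            )

    # Full scanned sequence; offset maps element coordinate -> string index.
    full = (element.flank5[len(element.flank5) - flank:] if flank else "") \
        + element.sequence \
        + (element.flank3[:flank] if flank else "")

    starts = list(range(-flank, L + flank - fragment_length + 1, step))
    terminal = L + flank - fragment_length
    if starts[-1] != terminal:
        starts.append(terminal)

    params = TilingParams(fragment_length, overlap, flank, clamp, primer_tail)
    fragments = []
    for i, s in enumerate(starts):
        core = full[s + flank: s + flank + fragment_length]
        fragments.append(Fragment(index=i, start=s, core=core,
                                  oligo=make_oligo(core, clamp, primer_tail)))
    return FragmentLibrary(element.id, fragments, params, L)


def bins_for_element(library: FragmentLibrary) -> list[tuple[int, float]]:
    """Step-sized bins tiling the covered span, with their mid positions.

    Each bin is the half-open interval ``[bin_start, bin_start + step)``; its
    mid position (``bin_start + step/2``) is used as the representative
    binding-event position.  A residual sub-step bin at the right edge, if the
    span is not a multiple of the step, gets its own center.
    """
    step = library.params.step
    lo, hi = library.span
    bins = []
    s = lo
    while s + step <= hi:
        bins.append((s, s + step / 2))
        s += step
    if s < hi:  # residual right-edge bin
        bins.append((s, s + (hi - s) / 2))
    return bins


def fragments_covering_bin(library: FragmentLibrary, bin_start: int) -> list[Fragment]:
    """Fragments that fully contain the bin ``[bin_start, bin_start+step)``
    (a residual edge bin is contained up to the span end)."""
    step = library.params.step
    lo, hi = library.span
    bin_end = min(bin_start + step, hi)
    return [f for f in library.fragments
            if f.start <= bin_start and f.end >= bin_end]


# ---------------------------------------------------------------------------
# I/O

def read_element_fasta(path: str | Path, element_id: str) -> RegulatoryElement:
    """Load an element and its flanks from FASTA.

    Record ids: ``<element>``, and optionally ``<element>_flank5`` /
    ``<element>_flank3``.
    """
    records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
    if element_id not in records:
        raise KeyError(f"record {element_id!r} not found in {path}")
    return RegulatoryElement(
        id=element_id,
        sequence=records[element_id],
        flank5=records.get(f"{element_id}_flank5", ""),
        flank3=records.get(f"{element_id}_flank3", ""),
    )


def write_library(library: FragmentLibrary, outdir: str | Path) -> dict[str, Path]:
    """Write the oligo order sheet (TSV), fragment BED and core FASTA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eid = library.element_id
    sheet = outdir / f"{eid}.oligos.tsv"
    bed = outdir / f"{eid}.fragments.bed"
    fasta = outdir / f"{eid}.cores.fasta"

    with open(sheet, "w") as fh:
        fh.write("index\tstart\tcore\toligo\n")
        for f in library.fragments:
            fh.write(f"{f.index}\t{f.start}\t{f.core}\t{f.oligo}\n")
    with open(bed, "w") as fh:
        for f in library.fragments:
            fh.write(f"{eid}\t{f.start}\t{f.end}\t{eid}_frag{f.index}\n")
    SeqIO.write(
        (SeqRecord(Seq(f.core), id=f"{eid}_frag{f.index}", description="")
         for f in library.fragments),
        str(fasta), "fasta")
    return {"oligos": sheet, "bed": bed, "fasta": fasta}


def library_to_frame(library: FragmentLibrary):
    """Fragment table as a DataFrame (index, start, end, core)."""
    import pandas as pd

    return pd.DataFrame(
        {"fragment_index": [f.index for f in library.fragments],
         "start": [f.start for f in library.fragments],
         "end": [f.end for f in library.fragments],
         "core": [f.core for f in library.fragments]})
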