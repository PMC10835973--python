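"""Sequence preparation for de novo motif discovery.

Coding/TF genes get a TSS-centred window of 2000 bp on either side of
the TSS (4001 bp total); when the TSS sits at the sequence start or end
the window becomes a one-sided 4000 bp extension instead, and when the
sequence is shorter than the full window it is clamped into bounds so
the TSS is always covered.  Pseudogenes get sliding windows of the
smallest-pseudogene length (462 bp) with a 52 bp overlap between
consecutive windows; the final window is anchored to the sequence end so
no suffix is lost (it may overlap its predecessor by more than 52 bp).
All coordinates are 0-based half-open.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

TSS_FLANK = 2000
SLIDE_WINDOW = 462
SLIDE_OVERLAP = 52


@dataclass
class SequenceWindow:
    """One extracted window on a source sequence."""

    gene: str
    index: int
    start: int  # 0-based inclusive
    end: int  # exclusive
    sequence: str
    anchor: str  # tss_centered | tss_forward | tss_backward | sliding

    @property
    def header(self) -> str:
        return f"{self.gene}|{self.index}|{self.start}-{self.end}"


def tss_window(gene: str, sequence: str, tss: int,
               flank: int = TSS_FLANK) -> SequenceWindow:
    """The TSS-anchored window for one gene.

    Branches: centred when both flanks fit; forward ([tss, tss+2f+1))
    when the left flank is missing; backward ([tss-2f, tss+1)) when the
    right flank is missing; either one clamped into bounds when the
    sequence cannot hold the full window.
    """
    if not 0 <= tss < len(sequence):
        raise ValueError(f"TSS {tss} outside sequence of length {len(sequence)}")
    length = min(2 * flank + 1, len(sequence))
    if tss - flank >= 0 and tss + flank + 1 <= len(sequence):
        start, anchor = tss - flank, "tss_centered"
    elif tss - flank < 0:
        start, anchor = min(tss, len(sequence) - length), "tss_forward"
    else:
        start, anchor = max(tss + 1 - length, 0), "tss_backward"
    end = start + length
    return SequenceWindow(gene, 0, start, end, sequence[start:end].upper(),
                          anchor)


def n_sliding_windows(length: int, window: int = SLIDE_WINDOW,
                      overlap: int = SLIDE_OVERLAP) -> int:
    """Closed-form window count: 1 + ceil((L - w)/step) for L > w, else 1."""
    step = window - overlap
    if length <= window:
        return 1
    return 1 + math.ceil((length - window) / step)


def sliding_windows(gene: str, sequence: str, window: int = SLIDE_WINDOW,
                    overlap: int = SLIDE_OVERLAP) -> list[SequenceWindow]:
    """Tile a sequence with fixed-size windows at step = window - overlap.

    Consecutive windows share exactly ``overlap`` bp, except possibly
    the final end-anchored window.
    """
    if overlap >= window:
        raise ValueError("overlap must be smaller than the window")
    length = len(sequence)
    step = window - overlap
    if length <= window:
        return [SequenceWindow(gene, 0, 0, length, sequence.upper(), "sliding")]
    starts = list(range(0, length - window, step))
    starts.append(length - window)  # end-anchored final window
    return [
        SequenceWindow(gene, i, s, s + window,
                       sequence[s:s + window].upper(), "sliding")
        for i, s in enumerate(starts)
    ]


def export_fasta(windows: list[SequenceWindow], path: str) -> None:
    """Write windows as FASTA with gene|index|start-end headers."""
    headers = [w.header for w in windows]
    if len(set(headers)) != len(headers):
        raise ValueError("duplicate window headers")
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.header}\n{w.sequence}\n")


_HEADER_RE = re.compile(r"^(?P<gene>.+)\|(?P<index>\d+)\|(?P<start>\d+)-(?P<end>\d+)$")


def read_windows_fasta(path: str) -> list[SequenceWindow]:
    """Round-trip reader for :func:`export_fasta` output."""
    windows: list[SequenceWindow] = []
    name, chunks = None, []

    def flush() -> None:
        if name is None:
            return
        m = _HEADER_RE.match(name)
        if not m:
            raise ValueError(f"malformed window header {name!r}")
        windows.append(SequenceWindow(
            m["gene"], int(m["index"]), int(m["start"]), int(m["end"]),
            "".join(chunks).upper(), "sliding"))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                flush()
                name, chunks = line[1:], []
            elif line:
                chunks.append(line)
    flush()
    return windows
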