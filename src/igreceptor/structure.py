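"""Receptor signalling-class prediction from protein sequence.

A single-pass (type I) receptor is classified from three features:

* a transmembrane (TM) segment, detected by Kyte-Doolittle hydropathy
  averaged over a sliding window (default window 19, threshold 1.6) —
  the highest-scoring run of passing windows is taken as the single TM,
  ties resolved toward the C terminus because these receptors anchor
  near their C-terminal end (and so a hydrophobic signal peptide is not
  mistaken for the TM);
* ITIM motifs — six-residue windows matching ``[VLSN] x Y x x [LV]`` —
  scanned only in the cytoplasmic tail (C-terminal of the TM);
* a charged arginine inside the TM, the hallmark of activating receptors
  that recruit ITAM-bearing adaptors.

Decision table: no TM -> soluble; TM with >=1 tail ITIM -> inhibitory;
TM, no ITIM, TM arginine -> activating; TM, no ITIM, no arginine ->
unclassified (a totality fallback, not a biological category).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

ITIM_RE = re.compile(r"(?=([VLSN].Y..[LV]))")

DEFAULT_TM_WINDOW = 19
DEFAULT_TM_THRESHOLD = 1.6


@dataclass(frozen=True)
class TMSegment:
    start: int  # 0-based half-open aa interval
    end: int
    mean_hydropathy: float  # hydropathy of the segment's best window

    @property
    def aa_interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ITIMSite:
    position: int
    matched_text: str

    @property
    def variant(self) -> str:
        return f"{self.matched_text[0]}xYxx{self.matched_text[5]}"


@dataclass(frozen=True)
class ReceptorClassification:
    protein_id: str
    tm: TMSegment | None
    itims: tuple[ITIMSite, ...]
    tm_arginine: bool
    class_call: str  # inhibitory | activating | soluble | unclassified
    non_signalling_itims: tuple[ITIMSite, ...] = field(default_factory=tuple)


def _hydropathy(aa: str) -> float:
    # unknown residues (X from ambiguous codons) are hydropathy-neutral
    return KYTE_DOOLITTLE.get(aa, 0.0)


def predict_tm(
    protein: str,
    window: int = DEFAULT_TM_WINDOW,
    threshold: float = DEFAULT_TM_THRESHOLD,
) -> TMSegment | None:
    """Detect the single best TM segment by sliding-window mean hydropathy.

    Consecutive window starts whose means reach the threshold form a run;
    the run with the highest peak window mean wins (ties go to the most
    C-terminal run).  The reported interval spans all residues of the
    run's windows.  Returns None when no window passes or the protein is
    shorter than the window.
    """
    if not protein:
        raise ValueError("empty protein")
    n = len(protein)
    if n < window:
        return None
    vals = [_hydropathy(a) for a in protein]
    total = sum(vals[:window])
    means = []
    for i in range(n - window + 1):
        if i > 0:
            total += vals[i + window - 1] - vals[i - 1]
        means.append(total / window)
    passing = [i for i, m in enumerate(means) if m >= threshold]
    if not passing:
        return None
    runs: list[tuple[int, int]] = []  # inclusive window-start ranges
    s = passing[0]
    prev = passing[0]
    for i in passing[1:]:
        if i == prev + 1:
            prev = i
        else:
            runs.append((s, prev))
            s = prev = i
    runs.append((s, prev))
    best = None
    for a, b in runs:
        peak = max(means[a : b + 1])
        if best is None or peak > best[0] or (peak == best[0] and a > best[1]):
            best = (peak, a, b)
    peak, a, b = best
    return TMSegment(start=a, end=b + window, mean_hydropathy=float(peak))


def scan_itims(protein: str, tail_start: int) -> list[ITIMSite]:
    """All (overlapping) ITIM windows at positions >= tail_start, left to right."""
    if tail_start > len(protein):
        raise ValueError("tail_start beyond protein end")
    sites = []
    for m in ITIM_RE.finditer(protein, tail_start):
        sites.append(ITIMSite(position=m.start(), matched_text=m.group(1)))
    return sites


def tm_arginine(protein: str, tm: TMSegment) -> bool:
    """True iff the TM segment contains at least one arginine."""
    if tm is None:
        raise ValueError("tm segment required")
    return "R" in protein[tm.start : tm.end]


def classify_receptor(
    protein_id: str,
    protein: str,
    window: int = DEFAULT_TM_WINDOW,
    threshold: float = DEFAULT_TM_THRESHOLD,
) -> ReceptorClassification:
    """Apply the full decision table to one protein."""
    tm = predict_tm(protein, window=window, threshold=threshold)
    if tm is None:
        # motif matches on a TM-less protein cannot signal; report separately
        matches = tuple(scan_itims(protein, 0))
        return ReceptorClassification(
            protein_id=protein_id,
            tm=None,
            itims=(),
            tm_arginine=False,
            class_call="soluble",
            non_signalling_itims=matches,
        )
    itims = tuple(scan_itims(protein, tm.end))
    has_r = tm_arginine(protein, tm)
    if itims:
        call = "inhibitory"
    elif has_r:
        call = "activating"
    else:
        call = "unclassified"
    return ReceptorClassification(
        protein_id=protein_id,
        tm=tm,
        itims=itims,
        tm_arginine=has_r,
        class_call=call,
    )
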