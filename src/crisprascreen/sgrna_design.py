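"""SaCas9-style sgRNA candidate design in TSS-upstream promoter windows.

Scans both strands of a promoter window for PAM matches (default
``NNGRRT``, the canonical *S. aureus* Cas9 motif; configurable) and emits
22-nt spacer candidates immediately 5' of each PAM, generates scramble
control spacers screened by exact k-mer exclusion against user-supplied
sequences, and assembles full sgRNA templates by appending the standard
SaCas9 scaffold/terminator.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SA_SCAFFOLD",
    "PromoterWindow",
    "GuideCandidate",
    "scan_pam_candidates",
    "make_scramble_spacer",
    "build_sgrna_sequence",
    "select_spaced_candidates",
    "read_promoter_fasta",
    "candidate_table",
]

#: SaCas9 sgRNA scaffold with poly-T terminator, appended 3' of the spacer
#: in the DNA template (83 nt).
SA_SCAFFOLD = (
    "GTTTTAGTACTCTGGAAACAGAATCTACTAAAACAAGGCAAAATGCCGTGTTTATCTCGTCAACTTGTTGGCGAGATTTTTTT"
)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGTN]",
}


@dataclass(frozen=True)
class PromoterWindow:
    """A promoter sequence with the TSS position in local coordinates.

    By convention the window is the region immediately upstream of the
    TSS, so ``tss_offset`` defaults to the window length (TSS at the
    right edge). Recommended window length is 500-600 bp; anything else
    draws a warning, not an error.
    """

    sequence: str
    tss_offset: int | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not re.fullmatch(r"[ACGTN]*", seq):
            raise ValueError("promoter sequence may only contain A, C, G, T, N")
        object.__setattr__(self, "sequence", seq)
        if self.tss_offset is None:
            object.__setattr__(self, "tss_offset", len(seq))
        if not 500 <= len(seq) <= 600:
            warnings.warn(
                f"promoter window {self.source_id or '<unnamed>'} is {len(seq)} bp; "
                "500-600 bp immediately upstream of the TSS is the recommended range",
                stacklevel=2,
            )


@dataclass(frozen=True)
class GuideCandidate:
    """A spacer/PAM candidate; ``start``/``end`` delimit the protospacer
    interval in promoter-local 0-based half-open coordinates."""

    guide_id: str
    spacer: str
    pam: str
    strand: str
    start: int
    end: int
    distance_to_tss: float


def _pam_regex(pattern: str) -> re.Pattern[str]:
    try:
        return re.compile("(?=(" + "".join(_IUPAC[c] for c in pattern.upper()) + "))")
    except KeyError as exc:
        raise ValueError(f"unknown IUPAC code {exc.args[0]!r} in PAM pattern") from None


def scan_pam_candidates(
    window: PromoterWindow,
    pam_pattern: str = "NNGRRT",
    spacer_len: int = 22,
) -> list[GuideCandidate]:
    """Enumerate all spacer candidates adjacent to a PAM on either strand.

    For a + strand match the protospacer is the ``spacer_len`` bases 5' of
    the PAM in the window; for the − strand, the scan runs over the
    reverse complement and coordinates are mirrored back. Candidates whose
    spacer would extend beyond the window are dropped. Overlapping PAM
    matches are all reported. Deterministic and idempotent.
    """
    seq = window.sequence
    L = len(seq)
    if L < spacer_len + len(pam_pattern):
        warnings.warn(
            f"window of {L} bp is shorter than spacer ({spacer_len}) + PAM "
            f"({len(pam_pattern)}); no candidates possible",
            stacklevel=2,
        )
        return []
    rx = _pam_regex(pam_pattern)
    out: list[GuideCandidate] = []
    tss = window.tss_offset

    def add(spacer: str, pam: str, strand: str, start: int, end: int) -> None:
        if "N" in spacer or "N" in pam:
            return
        mid = (start + end) / 2.0
        out.append(
            GuideCandidate(
                guide_id=f"{window.source_id or 'window'}_{strand}{start}",
                spacer=spacer,
                pam=pam,
                strand=strand,
                start=start,
                end=end,
                distance_to_tss=abs(mid - tss),
            )
        )

    plen = len(pam_pattern)
    for m in rx.finditer(seq):
        p = m.start()
        if p >= spacer_len:
            add(seq[p - spacer_len : p], seq[p : p + plen], "+", p - spacer_len, p)
    rc = str(Seq(seq).reverse_complement())
    for m in rx.finditer(rc):
        p = m.start()
        if p >= spacer_len:
            # protospacer occupies [L - p - spacer_len, L - p) ... no:
            # rc position p maps to original position L - p - 1; the spacer
            # rc[p-spacer_len:p] maps to original [L - p, L - p + spacer_len)
            add(rc[p - spacer_len : p], rc[p : p + plen], "-", L - p, L - p + spacer_len)
    out.sort(key=lambda c: (c.start, c.strand))
    return out


def make_scramble_spacer(
    length: int = 22,
    forbidden_sequences: Iterable[str] | None = None,
    k: int = 12,
    seed: int = 0,
    max_retries: int = 10_000,
) -> str:
    """Generate a scramble control spacer by seeded rejection sampling.

    The returned spacer shares no exact ``k``-mer, on either strand, with
    any sequence in ``forbidden_sequences`` (a desk-scale stand-in for a
    genome-wide alignment screen — supply the sequences you must avoid,
    e.g. the promoter windows being targeted). Deterministic for a given
    seed; raises after ``max_retries`` failed draws with a hint to lower
    ``k``.
    """
    if k > length:
        raise ValueError(f"k-mer size {k} exceeds spacer length {length}")
    forbidden_kmers: set[str] = set()
    for s in forbidden_sequences or ():
        s = str(s).upper().replace("U", "T")
        for i in range(len(s) - k + 1):
            forbidden_kmers.add(s[i : i + k])
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    for _ in range(max_retries):
        spacer = "".join(rng.choice(bases, size=length))
        rcs = str(Seq(spacer).reverse_complement())
        hit = any(
            spacer[i : i + k] in forbidden_kmers or rcs[i : i + k] in forbidden_kmers
            for i in range(length - k + 1)
        )
        if not hit:
            return spacer
    raise RuntimeError(
        f"no spacer free of forbidden {k}-mers after {max_retries} draws; "
        "consider a smaller k or fewer forbidden sequences"
    )


def build_sgrna_sequence(spacer: str) -> str:
    """Full sgRNA DNA template: spacer followed by the 83-nt SaCas9
    scaffold/terminator. An empty spacer returns the scaffold alone with a
    warning."""
    spacer = spacer.upper()
    if not re.fullmatch(r"[ACGT]*", spacer):
        raise ValueError("spacer may only contain A, C, G, T")
    if not spacer:
        warnings.warn("empty spacer: returning the bare scaffold", stacklevel=2)
    return spacer + SA_SCAFFOLD


def select_spaced_candidates(
    candidates: Sequence[GuideCandidate], n: int = 7
) -> list[GuideCandidate]:
    """Pick ``n`` candidates spread across the window (farthest-point
    greedy on protospacer midpoints, seeded with the two extremes).

    A simple spacing heuristic for shortlisting binding sites; no claim of
    activity ranking is made.
    """
    if len(candidates) <= n:
        return list(candidates)
    mids = np.array([(c.start + c.end) / 2 for c in candidates], dtype=float)
    order = np.argsort(mids)
    chosen = [order[0], order[-1]]
    remaining = [i for i in order[1:-1]]
    while len(chosen) < n and remaining:
        dists = [min(abs(mids[i] - mids[j]) for j in chosen) for i in remaining]
        best = int(np.argmax(dists))
        chosen.append(remaining.pop(best))
    return [candidates[i] for i in sorted(chosen)]


def read_promoter_fasta(path: str | Path) -> list[PromoterWindow]:
    """Read promoter windows from FASTA; a ``tss_offset=<int>`` key=value
    token in the description sets the TSS position (default: window
    length, i.e. the window sits immediately upstream of the TSS)."""
    windows: list[PromoterWindow] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tss = None
        for token in rec.description.split():
            if token.lower().startswith("tss_offset="):
                tss = int(token.split("=", 1)[1])
        windows.append(PromoterWindow(str(rec.seq), tss, rec.id))
    return windows


def candidate_table(candidates: Sequence[GuideCandidate]):
    """Candidate table in the output TSV schema."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "guide_id": c.guide_id,
                "spacer": c.spacer,
                "pam": c.pam,
                "strand": c.strand,
                "start": c.start,
                "end": c.end,
                "distance_to_tss": c.distance_to_tss,
            }
            for c in candidates
        ]
    )
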