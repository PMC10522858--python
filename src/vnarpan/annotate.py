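"""Anchor-based VNAR identification and CDR3 excision.

A read carries a VNAR cassette if some frame/strand translation contains a
5' framework anchor match followed by a 3' framework anchor match with a
stop-free, N-free CDR3 of legal length in between. The anchor motifs are
configuration, not constants: the defaults target the conserved
framework-3 cysteine block ([YF][YF]C, CDR3 starts after the C) and the
framework-4 start ([DN]G[AG]GT, CDR3 ends before it).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio.Data import CodonTable

from .seqio import Read

DEFAULT_ANCHOR_5P = r"[YF][YF]C"
DEFAULT_ANCHOR_3P = r"[DN]G[AG]GT"

# no_5p_anchor < no_3p_anchor < bad_length < stop_in_cdr3 < ambiguous_base:
# a higher-ranked reason means the read progressed further before failing.
REJECTION_REASONS = (
    "no_5p_anchor",
    "no_3p_anchor",
    "bad_length",
    "stop_in_cdr3",
    "ambiguous_base",
)
_REASON_RANK = {r: i for i, r in enumerate(REJECTION_REASONS)}

_standard = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def translate_frame(nt: str, offset: int) -> str:
    """Translate one frame under the standard genetic code.

    Trailing partial codons are ignored; stops render as '*'; any codon
    containing a non-ACGT base renders as 'X'.
    """
    if offset not in (0, 1, 2):
        raise ValueError(f"frame offset must be 0, 1 or 2, got {offset!r}")
    get = CODON_TO_AA.get
    end = offset + 3 * ((len(nt) - offset) // 3)
    return "".join(get(nt[i : i + 3], "X") for i in range(offset, end, 3))


@dataclass(frozen=True)
class AnchorConfig:
    """Anchor motifs (amino-acid regex) delimiting the CDR3."""

    five_prime_pattern: str = DEFAULT_ANCHOR_5P
    three_prime_pattern: str = DEFAULT_ANCHOR_3P
    min_cdr3_len: int = 3
    max_cdr3_len: int = 35

    def __post_init__(self):
        if not self.five_prime_pattern or not self.three_prime_pattern:
            raise ValueError("anchor patterns must be non-empty")
        if self.min_cdr3_len < 1 or self.max_cdr3_len < self.min_cdr3_len:
            raise ValueError("require 1 <= min_cdr3_len <= max_cdr3_len")
        object.__setattr__(self, "_re5", re.compile(self.five_prime_pattern))
        object.__setattr__(self, "_re3", re.compile(self.three_prime_pattern))


@dataclass
class Cdr3Record:
    """An extracted CDR3 with its coding nucleotides and provenance."""

    read_id: str
    aa: str
    nt: str
    frame: int
    strand: str  # '+' or '-'
    nt_span: tuple[int, int] = (0, 0)  # 0-based half-open on the stored read


@dataclass
class RejectionStats:
    by_reason: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REJECTION_REASONS}
    )

    @property
    def total(self) -> int:
        return sum(self.by_reason.values())


@dataclass(frozen=True)
class _Hit:
    frame: int
    strand: str
    aa: str
    aa_span: tuple[int, int]  # CDR3 span in the frame translation
    nt_span: tuple[int, int]  # CDR3 span on the original read, forward strand
    nt: str  # coding-strand nucleotides
    span_aa: int  # anchored span (5' match start .. 3' match end), for ranking


def _scan_frame(aa: str, anchors: AnchorConfig) -> tuple[Optional[tuple], str]:
    """Find the leftmost legal (5' anchor, 3' anchor) pair in one translation.

    Returns ((m5_start, cdr3_start, cdr3_end, m3_end), reason) where the
    tuple is None on failure and reason records how far the scan got.
    """
    best_reason = "no_5p_anchor"
    for m5 in anchors._re5.finditer(aa):
        if _REASON_RANK[best_reason] < _REASON_RANK["no_3p_anchor"]:
            best_reason = "no_3p_anchor"
        for m3 in anchors._re3.finditer(aa, m5.end()):
            cdr3 = aa[m5.end() : m3.start()]
            if len(cdr3) > anchors.max_cdr3_len:
                if _REASON_RANK[best_reason] < _REASON_RANK["bad_length"]:
                    best_reason = "bad_length"
                break  # later 3' matches only lengthen the CDR3
            if len(cdr3) < anchors.min_cdr3_len:
                if _REASON_RANK[best_reason] < _REASON_RANK["bad_length"]:
                    best_reason = "bad_length"
                continue
            if "*" in cdr3:
                if _REASON_RANK[best_reason] < _REASON_RANK["stop_in_cdr3"]:
                    best_reason = "stop_in_cdr3"
                continue
            if "X" in cdr3:
                if _REASON_RANK[best_reason] < _REASON_RANK["ambiguous_base"]:
                    best_reason = "ambiguous_base"
                continue
            return (m5.start(), m5.end(), m3.start(), m3.end()), best_reason
    return None, best_reason


def locate_vnar(
    read: Read, anchors: AnchorConfig = AnchorConfig()
) -> tuple[Optional[_Hit], str]:
    """Scan all six frame/strand combinations for an anchored CDR3.

    Among qualifying frames the longest anchored span wins; ties prefer the
    + strand, then the lowest frame. Returns (hit, reason); reason is the
    most-advanced failure code when hit is None.
    """
    seq = read.seq
    length = len(seq)
    rc = reverse_complement(seq)
    best: Optional[_Hit] = None
    best_reason = "no_5p_anchor"
    for strand, template in (("+", seq), ("-", rc)):
        for frame in (0, 1, 2):
            aa = translate_frame(template, frame)
            found, reason = _scan_frame(aa, anchors)
            if found is None:
                if _REASON_RANK[reason] > _REASON_RANK[best_reason]:
                    best_reason = reason
                continue
            m5s, c_start, c_end, m3e = found
            nt_lo = frame + 3 * c_start  # coords on the scanned template
            nt_hi = frame + 3 * c_end
            if strand == "+":
                nt_span = (nt_lo, nt_hi)
            else:
                nt_span = (length - nt_hi, length - nt_lo)
            hit = _Hit(
                frame=frame,
                strand=strand,
                aa=aa[c_start:c_end],
                aa_span=(c_start, c_end),
                nt_span=nt_span,
                nt=template[nt_lo:nt_hi],
                span_aa=m3e - m5s,
            )
            # longest anchored span wins; earlier (strand, frame) wins ties
            if best is None or hit.span_aa > best.span_aa:
                best = hit
    if best is None:
        return None, best_reason
    return best, ""


def annotate_all(
    reads: Iterable[Read], anchors: AnchorConfig = AnchorConfig()
) -> tuple[list[Cdr3Record], RejectionStats]:
    """Extract one Cdr3Record per matching read; tally rejections by reason.

    Conservation holds: len(records) + stats.total == number of input reads.
    Results are cached by sequence string, so duplicate reads cost one scan.
    """
    records: list[Cdr3Record] = []
    stats = RejectionStats()
    cache: dict[str, tuple[Optional[_Hit], str]] = {}
    for read in reads:
        result = cache.get(read.seq)
        if result is None:
            result = locate_vnar(read, anchors)
            cache[read.seq] = result
        hit, reason = result
        if hit is None:
            stats.by_reason[reason] += 1
        else:
            records.append(
                Cdr3Record(
                    read_id=read.id,
                    aa=hit.aa,
                    nt=hit.nt,
                    frame=hit.frame,
                    strand=hit.strand,
                    nt_span=hit.nt_span,
                )
            )
    return records, stats


def write_annotation_tsv(
    path: str,
    records: list[Cdr3Record],
) -> None:
    """Per-read annotation dump (one row per extracted CDR3)."""
    with open(path, "w", encoding="utf-8") as out:
        out.write("read_id\tstrand\tframe\tcdr3_aa\tcdr3_nt\n")
        for rec in records:
            out.write(f"{rec.read_id}\t{rec.strand}\t{rec.frame}\t{rec.aa}\t{rec.nt}\n")
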