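"""Rare/intermediate/common codon classification and rare-codon statistics.

Classification is by relative adaptiveness w = freq(codon) / max synonymous
freq, with configurable cutoffs: rare if w < rare_max_w, common if
w >= common_min_w, intermediate otherwise. Bundled per-thousand usage
tables ship for the two expression hosts (bacteria = E. coli K-12,
yeast = S. cerevisiae).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .annotate import CODON_TO_AA
from .errors import FormatError
from .seqio import RoundTable

log = logging.getLogger(__name__)

SENSE_CODONS = frozenset(c for c, aa in CODON_TO_AA.items() if aa != "*")
_BUNDLED = {"bacteria": "ecoli_k12_codon_usage.tsv", "yeast": "scerevisiae_codon_usage.tsv"}

DEFAULT_RARE_MAX_W = 1.0 / 3.0
DEFAULT_COMMON_MIN_W = 2.0 / 3.0


@dataclass
class CodonUsageTable:
    organism: str
    freq: dict[str, float]  # sense codon -> usage per thousand
    rare_max_w: float = DEFAULT_RARE_MAX_W
    common_min_w: float = DEFAULT_COMMON_MIN_W
    _w: dict[str, float] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        missing = SENSE_CODONS - set(self.freq)
        extra = set(self.freq) - SENSE_CODONS
        if missing or extra:
            raise FormatError(
                f"usage table must cover exactly the 61 sense codons "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )
        if any(f <= 0 for f in self.freq.values()):
            raise FormatError("all usage frequencies must be positive")
        if not (0 < self.rare_max_w <= self.common_min_w <= 1):
            raise ValueError("require 0 < rare_max_w <= common_min_w <= 1")
        family_max: dict[str, float] = {}
        for codon, f in self.freq.items():
            aa = CODON_TO_AA[codon]
            family_max[aa] = max(family_max.get(aa, 0.0), f)
        self._w = {c: f / family_max[CODON_TO_AA[c]] for c, f in self.freq.items()}


def load_usage_table(
    organism: str,
    rare_max_w: float = DEFAULT_RARE_MAX_W,
    common_min_w: float = DEFAULT_COMMON_MIN_W,
    path: Optional[str] = None,
) -> CodonUsageTable:
    """Load a bundled usage table ('bacteria' or 'yeast'), or a TSV at path.

    TSV columns: codon, aa, freq_per_thousand; '#' lines are comments.
    """
    if path is None:
        if organism not in _BUNDLED:
            raise ValueError(f"unknown organism {organism!r}; use one of {sorted(_BUNDLED)}")
        text = resources.files("vnarpan.data").joinpath(_BUNDLED[organism]).read_text()
    else:
        with open(path, "r", encoding="utf-8") as handle:
            text = handle.read()
    freq: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("codon\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"usage table line {lineno}: expected 3 columns")
        codon, aa, f = parts
        codon = codon.upper()
        if CODON_TO_AA.get(codon) != aa:
            raise FormatError(f"usage table line {lineno}: codon/aa mismatch {codon}/{aa}")
        freq[codon] = float(f)
    return CodonUsageTable(
        organism=organism, freq=freq, rare_max_w=rare_max_w, common_min_w=common_min_w
    )


def relative_adaptiveness(t: CodonUsageTable, codon: str) -> float:
    """w in (0, 1]: usage of the codon relative to its best synonymous codon."""
    codon = codon.upper()
    if codon not in SENSE_CODONS:
        raise ValueError(f"not a sense codon: {codon!r}")
    return t._w[codon]


def classify_codon(t: CodonUsageTable, codon: str) -> str:
    """'rare', 'intermediate' or 'common' under the table's w cutoffs."""
    w = relative_adaptiveness(t, codon)
    if w < t.rare_max_w:
        return "rare"
    if w >= t.common_min_w:
        return "common"
    return "intermediate"


def codon_classes(t: CodonUsageTable, nt: str) -> list[str]:
    if len(nt) % 3 != 0:
        raise ValueError(f"coding sequence length {len(nt)} is not a codon multiple")
    nt = nt.upper()
    classes = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if codon not in SENSE_CODONS:
            raise ValueError(f"stop or ambiguous codon {codon!r} at position {i}")
        classes.append(classify_codon(t, codon))
    return classes


def rare_codon_fraction(nt: str, t: CodonUsageTable) -> float:
    """Percentage of rare codons in a clean coding sequence."""
    classes = codon_classes(t, nt)
    return 100.0 * classes.count("rare") / len(classes)


@dataclass
class ClonotypeCodonReport:
    rank: int
    cdr3_aa: str
    rep_nt: str
    n_codons: int
    n_rare: int
    n_intermediate: int
    n_common: int
    rare_pct: float


@dataclass
class CohortStats:
    mean: float
    sd: float
    n: int
    per_clonotype: list[ClonotypeCodonReport]
    skipped: list[str]


def cohort_rare_codon_stats(
    table: RoundTable, t: CodonUsageTable, top: int = 10
) -> CohortStats:
    """Rare-codon stats over the representative coding sequences of the
    top-N clonotypes (sample SD, n-1 denominator; SD = 0 when n < 2).

    Clonotypes whose rep_nt cannot be scored are skipped with a warning.
    """
    from .repertoire import top_n  # deferred: avoids an import cycle

    if top < 1:
        raise ValueError("top must be >= 1")
    reports: list[ClonotypeCodonReport] = []
    skipped: list[str] = []
    for rank, (cdr3, _count, _pct) in enumerate(top_n(table, top), start=1):
        nt = table.rep_nt.get(cdr3, "")
        try:
            classes = codon_classes(t, nt) if nt else None
            if classes is None:
                raise ValueError("no representative coding sequence")
        except ValueError as exc:
            log.warning("skipping clonotype %s: %s", cdr3, exc)
            skipped.append(cdr3)
            continue
        n_rare = classes.count("rare")
        reports.append(
            ClonotypeCodonReport(
                rank=rank,
                cdr3_aa=cdr3,
                rep_nt=nt,
                n_codons=len(classes),
                n_rare=n_rare,
                n_intermediate=classes.count("intermediate"),
                n_common=classes.count("common"),
                rare_pct=100.0 * n_rare / len(classes),
            )
        )
    if not reports:
        return CohortStats(mean=math.nan, sd=math.nan, n=0, per_clonotype=[], skipped=skipped)
    values = [r.rare_pct for r in reports]
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1)) if n > 1 else 0.0
    return CohortStats(mean=mean, sd=sd, n=n, per_clonotype=reports, skipped=skipped)


def write_codon_report_tsv(path: str, stats: CohortStats) -> None:
    with open(path, "w", encoding="utf-8") as out:
        out.write(
            "rank\tcdr3_aa\trep_nt\tn_codons\tn_rare\tn_intermediate\tn_common\trare_pct\n"
        )
        for r in stats.per_clonotype:
            out.write(
                f"{r.rank}\t{r.cdr3_aa}\t{r.rep_nt}\t{r.n_codons}\t{r.n_rare}\t"
                f"{r.n_intermediate}\t{r.n_common}\t{r.rare_pct:.6f}\n"
            )
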