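"""Synthetic biopanning campaigns.

Generates a clone population with a multimodal CDR3 length distribution,
then runs capture--wash--amplify rounds where each clone's capture
probability combines antigen occupancy, display valence (avidity), and an
optional penalty growing with the clone's rare-codon content in the
expression host:

    b = C / (C + Kd)
    d = exp(-lambda * r / 100)
    q = d * (1 - (1 - b)^valence)

Phage mode defaults to valence 5 with a positive codon penalty; yeast mode
to valence 1 with no penalty. Paired mode runs both campaigns from the same
generated library and initial counts, so cross-library comparisons have a
known ground truth.
"""
from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .annotate import CODON_TO_AA, AnchorConfig, translate_frame
from .codon import load_usage_table, rare_codon_fraction
from .errors import UndefinedStatisticError
from .seqio import Read, RoundTable, write_fastq

log = logging.getLogger(__name__)

# Fixed synthetic cassette. FW3 ends with the default 5' anchor (...YYC) and
# FW4 starts with the default 3' anchor (DGAGT...); the flanks pad the read
# beyond the 400 bp filter for any legal CDR3 length.
DEFAULT_FW3_AA = "TNKESISRGGRYVETVNQGSKSFSLRIRDLRVEDSGTYYC"
DEFAULT_FW4_AA = "DGAGTVLTVNPGHHHHHHGSMDPKSSDLAALEAKLAKM"
DEFAULT_FLANK5_NT = ("CTGACTGGTTGGATCCGCATAGCATGCTAACGTTAGCC" * 3)[:88]
DEFAULT_FLANK3_NT = ("GGATCCTAGCATGCAACGTTAGCCTAGCATCGATCCTA" * 3)[:90]

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

_SYNONYMOUS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa != "*":
        _SYNONYMOUS.setdefault(_aa, []).append(_codon)

# fixed codon choice for framework amino acids (E. coli-preferred codons)
_FW_CODON = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGC",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCG", "Q": "CAG", "R": "CGT", "S": "AGC", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAT",
}


def _encode(aa: str) -> str:
    return "".join(_FW_CODON[x] for x in aa)


DEFAULT_LENGTH_MIXTURE: tuple[tuple[int, float], ...] = (
    (15, 0.10), (16, 0.30), (17, 0.10), (20, 0.08),
    (22, 0.20), (24, 0.20), (31, 0.02),
)

MODE_DEFAULTS = {
    "phage": {"valence": 5, "lambda_codon": 2.0, "organism": "bacteria"},
    "yeast": {"valence": 1, "lambda_codon": 0.0, "organism": "yeast"},
}

OBSERVED_MAX_CDR3 = 31  # longest CDR3 seen in the motivating repertoire


@dataclass
class SimConfig:
    """Campaign settings; valence/lambda_codon default per display mode."""

    n_clones: int = 200
    length_mixture: tuple[tuple[int, float], ...] = DEFAULT_LENGTH_MIXTURE
    rounds: int = 4
    pool_size: int = 100_000
    read_depth: int = 20_000
    antigen_conc: float = 1e-7
    valence: Optional[int] = None
    lambda_codon: Optional[float] = None
    error_rate: float = 1e-3
    seed: int = 0
    kd_min: float = 1e-9
    kd_max: float = 1e-4
    dirichlet_alpha: float = 1.0
    codon_source: str = "uniform"  # codon draw for clone coding sequences
    max_cdr3_len: int = 35
    fw3_aa: str = DEFAULT_FW3_AA
    fw4_aa: str = DEFAULT_FW4_AA
    flank5_nt: str = DEFAULT_FLANK5_NT
    flank3_nt: str = DEFAULT_FLANK3_NT

    def __post_init__(self):
        if self.n_clones < 1 or self.pool_size < 1 or self.read_depth < 1:
            raise ValueError("all sizes must be >= 1")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if any(w <= 0 for _, w in self.length_mixture):
            raise ValueError("length mixture weights must be positive")
        for length, _ in self.length_mixture:
            if length > self.max_cdr3_len:
                raise ValueError(
                    f"length {length} exceeds max_cdr3_len={self.max_cdr3_len}"
                )
            if length > OBSERVED_MAX_CDR3:
                log.warning(
                    "length %d exceeds the observed maximum of %d",
                    length, OBSERVED_MAX_CDR3,
                )

    def for_mode(self, mode: str) -> "SimConfig":
        if mode not in MODE_DEFAULTS:
            raise ValueError(f"unknown mode {mode!r}")
        defaults = MODE_DEFAULTS[mode]
        return replace(
            self,
            valence=self.valence if self.valence is not None else defaults["valence"],
            lambda_codon=(
                self.lambda_codon
                if self.lambda_codon is not None
                else defaults["lambda_codon"]
            ),
        )


@dataclass
class CloneGroundTruth:
    clone_id: int
    cdr3_aa: str
    cdr3_nt: str
    kd: float  # dissociation constant, molar
    r: float = 0.0  # rare-codon % of cdr3_nt in the campaign host


@dataclass
class Library:
    clones: list[CloneGroundTruth]
    counts0: np.ndarray  # initial particle counts, sums to pool_size


@dataclass
class CampaignResult:
    mode: str
    cfg: SimConfig
    clones: list[CloneGroundTruth]  # r set for this campaign's host
    q: np.ndarray
    counts: list[np.ndarray]  # per round 0..rounds, each sums to pool_size


def _draw_codon_probs(source: str) -> Optional[dict[str, np.ndarray]]:
    if source == "uniform":
        return None
    usage = load_usage_table(source)
    probs: dict[str, np.ndarray] = {}
    for aa, codons in _SYNONYMOUS.items():
        f = np.array([usage.freq[c] for c in codons])
        probs[aa] = f / f.sum()
    return probs


def generate_library(cfg: SimConfig, rng: np.random.Generator,
                     anchors: AnchorConfig = AnchorConfig()) -> Library:
    """Draw clone CDR3s, coding sequences, affinities and initial counts.

    CDR3 amino acids are uniform over the 20 letters; candidates whose
    junction with FW4 would shift the 3' anchor are redrawn, as are
    duplicate clonotypes, so extraction at error rate 0 is exact.
    """
    lengths = np.array([l for l, _ in cfg.length_mixture])
    weights = np.array([w for _, w in cfg.length_mixture], dtype=float)
    weights = weights / weights.sum()
    codon_probs = _draw_codon_probs(cfg.codon_source)
    re3 = anchors._re3

    clones: list[CloneGroundTruth] = []
    seen: set[str] = set()
    for clone_id in range(cfg.n_clones):
        while True:
            length = int(rng.choice(lengths, p=weights))
            aa = "".join(rng.choice(list(AA_LETTERS), size=length))
            if aa in seen:
                continue
            m = re3.search(aa + cfg.fw4_aa[:5])
            if m is None or m.start() != length:
                continue  # anchor would fire early inside/over the CDR3
            break
        seen.add(aa)
        if codon_probs is None:
            nt = "".join(
                _SYNONYMOUS[x][int(rng.integers(len(_SYNONYMOUS[x])))] for x in aa
            )
        else:
            nt = "".join(
                _SYNONYMOUS[x][int(rng.choice(len(_SYNONYMOUS[x]), p=codon_probs[x]))]
                for x in aa
            )
        kd = math.exp(rng.uniform(math.log(cfg.kd_min), math.log(cfg.kd_max)))
        clones.append(CloneGroundTruth(clone_id=clone_id, cdr3_aa=aa, cdr3_nt=nt, kd=kd))

    if cfg.n_clones == 1:
        counts0 = np.array([cfg.pool_size])
    else:
        p = rng.dirichlet(np.full(cfg.n_clones, cfg.dirichlet_alpha))
        counts0 = rng.multinomial(cfg.pool_size, p)
    return Library(clones=clones, counts0=counts0)


def capture_probability(kd: float, antigen_conc: float, r: float,
                        lambda_codon: float, valence: int) -> float:
    """Per-particle capture probability q in [0, 1]."""
    if kd <= 0 or antigen_conc < 0 or valence < 1 or lambda_codon < 0:
        raise ValueError("parameters out of domain")
    b = antigen_conc / (antigen_conc + kd)
    d = math.exp(-lambda_codon * r / 100.0)
    return d * (1.0 - (1.0 - b) ** valence)


def simulate_round(counts: np.ndarray, q: np.ndarray, pool_size: int,
                   rng: np.random.Generator, max_attempts: int = 1000) -> np.ndarray:
    """One capture-then-amplify round; output counts sum to pool_size."""
    if counts.sum() <= 0:
        raise ValueError("round input counts must be positive in total")
    for attempt in range(max_attempts):
        captured = rng.binomial(counts, q)
        total = captured.sum()
        if total > 0:
            if attempt > 0:
                log.warning("wash-out guard: resampled capture %d time(s)", attempt)
            p = captured / total
            return rng.multinomial(pool_size, p)
    raise RuntimeError("capture resampling failed: no clone was ever captured")


def run_campaign(cfg: SimConfig, mode: str, library: Library,
                 rng: np.random.Generator) -> CampaignResult:
    """Run capture/amplify rounds for one display mode over a shared library."""
    mode_cfg = cfg.for_mode(mode)
    usage = load_usage_table(MODE_DEFAULTS[mode]["organism"])
    clones = [replace(c) for c in library.clones]
    for clone in clones:
        clone.r = rare_codon_fraction(clone.cdr3_nt, usage)
    q = np.array([
        capture_probability(
            c.kd, mode_cfg.antigen_conc, c.r, mode_cfg.lambda_codon, mode_cfg.valence
        )
        for c in clones
    ])
    counts = [library.counts0.copy()]
    for _ in range(cfg.rounds):
        counts.append(simulate_round(counts[-1], q, cfg.pool_size, rng))
    return CampaignResult(mode=mode, cfg=mode_cfg, clones=clones, q=q, counts=counts)


def cassette_nt(cfg: SimConfig, cdr3_nt: str) -> str:
    """Full synthetic amplicon for one clone (always > 400 nt)."""
    return (
        cfg.flank5_nt + _encode(cfg.fw3_aa) + cdr3_nt + _encode(cfg.fw4_aa)
        + cfg.flank3_nt
    )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: str, n_err: int, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    positions = rng.choice(len(arr), size=n_err, replace=False)
    for pos in positions:
        current = arr[pos]
        choices = _BASES[_BASES != current]
        arr[pos] = choices[int(rng.integers(len(choices)))]
    return arr.tobytes().decode("ascii")


def sample_reads(result: CampaignResult, round_idx: int,
                 rng: np.random.Generator, prefix: str = "sim") -> list[Read]:
    """Sequencing reads for one round: multinomial depth over clone counts,
    full cassettes with per-base substitution errors."""
    cfg = result.cfg
    counts = result.counts[round_idx]
    total = counts.sum()
    picks = rng.multinomial(cfg.read_depth, counts / total)
    cassettes = [cassette_nt(cfg, c.cdr3_nt) for c in result.clones]
    reads: list[Read] = []
    serial = 0
    for clone_idx, k in enumerate(picks):
        if k == 0:
            continue
        base = cassettes[clone_idx]
        if cfg.error_rate > 0:
            n_errs = rng.binomial(len(base), cfg.error_rate, size=k)
        else:
            n_errs = np.zeros(k, dtype=int)
        for n_err in n_errs:
            seq = _mutate(base, int(n_err), rng) if n_err else base
            reads.append(
                Read(id=f"{prefix}_R{round_idx}_{serial:06d}", seq=seq, qual="I" * len(seq))
            )
            serial += 1
    return reads


def simulate_paired(cfg: SimConfig) -> tuple[CampaignResult, CampaignResult]:
    """Phage and yeast campaigns from the same library and initial counts."""
    ss = np.random.SeedSequence(cfg.seed)
    s_lib, s_phage, s_yeast = ss.spawn(3)
    library = generate_library(cfg, np.random.default_rng(s_lib))
    phage = run_campaign(cfg, "phage", library, np.random.default_rng(s_phage))
    yeast = run_campaign(cfg, "yeast", library, np.random.default_rng(s_yeast))
    return phage, yeast


def simulate_single(cfg: SimConfig, mode: str) -> CampaignResult:
    ss = np.random.SeedSequence(cfg.seed)
    s_lib, s_rounds = ss.spawn(2)
    library = generate_library(cfg, np.random.default_rng(s_lib))
    return run_campaign(cfg, mode, library, np.random.default_rng(s_rounds))


def write_ground_truth_tsv(path: str, result: CampaignResult) -> None:
    rounds = len(result.counts) - 1
    header = ["clone_id", "cdr3_aa", "cdr3_nt", "kd_M", "rare_pct", "q"]
    header += [f"count_r{r}" for r in range(rounds + 1)]
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t".join(header) + "\n")
        for idx, clone in enumerate(result.clones):
            row = [
                str(clone.clone_id), clone.cdr3_aa, clone.cdr3_nt,
                f"{clone.kd:.6e}", f"{clone.r:.6f}", f"{result.q[idx]:.6e}",
            ]
            row += [str(int(result.counts[r][idx])) for r in range(rounds + 1)]
            out.write("\t".join(row) + "\n")


def simulate_campaign(cfg: SimConfig, mode: str, out_dir: str,
                      gzip_output: bool = False) -> dict:
    """Simulate one campaign (or both for mode='paired') and write per-round
    FASTQ plus a ground-truth TSV per mode. Returns a manifest dict."""
    os.makedirs(out_dir, exist_ok=True)
    if mode == "paired":
        phage, yeast = simulate_paired(cfg)
        results = [phage, yeast]
    else:
        results = [simulate_single(cfg, mode)]
    ss = np.random.SeedSequence((cfg.seed, 0xC0FFEE))
    read_rngs = ss.spawn(len(results))
    manifest: dict = {"mode": mode, "seed": cfg.seed, "outputs": {}}
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    for result, read_seed in zip(results, read_rngs):
        rng = np.random.default_rng(read_seed)
        paths = []
        for round_idx in range(len(result.counts)):
            reads = sample_reads(result, round_idx, rng, prefix=result.mode)
            path = os.path.join(out_dir, f"{result.mode}_R{round_idx}{suffix}")
            write_fastq(reads, path)
            paths.append(path)
        truth_path = os.path.join(out_dir, f"{result.mode}_ground_truth.tsv")
        write_ground_truth_tsv(truth_path, result)
        manifest["outputs"][result.mode] = {"fastq": paths, "ground_truth": truth_path}
    return manifest


def estimate_enrichment(tables: Sequence[RoundTable], cdr3: str) -> tuple[float, list[int]]:
    """Least-squares slope of ln(abundance) vs round index over rounds where
    the clonotype has positive abundance."""
    from .repertoire import abundance

    points = []
    for idx, table in enumerate(tables):
        ab = abundance(table, cdr3)
        if ab > 0:
            points.append((idx, math.log(ab)))
    if len(points) < 2:
        raise UndefinedStatisticError(
            f"{cdr3!r}: positive abundance in {len(points)} round(s); need >= 2"
        )
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    slope = float(np.polyfit(xs, ys, 1)[0])
    return slope, [int(x) for x in xs]


def sanity_check_cassette(cfg: SimConfig = SimConfig(),
                          anchors: AnchorConfig = AnchorConfig()) -> None:
    """Assert the fixed cassette parts are anchor-clean (used by tests)."""
    fw3, fw4 = cfg.fw3_aa, cfg.fw4_aa
    assert anchors._re5.search(fw3).end() == len(fw3), "FW3 must end with the 5' anchor"
    assert anchors._re3.match(fw4), "FW4 must start with the 3' anchor"
    assert anchors._re3.search(fw3) is None
    assert anchors._re5.search(fw4) is None
    min_total = (
        len(cfg.flank5_nt) + 3 * len(fw3) + 3 * len(fw4) + len(cfg.flank3_nt) + 9
    )
    assert min_total > 400, "cassette must clear the read-length filter"
    # the frame translation containing the cassette must be clean
    aa = translate_frame(cassette_nt(cfg, _encode("ARS")), len(cfg.flank5_nt) % 3)
    assert fw3 in aa and fw4 in aa
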