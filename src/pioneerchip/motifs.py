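"""PWM scanning and two-dimensional binomial motif enrichment.

Dimension 1 asks whether a motif occurs in the 500-nt foreground around
the located binding element (region A) more often than in the outer
250-nt flanks 250-500 nt away on each side (regions X and Y). Dimension 2
contrasts region A of silent-gene loci against region A of active-gene
loci (and vice versa). Enrichment is a per-sequence presence/absence
binomial test; each matrix's log-odds hit threshold is optimized over a
quantile grid to maximize enrichment, mirroring the motifclass strategy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PositionWeightMatrix:
    """A nucleotide count matrix with log-odds scoring.

    ``counts`` is 4 x width, rows in A,C,G,T order. ``threshold`` is a
    log2-odds hit cutoff; it is typically set by ``optimize_threshold``.
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.25
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.counts.shape[0] != 4:
            raise ValueError("counts must have 4 rows (A,C,G,T)")
        if self.counts.shape[1] < 4:
            raise ValueError("motif width must be >= 4")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def probabilities(self) -> np.ndarray:
        """Column-normalized probabilities with pseudocounts."""
        colsum = self.counts.sum(axis=0)
        if self.pseudocount == 0 and np.any(colsum == 0):
            raise ValueError(f"motif {self.name}: all-zero column needs a pseudocount")
        return (self.counts + self.pseudocount) / (colsum + 4 * self.pseudocount)

    def log_odds(self) -> np.ndarray:
        """log2( p(base, position) / background(base) ), shape 4 x width."""
        return np.log2(self.probabilities() / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probabilities().argmax(axis=0))

    def reverse_complement_matrix(self) -> np.ndarray:
        """Log-odds matrix scoring the reverse strand at the same offsets."""
        return self.log_odds()[::-1, ::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Map A,C,G,T to 0..3 and anything else to 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        out[arr == ord(base)] = i
    return out


def _score_offsets(encoded: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score every offset of an encoded sequence against a log-odds matrix.

    Non-ACGT bases contribute 0 (the background expectation on the
    log-odds scale).
    """
    width = lo.shape[1]
    if len(encoded) < width:
        return np.empty(0)
    padded = np.vstack([lo, np.zeros((1, width))])  # row 4: unknown base
    windows = np.lib.stride_tricks.sliding_window_view(encoded, width)
    return padded[windows, np.arange(width)].sum(axis=1)


def scan_all_scores(sequence: str, pwm: PositionWeightMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset log-odds scores on the forward and reverse strand."""
    enc = encode_sequence(sequence)
    if np.any(enc == 4):
        logger.debug("sequence contains non-ACGT bases; scored as background")
    return _score_offsets(enc, pwm.log_odds()), _score_offsets(enc, pwm.reverse_complement_matrix())


@dataclass
class MotifHit:
    position: int
    strand: str
    score: float


def scan_sequence(sequence: str, pwm: PositionWeightMatrix) -> list[MotifHit]:
    """All offsets scoring at or above the matrix threshold.

    Both strands are scored at every offset; when both reach the
    threshold only the higher-scoring strand is recorded ('+' on ties).
    """
    if len(sequence) < pwm.width:
        raise ValueError("sequence shorter than the motif width")
    if pwm.threshold is None:
        raise ValueError(f"motif {pwm.name} has no threshold set")
    fwd, rev = scan_all_scores(sequence, pwm)
    hits = []
    for pos in np.nonzero((fwd >= pwm.threshold) | (rev >= pwm.threshold))[0]:
        if fwd[pos] >= rev[pos]:
            hits.append(MotifHit(int(pos), "+", float(fwd[pos])))
        else:
            hits.append(MotifHit(int(pos), "-", float(rev[pos])))
    return hits


def best_score(sequence_or_parts, pwm: PositionWeightMatrix) -> float:
    """Best log-odds score over both strands; a tuple/list of strings is
    treated as one unit (e.g. the X+Y flank pair), scanned part by part."""
    parts = (sequence_or_parts,) if isinstance(sequence_or_parts, str) else tuple(sequence_or_parts)
    best = -np.inf
    for part in parts:
        if len(part) < pwm.width:
            continue
        fwd, rev = scan_all_scores(part, pwm)
        best = max(best, float(fwd.max()), float(rev.max()))
    return best


def binomial_presence_test(k_fg: int, n_fg: int, k_bg: int, n_bg: int) -> tuple[float, float]:
    """Upper-tail binomial p for k_fg hits among n_fg foreground units.

    The background rate is floored at 0.5/(n_bg+1) so a hit-free
    background cannot force p = 0.
    """
    if n_fg == 0 or n_bg == 0:
        raise ValueError("foreground and background sets must be non-empty")
    p0 = max(k_bg / n_bg, 0.5 / (n_bg + 1))
    p = float(stats.binom.sf(k_fg - 1, n_fg, p0))
    return p0, min(1.0, p)


def binomial_enrichment(fg, bg, pwm: PositionWeightMatrix,
                        unit: str = "sequence") -> tuple[int, float, float]:
    """Enrichment of motif occurrences in ``fg`` over ``bg`` at the
    matrix's current threshold.

    ``unit='sequence'`` (default) scores presence/absence per sequence
    unit; ``unit='site'`` counts hits per scanned base. Returns
    ``(k_fg, p0, p)``.
    """
    if pwm.threshold is None:
        raise ValueError(f"motif {pwm.name} has no threshold set")
    if len(fg) == 0 or len(bg) == 0:
        raise ValueError("foreground and background sets must be non-empty")
    if unit == "sequence":
        k_fg = sum(best_score(s, pwm) >= pwm.threshold for s in fg)
        k_bg = sum(best_score(s, pwm) >= pwm.threshold for s in bg)
        p0, p = binomial_presence_test(k_fg, len(fg), k_bg, len(bg))
        return k_fg, p0, p
    if unit == "site":
        def site_counts(seqs):
            k = n = 0
            for s in seqs:
                parts = (s,) if isinstance(s, str) else s
                for part in parts:
                    if len(part) < pwm.width:
                        continue
                    fwd, rev = scan_all_scores(part, pwm)
                    k += int(np.sum((fwd >= pwm.threshold) | (rev >= pwm.threshold)))
                    n += len(fwd)
            return k, n
        k_fg, n_fg = site_counts(fg)
        k_bg, n_bg = site_counts(bg)
        p0, p = binomial_presence_test(k_fg, n_fg, k_bg, n_bg)
        return k_fg, p0, p
    raise ValueError(f"unknown enrichment unit {unit!r}")


@dataclass
class ThresholdResult:
    threshold: float
    k_fg: int
    n_fg: int
    p0: float
    p: float
    feasible: bool


def optimize_threshold(fg, bg, pwm: PositionWeightMatrix, grid_size: int = 50,
                       min_hits: int = 3) -> ThresholdResult:
    """Pick the hit threshold maximizing foreground enrichment.

    Candidate thresholds are ``grid_size`` quantiles of the pooled
    per-unit best scores. Among candidates with at least ``min_hits``
    foreground hits the one with the smallest binomial p wins; ties break
    toward the higher (more stringent) threshold. If no candidate is
    feasible the result carries p = 1 and ``feasible=False``.
    """
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    fg_best = np.array([best_score(s, pwm) for s in fg])
    bg_best = np.array([best_score(s, pwm) for s in bg])
    pooled = np.concatenate([fg_best, bg_best])
    pooled = pooled[np.isfinite(pooled)]
    if len(pooled) == 0:
        return ThresholdResult(np.inf, 0, len(fg_best), 0.5 / (len(bg_best) + 1), 1.0, False)
    qs = np.linspace(0.0, 1.0, grid_size) if grid_size > 1 else np.array([0.5])
    candidates = np.unique(np.quantile(pooled, qs))
    best: ThresholdResult | None = None
    for thr in candidates:
        k_fg = int(np.sum(fg_best >= thr))
        k_bg = int(np.sum(bg_best >= thr))
        p0, p = binomial_presence_test(k_fg, len(fg_best), k_bg, len(bg_best))
        if k_fg < min_hits:
            continue
        if best is None or p < best.p or (p == best.p and thr > best.threshold):
            best = ThresholdResult(float(thr), k_fg, len(fg_best), p0, p, True)
    if best is None:
        return ThresholdResult(float(candidates[-1]), 0, len(fg_best),
                               0.5 / (len(bg_best) + 1), 1.0, False)
    return best


@dataclass
class RegionSequenceSet:
    """Per-locus foreground/flank sequences with activity labels.

    For each locus: ``a`` is the 500-nt foreground centered on the
    binding element, ``x``/``y`` the outer 250-nt flanks (250-500 nt
    upstream/downstream of the element).
    """

    names: list[str]
    a: list[str]
    x: list[str]
    y: list[str]
    labels: list[str]  # "active" | "silent"

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.a) == len(self.x) == len(self.y) == len(self.labels) == n):
            raise ValueError("all per-locus lists must have equal length")
        for ai, xi, yi in zip(self.a, self.x, self.y):
            if len(xi) + len(yi) != len(ai):
                raise ValueError("flank lengths X+Y must equal the foreground length")
        bad = set(self.labels) - {"active", "silent"}
        if bad:
            raise ValueError(f"unknown activity labels: {bad}")

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def from_element_centered(cls, names, sequences, labels,
                              foreground: int = 500, flank: int = 250) -> "RegionSequenceSet":
        """Carve A/X/Y out of sequences centered on the binding element.

        Each input sequence must be at least ``foreground + 2*flank`` long
        with the element at its center.
        """
        need = foreground + 2 * flank
        a, x, y = [], [], []
        for s in sequences:
            if len(s) < need:
                raise ValueError(f"sequence of length {len(s)} too short for "
                                 f"foreground {foreground} + 2x{flank} flanks")
            c = len(s) // 2
            a.append(s[c - foreground // 2: c + foreground // 2])
            x.append(s[c - foreground // 2 - flank: c - foreground // 2])
            y.append(s[c + foreground // 2: c + foreground // 2 + flank])
        return cls(list(names), a, x, y, list(labels))

    def subset(self, label: str) -> list[str]:
        return [ai for ai, li in zip(self.a, self.labels) if li == label]

    def flank_units(self) -> list[tuple[str, str]]:
        """One (X, Y) background unit per locus."""
        return list(zip(self.x, self.y))


def two_dimensional_significance(regions: RegionSequenceSet,
                                 motif_library: list[PositionWeightMatrix],
                                 grid_size: int = 50, min_hits: int = 3,
                                 adjust: bool = False) -> pd.DataFrame:
    """Per-motif bound-vs-flank and silent-vs-active enrichment.

    Dimension 1 compares region A of all loci against the X+Y flank units.
    Dimension 2 is computed in both directions (A_silent vs A_active and
    the reverse) with independently optimized thresholds; the reported
    direction is the smaller p. Raw p-values are reported; set
    ``adjust=True`` for an extra Benjamini-Hochberg column on each
    dimension.
    """
    a_silent = regions.subset("silent")
    a_active = regions.subset("active")
    dim2_ok = len(a_silent) >= 3 and len(a_active) >= 3
    if not dim2_ok:
        logger.warning("a class has <3 loci: dimension-2 contrast unavailable")

    rows = []
    for pwm in motif_library:
        r1 = optimize_threshold(regions.a, regions.flank_units(), pwm,
                                grid_size=grid_size, min_hits=min_hits)
        row = {"motif": pwm.name, "threshold_dim1": r1.threshold,
               "k_fg": r1.k_fg, "n_fg": r1.n_fg, "p0": r1.p0,
               "p_dim1": r1.p, "dim1_feasible": r1.feasible}
        if dim2_ok:
            r_sil = optimize_threshold(a_silent, a_active, pwm,
                                       grid_size=grid_size, min_hits=min_hits)
            r_act = optimize_threshold(a_active, a_silent, pwm,
                                       grid_size=grid_size, min_hits=min_hits)
            row.update(p_dim2_silent=r_sil.p, p_dim2_active=r_act.p,
                       p_dim2=min(r_sil.p, r_act.p),
                       direction="silent-enriched" if r_sil.p <= r_act.p else "active-enriched",
                       dim2_available=True)
        else:
            row.update(p_dim2_silent=np.nan, p_dim2_active=np.nan, p_dim2=np.nan,
                       direction="unavailable", dim2_available=False)
        rows.append(row)
    table = pd.DataFrame(rows)
    table["neglog10_p_dim1"] = -np.log10(table["p_dim1"])
    table["neglog10_p_dim2"] = -np.log10(table["p_dim2"])
    if adjust:
        from statsmodels.stats.multitest import multipletests
        table["q_dim1"] = multipletests(table["p_dim1"], method="fdr_bh")[1]
    return table


# ---------------------------------------------------------------------------
# Motif library I/O (JASPAR / TRANSFAC via Biopython) and built-in matrices.
# ---------------------------------------------------------------------------

def read_motif_library(path, dialect: str = "jaspar") -> list[PositionWeightMatrix]:
    """Read count matrices from a JASPAR or TRANSFAC file."""
    from Bio import motifs as bio_motifs

    if dialect not in ("jaspar", "transfac"):
        raise ValueError(f"unknown motif dialect {dialect!r}")
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        logger.warning("empty motif file %s", path)
        return []
    from io import StringIO
    try:
        parsed = bio_motifs.parse(StringIO(text), dialect.upper() if dialect == "transfac" else dialect)
        out = []
        for m in parsed:
            counts = np.array([m.counts[b] for b in BASES], dtype=np.float64)
            name = m.name or getattr(m, "matrix_id", None) or f"motif_{len(out) + 1}"
            out.append(PositionWeightMatrix(name=str(name), counts=counts))
    except Exception as exc:
        raise ValueError(f"malformed {dialect} motif file {path}: {exc}") from exc
    return out


def write_motif_library(pwms: list[PositionWeightMatrix], path) -> None:
    """Write count matrices in JASPAR (4-row bracketed) format."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name} {pwm.name}\n")
            for i, base in enumerate(BASES):
                row = " ".join(f"{v:.2f}".rstrip("0").rstrip(".") for v in pwm.counts[i])
                fh.write(f"{base} [ {row} ]\n")


def _pwm_from_iupac(name: str, pattern: str, strong: float = 50.0,
                    weak: float = 0.5) -> PositionWeightMatrix:
    """Synthetic count matrix from an IUPAC consensus (stand-in matrices)."""
    iupac = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
             "W": "AT", "S": "CG", "K": "GT", "M": "AC", "N": "ACGT",
             "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG"}
    counts = np.full((4, len(pattern)), weak)
    for j, ch in enumerate(pattern):
        allowed = iupac[ch]
        for b in allowed:
            counts[_BASE_INDEX[b], j] = strong / len(allowed) if len(allowed) < 4 else weak
    return PositionWeightMatrix(name=name, counts=counts)


def foxa_pwm() -> PositionWeightMatrix:
    """Synthetic FoxA-like forkhead matrix (consensus TGTTTRYTT)."""
    return _pwm_from_iupac("FoxA_syn", "TGTTTRYTTAG")


def rfx_pwm() -> PositionWeightMatrix:
    """Synthetic Rfx-like X-box matrix (half-site GTTRCC + spacer + GGYAAC)."""
    return _pwm_from_iupac("Rfx_syn", "GTTGCCATGGCAAC")


def hnf4_pwm() -> PositionWeightMatrix:
    """Synthetic HNF4-like direct-repeat matrix."""
    return _pwm_from_iupac("Hnf4_syn", "AGGTCAAAGGTCA")


def decoy_library(n: int, width: int = 10, seed: int = 0) -> list[PositionWeightMatrix]:
    """Random informative matrices used as enrichment decoys."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        cols = rng.dirichlet(np.full(4, 0.3), size=width).T * 100
        out.append(PositionWeightMatrix(name=f"decoy_{i + 1:02d}", counts=cols))
    return out
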