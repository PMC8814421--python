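"""Position weight matrices, log-odds scoring, and exact match p-values.

A PWM stores per-position base counts (as read from JASPAR count-matrix
text).  Scoring converts counts to a log2-odds matrix against an i.i.d.
background; the match p-value of a window score is computed exactly by
dynamic-programming convolution of the per-column score distributions
after discretizing scores to a fixed grid (the same construction FIMO
uses).  For short motifs the p-value can be cross-checked by exhaustive
enumeration of all 4^w windows.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as _bio_motifs

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

__all__ = [
    "Background",
    "PWM",
    "LogOddsMatrix",
    "ScoreDistribution",
    "read_jaspar",
    "pwm_log_odds",
    "information_content",
    "score_window",
    "build_score_distribution",
    "score_pvalue",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


@dataclass(frozen=True)
class Background:
    """Zero-order i.i.d. base composition used for log-odds and p-values."""

    prob_A: float = 0.25
    prob_C: float = 0.25
    prob_G: float = 0.25
    prob_T: float = 0.25

    def __post_init__(self) -> None:
        probs = self.as_array()
        if not np.all((probs > 0) & (probs < 1)):
            raise ValueError("background probabilities must lie in (0, 1)")
        if abs(float(probs.sum()) - 1.0) > 1e-9:
            raise ValueError(f"background probabilities sum to {probs.sum()}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.prob_A, self.prob_C, self.prob_G, self.prob_T], float)

    @classmethod
    def uniform(cls) -> "Background":
        return cls(0.25, 0.25, 0.25, 0.25)

    @classmethod
    def from_sequence(cls, seq: str, pseudocount: float = 1.0) -> "Background":
        """Estimate a 0-order background from observed base frequencies.

        A pseudocount keeps all four probabilities strictly positive even
        when a base is absent from the sequence.
        """
        counts = np.full(4, float(pseudocount))
        for ch in seq.upper():
            i = BASE_INDEX.get(ch)
            if i is not None:
                counts[i] += 1
        probs = counts / counts.sum()
        return cls(*probs)


class JasparParseError(ValueError):
    """Raised for a malformed JASPAR count-matrix block."""


@dataclass
class PWM:
    """A TF binding preference as per-position base counts.

    ``counts`` has shape (4, width), rows in A, C, G, T order.
    """

    motif_id: str
    factor_name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"{self.motif_id}: counts must be 4 x width")
        if self.width < 1:
            raise ValueError(f"{self.motif_id}: width must be >= 1")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.motif_id}: counts must be non-negative")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError(f"{self.motif_id}: every column needs positive total count")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def probabilities(self) -> np.ndarray:
        """Column-normalized base probabilities (no pseudocount)."""
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def consensus(self) -> str:
        """Highest-count base per column (ties to the earlier base in ACGT)."""
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


def _parse_jaspar_block(header: str, body: list[str]) -> PWM:
    motif_id = header[1:].split()[0] if len(header) > 1 else "<unnamed>"
    rows: dict[str, list[float]] = {}
    for line in body:
        stripped = line.strip()
        if not stripped:
            continue
        base = stripped[0].upper()
        if base not in BASE_INDEX:
            raise JasparParseError(f"{motif_id}: unexpected row {stripped[:20]!r}")
        if base in rows:
            raise JasparParseError(f"{motif_id}: duplicate {base} row")
        payload = stripped[1:].replace("[", " ").replace("]", " ")
        try:
            rows[base] = [float(x) for x in payload.split()]
        except ValueError as exc:
            raise JasparParseError(f"{motif_id}: non-numeric count in {base} row") from exc
    missing = [b for b in BASES if b not in rows]
    if missing:
        raise JasparParseError(f"{motif_id}: missing base row(s) {','.join(missing)}")
    widths = {len(v) for v in rows.values()}
    if len(widths) != 1:
        raise JasparParseError(f"{motif_id}: ragged columns (row lengths {sorted(widths)})")
    if widths == {0}:
        raise JasparParseError(f"{motif_id}: empty matrix")
    # Round-trip the validated block through Biopython's JASPAR reader so the
    # accepted dialect (bracketed or bare rows, optional name) stays standard.
    block = header + "\n" + "\n".join(body) + "\n"
    parsed = list(_bio_motifs.parse(io.StringIO(block), "jaspar"))
    if len(parsed) != 1:
        raise JasparParseError(f"{motif_id}: block did not parse as a single motif")
    m = parsed[0]
    counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
    return PWM(motif_id=m.matrix_id or motif_id, factor_name=m.name or "", counts=counts)


def read_jaspar(source) -> list[PWM]:
    """Read JASPAR count-matrix text (one or more ``>id name`` blocks).

    ``source`` is a path or an open text handle.  Base rows are normalized
    to A, C, G, T order; counts are preserved exactly.  A malformed block
    (missing base row, ragged columns) raises :class:`JasparParseError`
    naming the offending motif id.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    pwms: list[PWM] = []
    header: str | None = None
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if header is not None:
                pwms.append(_parse_jaspar_block(header, body))
            header, body = line.rstrip(), []
        elif line.strip():
            if header is None:
                raise JasparParseError(f"count rows before any '>' header: {line[:30]!r}")
            body.append(line)
    if header is not None:
        pwms.append(_parse_jaspar_block(header, body))
    if not pwms:
        raise JasparParseError("no JASPAR blocks found")
    return pwms


@dataclass
class LogOddsMatrix:
    """Per-column log2-odds scores (bits) derived from a PWM and background."""

    motif_id: str
    factor_name: str
    scores: np.ndarray  # (4, width), bits
    background: Background
    pseudocount: float

    _dist_cache: dict = field(default_factory=dict, repr=False, compare=False)
    _rc: "LogOddsMatrix | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[0] != 4:
            raise ValueError("scores must be 4 x width")

    @property
    def width(self) -> int:
        return self.scores.shape[1]

    @property
    def min_score(self) -> float:
        return float(self.scores.min(axis=0).sum())

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=0).sum())

    def reverse_complement(self) -> "LogOddsMatrix":
        """The matrix that scores the reverse strand in forward orientation.

        Memoized so repeated scans reuse the compiled score distribution.
        """
        if self._rc is None:
            self._rc = LogOddsMatrix(
                motif_id=self.motif_id,
                factor_name=self.factor_name,
                scores=self.scores[::-1, ::-1].copy(),
                background=self.background,
                pseudocount=self.pseudocount,
            )
        return self._rc


def pwm_log_odds(pwm: PWM, bg: Background | None = None, pseudocount: float = 0.1) -> LogOddsMatrix:
    """Convert counts to log2-odds scores against ``bg``.

    The pseudocount is distributed across bases in proportion to the
    background (FIMO's convention)::

        score(b, j) = log2( (count(b,j) + pseudocount * bg(b))
                            / (total(j) + pseudocount) / bg(b) )

    A zero count with zero pseudocount would give an infinite log-odds and
    raises instead.
    """
    bg = bg or Background.uniform()
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and np.any(pwm.counts == 0):
        raise ValueError(
            f"{pwm.motif_id}: zero count with zero pseudocount gives infinite log-odds"
        )
    probs = bg.as_array()[:, None]
    totals = pwm.counts.sum(axis=0, keepdims=True)
    freq = (pwm.counts + pseudocount * probs) / (totals + pseudocount)
    scores = np.log2(freq / probs)
    return LogOddsMatrix(
        motif_id=pwm.motif_id,
        factor_name=pwm.factor_name,
        scores=scores,
        background=bg,
        pseudocount=pseudocount,
    )


def information_content(pwm: PWM) -> np.ndarray:
    """Per-column information content in bits: ``2 + sum_b p log2 p``.

    Uses the uniform-background convention; 0 log 0 is taken as 0.
    """
    p = pwm.probabilities()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return 2.0 + plogp.sum(axis=0)


_ENCODE_TABLE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to 0..3 codes; non-ACGT characters become -1."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii", "replace"), dtype=np.uint8)]


def score_window(lom: LogOddsMatrix, window: str) -> float:
    """Sum of per-position log2-odds for one window; bits."""
    if len(window) != lom.width:
        raise ValueError(f"window length {len(window)} != motif width {lom.width}")
    codes = encode(window)
    if np.any(codes < 0):
        raise ValueError(f"window contains non-ACGT character: {window!r}")
    return float(lom.scores[codes, np.arange(lom.width)].sum())


@dataclass
class ScoreDistribution:
    """Exact null distribution of the window score on a discretized grid.

    ``tail[k]`` is P(score >= (offset + k) * grid) for a single random
    background window; ``col_bins`` are the per-column integer scores that
    generated it, so a concrete window can be looked up without any further
    rounding.
    """

    motif_id: str
    grid_resolution: float
    col_bins: np.ndarray  # (4, width), int
    offset: int  # integer bin of the minimum score
    tail: np.ndarray  # tail[k] = P(binned score >= offset + k)
    support: np.ndarray  # achievable integer score bins, ascending
    min_score: float
    max_score: float

    _thr_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def width(self) -> int:
        return self.col_bins.shape[1]

    def window_bin(self, codes: np.ndarray) -> int:
        return int(self.col_bins[codes, np.arange(self.width)].sum())

    def tail_at_bin(self, k: int) -> float:
        idx = k - self.offset
        if idx <= 0:
            return 1.0
        if idx >= len(self.tail):
            return 0.0
        return float(self.tail[idx])

    def threshold_bin(self, p_threshold: float) -> int:
        """Smallest integer score bin whose tail probability is <= threshold.

        Because the tail is non-increasing, ``bin >= threshold_bin`` is
        exactly equivalent to ``p-value <= p_threshold``.
        """
        cached = self._thr_cache.get(p_threshold)
        if cached is not None:
            return cached
        hits = np.nonzero(self.tail <= p_threshold)[0]
        if len(hits) == 0:
            result = self.offset + len(self.tail)  # unattainable
        else:
            result = self.offset + int(hits[0])
        self._thr_cache[p_threshold] = result
        return result


def build_score_distribution(
    lom: LogOddsMatrix, bg: Background | None = None, grid_resolution: float = 1e-3
) -> ScoreDistribution:
    """Positionwise convolution of discretized column score distributions.

    Column scores are rounded to multiples of ``grid_resolution`` bits and
    the probability mass function of their sum is built column by column;
    cost is linear in width times the integer score range.
    """
    bg = bg or lom.background
    key = (bg.as_array().tobytes(), float(grid_resolution))
    cached = lom._dist_cache.get(key)
    if cached is not None:
        return cached
    probs = bg.as_array()
    col_bins = np.rint(lom.scores / grid_resolution).astype(np.int64)
    pmf = np.array([1.0])
    offset = 0
    for j in range(lom.width):
        ks = col_bins[:, j]
        lo, hi = int(ks.min()), int(ks.max())
        col_pmf = np.zeros(hi - lo + 1)
        for b in range(4):
            col_pmf[ks[b] - lo] += probs[b]
        pmf = np.convolve(pmf, col_pmf)
        offset += lo
    tail = pmf[::-1].cumsum()[::-1]
    # guard against cumsum drift
    tail = np.minimum(tail, 1.0)
    dist = ScoreDistribution(
        motif_id=lom.motif_id,
        grid_resolution=grid_resolution,
        col_bins=col_bins,
        offset=offset,
        tail=tail,
        support=offset + np.nonzero(pmf > 0)[0],
        min_score=lom.min_score,
        max_score=lom.max_score,
    )
    lom._dist_cache[key] = dist
    return dist


def score_pvalue(dist: ScoreDistribution, s: float) -> float:
    """P(window score >= s) for a random i.i.d.-background window.

    Scores below the minimum clamp to 1; above the maximum to 0.  The
    query is quantized to the distribution's grid and snapped to the
    nearest achievable window score within the accumulated rounding
    tolerance (half a grid bin per motif column), so a query at an exact
    window score returns that window's tail probability.
    """
    if s <= dist.min_score:
        return 1.0
    if s > dist.max_score + dist.grid_resolution:
        return 0.0
    k = int(math.floor(s / dist.grid_resolution + 0.5))
    tol = (dist.width + 1) // 2
    i = int(np.searchsorted(dist.support, k))
    nearby = [
        int(b)
        for b in dist.support[max(i - 1, 0) : i + 1]
        if abs(int(b) - k) <= tol
    ]
    if nearby:
        # ties snap to the lower bin (the larger, conservative p-value)
        k = min(nearby, key=lambda b: (abs(b - k), b))
    return dist.tail_at_bin(k)
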