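"""FIMO-style scanning of sequences for motif occurrences.

Hits are windows whose exact match p-value passes a threshold, reported on
both strands in forward-strand coordinates.  Internally positions are
0-based half-open; reported coordinates are 1-based inclusive (the FIMO
dialect).  Conversion happens only in :func:`_make_hit`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import (
    Background,
    LogOddsMatrix,
    build_score_distribution,
    encode,
)

__all__ = ["ScanConfig", "MotifHit", "scan_sequence", "overlap_positions", "hits_to_frame", "hits_to_bed"]


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters: p-value threshold, pseudocount, strands, grid.

    A window is a hit iff its match p-value is <= ``p_threshold``.
    """

    p_threshold: float = 1e-3
    pseudocount: float = 0.1
    both_strands: bool = True
    grid_resolution: float = 1e-3

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.grid_resolution <= 0:
            raise ValueError("grid_resolution must be > 0")


@dataclass(frozen=True)
class MotifHit:
    """A predicted TFBS: 1-based inclusive coordinates on the forward strand.

    ``matched_seq`` is always the forward-strand subsequence, even for
    reverse-strand hits.
    """

    motif_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    score: float
    p_value: float
    matched_seq: str

    @property
    def key(self) -> tuple[str, int, int, str]:
        """Identity used to match hits across rescans: motif, interval, strand."""
        return (self.motif_id, self.start, self.end, self.strand)

    @property
    def hit_id(self) -> str:
        return f"{self.motif_id}@{self.start}-{self.end}({self.strand})"

    def interval0(self) -> tuple[int, int]:
        """0-based half-open interval."""
        return (self.start - 1, self.end)


def _make_hit(
    motif_id: str, seq_id: str, start0: int, width: int, strand: str,
    score: float, p_value: float, matched_seq: str,
) -> MotifHit:
    return MotifHit(
        motif_id=motif_id,
        seq_id=seq_id,
        start=start0 + 1,
        end=start0 + width,
        strand=strand,
        score=round(score, 6),
        p_value=p_value,
        matched_seq=matched_seq.upper(),
    )


def _strand_pass(
    codes: np.ndarray, lom: LogOddsMatrix, dist, cfg: ScanConfig,
    seq: str, seq_id: str, strand: str,
) -> list[MotifHit]:
    w = lom.width
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return []
    valid = codes >= 0
    ok = np.ones(n_win, dtype=bool)
    bins = np.zeros(n_win, dtype=np.int64)
    safe = np.where(valid, codes, 0)
    for j in range(w):
        ok &= valid[j : j + n_win]
        bins += dist.col_bins[safe[j : j + n_win], j]
    # a window is a hit iff its integer score bin reaches the bin whose
    # tail probability first drops to the threshold (exact, vectorized)
    ok &= bins >= dist.threshold_bin(cfg.p_threshold)
    hits = []
    for start0 in np.nonzero(ok)[0]:
        p = dist.tail_at_bin(int(bins[start0]))
        window = seq[start0 : start0 + w]
        codes_w = codes[start0 : start0 + w]
        score = float(lom.scores[codes_w, np.arange(w)].sum())
        hits.append(
            _make_hit(lom.motif_id, seq_id, int(start0), w, strand, score, p, window)
        )
    return hits


def scan_sequence(
    seq: str,
    lom: LogOddsMatrix,
    bg: Background | None = None,
    cfg: ScanConfig | None = None,
    seq_id: str = "seq",
) -> list[MotifHit]:
    """Report every window with match p-value <= threshold.

    Both strands are scanned when configured; reverse-strand windows are
    scored with the reverse-complemented matrix so all coordinates stay on
    the forward strand.  Windows containing non-ACGT characters are
    skipped.  Hits are sorted by start, then strand ('+' before '-').
    """
    cfg = cfg or ScanConfig()
    bg = bg or lom.background
    codes = encode(seq)
    dist_fwd = build_score_distribution(lom, bg, cfg.grid_resolution)
    hits = _strand_pass(codes, lom, dist_fwd, cfg, seq, seq_id, "+")
    if cfg.both_strands:
        rc_lom = lom.reverse_complement()
        dist_rev = build_score_distribution(rc_lom, bg, cfg.grid_resolution)
        hits += _strand_pass(codes, rc_lom, dist_rev, cfg, seq, seq_id, "-")
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def overlap_positions(
    hits_a: list[MotifHit], hits_b: list[MotifHit]
) -> list[tuple[MotifHit, MotifHit, str]]:
    """Pairs of hits whose intervals share at least one position.

    Each pair is annotated ``"full"`` when one interval contains the other
    (identical intervals included), ``"partial"`` otherwise.  Hits are
    assumed to lie on the same sequence.
    """
    pairs = []
    for a in hits_a:
        for b in hits_b:
            if a.start <= b.end and b.start <= a.end:
                contained = (a.start <= b.start and b.end <= a.end) or (
                    b.start <= a.start and a.end <= b.end
                )
                pairs.append((a, b, "full" if contained else "partial"))
    return pairs


def hits_to_frame(hits: list[MotifHit]) -> pd.DataFrame:
    """FIMO-like tabular form (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "motif_id": h.motif_id,
                "seq_id": h.seq_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "score": h.score,
                "p_value": h.p_value,
                "matched_seq": h.matched_seq,
            }
            for h in hits
        ],
        columns=[
            "motif_id", "seq_id", "start", "end", "strand", "score", "p_value", "matched_seq",
        ],
    )


def hits_to_bed(hits: list[MotifHit], max_score: int = 1000) -> pd.DataFrame:
    """BED6 export: 0-based half-open, score = min(round(-100 log10 p), 1000)."""
    rows = []
    for h in hits:
        logp = -np.log10(max(h.p_value, 1e-300))
        rows.append(
            {
                "chrom": h.seq_id,
                "chromStart": h.start - 1,
                "chromEnd": h.end,
                "name": h.motif_id,
                "score": int(min(round(100 * logp), max_score)),
                "strand": h.strand,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "chromStart", "chromEnd", "name", "score", "strand"]
    )
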