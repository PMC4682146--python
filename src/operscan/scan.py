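"""Bipartite operator scanning, pentamer arrays, promoter assignment and
the random-placement null for operator clusters.

The operator searched for is two 5-bp consensus blocks (default TTAAG)
separated by an unconstrained spacer; only pentamer positions count as
mismatches. Hits are reported in plus-strand 0-based half-open
coordinates regardless of the strand on which the motif reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BASE_INDEX, GeneAnnotation, GenomeSequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BipartiteMotif:
    """Two consensus pentamers around a free spacer, with a mismatch budget."""

    upstream_consensus: str = "TTAAG"
    downstream_consensus: str = "TTAAG"
    allowed_spacer_lengths: frozenset = frozenset({6})
    max_total_mismatches: int = 0

    def __post_init__(self) -> None:
        for block in (self.upstream_consensus, self.downstream_consensus):
            if len(block) != 5 or set(block) - set("ACGT"):
                raise ValueError(f"consensus block must be an ACGT 5-mer: {block!r}")
        object.__setattr__(self, "allowed_spacer_lengths",
                           frozenset(int(s) for s in self.allowed_spacer_lengths))
        if any(s < 0 for s in self.allowed_spacer_lengths):
            raise ValueError("spacer lengths must be non-negative")
        if not 0 <= self.max_total_mismatches <= 10:
            raise ValueError("max_total_mismatches must be in [0, 10]")


@dataclass(frozen=True)
class OperatorHit:
    """One bipartite motif occurrence in plus-strand coordinates.

    Sequence fields are as read on the motif strand; on circular
    contigs ``end`` may exceed the contig length for origin-wrapping
    hits (``end - start`` is always 10 + spacer_length).
    """

    contig_id: str
    strand: str
    start: int
    end: int
    upstream_seq: str
    spacer_seq: str
    downstream_seq: str
    mismatch_up: int
    mismatch_down: int
    spacer_length: int

    @property
    def total_mismatches(self) -> int:
        return self.mismatch_up + self.mismatch_down

    def operator_sequence(self) -> str:
        return self.upstream_seq + self.spacer_seq + self.downstream_seq


@dataclass(frozen=True)
class PentamerArray:
    """A maximal run of >= 2 pentamer matches at fixed 5+spacer spacing.

    ``n_pentamers`` pentamers imply ``n_pentamers - 1`` overlapping
    operators sharing their interior pentamers.
    """

    contig_id: str
    strand: str
    pentamer_starts: tuple
    spacer_length: int

    @property
    def n_pentamers(self) -> int:
        return len(self.pentamer_starts)

    @property
    def n_implied_operators(self) -> int:
        return self.n_pentamers - 1


def _codes(seq: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _block_mismatches(codes: np.ndarray, block: str) -> np.ndarray:
    """mism[i] = mismatches of codes[i:i+5] vs block (N always mismatches)."""
    n = len(codes) - len(block) + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int8)
    mism = np.zeros(n, dtype=np.int8)
    for j, base in enumerate(block):
        mism += codes[j:j + n] != BASE_INDEX[base]
    return mism


def scan_bipartite(genome: GenomeSequence, motif: BipartiteMotif,
                   strands: str = "both") -> list[OperatorHit]:
    """Report every window matching the bipartite motif within budget.

    Each (position, strand, spacer length) combination is reported
    once; minus-strand hits carry plus-strand coordinates. On circular
    contigs windows wrapping the origin are included, with start
    normalized into [0, L).
    """
    if strands not in ("+", "-", "both"):
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")
    L = len(genome.sequence)
    max_spacer = max(motif.allowed_spacer_lengths, default=0)
    w_max = 10 + max_spacer
    seq = genome.sequence
    if genome.circular and L >= w_max:
        seq = seq + seq[: w_max - 1]
    hits: list[OperatorHit] = []
    want = [s for s in ("+", "-") if strands in (s, "both")]
    for strand in want:
        scan_seq = seq if strand == "+" else reverse_complement(seq)
        codes = _codes(scan_seq)
        m_up = _block_mismatches(codes, motif.upstream_consensus)
        m_down = _block_mismatches(codes, motif.downstream_consensus)
        for spacer in sorted(motif.allowed_spacer_lengths):
            w = 10 + spacer
            n = len(scan_seq) - w + 1
            if n <= 0:
                continue
            total = m_up[:n] + m_down[5 + spacer: 5 + spacer + n]
            for i in np.flatnonzero(total <= motif.max_total_mismatches):
                i = int(i)
                if strand == "+":
                    start = i
                else:
                    start = len(scan_seq) - i - w
                if start >= L:  # circular duplicate of an unwrapped window
                    continue
                window = scan_seq[i:i + w]
                hits.append(OperatorHit(
                    contig_id=genome.contig_id,
                    strand=strand,
                    start=start,
                    end=start + w,
                    upstream_seq=window[:5],
                    spacer_seq=window[5:5 + spacer],
                    downstream_seq=window[5 + spacer:],
                    mismatch_up=int(m_up[i]),
                    mismatch_down=int(m_down[i + 5 + spacer]),
                    spacer_length=spacer,
                ))
    hits.sort(key=lambda h: (h.start, h.spacer_length, h.strand))
    return hits


def count_hits_by_mismatch(hits: list[OperatorHit]) -> pd.DataFrame:
    """Tabulate hits by (spacer_length, total_mismatches); cells partition the list."""
    if not hits:
        return pd.DataFrame(columns=["spacer_length", "total_mismatches", "count"])
    rows = pd.DataFrame({
        "spacer_length": [h.spacer_length for h in hits],
        "total_mismatches": [h.total_mismatches for h in hits],
    })
    out = (rows.value_counts().rename("count").reset_index()
           .sort_values(["spacer_length", "total_mismatches"])
           .reset_index(drop=True))
    return out


def find_pentamer_arrays(genome: GenomeSequence, pentamer_consensus: str = "TTAAG",
                         spacer_length: int = 6, max_pentamer_mismatch: int = 0,
                         strands: str = "both") -> list[PentamerArray]:
    """Find maximal runs of >= 2 pentamer matches spaced exactly 5+spacer apart."""
    if spacer_length < 0:
        raise ValueError("spacer_length must be >= 0")
    step = 5 + spacer_length
    L = len(genome.sequence)
    arrays: list[PentamerArray] = []
    want = [s for s in ("+", "-") if strands in (s, "both")]
    for strand in want:
        scan_seq = (genome.sequence if strand == "+"
                    else reverse_complement(genome.sequence))
        codes = _codes(scan_seq)
        mism = _block_mismatches(codes, pentamer_consensus)
        match_pos = set(np.flatnonzero(mism <= max_pentamer_mismatch).tolist())
        for p in sorted(match_pos):
            if p - step in match_pos:
                continue  # not the leftmost pentamer of its run
            run = [p]
            while run[-1] + step in match_pos:
                run.append(run[-1] + step)
            if len(run) >= 2:
                if strand == "+":
                    starts = tuple(run)
                else:
                    starts = tuple(sorted(L - q - 5 for q in run))
                arrays.append(PentamerArray(genome.contig_id, strand, starts,
                                            spacer_length))
    arrays.sort(key=lambda a: (a.pentamer_starts[0], a.strand))
    return arrays


def promoter_window(gene: GeneAnnotation, window_bp: int = 600,
                    anchor: str = "cds") -> tuple[int, int] | None:
    """The [start, end) interval immediately upstream of the gene's anchor.

    Returns None when anchor='tss' and the gene has no TSS.
    """
    if anchor == "cds":
        pos = gene.cds_start if gene.strand == "+" else gene.cds_end
    elif anchor == "tss":
        if gene.tss is None:
            return None
        pos = gene.tss
    else:
        raise ValueError(f"anchor must be 'cds' or 'tss', got {anchor!r}")
    if gene.strand == "+":
        return max(pos - window_bp, 0), pos
    return pos, pos + window_bp


def assign_to_promoters(hits: list[OperatorHit],
                        annotations: list[GeneAnnotation],
                        window_bp: int = 600,
                        anchor: str = "cds") -> dict[str, list[OperatorHit]]:
    """Map gene_id -> hits fully contained in its upstream promoter window.

    A hit may be assigned to multiple genes. Genes lacking a TSS under
    anchor='tss' are skipped with a warning.
    """
    assignments: dict[str, list[OperatorHit]] = {}
    for gene in annotations:
        window = promoter_window(gene, window_bp, anchor)
        if window is None:
            logger.warning("gene %s has no TSS; skipped under anchor='tss'",
                           gene.gene_id)
            continue
        lo, hi = window
        assigned = [h for h in hits
                    if h.contig_id == gene.contig_id
                    and lo <= h.start and h.end <= hi]
        assignments[gene.gene_id] = assigned
    return assignments


@dataclass
class PlacementNull:
    """Monte-Carlo distribution of per-window operator counts under
    uniform random placement of operator start positions."""

    ks: np.ndarray  # operator counts 0..k_max
    mean_windows_per_k: np.ndarray  # mean number of windows with k operators
    se_windows_per_k: np.ndarray
    mean_count_per_window: float
    se_count_per_window: float
    n_iterations: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.ks,
                             "mean_windows": self.mean_windows_per_k,
                             "se_windows": self.se_windows_per_k})


def cluster_count_null(genome_length: int, n_operators: int,
                       promoter_windows: list[tuple[int, int]],
                       n_iterations: int = 2000, seed: int = 0) -> PlacementNull:
    """Random-placement null for operator-per-promoter counts.

    Each iteration drops ``n_operators`` start positions uniformly and
    independently on [0, genome_length) and counts how many fall in
    each promoter window; the histogram of per-window counts is
    averaged over iterations with its Monte-Carlo standard error.
    """
    if not promoter_windows:
        raise ValueError("promoter window list is empty")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    n_win = len(promoter_windows)
    counts = np.zeros((n_iterations, n_win), dtype=np.int64)
    if n_operators > 0:
        pos = rng.integers(0, genome_length, size=(n_iterations, n_operators))
        for j, (lo, hi) in enumerate(promoter_windows):
            counts[:, j] = ((pos >= lo) & (pos < hi)).sum(axis=1)
    k_max = int(counts.max())
    ks = np.arange(k_max + 1)
    # per-iteration histogram of window counts
    hist = np.zeros((n_iterations, k_max + 1))
    for k in ks:
        hist[:, k] = (counts == k).sum(axis=1)
    per_window = counts.mean(axis=1)
    return PlacementNull(
        ks=ks,
        mean_windows_per_k=hist.mean(axis=0),
        se_windows_per_k=hist.std(axis=0, ddof=1) / np.sqrt(n_iterations),
        mean_count_per_window=float(per_window.mean()),
        se_count_per_window=float(per_window.std(ddof=1) / np.sqrt(n_iterations)),
        n_iterations=n_iterations,
    )
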