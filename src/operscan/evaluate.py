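"""Comparison of predicted to measured expression, error stratification,
secondary-TF co-occurrence, and regulon-overlap statistics.

Error summaries are geometric means: prediction error is the ratio of
predicted to measured fold change, a multiplicative quantity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import ExpressionTable, GenomeSequence
from .matrices import PositionWeightMatrix
from .predict import PromoterPrediction
from .scan import OperatorHit, reverse_complement

logger = logging.getLogger(__name__)


@dataclass
class PredictionErrorRecord:
    unit_id: str
    predicted_fc: float
    measured_fc: float
    error_ratio: float
    distance_to_tss: int | None = None
    n_operators: int = 0

    def __post_init__(self) -> None:
        if self.error_ratio <= 0:
            raise ValueError(f"{self.unit_id}: error ratio must be positive")


@dataclass
class RegulonSet:
    name: str
    members: set

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class OverlapResult:
    overlap: int
    size_a: int
    size_b: int
    universe: int
    p_value: float


def classify_regulated(expression: ExpressionTable, threshold: float = 2.0,
                       symmetric: bool = False) -> set[str]:
    """Units whose measured fold change is >= threshold (boundary inclusive).

    ``symmetric`` also counts downregulation: |log fc| >= log threshold.
    """
    fc = expression.df["fold_change"].to_numpy(dtype=float)
    if symmetric:
        mask = np.abs(np.log(fc)) >= np.log(threshold)
    else:
        mask = fc >= threshold
    return set(expression.df.loc[mask, "unit_id"])


def prediction_error(predictions: dict[str, PromoterPrediction],
                     measurements: ExpressionTable,
                     tss_distances: dict[str, int] | None = None
                     ) -> list[PredictionErrorRecord]:
    """One record per unit with both a prediction and a measurement."""
    measured = measurements.fold_changes()
    records = []
    for uid, pred in sorted(predictions.items()):
        if uid not in measured:
            logger.info("unit %s has no measurement; skipped", uid)
            continue
        m = measured[uid]
        records.append(PredictionErrorRecord(
            unit_id=uid,
            predicted_fc=pred.predicted_fold_change,
            measured_fc=m,
            error_ratio=pred.predicted_fold_change / m,
            distance_to_tss=None if tss_distances is None
            else tss_distances.get(uid),
            n_operators=len(pred.operators),
        ))
    return records


def operator_tss_distance(hit: OperatorHit, tss: int, gene_strand: str) -> int:
    """Signed operator-midpoint-to-TSS distance; negative is upstream of the TSS."""
    mid = (hit.start + hit.end) / 2
    d = mid - tss
    return int(round(d if gene_strand == "+" else -d))


def _geometric_mean(ratios: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(ratios))))


def stratify_error(records: list[PredictionErrorRecord], by: str,
                   bin_edges: list[float] | None = None) -> pd.DataFrame:
    """Geometric-mean error ratio per stratum.

    ``by='n_operators'`` groups on the operator count;
    ``by='tss_distance_bins'`` bins the signed TSS distance with the
    supplied edges (records lacking a distance are dropped).
    """
    if any(r.error_ratio <= 0 for r in records):
        raise ValueError("error ratios must be positive")
    if by == "n_operators":
        keys = [r.n_operators for r in records]
        labels = sorted(set(keys))
        groups = {lab: [r.error_ratio for r, k in zip(records, keys) if k == lab]
                  for lab in labels}
    elif by == "tss_distance_bins":
        if bin_edges is None:
            raise ValueError("tss_distance_bins mode requires bin_edges")
        edges = np.asarray(bin_edges, dtype=float)
        groups = {}
        for lo, hi in zip(edges[:-1], edges[1:]):
            lab = f"[{lo:g},{hi:g})"
            groups[lab] = [r.error_ratio for r in records
                           if r.distance_to_tss is not None
                           and lo <= r.distance_to_tss < hi]
    else:
        raise ValueError(f"unknown stratification {by!r}")
    rows = []
    for lab, ratios in groups.items():
        if ratios:
            rows.append((lab, _geometric_mean(np.asarray(ratios)), len(ratios)))
        else:
            rows.append((lab, np.nan, 0))
    return pd.DataFrame(rows, columns=["stratum", "geometric_mean_error", "n"])


def regulon_overlap_test(set_a: set, set_b: set, universe_size: int,
                         name_a: str = "A", name_b: str = "B") -> OverlapResult:
    """Upper-tail hypergeometric test: P[X >= observed overlap].

    X counts shared members when |B| units are drawn from a universe of
    ``universe_size`` containing |A| marked units.
    """
    k = len(set_a & set_b)
    na, nb = len(set_a), len(set_b)
    if max(na, nb) > universe_size:
        raise ValueError("set sizes exceed the universe")
    if k > min(na, nb):
        raise ValueError("overlap exceeds the smaller set")
    p = float(hypergeom.sf(k - 1, universe_size, na, nb))
    return OverlapResult(overlap=k, size_a=na, size_b=nb,
                         universe=universe_size, p_value=min(p, 1.0))


def _pwm_site_scores(pwm: PositionWeightMatrix, genome: GenomeSequence):
    """Yield (score, contig, start, strand) for every full-length window."""
    from .scan import _codes

    L = pwm.length
    lo = pwm.log_odds
    for strand in ("+", "-"):
        seq = genome.sequence if strand == "+" else reverse_complement(genome.sequence)
        codes = _codes(seq)
        n = len(seq) - L + 1
        if n <= 0:
            continue
        scores = np.zeros(n)
        valid = np.ones(n, dtype=bool)
        for j in range(L):
            window_codes = codes[j:j + n]
            ok = window_codes < 4
            valid &= ok
            scores += np.where(ok, lo[j, np.minimum(window_codes, 3)], 0.0)
        for i in np.flatnonzero(valid):
            i = int(i)
            start = i if strand == "+" else len(seq) - i - L
            yield float(scores[i]), genome.contig_id, start, strand


def secondary_tf_scan(genomes: list[GenomeSequence],
                      promoter_windows: dict[str, tuple[str, int, int]],
                      tf_pwms: dict[str, PositionWeightMatrix],
                      top_n: int = 100) -> dict[str, set]:
    """Flag units whose promoter contains one of a TF's top-N genome sites.

    For each TF, every position on both strands of every contig is
    scored; only the ``top_n`` highest-scoring sites genome-wide are
    retained (ties broken by contig, position, strand), and a unit is
    flagged when a retained site lies fully inside its promoter window.
    """
    flags: dict[str, set] = {}
    for tf, pwm in tf_pwms.items():
        sites = []
        for genome in genomes:
            sites.extend(_pwm_site_scores(pwm, genome))
        sites.sort(key=lambda s: (-s[0], s[1], s[2], s[3]))
        retained = sites[:top_n]
        flagged = set()
        for score, contig, start, strand in retained:
            end = start + pwm.length
            for uid, (wc, lo_w, hi_w) in promoter_windows.items():
                if contig == wc and lo_w <= start and end <= hi_w:
                    flagged.add(uid)
        flags[tf] = flagged
    return flags


def mean_error_by_tf(records: list[PredictionErrorRecord],
                     tf_flags: dict[str, set]) -> pd.DataFrame:
    """Geometric-mean prediction error over each TF's flagged units."""
    by_unit = {r.unit_id: r.error_ratio for r in records}
    rows = []
    for tf, units in sorted(tf_flags.items()):
        ratios = [by_unit[u] for u in units if u in by_unit]
        if ratios:
            rows.append((tf, _geometric_mean(np.asarray(ratios)), len(ratios)))
        else:
            rows.append((tf, np.nan, 0))
    return pd.DataFrame(rows, columns=["tf", "geometric_mean_error", "n"])


def detect_operator_overlap(bqsr_hits: list[OperatorHit],
                            tf_sites: list[tuple[str, int, int]]
                            ) -> list[tuple[OperatorHit, tuple, int]]:
    """Pairs of (operator hit, TF site, overlap bp) intersecting by >= 1 bp.

    TF sites are (contig, start, end) in plus-strand half-open
    coordinates.
    """
    pairs = []
    for h in bqsr_hits:
        for site in tf_sites:
            contig, s, e = site
            if contig != h.contig_id:
                continue
            ov = min(h.end, e) - max(h.start, s)
            if ov >= 1:
                pairs.append((h, site, ov))
    return pairs
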