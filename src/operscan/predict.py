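"""Per-promoter and per-transcriptional-unit fold-change prediction.

Each candidate operator's energy is converted to a fold change
fc = fc_ref * exp(-dE); a promoter's prediction aggregates its
operators under one of four modes: additive (sum of per-operator fold
changes, the default multi-operator assumption), strongest (max),
most_downstream (the operator closest to the promoter anchor), or a
two-site thermodynamic occupancy model. Candidates are pre-filtered to
<= 3 pentamer mismatches within the 600-bp upstream window, and only
spacer-6 operators carry energy parameters (other spacer lengths
contribute no regulation, fc = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneAnnotation, TranscriptionalUnitTable
from .matrices import EnergyMatrix, energy_to_fold_change
from .scan import OperatorHit, promoter_window

MODES = ("additive", "strongest", "most_downstream", "thermodynamic")


@dataclass
class PromoterPrediction:
    unit_id: str
    operators: list  # (OperatorHit, dE or None, per-operator fold change)
    mode: str
    predicted_fold_change: float
    raw_fold_change: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.raw_fold_change is None:
            self.raw_fold_change = self.predicted_fold_change


def predict_operator_fold_change(dE: float, reference_fold_change: float) -> float:
    """fc = fc_ref * exp(-dE): strictly decreasing in the binding energy."""
    return energy_to_fold_change(dE, reference_fold_change)


def filter_candidates(hits: list[OperatorHit], gene: GeneAnnotation | None = None,
                      max_mismatches: int = 3, window_bp: int = 600,
                      anchor: str = "cds") -> list[OperatorHit]:
    """Keep hits within the pentamer-mismatch cap and the upstream window."""
    out = [h for h in hits if h.total_mismatches <= max_mismatches]
    if gene is not None:
        window = promoter_window(gene, window_bp, anchor)
        if window is None:
            return []
        lo, hi = window
        out = [h for h in out
               if h.contig_id == gene.contig_id and lo <= h.start and h.end <= hi]
    return out


def _anchor_distance(hit: OperatorHit, gene: GeneAnnotation, anchor: str) -> int:
    """Distance from the operator's gene-proximal end to the promoter anchor."""
    pos = promoter_window(gene, 0, anchor)[0]  # zero-width window sits at anchor
    if gene.strand == "+":
        return pos - hit.end
    return hit.start - pos


def hit_16mer(hit: OperatorHit, gene_strand: str | None = None) -> str:
    """The operator 16-mer on the motif strand (spacer length must be 6)."""
    return hit.operator_sequence()


def two_operator_thermodynamic(dE1: float, dE2: float, tf_weight: float,
                               fc_max: float) -> float:
    """Two-site independent-binding occupancy model.

    Statistical weights w_i = lambda * exp(-dE_i); the promoter is
    active when at least one site is occupied, with occupancy
    p = (w1 + w2 + w1 w2) / (1 + w1 + w2 + w1 w2) and fold change
    fc = 1 + (fc_max - 1) p, interpolating between 1 (no regulator)
    and fc_max (saturation).
    """
    if tf_weight < 0:
        raise ValueError("tf_weight must be non-negative")
    if fc_max <= 1:
        raise ValueError("fc_max must exceed 1")
    w1 = tf_weight * np.exp(-dE1)
    w2 = tf_weight * np.exp(-dE2)
    z = w1 + w2 + w1 * w2
    p = z / (1.0 + z)
    return float(1.0 + (fc_max - 1.0) * p)


def calibrate_thermodynamic(matrix: EnergyMatrix,
                            fc_max_factor: float = 2.0) -> tuple[float, float]:
    """Choose (tf_weight, fc_max) so a lone reference operator matches the
    additive model. With fc_max = fc_max_factor * fc_ref, solve
    1 + (fc_max - 1) * w/(1+w) = fc_ref for the single-site weight w."""
    fc_ref = matrix.reference_fold_change
    fc_max = fc_max_factor * fc_ref
    if fc_ref <= 1:
        return 1.0, max(fc_max, 2.0)
    w = (fc_ref - 1.0) / (fc_max - fc_ref)
    return float(w), float(fc_max)


def predict_promoter(unit_id: str, hits: list[OperatorHit], matrix: EnergyMatrix,
                     mode: str = "additive", orientation_policy: str = "both",
                     gene: GeneAnnotation | None = None, anchor: str = "cds",
                     tf_weight: float | None = None,
                     fc_max: float | None = None) -> PromoterPrediction:
    """Aggregate a promoter's (pre-filtered) operators into one prediction.

    An empty operator list predicts fold change 1 (no regulation).
    Spacer lengths other than 6 carry no energy parameters and
    contribute fc = 1. ``orientation_policy='sense_only'`` drops hits
    on the strand opposite the gene.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if orientation_policy not in ("both", "sense_only"):
        raise ValueError(f"unknown orientation_policy {orientation_policy!r}")
    use = list(hits)
    if orientation_policy == "sense_only":
        if gene is None:
            raise ValueError("sense_only policy requires the gene annotation")
        use = [h for h in use if h.strand == gene.strand]
    scored = []
    for h in use:
        if h.spacer_length == 6:
            dE = matrix.sequence_energy(hit_16mer(h))
            fc = predict_operator_fold_change(dE, matrix.reference_fold_change)
        else:
            dE, fc = None, 1.0
        scored.append((h, dE, fc))
    if not scored:
        return PromoterPrediction(unit_id, [], mode, 1.0)
    fcs = [fc for _, _, fc in scored]
    if mode == "additive":
        total = float(sum(fcs))
    elif mode == "strongest":
        total = float(max(fcs))
    elif mode == "most_downstream":
        if gene is None:
            raise ValueError("most_downstream mode requires the gene annotation")
        idx = min(range(len(scored)),
                  key=lambda i: _anchor_distance(scored[i][0], gene, anchor))
        total = float(scored[idx][2])
    else:  # thermodynamic
        if len(scored) != 2:
            raise ValueError(
                "thermodynamic mode is defined for exactly 2 operators; "
                "use additive mode otherwise"
            )
        if tf_weight is None or fc_max is None:
            tf_weight, fc_max = calibrate_thermodynamic(matrix)
        d1 = scored[0][1] if scored[0][1] is not None else np.inf
        d2 = scored[1][1] if scored[1][1] is not None else np.inf
        total = two_operator_thermodynamic(d1, d2, tf_weight, fc_max)
    return PromoterPrediction(unit_id, scored, mode, total)


def predict_all_promoters(assignments: dict[str, list[OperatorHit]],
                          annotations: list[GeneAnnotation],
                          matrix: EnergyMatrix, mode: str = "additive",
                          orientation_policy: str = "both",
                          max_mismatches: int = 3,
                          anchor: str = "cds") -> dict[str, PromoterPrediction]:
    """Filter and predict every gene's promoter; genes map to their prediction."""
    genes = {g.gene_id: g for g in annotations}
    out = {}
    for gene_id, hits in assignments.items():
        gene = genes.get(gene_id)
        kept = [h for h in hits if h.total_mismatches <= max_mismatches]
        out[gene_id] = predict_promoter(gene_id, kept, matrix, mode=mode,
                                        orientation_policy=orientation_policy,
                                        gene=gene, anchor=anchor)
    return out


def normalize_to_reference(predictions: dict[str, PromoterPrediction],
                           reference_unit: str,
                           anchor_value: float | None = None
                           ) -> dict[str, PromoterPrediction]:
    """Rescale all predictions so the reference unit's equals its anchor.

    The anchor defaults to the reference unit's own raw prediction
    (scale 1); passing the measured fold change of the reference gene
    reproduces normalization to its expression level.
    """
    if reference_unit not in predictions:
        raise KeyError(f"reference unit {reference_unit!r} has no prediction")
    ref_raw = predictions[reference_unit].raw_fold_change
    if ref_raw <= 0:
        raise ValueError("reference prediction must be positive")
    if anchor_value is None:
        anchor_value = ref_raw
    scale = anchor_value / ref_raw
    out = {}
    for uid, p in predictions.items():
        out[uid] = PromoterPrediction(uid, p.operators, p.mode,
                                      p.raw_fold_change * scale,
                                      raw_fold_change=p.raw_fold_change)
    return out


def aggregate_to_transcriptional_units(
    gene_predictions: dict[str, PromoterPrediction],
    tu_table: TranscriptionalUnitTable,
    policy: str = "first",
) -> dict[str, PromoterPrediction]:
    """Roll gene-level predictions up to transcriptional units.

    ``first`` (default) takes the lead (most upstream) gene's promoter
    prediction; ``max`` takes the largest member prediction. Genes not
    covered by the table become singleton TUs under their own id.
    """
    if policy not in ("first", "max"):
        raise ValueError(f"policy must be 'first' or 'max', got {policy!r}")
    out: dict[str, PromoterPrediction] = {}
    covered: set[str] = set()
    for tu_id, genes in tu_table.units.items():
        members = [gene_predictions[g] for g in genes if g in gene_predictions]
        covered.update(genes)
        if not members:
            continue
        if policy == "first":
            chosen = members[0]
        else:
            chosen = max(members, key=lambda p: p.predicted_fold_change)
        out[tu_id] = PromoterPrediction(tu_id, chosen.operators, chosen.mode,
                                        chosen.predicted_fold_change,
                                        raw_fold_change=chosen.raw_fold_change)
    for gene_id, p in gene_predictions.items():
        if gene_id not in covered:
            out[gene_id] = p
    return out


def predictions_to_frame(predictions: dict[str, PromoterPrediction]) -> pd.DataFrame:
    rows = []
    for uid, p in sorted(predictions.items()):
        energies = ",".join("NA" if dE is None else f"{dE:.6g}"
                            for _, dE, _ in p.operators)
        rows.append((uid, len(p.operators), energies, p.mode,
                     p.predicted_fold_change, p.raw_fold_change))
    return pd.DataFrame(rows, columns=["unit_id", "n_operators", "operator_dE",
                                       "mode", "predicted_fold_change",
                                       "raw_fold_change"])
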