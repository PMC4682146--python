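"""Synthetic genomes, reporter libraries, expression tables and regulons
with fully known ground truth.

The generator emulates the study system: a high-GC bacterial chromosome
(default GC 0.66, pseudomonad-like) carrying planted bipartite
TTAAG-N6-TTAAG operators at controlled mismatch counts in the promoter
windows of synthetic genes, a ground-truth 16-position energy matrix, a
synthetic-promoter reporter library with multiplicative lognormal
replicate noise, and regulon gene sets with a forced overlap. A single
root seed determines every substream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import RegulonSet
from .io import (BASES, ExpressionTable, GeneAnnotation, GenomeSequence,
                 TranscriptionalUnitTable)
from .matrices import (OPERATOR_LENGTH, SPACER_SLICE, EnergyMatrix,
                       LibraryMeasurement, _encode)
from .scan import BipartiteMotif, reverse_complement, scan_bipartite

PENTAMER = "TTAAG"


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def lognormal_sigma(cv: float) -> float:
    """ln-scale sigma giving a multiplicative noise with the requested CV."""
    return float(np.sqrt(np.log(1.0 + cv ** 2)))


@dataclass(frozen=True)
class PlantedOperator:
    position: int  # plus-strand start of the full operator
    strand: str
    sequence: str  # as read on the motif strand
    mismatch_up: int
    mismatch_down: int
    spacer_length: int
    gene_id: str


@dataclass
class PlantSpec:
    """What to plant: operators per mismatch class, plus pentamer arrays.

    Each planted operator (or array) is placed at a random offset inside
    the promoter window of its own synthetic gene;
    ``operators_per_promoter`` > 1 stacks that many operators of the
    same class into one promoter. Gene strands alternate so both
    orientations are exercised.
    """

    n_per_mismatch: dict = field(default_factory=lambda: {0: 5})
    array_sizes: tuple = ()
    spacer_length: int = 6
    operators_per_promoter: int = 1
    promoter_window: int = 600
    gene_length: int = 900
    margin: int = 60


@dataclass
class SyntheticTruth:
    seed: int
    genome: GenomeSequence
    planted_operators: list
    annotations: list
    tu_table: TranscriptionalUnitTable
    true_energy_matrix: EnergyMatrix | None = None
    noise_cv: float = 0.0
    planted_regulons: tuple | None = None
    spurious_hits: dict = field(default_factory=dict)


def random_sequence(rng: np.random.Generator, length: int,
                    gc_fraction: float = 0.66) -> str:
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def _mutate_pentamers(rng: np.random.Generator, operator: str,
                      n_mismatches: int) -> tuple[str, int, int]:
    """Introduce n mismatches into the 10 pentamer positions of a 16-mer."""
    pent_positions = list(range(0, 5)) + list(range(11, 16))
    chosen = rng.choice(len(pent_positions), size=n_mismatches, replace=False)
    seq = list(operator)
    up = down = 0
    for c in chosen:
        i = pent_positions[int(c)]
        alternatives = [b for b in BASES if b != seq[i]]
        seq[i] = alternatives[int(rng.integers(3))]
        if i < 5:
            up += 1
        else:
            down += 1
    return "".join(seq), up, down


def random_energy_matrix(seed: int, reference_sequence: str | None = None,
                         low: float = 0.1, high: float = 2.5) -> EnergyMatrix:
    """A ground-truth matrix: uniform positive penalties off the reference.

    The range emulates the measured library, where single pentamer
    mutations reduced expression by up to roughly tenfold (dE ~ 2.3).
    """
    rng = np.random.default_rng(seed)
    if reference_sequence is None:
        reference_sequence = PENTAMER + random_sequence(rng, 6, 0.5) + PENTAMER
    dE = rng.uniform(low, high, size=(OPERATOR_LENGTH, 4))
    ref_codes = _encode(reference_sequence)
    dE[np.arange(OPERATOR_LENGTH), ref_codes] = 0.0
    return EnergyMatrix(dE, reference_sequence)


def generate_genome(length: int, gc_fraction: float = 0.66,
                    plant_spec: PlantSpec | None = None,
                    seed: int = 0, contig_id: str = "synthetic_chr",
                    circular: bool = False) -> tuple[GenomeSequence, SyntheticTruth]:
    """Background genome at the given GC with planted operators.

    Planted sequences overwrite the background at recorded positions;
    spurious background motifs that happen to match at each planted
    mismatch level are counted and reported in the truth object, not
    removed.
    """
    if plant_spec is None:
        plant_spec = PlantSpec(n_per_mismatch={})
    rng_bg, rng_place, rng_mut = _substreams(seed, 3)
    seq = list(random_sequence(rng_bg, length, gc_fraction))

    spacer = plant_spec.spacer_length
    op_len = 10 + spacer
    window = plant_spec.promoter_window
    # one slot per promoter: window + gene + margin
    slot = window + plant_spec.gene_length + plant_spec.margin
    items: list[tuple[str, object]] = []  # ("ops", [mismatch counts]) | ("array", n)
    for mm, count in sorted(plant_spec.n_per_mismatch.items()):
        ops = [mm] * count
        for i in range(0, len(ops), plant_spec.operators_per_promoter):
            items.append(("ops", ops[i:i + plant_spec.operators_per_promoter]))
    for n_pent in plant_spec.array_sizes:
        if n_pent < 2:
            raise ValueError("array sizes must be >= 2 pentamers")
        items.append(("array", n_pent))
    if len(items) * slot > length:
        raise ValueError(
            f"plant spec needs {len(items) * slot} bp but genome is {length} bp"
        )

    planted: list[PlantedOperator] = []
    annotations: list[GeneAnnotation] = []
    for idx, (kind, payload) in enumerate(items):
        slot_start = idx * slot
        gene_id = f"gene{idx + 1:04d}"
        strand = "+" if idx % 2 == 0 else "-"
        if strand == "+":
            cds_start = slot_start + window
            cds_end = cds_start + plant_spec.gene_length
            win_lo, win_hi = cds_start - window, cds_start
            tss = cds_start - 40
        else:
            cds_start = slot_start + plant_spec.margin // 2
            cds_end = cds_start + plant_spec.gene_length
            win_lo, win_hi = cds_end, cds_end + window
            tss = cds_end + 39
        annotations.append(GeneAnnotation(gene_id, contig_id, strand,
                                          cds_start, cds_end, tss=tss))
        if kind == "ops":
            mismatches: list[int] = payload  # type: ignore[assignment]
            # non-overlapping offsets inside the window
            n_ops = len(mismatches)
            gap = (win_hi - win_lo) // n_ops
            for j, mm in enumerate(mismatches):
                lo = win_lo + j * gap
                offset = int(rng_place.integers(0, gap - op_len))
                start = lo + offset
                base_op = (PENTAMER + random_sequence(rng_place, spacer, 0.5)
                           + PENTAMER)
                op_seq, up, down = _mutate_pentamers(rng_mut, base_op, mm)
                written = op_seq if strand == "+" else reverse_complement(op_seq)
                seq[start:start + op_len] = list(written)
                planted.append(PlantedOperator(start, strand, op_seq, up, down,
                                               spacer, gene_id))
        else:
            n_pent: int = payload  # type: ignore[assignment]
            arr_len = n_pent * 5 + (n_pent - 1) * spacer
            offset = int(rng_place.integers(0, win_hi - win_lo - arr_len))
            start = win_lo + offset
            parts = [PENTAMER]
            for _ in range(n_pent - 1):
                parts.append(random_sequence(rng_place, spacer, 0.5))
                parts.append(PENTAMER)
            arr_seq = "".join(parts)
            written = arr_seq if strand == "+" else reverse_complement(arr_seq)
            seq[start:start + arr_len] = list(written)
            for j in range(n_pent - 1):
                op_start_local = j * (5 + spacer)
                op_seq = arr_seq[op_start_local:op_start_local + op_len]
                if strand == "+":
                    op_start = start + op_start_local
                else:
                    op_start = start + arr_len - op_start_local - op_len
                planted.append(PlantedOperator(op_start, strand, op_seq, 0, 0,
                                               spacer, gene_id))

    genome = GenomeSequence(contig_id, "".join(seq), circular=circular)
    tu_table = TranscriptionalUnitTable(
        {f"TU_{a.gene_id}": [a.gene_id] for a in annotations})
    truth = SyntheticTruth(seed=seed, genome=genome, planted_operators=planted,
                           annotations=annotations, tu_table=tu_table)
    # report (do not remove) spurious background matches at each planted level
    planted_keys = {(p.position, p.strand) for p in planted}
    for mm in sorted({p.mismatch_up + p.mismatch_down for p in planted}):
        motif = BipartiteMotif(allowed_spacer_lengths=frozenset({spacer}),
                               max_total_mismatches=mm)
        found = scan_bipartite(genome, motif)
        truth.spurious_hits[mm] = sum(
            1 for h in found if (h.start, h.strand) not in planted_keys)
    return genome, truth


def single_mutant_library(reference_sequence: str,
                          positions: range = range(0, 5)) -> list[str]:
    """All single-point mutants of the reference over the given positions
    (default: the upstream pentamer, 15 constructs)."""
    out = []
    for i in positions:
        for b in BASES:
            if b != reference_sequence[i]:
                out.append(reference_sequence[:i] + b + reference_sequence[i + 1:])
    return out


def spacer_single_variants(reference_sequence: str, n: int = 7) -> list[str]:
    """The first ``n`` single-point spacer variants in (position, base) order."""
    out = []
    for i in range(SPACER_SLICE.start, SPACER_SLICE.stop):
        for b in BASES:
            if b != reference_sequence[i]:
                out.append(reference_sequence[:i] + b + reference_sequence[i + 1:])
            if len(out) == n:
                return out
    return out


def all_spacer_sequences(reference_sequence: str) -> list[str]:
    """Every 16-mer varying the 6 spacer positions over ACGT (4^6 = 4096)."""
    head = reference_sequence[:SPACER_SLICE.start]
    tail = reference_sequence[SPACER_SLICE.stop:]
    return [head + "".join(combo) + tail
            for combo in itertools.product(BASES, repeat=6)]


def generate_library_measurements(matrix: EnergyMatrix, constructs: list[str],
                                  noise_cv: float = 0.1, n_replicates: int = 3,
                                  seed: int = 0) -> list[LibraryMeasurement]:
    """Simulated reporter measurements relative to the reference construct.

    Each replicate is exp(-dE(seq)) times a lognormal factor with the
    requested coefficient of variation; the reported relative
    expression is the replicate mean.
    """
    rng = np.random.default_rng(seed)
    sigma = lognormal_sigma(noise_cv)
    out = []
    for i, seq in enumerate(constructs):
        true_rel = float(np.exp(-matrix.sequence_energy(seq)))
        if noise_cv > 0:
            reps = true_rel * rng.lognormal(0.0, sigma, size=n_replicates)
            rel = float(reps.mean())
            se = (float(reps.std(ddof=1) / np.sqrt(n_replicates))
                  if n_replicates > 1 else 0.0)
        else:
            rel, se = true_rel, 0.0
        out.append(LibraryMeasurement(f"construct{i + 1:03d}", seq, rel, se=se))
    return out


def generate_expression_table(predictions: dict[str, float],
                              noise_cv: float = 0.0, seed: int = 0,
                              extra_units: list[str] | None = None
                              ) -> ExpressionTable:
    """Measured fold changes: predicted times lognormal noise.

    Units listed in ``extra_units`` but absent from the predictions get
    a fold change drawn around 1 (unregulated baseline).
    """
    rng = np.random.default_rng(seed)
    sigma = lognormal_sigma(noise_cv)
    rows = []
    for uid, fc in sorted(predictions.items()):
        noise = rng.lognormal(0.0, sigma) if noise_cv > 0 else 1.0
        rows.append((uid, fc * noise))
    for uid in extra_units or []:
        if uid not in predictions:
            noise = rng.lognormal(0.0, sigma) if noise_cv > 0 else 1.0
            rows.append((uid, noise))
    return ExpressionTable(pd.DataFrame(rows, columns=["unit_id", "fold_change"]))


def generate_regulons(universe_size: int, size_a: int, size_b: int,
                      forced_overlap: int | None, seed: int = 0,
                      name_a: str = "A", name_b: str = "B"
                      ) -> tuple[RegulonSet, RegulonSet]:
    """Two regulons over tu0001..tuN sharing exactly ``forced_overlap`` members.

    ``forced_overlap=None`` draws the two sets independently and
    uniformly (overlap hypergeometric-distributed): the null of the
    overlap test, used for type-I calibration.
    """
    if max(size_a, size_b) > universe_size:
        raise ValueError("regulon size exceeds the universe")
    rng = np.random.default_rng(seed)
    universe = [f"tu{i + 1:04d}" for i in range(universe_size)]
    if forced_overlap is None:
        a = rng.choice(universe_size, size=size_a, replace=False)
        b = rng.choice(universe_size, size=size_b, replace=False)
        return (RegulonSet(name_a, {universe[i] for i in a}),
                RegulonSet(name_b, {universe[i] for i in b}))
    if forced_overlap > min(size_a, size_b):
        raise ValueError("forced overlap exceeds a regulon size")
    if size_a + size_b - forced_overlap > universe_size:
        raise ValueError("regulons do not fit in the universe")
    perm = rng.permutation(universe_size)
    shared = [universe[i] for i in perm[:forced_overlap]]
    rest = perm[forced_overlap:]
    only_a = [universe[i] for i in rest[: size_a - forced_overlap]]
    only_b = [universe[i]
              for i in rest[size_a - forced_overlap: size_a + size_b
                            - 2 * forced_overlap]]
    return (RegulonSet(name_a, set(shared) | set(only_a)),
            RegulonSet(name_b, set(shared) | set(only_b)))
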