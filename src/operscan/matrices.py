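"""Sequence-to-affinity models for the bipartite operator.

Two model families live here. The position weight matrix (PWM) scores a
candidate operator by summed per-position log-odds of base frequency
versus background, and an exponential link strength = exp(a*S + b)
relates that score S to a predicted fold change in expression. The
binding energy matrix instead assigns each base at each of the 16
operator positions (5 upstream pentamer + 6 spacer + 5 downstream
pentamer) an additive energy penalty dE in kBT units relative to a
reference operator; a reporter measurement of relative expression fc
converts to energy via dE = -ln(fc / fc_ref), so destabilizing changes
(lower expression) carry positive dE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BASES, BASE_INDEX

UPSTREAM_SLICE = slice(0, 5)
SPACER_SLICE = slice(5, 11)
DOWNSTREAM_SLICE = slice(11, 16)
OPERATOR_LENGTH = 16


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([BASE_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGT base {exc.args[0]!r}") from None


@dataclass
class PositionWeightMatrix:
    """Per-position base probabilities with background, scored as log2 odds."""

    probabilities: np.ndarray  # (L, 4)
    background: np.ndarray  # (4,)
    pseudocount: float = 1.0
    source_count: int = 0

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] != 4:
            raise ValueError("probabilities must be (L, 4)")
        if not np.allclose(self.probabilities.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("probability columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.probabilities.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probabilities / self.background)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=1))

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())


def build_pwm(sequences: list[str], background: np.ndarray | None = None,
              pseudocount: float = 1.0) -> PositionWeightMatrix:
    """Build a PWM from aligned equal-length training sequences.

    Column probabilities are (count + pseudocount) / (n + 4*pseudocount);
    pseudocount 0 is allowed only if every base occurs at every position.
    """
    if not sequences:
        raise ValueError("need at least one training sequence")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("training sequences must all have the same length")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    counts = np.zeros((L, 4))
    for s in sequences:
        codes = _encode(s)
        counts[np.arange(L), codes] += 1
    n = len(sequences)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    if background is None:
        background = np.full(4, 0.25)
    return PositionWeightMatrix(probs, np.asarray(background, float),
                                pseudocount=pseudocount, source_count=n)


def score_sequence(pwm: PositionWeightMatrix, seq: str) -> float:
    """PWM score S: the sum of per-position log-odds entries for ``seq``."""
    if len(seq) != pwm.length:
        raise ValueError(f"sequence length {len(seq)} != motif length {pwm.length}")
    codes = _encode(seq)
    entries = pwm.log_odds[np.arange(pwm.length), codes]
    if np.isneginf(entries).any():
        raise ValueError(
            "sequence hits a zero-probability cell (pseudocount 0); "
            "rebuild the PWM with a positive pseudocount"
        )
    return float(entries.sum())


def information_content(pwm: PositionWeightMatrix) -> np.ndarray:
    """Per-position information content in bits (relative entropy to background)."""
    p = pwm.probabilities
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p / pwm.background), 0.0)
    return terms.sum(axis=1)


@dataclass
class StrengthLink:
    """Parameters (a, b) linking PWM score S to predicted operator strength."""

    a: float
    b: float
    form: str = "exponential"

    def __post_init__(self) -> None:
        if self.form not in ("exponential", "linear"):
            raise ValueError(f"unknown link form {self.form!r}")


def operator_strength(S: float, link: StrengthLink) -> float:
    """Predicted fold change for PWM score S under the fitted link."""
    if link.form == "exponential":
        return float(np.exp(link.a * S + link.b))
    return float(max(link.a * S + link.b, 0.0))


def fit_strength_params(scores, measured_fold_changes,
                        form: str = "exponential") -> tuple[StrengthLink, dict]:
    """Fit (a, b) by least squares of ln(fold change) on PWM score.

    Returns the fitted link and a residual summary (rss, n on the log
    scale for the exponential form).
    """
    S = np.asarray(scores, dtype=float)
    fc = np.asarray(measured_fold_changes, dtype=float)
    if len(S) < 2:
        raise ValueError("need at least two (score, fold change) points")
    if (fc <= 0).any():
        raise ValueError("fold changes must be positive")
    if np.ptp(S) == 0:
        raise ValueError("all scores identical: slope a is unidentifiable")
    y = np.log(fc) if form == "exponential" else fc
    A = np.vstack([S, np.ones_like(S)]).T
    (a, b), res, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(res[0]) if res.size else float(((A @ [a, b] - y) ** 2).sum())
    return StrengthLink(float(a), float(b), form=form), {"rss": rss, "n": len(S)}


def fold_change_to_energy(fc: float, fc_ref: float = 1.0) -> float:
    """dE = -ln(fc / fc_ref) in kBT; positive dE means weaker binding."""
    if fc <= 0 or fc_ref <= 0:
        raise ValueError("fold changes must be positive")
    return float(-np.log(fc / fc_ref))


def energy_to_fold_change(dE: float, fc_ref: float = 1.0) -> float:
    """Inverse of :func:`fold_change_to_energy`: fc = fc_ref * exp(-dE)."""
    if fc_ref <= 0:
        raise ValueError("reference fold change must be positive")
    return float(fc_ref * np.exp(-dE))


@dataclass
class LibraryMeasurement:
    """One synthetic-promoter construct and its expression relative to reference."""

    construct_id: str
    operator_sequence: str
    relative_expression: float
    se: float | None = None

    def __post_init__(self) -> None:
        if len(self.operator_sequence) != OPERATOR_LENGTH:
            raise ValueError(
                f"{self.construct_id}: operator must be {OPERATOR_LENGTH}-mer"
            )
        if self.relative_expression <= 0:
            raise ValueError(f"{self.construct_id}: relative expression must be > 0")


@dataclass
class EnergyMatrix:
    """Additive 16-position binding-energy matrix in kBT units.

    ``dE[i, b]`` is the energy change of placing base ``BASES[b]`` at
    position ``i`` relative to the reference operator, whose entries are
    0 by construction. ``missing`` flags cells never constrained by any
    measurement; they default to 0 when scoring.
    """

    dE: np.ndarray  # (16, 4)
    reference_sequence: str
    reference_fold_change: float = 1.0
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dE = np.asarray(self.dE, dtype=float)
        if self.dE.shape != (OPERATOR_LENGTH, 4):
            raise ValueError(f"dE must be ({OPERATOR_LENGTH}, 4)")
        if len(self.reference_sequence) != OPERATOR_LENGTH:
            raise ValueError(f"reference sequence must be {OPERATOR_LENGTH}-mer")
        if self.reference_fold_change <= 0:
            raise ValueError("reference fold change must be positive")
        if self.missing is None:
            self.missing = np.zeros_like(self.dE, dtype=bool)
        ref_codes = _encode(self.reference_sequence)
        if not np.all(self.dE[np.arange(OPERATOR_LENGTH), ref_codes] == 0):
            raise ValueError("reference-base entries must all be exactly 0")

    def sequence_energy(self, seq: str) -> float:
        """Total dE of a 16-mer: the sum of its per-position matrix entries."""
        if len(seq) != OPERATOR_LENGTH:
            raise ValueError(f"operator must be a {OPERATOR_LENGTH}-mer")
        codes = _encode(seq)
        return float(self.dE[np.arange(OPERATOR_LENGTH), codes].sum())

    def predicted_fold_change(self, seq: str) -> float:
        return energy_to_fold_change(self.sequence_energy(seq),
                                     self.reference_fold_change)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.dE.T, index=list(BASES),
                          columns=[f"pos{i + 1}" for i in range(OPERATOR_LENGTH)])
        with open(path, "w") as fh:
            fh.write(f"# reference_sequence={self.reference_sequence}\n")
            fh.write(f"# reference_fold_change={self.reference_fold_change!r}\n")
            df.to_csv(fh, sep="\t", index_label="base")

    @classmethod
    def from_tsv(cls, path) -> "EnergyMatrix":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for ln in lines:
            if ln.startswith("#"):
                k, _, v = ln[1:].strip().partition("=")
                meta[k.strip()] = v.strip()
            else:
                body.append(ln)
        from io import StringIO

        df = pd.read_csv(StringIO("".join(body)), sep="\t", index_col="base")
        dE = df.loc[list(BASES)].to_numpy().T
        return cls(dE, meta["reference_sequence"],
                   float(meta.get("reference_fold_change", 1.0)))


def build_pentamer_energies(
    measurements: list[LibraryMeasurement],
    reference_sequence: str,
    mirror_downstream: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill pentamer energy cells from single-point-mutant reporter data.

    Each construct must differ from the reference at exactly one
    position; its cell gets dE = -ln(relative expression). With
    ``mirror_downstream`` the downstream pentamer inherits the upstream
    measurements position-by-position (the two pentamers are assumed to
    contact the regulator equivalently; direct downstream measurements
    override the mirror when present).

    Returns (dE, missing) arrays of shape (16, 4) covering only the
    pentamer positions; spacer columns are left missing.
    """
    ref_codes = _encode(reference_sequence)
    dE = np.zeros((OPERATOR_LENGTH, 4))
    missing = np.ones((OPERATOR_LENGTH, 4), dtype=bool)
    missing[np.arange(OPERATOR_LENGTH), ref_codes] = False
    filled: dict[tuple[int, int], float] = {}
    conflicts = []
    for m in measurements:
        codes = _encode(m.operator_sequence)
        diff = np.flatnonzero(codes != ref_codes)
        if len(diff) != 1:
            raise ValueError(
                f"{m.construct_id}: expected exactly one mutated position, "
                f"found {len(diff)}"
            )
        i = int(diff[0])
        b = int(codes[i])
        val = fold_change_to_energy(m.relative_expression)
        if (i, b) in filled and not np.isclose(filled[(i, b)], val):
            conflicts.append((i, b, filled[(i, b)], val))
        filled[(i, b)] = val
    if conflicts:
        raise ValueError(f"conflicting duplicate measurements: {conflicts}")
    for (i, b), val in filled.items():
        dE[i, b] = val
        missing[i, b] = False
    if mirror_downstream:
        up, down = range(5), range(11, 16)
        for iu, id_ in zip(up, down):
            for b in range(4):
                if missing[id_, b] and not missing[iu, b]:
                    dE[id_, b] = dE[iu, b]
                    missing[id_, b] = False
    return dE, missing


def fit_spacer_energies(
    measurements: list[LibraryMeasurement],
    reference_sequence: str,
    ridge_lambda: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit spacer-position energies from spacer-variant reporter data.

    Solves X e = y with y = -ln(relative expression) and X the
    base-at-position indicator design over the 6 spacer positions x 3
    non-reference bases (reference bases are the zero gauge). The
    default is the exact minimum-norm least-squares solution
    (pseudoinverse); ``ridge_lambda > 0`` switches to ridge
    regularization. Cells whose base never appears in any variant are
    reported missing (value 0, flagged).
    """
    if not measurements:
        raise ValueError("need at least one spacer variant")
    ref_codes = _encode(reference_sequence)
    spacer_pos = list(range(SPACER_SLICE.start, SPACER_SLICE.stop))
    free_cells = [(i, b) for i in spacer_pos for b in range(4) if b != ref_codes[i]]
    col_of = {cell: j for j, cell in enumerate(free_cells)}
    X = np.zeros((len(measurements), len(free_cells)))
    y = np.zeros(len(measurements))
    for r, m in enumerate(measurements):
        codes = _encode(m.operator_sequence)
        pent_diff = [i for i in range(OPERATOR_LENGTH)
                     if i not in spacer_pos and codes[i] != ref_codes[i]]
        if pent_diff:
            raise ValueError(
                f"{m.construct_id}: varies outside the spacer at {pent_diff}"
            )
        for i in spacer_pos:
            if codes[i] != ref_codes[i]:
                X[r, col_of[(i, int(codes[i]))]] = 1.0
        y[r] = fold_change_to_energy(m.relative_expression)
    if not X.any():
        raise ValueError("design matrix is all-zero: no spacer variation observed")
    if ridge_lambda > 0:
        e = np.linalg.solve(X.T @ X + ridge_lambda * np.eye(X.shape[1]), X.T @ y)
    else:
        e = np.linalg.pinv(X) @ y
    dE = np.zeros((OPERATOR_LENGTH, 4))
    missing = np.ones((OPERATOR_LENGTH, 4), dtype=bool)
    observed_cols = X.any(axis=0)
    for j, (i, b) in enumerate(free_cells):
        if observed_cols[j]:
            dE[i, b] = e[j]
            missing[i, b] = False
        else:
            dE[i, b] = 0.0  # unidentifiable, flagged missing
    for i in spacer_pos:
        missing[i, ref_codes[i]] = False  # gauge cells
    return dE, missing


def assemble_energy_matrix(
    pentamer_entries: tuple[np.ndarray, np.ndarray],
    spacer_entries: tuple[np.ndarray, np.ndarray],
    reference_sequence: str,
    reference_fold_change: float = 1.0,
) -> EnergyMatrix:
    """Combine pentamer and spacer fits into the full 16-position matrix."""
    if len(reference_sequence) != OPERATOR_LENGTH:
        raise ValueError(f"reference sequence must be {OPERATOR_LENGTH}-mer")
    pent_dE, pent_missing = pentamer_entries
    sp_dE, sp_missing = spacer_entries
    dE = np.where(~pent_missing, pent_dE, 0.0) + np.where(~sp_missing, sp_dE, 0.0)
    missing = pent_missing & sp_missing
    ref_codes = _encode(reference_sequence)
    dE[np.arange(OPERATOR_LENGTH), ref_codes] = 0.0
    missing[np.arange(OPERATOR_LENGTH), ref_codes] = False
    return EnergyMatrix(dE, reference_sequence, reference_fold_change,
                        missing=missing)


def pwm_to_energy_matrix(pwm: PositionWeightMatrix, link: StrengthLink,
                         reference_sequence: str | None = None,
                         reference_fold_change: float = 1.0) -> EnergyMatrix:
    """Convert a 16-position PWM into an energy matrix via the strength link.

    dE(b, i) = -a * (score(b, i) - score(ref_b, i)), so that
    exp(-ddE) between any two sequences reproduces the ratio of their
    exponential-link strengths exp(a*S + b).
    """
    if pwm.length != OPERATOR_LENGTH:
        raise ValueError(f"PWM must have {OPERATOR_LENGTH} positions")
    if link.form != "exponential":
        raise ValueError("energy conversion requires the exponential link")
    if reference_sequence is None:
        reference_sequence = pwm.consensus
    ref_codes = _encode(reference_sequence)
    lo = pwm.log_odds
    ref_scores = lo[np.arange(OPERATOR_LENGTH), ref_codes][:, None]
    dE = -link.a * (lo - ref_scores)
    return EnergyMatrix(dE, reference_sequence, reference_fold_change)
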