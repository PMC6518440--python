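"""Poisson significance of triplex counts with length-calibrated expectation.

The number of qualifying windows N_tpx between random sequences grows with
both sequence lengths, so the Poisson mean is modelled as a linear function

    lambda(L_RNA, L_DNA) = theta0 + theta1 * L_RNA + theta2 * L_DNA

calibrated by simulation over a grid of length combinations with uniform
random sequences.  A default model ships with coefficients theta0 = -0.688,
theta1 = 5.37e-4, theta2 = 6.03e-4 from a large-scale calibration of
Triplexator-style "Total (abs)" counts (100 sequences per side over
L_RNA in {500,1000,1500,2000} x L_DNA in {200,...,2000}); refitting against
the bundled engine is an explicit user action via
:func:`simulate_lambda_grid` + :func:`fit_lambda_model`.

An observed count is scored by the exact Poisson upper tail
P(X >= N_tpx | X ~ Pois(lambda)), with Bonferroni adjustment across the
tested family.  The linear model can predict non-positive lambda for short
inputs; such values are clamped to a small positive floor (which makes any
observed window significant there, and is therefore logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .engine import EngineParams, count_triplexes
from .io import NucleicSequence

__all__ = [
    "CalibrationGridCell",
    "CalibrationModel",
    "simulate_lambda_grid",
    "fit_lambda_model",
    "expected_lambda",
    "triplex_pvalue",
    "bonferroni_adjust",
]

logger = logging.getLogger(__name__)

_RNA_BASES = np.frombuffer(b"ACGU", dtype="S1")
_DNA_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class CalibrationGridCell:
    """Mean window count over all RNA x DNA pairs of one length combination."""

    L_RNA: int
    L_DNA: int
    n_pairs: int
    mean_count: float

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.mean_count < 0:
            raise ValueError("mean_count must be >= 0")


@dataclass(frozen=True)
class CalibrationModel:
    """Linear length-calibration of the Poisson mean.

    ``provenance`` is ``"reference"`` for the shipped default coefficients
    and ``"refit"`` for models fitted from a simulated grid.
    """

    theta0: float
    theta1: float
    theta2: float
    lambda_floor: float = 1e-3
    adj_r2: float | None = None
    provenance: str = "refit"

    def __post_init__(self) -> None:
        if self.lambda_floor <= 0:
            raise ValueError("lambda_floor must be > 0")

    @classmethod
    def default(cls, lambda_floor: float = 1e-3) -> "CalibrationModel":
        """The shipped reference coefficients (genome-scale calibration)."""
        return cls(theta0=-0.688, theta1=5.37e-4, theta2=6.03e-4,
                   lambda_floor=lambda_floor, adj_r2=0.87,
                   provenance="reference")

    def predict(self, L_RNA: int, L_DNA: int) -> float:
        return expected_lambda(self, L_RNA, L_DNA)


def _random_seqs(rng: np.random.Generator, n: int, length: int,
                 bases: np.ndarray, kind: str) -> list[NucleicSequence]:
    out = []
    for i in range(n):
        residues = rng.choice(bases, size=length).tobytes().decode("ascii")
        out.append(NucleicSequence(id=f"sim_{kind}_{i}", residues=residues,
                                   kind=kind))  # type: ignore[arg-type]
    return out


def simulate_lambda_grid(params: EngineParams,
                         rna_lengths: Sequence[int],
                         dna_lengths: Sequence[int],
                         reps_per_side: int,
                         seed: int) -> list[CalibrationGridCell]:
    """Simulate the null window-count mean over a length grid.

    For each (L_RNA, L_DNA) cell, ``reps_per_side`` RNA and
    ``reps_per_side`` DNA sequences are drawn with equal base frequencies
    and all reps^2 pairs are counted; the cell mean is over all pairs.
    Fully reproducible from ``seed``.
    """
    if reps_per_side < 1:
        raise ValueError("reps_per_side must be >= 1")
    for L in list(rna_lengths) + list(dna_lengths):
        if L < params.min_length:
            raise ValueError(
                f"grid length {L} is below min_length={params.min_length}")
    cells = []
    for ci, L_RNA in enumerate(rna_lengths):
        for cj, L_DNA in enumerate(dna_lengths):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, ci, cj]))
            rnas = _random_seqs(rng, reps_per_side, L_RNA, _RNA_BASES, "RNA")
            dnas = _random_seqs(rng, reps_per_side, L_DNA, _DNA_BASES, "DNA")
            counts = [count_triplexes(r, d, params) for r in rnas for d in dnas]
            cells.append(CalibrationGridCell(
                L_RNA=L_RNA, L_DNA=L_DNA, n_pairs=len(counts),
                mean_count=float(np.mean(counts))))
    return cells


def fit_lambda_model(grid: Sequence[CalibrationGridCell],
                     lambda_floor: float = 1e-3) -> CalibrationModel:
    """Ordinary least squares of cell means on (L_RNA, L_DNA) with intercept."""
    if len(grid) < 3:
        raise ValueError("need >= 3 grid cells to fit the calibration")
    L1 = np.array([c.L_RNA for c in grid], dtype=float)
    L2 = np.array([c.L_DNA for c in grid], dtype=float)
    if len(set(L1)) < 2 or len(set(L2)) < 2:
        raise ValueError(
            "underdetermined fit: need >= 2 distinct values of each length")
    y = np.array([c.mean_count for c in grid], dtype=float)
    X = sm.add_constant(np.column_stack([L1, L2]))
    res = sm.OLS(y, X).fit()
    b0, b1, b2 = res.params
    return CalibrationModel(theta0=float(b0), theta1=float(b1),
                            theta2=float(b2), lambda_floor=lambda_floor,
                            adj_r2=float(res.rsquared_adj),
                            provenance="refit")


def expected_lambda(model: CalibrationModel, L_RNA: int, L_DNA: int) -> float:
    """Predicted Poisson mean, clamped below at ``model.lambda_floor``.

    Non-positive raw predictions (possible for short inputs) are clamped
    with a logged warning: at such lengths any observed window becomes
    significant, which is conservative in the opposite direction.
    """
    if L_RNA < 1 or L_DNA < 1:
        raise ValueError("lengths must be >= 1")
    raw = model.theta0 + model.theta1 * L_RNA + model.theta2 * L_DNA
    if raw < model.lambda_floor:
        if raw <= 0:
            logger.warning(
                "calibration predicts lambda=%.4g <= 0 at (L_RNA=%d, L_DNA=%d); "
                "clamping to floor %.3g", raw, L_RNA, L_DNA, model.lambda_floor)
        return model.lambda_floor
    return raw


def triplex_pvalue(n_tpx: int, lam: float) -> float:
    """Exact Poisson upper tail P(X >= n_tpx | X ~ Pois(lam)); 1 for n_tpx=0."""
    if lam <= 0:
        raise ValueError("lambda must be > 0 (clamp before scoring)")
    if n_tpx < 0:
        raise ValueError("n_tpx must be >= 0")
    if n_tpx == 0:
        return 1.0
    return float(stats.poisson.sf(n_tpx - 1, lam))


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, m*p) for a family of m tests.

    p = 0.0 is accepted: exact Poisson tails underflow to zero for very
    large observed counts.
    """
    if not (0 <= p <= 1):
        raise ValueError("p must be in [0, 1]")
    if m < 1:
        raise ValueError("family size m must be >= 1")
    return min(1.0, m * p)
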